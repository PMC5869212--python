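"""End-to-end orchestration: images + field + acoustics -> fitted models.

``run_pipeline`` consumes a data bundle directory (the formats written
by :func:`greenmig.synthetic_data.make_fixture_bundle`, which are also
the real-data loader schemas), computes the per-site complexity and
vegetation descriptors and the acoustic responses, screens and filters
the candidate predictors, and runs stepwise-AIC model selection for
each configured response.  All stage outputs are written as CSVs so
stages are independently inspectable, plus a JSON run manifest.
"""

from __future__ import annotations

import json
import platform
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .acoustic_response import load_species_config, site_summaries
from .field_vegetation import descriptors_from_tables
from .image_complexity import compute_site_migs
from .stats_pipeline import (
    FitResult,
    fit_activity_model,
    fit_richness_model,
    log_activity,
    pearson_screen,
    standardize_predictors,
    stepwise_aic,
    vif_filter,
)

__all__ = ["PipelineConfig", "run_pipeline"]

#: post-collinearity clutter heights offered as candidate predictors
CANDIDATE_CLUTTER = ("clutter_0.5-1", "clutter_2-3", "clutter_5-7", "clutter_>15")

DEFAULT_RESPONSES = (
    "activity_total",
    "activity_edge",
    "activity_open",
    "activity_noctula",
    "activity_pygmaeus",
    "richness_total",
    "richness_edge",
    "richness_open",
)


@dataclass(frozen=True)
class PipelineConfig:
    data_dir: str | Path
    out_dir: str | Path
    m_bins: int = 256
    pearson_threshold: float = 0.5
    vif_threshold: float = 2.0
    overdispersion_threshold: float = 1.5
    mig_mode: str = "separate"  # "separate" (sides + top) or "all" (single index)
    responses: tuple[str, ...] = DEFAULT_RESPONSES
    activity_method: str = "nightly_total_median"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        """Load a run configuration from a YAML file."""
        import yaml

        raw = yaml.safe_load(Path(path).read_text())
        if not isinstance(raw, dict):
            raise ValueError(f"{path}: expected a mapping of config keys")
        unknown = set(raw) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"{path}: unknown config keys {sorted(unknown)}")
        if "responses" in raw:
            raw["responses"] = tuple(raw["responses"])
        return cls(**raw)


def _require(path: Path) -> Path:
    if not path.exists():
        raise FileNotFoundError(f"required input {path} is missing")
    return path


def _read_table(path: Path, columns: set[str]) -> pd.DataFrame:
    df = pd.read_csv(_require(path))
    missing = columns - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    return df


def assemble_design(
    migs: pd.DataFrame,
    descriptors: pd.DataFrame,
    sites: pd.DataFrame,
    mig_mode: str = "separate",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Merge stage tables into the candidate predictor matrix.

    Returns ``(X, meta)`` with one row per site: continuous candidates
    (clutter heights, ground cover, vertical heterogeneity, tree
    counts, DBH, green-space size-class index, MIG per ``mig_mode``)
    and the meta columns (site_id, green_space_type).  Sites with no
    large trees carry mean_dbh = 0.
    """
    df = migs.merge(descriptors, on="site_id").merge(
        sites[["site_id", "green_space_type", "size_class"]], on="site_id"
    )
    if len(df) != len(migs):
        raise ValueError("site_id mismatch between image, vegetation and design tables")
    mig_cols = ["mig_all"] if mig_mode == "all" else ["mig_sides", "mig_top"]
    cols = (
        list(CANDIDATE_CLUTTER)
        + ["ground_cover", "vertical_heterogeneity", "tree_density", "mean_dbh", "size_class"]
        + mig_cols
    )
    X = df[cols].copy()
    X["mean_dbh"] = X["mean_dbh"].fillna(0.0)
    if X.isna().any().any():
        bad = X.columns[X.isna().any()].tolist()
        raise ValueError(f"missing values after assembly in columns {bad}")
    return X, df[["site_id", "green_space_type"]]


def _fit_table(fit: FitResult, response: str) -> pd.DataFrame:
    rows = []
    for term in fit.params.index:
        rows.append(
            {
                "response": response,
                "term": term,
                "estimate": fit.params[term],
                "se": fit.bse[term],
                "t_value": fit.tvalues[term],
                "p_value": fit.pvalues[term],
            }
        )
    out = pd.DataFrame(rows)
    out["family"] = fit.family
    out["aic"] = fit.aic
    out["pseudo_r2"] = fit.pseudo_r2
    out["dispersion"] = np.nan if fit.dispersion is None else fit.dispersion
    out["random_intercept_variance"] = (
        np.nan if fit.random_intercept_variance is None else fit.random_intercept_variance
    )
    return out


def run_pipeline(cfg: PipelineConfig) -> dict[str, FitResult]:
    """Run every stage and write the report bundle; returns the fits."""
    data = Path(cfg.data_dir)
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    migs = compute_site_migs(_require(data / "manifest.csv"), m=cfg.m_bins)
    touches = _read_table(data / "touches.csv", {"site_id", "position_id", "height_class", "touch"})
    readings = _read_table(
        data / "readings.csv",
        {"site_id", "position_id", "ground_cover_pct", "canopy_cover_pct", "vegetation_height_m"},
    )
    trees = _read_table(data / "trees.csv", {"site_id", "dbh_m"})
    surveys = _read_table(
        data / "surveys.csv", {"site_id", "night_index", "species_label", "sequence_length_s"}
    )
    sites = _read_table(data / "sites.csv", {"site_id", "green_space_type", "size_class"})

    descriptors = descriptors_from_tables(touches, readings, trees)
    responses = site_summaries(surveys, load_species_config(), method=cfg.activity_method)
    # silent sites appear in the design but not in the survey records
    responses = (
        sites[["site_id"]].merge(responses, on="site_id", how="left").fillna(0.0)
    )

    migs.to_csv(out / "mig.csv", index=False)
    descriptors.to_csv(out / "descriptors.csv", index=False)
    responses.to_csv(out / "responses.csv", index=False)

    X, meta = assemble_design(migs, descriptors, sites, mig_mode=cfg.mig_mode)
    screen = pearson_screen(X, threshold=cfg.pearson_threshold)
    screen.corr.to_csv(out / "correlations.csv")
    # Collinearity filtering runs over the field-based descriptors; the
    # image-complexity indices are the focal predictors and are added to
    # the candidate set afterwards (they stand in for the collinear
    # canopy descriptors rather than competing with the filter).
    mig_cols = [c for c in X.columns if c.startswith("mig_")]
    kept_fields, trace = vif_filter(X.drop(columns=mig_cols), threshold=cfg.vif_threshold)
    kept = sorted(kept_fields) + sorted(mig_cols)
    Xz = standardize_predictors(X[kept])
    groups = meta["green_space_type"].to_numpy()

    fits: dict[str, FitResult] = {}
    tables, logs = [], []
    for response in cfg.responses:
        if response not in responses.columns:
            raise ValueError(f"unknown response {response!r}")
        y_raw = responses[response].to_numpy(float)
        if response.startswith("activity"):
            y = log_activity(y_raw)
            fitter = lambda terms: fit_activity_model(y, Xz, groups, terms)  # noqa: E731
        else:
            y = y_raw
            fitter = lambda terms: fit_richness_model(  # noqa: E731
                y, Xz, terms, overdispersion_threshold=cfg.overdispersion_threshold
            )
        fit = stepwise_aic(kept, fitter)
        fits[response] = fit
        tables.append(_fit_table(fit, response))
        logs.append({"response": response, "path": list(fit.selection_path)})

    pd.concat(tables, ignore_index=True).to_csv(out / "coefficients.csv", index=False)
    manifest = {
        "greenmig_version": __version__,
        "python": platform.python_version(),
        "numpy": np.__version__,
        "pandas": pd.__version__,
        "config": {k: str(v) for k, v in cfg.__dict__.items()},
        "n_sites": int(len(meta)),
        "vif_kept": kept,
        "vif_trace": [{k: (v if isinstance(v, str) else float(v)) for k, v in t.items()} for t in trace],
        "pearson_flagged": [[a, b, float(r)] for a, b, r in screen.flagged],
        "selection_logs": logs,
    }
    (out / "run_manifest.json").write_text(json.dumps(manifest, indent=2))
    return fits
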