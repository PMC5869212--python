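"""Field-based vegetation descriptors from the cover-board protocol.

A sampling plot (20-m radius) is surveyed at 17 positions: the centre
plus four positions at 5-m intervals along each cardinal direction.  At
each position the presence/absence of foliage touching a vertical pole
is recorded in 10 height classes; cover and height are estimated per
position, and all trees in the plot are measured (DBH in metres).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "N_POSITIONS",
    "HEIGHT_CLASSES",
    "VegetationProfile",
    "PlotDescriptors",
    "clutter_by_height",
    "vertical_heterogeneity",
    "summarize_plot",
    "descriptors_from_tables",
]

#: centre + 4 positions x 4 cardinal directions
N_POSITIONS = 17

#: ordered foliage height classes (metres above ground)
HEIGHT_CLASSES = (
    "0-0.5",
    "0.5-1",
    "1-1.5",
    "1.5-2",
    "2-3",
    "3-5",
    "5-7",
    "7-10",
    "10-15",
    ">15",
)

#: plot area in m^2 (20-m radius circle), for per-hectare conversion
PLOT_AREA_M2 = 400.0 * np.pi

DBH_TREE_THRESHOLD_M = 0.16  # counted as a tree if DBH strictly above
DBH_LARGE_TREE_THRESHOLD_M = 0.30  # "large tree" if DBH strictly above


@dataclass(frozen=True)
class VegetationProfile:
    """Presence/absence foliage-touch matrix: 17 positions x 10 height classes."""

    touches: np.ndarray

    def __post_init__(self) -> None:
        t = np.asarray(self.touches)
        if t.shape != (N_POSITIONS, len(HEIGHT_CLASSES)):
            raise ValueError(
                f"touch matrix must be {N_POSITIONS}x{len(HEIGHT_CLASSES)}, "
                f"got {t.shape}"
            )
        if not np.isin(t, (0, 1)).all():
            raise ValueError("touches must be 0/1 presence-absence")


def clutter_by_height(profile: VegetationProfile) -> np.ndarray:
    """Proportion of the 17 positions with foliage, per height class.

    The per-class average of touches is the vegetation-clutter proxy for
    that height.  Returns a length-10 array in [0, 1].
    """
    return np.asarray(profile.touches, dtype=float).mean(axis=0)


def vertical_heterogeneity(profile: VegetationProfile) -> float:
    """Shannon diversity H (nats) of foliage touches across height classes.

    Touch counts per class play the role of individuals per species:
    H = -sum_c p_c ln p_c with p_c = touches_c / total touches.  An
    all-zero profile (no vegetation) has no heterogeneity; H is defined
    as 0 with a warning.
    """
    counts = np.asarray(profile.touches).sum(axis=0).astype(float)
    total = counts.sum()
    if total == 0:
        warnings.warn("all-zero vegetation profile; vertical heterogeneity set to 0")
        return 0.0
    p = counts[counts > 0] / total
    return float(-np.sum(p * np.log(p)))


@dataclass(frozen=True)
class PlotDescriptors:
    clutter: np.ndarray  # per height class, proportion in [0, 1]
    vertical_heterogeneity: float  # Shannon H, nats
    ground_cover: float  # mean % over positions
    canopy_cover: float  # mean % over positions
    vegetation_height: float  # mean m over positions
    tree_density: int  # trees with DBH > 0.16 m in the plot
    n_large_trees: int  # trees with DBH > 0.30 m
    mean_dbh: float  # mean DBH (m) of large trees; nan if none

    @property
    def tree_density_per_ha(self) -> float:
        return self.tree_density * 10_000.0 / PLOT_AREA_M2


def summarize_plot(
    profile: VegetationProfile,
    ground_cover_pct: np.ndarray,
    canopy_cover_pct: np.ndarray,
    vegetation_height_m: np.ndarray,
    dbh_m: np.ndarray | list[float],
) -> PlotDescriptors:
    """Derive the per-plot descriptor set from raw field records.

    Cover and height inputs are the 17 per-position estimates; ``dbh_m``
    lists every measured tree in the plot.  Thresholds are strict:
    DBH > 0.16 m counts as a tree, DBH > 0.30 m as a large tree;
    mean_dbh averages large trees only.
    """
    for name, arr in (
        ("ground_cover_pct", ground_cover_pct),
        ("canopy_cover_pct", canopy_cover_pct),
        ("vegetation_height_m", vegetation_height_m),
    ):
        if len(np.atleast_1d(arr)) != N_POSITIONS:
            raise ValueError(f"{name} must have {N_POSITIONS} position records")
    dbh = np.asarray(dbh_m, dtype=float)
    if dbh.size and (dbh < 0).any():
        raise ValueError("negative DBH value in tree list")
    large = dbh[dbh > DBH_LARGE_TREE_THRESHOLD_M]
    return PlotDescriptors(
        clutter=clutter_by_height(profile),
        vertical_heterogeneity=vertical_heterogeneity(profile),
        ground_cover=float(np.mean(ground_cover_pct)),
        canopy_cover=float(np.mean(canopy_cover_pct)),
        vegetation_height=float(np.mean(vegetation_height_m)),
        tree_density=int((dbh > DBH_TREE_THRESHOLD_M).sum()),
        n_large_trees=int(large.size),
        mean_dbh=float(large.mean()) if large.size else float("nan"),
    )


def descriptors_from_tables(
    touches: pd.DataFrame, readings: pd.DataFrame, trees: pd.DataFrame
) -> pd.DataFrame:
    """One descriptor row per site from long-format field tables.

    ``touches``: site_id, position_id (1-17), height_class, touch (0/1);
    ``readings``: site_id, position_id, ground_cover_pct,
    canopy_cover_pct, vegetation_height_m; ``trees``: site_id, dbh_m.
    """
    class_index = {c: i for i, c in enumerate(HEIGHT_CLASSES)}
    rows = []
    for site_id, grp in touches.groupby("site_id", sort=True):
        mat = np.zeros((N_POSITIONS, len(HEIGHT_CLASSES)), dtype=int)
        for _, rec in grp.iterrows():
            hc = str(rec["height_class"])
            if hc not in class_index:
                raise ValueError(f"site {site_id}: unknown height class {hc!r}")
            pos = int(rec["position_id"]) - 1
            if not 0 <= pos < N_POSITIONS:
                raise ValueError(f"site {site_id}: position_id out of range")
            mat[pos, class_index[hc]] = int(rec["touch"])
        rd = readings[readings["site_id"] == site_id].sort_values("position_id")
        tr = trees[trees["site_id"] == site_id]
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # silent sites are expected in bulk runs
            d = summarize_plot(
                VegetationProfile(mat),
                rd["ground_cover_pct"].to_numpy(),
                rd["canopy_cover_pct"].to_numpy(),
                rd["vegetation_height_m"].to_numpy(),
                tr["dbh_m"].to_numpy(),
            )
        rows.append(descriptor_row(site_id, d))
    return pd.DataFrame(rows)


def descriptor_row(site_id, d: PlotDescriptors) -> dict:
    """Flatten a PlotDescriptors into one table row (clutter per class)."""
    row = {"site_id": site_id}
    for i, c in enumerate(HEIGHT_CLASSES):
        row[f"clutter_{c}"] = d.clutter[i]
    row.update(
        vertical_heterogeneity=d.vertical_heterogeneity,
        ground_cover=d.ground_cover,
        canopy_cover=d.canopy_cover,
        vegetation_height=d.vegetation_height,
        tree_density=d.tree_density,
        n_large_trees=d.n_large_trees,
        mean_dbh=d.mean_dbh,
    )
    return row
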