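"""Mean information gain (MIG): spatial complexity of digital images.

MIG quantifies the structural complexity of a scene from the spatial
arrangement of pixel intensities.  The image's HSV value channel is
quantized into ``M`` bins and two Shannon entropies are estimated from
plug-in (relative-frequency) probabilities:

* the *marginal* entropy of single-pixel intensities, ignoring location
  (aspatial heterogeneity), and
* the *joint* entropy of 2x2-pixel neighbourhood configurations
  (spatial heterogeneity).

The index is the normalized difference::

    MIG = (H_joint - H_marginal) / ((k - 1) * ln M),   k = 4

which is 0 for a perfectly uniform image (a single colour), 0 for any
deterministic periodic pattern such as a checkerboard, and tends to 1
for spatially random (iid) images as the image grows.  The value is
base-invariant: computing both entropies and the denominator in any
common logarithm base gives the identical number.

No clamping is applied: on very small images the plug-in estimates can
push MIG slightly outside [0, 1]; values are reported as computed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import imageio.v3 as iio
import numpy as np
import pandas as pd

__all__ = [
    "SIDE_VIEWS",
    "ALL_VIEWS",
    "QuantizedField",
    "NeighborhoodDistribution",
    "MIGResult",
    "SiteMIG",
    "value_channel_from_rgb",
    "quantize_intensities",
    "neighborhood_distribution",
    "entropy_components",
    "mean_information_gain",
    "mig_of_image",
    "site_mig_summary",
    "compute_site_migs",
]

SIDE_VIEWS = ("N", "E", "S", "W")
ALL_VIEWS = SIDE_VIEWS + ("TOP",)

#: Neighbourhood size: 2x2 window, four pixels.
NEIGHBORHOOD_K = 4


@dataclass(frozen=True)
class QuantizedField:
    """Integer-binned intensity raster; substrate for entropy estimation."""

    values: np.ndarray  # 2-D array of bin indices in {0, ..., m - 1}
    m: int  # number of frequency bins
    view: str | None = None  # provenance: N/E/S/W side or TOP

    def __post_init__(self) -> None:
        v = np.asarray(self.values)
        if v.ndim != 2:
            raise ValueError(f"quantized field must be 2-D, got shape {v.shape}")
        if self.m < 1:
            raise ValueError(f"bin count M must be >= 1, got {self.m}")
        if v.size and (v.min() < 0 or v.max() >= self.m):
            raise ValueError("bin indices must lie in [0, M)")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape  # type: ignore[return-value]


@dataclass(frozen=True)
class NeighborhoodDistribution:
    """Empirical distributions of pixel bins and 2x2 configurations.

    ``config_counts`` maps each observed configuration chi (a tuple of the
    four bin values, row-major) to its count over all overlapping 2x2
    windows fully inside the image; ``marginal_counts`` maps each bin
    gamma to its pixel count.
    """

    k: int
    config_counts: Mapping[tuple[int, int, int, int], int]
    marginal_counts: Mapping[int, int]
    n_windows: int
    n_pixels: int


def value_channel_from_rgb(img: np.ndarray) -> np.ndarray:
    """HSV value channel of an 8-bit RGB image: V = max(R, G, B) / 255.

    Accepts an ``(h, w, 3)`` uint8-like array (an extra alpha channel is
    ignored); returns float64 intensities in [0, 1].
    """
    arr = np.asarray(img)
    if arr.size == 0:
        raise ValueError("empty image")
    if arr.ndim == 2:  # already single-band; treat as intensity
        return arr.astype(np.float64) / 255.0
    if arr.ndim != 3 or arr.shape[2] < 3:
        raise ValueError(f"expected an RGB image, got shape {arr.shape}")
    return arr[:, :, :3].max(axis=2).astype(np.float64) / 255.0


def quantize_intensities(
    intensities: np.ndarray, m: int = 256, view: str | None = None
) -> QuantizedField:
    """Bin intensities in [0, 1] into ``m`` equal-width bins.

    gamma = min(floor(v * m), m - 1); the top edge v = 1 is clamped into
    the last bin.  The default m = 256 matches the native resolution of
    8-bit channels.
    """
    if m < 1:
        raise ValueError(f"bin count M must be >= 1, got {m}")
    v = np.asarray(intensities, dtype=np.float64)
    if v.size == 0:
        raise ValueError("empty intensity field")
    bins = np.minimum(np.floor(v * m).astype(np.int64), m - 1)
    return QuantizedField(values=bins, m=m, view=view)


def _require_window(qf: QuantizedField) -> np.ndarray:
    g = np.asarray(qf.values, dtype=np.int64)
    if g.shape[0] < 2 or g.shape[1] < 2:
        raise ValueError(
            f"image must be at least 2x2 for joint entropy, got {g.shape}"
        )
    return g


def _config_codes(g: np.ndarray, m: int) -> np.ndarray:
    # Pack each sliding 2x2 window into one integer, base-M, row-major.
    # m <= 65536 keeps the code within uint64.
    m = np.uint64(m)
    a = g[:-1, :-1].astype(np.uint64)
    b = g[:-1, 1:].astype(np.uint64)
    c = g[1:, :-1].astype(np.uint64)
    d = g[1:, 1:].astype(np.uint64)
    return ((a * m + b) * m + c) * m + d


def neighborhood_distribution(qf: QuantizedField) -> NeighborhoodDistribution:
    """Count pixel bins and overlapping 2x2 configurations.

    Only windows fully inside the image are counted (no padding or
    wraparound), so n_windows = (h - 1) * (w - 1).
    """
    g = _require_window(qf)
    h, w = g.shape
    codes = _config_codes(g, qf.m)
    uc, cc = np.unique(codes, return_counts=True)
    m = np.uint64(qf.m)
    configs: dict[tuple[int, int, int, int], int] = {}
    for code, n in zip(uc, cc):
        d = int(code % m)
        rest = code // m
        c = int(rest % m)
        rest //= m
        b = int(rest % m)
        a = int(rest // m)
        configs[(a, b, c, d)] = int(n)
    ug, cg = np.unique(g, return_counts=True)
    return NeighborhoodDistribution(
        k=NEIGHBORHOOD_K,
        config_counts=configs,
        marginal_counts={int(x): int(n) for x, n in zip(ug, cg)},
        n_windows=(h - 1) * (w - 1),
        n_pixels=h * w,
    )


def _plugin_entropy(counts: np.ndarray) -> float:
    # Shannon entropy (nats) of empirical relative frequencies; 0 ln 0 = 0.
    counts = counts[counts > 0]
    p = counts / counts.sum()
    return float(-np.sum(p * np.log(p)))


def entropy_components(qf: QuantizedField) -> tuple[float, float]:
    """Marginal and joint plug-in entropies (nats) of a quantized field.

    Returns ``(h_marginal, h_joint)`` where the marginal entropy is over
    all pixel bins and the joint entropy is over all overlapping 2x2
    windows fully inside the image.
    """
    g = _require_window(qf)
    _, marg_counts = np.unique(g, return_counts=True)
    _, joint_counts = np.unique(_config_codes(g, qf.m), return_counts=True)
    return _plugin_entropy(marg_counts), _plugin_entropy(joint_counts)


@dataclass(frozen=True)
class MIGResult:
    h_marginal: float  # nats, in [0, ln M]
    h_joint: float  # nats, in [0, k ln M]
    mig: float  # dimensionless; ~[0, 1] for large images
    m: int
    k: int = NEIGHBORHOOD_K


def mean_information_gain(qf: QuantizedField) -> MIGResult:
    """MIG = (H_joint - H_marginal) / ((k - 1) ln M) for a quantized field.

    Requires M >= 2 (M is the configured bin count, not the number of
    observed distinct values); M = 1 makes the denominator zero.
    """
    if qf.m < 2:
        raise ValueError("MIG requires M >= 2 (denominator ln(M^k / M) is zero for M = 1)")
    h_marg, h_joint = entropy_components(qf)
    denom = (NEIGHBORHOOD_K - 1) * np.log(qf.m)
    return MIGResult(h_marginal=h_marg, h_joint=h_joint, mig=float((h_joint - h_marg) / denom), m=qf.m)


def mig_of_image(img: np.ndarray, m: int = 256, view: str | None = None) -> MIGResult:
    """MIG of an RGB (or single-band) image array via its value channel."""
    return mean_information_gain(quantize_intensities(value_channel_from_rgb(img), m, view=view))


@dataclass(frozen=True)
class SiteMIG:
    """Per-site complexity summary over the five views.

    mig_all is the mean over all five images, mig_sides the mean over
    the four cardinal side views, mig_top the single upward view; hence
    mig_all = (4 * mig_sides + mig_top) / 5.
    """

    mig_all: float
    mig_sides: float
    mig_top: float
    m: int
    per_view: dict[str, float] = field(default_factory=dict)


def site_mig_summary(views: Mapping[str, np.ndarray], m: int = 256) -> SiteMIG:
    """Aggregate MIG over a site's five photographs.

    ``views`` maps view labels (N, E, S, W, TOP) to RGB image arrays;
    exactly the five labels must be present.
    """
    missing = [v for v in ALL_VIEWS if v not in views]
    extra = [v for v in views if v not in ALL_VIEWS]
    if missing or extra:
        raise ValueError(
            f"site must have exactly views {list(ALL_VIEWS)}; "
            f"missing={missing} unexpected={extra}"
        )
    per_view = {v: mig_of_image(views[v], m, view=v).mig for v in ALL_VIEWS}
    sides = float(np.mean([per_view[v] for v in SIDE_VIEWS]))
    top = per_view["TOP"]
    return SiteMIG(
        mig_all=float((4.0 * sides + top) / 5.0),
        mig_sides=sides,
        mig_top=top,
        m=m,
        per_view=per_view,
    )


def compute_site_migs(manifest: pd.DataFrame | str | Path, m: int = 256) -> pd.DataFrame:
    """Per-site MIG table from a manifest of image paths.

    The manifest (DataFrame or CSV path) has columns ``site_id``,
    ``view`` (N/E/S/W/TOP) and ``path``; image paths are resolved
    relative to the CSV's directory when a path is given.  Returns one
    row per site: site_id, mig_all, mig_sides, mig_top, M, k.
    """
    base = Path(".")
    if not isinstance(manifest, pd.DataFrame):
        base = Path(manifest).parent
        manifest = pd.read_csv(manifest)
    required = {"site_id", "view", "path"}
    if not required.issubset(manifest.columns):
        raise ValueError(f"manifest must have columns {sorted(required)}")
    rows = []
    for site_id, grp in manifest.groupby("site_id", sort=True):
        views: dict[str, np.ndarray] = {}
        for _, rec in grp.iterrows():
            p = Path(rec["path"])
            if not p.is_absolute():
                p = base / p
            if not p.exists():
                raise FileNotFoundError(
                    f"site {site_id}, view {rec['view']}: missing image {p}"
                )
            views[str(rec["view"])] = iio.imread(p)
        s = site_mig_summary(views, m=m)
        rows.append(
            {
                "site_id": site_id,
                "mig_all": s.mig_all,
                "mig_sides": s.mig_sides,
                "mig_top": s.mig_top,
                "M": m,
                "k": NEIGHBORHOOD_K,
            }
        )
    return pd.DataFrame(rows)
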