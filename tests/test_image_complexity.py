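"""Mean-information-gain math against brute-force oracles and analytic limits."""

import math
from collections import Counter

import numpy as np
import pytest

from conftest import gray_image
from greenmig.image_complexity import (
    ALL_VIEWS,
    QuantizedField,
    compute_site_migs,
    entropy_components,
    mean_information_gain,
    mig_of_image,
    neighborhood_distribution,
    quantize_intensities,
    site_mig_summary,
    value_channel_from_rgb,
)


def brute_force_entropies(grid: np.ndarray) -> tuple[float, float]:
    """Direct enumeration of pixels and sliding 2x2 windows."""
    h, w = grid.shape
    marg = Counter(int(v) for v in grid.ravel())
    joint = Counter(
        (int(grid[i, j]), int(grid[i, j + 1]), int(grid[i + 1, j]), int(grid[i + 1, j + 1]))
        for i in range(h - 1)
        for j in range(w - 1)
    )

    def ent(counter):
        n = sum(counter.values())
        return -sum((c / n) * math.log(c / n) for c in counter.values())

    return ent(marg), ent(joint)


@pytest.mark.parametrize(
    "pixel,expected",
    [((255, 255, 255), 1.0), ((0, 0, 0), 0.0), ((255, 0, 0), 1.0), ((255, 255, 0), 1.0)],
)
def test_value_channel_is_max_of_rgb(pixel, expected):
    img = np.tile(np.array(pixel, dtype=np.uint8), (3, 3, 1))
    assert value_channel_from_rgb(img)[1, 1] == expected


def test_value_channel_rejects_empty():
    with pytest.raises(ValueError):
        value_channel_from_rgb(np.empty((0, 0, 3), dtype=np.uint8))


@pytest.mark.parametrize(
    "v,m,expected", [(0.0, 2, 0), (1.0, 2, 1), (0.5, 256, 128), (0.999, 4, 3)]
)
def test_quantize_bin_assignment(v, m, expected):
    qf = quantize_intensities(np.full((2, 2), v), m)
    assert qf.values[0, 0] == expected


def test_quantize_rejects_invalid_bin_count():
    with pytest.raises(ValueError):
        quantize_intensities(np.zeros((2, 2)), 0)


def test_entropy_of_constant_image_is_zero():
    qf = QuantizedField(np.full((8, 8), 3), m=8)
    assert entropy_components(qf) == (0.0, 0.0)


def test_entropy_of_single_window():
    # one 2x2 window with probability 1: joint entropy 0, marginal ln 2
    qf = QuantizedField(np.array([[0, 1], [1, 0]]), m=2)
    h_marg, h_joint = entropy_components(qf)
    assert h_marg == pytest.approx(math.log(2), abs=1e-12)
    assert h_joint == 0.0


def test_entropy_requires_two_by_two():
    with pytest.raises(ValueError):
        entropy_components(QuantizedField(np.zeros((1, 5), dtype=int), m=2))


@pytest.mark.parametrize("m", [2, 3])
def test_entropy_matches_brute_force_enumeration(m, rng):
    """Vectorized entropies equal direct enumeration on >=100 small rasters."""
    for _ in range(120):
        h, w = rng.integers(2, 7, size=2)
        grid = rng.integers(0, m, size=(h, w))
        qf = QuantizedField(grid, m=m)
        expected = brute_force_entropies(grid)
        got = entropy_components(qf)
        assert got[0] == pytest.approx(expected[0], abs=1e-12)
        assert got[1] == pytest.approx(expected[1], abs=1e-12)


def test_neighborhood_distribution_totals(rng):
    grid = rng.integers(0, 4, size=(9, 7))
    nd = neighborhood_distribution(QuantizedField(grid, m=4))
    assert sum(nd.config_counts.values()) == nd.n_windows == 8 * 6
    assert sum(nd.marginal_counts.values()) == nd.n_pixels == 63
    assert len(nd.config_counts) <= min(nd.n_windows, 4**4)
    # counts agree with the brute-force window enumeration
    marg, joint = brute_force_entropies(grid)
    got_m, got_j = entropy_components(QuantizedField(grid, m=4))
    assert (got_m, got_j) == pytest.approx((marg, joint), abs=1e-12)


@pytest.mark.parametrize("m", [2, 16, 256])
def test_constant_image_has_zero_mig(m):
    img = gray_image(np.full((32, 32), 0.5))
    assert mig_of_image(img, m=m).mig == 0.0


@pytest.mark.parametrize("m", [2, 4])
def test_iid_uniform_image_mig_approaches_one(m, rng):
    """Spatially random patterns have MIG -> 1 (deviation < 0.01 at 512x512)."""
    img = gray_image(rng.random((512, 512)))
    res = mig_of_image(img, m=m)
    assert abs(res.mig - 1.0) < 0.01
    assert res.h_marginal == pytest.approx(math.log(m), abs=0.01)
    assert res.h_joint == pytest.approx(4 * math.log(m), rel=0.01)


def test_checkerboard_is_perfectly_ordered():
    # odd window count splits the two configurations 1985/1984, so the
    # joint entropy sits a hair under ln 2 (values are not clamped)
    grid = (np.indices((64, 64)).sum(axis=0) % 2).astype(float)
    res = mig_of_image(gray_image(grid), m=2)
    assert res.mig == pytest.approx(0.0, abs=1e-7)
    assert res.h_marginal == pytest.approx(math.log(2), abs=1e-12)


def test_mig_requires_two_bins():
    with pytest.raises(ValueError):
        mean_information_gain(QuantizedField(np.zeros((4, 4), dtype=int), m=1))


def test_mig_is_base_invariant(rng):
    """Entropies and denominator in base 2 give the identical index."""
    grid = rng.integers(0, 8, size=(40, 40))
    qf = QuantizedField(grid, m=8)
    h_marg, h_joint = entropy_components(qf)
    mig_nats = mean_information_gain(qf).mig
    mig_base2 = (h_joint / math.log(2) - h_marg / math.log(2)) / (3 * math.log2(8))
    assert mig_nats == pytest.approx(mig_base2, abs=1e-12)


def test_mig_monotone_in_noise_fraction():
    """Mixing a constant field with iid noise: mean MIG non-decreasing in q."""
    means = []
    for q in (0.0, 0.25, 0.5, 0.75, 1.0):
        vals = []
        for seed in range(20):
            r = np.random.default_rng((seed, int(q * 100)))
            field = np.full((64, 64), 0.4)
            mask = r.random((64, 64)) < q
            img = gray_image(np.where(mask, r.random((64, 64)), field))
            vals.append(mig_of_image(img, m=4).mig)
        means.append(np.mean(vals))
    assert all(b >= a for a, b in zip(means, means[1:]))


def test_mig_entropy_bounds(rng):
    for _ in range(20):
        m = int(rng.integers(2, 9))
        grid = rng.integers(0, m, size=rng.integers(2, 12, size=2))
        h_marg, h_joint = entropy_components(QuantizedField(grid, m=m))
        n_windows = (grid.shape[0] - 1) * (grid.shape[1] - 1)
        assert 0.0 <= h_marg <= math.log(m) + 1e-12
        assert 0.0 <= h_joint <= min(4 * math.log(m), math.log(n_windows)) + 1e-12


def test_mig_deterministic_for_identical_bytes(rng):
    img = gray_image(rng.random((32, 32)))
    assert mig_of_image(img, m=16) == mig_of_image(img.copy(), m=16)


def test_site_summary_aggregation(rng):
    views = {v: gray_image(rng.random((24, 24))) for v in ALL_VIEWS}
    s = site_mig_summary(views, m=4)
    per = [mig_of_image(views[v], m=4).mig for v in ("N", "E", "S", "W")]
    assert s.mig_sides == pytest.approx(np.mean(per), abs=1e-12)
    assert s.mig_top == pytest.approx(mig_of_image(views["TOP"], m=4).mig, abs=1e-12)
    assert s.mig_all == pytest.approx((4 * s.mig_sides + s.mig_top) / 5, abs=1e-12)


def test_site_summary_identical_views(rng):
    img = gray_image(rng.random((24, 24)))
    s = site_mig_summary({v: img for v in ALL_VIEWS}, m=4)
    assert s.mig_all == s.mig_sides == s.mig_top


def test_site_summary_names_missing_view(rng):
    views = {v: gray_image(rng.random((8, 8))) for v in ("N", "E", "S", "TOP")}
    with pytest.raises(ValueError, match="W"):
        site_mig_summary(views, m=4)


def test_manifest_missing_image_is_reported(tmp_path):
    import pandas as pd

    manifest = pd.DataFrame(
        {"site_id": ["A"] * 5, "view": list(ALL_VIEWS), "path": ["nope.png"] * 5}
    )
    with pytest.raises(FileNotFoundError, match="site A"):
        compute_site_migs(manifest)
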