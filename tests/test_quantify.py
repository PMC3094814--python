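"""SUR statistics, AR/RMSCOV/aSUR aggregates, curves and matched-noise logic."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import striatospect as ss
from striatospect.quantify import (BiasNoiseCurve, average_recovery,
                                   average_sur, bias_noise_curve,
                                   matched_noise_compare, percent_variation,
                                   rmscov, stats_frame, voxel_sur)


def _stats_table(rows):
    return pd.DataFrame(rows, columns=["v", "p", "r", "s", "sur_mean",
                                       "sur_sd", "n_voxels"])


# ------------------------------------------------------------- voxelwise SUR

def test_voxel_sur_definition(default_phantom, default_vois):
    values = np.full(default_phantom.grid.shape, 5.0)
    values[default_vois.left_striatum] = 15.0
    sur, bg = voxel_sur(values, default_vois)
    assert bg == pytest.approx(5.0)
    assert np.allclose(sur["left_striatum"], 2.0)
    assert np.allclose(sur["right_striatum"], 0.0)


def test_uniform_volume_gives_zero_sur_and_sd(default_phantom, default_vois):
    values = np.full(default_phantom.grid.shape, 7.0)
    stats = ss.voi_stats(values, default_vois, p=0, r="x", s=0.0)
    for st_ in stats:
        assert st_.sur_mean == 0.0 and st_.sur_sd == 0.0


def test_nonpositive_background_rejected(default_phantom, default_vois):
    with pytest.raises(ValueError):
        voxel_sur(np.zeros(default_phantom.grid.shape), default_vois)


def test_voi_stats_match_two_pass_oracle(default_phantom, default_vois, rng):
    values = rng.uniform(1.0, 10.0, default_phantom.grid.shape)
    stats = ss.voi_stats(values, default_vois, p=3, r="m", s=2.0)
    bg = values[default_vois.background].mean()
    for st_ in stats:
        mask = default_vois.masks()[st_.v]
        sur = (values[mask] - bg) / bg
        mean = sur.sum() / sur.size
        sd = np.sqrt(((sur - mean) ** 2).sum() / (sur.size - 1))
        assert st_.sur_mean == pytest.approx(mean, rel=1e-12)
        assert st_.sur_sd == pytest.approx(sd, rel=1e-12)
        assert st_.n_voxels == mask.sum()


# ----------------------------------------------------------- Eq aggregates

def test_average_recovery_examples():
    t = _stats_table([("L", 0, "r", 0.0, 1.5, 0.1, 30)])
    assert average_recovery(t, {("L", 0): 3.0}) == pytest.approx(50.0)
    t2 = _stats_table([("L", 0, "r", 0.0, 0.2, 0.0, 30),
                       ("R", 0, "r", 0.0, 0.4, 0.0, 30)])
    assert average_recovery(t2, {("L", 0): 1.0, ("R", 0): 1.0}) == pytest.approx(30.0)


def test_rmscov_examples():
    t = _stats_table([("L", 0, "r", 0.0, 2.0, 1.0, 30)])
    assert rmscov(t) == pytest.approx(50.0)
    t2 = _stats_table([("L", 0, "r", 0.0, 1.0, 0.3, 30),
                       ("R", 0, "r", 0.0, 1.0, 0.4, 30)])
    assert rmscov(t2) == pytest.approx(100 * np.sqrt(0.125))
    t3 = _stats_table([("L", 0, "r", 0.0, 2.0, 0.0, 30)])
    assert rmscov(t3) == 0.0


def test_average_sur_examples():
    t = _stats_table([("L", 0, "r", 0.0, 1.0, 0.0, 30),
                      ("R", 0, "r", 0.0, 3.0, 0.0, 30)])
    assert average_sur(t) == pytest.approx(2.0)


def test_missing_reference_rejected():
    t = _stats_table([("L", 0, "r", 0.0, 1.0, 0.0, 30)])
    with pytest.raises(ValueError, match="missing"):
        average_recovery(t, {("L", 1): 2.0})


def test_mixed_cells_rejected():
    t = _stats_table([("L", 0, "a", 0.0, 1.0, 0.0, 30),
                      ("L", 0, "b", 0.0, 1.0, 0.0, 30)])
    with pytest.raises(ValueError):
        average_sur(t)


@settings(max_examples=40, deadline=None, derandomize=True)
@given(st.lists(st.tuples(st.floats(0.1, 10.0), st.floats(0.0, 5.0),
                          st.floats(0.5, 20.0)),
                min_size=1, max_size=12))
def test_aggregates_agree_with_bruteforce(cells):
    """AR, RMSCOV and aSUR agree exactly with longhand loops over randomised
    statistics tables."""
    rows, refs = [], {}
    for i, (mean, sd, ref) in enumerate(cells):
        rows.append((f"v{i}", 0, "r", 0.0, mean, sd, 30))
        refs[(f"v{i}", 0)] = ref
    t = _stats_table(rows)
    n = len(cells)
    ar = 100.0 / n * sum(m / refs[(f"v{i}", 0)]
                         for i, (m, _, _) in enumerate(cells))
    rc = 100.0 * np.sqrt(sum((sd / m) ** 2 for m, sd, _ in cells) / n)
    asur = sum(m for m, _, _ in cells) / n
    assert average_recovery(t, refs) == pytest.approx(ar, rel=1e-12)
    assert rmscov(t) == pytest.approx(rc, rel=1e-12)
    assert average_sur(t) == pytest.approx(asur, rel=1e-12)


def test_asur_is_ar_times_mean_ref_when_refs_equal():
    t = _stats_table([("L", 0, "r", 0.0, 1.2, 0.1, 30),
                      ("R", 0, "r", 0.0, 2.2, 0.1, 30),
                      ("L", 1, "r", 0.0, 0.7, 0.1, 30),
                      ("R", 1, "r", 0.0, 1.9, 0.1, 30)])
    refs = {k: 4.0 for k in [("L", 0), ("R", 0), ("L", 1), ("R", 1)]}
    assert average_sur(t) == pytest.approx(
        average_recovery(t, refs) * 4.0 / 100.0, rel=1e-12)


# -------------------------------------------------------------------- curves

def _synthetic_curve_table(r, levels, bias_fn, cov_fn):
    rows = []
    for s in levels:
        for v, p in (("L", 0), ("R", 0)):
            rows.append((v, p, r, s, bias_fn(s), bias_fn(s) * cov_fn(s), 30))
    return _stats_table(rows)


def test_curve_has_one_point_per_level():
    levels = [0.0] + list(range(1, 17))
    t = _synthetic_curve_table("r", levels, lambda s: 2.0 - 0.05 * s,
                               lambda s: 0.5 / (1 + s))
    c = bias_noise_curve(t, refs={("L", 0): 4.0, ("R", 0): 4.0}, metric="AR")
    assert len(c.smoothing) == 17
    assert np.all(np.diff(c.smoothing) > 0)
    assert np.all(np.diff(c.noise) < 0)


def test_curve_requires_unsmoothed_anchor():
    t = _synthetic_curve_table("r", [1.0, 2.0], lambda s: 1.0, lambda s: 0.1)
    with pytest.raises(ValueError):
        bias_noise_curve(t, metric="aSUR")


def test_matched_noise_interpolation_example():
    """Two-point curves {(noise 60, AR 30), (70, 28)} queried at 65 -> 29."""
    ref = BiasNoiseCurve(r="ref", metric="AR", smoothing=[0.0, 1.0],
                         bias=[31.0, 30.0], noise=[80.0, 65.0], n_p=1, n_v=2)
    other = BiasNoiseCurve(r="other", metric="AR", smoothing=[0.0, 1.0],
                           bias=[30.0, 28.0], noise=[60.0, 70.0], n_p=1, n_v=2)
    summary, _ = matched_noise_compare([ref, other])
    assert summary.set_index("r").loc["ref", "ref_noise"] == 80.0
    row = summary.set_index("r").loc["other"]
    # ref noise 80 is outside other's range -> clamped and flagged
    assert bool(row["extrapolated"])
    summary2, _ = matched_noise_compare([other], reference="other")
    assert summary2.loc[0, "matched_bias"] == pytest.approx(30.0)
    b, _, extr = ss.quantify._interp_on_curve(other, 65.0)
    assert b == pytest.approx(29.0) and not extr


def test_identical_curves_get_identical_matched_bias():
    curves = [BiasNoiseCurve(r=f"m{i}", metric="AR", smoothing=[0.0, 1.0, 2.0],
                             bias=[30.0, 28.0, 25.0], noise=[70.0, 60.0, 50.0],
                             n_p=1, n_v=2) for i in range(3)]
    summary, _ = matched_noise_compare(curves)
    assert summary["matched_bias"].nunique() == 1


def test_dominated_curve_reports_lower_matched_bias():
    hi = BiasNoiseCurve(r="hi", metric="AR", smoothing=[0.0, 1.0, 2.0],
                        bias=[32.0, 30.0, 28.0], noise=[70.0, 60.0, 50.0],
                        n_p=1, n_v=2)
    lo = BiasNoiseCurve(r="lo", metric="AR", smoothing=[0.0, 1.0, 2.0],
                        bias=[28.0, 26.0, 24.0], noise=[70.0, 60.0, 50.0],
                        n_p=1, n_v=2)
    summary, _ = matched_noise_compare([hi, lo])
    s = summary.set_index("r")
    assert s.loc["lo", "matched_bias"] < s.loc["hi", "matched_bias"]


def test_empty_curve_set_rejected():
    with pytest.raises(ValueError):
        matched_noise_compare([])


# --------------------------------------------------------- percent variation

def test_percent_variation_of_printed_extremes():
    assert percent_variation([2.68, 2.76]) == pytest.approx(2.985, abs=0.001)


def test_percent_variation_degenerate_and_errors():
    assert percent_variation([1.7]) == 0.0
    with pytest.raises(ValueError):
        percent_variation([])
    with pytest.raises(ValueError):
        percent_variation([0.0, 1.0])
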