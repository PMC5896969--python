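import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from hipload.metrics import (
    ForceSeries,
    PfpWindow,
    bland_altman,
    correlate,
    default_stem_rotation,
    detect_pfp,
    mad_pfp,
    mae_components,
    mape_pfp,
    nonparam_tests,
    normalize_bw,
    pd_pfp,
    resample_cycle,
    rmse_components,
    to_orthoload_frame,
)

CYC = np.linspace(0.0, 100.0, 101)


def series(f, frame="OrthoLoad_femur", side="L", cycle=CYC):
    return ForceSeries(cycle=cycle, f=np.asarray(f, dtype=float), frame=frame, side=side)


def const_series(vec, **kw):
    return series(np.tile(vec, (101, 1)), **kw)


# ---------------------------------------------------------------------------
# normalization and resampling


@pytest.mark.parametrize(
    "force,mass,expected",
    [(882.9, 90.0, 100.0), (0.0, 50.0, 0.0), (1800.0, 61.2, 300.0)],
)
def test_normalize_bw(force, mass, expected):
    assert normalize_bw(force, mass) == pytest.approx(expected, abs=0.2)


def test_normalize_bw_rejects_bad_mass():
    with pytest.raises(ValueError):
        normalize_bw(100.0, 0.0)


def test_resample_identity_and_ramp():
    ramp = series(np.column_stack([np.linspace(0, 100, 101)] * 3))
    out = resample_cycle(ramp, 101)
    np.testing.assert_allclose(out.f, ramp.f, atol=1e-12)
    coarse = ForceSeries(
        cycle=np.array([0.0, 100.0]),
        f=np.array([[0.0, 0, 0], [100.0, 0, 0]]),
        frame="OrthoLoad_femur",
        side="L",
    )
    fine = resample_cycle(coarse, 101)
    assert fine.f[33, 0] == pytest.approx(33.0)
    const = resample_cycle(const_series([5.0, -1.0, 2.0]), 50)
    np.testing.assert_allclose(const.f, np.tile([5.0, -1.0, 2.0], (50, 1)))


# ---------------------------------------------------------------------------
# frame transform


def test_orthoload_identity_rotation_right_side_maps_components():
    s = const_series([1.0, 2.0, -3.0], frame="ISB_femur", side="R")
    out = to_orthoload_frame(s, rotation=np.eye(3))
    # x(ant) -> PA, y -> ML (right side: +y is medial), z -> IS; no sign flips
    np.testing.assert_allclose(out.f[0], [2.0, 1.0, -3.0])
    assert out.frame == "OrthoLoad_femur"


def test_orthoload_preserves_resultant():
    rng = np.random.default_rng(3)
    s = series(rng.normal(size=(101, 3)), frame="ISB_femur", side="L")
    out = to_orthoload_frame(s)
    np.testing.assert_allclose(out.resultant, s.resultant, atol=1e-9)


def test_orthoload_mirrors_left_to_right_convention():
    rng = np.random.default_rng(4)
    f_r = rng.normal(size=(101, 3))
    f_l = f_r * np.array([1.0, -1.0, 1.0])  # left series mirrored in ML
    out_r = to_orthoload_frame(series(f_r, frame="ISB_femur", side="R"))
    out_l = to_orthoload_frame(series(f_l, frame="ISB_femur", side="L"))
    np.testing.assert_allclose(out_l.f, out_r.f, atol=1e-9)


def test_orthoload_rejects_double_transform():
    s = const_series([1.0, 0, 0])
    with pytest.raises(ValueError):
        to_orthoload_frame(s)


def test_stem_rotation_is_orthonormal():
    for side in "LR":
        R = default_stem_rotation(side)
        np.testing.assert_allclose(R @ R.T, np.eye(3), atol=1e-12)


# ---------------------------------------------------------------------------
# peak force phase


def _trapezoid(lo=30.0, hi=70.0, plateau=250.0):
    r = np.interp(CYC, [0, lo - 2, lo, hi, hi + 2, 100], [50.0, 50.0, plateau, plateau, 50.0, 50.0])
    f = np.zeros((101, 3))
    f[:, 2] = -r
    return series(f)


def test_pfp_stance_trapezoid():
    w = detect_pfp(_trapezoid(), "one_leg_stance")
    assert (w.start_pct, w.end_pct) == (30.0, 70.0)


def test_pfp_stance_constant_gets_central_window():
    w = detect_pfp(const_series([0, 0, -200.0]), "one_leg_stance")
    assert (w.start_pct, w.end_pct) == (25.0, 75.0)


def test_pfp_gait_window_around_peak():
    r = 100.0 + 150.0 * np.exp(-(((CYC - 33.0) / 5.0) ** 2))
    f = np.zeros((101, 3))
    f[:, 2] = -r
    w = detect_pfp(series(f), "level_walking", {"contralateral_toe_off": 32.0})
    assert (w.start_pct, w.end_pct) == (30.5, 35.5)
    assert w.end_pct - w.start_pct == pytest.approx(5.0)


def test_pfp_gait_requires_event():
    with pytest.raises(ValueError):
        detect_pfp(_trapezoid(), "level_walking")


# ---------------------------------------------------------------------------
# scalar metrics


def test_pd_and_mape():
    vivo = const_series([0, 0, -200.0])
    sim = const_series([0, 0, -220.0])
    w = PfpWindow(25, 75)
    assert pd_pfp(sim, vivo, w) == pytest.approx(10.0)
    assert pd_pfp(vivo, vivo, w) == 0.0
    assert mape_pfp([10.0, -10.0, 20.0]) == pytest.approx(13.333, abs=1e-3)


def test_mad_examples():
    w = PfpWindow(25, 75)
    a = const_series([1.0, 0.0, -2.0])
    b = const_series([1.0, -1.0, -2.0])
    same = mad_pfp(a, a, w)
    for val in (same.fe, same.aa, same.ie, same.d3):
        assert val == pytest.approx(0.0, abs=1e-5)
    d = mad_pfp(a, b, w)
    assert d.d3 == pytest.approx(np.degrees(np.arccos(5 / np.sqrt(30))), abs=1e-6)


def test_mad_frontal_rotation():
    w = PfpWindow(25, 75)
    v = np.array([0.0, 0.0, -2.0])
    ang = np.radians(5.0)
    # frontal plane = (ML, IS): rotate v by 5 deg within that plane
    vr = np.array([-v[2] * np.sin(ang), 0.0, v[2] * np.cos(ang)])
    d = mad_pfp(const_series(v), const_series(vr), w)
    assert d.aa == pytest.approx(5.0, abs=1e-9)
    assert d.d3 == pytest.approx(5.0, abs=1e-9)


def test_rmse_and_mae():
    a = const_series([10.0, 0.0, -100.0])
    b = const_series([10.0, 0.0, -110.0])
    r = rmse_components(a, b)
    assert (r["ML"], r["PA"], r["IS"]) == (0.0, 0.0, 10.0)
    assert r["R"] == pytest.approx(abs(a.resultant[0] - b.resultant[0]))
    zero = rmse_components(a, a)
    assert all(v == 0 for v in zero.values())
    m = mae_components(a, b)
    assert m["IS"] == pytest.approx(10.0)


def test_correlation_identity_and_gain():
    x = np.linspace(0, 100, 101) + np.sin(np.linspace(0, 9, 101))
    same = correlate(x, x)
    assert same["r2"] == pytest.approx(1.0)
    assert same["slope"] == pytest.approx(1.0)
    assert same["intercept"] == pytest.approx(0.0, abs=1e-9)
    double = correlate(2 * x, x)
    assert double["slope"] == pytest.approx(2.0)
    assert double["r2"] == pytest.approx(1.0)


def test_correlation_independent_noise_monte_carlo():
    """Uncorrelated series: r^2 < 0.01 and p > 0.05 in the vast majority of seeds."""
    hits = 0
    for seed in range(100):
        rng = np.random.default_rng(seed)
        a, b = rng.normal(size=1000), rng.normal(size=1000)
        res = correlate(a, b)
        hits += res["r2"] < 0.01 and res["p"] > 0.05
    assert hits >= 93


def test_bland_altman_worked_example():
    out = bland_altman(np.array([1.0, 2, 3, 4, 5]), np.zeros(5))
    assert out["median_diff"] == pytest.approx(3.0)
    assert out["loa_low"] == pytest.approx(0.1)
    assert out["loa_high"] == pytest.approx(5.9)


@given(st.floats(-50, 50))
@settings(max_examples=25, deadline=None)
def test_bland_altman_shift_equivariance(c):
    base = np.array([1.0, 2, 3, 4, 5, 9, -2])
    a = bland_altman(base, np.zeros(7))
    b = bland_altman(base + c, np.zeros(7))
    assert b["median_diff"] == pytest.approx(a["median_diff"] + c, abs=1e-9)
    assert b["loa_low"] == pytest.approx(a["loa_low"] + c, abs=1e-9)
    assert b["loa_high"] == pytest.approx(a["loa_high"] + c, abs=1e-9)
    # interval always contains the median, width fixed by the IQR
    assert b["loa_low"] <= b["median_diff"] <= b["loa_high"]


def test_nonparametric_tests():
    rng = np.random.default_rng(0)
    x = rng.normal(size=1000)
    same = nonparam_tests(x, x)
    assert same["mannwhitney_p"] == pytest.approx(1.0)
    shifted = nonparam_tests(x + 50.0, x)
    assert shifted["mannwhitney_p"] < 0.05
    with pytest.raises(ValueError):
        nonparam_tests(x[:5], x[:5])


def test_ks_normal_differences_monte_carlo():
    hits = 0
    for seed in range(100):
        rng = np.random.default_rng(seed)
        d = rng.normal(size=500)
        res = nonparam_tests(d, np.zeros(500))
        hits += res["ks_p"] > 0.05
    assert hits >= 90
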