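import numpy as np
import pytest
from scipy.signal import find_peaks

from hipload import (
    GaitParams,
    NoiseParams,
    StanceParams,
    generate_gait_trial,
    generate_invivo_series,
    generate_stance_trial,
)
from hipload.metrics import PfpWindow, mad_pfp
from hipload.synthetic import add_soft_tissue_artifact

from conftest import CLEAN_GAIT, CLEAN_STANCE


def _assert_trials_identical(a, b):
    for ma, mb in zip(a.markers, b.markers):
        np.testing.assert_array_equal(ma.positions, mb.positions)
    np.testing.assert_array_equal(a.grf.force, b.grf.force)
    np.testing.assert_array_equal(a.truth.f, b.truth.f)


def test_stance_trial_is_seed_deterministic(h1l):
    t1 = generate_stance_trial(h1l, StanceParams(), seed=7)
    t2 = generate_stance_trial(h1l, StanceParams(), seed=7)
    _assert_trials_identical(t1, t2)


def test_gait_trial_is_seed_deterministic(h1l):
    t1 = generate_gait_trial(h1l, GaitParams(), seed=7)
    t2 = generate_gait_trial(h1l, GaitParams(), seed=7)
    _assert_trials_identical(t1, t2)


def test_stance_plateau_morphology(clean_stance_trial):
    """The resultant exceeds 75 % of its maximum on a window containing the
    requested 30-70 % plateau span, and the plateau sits near the target."""
    tr = clean_stance_trial.truth
    r = tr.resultant
    above = tr.cycle[r >= 0.75 * r.max()]
    assert above.min() <= 30.0 and above.max() >= 70.0
    mid = (tr.cycle >= 30) & (tr.cycle <= 70)
    assert r[mid].mean() == pytest.approx(259.0, abs=8.0)
    # medial / posterior / inferior sign convention during the plateau
    assert np.all(tr.f[mid, 0] > 0)
    assert np.all(tr.f[mid, 1] < 0)
    assert np.all(tr.f[mid, 2] < 0)


def test_stance_rejects_bad_plateau_span(h1l):
    with pytest.raises(ValueError):
        StanceParams(plateau_span=(70.0, 30.0))
    with pytest.raises(ValueError):
        StanceParams(plateau_span=(0.0, 110.0))


def test_gait_double_peak_morphology(h1l):
    trial = generate_gait_trial(h1l, CLEAN_GAIT, seed=3)
    tr = trial.truth
    r = tr.resultant
    stance = (tr.cycle > 2) & (tr.cycle < 58)
    peaks, _ = find_peaks(r, prominence=15.0)
    peaks = [p for p in peaks if stance[p]]
    assert len(peaks) == 2
    assert tr.cycle[peaks[0]] == pytest.approx(15.0, abs=3.0)
    assert tr.cycle[peaks[1]] == pytest.approx(45.0, abs=3.0)
    assert r[peaks[0]] == pytest.approx(255.0, abs=8.0)
    assert r[peaks[1]] == pytest.approx(230.0, abs=8.0)
    # force plate silent during swing
    assert np.all(trial.grf.force[tr.cycle >= 60] == 0.0)
    ev = trial.events
    assert ev["ipsilateral_heel_strike"] < ev["contralateral_toe_off"] < ev[
        "contralateral_heel_strike"
    ]


def test_gait_rejects_nonincreasing_peaks():
    with pytest.raises(ValueError):
        GaitParams(peak1_phase=45.0, peak2_phase=15.0)


def test_gait_mass_doubling_scales_grf_not_pct_bw(h1l):
    from hipload.anthro import Anthropometrics

    heavy = Anthropometrics(
        "H1X", h1l.side, h1l.age, h1l.sex, 2 * h1l.mass, h1l.height, h1l.hjw_ct
    )
    t1 = generate_gait_trial(h1l, CLEAN_GAIT, seed=5)
    t2 = generate_gait_trial(heavy, CLEAN_GAIT, seed=5)
    w1 = t1.grf.force[:, 2].max()
    w2 = t2.grf.force[:, 2].max()
    assert w2 / w1 == pytest.approx(2.0, rel=0.05)
    assert t2.truth.resultant.max() == pytest.approx(t1.truth.resultant.max(), abs=8.0)


def test_soft_tissue_artifact_offsets():
    rng = np.random.default_rng(0)
    from hipload.kinematics import MarkerTrajectory

    def mk(mid, seg):
        return MarkerTrajectory(mid, rng.normal(0, 100, (50, 3)), 25.0, segment=seg)

    markers = [mk("LASI", "pelvis"), mk("RASI", "pelvis"), mk("LKNE", "femur_l")]
    # below BMI threshold: no systematic offset
    out = add_soft_tissue_artifact(markers, bmi=24.0, scale=1.0, seed=1)
    for a, b in zip(out, markers):
        np.testing.assert_array_equal(a.positions, b.positions)
    # scale zero: identity
    out = add_soft_tissue_artifact(markers, bmi=40.0, scale=0.0, seed=1)
    for a, b in zip(out, markers):
        np.testing.assert_array_equal(a.positions, b.positions)
    # H9L-like subject: 12.2 mm lateral offset per side, pelvis markers only
    out = add_soft_tissue_artifact(markers, bmi=37.2, scale=1.0, seed=1)
    d_lasi = (out[0].positions - markers[0].positions)[:, 1]
    d_rasi = (out[1].positions - markers[1].positions)[:, 1]
    assert d_lasi.mean() == pytest.approx(+12.2, abs=2.0)
    assert d_rasi.mean() == pytest.approx(-12.2, abs=2.0)
    np.testing.assert_array_equal(out[2].positions, markers[2].positions)


def test_invivo_zero_noise_is_identity(clean_stance_trial):
    vivo = generate_invivo_series(
        clean_stance_trial.truth, NoiseParams(noise_bw=0.0, misalignment_deg=0.0), seed=2
    )
    np.testing.assert_array_equal(vivo.series.f, clean_stance_trial.truth.f)


def test_invivo_misalignment_sets_angular_deviation(clean_stance_trial):
    vivo = generate_invivo_series(
        clean_stance_trial.truth, NoiseParams(noise_bw=0.0, misalignment_deg=3.0), seed=2
    )
    d = mad_pfp(vivo.series, clean_stance_trial.truth, PfpWindow(30, 70))
    assert d.d3 == pytest.approx(3.0, abs=0.1)


def test_invivo_seed_deterministic(clean_stance_trial):
    v1 = generate_invivo_series(clean_stance_trial.truth, NoiseParams(), seed=9)
    v2 = generate_invivo_series(clean_stance_trial.truth, NoiseParams(), seed=9)
    np.testing.assert_array_equal(v1.series.f, v2.series.f)


def test_stance_events_empty_and_cycle_grid(clean_stance_trial):
    assert clean_stance_trial.events == {}
    tr = clean_stance_trial.truth
    assert tr.cycle[0] == 0.0 and tr.cycle[-1] == 100.0
    assert np.all(tr.resultant >= 0.0)
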