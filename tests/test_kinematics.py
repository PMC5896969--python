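import numpy as np
import pytest

from hipload import build_reference_model, reference_cohort
from hipload.kinematics import (
    MarkerTrajectory,
    default_marker_set,
    forward_markers,
    load_markers,
    marker_weights,
    optimize_parameters,
    save_markers,
    solve_frame_kinematics,
)
from hipload.model import set_hjw
from hipload.synthetic import add_soft_tissue_artifact


def test_marker_weights_examples():
    assert marker_weights(0.0) == 1.0
    assert marker_weights(5.0) == pytest.approx(0.9412, abs=1e-4)
    assert marker_weights(50.0) == pytest.approx(0.1379, abs=1e-4)
    assert marker_weights(np.array([3.0]), validity=np.array([False]))[0] == 0.0
    with pytest.raises(ValueError):
        marker_weights(-1.0)


def test_marker_weights_monotone_in_residual():
    r = np.linspace(0, 200, 100)
    w = marker_weights(r)
    assert np.all(np.diff(w) <= 0)
    assert np.all((w >= 0) & (w <= 1))


def _markers_from_pose(model, qs, rate=25.0):
    defs = default_marker_set(model)
    T = len(qs)
    out = []
    for mid, (seg, off) in defs.items():
        pos = np.stack([1000.0 * forward_markers(model, q, {mid: (seg, off)})[mid] for q in qs])
        out.append(MarkerTrajectory(mid, pos, rate, segment=seg, local_offset=1000 * off))
    return out


def test_scale_recovery_on_exact_markers(clean_stance_trial, h1l):
    """Noise-free markers: segment lengths recovered to 1e-3 relative."""
    model = build_reference_model(h1l)
    fit = optimize_parameters(model, clean_stance_trial.markers)
    for name, true in clean_stance_trial.true_scales.items():
        assert fit.length_scales[name] == pytest.approx(true, rel=1e-3)
    kin = solve_frame_kinematics(model, clean_stance_trial.markers, fit)
    assert np.nanmean(kin.residuals) < 0.5  # mm


def test_objective_history_monotone(clean_stance_trial, h1l):
    model = build_reference_model(h1l)
    fit = optimize_parameters(model, clean_stance_trial.markers)
    h = np.array(fit.objective_history)
    assert np.all(np.diff(h) <= 0)
    assert fit.converged


def test_ct_mode_freezes_hjw_and_drops_one_parameter(clean_stance_trial, h1l):
    model_ct = build_reference_model(h1l)
    fit_ct = optimize_parameters(model_ct, clean_stance_trial.markers)
    assert fit_ct.hjw_c3d == model_ct.hjw  # frozen exactly
    model_c3d = set_hjw(model_ct, model_ct.hjw, "C3D")
    fit_c3d = optimize_parameters(model_c3d, clean_stance_trial.markers)
    assert fit_c3d.n_free_params == fit_ct.n_free_params + 1


def test_soft_tissue_artifact_inflates_free_hjw(clean_stance_trial, h1l):
    """+10 mm lateral pelvis-marker offset per side inflates the marker-derived
    width by roughly the geometric 2x10 mm (leg markers pull it partway back),
    while the CT mode stays untouched."""
    markers = add_soft_tissue_artifact(clean_stance_trial.markers, bmi=35.0, scale=1.0)
    model = set_hjw(build_reference_model(h1l), h1l.hjw_ct, "C3D")
    fit = optimize_parameters(model, markers)
    inflation = fit.hjw_c3d - h1l.hjw_ct
    assert 6.0 < inflation < 26.0
    fit_ct = optimize_parameters(build_reference_model(h1l), markers)
    assert fit_ct.hjw_c3d == h1l.hjw_ct


def test_rigid_transform_invariance(clean_stance_trial, h1l):
    """A common lab-frame rotation+translation changes no joint angle."""
    from scipy.spatial.transform import Rotation

    model = build_reference_model(h1l)
    fit = optimize_parameters(model, clean_stance_trial.markers)
    kin = solve_frame_kinematics(model, clean_stance_trial.markers, fit)
    R = Rotation.from_rotvec([0.1, -0.2, 0.5]).as_matrix()
    t = np.array([400.0, -250.0, 120.0])
    moved = []
    for m in clean_stance_trial.markers:
        moved.append(
            MarkerTrajectory(
                m.marker_id, m.positions @ R.T + t, m.rate, m.validity.copy(),
                m.segment, m.local_offset,
            )
        )
    fit2 = optimize_parameters(model, moved)
    kin2 = solve_frame_kinematics(model, moved, fit2)
    np.testing.assert_allclose(kin2.joint_angles, kin.joint_angles, atol=1e-5)
    np.testing.assert_allclose(
        np.nanmean(kin2.residuals), np.nanmean(kin.residuals), atol=1e-3
    )


def test_static_markers_give_zero_velocity(h1l):
    model = build_reference_model(h1l)
    q = np.zeros(16)
    q[2] = 0.95
    markers = _markers_from_pose(model, [q] * 20)
    fit = optimize_parameters(model, markers)
    kin = solve_frame_kinematics(model, markers, fit)
    assert np.abs(kin.qd).max() < 1e-6


def test_rigid_rotation_about_hip_recovers_angle(h1l):
    """Markers rotated 10 deg about the hip flexion axis read back as 10 deg
    of hip flexion with near-zero residuals."""
    model = build_reference_model(h1l)
    q = np.zeros(16)
    q[2] = 0.95
    q[6:9] = [0.0, -np.radians(10.0), 0.0]  # left hip flexion
    markers = _markers_from_pose(model, [q] * 5)
    fit = optimize_parameters(model, markers)
    kin = solve_frame_kinematics(model, markers, fit)
    fe = kin.joint_angles[:, kin.joint_angle_names.index("hip_fe_l")]
    np.testing.assert_allclose(np.degrees(fe), 10.0, atol=1e-3)
    assert np.nanmax(kin.residuals) < 0.1


def test_underdetermined_marker_set_rejected(h1l, clean_stance_trial):
    model = build_reference_model(h1l)
    few = [m for m in clean_stance_trial.markers if m.segment == "pelvis"][:2]
    with pytest.raises(ValueError, match="under-determined"):
        optimize_parameters(model, few)


def test_marker_csv_roundtrip(tmp_path, clean_stance_trial):
    path = tmp_path / "markers.csv"
    save_markers(clean_stance_trial.markers, path)
    again = load_markers(path)
    orig = {m.marker_id: m for m in clean_stance_trial.markers}
    assert set(m.marker_id for m in again) == set(orig)
    for m in again:
        np.testing.assert_allclose(m.positions, orig[m.marker_id].positions, atol=1e-6)
        assert m.rate == pytest.approx(orig[m.marker_id].rate, rel=1e-6)
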