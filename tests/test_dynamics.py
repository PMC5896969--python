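import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from hipload import build_reference_model
from hipload.dynamics import (
    ComboSpec,
    GroundReaction,
    RecruitmentProblem,
    hip_reaction,
    load_grf,
    moment_arm_matrix,
    net_joint_loads,
    recruit_minmax,
    recruit_polynomial,
    save_grf,
    strength_hill,
    strength_simple,
)
from hipload.kinematics import segment_poses
from hipload.synthetic import kinematics_from_q


# ---------------------------------------------------------------------------
# muscle models


def test_simple_strength_is_sigma_times_pcsa(h1l):
    model = build_reference_model(h1l)
    fas = model.fascicles[0]
    assert strength_simple(fas, 90.0) == pytest.approx(90.0 * fas.pcsa)
    assert strength_simple(fas, 40.0) == pytest.approx(40.0 * fas.pcsa)
    with pytest.raises(ValueError):
        strength_simple(fas, 0.0)


def test_hill_reduces_to_simple_at_optimum(h1l):
    fas = build_reference_model(h1l).fascicles[0]
    active, passive = strength_hill(fas, 1.0, 0.0, 90.0)
    assert active == pytest.approx(90.0 * fas.pcsa)
    assert passive == 0.0


def test_hill_force_length_gaussian(h1l):
    fas = build_reference_model(h1l).fascicles[0]  # flw = 0.45
    active, _ = strength_hill(fas, 1.45, 0.0, 90.0)
    assert active == pytest.approx(90.0 * fas.pcsa * np.exp(-1.0), rel=1e-9)


def test_hill_force_velocity_endpoint_and_passive_monotone(h1l):
    fas = build_reference_model(h1l).fascicles[0]
    active, _ = strength_hill(fas, 1.0, fas.hill.max_velocity, 90.0)
    assert active == 0.0
    passives = [strength_hill(fas, l, 0.0, 90.0)[1] for l in np.linspace(0.8, 1.6, 30)]
    assert all(p == 0 for p in passives[:7])  # below optimal length
    assert np.all(np.diff(passives) >= 0)


# ---------------------------------------------------------------------------
# recruitment closed forms


def test_single_muscle_fully_determined():
    sol = recruit_polynomial(RecruitmentProblem(C=[[0.05]], d=[60.0], N=[2000.0]))
    assert sol.ok
    assert sol.f[0] == pytest.approx(1200.0, rel=1e-9)


def test_symmetric_muscles_split_equally():
    prob = RecruitmentProblem(C=[[1.0, 1.0]], d=[80.0], N=[500.0, 500.0])
    for solver in (recruit_polynomial, recruit_minmax):
        sol = solver(prob)
        assert sol.f[0] == pytest.approx(sol.f[1], rel=1e-6)
        assert sol.f.sum() == pytest.approx(80.0, rel=1e-9)


def test_polynomial_strength_ratio_closed_form():
    """Equal arms, N1 = 2 N2: the p=3 optimum carries f1/f2 = 2^(3/2)."""
    sol = recruit_polynomial(RecruitmentProblem(C=[[1.0, 1.0]], d=[100.0], N=[2.0, 1.0]))
    assert sol.f[0] / sol.f[1] == pytest.approx(2**1.5, rel=1e-6)
    assert sol.f[0] == pytest.approx(100.0 * 2**1.5 / (1 + 2**1.5), rel=1e-6)


def test_minmax_equalizes_activations():
    sol = recruit_minmax(RecruitmentProblem(C=[[1.0, 1.0]], d=[90.0], N=[600.0, 300.0]))
    np.testing.assert_allclose(sol.activations, sol.activations[0], rtol=1e-6)
    np.testing.assert_allclose(sol.f, [60.0, 30.0], rtol=1e-6)


def test_capacity_bound_makes_problem_infeasible():
    prob = RecruitmentProblem(
        C=[[0.05, 0.04]], d=[100.0], N=[500.0, 400.0], cap=np.array([500.0, 400.0])
    )
    assert recruit_minmax(prob).status == "infeasible"
    assert recruit_polynomial(prob).status == "infeasible"


def test_polynomial_invariant_under_uniform_strength_scaling():
    prob1 = RecruitmentProblem(C=[[0.9, 0.4, 0.2], [0.1, 0.8, 0.5]], d=[50.0, 30.0],
                               N=[900.0, 500.0, 300.0])
    prob2 = RecruitmentProblem(C=prob1.C, d=prob1.d, N=prob1.N * 7.5)
    f1 = recruit_polynomial(prob1).f
    f2 = recruit_polynomial(prob2).f
    np.testing.assert_allclose(f1, f2, rtol=1e-6)


@given(st.integers(0, 500))
@settings(max_examples=40, deadline=None)
def test_equilibrium_residual_tolerance(seed):
    """Feasible solutions satisfy the equilibrium to 1e-6 relative, f >= 0."""
    rng = np.random.default_rng(seed)
    n = rng.integers(4, 8)
    C = rng.uniform(-1.0, 1.0, size=(3, n))
    f_true = rng.uniform(0.0, 500.0, size=n)
    d = C @ f_true
    N = rng.uniform(200.0, 2000.0, size=n)
    for solver in (recruit_polynomial, recruit_minmax):
        sol = solver(RecruitmentProblem(C=C, d=d, N=N))
        assert sol.ok
        scale = max(np.abs(d).max(), 1.0)
        assert np.abs(C @ sol.f - d).max() <= 1e-6 * scale
        assert sol.f.min() >= -1e-9


# ---------------------------------------------------------------------------
# inverse dynamics oracles


def _static_setup(anthro, cop_offset_y=0.0, w_n=600.0, T=5):
    model = build_reference_model(anthro)
    q = np.zeros(16)
    q[2] = 0.95
    kin = kinematics_from_q(model, np.tile(q, (T, 1)), 25.0)
    poses = segment_poses(model, q)
    hip = poses[f"femur_{anthro.side.lower()}"][1]
    cop = np.tile([1000 * hip[0], 1000 * (hip[1] + cop_offset_y), 0.0], (T, 1))
    grf = GroundReaction(
        times=np.arange(T) / 25.0,
        force=np.tile([0.0, 0.0, w_n], (T, 1)),
        cop_mm=cop,
    )
    return model, kin, grf


def test_abduction_moment_from_medial_cop(h1l):
    """600 N acting 100 mm medial of the hip adds exactly 60 N m of abduction
    demand relative to a load acting directly under the hip."""
    model, kin, grf0 = _static_setup(h1l, cop_offset_y=0.0)
    _, _, grf1 = _static_setup(h1l, cop_offset_y=-0.100)  # medial of left hip
    d0 = net_joint_loads(model, kin, grf0, side="L").moments[2]
    d1 = net_joint_loads(model, kin, grf1, side="L").moments[2]
    assert d1[0] - d0[0] == pytest.approx(60.0, rel=1e-9)


def test_net_loads_linear_in_grf(h1l):
    model, kin, grf = _static_setup(h1l, cop_offset_y=-0.08, w_n=600.0)
    _, _, grf2 = _static_setup(h1l, cop_offset_y=-0.08, w_n=1200.0)
    _, _, grf_zero = _static_setup(h1l, cop_offset_y=-0.08, w_n=0.0)
    d = net_joint_loads(model, kin, grf, side="L").moments[2]
    d2 = net_joint_loads(model, kin, grf2, side="L").moments[2]
    dz = net_joint_loads(model, kin, grf_zero, side="L").moments[2]
    np.testing.assert_allclose(d2 - dz, 2 * (d - dz), atol=1e-9)


def test_frontal_plane_statics_oracle():
    """Classic single-leg-stance estimate: supported weight 600 N with a
    100 mm medial lever and a 50 mm abductor arm gives a 1200 N abductor
    force and a 1800 N (300 % of 600 N) hip resultant."""
    f = recruit_polynomial(RecruitmentProblem(C=[[0.05]], d=[60.0], N=[3000.0])).f
    assert f[0] == pytest.approx(1200.0, rel=1e-9)
    contact = np.array([0.0, 0.0, -600.0]) - f[0] * np.array([0.0, 0.0, 1.0])
    assert np.linalg.norm(contact) == pytest.approx(1800.0, rel=1e-9)
    assert np.linalg.norm(contact) / 600.0 == pytest.approx(3.0)


def test_hip_reaction_force_balance(h1l):
    """The reported contact force equals the intersegmental force minus the
    summed muscle pulls, in every frame."""
    model, kin, grf = _static_setup(h1l, cop_offset_y=-0.08)
    loads = net_joint_loads(model, kin, grf, side="L")
    combo = ComboSpec()
    res = hip_reaction(model, kin, loads, combo)
    for t in range(len(kin.q)):
        poses = segment_poses(model, kin.q[t])
        C, U, fas = moment_arm_matrix(model, poses, "L")
        N = np.array([strength_simple(f, combo.sigma) for f in fas])
        sol = recruit_polynomial(RecruitmentProblem(C=C, d=loads.moments[t], N=N, cap=N))
        contact = loads.forces[t] - U.T @ sol.f
        Rf = poses["femur_l"][0]
        np.testing.assert_allclose(res.force_isb[t], Rf.T @ contact, atol=1e-6)


def test_mirrored_toy_has_mirrored_reaction(cohort):
    """Right-sided subject: same magnitude, ML sign flips in the lab frame."""
    left = cohort[0]
    from hipload.anthro import Anthropometrics

    right = Anthropometrics("H1R", "R", left.age, left.sex, left.mass, left.height,
                            left.hjw_ct)
    mags = {}
    for a in (left, right):
        model, kin, grf = _static_setup(a, cop_offset_y=-0.08 if a.side == "L" else 0.08)
        # reuse helper with explicit side
        loads = net_joint_loads(model, kin, grf, side=a.side)
        res = hip_reaction(model, kin, loads, ComboSpec())
        mags[a.side] = np.linalg.norm(res.force_isb[2])
    assert mags["L"] == pytest.approx(mags["R"], rel=1e-6)


def test_grf_frame_count_mismatch_rejected(h1l):
    model, kin, grf = _static_setup(h1l)
    short = GroundReaction(times=grf.times[:3], force=grf.force[:3], cop_mm=grf.cop_mm[:3])
    with pytest.raises(ValueError):
        net_joint_loads(model, kin, short, side="L")


def test_combospec_validation():
    with pytest.raises(ValueError):
        ComboSpec(sigma=-1.0)
    with pytest.raises(ValueError):
        ComboSpec(recruitment="XX")


def test_grf_csv_roundtrip(tmp_path, h1l):
    _, _, grf = _static_setup(h1l)
    path = tmp_path / "grf.csv"
    save_grf(grf, path)
    again = load_grf(path)
    np.testing.assert_allclose(again.force, grf.force, atol=1e-9)
    np.testing.assert_allclose(again.cop_mm, grf.cop_mm, atol=1e-9)
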