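"""Inverse dynamics and muscle recruitment at the hip.

Step 2 of the pipeline: from the scaled model, the joint-angle time series and
the force-plate wrench, compute per-frame net hip loads, resolve the muscle
redundancy problem with either a third-power polynomial criterion (PN) or a
strict min/max criterion (MM), and assemble the hip joint contact force.

Equilibrium is enforced at the 3 DOFs of the analysed hip only; the remaining
joints are resolved by ideal torque providers.  Quasi-static gravity and
ground-reaction terms are exact; translational inertia of the distal segments
enters through low-pass-filtered accelerations (angular inertia of the thin
leg segments is neglected).  g = 9.81 m/s^2.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import linprog, minimize

from .kinematics import KinematicsResult, lowpass, segment_poses
from .model import BodyModel, MuscleFascicle

__all__ = [
    "GroundReaction",
    "NetLoads",
    "RecruitmentProblem",
    "RecruitmentSolution",
    "ComboSpec",
    "net_joint_loads",
    "strength_simple",
    "strength_hill",
    "recruit_polynomial",
    "recruit_minmax",
    "moment_arm_matrix",
    "hip_reaction",
    "TrialDynamicsError",
    "load_grf",
    "save_grf",
]

G = np.array([0.0, 0.0, -9.81])
_EQ_TOL_REL = 1e-6


class TrialDynamicsError(RuntimeError):
    """Raised when a whole-trial simulation fails (e.g. an infeasible frame)."""


@dataclass(frozen=True)
class ComboSpec:
    """One cell of the factorial study."""

    hjw_mode: str = "CT"  # "C3D" | "CT"
    sigma: float = 90.0  # muscle strength, N/cm^2
    recruitment: str = "PN"  # "PN" | "MM"
    muscle_model: str = "simple"  # "simple" | "hill"

    def __post_init__(self):
        if self.sigma <= 0:
            raise ValueError("sigma must be positive")
        if self.hjw_mode not in ("C3D", "CT"):
            raise ValueError("hjw_mode must be 'C3D' or 'CT'")
        if self.recruitment not in ("PN", "MM"):
            raise ValueError("recruitment must be 'PN' or 'MM'")
        if self.muscle_model not in ("simple", "hill"):
            raise ValueError("muscle_model must be 'simple' or 'hill'")

    @property
    def label(self) -> str:
        return f"{self.hjw_mode}-{self.sigma:g}-{self.recruitment}-{self.muscle_model}"


@dataclass
class GroundReaction:
    """Force-plate series: forces in N, COP in mm (lab frame, plate at z=0)."""

    times: np.ndarray  # (T,)
    force: np.ndarray  # (T, 3) N
    cop_mm: np.ndarray  # (T, 3) mm

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.force = np.asarray(self.force, dtype=float)
        self.cop_mm = np.asarray(self.cop_mm, dtype=float)
        if not (len(self.times) == len(self.force) == len(self.cop_mm)):
            raise ValueError("GRF series lengths differ")


@dataclass
class NetLoads:
    """Per-frame net hip demand for the analysed side."""

    moments: np.ndarray  # (T, 3) N m, lab frame: required muscle moment about the hip
    forces: np.ndarray  # (T, 3) N, lab frame: intersegmental force at the hip
    hip_center: np.ndarray  # (T, 3) m
    side: str

    def __post_init__(self):
        if not (np.isfinite(self.moments).all() and np.isfinite(self.forces).all()):
            raise ValueError("net loads contain non-finite values")


@dataclass
class RecruitmentProblem:
    C: np.ndarray  # (m, n) moment-arm/equilibrium matrix
    d: np.ndarray  # (m,) demanded moments
    N: np.ndarray  # (n,) instantaneous strengths, N
    cap: np.ndarray | None = None  # (n,) upper force bounds (None = unbounded)

    def __post_init__(self):
        self.C = np.atleast_2d(np.asarray(self.C, dtype=float))
        self.d = np.atleast_1d(np.asarray(self.d, dtype=float))
        self.N = np.atleast_1d(np.asarray(self.N, dtype=float))
        if np.any(self.N <= 0):
            raise ValueError("strengths must be positive")
        if self.C.shape[0] > self.C.shape[1]:
            raise ValueError("need at least as many muscles as DOFs")


@dataclass
class RecruitmentSolution:
    f: np.ndarray  # (n,) fascicle forces, N
    activations: np.ndarray  # f / N
    status: str  # "ok" | "infeasible" | "not_converged"
    criterion_value: float

    @property
    def ok(self) -> bool:
        return self.status == "ok"


# ---------------------------------------------------------------------------
# Muscle models


def strength_simple(fascicle: MuscleFascicle, sigma: float) -> float:
    """Constant strength sigma * PCSA (N); no length/velocity dependence."""
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    return sigma * fascicle.pcsa


def strength_hill(
    fascicle: MuscleFascicle, norm_length: float, norm_velocity: float, sigma: float
) -> tuple[float, float]:
    """Hill-type instantaneous strength: (active cap, passive force), N.

    active = sigma*pcsa * fl(l) * fv(v) with a Gaussian force-length curve of
    width ``flw`` and a Hill hyperbola force-velocity curve (shortening
    positive, zero force at the maximal shortening velocity, eccentric plateau
    at 1.5).  The passive element is zero at or below optimal length and grows
    quadratically, reaching sigma*pcsa at stretch 1 + passive_strain_scale.
    """
    h = fascicle.hill
    f0 = sigma * fascicle.pcsa
    fl = np.exp(-(((norm_length - 1.0) / h.flw) ** 2))
    v = norm_velocity  # optimal lengths / s, shortening positive
    vmax = h.max_velocity
    if v >= vmax:
        fv = 0.0
    elif v >= 0.0:
        fv = (vmax - v) / (vmax + v / 0.25)
    else:
        fv = 1.5 - 0.5 * (vmax + v) / (vmax - 7.56 * v / 0.25)
    strain = max(norm_length - 1.0, 0.0)
    passive = f0 * (strain / h.passive_strain_scale) ** 2
    return float(f0 * fl * fv), float(passive)


# ---------------------------------------------------------------------------
# Recruitment criteria


def _feasible(C, d, f, tol_rel=_EQ_TOL_REL) -> bool:
    scale = max(np.abs(d).max(), 1.0)
    return bool(np.abs(C @ f - d).max() <= tol_rel * scale and f.min() >= -1e-9)


def _start_point(prob: RecruitmentProblem):
    """LP feasibility start: minimize sum(f/N) subject to the constraints."""
    n = prob.C.shape[1]
    ub = prob.cap if prob.cap is not None else [None] * n
    res = linprog(
        c=1.0 / prob.N,
        A_eq=prob.C,
        b_eq=prob.d,
        bounds=[(0.0, None if u is None else float(u)) for u in ub],
        method="highs",
    )
    return (res.x, True) if res.status == 0 else (None, False)


def _pn_dual_newton(prob: RecruitmentProblem, p: int, lam0=None):
    """Semismooth Newton on the dual of the polynomial recruitment problem.

    KKT: f_i(lam) = N_i (N_i c_i.lam / p)^(1/(p-1)) clipped to [0, cap_i];
    solve C f(lam) = d for the m-vector lam.  Returns (f, lam) or None.
    """
    C, d, N = prob.C, prob.d, prob.N
    m, n = C.shape
    cap = prob.cap if prob.cap is not None else np.full(n, np.inf)
    expo = 1.0 / (p - 1.0)
    scale = max(np.abs(d).max(), 1.0)
    if lam0 is not None and np.isfinite(lam0).all():
        lam = np.asarray(lam0, dtype=float).copy()
    else:
        # initialize from the minimum-norm force estimate via the KKT relation
        f_ls, *_ = np.linalg.lstsq(C, d, rcond=None)
        mu0 = p * (np.abs(f_ls) ** (p - 1)) / N**p
        lam = np.linalg.lstsq(C.T, mu0, rcond=None)[0]

    def forces(lam_):
        mu = C.T @ lam_  # (n,)
        base = np.maximum(N * mu / p, 0.0)
        f = N * base**expo
        return np.minimum(f, cap), mu

    best = None
    for _ in range(100):
        f, mu = forces(lam)
        g = C @ f - d
        r = np.abs(g).max()
        if best is None or r < best[0]:
            best = (r, f.copy())
        if r <= 1e-10 * scale:
            return f, lam
        # d f_i / d mu_i on the active (unclipped, positive) set
        act = (f < cap - 1e-12) & (mu > 0)
        df = np.zeros(len(f))
        df[act] = (
            N[act] ** (1.0 + expo) * expo * (N[act] * mu[act] / p) ** (expo - 1.0) / p
        )
        H = (C * df) @ C.T
        try:
            step = np.linalg.solve(H + 1e-12 * np.eye(m), -g)
        except np.linalg.LinAlgError:
            return None
        # backtracking on the equilibrium residual
        ok = False
        for t in range(12):
            lam_new = lam + step * (0.5**t)
            f_new, _ = forces(lam_new)
            if np.abs(C @ f_new - d).max() < r:
                lam = lam_new
                ok = True
                break
        if not ok:
            break
    if best is not None and best[0] <= 1e-8 * scale:
        return best[1], lam
    return None


def _dual_from_forces(prob: RecruitmentProblem, f: np.ndarray, p: int) -> np.ndarray:
    """Dual estimate consistent with forces ``f`` through the KKT relation."""
    mu = p * (np.maximum(f, 1e-12) ** (p - 1)) / prob.N**p
    return np.linalg.lstsq(prob.C.T, mu, rcond=None)[0]


def recruit_polynomial(
    prob: RecruitmentProblem, p: int = 3, warm=None
) -> RecruitmentSolution:
    """Polynomial recruitment: minimize sum_i (f_i/N_i)^p s.t. C f = d, bounds.

    A convex program (p >= 2), solved by a dual Newton iteration (with an
    SLSQP fallback from an LP-feasible start).  ``warm`` may carry the dual
    variables of a previous, similar problem.
    """
    if p < 2:
        raise ValueError("p must be >= 2")
    n = prob.C.shape[1]
    Np = prob.N

    def obj(f):
        return float(np.sum((f / Np) ** p))

    if warm is None and p > 3:
        # continuation in the power: the dual surface becomes extremely flat
        # for large p, so walk up from p=3 rescaling the dual via the KKT map
        warm_f = None
        for q in [3] + [q for q in (5, 9, 17) if q < p]:
            res_q = _pn_dual_newton(prob, q, lam0=None if warm_f is None else _dual_from_forces(prob, warm_f, q))
            if res_q is not None:
                warm_f = res_q[0]
        if warm_f is not None:
            warm = _dual_from_forces(prob, warm_f, p)

    res = _pn_dual_newton(prob, p, lam0=warm)
    candidates = []
    if res is not None and _feasible(prob.C, prob.d, res[0]):
        if p <= 3:
            sol = RecruitmentSolution(res[0], res[0] / Np, "ok", obj(res[0]))
            sol.dual = res[1]  # type: ignore[attr-defined]
            return sol
        candidates.append((res[0], res[1]))

    # primal refinement on the well-scaled p-norm objective (sum a^p)^(1/p)
    x0 = candidates[0][0] if candidates else None
    if x0 is None:
        x0, feas = _start_point(prob)
        if not feas:
            return RecruitmentSolution(np.zeros(n), np.zeros(n), "infeasible", np.inf)
    ub = prob.cap if prob.cap is not None else np.full(n, np.inf)
    cons = [{"type": "eq", "fun": lambda f: prob.C @ f - prob.d, "jac": lambda f: prob.C}]

    def pnorm(f):
        a = np.maximum(f, 0.0) / Np
        return float(np.sum(a**p) ** (1.0 / p))

    def pnorm_grad(f):
        a = np.maximum(f, 1e-300) / Np
        s = np.sum(a**p)
        return (a ** (p - 1)) / (Np * s ** (1.0 - 1.0 / p))

    res2 = minimize(
        pnorm,
        np.clip(x0, 0.0, ub),
        jac=pnorm_grad,
        bounds=[(0.0, float(u)) for u in ub],
        constraints=cons,
        method="SLSQP",
        options={"maxiter": 400, "ftol": 1e-14},
    )
    f2 = np.clip(res2.x, 0.0, ub)
    if _feasible(prob.C, prob.d, f2):
        candidates.append((f2, None))
    if not candidates:
        return RecruitmentSolution(np.zeros(n), np.zeros(n), "not_converged", np.inf)
    f_best, lam_best = min(candidates, key=lambda c: obj(c[0]))
    sol = RecruitmentSolution(f_best, f_best / Np, "ok", obj(f_best))
    if lam_best is not None:
        sol.dual = lam_best  # type: ignore[attr-defined]
    return sol


def recruit_minmax(prob: RecruitmentProblem) -> RecruitmentSolution:
    """Strict min/max recruitment: minimize max_i f_i/N_i s.t. C f = d, f >= 0.

    Solved as an LP (variables f and the envelope t); among minimax-optimal
    solutions, uniqueness is fixed by a secondary pass minimizing sum f_i^2 at
    the optimal envelope.  LP infeasibility is the "unsuccessful simulation"
    failure mode.
    """
    m, n = prob.C.shape
    ub = prob.cap if prob.cap is not None else [None] * n
    A_ub = np.hstack([np.eye(n), -prob.N[:, None]])
    res = linprog(
        c=np.r_[np.zeros(n), 1.0],
        A_ub=A_ub,
        b_ub=np.zeros(n),
        A_eq=np.hstack([prob.C, np.zeros((m, 1))]),
        b_eq=prob.d,
        bounds=[(0.0, None if u is None else float(u)) for u in ub] + [(0.0, None)],
        method="highs",
    )
    if res.status != 0:
        return RecruitmentSolution(np.zeros(n), np.zeros(n), "infeasible", np.inf)
    t_star = float(res.x[-1])
    f_lp = res.x[:n]
    cap2 = prob.N * t_star * (1.0 + 1e-9)
    if prob.cap is not None:
        cap2 = np.minimum(cap2, prob.cap)
    res2 = minimize(
        lambda f: float(f @ f),
        np.minimum(f_lp, cap2),
        jac=lambda f: 2.0 * f,
        bounds=[(0.0, float(u)) for u in cap2],
        constraints=[{"type": "eq", "fun": lambda f: prob.C @ f - prob.d, "jac": lambda f: prob.C}],
        method="SLSQP",
        options={"maxiter": 200, "ftol": 1e-14},
    )
    f = np.clip(res2.x, 0.0, cap2) if _feasible(prob.C, prob.d, res2.x) else f_lp
    return RecruitmentSolution(f, f / prob.N, "ok", float(np.max(f / prob.N)))


# ---------------------------------------------------------------------------
# Inverse dynamics


def _distal_segments(side: str) -> list[str]:
    sfx = side.lower()
    return [f"femur_{sfx}", f"shank_{sfx}", f"foot_{sfx}"]


def net_joint_loads(
    model: BodyModel, kin: KinematicsResult, grf: GroundReaction, side: str = "L"
) -> NetLoads:
    """Bottom-up Newton-Euler net loads at the analysed hip.

    The required muscle moment about the hip is the moment of the inertial
    minus gravitational loads of the distal chain (femur+shank+foot) minus the
    ground-reaction moment; the intersegmental force is the matching force
    balance.  ``grf`` must be time-synchronized with the kinematics.
    """
    T = len(kin.q)
    if len(grf.force) != T:
        raise ValueError(f"force-plate series has {len(grf.force)} frames, kinematics {T}")
    segs = _distal_segments(side)
    masses = np.array([model.segment(s).mass for s in segs])
    coms = [model.segment(s).com_offset for s in segs]
    # COM world positions
    com_w = np.zeros((T, len(segs), 3))
    hip_w = np.zeros((T, 3))
    for t in range(T):
        poses = segment_poses(model, kin.q[t])
        for i, s in enumerate(segs):
            R, o = poses[s]
            com_w[t, i] = o + R @ coms[i]
        hip_w[t] = poses[f"femur_{side.lower()}"][1]
    # filtered COM accelerations
    acc = np.zeros_like(com_w)
    if T >= 3:
        for i in range(len(segs)):
            sm = lowpass(com_w[:, i, :], kin.rate)
            vel = np.gradient(sm, kin.times, axis=0)
            acc[:, i, :] = np.gradient(vel, kin.times, axis=0)
    cop_m = grf.cop_mm / 1000.0
    F = np.zeros((T, 3))
    M = np.zeros((T, 3))
    for t in range(T):
        inert = masses[:, None] * (acc[t] - G)  # (nseg, 3)
        F[t] = inert.sum(axis=0) - grf.force[t]
        M[t] = np.cross(com_w[t] - hip_w[t], inert).sum(axis=0) - np.cross(
            cop_m[t] - hip_w[t], grf.force[t]
        )
    return NetLoads(moments=M, forces=F, hip_center=hip_w, side=side)


def moment_arm_matrix(
    model: BodyModel, poses: dict, side: str
) -> tuple[np.ndarray, np.ndarray, list]:
    """Hip moment-arm matrix C (3 x n, lab axes), line-of-action units u, fascicles.

    Column i is the moment about the hip center of a unit force pulling the
    femoral attachment of fascicle i toward its pelvic attachment.
    """
    fascicles = model.fascicles_of(side)
    hip = poses[f"femur_{side.lower()}"][1]
    C = np.zeros((3, len(fascicles)))
    U = np.zeros((len(fascicles), 3))
    for i, f in enumerate(fascicles):
        (seg_a, pt_a), (seg_b, pt_b) = f.path[0], f.path[-1]
        Ra, oa = poses[seg_a]
        Rb, ob = poses[seg_b]
        p_pelv = oa + Ra @ pt_a
        p_fem = ob + Rb @ pt_b
        u = p_pelv - p_fem
        u = u / np.linalg.norm(u)
        C[:, i] = np.cross(p_fem - hip, u)
        U[i] = u
    return C, U, fascicles


def _fascicle_lengths(model: BodyModel, poses: dict, side: str) -> np.ndarray:
    out = []
    for f in model.fascicles_of(side):
        (seg_a, pt_a), (seg_b, pt_b) = f.path[0], f.path[-1]
        Ra, oa = poses[seg_a]
        Rb, ob = poses[seg_b]
        out.append(np.linalg.norm((oa + Ra @ pt_a) - (ob + Rb @ pt_b)))
    return np.array(out)


@dataclass
class HipForceResult:
    """Per-frame hip contact force in the ISB femoral frame (x ant, y left, z sup)."""

    times: np.ndarray
    force_isb: np.ndarray  # (T, 3) N
    side: str
    activations: np.ndarray  # (T, n)
    fascicle_names: list
    statuses: list
    max_activation: float


def hip_reaction(
    model: BodyModel,
    kin: KinematicsResult,
    loads: NetLoads,
    combo: ComboSpec,
    bounds_enabled: bool = True,
) -> HipForceResult:
    """Solve recruitment per frame and assemble the hip contact force.

    The contact force on the femoral head equals the intersegmental force
    minus the sum of hip-spanning muscle pulls, expressed in the femur (ISB)
    frame.  A single infeasible frame fails the whole trial
    (:class:`TrialDynamicsError`), mirroring the exclusion of unsuccessful
    simulations from the analysis.
    """
    side = loads.side
    T = len(kin.q)
    fascicles = model.fascicles_of(side)
    n = len(fascicles)
    # reference lengths at neutral pose for the Hill model
    neutral = segment_poses(model, np.zeros(16))
    l_ref = _fascicle_lengths(model, neutral, side)
    # fascicle length series for Hill velocity
    if combo.muscle_model == "hill":
        l_series = np.zeros((T, n))
        for t in range(T):
            l_series[t] = _fascicle_lengths(model, segment_poses(model, kin.q[t]), side)
        l_smooth = lowpass(l_series, kin.rate)
        l_dot = np.gradient(l_smooth, kin.times, axis=0)

    force = np.zeros((T, 3))
    acts = np.zeros((T, n))
    statuses = []
    lam_warm = None
    for t in range(T):
        poses = segment_poses(model, kin.q[t])
        C, U, _ = moment_arm_matrix(model, poses, side)
        if combo.muscle_model == "simple":
            N = np.array([strength_simple(f, combo.sigma) for f in fascicles])
            cap = N.copy() if bounds_enabled else None
            f_lower = np.zeros(n)
        else:
            N = np.zeros(n)
            passive = np.zeros(n)
            for i, f in enumerate(fascicles):
                lnorm = _hill_norm_length(l_series[t, i], l_ref[i], f)
                vnorm = -l_dot[t, i] / f.hill.optimal_fiber_length  # shortening positive
                a_cap, p_f = strength_hill(f, lnorm, vnorm, combo.sigma)
                N[i] = max(a_cap, 1e-6 * strength_simple(f, combo.sigma))
                passive[i] = p_f
            cap = N + passive if bounds_enabled else None
            f_lower = passive  # passive force is always transmitted
        # demand net of passive muscle moments (Hill); simple model: f_lower = 0
        d_eff = loads.moments[t] - C @ f_lower
        prob = RecruitmentProblem(C=C, d=d_eff, N=N, cap=None if cap is None else cap - f_lower)
        if combo.recruitment == "PN":
            sol = recruit_polynomial(prob, warm=lam_warm)
            lam_warm = getattr(sol, "dual", None)
        else:
            sol = recruit_minmax(prob)
        statuses.append(sol.status)
        if not sol.ok:
            raise TrialDynamicsError(
                f"recruitment {sol.status} at frame {t} "
                f"(combo {combo.label}, side {side})"
            )
        f_tot = sol.f + f_lower
        acts[t] = f_tot / N
        contact = loads.forces[t] - U.T @ f_tot
        Rf = poses[f"femur_{side.lower()}"][0]
        force[t] = Rf.T @ contact
    return HipForceResult(
        times=kin.times,
        force_isb=force,
        side=side,
        activations=acts,
        fascicle_names=[f.name for f in fascicles],
        statuses=statuses,
        max_activation=float(acts.max()) if T else 0.0,
    )


def _hill_norm_length(l_now: float, l_ref: float, fascicle: MuscleFascicle) -> float:
    """Normalized fiber length: unity at the neutral-pose musculotendon length.

    The tendon is rigid and the fiber absorbs the full length change scaled by
    the optimal fiber length.
    """
    return 1.0 + (l_now - l_ref) / fascicle.hill.optimal_fiber_length


# ---------------------------------------------------------------------------
# Force-plate CSV dialect: time_s, Fx_N, Fy_N, Fz_N, COPx_mm, COPy_mm, plate_id


def save_grf(grf: GroundReaction, path, plate_id: int = 1) -> None:
    pd.DataFrame(
        {
            "time_s": grf.times,
            "Fx_N": grf.force[:, 0],
            "Fy_N": grf.force[:, 1],
            "Fz_N": grf.force[:, 2],
            "COPx_mm": grf.cop_mm[:, 0],
            "COPy_mm": grf.cop_mm[:, 1],
            "plate_id": plate_id,
        }
    ).to_csv(path, index=False)


def load_grf(path) -> GroundReaction:
    df = pd.read_csv(path)
    cop = np.column_stack(
        [df["COPx_mm"], df["COPy_mm"], np.zeros(len(df))]
    )
    return GroundReaction(
        times=df["time_s"].to_numpy(),
        force=df[["Fx_N", "Fy_N", "Fz_N"]].to_numpy(),
        cop_mm=cop,
    )
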