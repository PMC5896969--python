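"""Marker-driven kinematics: scaling optimization and per-frame pose solves.

Step 1 of the simulation pipeline.  A weighted least-squares fit of the model
to skin-marker trajectories determines the per-subject segment length scales
(and, unless frozen to the CT value, the hip joint width), followed by a
per-frame pose solve yielding joint angle time series.

The generalized coordinate vector ``q`` has 16 entries::

    q[0:3]   pelvis position (m, lab frame)
    q[3:6]   pelvis orientation (rotation vector, rad)
    q[6:9]   left hip rotation vector (rad)
    q[9]     left knee angle, q[10] left ankle angle (rad)
    q[11:14] right hip rotation vector
    q[14]    right knee, q[15] right ankle

Lab frame: +X anterior, +Y left, +Z up.  Marker positions are exchanged in mm
(the CSV dialect and :class:`MarkerTrajectory`), geometry is in meters.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import least_squares
from scipy.signal import butter, filtfilt

from .model import BodyModel, _assemble

__all__ = [
    "MarkerTrajectory",
    "KinematicsResult",
    "ScaleFit",
    "default_marker_set",
    "marker_weights",
    "optimize_parameters",
    "solve_frame_kinematics",
    "forward_markers",
    "segment_poses",
    "load_markers",
    "save_markers",
    "lowpass",
]

N_Q = 16
_R0_WEIGHT_MM = 20.0  # residual scale of the marker weighting function
_MARKER_STIFFNESS_N_PER_MM = 10.0  # nominal stiffness for %BW-equivalent residual report


@dataclass
class MarkerTrajectory:
    """One marker's lab-frame trajectory (positions in mm)."""

    marker_id: str
    positions: np.ndarray  # (T, 3) mm
    rate: float  # Hz
    validity: np.ndarray = None  # (T,) bool
    segment: str | None = None
    local_offset: np.ndarray | None = None  # (3,) mm, segment frame

    def __post_init__(self):
        self.positions = np.asarray(self.positions, dtype=float)
        if self.positions.ndim != 2 or self.positions.shape[1] != 3 or len(self.positions) < 2:
            raise ValueError("positions must be (T>=2, 3)")
        if self.rate <= 0:
            raise ValueError("rate must be positive")
        if self.validity is None:
            self.validity = np.ones(len(self.positions), dtype=bool)
        else:
            self.validity = np.asarray(self.validity, dtype=bool)


def default_marker_set(model: BodyModel) -> dict[str, tuple[str, np.ndarray]]:
    """The 25-marker protocol: marker_id -> (segment, local offset in m).

    Pelvis markers sit laterally at exactly +/- HJW/2 so that the marker
    cloud's lateral spread identifies the hip joint width; all other offsets
    scale with their segment, keeping lengths identifiable from rigid marker
    clusters.
    """
    w2 = model.hjw / 2000.0
    hr = model.height / 1.74
    lf = model.segment("femur_l").length
    ls = model.segment("shank_l").length
    lft = model.segment("foot_l").length
    mk: dict[str, tuple[str, np.ndarray]] = {}

    def add(name, seg, x, y, z):
        mk[name] = (seg, np.array([x, y, z], dtype=float))

    add("LASI", "pelvis", 0.09 * hr, +w2, 0.03 * hr)
    add("RASI", "pelvis", 0.09 * hr, -w2, 0.03 * hr)
    add("LPSI", "pelvis", -0.11 * hr, +w2, 0.05 * hr)
    add("RPSI", "pelvis", -0.11 * hr, -w2, 0.05 * hr)
    add("C7", "hat", -0.05 * hr, 0.0, 0.46 * hr)
    add("CLAV", "hat", 0.03 * hr, 0.0, 0.42 * hr)
    add("STRN", "hat", 0.07 * hr, 0.0, 0.32 * hr)
    for side, s in (("L", +1.0), ("R", -1.0)):
        sfx = side.lower()
        add(f"{side}THI1", f"femur_{sfx}", 0.10 * lf, s * 0.14 * lf, -0.30 * lf)
        add(f"{side}THI2", f"femur_{sfx}", 0.00, s * 0.16 * lf, -0.55 * lf)
        add(f"{side}KNE", f"femur_{sfx}", 0.0, s * 0.13 * lf, -1.0 * lf)
        add(f"{side}TIB1", f"shank_{sfx}", 0.08 * ls, s * 0.10 * ls, -0.30 * ls)
        add(f"{side}TIB2", f"shank_{sfx}", 0.0, s * 0.12 * ls, -0.62 * ls)
        add(f"{side}ANK", f"shank_{sfx}", 0.0, s * 0.10 * ls, -1.0 * ls)
        add(f"{side}HEE", f"foot_{sfx}", -0.25 * lft, 0.0, -0.20 * lft)
        add(f"{side}TOE", f"foot_{sfx}", 0.60 * lft, -s * 0.05 * lft, -0.25 * lft)
        add(f"{side}MT5", f"foot_{sfx}", 0.35 * lft, s * 0.20 * lft, -0.25 * lft)
    return mk


# ---------------------------------------------------------------------------
# Rotations (small hand-inlined helpers keep the per-frame solve fast)


def _rodrigues(r: np.ndarray) -> np.ndarray:
    theta = np.linalg.norm(r)
    if theta < 1e-12:
        K = np.array([[0, -r[2], r[1]], [r[2], 0, -r[0]], [-r[1], r[0], 0]])
        return np.eye(3) + K
    k = r / theta
    K = np.array([[0, -k[2], k[1]], [k[2], 0, -k[0]], [-k[1], k[0], 0]])
    return np.eye(3) + np.sin(theta) * K + (1 - np.cos(theta)) * (K @ K)


def _roty(a: float) -> np.ndarray:
    c, s = np.cos(a), np.sin(a)
    return np.array([[c, 0.0, s], [0.0, 1.0, 0.0], [-s, 0.0, c]])


def _skew(v: np.ndarray) -> np.ndarray:
    return np.array([[0, -v[2], v[1]], [v[2], 0, -v[0]], [-v[1], v[0], 0]])


def _rotvec_right_jacobian(r: np.ndarray) -> np.ndarray:
    """Right Jacobian of SO(3): exp(r + d) ~ exp(r) exp(Jr(r) d)."""
    theta = np.linalg.norm(r)
    K = _skew(r)
    if theta < 1e-8:
        return np.eye(3) - 0.5 * K
    return (
        np.eye(3)
        - ((1 - np.cos(theta)) / theta**2) * K
        + ((theta - np.sin(theta)) / theta**3) * (K @ K)
    )


def _droty(a: float) -> np.ndarray:
    c, s = np.cos(a), np.sin(a)
    return np.array([[-s, 0.0, c], [0.0, 0.0, 0.0], [-c, 0.0, -s]])


def segment_poses(model: BodyModel, q: np.ndarray) -> dict[str, tuple[np.ndarray, np.ndarray]]:
    """Per-segment world pose (R, origin) for one frame."""
    w2 = model.hjw / 2000.0
    lf = model.segment("femur_l").length
    ls = model.segment("shank_l").length
    p0 = q[0:3]
    r0 = _rodrigues(q[3:6])
    poses = {"pelvis": (r0, p0), "hat": (r0, p0)}
    for side, s, off in (("l", +1.0, 6), ("r", -1.0, 11)):
        hip = p0 + r0 @ np.array([0.0, s * w2, 0.0])
        rf = r0 @ _rodrigues(q[off : off + 3])
        knee = hip + rf @ np.array([0.0, 0.0, -lf])
        rs = rf @ _roty(q[off + 3])
        ankle = knee + rs @ np.array([0.0, 0.0, -ls])
        rft = rs @ _roty(q[off + 4])
        poses[f"femur_{side}"] = (rf, hip)
        poses[f"shank_{side}"] = (rs, knee)
        poses[f"foot_{side}"] = (rft, ankle)
    return poses


def forward_markers(model: BodyModel, q: np.ndarray, marker_defs=None) -> dict[str, np.ndarray]:
    """Predicted marker positions (m) for one frame."""
    if marker_defs is None:
        marker_defs = default_marker_set(model)
    poses = segment_poses(model, q)
    out = {}
    for mid, (seg, off) in marker_defs.items():
        r, o = poses[seg]
        out[mid] = o + r @ off
    return out


# ---------------------------------------------------------------------------
# Weighting


def marker_weights(residuals, validity=None, r0: float = _R0_WEIGHT_MM):
    """Weights in [0, 1] from marker residuals (mm): w = 1/(1 + (r/r0)^2).

    Weights are monotonically non-increasing in the residual; invalid entries
    get weight 0; zero-residual valid markers get weight 1.
    """
    r = np.asarray(residuals, dtype=float)
    if np.any(r < 0):
        raise ValueError("residuals must be non-negative")
    w = 1.0 / (1.0 + (r / r0) ** 2)
    if validity is not None:
        w = np.where(np.asarray(validity, dtype=bool), w, 0.0)
    return w


# ---------------------------------------------------------------------------
# Per-frame pose solve


class _FrameFitter:
    """Caches marker geometry for fast repeated single-frame solves.

    Marker predictions and the analytic pose Jacobian (chain rule through the
    rotation-vector right Jacobian) are evaluated per segment group.
    """

    def __init__(self, model: BodyModel, markers: list[MarkerTrajectory], weights: dict):
        self.model = model
        defs = default_marker_set(model)
        self.ids = [m.marker_id for m in markers]
        for m in markers:
            if m.marker_id not in defs:
                raise KeyError(f"marker {m.marker_id!r} not in the model marker set")
        self.defs = {mid: defs[mid] for mid in self.ids}
        self.meas_m = np.stack([m.positions for m in markers], axis=1) / 1000.0  # (T, M, 3)
        self.validity = np.stack([m.validity for m in markers], axis=1)  # (T, M)
        self.w_marker = np.array([weights.get(mid, 1.0) for mid in self.ids])
        self.T = self.meas_m.shape[0]
        self.M = len(self.ids)
        # group markers by segment
        self.groups: dict[str, tuple[np.ndarray, np.ndarray]] = {}
        for seg in ("pelvis", "hat", "femur_l", "shank_l", "foot_l",
                    "femur_r", "shank_r", "foot_r"):
            idx = [i for i, mid in enumerate(self.ids) if self.defs[mid][0] == seg]
            if idx:
                offs = np.stack([self.defs[self.ids[i]][1] for i in idx])
                self.groups[seg] = (np.array(idx), offs)
        self.w2 = model.hjw / 2000.0
        self.lf = model.segment("femur_l").length
        self.ls = model.segment("shank_l").length

    def frame_weights(self, t: int) -> np.ndarray:
        return self.w_marker * self.validity[t]

    def _fk_jac(self, q: np.ndarray, want_jac: bool):
        pred = np.empty((self.M, 3))
        J = np.zeros((self.M, 3, N_Q)) if want_jac else None
        p0 = q[0:3]
        r0 = q[3:6]
        R0 = _rodrigues(r0)
        Jr0 = _rotvec_right_jacobian(r0) if want_jac else None
        for seg in ("pelvis", "hat"):
            if seg not in self.groups:
                continue
            idx, offs = self.groups[seg]
            pred[idx] = p0 + offs @ R0.T
            if want_jac:
                J[idx, :, 0:3] = np.eye(3)
                for i, o in zip(idx, offs):
                    J[i, :, 3:6] = -R0 @ _skew(o) @ Jr0
        for side, s, off in (("l", +1.0, 6), ("r", -1.0, 11)):
            h = np.array([0.0, s * self.w2, 0.0])
            k = np.array([0.0, 0.0, -self.lf])
            a = np.array([0.0, 0.0, -self.ls])
            rh = q[off : off + 3]
            Rh = _rodrigues(rh)
            Ryk = _roty(q[off + 3])
            Rya = _roty(q[off + 4])
            A = R0
            B = A @ Rh
            Cm = B @ Ryk
            D = Cm @ Rya
            o_f = p0 + A @ h
            o_s = o_f + B @ k
            o_ft = o_s + Cm @ a
            if want_jac:
                Jrh = _rotvec_right_jacobian(rh)
                dRyk = _droty(q[off + 3])
                dRya = _droty(q[off + 4])
            for seg, origin, Rm in (
                (f"femur_{side}", o_f, B),
                (f"shank_{side}", o_s, Cm),
                (f"foot_{side}", o_ft, D),
            ):
                if seg not in self.groups:
                    continue
                idx, offs = self.groups[seg]
                pred[idx] = origin + offs @ Rm.T
                if not want_jac:
                    continue
                J[idx, :, 0:3] = np.eye(3)
                for i, o in zip(idx, offs):
                    if seg.startswith("femur"):
                        v_h = o
                    elif seg.startswith("shank"):
                        v_h = k + Ryk @ o
                        J[i, :, off + 3] = B @ dRyk @ o
                    else:
                        v_ka = a + Rya @ o
                        v_h = k + Ryk @ v_ka
                        J[i, :, off + 3] = B @ dRyk @ v_ka
                        J[i, :, off + 4] = Cm @ dRya @ o
                    J[i, :, off : off + 3] = -B @ _skew(v_h) @ Jrh
                    J[i, :, 3:6] = -A @ _skew(h + Rh @ v_h) @ Jr0
        return pred, J

    def solve_frame(self, t: int, q0: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Returns (q, per-marker residual norms in mm)."""
        sw = np.sqrt(self.frame_weights(t))
        meas = self.meas_m[t]
        cache = {}

        def fun(q):
            pred, _ = self._fk_jac(q, want_jac=False)
            return ((pred - meas) * sw[:, None]).ravel()

        def jac(q):
            _, Jm = self._fk_jac(q, want_jac=True)
            return (Jm * sw[:, None, None]).reshape(3 * self.M, N_Q)

        sol = least_squares(fun, q0, jac=jac, method="lm", xtol=1e-12, ftol=1e-12)
        pred, _ = self._fk_jac(sol.x, want_jac=False)
        return sol.x, 1000.0 * np.linalg.norm(pred - meas, axis=1)

    def initial_guess(self) -> np.ndarray:
        q0 = np.zeros(N_Q)
        if "pelvis" in self.groups:
            idx, offs = self.groups["pelvis"]
            q0[0:3] = self.meas_m[0, idx].mean(axis=0) - offs.mean(axis=0)
        return q0


# ---------------------------------------------------------------------------
# Scaling optimization (outer Levenberg-Marquardt with explicit history)


@dataclass
class ScaleFit:
    length_scales: dict
    hjw_c3d: float  # mm
    weights: dict  # marker_id -> weight in [0, 1]
    objective_history: list
    converged: bool
    n_free_params: int


def _apply_scales(model: BodyModel, scales: dict, hjw_mm: float) -> BodyModel:
    n = len(model.fascicles_of("L"))
    merged = dict(model.length_scales)
    merged.update(scales)
    return _assemble(model.mass, model.height, hjw_mm, model.hjw_mode, merged, n)


def _check_determined(markers: list[MarkerTrajectory], model: BodyModel) -> None:
    defs = default_marker_set(model)
    per_seg: dict[str, int] = {}
    for m in markers:
        if m.marker_id in defs and m.validity.any():
            per_seg[defs[m.marker_id][0]] = per_seg.get(defs[m.marker_id][0], 0) + 1
    for seg in ("pelvis", "femur_l", "shank_l", "femur_r", "shank_r"):
        if per_seg.get(seg, 0) < 3 and seg != "pelvis":
            raise ValueError(f"under-determined marker set: segment {seg} has "
                             f"{per_seg.get(seg, 0)} markers (need >= 3)")
    if per_seg.get("pelvis", 0) < 3:
        raise ValueError("under-determined marker set: pelvis needs >= 3 markers")


def optimize_parameters(
    model: BodyModel,
    markers: list[MarkerTrajectory],
    max_iter: int = 200,
    tol: float = 1e-8,
    n_calib_frames: int = 10,
) -> ScaleFit:
    """Fit segment length scales (and free HJW) to marker trajectories.

    Minimizes the summed weighted squared marker residuals over the scale
    parameters with nested per-frame pose solves, via a damped Gauss-Newton
    (Levenberg-Marquardt) outer loop that only ever accepts cost-decreasing
    steps.  Marker weights are recomputed once after an initial unweighted
    pass, down-weighting markers with large residuals (dropout handling).

    In ``hjw_mode="CT"`` the hip joint width is frozen at the model value and
    the parameter vector has exactly one entry fewer than in ``"C3D"`` mode.
    """
    _check_determined(markers, model)
    T = len(markers[0].positions)
    cal_idx = np.unique(np.linspace(0, T - 1, min(T, n_calib_frames)).astype(int))
    free_hjw = model.hjw_mode == "C3D"
    scale_names = ("femur", "shank", "foot")

    def theta_to_model(theta) -> BodyModel:
        scales = {n: float(np.exp(th)) for n, th in zip(scale_names, theta[:3])}
        hjw = float(theta[3]) if free_hjw else model.hjw
        return _apply_scales(model, scales, hjw)

    uniform_w = {m.marker_id: 1.0 for m in markers}

    def stacked_residuals(theta, weights, q_warm):
        """Inner pose solves at the calibration frames; returns weighted residual vec."""
        mdl = theta_to_model(theta)
        fitter = _FrameFitter(mdl, markers, weights)
        res_all, resid_mm = [], []
        q = q_warm[0] if q_warm[0] is not None else fitter.initial_guess()
        for j, t in enumerate(cal_idx):
            if q_warm[j] is not None:
                q = q_warm[j]
            q, rmm = fitter.solve_frame(t, q)
            q_warm[j] = q.copy()
            sw = np.sqrt(fitter.frame_weights(t))
            pred, _ = fitter._fk_jac(q, want_jac=False)
            res = pred - fitter.meas_m[t]
            res_all.append((res * sw[:, None]).ravel())
            resid_mm.append(rmm)
        return np.concatenate(res_all), np.stack(resid_mm)

    # -- initial unweighted pass to estimate per-marker residual levels
    theta = np.zeros(4 if free_hjw else 3)
    if free_hjw:
        theta[3] = model.hjw
    q_warm = [None] * len(cal_idx)
    _, resid_mm = stacked_residuals(theta, uniform_w, q_warm)
    valid = np.stack([m.validity[cal_idx] for m in markers], axis=1)
    mean_resid = np.where(valid, resid_mm, np.nan)
    with np.errstate(invalid="ignore"):
        mean_resid = np.nanmean(mean_resid, axis=0)
    mean_resid = np.nan_to_num(mean_resid, nan=0.0)
    w_arr = marker_weights(mean_resid)
    weights = {m.marker_id: float(w) for m, w in zip(markers, w_arr)}
    if not any(weights.values()):
        weights = uniform_w  # total dropout: flagged by zero weights upstream

    # -- Levenberg-Marquardt over theta with nested pose solves
    r, _ = stacked_residuals(theta, weights, q_warm)
    cost = float(r @ r)
    history = [cost]
    lam = 1e-3
    converged = False
    step_mm = 1.0  # finite-difference step for hjw (mm)
    step_log = 1e-4
    for _ in range(max_iter):
        # Jacobian wrt theta holding inner poses fixed (envelope approximation)
        frozen_warm = [q.copy() for q in q_warm]
        J = np.empty((len(r), len(theta)))
        for i in range(len(theta)):
            d = step_mm if (free_hjw and i == 3) else step_log
            th = theta.copy()
            th[i] += d
            rp, _ = stacked_residuals(th, weights, [q.copy() for q in frozen_warm])
            J[:, i] = (rp - r) / d
        g = J.T @ r
        H = J.T @ J
        accepted = False
        for _try in range(8):
            delta = np.linalg.solve(H + lam * np.diag(np.diag(H) + 1e-12), -g)
            th_new = theta + delta
            if free_hjw:
                th_new[3] = max(th_new[3], 1.0)
            warm_new = [q.copy() for q in q_warm]
            r_new, _ = stacked_residuals(th_new, weights, warm_new)
            cost_new = float(r_new @ r_new)
            if cost_new < cost:
                theta, r, q_warm = th_new, r_new, warm_new
                drop = cost - cost_new
                cost = cost_new
                history.append(cost)
                lam = max(lam / 3.0, 1e-10)
                accepted = True
                break
            lam *= 10.0
        if not accepted:
            converged = True
            break
        if drop <= tol * max(cost, 1e-30):
            converged = True
            break

    scales = {n: float(np.exp(th)) for n, th in zip(scale_names, theta[:3])}
    hjw_c3d = float(theta[3]) if free_hjw else float(model.hjw)
    return ScaleFit(
        length_scales=scales,
        hjw_c3d=hjw_c3d,
        weights=weights,
        objective_history=history,
        converged=converged,
        n_free_params=len(theta),
    )


# ---------------------------------------------------------------------------
# Full-trial pose solve


@dataclass
class KinematicsResult:
    times: np.ndarray  # (T,)
    rate: float
    q: np.ndarray  # (T, 16)
    qd: np.ndarray  # (T, 16) filtered velocities
    qdd: np.ndarray  # (T, 16) filtered accelerations
    joint_angles: np.ndarray  # (T, n_angles) rad
    joint_angle_names: list
    residuals: np.ndarray  # (T, M) mm
    marker_ids: list
    marker_weights: dict
    length_scales: dict
    hjw_c3d: float  # mm
    model: BodyModel  # scaled model actually used
    interpolated: np.ndarray  # (T,) bool, frames with too few markers
    mean_abs_residual_mm: np.ndarray = field(default=None)  # (3,) per lab axis
    mean_abs_residual_bw: np.ndarray = field(default=None)  # (3,) %BW-equivalent


def _euler_yxz(R: np.ndarray) -> tuple[float, float, float]:
    # intrinsic y-x-z factorization: R = Ry(a) Rx(b) Rz(c)
    b = np.arcsin(np.clip(-R[1, 2], -1.0, 1.0))
    a = np.arctan2(R[0, 2], R[2, 2])
    c = np.arctan2(R[1, 0], R[1, 1])
    return a, b, c


def _extract_angles(q: np.ndarray) -> tuple[np.ndarray, list]:
    names, vals = [], []
    for side, s, off in (("l", +1.0, 6), ("r", -1.0, 11)):
        R = _rodrigues(q[off : off + 3])
        a, b, c = _euler_yxz(R)
        names += [f"hip_fe_{side}", f"hip_aa_{side}", f"hip_ie_{side}",
                  f"knee_{side}", f"ankle_{side}"]
        vals += [-a, -s * b, -s * c, q[off + 3], q[off + 4]]
    return np.array(vals), names


def lowpass(x: np.ndarray, fs: float, cutoff: float = 6.0, order: int = 2) -> np.ndarray:
    """Zero-phase Butterworth low-pass along axis 0; identity if fs too low."""
    if fs <= 2.0 * cutoff * 1.05 or len(x) < 12:
        return np.asarray(x, dtype=float)
    b, a = butter(order, cutoff / (fs / 2.0))
    return filtfilt(b, a, x, axis=0)


def solve_frame_kinematics(
    model: BodyModel, markers: list[MarkerTrajectory], fit: ScaleFit
) -> KinematicsResult:
    """Per-frame weighted least-squares pose solve on the scaled model.

    Velocities and accelerations are central differences of low-pass-filtered
    (2nd-order Butterworth, 6 Hz cutoff) coordinate trajectories.  Frames with
    fewer than 3 usable markers on the pelvis are linearly interpolated from
    their neighbours and flagged.
    """
    hjw = fit.hjw_c3d if model.hjw_mode == "C3D" else model.hjw
    scaled = _apply_scales(model, fit.length_scales, hjw)
    fitter = _FrameFitter(scaled, markers, fit.weights)
    T = fitter.T
    rate = markers[0].rate
    qs = np.zeros((T, N_Q))
    resid = np.zeros((T, len(fitter.ids)))
    interp = np.zeros(T, dtype=bool)
    q = fitter.initial_guess()
    for t in range(T):
        w = fitter.frame_weights(t)
        if np.count_nonzero(w > 1e-6) < 3:
            interp[t] = True
            qs[t] = q
            continue
        q, rmm = fitter.solve_frame(t, q)
        qs[t] = q
        resid[t] = rmm
    if interp.any() and not interp.all():
        good = np.flatnonzero(~interp)
        for col in range(N_Q):
            qs[interp, col] = np.interp(np.flatnonzero(interp), good, qs[good, col])

    qf = lowpass(qs, rate)
    times = np.arange(T) / rate
    qd = np.gradient(qf, times, axis=0)
    qdd = np.gradient(qd, times, axis=0)
    angles = np.zeros((T, 10))
    for t in range(T):
        angles[t], names = _extract_angles(qs[t])

    # residual summary per lab axis (valid frames only)
    pred_err = []
    for t in np.flatnonzero(~interp):
        pred, _ = fitter._fk_jac(qs[t], want_jac=False)
        err = pred - fitter.meas_m[t]
        pred_err.append(np.abs(err[fitter.validity[t]]))
    if pred_err:
        mean_abs_mm = 1000.0 * np.concatenate(pred_err).mean(axis=0)
    else:
        mean_abs_mm = np.full(3, np.nan)
    bw = 100.0 * _MARKER_STIFFNESS_N_PER_MM * mean_abs_mm / (scaled.mass * 9.81)

    return KinematicsResult(
        times=times,
        rate=rate,
        q=qs,
        qd=qd,
        qdd=qdd,
        joint_angles=angles,
        joint_angle_names=names,
        residuals=resid,
        marker_ids=list(fitter.ids),
        marker_weights=dict(fit.weights),
        length_scales=dict(fit.length_scales),
        hjw_c3d=fit.hjw_c3d,
        model=scaled,
        interpolated=interp,
        mean_abs_residual_mm=mean_abs_mm,
        mean_abs_residual_bw=bw,
    )


# ---------------------------------------------------------------------------
# CSV dialect: time_s, marker_id, x_mm, y_mm, z_mm, valid


def save_markers(markers: list[MarkerTrajectory], path) -> None:
    rows = []
    for m in markers:
        t = np.arange(len(m.positions)) / m.rate
        for i in range(len(m.positions)):
            rows.append(
                (t[i], m.marker_id, m.positions[i, 0], m.positions[i, 1],
                 m.positions[i, 2], int(m.validity[i]))
            )
    pd.DataFrame(rows, columns=["time_s", "marker_id", "x_mm", "y_mm", "z_mm", "valid"]).to_csv(
        path, index=False
    )


def load_markers(path) -> list[MarkerTrajectory]:
    df = pd.read_csv(path)
    out = []
    for mid, grp in df.groupby("marker_id", sort=False):
        grp = grp.sort_values("time_s")
        dt = np.diff(grp["time_s"].to_numpy())
        rate = 1.0 / np.median(dt)
        out.append(
            MarkerTrajectory(
                marker_id=str(mid),
                positions=grp[["x_mm", "y_mm", "z_mm"]].to_numpy(),
                rate=float(rate),
                validity=grp["valid"].to_numpy().astype(bool),
            )
        )
    return out
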