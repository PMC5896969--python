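"""Validation metric suite for simulated vs. measured hip joint forces.

Both force series are expressed on a common 0-100% motion-cycle grid in
percent body weight (%BW) in the femoral frame of the telemetry database
("OrthoLoad frame"): components F_ML (medial positive, left sides mirrored),
F_PA (anterior positive) and F_IS (superior positive); during stance the
contact force on the femoral head is medial, posterior and inferior, i.e.
F_ML > 0, F_PA < 0, F_IS < 0.

Metrics: percentage deviation and cohort MAPE of the peak-force-phase (PFP)
resultant; angular deviations (MAD) of the PFP mean force vector in the three
anatomical planes and in 3D; per-component RMSE; squared Pearson correlation
with slope/intercept; Bland-Altman with nonparametric limits of agreement
median(d) +/- 1.45*IQR(d); Kolmogorov-Smirnov normality and Mann-Whitney U
tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats
from scipy.signal import find_peaks

__all__ = [
    "ForceSeries",
    "PfpWindow",
    "SubjectMetrics",
    "to_orthoload_frame",
    "normalize_bw",
    "resample_cycle",
    "detect_pfp",
    "pd_pfp",
    "mape_pfp",
    "mad_pfp",
    "rmse_components",
    "mae_components",
    "correlate",
    "bland_altman",
    "nonparam_tests",
    "compare_series",
    "load_force_series",
    "save_force_series",
]

COMPONENTS = ("ML", "PA", "IS")
LOA_IQR_FACTOR = 1.45
ALPHA = 0.05


@dataclass
class ForceSeries:
    """A 3-component hip force over the motion cycle.

    In frame ``"ISB_femur"`` the columns of ``f`` are the raw femur-frame
    components (x anterior, y left, z superior); in ``"OrthoLoad_femur"``
    they are (F_ML, F_PA, F_IS) with the medial-positive convention shared by
    both sides.
    """

    cycle: np.ndarray  # (n,) % of motion cycle, strictly increasing
    f: np.ndarray  # (n, 3) %BW
    frame: str  # "ISB_femur" | "OrthoLoad_femur"
    side: str  # "L" | "R"
    subject_id: str = ""
    activity: str = ""

    def __post_init__(self):
        self.cycle = np.asarray(self.cycle, dtype=float)
        self.f = np.asarray(self.f, dtype=float)
        if np.any(np.diff(self.cycle) <= 0):
            raise ValueError("cycle grid must be strictly increasing")
        if self.f.shape != (len(self.cycle), 3):
            raise ValueError("f must be (n, 3)")

    @property
    def resultant(self) -> np.ndarray:
        return np.linalg.norm(self.f, axis=1)


@dataclass(frozen=True)
class PfpWindow:
    start_pct: float
    end_pct: float

    def __post_init__(self):
        if not (0.0 <= self.start_pct < self.end_pct <= 100.0):
            raise ValueError(f"invalid PFP window [{self.start_pct}, {self.end_pct}]")

    def mask(self, cycle: np.ndarray) -> np.ndarray:
        return (cycle >= self.start_pct - 1e-9) & (cycle <= self.end_pct + 1e-9)


def normalize_bw(force_n, mass_kg: float):
    """Normalize forces (N) by body weight: 100 * F / (m g)."""
    if mass_kg <= 0:
        raise ValueError("mass must be positive")
    return 100.0 * np.asarray(force_n, dtype=float) / (mass_kg * 9.81)


# Default orientation offset between the mechanical-axis (ISB) femur frame and
# the implant-stem frame of the telemetry database: the stem/shaft axis is
# tilted by the neck-shaft obliquity in the frontal plane (adduction-ward) and
# slightly in the sagittal plane.
STEM_FRONTAL_DEG = 15.0
STEM_SAGITTAL_DEG = 5.0


def default_stem_rotation(side: str) -> np.ndarray:
    """ISB-femur -> telemetry-femur axis rotation for one side."""
    s = +1.0 if side == "L" else -1.0
    a = np.radians(-s * STEM_FRONTAL_DEG)
    b = np.radians(STEM_SAGITTAL_DEG)
    ca, sa, cb, sb = np.cos(a), np.sin(a), np.cos(b), np.sin(b)
    rx = np.array([[1, 0, 0], [0, ca, -sa], [0, sa, ca]])
    ry = np.array([[cb, 0, sb], [0, 1, 0], [-sb, 0, cb]])
    return rx @ ry


def to_orthoload_frame(
    series: ForceSeries, rotation: np.ndarray | None = None, side: str | None = None
) -> ForceSeries:
    """Rotate an ISB-femur series into the telemetry femoral frame.

    ``rotation`` is the fixed 3x3 frame rotation (default: the stem-obliquity
    rotation of :func:`default_stem_rotation`, under which the stance-phase
    force is medial, posterior and inferior).  Left-side series are mirrored
    in ML so both sides share F_ML > 0 = medial.  The resultant is preserved
    exactly.
    """
    if series.frame != "ISB_femur":
        raise ValueError(f"expected ISB_femur input, got {series.frame}")
    side = side or series.side
    R = default_stem_rotation(side) if rotation is None else np.asarray(rotation, dtype=float)
    fr = series.f @ R.T  # rotated, still (x ant, y left, z sup)
    s = +1.0 if side == "L" else -1.0
    ml = -s * fr[:, 1]  # medial positive on both sides
    pa = fr[:, 0]  # anterior positive
    is_ = fr[:, 2]  # superior positive
    return replace(series, f=np.column_stack([ml, pa, is_]), frame="OrthoLoad_femur", side=side)


def resample_cycle(series: ForceSeries, n: int = 101) -> ForceSeries:
    """Linear interpolation onto a uniform 0-100% grid; endpoints preserved."""
    if len(series.cycle) < 2:
        raise ValueError("need at least 2 samples")
    grid = np.linspace(0.0, 100.0, n)
    src = 100.0 * (series.cycle - series.cycle[0]) / (series.cycle[-1] - series.cycle[0])
    f = np.column_stack([np.interp(grid, src, series.f[:, i]) for i in range(3)])
    return replace(series, cycle=grid, f=f)


# ---------------------------------------------------------------------------
# Peak force phase


def detect_pfp(series: ForceSeries, activity: str, events: dict | None = None) -> PfpWindow:
    """Locate the peak-force-phase window on the resultant force.

    One-leg stance: restrict to the central [25%, 75%] of the cycle (lifting
    and lowering of the leg omitted) and take the longest contiguous run with
    resultant >= 75% of the maximum.  Level walking: the local maximum of the
    resultant nearest the contralateral toe-off event, +/- 2.5% of the cycle.
    """
    r = series.resultant
    c = series.cycle
    if activity == "one_leg_stance":
        mask = (c >= 25.0) & (c <= 75.0)
        if not mask.any():
            raise ValueError("no samples in the central cycle window")
        thr = 0.75 * r[mask].max()
        above = mask & (r >= thr)
        if not above.any():
            raise ValueError("empty plateau: no samples above threshold in [25, 75]%")
        # longest contiguous run
        idx = np.flatnonzero(above)
        splits = np.split(idx, np.flatnonzero(np.diff(idx) > 1) + 1)
        run = max(splits, key=len)
        return PfpWindow(float(c[run[0]]), float(c[run[-1]]))
    if activity == "level_walking":
        if not events or "contralateral_toe_off" not in events:
            raise ValueError("level walking PFP requires the contralateral toe-off event")
        peaks, _ = find_peaks(r)
        if len(peaks) == 0:
            raise ValueError("no local maximum in the resultant force")
        cto = float(events["contralateral_toe_off"])
        peak = peaks[np.argmin(np.abs(c[peaks] - cto))]
        return PfpWindow(max(c[peak] - 2.5, 0.0), min(c[peak] + 2.5, 100.0))
    raise ValueError(f"unknown activity {activity!r}")


def pd_pfp(sim: ForceSeries, vivo: ForceSeries, window: PfpWindow) -> float:
    """Percentage deviation of the window-averaged resultant (sim vs vivo)."""
    m = window.mask(vivo.cycle)
    ref = vivo.resultant[m].mean()
    if ref == 0:
        raise ValueError("in vivo PFP mean resultant is zero")
    return 100.0 * (sim.resultant[window.mask(sim.cycle)].mean() - ref) / ref


def mape_pfp(pds) -> float:
    """Cohort mean absolute percentage error over per-subject deviations."""
    return float(np.mean(np.abs(np.asarray(pds, dtype=float))))


@dataclass
class AngularDeviation:
    fe: float  # sagittal (PA-IS) plane, deg
    aa: float  # frontal (ML-IS) plane, deg
    ie: float  # transverse (ML-PA) plane, deg
    d3: float  # full 3D angle, deg
    degenerate: bool = False


def _plane_angle(u2: np.ndarray, v2: np.ndarray) -> tuple[float, bool]:
    nu, nv = np.linalg.norm(u2), np.linalg.norm(v2)
    if nu < 1e-12 or nv < 1e-12:
        return 0.0, True
    cosang = np.clip(np.dot(u2, v2) / (nu * nv), -1.0, 1.0)
    return float(np.degrees(np.arccos(cosang))), False


def mad_pfp(sim: ForceSeries, vivo: ForceSeries, window: PfpWindow) -> AngularDeviation:
    """Angular deviation between the window-mean force vectors.

    3D is the full angle; FE/AA/IE are angles between the projections onto the
    sagittal (PA-IS), frontal (ML-IS) and transverse (ML-PA) planes.  All
    values are absolute (>= 0).
    """
    u = sim.f[window.mask(sim.cycle)].mean(axis=0)
    v = vivo.f[window.mask(vivo.cycle)].mean(axis=0)
    if not window.mask(sim.cycle).any():
        raise ValueError("empty PFP window")
    d3, deg3 = _plane_angle(u, v)
    fe, d1 = _plane_angle(u[[1, 2]], v[[1, 2]])
    aa, d2 = _plane_angle(u[[0, 2]], v[[0, 2]])
    ie, d4 = _plane_angle(u[[0, 1]], v[[0, 1]])
    return AngularDeviation(fe, aa, ie, d3, degenerate=deg3 or d1 or d2 or d4)


# ---------------------------------------------------------------------------
# Full-cycle metrics


def _check_grids(sim: ForceSeries, vivo: ForceSeries) -> None:
    if len(sim.cycle) != len(vivo.cycle):
        raise ValueError("series length mismatch")


def rmse_components(sim: ForceSeries, vivo: ForceSeries) -> dict:
    """Pointwise RMSE per component and on the resultant, %BW."""
    _check_grids(sim, vivo)
    out = {
        comp: float(np.sqrt(np.mean((sim.f[:, i] - vivo.f[:, i]) ** 2)))
        for i, comp in enumerate(COMPONENTS)
    }
    out["R"] = float(np.sqrt(np.mean((sim.resultant - vivo.resultant) ** 2)))
    return out


def mae_components(sim: ForceSeries, vivo: ForceSeries) -> dict:
    """Pointwise mean absolute error per component and resultant, %BW."""
    _check_grids(sim, vivo)
    out = {
        comp: float(np.mean(np.abs(sim.f[:, i] - vivo.f[:, i])))
        for i, comp in enumerate(COMPONENTS)
    }
    out["R"] = float(np.mean(np.abs(sim.resultant - vivo.resultant)))
    return out


def correlate(sim_vals: np.ndarray, vivo_vals: np.ndarray) -> dict:
    """Pearson r^2, two-sided p, and regression slope/intercept (sim on vivo)."""
    sim_vals = np.asarray(sim_vals, dtype=float).ravel()
    vivo_vals = np.asarray(vivo_vals, dtype=float).ravel()
    if len(sim_vals) < 3:
        raise ValueError("need at least 3 paired samples")
    if np.std(vivo_vals) < 1e-12 or np.std(sim_vals) < 1e-12:
        return {"r2": np.nan, "p": np.nan, "slope": np.nan, "intercept": np.nan,
                "significant": False, "degenerate": True}
    res = stats.linregress(vivo_vals, sim_vals)
    return {
        "r2": float(res.rvalue**2),
        "p": float(res.pvalue),
        "slope": float(res.slope),
        "intercept": float(res.intercept),
        "significant": bool(res.pvalue < ALPHA),
        "degenerate": False,
    }


def bland_altman(sim_vals: np.ndarray, vivo_vals: np.ndarray) -> dict:
    """Nonparametric Bland-Altman: median difference and LOA = median +/- 1.45*IQR.

    Quartiles use linear interpolation of the order statistics.
    """
    d = np.asarray(sim_vals, dtype=float).ravel() - np.asarray(vivo_vals, dtype=float).ravel()
    if d.size == 0:
        raise ValueError("empty input")
    med = float(np.median(d))
    q1, q3 = np.percentile(d, [25.0, 75.0])
    iqr = float(q3 - q1)
    return {
        "median_diff": med,
        "loa_low": med - LOA_IQR_FACTOR * iqr,
        "loa_high": med + LOA_IQR_FACTOR * iqr,
        "iqr": iqr,
    }


def nonparam_tests(sim_vals: np.ndarray, vivo_vals: np.ndarray) -> dict:
    """Normality of differences (KS vs fitted normal) and Mann-Whitney U.

    The Mann-Whitney U test is two-sided on the pooled simulated vs measured
    samples; alpha = 0.05 is reported alongside the p-values.
    """
    sim_vals = np.asarray(sim_vals, dtype=float).ravel()
    vivo_vals = np.asarray(vivo_vals, dtype=float).ravel()
    if len(sim_vals) < 8 or len(vivo_vals) < 8:
        raise ValueError("need at least 8 samples")
    d = sim_vals - vivo_vals if len(sim_vals) == len(vivo_vals) else sim_vals
    sd = d.std(ddof=1)
    if sd < 1e-12:
        ks_p = 1.0
    else:
        ks_p = float(stats.kstest(d, "norm", args=(d.mean(), sd)).pvalue)
    mw = stats.mannwhitneyu(
        sim_vals, vivo_vals, alternative="two-sided", use_continuity=False,
        method="asymptotic",
    )
    return {"ks_p": ks_p, "mannwhitney_p": float(mw.pvalue), "alpha": ALPHA}


# ---------------------------------------------------------------------------
# Per-subject comparison bundle


@dataclass
class SubjectMetrics:
    subject_id: str
    activity: str
    window: PfpWindow
    pd_pfp: float
    mad: AngularDeviation
    rmse: dict
    mae: dict
    pfp_resultant_sim: float
    pfp_resultant_vivo: float
    sim: ForceSeries = field(repr=False, default=None)
    vivo: ForceSeries = field(repr=False, default=None)


def compare_series(
    sim: ForceSeries, vivo: ForceSeries, activity: str, events: dict | None = None
) -> SubjectMetrics:
    """All per-subject error metrics; the PFP is located on the in vivo data."""
    _check_grids(sim, vivo)
    window = detect_pfp(vivo, activity, events)
    mwin = window.mask(vivo.cycle)
    return SubjectMetrics(
        subject_id=sim.subject_id or vivo.subject_id,
        activity=activity,
        window=window,
        pd_pfp=pd_pfp(sim, vivo, window),
        mad=mad_pfp(sim, vivo, window),
        rmse=rmse_components(sim, vivo),
        mae=mae_components(sim, vivo),
        pfp_resultant_sim=float(sim.resultant[window.mask(sim.cycle)].mean()),
        pfp_resultant_vivo=float(vivo.resultant[mwin].mean()),
        sim=sim,
        vivo=vivo,
    )


# ---------------------------------------------------------------------------
# CSV dialect: cycle_pct, F_ML_pctBW, F_PA_pctBW, F_IS_pctBW, side, subject_id, activity


def save_force_series(series: ForceSeries, path) -> None:
    if series.frame != "OrthoLoad_femur":
        raise ValueError("only OrthoLoad-frame series are exchanged as CSV")
    pd.DataFrame(
        {
            "cycle_pct": series.cycle,
            "F_ML_pctBW": series.f[:, 0],
            "F_PA_pctBW": series.f[:, 1],
            "F_IS_pctBW": series.f[:, 2],
            "side": series.side,
            "subject_id": series.subject_id,
            "activity": series.activity,
        }
    ).to_csv(path, index=False)


def load_force_series(path) -> ForceSeries:
    df = pd.read_csv(path)
    return ForceSeries(
        cycle=df["cycle_pct"].to_numpy(),
        f=df[["F_ML_pctBW", "F_PA_pctBW", "F_IS_pctBW"]].to_numpy(),
        frame="OrthoLoad_femur",
        side=str(df["side"].iloc[0]),
        subject_id=str(df["subject_id"].iloc[0]),
        activity=str(df["activity"].iloc[0]),
    )
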