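"""Factorial parameter study, strength sweep and cohort reporting.

Four model parameters are crossed: hip-joint-width source (marker-optimized
C3D vs frozen CT), muscle strength (40 vs 90 N/cm^2), recruitment criterion
(third-power polynomial PN vs strict min/max MM) and muscle model (simple vs
Hill).  Each (combo, subject, activity) cell runs the full two-step pipeline
against the pseudo-in-vivo measurement; infeasible recruitment fails the run
and excludes it from aggregation, mirroring how unsuccessful simulations are
excluded from a validation study.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .dynamics import ComboSpec, TrialDynamicsError, hip_reaction, net_joint_loads
from .kinematics import optimize_parameters, solve_frame_kinematics
from .metrics import (
    SubjectMetrics,
    compare_series,
    correlate,
    normalize_bw,
    resample_cycle,
    to_orthoload_frame,
)
from .metrics import ForceSeries
from .model import build_reference_model, set_hjw
from .synthetic import InVivoSeries, TrialData

__all__ = [
    "RunRecord",
    "SweepResult",
    "default_combos",
    "run_combo",
    "factorial_sweep",
    "strength_sweep",
    "aggregate_report",
    "build_subject_table",
]


def default_combos() -> list[ComboSpec]:
    """The 16 cells of the factorial design."""
    return [
        ComboSpec(hjw_mode=h, sigma=s, recruitment=r, muscle_model=m)
        for h, s, r, m in itertools.product(
            ("C3D", "CT"), (40.0, 90.0), ("PN", "MM"), ("simple", "hill")
        )
    ]


@dataclass
class RunRecord:
    subject_id: str
    activity: str
    combo: ComboSpec
    status: str  # "ok" | "failed"
    reason: str = ""
    sim: ForceSeries | None = None
    metrics: SubjectMetrics | None = None
    hjw_c3d: float = np.nan
    max_activation: float = np.nan


def run_combo(
    trial: TrialData,
    vivo: InVivoSeries,
    combo: ComboSpec,
    kin_cache: dict | None = None,
    bounds_enabled: bool = True,
) -> RunRecord:
    """Run kinematics -> dynamics -> validation for one trial and one combo.

    The kinematic solution depends only on the trial and the HJW mode, so it
    is shared across combos through ``kin_cache``.
    """
    if vivo.series.subject_id != trial.anthro.subject_id or (
        vivo.series.activity != trial.activity
    ):
        raise ValueError("trial and in vivo series must share subject and activity")
    anthro = trial.anthro
    key = (anthro.subject_id, trial.activity, trial.seed, combo.hjw_mode)
    kin = None if kin_cache is None else kin_cache.get(key)
    if kin is None:
        model = build_reference_model(anthro)
        if combo.hjw_mode == "C3D":
            model = set_hjw(model, model.hjw, "C3D")
        fit = optimize_parameters(model, trial.markers)
        kin = solve_frame_kinematics(model, trial.markers, fit)
        if kin_cache is not None:
            kin_cache[key] = kin
    loads = net_joint_loads(kin.model, kin, trial.grf, side=anthro.side)
    try:
        hip = hip_reaction(kin.model, kin, loads, combo, bounds_enabled=bounds_enabled)
    except TrialDynamicsError as exc:
        return RunRecord(
            subject_id=anthro.subject_id,
            activity=trial.activity,
            combo=combo,
            status="failed",
            reason=str(exc),
            hjw_c3d=kin.hjw_c3d,
        )
    series = ForceSeries(
        cycle=100.0 * kin.times / kin.times[-1],
        f=normalize_bw(hip.force_isb, anthro.mass),
        frame="ISB_femur",
        side=anthro.side,
        subject_id=anthro.subject_id,
        activity=trial.activity,
    )
    sim = to_orthoload_frame(resample_cycle(series, len(vivo.series.cycle)))
    metrics = compare_series(sim, vivo.series, trial.activity, trial.events or None)
    return RunRecord(
        subject_id=anthro.subject_id,
        activity=trial.activity,
        combo=combo,
        status="ok",
        sim=sim,
        metrics=metrics,
        hjw_c3d=kin.hjw_c3d,
        max_activation=hip.max_activation,
    )


@dataclass
class SweepResult:
    rows: pd.DataFrame  # one row per (activity, combo)
    records: list = field(repr=False, default_factory=list)

    @property
    def failures(self) -> list:
        return [r for r in self.records if r.status == "failed"]


def _pooled_stats(records: list[RunRecord]) -> dict:
    """Cohort statistics pooling all subjects' resampled cycles."""
    comp_idx = {"ML": 0, "PA": 1, "IS": 2}
    sim_all = np.vstack([r.sim.f for r in records])
    vivo_all = np.vstack([r.metrics.vivo.f for r in records])
    sim_r = np.concatenate([r.sim.resultant for r in records])
    vivo_r = np.concatenate([r.metrics.vivo.resultant for r in records])
    out = {}
    for comp, i in comp_idx.items():
        out[f"rmse_{comp}"] = float(np.sqrt(np.mean((sim_all[:, i] - vivo_all[:, i]) ** 2)))
        c = correlate(sim_all[:, i], vivo_all[:, i])
        out[f"r2_{comp}"] = c["r2"]
        out[f"r2_{comp}_sig"] = c["significant"]
    out["rmse_R"] = float(np.sqrt(np.mean((sim_r - vivo_r) ** 2)))
    c = correlate(sim_r, vivo_r)
    out["r2_R"] = c["r2"]
    out["r2_R_sig"] = c["significant"]
    return out


def _aggregate_combo(records: list[RunRecord], n_requested: int) -> dict:
    ok = [r for r in records if r.status == "ok"]
    row = {"n_requested": n_requested, "n_success": len(ok)}
    if not ok:
        return row
    pds = np.array([r.metrics.pd_pfp for r in ok])
    row["mape_pfp"] = float(np.mean(np.abs(pds)))
    row["mape_pfp_sd"] = float(np.std(np.abs(pds), ddof=1)) if len(pds) > 1 else 0.0
    for plane in ("fe", "aa", "ie", "d3"):
        vals = np.array([getattr(r.metrics.mad, plane) for r in ok])
        row[f"mad_{plane}"] = float(vals.mean())
        row[f"mad_{plane}_sd"] = float(vals.std(ddof=1)) if len(vals) > 1 else 0.0
    row.update(_pooled_stats(ok))
    row["pfp_vivo_mean"] = float(np.mean([r.metrics.pfp_resultant_vivo for r in ok]))
    row["pfp_sim_mean"] = float(np.mean([r.metrics.pfp_resultant_sim for r in ok]))
    return row


def factorial_sweep(
    pairs: list[tuple[TrialData, InVivoSeries]],
    combos: list[ComboSpec] | None = None,
) -> SweepResult:
    """Run every combo for every (trial, in vivo) pair and aggregate.

    The total number of runs is |combos| * |pairs|; per-combo aggregation uses
    successful runs only, and the run order (and hence the result) is
    deterministic.
    """
    if not pairs:
        raise ValueError("cohort is empty")
    combos = default_combos() if combos is None else combos
    kin_cache: dict = {}
    records = []
    for trial, vivo in pairs:
        for combo in combos:
            records.append(run_combo(trial, vivo, combo, kin_cache))
    rows = []
    activities = sorted({t.activity for t, _ in pairs})
    for activity in activities:
        for combo in combos:
            sel = [
                r
                for r in records
                if r.activity == activity and r.combo == combo
            ]
            row = {
                "activity": activity,
                "hjw_mode": combo.hjw_mode,
                "sigma": combo.sigma,
                "recruitment": combo.recruitment,
                "muscle_model": combo.muscle_model,
            }
            row.update(_aggregate_combo(sel, len(sel)))
            rows.append(row)
    return SweepResult(rows=pd.DataFrame(rows), records=records)


def strength_sweep(
    pairs: list[tuple[TrialData, InVivoSeries]],
    sigmas: list[float],
    hjw_mode: str = "CT",
    recruitment: str = "PN",
    muscle_model: str = "simple",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Mean absolute resultant error (MAE_R) as muscle strength is reduced.

    Runs the base combo at each sigma (ascending); reports per-sigma MAE_R
    over the full cycle, the share of runs with saturated muscles, and the
    Mann-Whitney p-value between consecutive sigma levels.
    """
    if list(sigmas) != sorted(sigmas):
        raise ValueError("sigmas must be sorted ascending")
    kin_cache: dict = {}
    per_run = []
    for sigma in sigmas:
        combo = ComboSpec(
            hjw_mode=hjw_mode, sigma=float(sigma), recruitment=recruitment,
            muscle_model=muscle_model,
        )
        for trial, vivo in pairs:
            rec = run_combo(trial, vivo, combo, kin_cache)
            per_run.append(
                {
                    "sigma": float(sigma),
                    "subject_id": rec.subject_id,
                    "activity": rec.activity,
                    "status": rec.status,
                    "mae_R": rec.metrics.mae["R"] if rec.status == "ok" else np.nan,
                    "max_activation": rec.max_activation,
                }
            )
    runs = pd.DataFrame(per_run)
    rows = []
    prev_vals = None
    for sigma in sigmas:
        grp = runs[(runs.sigma == sigma) & (runs.status == "ok")]
        vals = grp.mae_R.to_numpy()
        p = np.nan
        if prev_vals is not None and len(vals) and len(prev_vals):
            p = float(stats.mannwhitneyu(prev_vals, vals, alternative="two-sided").pvalue)
        rows.append(
            {
                "sigma": float(sigma),
                "n_success": int(len(grp)),
                "n_failed": int((runs.sigma == sigma).sum() - len(grp)),
                "mae_R_mean": float(vals.mean()) if len(vals) else np.nan,
                "mae_R_sd": float(vals.std(ddof=1)) if len(vals) > 1 else np.nan,
                "saturated_share": float((grp.max_activation >= 1.0 - 1e-6).mean())
                if len(grp)
                else np.nan,
                "p_vs_previous": p,
            }
        )
        prev_vals = vals
    return pd.DataFrame(rows), runs


# ---------------------------------------------------------------------------
# Per-subject full-cycle reporting


def build_subject_table(records: list[RunRecord]) -> pd.DataFrame:
    """Per-subject full-cycle summary of one combo's successful runs.

    Long format: activity, subject_id, component (ML/PA/IS/R), source
    (AB = simulated, OL = in vivo, MAE), mean and sd in %BW over the cycle.
    """
    rows = []
    for r in records:
        if r.status != "ok":
            continue
        m = r.metrics
        for i, comp in enumerate(("ML", "PA", "IS")):
            for source, vals in (
                ("AB", m.sim.f[:, i]),
                ("OL", m.vivo.f[:, i]),
                ("MAE", np.abs(m.sim.f[:, i] - m.vivo.f[:, i])),
            ):
                rows.append(
                    {
                        "activity": r.activity,
                        "subject_id": r.subject_id,
                        "component": comp,
                        "source": source,
                        "mean": float(np.mean(vals)),
                        "sd": float(np.std(vals, ddof=1)),
                    }
                )
        for source, vals in (
            ("AB", m.sim.resultant),
            ("OL", m.vivo.resultant),
            ("MAE", np.abs(m.sim.resultant - m.vivo.resultant)),
        ):
            rows.append(
                {
                    "activity": r.activity,
                    "subject_id": r.subject_id,
                    "component": "R",
                    "source": source,
                    "mean": float(np.mean(vals)),
                    "sd": float(np.std(vals, ddof=1)),
                }
            )
    return pd.DataFrame(rows)


def aggregate_report(per_subject: pd.DataFrame, mae_flag_bw: float = 50.0) -> pd.DataFrame:
    """Cohort aggregation of a per-subject table.

    The cohort mean is the mean over pooled samples, which with equal samples
    per subject equals the mean of the subject means; MAE cells above
    ``mae_flag_bw`` %BW are flagged.  Missing subjects (incomplete groups)
    are flagged as gaps.
    """
    required = {"activity", "subject_id", "component", "source", "mean"}
    if not required.issubset(per_subject.columns):
        raise ValueError(f"per-subject table needs columns {sorted(required)}")
    n_subjects = per_subject.subject_id.nunique()
    rows = []
    for (activity, comp, source), grp in per_subject.groupby(
        ["activity", "component", "source"], sort=False
    ):
        rows.append(
            {
                "activity": activity,
                "component": comp,
                "source": source,
                "cohort_mean": float(grp["mean"].mean()),
                "cohort_sd": float(grp["mean"].std(ddof=1)) if len(grp) > 1 else 0.0,
                "n_subjects": int(len(grp)),
                "gap": bool(len(grp) < n_subjects),
                "flagged_subjects": sorted(
                    grp.loc[grp["mean"] > mae_flag_bw, "subject_id"].tolist()
                )
                if source == "MAE"
                else [],
            }
        )
    return pd.DataFrame(rows)
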