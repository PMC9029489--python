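"""End-to-end study orchestration: derive, correct, align, segment, score.

Stages run in a fixed order for every trial:

1. inertial joint-angle derivation (sensor-to-segment alignment, relative
   orientation, Euler decomposition, sign flips, initialization to the
   reference's starting values);
2. convention corrections (gimbal/anatomical-limit screening for the IMU,
   +15 deg device-offset correction for the markerless elbow);
3. markerless resampling to the common 100 Hz rate and spike-based alignment;
4. windowing to the last object-interaction segment;
5. agreement metrics (RMSE, bias) per test system against the reference,
   range-of-motion per system, ICC(3,1) per system/DOF/task over the
   subjects x trials RoM matrix, and boxplot distribution summaries.

Per-trial failures are logged and skipped, never silently dropped; the run
aborts if more than half the trials fail.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd

from . import kinematics as kin
from . import metrics, synchronize
from .errors import MocapError
from .segment import last_segment_window
from .trial import TrialRecord


@dataclass(frozen=True)
class AnalysisSettings:
    """Tunable pipeline parameters (defaults follow the study conventions)."""

    target_rate: float = 100.0
    sync_channel: tuple[str, str] = synchronize.SYNC_CHANNEL
    spike_threshold_deg_s: float = synchronize.DEFAULT_SPIKE_THRESHOLD
    level_match: str = "replace"
    gimbal_tol_deg: float = 2.0
    exclusion_threshold: float = 0.05
    elbow_offset_deg: float = 15.0
    icc_alpha: float = 0.05
    max_failure_fraction: float = 0.5


@dataclass
class StudyReport:
    """Tables produced by a study run (tidy DataFrames + logs)."""

    agreement: pd.DataFrame  # one row per trial x system x analyzed DOF
    rom: pd.DataFrame  # one row per trial x system x analyzed DOF
    icc: pd.DataFrame  # one row per system x DOF x task
    summary: pd.DataFrame  # boxplot summary per system x DOF x task
    exclusions: pd.DataFrame  # gimbal-anomaly removals
    sync_log: pd.DataFrame  # per-trial detected indices and shifts
    failures: list[dict] = field(default_factory=list)

    def to_json(self) -> str:
        """Deterministic machine-readable mirror of all tables."""
        payload = {
            name: getattr(self, name).to_dict(orient="records")
            for name in ("agreement", "rom", "icc", "summary", "exclusions", "sync_log")
        }
        payload["failures"] = self.failures
        return json.dumps(payload, sort_keys=True, indent=1, default=float)

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        for name in ("agreement", "rom", "icc", "summary", "exclusions", "sync_log"):
            getattr(self, name).to_csv(outdir / f"{name}.csv", index=False)
        (outdir / "report.json").write_text(self.to_json())


def analyze_trial(
    trial: TrialRecord,
    settings: AnalysisSettings = AnalysisSettings(),
    joints: dict | None = None,
    placements: dict | None = None,
) -> tuple[TrialRecord, synchronize.SyncResult, list[dict]]:
    """Run stages 1-4 on one trial; returns the windowed trial and logs."""
    joints = joints or kin.default_joint_definitions()
    placements = placements or kin.default_placements()
    exclusions: list[dict] = []

    # 1. inertial joint angles
    if trial.sensors and "imu" not in trial.series:
        aligned_sensors = {
            sid: kin.align_sensor_to_segment(s, placements[sid])
            for sid, s in trial.sensors.items()
        }
        imu: dict = {}
        ref = trial.series["reference"]
        for joint, jd in joints.items():
            ref_initial = [
                ref[(joint, d)].values[0] if (joint, d) in ref else 0.0
                for d in jd.dof_labels
            ]
            derived = kin.derive_joint_angles(
                aligned_sensors[jd.parent_sensor],
                aligned_sensors[jd.child_sensor],
                jd,
                reference_initial=ref_initial,
                gimbal_tol_deg=settings.gimbal_tol_deg,
            )
            for s in derived:
                imu[(joint, s.dof)] = s
        trial.series["imu"] = imu

    # 2. convention corrections
    def correct(system, ch, s):
        joint, dof = ch
        if system == "imu" and joint in joints and dof in joints[joint].dof_labels:
            s = kin.flag_gimbal_anomalies(
                s, joints[joint].limits_for(dof), settings.exclusion_threshold
            )
            if s.excluded:
                exclusions.append(
                    {
                        "trial_id": trial.trial_id,
                        "system": system,
                        "joint": joint,
                        "dof": dof,
                        "invalid_fraction": float(1.0 - s.quality_mask.mean()),
                    }
                )
        if system == "markerless" and joint == "elbow" and dof == "flexion_extension":
            s = kin.apply_elbow_offset(s, settings.elbow_offset_deg)
        return s

    trial = trial.map_series(correct)

    # 3. resample markerless to the common rate, then spike alignment
    def to_common(system, ch, s):
        if s.rate != settings.target_rate:
            return synchronize.resample_series(s, settings.target_rate)
        return s

    trial = trial.map_series(to_common)
    aligned, sync = synchronize.align_trial(
        trial,
        sync_channel=settings.sync_channel,
        threshold=settings.spike_threshold_deg_s,
        level_match=settings.level_match,
    )

    # 4. last object-interaction window
    windowed = last_segment_window(aligned, aligned.events)
    return windowed, sync, exclusions


def analyze_study(
    trials: list[TrialRecord],
    settings: AnalysisSettings = AnalysisSettings(),
    joints: dict | None = None,
    placements: dict | None = None,
) -> StudyReport:
    """Run the full pipeline over a collection of trials and tabulate results."""
    joints = joints or kin.default_joint_definitions()
    agreement_rows: list[dict] = []
    rom_rows: list[dict] = []
    excl_rows: list[dict] = []
    sync_rows: list[dict] = []
    failures: list[dict] = []

    for trial in trials:
        try:
            windowed, sync, excl = analyze_trial(trial, settings, joints, placements)
        except MocapError as exc:
            failures.append({"trial_id": trial.trial_id, "error": str(exc)})
            continue
        excl_rows.extend(excl)
        sync_rows.append(
            {
                "trial_id": trial.trial_id,
                "threshold_deg_s": sync.threshold,
                **{
                    f"index_{k}": v
                    for k, v in sorted(sync.detected_index_per_system.items())
                },
                **{f"shift_s_{k}": v for k, v in sorted(sync.applied_shift.items())},
            }
        )
        excluded_chs = {(e["system"], e["joint"], e["dof"]) for e in excl}
        ref = windowed.series["reference"]
        for system in windowed.systems():
            for joint, dof in kin.ANALYZED_DOFS:
                ch = (joint, dof)
                if ch not in windowed.series[system] or ch not in ref:
                    continue
                if (system, joint, dof) in excluded_chs:
                    continue
                s = windowed.series[system][ch]
                base = {
                    "subject": windowed.subject,
                    "task": windowed.task,
                    "trial": windowed.trial,
                    "system": system,
                    "joint": joint,
                    "dof": dof,
                }
                rom_rows.append(
                    {**base, "rom_deg": metrics.range_of_motion(s)}
                )
                if system == "reference":
                    continue
                w = metrics.PairedWindow.from_series(s, ref[ch], task=windowed.task)
                agreement_rows.append(
                    {
                        **base,
                        "rmse_deg": metrics.rmse(w),
                        "bias_deg": metrics.bias(w),
                        "n": w.n,
                    }
                )

    if trials and len(failures) > settings.max_failure_fraction * len(trials):
        raise MocapError(
            f"{len(failures)}/{len(trials)} trials failed; aborting "
            f"(first: {failures[0]})"
        )

    agreement = pd.DataFrame(
        agreement_rows,
        columns=[
            "subject", "task", "trial", "system", "joint", "dof",
            "rmse_deg", "bias_deg", "n",
        ],
    )
    rom = pd.DataFrame(
        rom_rows,
        columns=["subject", "task", "trial", "system", "joint", "dof", "rom_deg"],
    )

    icc_rows: list[dict] = []
    if not rom.empty:
        for (system, joint, dof, task), grp in rom.groupby(
            ["system", "joint", "dof", "task"], sort=True
        ):
            mat = grp.pivot_table(
                index="subject", columns="trial", values="rom_deg"
            )
            if mat.isna().any().any() or mat.shape[0] < 2 or mat.shape[1] < 2:
                continue
            res = metrics.icc_3_1(mat.to_numpy(), alpha=settings.icc_alpha)
            icc_rows.append(
                {
                    "system": system,
                    "joint": joint,
                    "dof": dof,
                    "task": task,
                    "icc": res.icc,
                    "ci_low": res.ci_low,
                    "ci_high": res.ci_high,
                    "category": res.category,
                    "degenerate": res.degenerate,
                }
            )
    icc = pd.DataFrame(
        icc_rows,
        columns=[
            "system", "joint", "dof", "task",
            "icc", "ci_low", "ci_high", "category", "degenerate",
        ],
    )

    summary_rows: list[dict] = []
    if not agreement.empty:
        for (system, joint, dof, task), grp in agreement.groupby(
            ["system", "joint", "dof", "task"], sort=True
        ):
            for metric_name in ("rmse_deg", "bias_deg"):
                b = metrics.boxplot_summary(grp[metric_name].to_numpy())
                summary_rows.append(
                    {
                        "system": system,
                        "joint": joint,
                        "dof": dof,
                        "task": task,
                        "metric": metric_name,
                        **{k: v for k, v in asdict(b).items() if k != "outliers"},
                        "n_outliers": len(b.outliers),
                    }
                )
    summary = pd.DataFrame(
        summary_rows,
        columns=[
            "system", "joint", "dof", "task", "metric",
            "median", "q1", "q3", "whisker_low", "whisker_high", "n", "n_outliers",
        ],
    )

    return StudyReport(
        agreement=agreement,
        rom=rom,
        icc=icc,
        summary=summary,
        exclusions=pd.DataFrame(
            excl_rows,
            columns=["trial_id", "system", "joint", "dof", "invalid_fraction"],
        ),
        sync_log=pd.DataFrame(sync_rows),
        failures=failures,
    )


def render_icc_table(report: StudyReport) -> pd.DataFrame:
    """Pivot the ICC table: rows per joint/DOF x task, one column per system.

    Cells are formatted "icc [ci_low, ci_high] (category)", mirroring the
    color-coded reliability table layout.
    """
    if report.icc.empty:
        return pd.DataFrame()
    df = report.icc.copy()
    df["cell"] = [
        f"{r.icc:.2f} [{r.ci_low:.2f}, {r.ci_high:.2f}] ({r.category})"
        for r in df.itertuples()
    ]
    return df.pivot_table(
        index=["joint", "dof", "task"],
        columns="system",
        values="cell",
        aggfunc="first",
    )
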