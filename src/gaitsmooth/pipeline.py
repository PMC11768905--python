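"""End-to-end orchestration: signals → events → strides → metrics → stats.

Everything the CLI does is callable from here, so cohort analyses can be
scripted without shelling out. Exclusion accounting is first-class: every
dropped stride, skipped window and invalid trial is recorded in the trial
result and the run log.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import events as ev
from . import io as gio
from . import smoothness as sm
from . import stats as st
from .config import PipelineConfig
from .errors import InputError

logger = logging.getLogger(__name__)

__all__ = ["TrialResult", "process_trial", "run_pipeline", "detect_trial_events"]


@dataclass
class TrialResult:
    trial: gio.IMUTrial
    events: list[ev.GaitEvent]
    validity: ev.TrialValidity
    temporal: ev.TemporalParams | None
    records: list[sm.SmoothnessRecord] = field(default_factory=list)

    @property
    def valid(self) -> bool:
        return self.validity.valid


def detect_trial_events(trial: gio.IMUTrial, config: PipelineConfig
                        ) -> tuple[list[ev.GaitEvent], dict[str, list[ev.Stride]]]:
    """Detect FO/FS on each available foot sensor and segment into strides."""
    params = ev.DetectionParams(min_separation=config.events.min_separation,
                                prominence_factor=config.events.prominence_factor)
    detected: list[ev.GaitEvent] = []
    strides: dict[str, list[ev.Stride]] = {}
    for loc in (gio.Location.foot_L, gio.Location.foot_R):
        if loc not in trial.sensors:
            continue
        side = loc.side
        fo = ev.detect_foot_off(trial.gyro(loc).y, trial.sample_rate, params)
        fs = ev.detect_foot_strike(trial.accel(loc).y, trial.sample_rate, params)
        detected += [ev.GaitEvent(ev.EventType.foot_off, side, float(t)) for t in fo]
        detected += [ev.GaitEvent(ev.EventType.foot_strike, side, float(t)) for t in fs]
        strides[side] = ev.segment_strides(fo, fs, side,
                                           anchor=config.events.stride_anchor)
    detected.sort(key=lambda e: e.time)
    return detected, strides


def process_trial(trial: gio.IMUTrial, config: PipelineConfig,
                  preprocess: bool = True) -> TrialResult:
    """Run the per-trial pipeline; invalid trials yield a flagged result."""
    if not trial.has_foot_sensor():
        raise InputError("trial has no foot sensor; events cannot be detected")
    if preprocess:
        trial = gio.preprocess_trial(trial, config.io.target_rate,
                                     config.io.filter_order, config.io.filter_fc)
    detected, strides = detect_trial_events(trial, config)
    validity = ev.apply_trial_rules(strides, config.events.min_strides)
    if not validity.valid:
        logger.warning("trial %s/%s invalid: %s", trial.subject_id, trial.trial_id,
                       validity.reason)
        return TrialResult(trial, detected, validity, None)
    temporal = ev.temporal_params(validity.strides)
    sp = sm.SparcParams(fc_max=config.smoothness.fc_max,
                        amp_threshold=config.smoothness.amp_threshold,
                        zero_pad_factor=config.smoothness.zero_pad_factor,
                        fixed_cutoff=config.smoothness.fixed_cutoff)
    records = sm.smoothness_table(
        trial, validity.strides, sparc_params=sp,
        profile_source=config.smoothness.profile_source,
        sparc_abs=config.smoothness.sparc_abs,
        min_window=config.smoothness.min_window)
    return TrialResult(trial, detected, validity, temporal, records)


def events_frame(result: TrialResult) -> pd.DataFrame:
    return pd.DataFrame([{"side": e.side, "type": e.type.value,
                          "time_s": e.time, "source": e.source}
                         for e in result.events])


def strides_frame(result: TrialResult) -> pd.DataFrame:
    rows = [{"side": s.side, "index": s.index, "fo_start": s.fo_start,
             "fs": s.fs, "fo_end": s.fo_end}
            for strides in result.validity.strides.values() for s in strides]
    return pd.DataFrame(rows, columns=["side", "index", "fo_start", "fs", "fo_end"])


def cohort_reports(records: pd.DataFrame, config: PipelineConfig) -> dict[str, object]:
    """Cohort-level statistics from a pooled smoothness table."""
    alpha = config.stats.alpha
    pooling = config.stats.pooling
    reports: dict[str, object] = {}
    reports["complete_vs_stride"] = st.compare_complete_vs_stride(
        records, alpha=alpha, pooling=pooling)
    try:
        ranking = st.variance_ranking(records)
        reports["variance_ranking"] = ranking.table
        reports["variance_winner"] = {"winner": ranking.winner, "wins": ranking.wins}
    except InputError as exc:
        logger.warning("variance ranking skipped: %s", exc)
    try:
        reports["location_comparison"] = st.compare_locations(
            records, alpha=alpha, pooling=pooling,
            posthoc_method=config.stats.posthoc_method)
    except InputError as exc:
        logger.warning("location comparison skipped: %s", exc)
    return reports


def run_pipeline(trials: list[gio.IMUTrial], config: PipelineConfig,
                 out_dir: str | Path | None = None) -> dict[str, object]:
    """Process a cohort of trials and (optionally) write all artifacts.

    Returns a dict with per-trial results, the pooled smoothness table and
    the cohort statistics reports. Raises InputError if no trial survives
    the validity rules.
    """
    results = []
    excluded = []
    for trial in trials:
        res = process_trial(trial, config)
        results.append(res)
        if not res.valid:
            excluded.append({"subject": trial.subject_id, "trial": trial.trial_id,
                             "reason": res.validity.reason})
    valid = [r for r in results if r.valid]
    if not valid:
        raise InputError("no valid trials after applying trial rules")
    records = pd.concat([sm.records_to_dataframe(r.records) for r in valid],
                        ignore_index=True)
    reports = cohort_reports(records, config)
    out = {"results": results, "records": records, "reports": reports,
           "excluded": excluded}
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        records.to_csv(out_dir / "smoothness.csv", index=False)
        for r in valid:
            stem = f"{r.trial.subject_id}_{r.trial.trial_id}"
            events_frame(r).to_csv(out_dir / f"{stem}_events.csv", index=False)
            strides_frame(r).to_csv(out_dir / f"{stem}_strides.csv", index=False)
        for name, rep in reports.items():
            if isinstance(rep, pd.DataFrame):
                rep.to_csv(out_dir / f"report_{name}.csv", index=False)
        provenance = {
            "config": config.to_dict(), "config_hash": config.hash(),
            "seed": config.seed,
            "n_trials": len(trials), "n_valid": len(valid), "excluded": excluded,
        }
        (out_dir / "run_info.json").write_text(json.dumps(provenance, indent=1))
    return out
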