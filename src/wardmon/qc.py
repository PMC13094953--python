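"""Rule-based artifact detection and data-completeness accounting.

Three numerical criteria are applied to each patient's per-parameter
sequence of obtained values:

* **range** — a value strictly outside the configured physiological limits
  (boundary values pass).
* **deviation** — a value deviating from the prior reading by more than 50%
  is a spike candidate; it is kept only when the next obtained value
  confirms the new level (within 25% of the candidate).  The "prior
  reading" is the previous obtained, non-flagged value, regardless of how
  long ago it was obtained; flagged values never serve as the prior, so one
  spike cannot cascade.
* **spo2_step** — an SpO2 change of >= 8 percentage points between
  consecutive readings marks the later reading as a candidate; it is kept
  only when the next obtained value stays within 8 points of it (a return
  jump at least as large as the step threshold is the spike signature).

Completeness accounting measures the expected 5-minute slot grid per
episode against the records actually obtained, and per-parameter absence
among obtained records.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import (
    ANALYSIS_PARAMETERS,
    MonitoringEpisode,
    Parameter,
    QCRuleConfig,
    slot_grid,
)

logger = logging.getLogger(__name__)

__all__ = [
    "flag_range",
    "flag_deviation",
    "flag_spo2_step",
    "apply_qc",
    "completeness",
    "CompletenessReport",
]


# ---------------------------------------------------------------------------
# Per-series rules.  Each takes the obtained (non-missing) values of one
# parameter for one patient, in time order, and returns flagged positions
# (indices into that obtained series).
# ---------------------------------------------------------------------------


def flag_range(values: np.ndarray, limits: tuple[float, float]) -> np.ndarray:
    """Indices of values strictly outside the closed interval ``limits``."""
    lo, hi = limits
    v = np.asarray(values, dtype=float)
    return np.nonzero((v < lo) | (v > hi))[0]


def flag_deviation(
    values: np.ndarray,
    config: QCRuleConfig,
    gaps_seconds: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Flag unconfirmed >50% jumps from the prior reading.

    Returns ``(flagged_indices, gap_seconds_at_flag)``; the gap is the time
    since the prior reading (``nan`` when timestamps were not supplied),
    recorded because the rule is applied across gaps of any length.
    """
    v = np.asarray(values, dtype=float)
    n = len(v)
    flagged: list[int] = []
    gaps_out: list[float] = []
    prior_idx: int | None = None
    for i in range(n):
        if prior_idx is None:
            prior_idx = i
            continue
        p = v[prior_idx]
        if p <= 0:
            logger.debug("nonpositive prior %s at index %d; comparison skipped", p, i)
            prior_idx = i
            continue
        if abs(v[i] - p) / p > config.deviation_fraction:
            if config.deviation_semantics == "confirmation":
                # genuine iff the next value confirms the new level
                ok = (
                    i + 1 < n
                    and v[i] != 0
                    and abs(v[i + 1] - v[i]) / abs(v[i]) <= config.confirmation_fraction
                )
            else:  # "recovery": artifact iff the next value returns to baseline
                ok = not (
                    i + 1 < n
                    and abs(v[i + 1] - p) / p <= config.confirmation_fraction
                )
            if ok:
                prior_idx = i
            else:
                flagged.append(i)
                if gaps_seconds is not None:
                    gaps_out.append(float(gaps_seconds[i] - gaps_seconds[prior_idx]))
                else:
                    gaps_out.append(float("nan"))
        else:
            prior_idx = i
    return np.asarray(flagged, dtype=int), np.asarray(gaps_out, dtype=float)


def flag_spo2_step(values: np.ndarray, config: QCRuleConfig) -> np.ndarray:
    """Flag unconfirmed SpO2 steps of >= ``spo2_step_points`` points.

    The later reading of a consecutive pair with an absolute change of at
    least the step threshold is a candidate; it is genuine only when the
    next obtained value stays strictly within the step threshold of it.
    Flagged readings do not serve as the comparison baseline for the next
    pair.
    """
    v = np.asarray(values, dtype=float)
    n = len(v)
    flagged: list[int] = []
    prior_idx: int | None = None
    for i in range(n):
        if prior_idx is None:
            prior_idx = i
            continue
        if abs(v[i] - v[prior_idx]) >= config.spo2_step_points:
            confirmed = i + 1 < n and abs(v[i + 1] - v[i]) < config.spo2_step_points
            if confirmed:
                prior_idx = i
            else:
                flagged.append(i)
        else:
            prior_idx = i
    return np.asarray(flagged, dtype=int)


# ---------------------------------------------------------------------------
# Cohort-level QC
# ---------------------------------------------------------------------------


def apply_qc(
    device: pd.DataFrame, config: QCRuleConfig | None = None
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Apply all three artifact rules to a cohort device table.

    Returns ``(clean, flags, rates)``:

    * ``clean`` — a copy of ``device`` with flagged values set absent.
    * ``flags`` — one row per (record, parameter, rule) flag with the
      offending value and, for deviation flags, the gap since the prior
      reading.  A record may carry several flags (distinct rules); it is
      removed once but tallied once per rule.
    * ``rates`` — per (parameter, rule) flag counts and rates, the rate
      denominator being the obtained measurements of that parameter.
    """
    if config is None:
        config = QCRuleConfig()
    clean = device.copy()
    flag_rows: list[dict] = []

    for patient_id, grp in device.groupby("patient_id", sort=False):
        grp = grp.sort_values("timestamp")
        times = grp["timestamp"].to_numpy()
        secs = (times - times[0]) / np.timedelta64(1, "s")
        for param in Parameter:
            col = param.value
            if col not in grp.columns:
                continue
            obtained = grp[col].notna().to_numpy()
            if not obtained.any():
                continue
            idx = grp.index.to_numpy()[obtained]
            vals = grp.loc[idx, col].to_numpy(dtype=float)
            vsecs = secs[obtained]

            def add(positions, rule, gaps=None):
                for j, pos in enumerate(positions):
                    flag_rows.append(
                        {
                            "patient_id": patient_id,
                            "timestamp": times[obtained][pos],
                            "parameter": col,
                            "rule": rule,
                            "value": vals[pos],
                            "gap_seconds": float(gaps[j]) if gaps is not None else np.nan,
                            "_row": idx[pos],
                        }
                    )

            limits = config.range_limits.get(param)
            if limits is None:
                logger.info("no range limits configured for %s; range rule skipped", col)
                range_pos = np.array([], dtype=int)
            else:
                range_pos = flag_range(vals, limits)
                add(range_pos, "range")

            # range-flagged values are excluded before the sequential rules
            keep = np.setdiff1d(np.arange(len(vals)), range_pos)
            sub_vals, sub_secs, sub_idx = vals[keep], vsecs[keep], keep
            dev_pos, dev_gaps = flag_deviation(sub_vals, config, gaps_seconds=sub_secs)
            add(sub_idx[dev_pos] if len(dev_pos) else [], "deviation", dev_gaps)
            if param is Parameter.SPO2:
                step_pos = flag_spo2_step(sub_vals, config)
                add(sub_idx[step_pos] if len(step_pos) else [], "spo2_step")

    flags = pd.DataFrame(
        flag_rows,
        columns=[
            "patient_id", "timestamp", "parameter", "rule", "value",
            "gap_seconds", "_row",
        ],
    )
    for _, f in flags.iterrows():
        clean.loc[f["_row"], f["parameter"]] = np.nan
    flags = flags.drop(columns="_row")

    obtained_counts = {
        p.value: int(device[p.value].notna().sum())
        for p in Parameter
        if p.value in device.columns
    }
    rate_rows = []
    for param in obtained_counts:
        for rule in ("range", "deviation", "spo2_step"):
            k = int(((flags["parameter"] == param) & (flags["rule"] == rule)).sum()) \
                if len(flags) else 0
            if rule == "spo2_step" and param != "SPO2":
                continue
            n_obt = obtained_counts[param]
            rate_rows.append(
                {
                    "parameter": param,
                    "rule": rule,
                    "n_flags": k,
                    "n_obtained": n_obt,
                    "rate": k / n_obt if n_obt else 0.0,
                }
            )
    rates = pd.DataFrame(rate_rows)
    return clean, flags, rates


# ---------------------------------------------------------------------------
# Completeness
# ---------------------------------------------------------------------------


@dataclass
class CompletenessReport:
    """Expected-vs-obtained slot accounting for a cohort.

    ``complete_records`` counts obtained records carrying all five analysis
    parameters.  ``parameter_absent`` counts, per parameter, obtained
    records lacking that parameter.  Fractions are exact; render at 0.1%.
    """

    expected_slots: int
    obtained_slots: int
    missing_slots: int
    complete_records: int
    parameter_absent: dict[str, int] = field(default_factory=dict)
    excluded_records: int = 0
    manual_flags: int | None = None  # externally supplied expert-review count

    @property
    def missing_fraction(self) -> float:
        return self.missing_slots / self.expected_slots if self.expected_slots else 0.0

    def to_dict(self) -> dict:
        d = {
            "expected_slots": self.expected_slots,
            "obtained_slots": self.obtained_slots,
            "missing_slots": self.missing_slots,
            "missing_pct": round(100.0 * self.missing_fraction, 1),
            "complete_records": self.complete_records,
            "parameter_absent": dict(self.parameter_absent),
            "parameter_absent_pct": {
                k: round(100.0 * v / self.obtained_slots, 1) if self.obtained_slots else 0.0
                for k, v in self.parameter_absent.items()
            },
            "excluded_records": self.excluded_records,
        }
        if self.manual_flags is not None:
            d["manual_flags"] = self.manual_flags
        return d


def completeness(
    device: pd.DataFrame, episodes: list[MonitoringEpisode]
) -> CompletenessReport:
    """Account for missing 5-minute slots and per-parameter absence.

    Each record is assigned to the nearest slot of its patient's grid;
    records outside their episode are excluded (and counted).  The expected
    count is the sum of per-patient slot-grid sizes.
    """
    by_patient = {e.patient_id: e for e in episodes}
    unknown = set(device["patient_id"]) - set(by_patient)
    if unknown:
        raise ValueError(f"records for patients without an episode: {sorted(unknown)}")

    expected = 0
    obtained = 0
    complete = 0
    excluded = 0
    absent = {p.value: 0 for p in ANALYSIS_PARAMETERS}
    analysis_cols = [p.value for p in ANALYSIS_PARAMETERS]

    groups = dict(tuple(device.groupby("patient_id", sort=False)))
    for pid, episode in by_patient.items():
        grid = slot_grid(episode)
        expected += len(grid)
        grp = groups.get(pid)
        if grp is None or grp.empty:
            continue
        ts = pd.to_datetime(grp["timestamp"])
        inside = (ts >= episode.ward_admission) & (ts <= episode.sensor_removal)
        n_out = int((~inside).sum())
        if n_out:
            logger.info("%d record(s) outside episode for %s excluded", n_out, pid)
            excluded += n_out
        grp = grp.loc[inside.to_numpy()]
        if grp.empty:
            continue
        # nearest-slot assignment; a slot with >=1 record counts as obtained
        t64 = pd.to_datetime(grp["timestamp"]).astype("int64").to_numpy()
        pos = np.searchsorted(grid.asi8, t64)
        pos = np.clip(pos, 0, len(grid) - 1)
        left = np.clip(pos - 1, 0, len(grid) - 1)
        choose_left = np.abs(t64 - grid.asi8[left]) <= np.abs(t64 - grid.asi8[pos])
        slots = np.where(choose_left, left, pos)
        obtained += len(np.unique(slots))
        complete += int(grp[analysis_cols].notna().all(axis=1).sum())
        for col in analysis_cols:
            absent[col] += int(grp[col].isna().sum())

    return CompletenessReport(
        expected_slots=expected,
        obtained_slots=obtained,
        missing_slots=expected - obtained,
        complete_records=complete,
        parameter_absent=absent,
        excluded_records=excluded,
    )
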