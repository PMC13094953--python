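"""Time-alignment of nurse spot-checks with device records.

For each nurse observation and each parameter it carries, the device record
with that parameter present and the smallest |Δt| within the pairing window
(default 5 minutes) is selected; ties break toward the earlier device
record.  Observations with no eligible device value are logged with a
reason rather than silently dropped.  A device record may legitimately
serve two back-to-back nurse checks when both fall within the window; such
reuse is allowed and logged.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .core import ANALYSIS_PARAMETERS, PairingConfig, Parameter

logger = logging.getLogger(__name__)

__all__ = ["match_pairs", "pair_counts", "PAIR_COLUMNS"]

PAIR_COLUMNS = [
    "patient_id",
    "parameter",
    "nurse_value",
    "device_value",
    "nurse_time",
    "device_time",
    "delta_seconds",
]

EXCLUSION_COLUMNS = ["patient_id", "parameter", "nurse_time", "reason"]


def match_pairs(
    nurse: pd.DataFrame,
    device_clean: pd.DataFrame,
    config: PairingConfig | None = None,
    parameters: tuple[Parameter, ...] = ANALYSIS_PARAMETERS,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Pair nurse observations with QC-cleaned device records.

    Returns ``(pairs, exclusions)``.  Each (nurse observation, parameter)
    yields at most one pair with ``delta_seconds <= window``.  TEMP pairing
    requires the nurse table to be auricular-adjusted (``temp_adjusted``).
    """
    if config is None:
        config = PairingConfig()
    window_s = config.window_minutes * 60.0

    if "temp_adjusted" in nurse.columns:
        unadj = nurse["TEMP"].notna() & ~nurse["temp_adjusted"].astype(bool)
        if unadj.any():
            raise ValueError(
                "nurse TEMP values must be auricular-adjusted before pairing; "
                f"{int(unadj.sum())} observation(s) are not"
            )

    pair_rows: list[dict] = []
    excl_rows: list[dict] = []

    dev_groups = dict(tuple(device_clean.groupby("patient_id", sort=False)))
    for _, obs in nurse.iterrows():
        pid = obs["patient_id"]
        nurse_t = pd.Timestamp(obs["timestamp"])
        grp = dev_groups.get(pid)
        for param in parameters:
            col = param.value
            nv = obs.get(col)
            if pd.isna(nv):
                continue
            if grp is None or grp.empty:
                excl_rows.append(
                    dict(patient_id=pid, parameter=col, nurse_time=nurse_t,
                         reason="no_device_data_in_window")
                )
                continue
            have = grp[col].notna()
            cand = grp.loc[have, ["timestamp", col]]
            if cand.empty:
                excl_rows.append(
                    dict(patient_id=pid, parameter=col, nurse_time=nurse_t,
                         reason="parameter_absent")
                )
                continue
            dt = (pd.to_datetime(cand["timestamp"]) - nurse_t).dt.total_seconds()
            absdt = dt.abs()
            in_win = absdt <= window_s
            if not in_win.any():
                excl_rows.append(
                    dict(patient_id=pid, parameter=col, nurse_time=nurse_t,
                         reason="no_device_data_in_window")
                )
                continue
            sub = cand.loc[in_win]
            sub_abs = absdt.loc[in_win]
            if config.selection == "first":
                best = sub["timestamp"].idxmin()
            else:
                best_abs = sub_abs.min()
                tied = sub.loc[sub_abs == best_abs]
                best = tied["timestamp"].idxmin()  # tie -> earlier record
            pair_rows.append(
                dict(
                    patient_id=pid,
                    parameter=col,
                    nurse_value=float(nv),
                    device_value=float(sub.loc[best, col]),
                    nurse_time=nurse_t,
                    device_time=pd.Timestamp(sub.loc[best, "timestamp"]),
                    delta_seconds=float(sub_abs.loc[best]),
                )
            )

    pairs = pd.DataFrame(pair_rows, columns=PAIR_COLUMNS)
    exclusions = pd.DataFrame(excl_rows, columns=EXCLUSION_COLUMNS)

    if len(pairs):
        reused = pairs.duplicated(subset=["patient_id", "parameter", "device_time"])
        if reused.any():
            logger.info(
                "%d device record(s) matched more than one nurse observation",
                int(reused.sum()),
            )
    return pairs, exclusions


def pair_counts(pairs: pd.DataFrame) -> dict[str, int]:
    """Per-parameter pair tallies (zero for parameters without pairs)."""
    counts = {p.value: 0 for p in ANALYSIS_PARAMETERS}
    if len(pairs):
        for param, k in pairs.groupby("parameter").size().items():
            counts[str(param)] = int(k)
    return counts
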