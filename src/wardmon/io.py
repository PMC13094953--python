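"""Delimited-text readers and writers.

Wide CSV tables with ISO-8601 timestamps: one row per time point, one
column per parameter, blank cells for absent values.  Round-tripping a
table through :func:`write_device_table` / :func:`read_device_table`
preserves every numeric value bit-identically and never turns an absent
cell into a number.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .core import (
    MonitoringEpisode,
    Parameter,
    PairingConfig,
    QCRuleConfig,
    AbnormalityThreshold,
    AgreementConfig,
)

PARAM_COLUMNS = [p.value for p in Parameter]

DEVICE_COLUMNS = ["patient_id", "timestamp"] + PARAM_COLUMNS
NURSE_COLUMNS = DEVICE_COLUMNS + ["temp_adjusted"]


class TableFormatError(ValueError):
    """A delimited table violates the expected layout or invariants."""


def _read_table(path: str | Path, required: list[str]) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, dtype={"patient_id": str})
    missing = [c for c in ("patient_id", "timestamp") if c not in df.columns]
    if missing:
        raise TableFormatError(f"{path}: missing required columns {missing}")
    try:
        df["timestamp"] = pd.to_datetime(df["timestamp"], format="ISO8601")
    except (ValueError, TypeError) as exc:
        # name the offending row for the error message
        for i, raw in enumerate(pd.read_csv(path, dtype=str)["timestamp"]):
            try:
                pd.to_datetime(raw, format="ISO8601")
            except (ValueError, TypeError):
                raise TableFormatError(
                    f"{path}: malformed timestamp {raw!r} in data row {i}"
                ) from exc
        raise TableFormatError(f"{path}: malformed timestamps") from exc
    for col in required:
        if col not in df.columns:
            df[col] = np.nan
    for col in PARAM_COLUMNS:
        if col in df.columns:
            df[col] = pd.to_numeric(df[col], errors="raise")
    dup = df.duplicated(subset=["patient_id", "timestamp"])
    if dup.any():
        first = df.loc[dup, ["patient_id", "timestamp"]].iloc[0]
        raise TableFormatError(
            f"{path}: duplicate (patient, timestamp) record "
            f"({first['patient_id']}, {first['timestamp']})"
        )
    return df.sort_values(["patient_id", "timestamp"], kind="mergesort").reset_index(
        drop=True
    )


def read_device_table(path: str | Path) -> pd.DataFrame:
    """Read a wide device-stream CSV into a sorted DataFrame.

    Blank cells become ``NaN`` (absent), never zeros.  Duplicate
    (patient, timestamp) rows and malformed timestamps are errors.
    """
    return _read_table(path, PARAM_COLUMNS)[DEVICE_COLUMNS]


def read_nurse_table(path: str | Path, temp_adjusted: bool | None = None) -> pd.DataFrame:
    """Read a nurse-observation CSV.

    ``temp_adjusted`` declares whether TEMP values in the file already carry
    the +0.5 degC auricular correction; it overrides any column of that name
    in the file.  If the file has no such column it must be supplied.
    """
    df = _read_table(path, PARAM_COLUMNS)
    if temp_adjusted is not None:
        df["temp_adjusted"] = bool(temp_adjusted)
    elif "temp_adjusted" not in df.columns:
        raise TableFormatError(
            f"{path}: no temp_adjusted column and no temp_adjusted argument; "
            "declare whether auricular TEMP values are already adjusted"
        )
    df["temp_adjusted"] = df["temp_adjusted"].astype(bool)
    return df[NURSE_COLUMNS]


def write_table(df: pd.DataFrame, path: str | Path) -> None:
    """Write a table as CSV with ISO timestamps and blank absent cells."""
    out = df.copy()
    if "timestamp" in out.columns:
        out["timestamp"] = pd.to_datetime(out["timestamp"]).dt.strftime(
            "%Y-%m-%dT%H:%M:%S"
        )
    for col in ("ward_admission", "sensor_removal", "nurse_time", "device_time"):
        if col in out.columns:
            out[col] = pd.to_datetime(out[col]).dt.strftime("%Y-%m-%dT%H:%M:%S")
    out.to_csv(path, index=False)


def read_episode_table(path: str | Path) -> list[MonitoringEpisode]:
    df = pd.read_csv(path, dtype={"patient_id": str})
    for col in ("ward_admission", "sensor_removal"):
        df[col] = pd.to_datetime(df[col], format="ISO8601")
    return [
        MonitoringEpisode(r.patient_id, r.ward_admission.to_pydatetime(),
                          r.sensor_removal.to_pydatetime())
        for r in df.itertuples()
    ]


def write_episode_table(episodes: list[MonitoringEpisode], path: str | Path) -> None:
    df = pd.DataFrame(
        {
            "patient_id": [e.patient_id for e in episodes],
            "ward_admission": [e.ward_admission for e in episodes],
            "sensor_removal": [e.sensor_removal for e in episodes],
        }
    )
    write_table(df, path)


# ---------------------------------------------------------------------------
# YAML configuration
# ---------------------------------------------------------------------------


def qc_config_from_dict(d: dict) -> QCRuleConfig:
    kw = dict(d)
    if "range_limits" in kw:
        kw["range_limits"] = {
            Parameter(k): (float(v[0]), float(v[1]))
            for k, v in kw["range_limits"].items()
        }
    return QCRuleConfig(**kw)


def qc_config_to_dict(cfg: QCRuleConfig) -> dict:
    return {
        "deviation_fraction": cfg.deviation_fraction,
        "confirmation_fraction": cfg.confirmation_fraction,
        "spo2_step_points": cfg.spo2_step_points,
        "deviation_semantics": cfg.deviation_semantics,
        "range_limits": {p.value: list(lims) for p, lims in cfg.range_limits.items()},
    }


def thresholds_from_list(items: list[dict]) -> list[AbnormalityThreshold]:
    return [
        AbnormalityThreshold(
            Parameter(it["parameter"]),
            it["direction"],
            float(it["cutoff"]),
            bool(it.get("strict", True)),
            int(it.get("min_consecutive_samples", 1)),
        )
        for it in items
    ]


def thresholds_to_list(ths: list[AbnormalityThreshold]) -> list[dict]:
    return [
        {
            "parameter": t.parameter.value,
            "direction": t.direction,
            "cutoff": t.cutoff,
            "strict": t.strict,
            "min_consecutive_samples": t.min_consecutive_samples,
        }
        for t in ths
    ]


def load_yaml(path: str | Path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh) or {}


def dump_yaml(obj: dict, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(obj, fh, sort_keys=True)


def pairing_config_from_dict(d: dict) -> PairingConfig:
    return PairingConfig(**d)


def agreement_config_from_dict(d: dict) -> AgreementConfig:
    return AgreementConfig(**d)
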