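"""Domain types and small shared transforms for ward-monitoring analysis.

The analysis compares two sources of ward vital signs: a wearable chest
sensor streaming one multi-parameter record per 5-minute slot, and nurse
spot-checks performed 2-3 times daily.  Everything downstream (artifact QC,
pairing, agreement, concordance) works on the types defined here.

Tabular collections are plain :class:`pandas.DataFrame` objects in wide
format (one row per time point, one column per parameter, ``NaN`` = value
absent); the dataclasses below describe single records and configuration.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field, replace
from datetime import datetime, timedelta
from typing import Mapping

import pandas as pd

__all__ = [
    "Parameter",
    "PARAMETER_UNITS",
    "ANALYSIS_PARAMETERS",
    "DeviceRecord",
    "NurseObservation",
    "MonitoringEpisode",
    "QCRuleConfig",
    "PairingConfig",
    "AbnormalityThreshold",
    "AgreementConfig",
    "DEFAULT_THRESHOLDS",
    "adjust_auricular_temperature",
    "slot_grid",
    "SLOT_STEP",
]


class Parameter(str, enum.Enum):
    """A monitored vital-sign parameter."""

    PR = "PR"
    SBP = "SBP"
    DBP = "DBP"
    MBP = "MBP"
    RR = "RR"
    SPO2 = "SPO2"
    TEMP = "TEMP"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


PARAMETER_UNITS: dict[Parameter, str] = {
    Parameter.PR: "bpm",
    Parameter.SBP: "mmHg",
    Parameter.DBP: "mmHg",
    Parameter.MBP: "mmHg",
    Parameter.RR: "breaths/min",
    Parameter.SPO2: "%",
    Parameter.TEMP: "degC",
}

#: The five parameters entering the agreement analyses (systolic/diastolic
#: pressure are carried through I/O but not analysed; only MBP is compared).
ANALYSIS_PARAMETERS: tuple[Parameter, ...] = (
    Parameter.PR,
    Parameter.MBP,
    Parameter.RR,
    Parameter.SPO2,
    Parameter.TEMP,
)

#: Cadence of the device stream.
SLOT_STEP = timedelta(minutes=5)


@dataclass(frozen=True)
class DeviceRecord:
    """One timestamped multi-parameter measurement from the wearable sensor.

    ``values`` maps parameters to numbers; any subset may be present.
    Validity of the numbers is judged later by QC, not here.
    """

    patient_id: str
    timestamp: datetime
    values: Mapping[Parameter, float] = field(default_factory=dict)


@dataclass(frozen=True)
class NurseObservation:
    """One timestamped nurse spot-check.

    ``temp_adjusted`` records whether the +0.5 degC auricular-to-core
    correction has already been applied to TEMP; pairing on TEMP requires it.
    """

    patient_id: str
    timestamp: datetime
    values: Mapping[Parameter, float] = field(default_factory=dict)
    temp_adjusted: bool = False


@dataclass(frozen=True)
class MonitoringEpisode:
    """Per-patient window from ward admission to sensor removal."""

    patient_id: str
    ward_admission: datetime
    sensor_removal: datetime

    def __post_init__(self) -> None:
        if self.sensor_removal <= self.ward_admission:
            raise ValueError(
                f"episode for {self.patient_id}: sensor_removal must be after "
                "ward_admission"
            )
        hours = (self.sensor_removal - self.ward_admission).total_seconds() / 3600.0
        if not (1.0 <= hours <= 200.0):
            raise ValueError(
                f"episode for {self.patient_id}: duration {hours:.1f} h outside "
                "the plausible 1-200 h range"
            )

    @property
    def duration(self) -> timedelta:
        return self.sensor_removal - self.ward_admission


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------

#: Physiological range limits, closed-form defaults.  PR and SBP limits are
#: the published criteria; the others are conventional plausibility bounds
#: and are config-overridable (they are echoed in output metadata).
DEFAULT_RANGE_LIMITS: dict[Parameter, tuple[float, float]] = {
    Parameter.PR: (5.0, 250.0),
    Parameter.SBP: (20.0, 300.0),
    Parameter.MBP: (10.0, 250.0),
    Parameter.RR: (0.0, 80.0),
    Parameter.SPO2: (0.0, 100.0),
    Parameter.TEMP: (30.0, 45.0),
}


@dataclass
class QCRuleConfig:
    """Numerical artifact criteria.

    deviation_fraction
        A value deviating from the prior reading by more than this fraction
        is an artifact candidate (default 0.50).
    confirmation_fraction
        A candidate is genuine if the next obtained value lies within this
        fraction of it (default 0.25).
    spo2_step_points
        Absolute SpO2 change (percentage points) between consecutive
        readings that makes the later reading a candidate (default 8).
    range_limits
        Closed plausibility interval per parameter; values strictly outside
        are artifacts.
    deviation_semantics
        ``"confirmation"`` (default): an unconfirmed jump is an artifact.
        ``"recovery"``: a jump is an artifact only when the next value
        returns to within ``confirmation_fraction`` of the *prior* reading
        (the literal reading of the published criterion).
    """

    deviation_fraction: float = 0.50
    confirmation_fraction: float = 0.25
    spo2_step_points: float = 8.0
    range_limits: dict[Parameter, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_RANGE_LIMITS)
    )
    deviation_semantics: str = "confirmation"

    def __post_init__(self) -> None:
        for name in ("deviation_fraction", "confirmation_fraction"):
            v = getattr(self, name)
            if not (0.0 < v < 1.0):
                raise ValueError(f"{name} must lie in (0, 1); got {v}")
        if self.spo2_step_points <= 0:
            raise ValueError("spo2_step_points must be positive")
        for p, (lo, hi) in self.range_limits.items():
            if not lo < hi:
                raise ValueError(f"range limits for {p}: lower must be < upper")
        if self.deviation_semantics not in ("confirmation", "recovery"):
            raise ValueError("deviation_semantics must be 'confirmation' or 'recovery'")


@dataclass
class PairingConfig:
    """Time window for matching nurse observations to device records."""

    window_minutes: float = 5.0
    #: ``"nearest"`` (default) or ``"first"`` (earliest record in window).
    selection: str = "nearest"

    def __post_init__(self) -> None:
        if self.window_minutes <= 0:
            raise ValueError("window_minutes must be positive")
        if self.selection not in ("nearest", "first"):
            raise ValueError("selection must be 'nearest' or 'first'")


@dataclass(frozen=True)
class AbnormalityThreshold:
    """A directional vital-sign cutoff defining a per-patient abnormality.

    ``strict`` mirrors the printed symbol: ``<``/``>`` are strict,
    ``≤``/``≥`` are not.  ``min_consecutive_samples`` is the number of
    consecutive obtained values that must satisfy the comparison (default 1:
    any single exceedance makes the patient positive).
    """

    parameter: Parameter
    direction: str  # "below" | "above"
    cutoff: float
    strict: bool = True
    min_consecutive_samples: int = 1

    def __post_init__(self) -> None:
        if self.direction not in ("below", "above"):
            raise ValueError("direction must be 'below' or 'above'")
        if self.min_consecutive_samples < 1:
            raise ValueError("min_consecutive_samples must be >= 1")
        lo, hi = DEFAULT_RANGE_LIMITS[self.parameter]
        if not (lo <= self.cutoff <= hi):
            raise ValueError(
                f"cutoff {self.cutoff} outside plausible range for {self.parameter}"
            )

    @property
    def label(self) -> str:
        sym = {("below", True): "<", ("below", False): "<=",
               ("above", True): ">", ("above", False): ">="}[
            (self.direction, self.strict)
        ]
        cut = self.cutoff
        cut_s = f"{cut:g}"
        return f"{self.parameter.value}{sym}{cut_s}"

    def test(self, value: float) -> bool:
        """Whether a single value satisfies the directional comparison."""
        if self.direction == "below":
            return value < self.cutoff if self.strict else value <= self.cutoff
        return value > self.cutoff if self.strict else value >= self.cutoff


def _t(param: Parameter, direction: str, cutoff: float, strict: bool = True):
    return AbnormalityThreshold(param, direction, cutoff, strict)


#: The 16 abnormality thresholds of the concordance analysis, as printed
#: (<, > strict; <=, >= non-strict).
DEFAULT_THRESHOLDS: tuple[AbnormalityThreshold, ...] = (
    _t(Parameter.MBP, "below", 60),
    _t(Parameter.MBP, "below", 65),
    _t(Parameter.MBP, "below", 70),
    _t(Parameter.MBP, "above", 100),
    _t(Parameter.MBP, "above", 110),
    _t(Parameter.MBP, "above", 120),
    _t(Parameter.PR, "below", 40, strict=False),
    _t(Parameter.PR, "above", 100, strict=False),
    _t(Parameter.RR, "below", 8),
    _t(Parameter.RR, "above", 20),
    _t(Parameter.SPO2, "below", 95),
    _t(Parameter.SPO2, "below", 92),
    _t(Parameter.SPO2, "below", 90),
    _t(Parameter.SPO2, "below", 85),
    _t(Parameter.TEMP, "below", 36.8),
    _t(Parameter.TEMP, "above", 38),
    _t(Parameter.TEMP, "above", 39),
)


@dataclass
class AgreementConfig:
    """Settings for continuous-scale agreement (limits of agreement)."""

    loa_multiplier: float = 1.96
    #: decimal places used when rendering agreement summaries
    rounding: int = 2

    def __post_init__(self) -> None:
        if self.loa_multiplier <= 0:
            raise ValueError("loa_multiplier must be positive")


# ---------------------------------------------------------------------------
# Transforms
# ---------------------------------------------------------------------------

AURICULAR_OFFSET_C = 0.5


def adjust_auricular_temperature(obs: NurseObservation) -> NurseObservation:
    """Apply the +0.5 degC auricular-to-core temperature correction.

    Raises ``ValueError`` if the observation is already adjusted (the
    correction must never be applied twice) or carries no TEMP value.
    """
    if obs.temp_adjusted:
        raise ValueError(
            f"observation for {obs.patient_id} at {obs.timestamp} is already "
            "temperature-adjusted"
        )
    if Parameter.TEMP not in obs.values:
        raise ValueError("observation has no TEMP value to adjust")
    values = dict(obs.values)
    values[Parameter.TEMP] = values[Parameter.TEMP] + AURICULAR_OFFSET_C
    return replace(obs, values=values, temp_adjusted=True)


def adjust_nurse_frame(nurse: pd.DataFrame) -> pd.DataFrame:
    """Vectorised auricular adjustment for a nurse observation table.

    Rows with ``temp_adjusted`` already true are left untouched; rows with a
    TEMP value and ``temp_adjusted`` false get +0.5 degC and the flag set.
    """
    out = nurse.copy()
    if "temp_adjusted" not in out.columns:
        out["temp_adjusted"] = False
    needs = (~out["temp_adjusted"].astype(bool)) & out["TEMP"].notna()
    out.loc[needs, "TEMP"] = out.loc[needs, "TEMP"] + AURICULAR_OFFSET_C
    out.loc[out["TEMP"].notna(), "temp_adjusted"] = True
    return out


def slot_grid(
    episode: MonitoringEpisode, step: timedelta = SLOT_STEP
) -> pd.DatetimeIndex:
    """Expected measurement times: admission, admission+step, ... <= removal.

    The count is ``floor(duration / step) + 1`` (the admission slot counts).
    """
    n = math.floor(episode.duration.total_seconds() / step.total_seconds()) + 1
    return pd.DatetimeIndex(
        [episode.ward_admission + i * step for i in range(n)], name="timestamp"
    )
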