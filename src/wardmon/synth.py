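"""Synthetic ward-monitoring cohorts with ground truth.

Generates, per patient, a smooth latent AR(1) trajectory for each vital
sign on the 5-minute slot grid, superimposes configurable abnormality
episodes (ramped so the transitions themselves never trip the artifact
rules), applies burst-structured slot loss jointly to all parameters plus
additional per-parameter dropout (dominated by SpO2), injects isolated
spike artifacts that each violate exactly one QC rule, and samples nurse
spot-checks at 2-3 scheduled visits per day from the latent truth with
measurement noise and systematic biases (nurse RR higher than the device,
device temperature higher than the nurse).

Every random draw for patient *i* comes from a dedicated stream derived
from ``(seed, i)``, so cohorts are bit-identical for a given seed and
stable under parallel generation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import datetime, timedelta

import numpy as np
import pandas as pd

from .core import (
    ANALYSIS_PARAMETERS,
    AbnormalityThreshold,
    MonitoringEpisode,
    Parameter,
    QCRuleConfig,
    SLOT_STEP,
)
from .concordance import detect_abnormal

__all__ = ["SynthConfig", "EpisodeSpec", "GroundTruth", "generate_cohort",
           "inject_artifact"]

_BASE_TIME = datetime(2021, 1, 4, 0, 0, 0)


@dataclass(frozen=True)
class EpisodeSpec:
    """One class of true abnormality episode to superimpose.

    With probability ``prevalence`` a patient receives one episode in which
    the parameter is pushed past ``cutoff`` (in ``direction``) by ``depth``
    units for ``duration_minutes``, with a 3-slot linear ramp in and out.
    """

    parameter: Parameter
    direction: str  # "below" | "above"
    cutoff: float
    prevalence: float
    duration_minutes: float
    depth: float


def _default_episode_specs() -> tuple[EpisodeSpec, ...]:
    P = Parameter
    return (
        EpisodeSpec(P.MBP, "below", 60.0, 0.10, 45.0, 6.0),
        EpisodeSpec(P.MBP, "above", 110.0, 0.30, 120.0, 10.0),
        EpisodeSpec(P.PR, "above", 100.0, 0.40, 180.0, 12.0),
        EpisodeSpec(P.RR, "above", 20.0, 0.50, 120.0, 4.0),
        EpisodeSpec(P.SPO2, "below", 92.0, 0.40, 60.0, 2.0),
        EpisodeSpec(P.TEMP, "above", 38.0, 0.50, 240.0, 0.5),
    )


@dataclass
class SynthConfig:
    """Study-condition settings for cohort generation.

    Defaults emulate the monitored-ward structure the analysis assumes:
    episodes of 12-118 h, 43.8% slot loss in bursts, SpO2 absent in 16.1%
    of obtained records, rare spike artifacts at roughly the observed
    per-parameter rates, and 2-3 noisy nurse checks per day with a +3
    breaths/min nurse RR offset and a +0.4 degC device temperature offset.
    """

    n_patients: int = 10
    seed: int = 0
    episode_hours: tuple[float, float] = (12.0, 118.0)  # uniform range
    #: per-parameter (center, stationary SD) of the latent trajectories
    baselines: dict[Parameter, tuple[float, float]] = field(
        default_factory=lambda: {
            Parameter.MBP: (89.0, 8.0),
            Parameter.PR: (77.0, 10.0),
            Parameter.RR: (16.0, 2.0),
            Parameter.SPO2: (96.0, 1.5),
            Parameter.TEMP: (37.8, 0.3),
        }
    )
    ar1_coefficient: float = 0.9  # at 5-minute lag
    slot_loss_fraction: float = 0.438
    mean_missing_burst_slots: float = 6.0
    #: fraction of obtained records lacking each parameter
    dropout_fractions: dict[Parameter, float] = field(
        default_factory=lambda: {
            Parameter.SPO2: 0.161,
            Parameter.MBP: 0.020,
            Parameter.RR: 0.016,
            Parameter.PR: 0.0002,
            Parameter.TEMP: 0.0001,
        }
    )
    #: per-record spike probability per parameter
    artifact_rates: dict[Parameter, float] = field(
        default_factory=lambda: {
            Parameter.PR: 0.0004,
            Parameter.MBP: 0.0004,
            Parameter.RR: 0.0014,
            Parameter.SPO2: 0.0031,
            Parameter.TEMP: 0.0017,
        }
    )
    episode_specs: tuple[EpisodeSpec, ...] = field(
        default_factory=_default_episode_specs
    )
    nurse_visits_per_day: int = 3
    nurse_noise: dict[Parameter, float] = field(
        default_factory=lambda: {
            Parameter.MBP: 4.0,
            Parameter.PR: 3.0,
            Parameter.RR: 1.5,
            Parameter.SPO2: 1.0,
            Parameter.TEMP: 0.2,
        }
    )
    nurse_rr_bias: float = 3.0  # nurse RR above latent (device underestimates)
    nurse_temp_bias: float = 0.4  # device TEMP above nurse
    nurse_temp_recorded_adjusted: bool = True

    def __post_init__(self) -> None:
        for name in ("slot_loss_fraction",):
            v = getattr(self, name)
            if not (0.0 <= v < 1.0):
                raise ValueError(f"{name} must lie in [0, 1); got {v}")
        for p, f in self.dropout_fractions.items():
            if not (0.0 <= f <= 1.0):
                raise ValueError(f"dropout fraction for {p} outside [0, 1]")
        if self.nurse_visits_per_day not in (2, 3):
            raise ValueError("nurse_visits_per_day must be 2 or 3")
        lo, hi = self.episode_hours
        if not (1.0 <= lo <= hi <= 200.0):
            raise ValueError("episode_hours must lie within [1, 200]")
        for spec in self.episode_specs:
            if spec.duration_minutes / 60.0 > lo:
                raise ValueError(
                    f"episode spec {spec.parameter}: duration exceeds the "
                    "shortest monitoring window"
                )


@dataclass
class GroundTruth:
    """What the generator actually planted, for recovery tests."""

    #: per patient, boolean mask over the slot grid (True = slot lost)
    missing_slot_mask: dict[str, np.ndarray]
    #: one row per injected artifact: patient_id, timestamp, parameter, rule
    artifact_locations: pd.DataFrame
    #: planted abnormality windows: patient_id, parameter, direction,
    #: cutoff, start, end
    episode_windows: pd.DataFrame
    #: per threshold label, per patient: latent-truth abnormality
    true_labels: dict[str, dict[str, bool]]


# ---------------------------------------------------------------------------
# Artifact injection
# ---------------------------------------------------------------------------


def inject_artifact(
    series: np.ndarray,
    kind: str,
    position: int,
    rng: np.random.Generator,
    qc_config: QCRuleConfig | None = None,
    parameter: Parameter | None = None,
) -> tuple[np.ndarray, dict]:
    """Overwrite one obtained value with a spike violating one QC rule.

    ``series`` holds consecutive obtained values of one parameter;
    ``position`` must have an obtained neighbour on both sides.  Returns
    the modified copy and a label describing the injection.  Raises
    ``ValueError`` at series boundaries or when the local context cannot
    host an unconfirmed spike of the requested kind.
    """
    if qc_config is None:
        qc_config = QCRuleConfig()
    v = np.asarray(series, dtype=float).copy()
    if position <= 0 or position >= len(v) - 1:
        raise ValueError("artifact position must have a prior and a following value")
    prior, after = v[position - 1], v[position + 1]

    if kind == "deviation_spike":
        # guards keep the spike an unconfirmed >50% jump even after the
        # device's integer rounding of the recorded value
        if prior < 8.0:
            raise ValueError("prior too small to host a rounding-safe spike")
        if abs(after - prior) / prior > 0.15:
            raise ValueError("following value too far from prior; spike would confirm")
        v[position] = prior * rng.uniform(1.75, 2.2)
    elif kind == "range":
        limits = qc_config.range_limits[parameter]
        lo, hi = limits
        if parameter is Parameter.TEMP:
            v[position] = rng.uniform(lo - 6.0, lo - 4.0)  # e.g. a detached sensor
        else:
            v[position] = hi + rng.uniform(0.05, 0.25) * (hi - lo)
    elif kind == "spo2_step":
        # the drop must exceed the step threshold by >2 points beyond the
        # neighbour's distance from the prior, so the return jump is itself
        # >= the threshold (unconfirmed) even after integer rounding
        if abs(after - prior) > 2.0:
            raise ValueError("following value too far from prior; step would confirm")
        step = rng.uniform(11.0, 15.0)
        if prior - step < 40.0:
            raise ValueError("prior SpO2 too low to host a step artifact")
        v[position] = prior - step
    else:
        raise ValueError(f"unknown artifact kind {kind!r}")

    label = {"kind": kind, "position": position, "value": float(v[position])}
    return v, label


_ARTIFACT_KIND: dict[Parameter, str] = {
    Parameter.PR: "deviation_spike",
    Parameter.MBP: "deviation_spike",
    Parameter.RR: "deviation_spike",
    Parameter.SPO2: "spo2_step",
    Parameter.TEMP: "range",
}

#: rule of :mod:`wardmon.qc` each injection kind violates
KIND_TO_RULE = {"deviation_spike": "deviation", "range": "range",
                "spo2_step": "spo2_step"}

_ROUNDING: dict[Parameter, int] = {
    Parameter.PR: 0,
    Parameter.MBP: 0,
    Parameter.RR: 0,
    Parameter.SPO2: 0,
    Parameter.TEMP: 1,
}


# ---------------------------------------------------------------------------
# Cohort generation
# ---------------------------------------------------------------------------


def _ar1(rng, n, center, sd, phi):
    x = np.empty(n)
    x[0] = center + sd * rng.standard_normal()
    innov_sd = sd * np.sqrt(1.0 - phi * phi)
    eps = rng.standard_normal(n - 1) * innov_sd if n > 1 else np.empty(0)
    for i in range(1, n):
        x[i] = center + phi * (x[i - 1] - center) + eps[i - 1]
    return x


def _burst_mask(rng, n, loss_fraction, mean_missing) -> np.ndarray:
    """Alternating obtained/lost runs with geometric lengths."""
    if loss_fraction <= 0.0:
        return np.zeros(n, dtype=bool)
    mean_obtained = mean_missing * (1.0 - loss_fraction) / loss_fraction
    p_m = 1.0 / mean_missing
    p_o = min(1.0, 1.0 / mean_obtained)
    mask = np.zeros(n, dtype=bool)
    pos = 0
    state_missing = rng.random() < loss_fraction
    while pos < n:
        run = rng.geometric(p_m if state_missing else p_o)
        if state_missing:
            mask[pos: pos + run] = True
        pos += run
        state_missing = not state_missing
    return mask


def _apply_episode(values, slots_active, cutoff, direction, depth, ramp=3):
    """Pin the latent trajectory past the cutoff over a window, with ramps."""
    target = cutoff - depth if direction == "below" else cutoff + depth
    idx = np.nonzero(slots_active)[0]
    if idx.size == 0:
        return values
    out = values.copy()
    base_start = out[idx[0]]
    base_end = out[idx[-1]]
    for j, i in enumerate(idx):
        w = 1.0
        if j < ramp:
            w = (j + 1) / (ramp + 1)
        if idx.size - 1 - j < ramp:
            w = min(w, (idx.size - j) / (ramp + 1))
        base = base_start if j < idx.size / 2 else base_end
        out[i] = (1 - w) * base + w * target
    return out


def generate_cohort(
    config: SynthConfig,
) -> tuple[pd.DataFrame, pd.DataFrame, list[MonitoringEpisode], GroundTruth]:
    """Generate device records, nurse observations, episodes and truth."""
    qc_config = QCRuleConfig()
    device_rows: list[pd.DataFrame] = []
    nurse_rows: list[dict] = []
    episodes: list[MonitoringEpisode] = []
    masks: dict[str, np.ndarray] = {}
    artifact_rows: list[dict] = []
    window_rows: list[dict] = []
    label_thresholds = {
        f"{s.parameter.value}{'<' if s.direction == 'below' else '>'}{s.cutoff:g}":
            AbnormalityThreshold(s.parameter, s.direction, s.cutoff)
        for s in config.episode_specs
    }
    true_labels: dict[str, dict[str, bool]] = {k: {} for k in label_thresholds}

    phi = config.ar1_coefficient
    step_s = SLOT_STEP.total_seconds()

    for i in range(config.n_patients):
        rng = np.random.default_rng(np.random.SeedSequence((config.seed, i)))
        pid = f"P{i + 1:03d}"

        hours = rng.uniform(*config.episode_hours)
        admission = _BASE_TIME + timedelta(minutes=float(rng.integers(0, 1440)))
        removal = admission + timedelta(hours=float(hours))
        episode = MonitoringEpisode(pid, admission, removal)
        episodes.append(episode)
        n_slots = int(np.floor((removal - admission).total_seconds() / step_s)) + 1
        slot_times = pd.DatetimeIndex(
            [admission + k * SLOT_STEP for k in range(n_slots)]
        )

        # latent trajectories
        latent: dict[Parameter, np.ndarray] = {}
        for param, (center, sd) in config.baselines.items():
            latent[param] = _ar1(rng, n_slots, center, sd, phi)
        latent[Parameter.SPO2] = np.clip(latent[Parameter.SPO2], 50.0, 100.0)

        # planted abnormality episodes
        for spec in config.episode_specs:
            if rng.random() >= spec.prevalence:
                continue
            dur_slots = max(1, int(round(spec.duration_minutes * 60.0 / step_s)))
            if dur_slots >= n_slots:
                continue
            start = int(rng.integers(0, n_slots - dur_slots))
            active = np.zeros(n_slots, dtype=bool)
            active[start: start + dur_slots] = True
            latent[spec.parameter] = _apply_episode(
                latent[spec.parameter], active, spec.cutoff, spec.direction,
                spec.depth,
            )
            window_rows.append(
                {
                    "patient_id": pid,
                    "parameter": spec.parameter.value,
                    "direction": spec.direction,
                    "cutoff": spec.cutoff,
                    "start": slot_times[start],
                    "end": slot_times[start + dur_slots - 1],
                }
            )
        if Parameter.SPO2 in latent:
            latent[Parameter.SPO2] = np.clip(latent[Parameter.SPO2], 50.0, 100.0)

        # latent-truth abnormality labels (no loss, no artifacts)
        for label, th in label_thresholds.items():
            true_labels[label][pid] = detect_abnormal(latent[th.parameter], th)

        # slot loss and per-parameter dropout
        mask = _burst_mask(rng, n_slots, config.slot_loss_fraction,
                           config.mean_missing_burst_slots)
        masks[pid] = mask
        obtained = ~mask
        observed: dict[Parameter, np.ndarray] = {}
        for param in config.baselines:
            vals = np.round(latent[param], _ROUNDING[param]).astype(float)
            present = obtained.copy()
            frac = config.dropout_fractions.get(param, 0.0)
            if frac > 0:
                present &= rng.random(n_slots) >= frac
            vals = np.where(present, vals, np.nan)
            observed[param] = vals

        # artifact injection on the final obtained series
        for param in config.baselines:
            rate = config.artifact_rates.get(param, 0.0)
            if rate <= 0:
                continue
            present_idx = np.nonzero(~np.isnan(observed[param]))[0]
            if present_idx.size < 3:
                continue
            series = observed[param][present_idx]
            n_obt = present_idx.size
            hit = np.nonzero(rng.random(n_obt) < rate)[0]
            taken: list[int] = []
            for pos in hit:
                if pos <= 0 or pos >= n_obt - 1:
                    continue
                if any(abs(pos - t) < 2 for t in taken):
                    continue
                kind = _ARTIFACT_KIND[param]
                try:
                    series, _label = inject_artifact(
                        series, kind, int(pos), rng, qc_config, param
                    )
                except ValueError:
                    continue
                series[pos] = np.round(series[pos], _ROUNDING[param])
                taken.append(int(pos))
                artifact_rows.append(
                    {
                        "patient_id": pid,
                        "timestamp": slot_times[present_idx[pos]],
                        "parameter": param.value,
                        "rule": KIND_TO_RULE[kind],
                        "value": float(series[pos]),
                    }
                )
            observed[param][present_idx] = series

        frame = pd.DataFrame({"patient_id": pid, "timestamp": slot_times})
        for p in Parameter:
            frame[p.value] = observed.get(p, np.nan)
        # keep only rows where at least one parameter was obtained
        any_obtained = frame[[p.value for p in ANALYSIS_PARAMETERS]].notna().any(axis=1)
        device_rows.append(frame.loc[any_obtained])

        # nurse visits
        windows = [(7, 9), (12, 14), (18, 20)]
        if config.nurse_visits_per_day == 2:
            windows = [(7, 9), (18, 20)]
        day = admission.replace(hour=0, minute=0, second=0)
        while day <= removal:
            for w_lo, w_hi in windows:
                t = day + timedelta(hours=float(rng.uniform(w_lo, w_hi)))
                if not (admission <= t <= removal):
                    continue
                slot = int(round((t - admission).total_seconds() / step_s))
                slot = min(max(slot, 0), n_slots - 1)
                row: dict = {"patient_id": pid, "timestamp": t}
                for param in config.baselines:
                    truth = latent[param][slot]
                    noise = config.nurse_noise.get(param, 0.0) * rng.standard_normal()
                    val = truth + noise
                    if param is Parameter.RR:
                        val += config.nurse_rr_bias
                    elif param is Parameter.TEMP:
                        val -= config.nurse_temp_bias
                    if param is Parameter.SPO2:
                        val = min(val, 100.0)
                    row[param.value] = round(float(val), _ROUNDING[param])
                row["temp_adjusted"] = config.nurse_temp_recorded_adjusted
                nurse_rows.append(row)
            day += timedelta(days=1)

    device = (
        pd.concat(device_rows, ignore_index=True)
        if device_rows
        else pd.DataFrame(columns=["patient_id", "timestamp"])
    )
    nurse = pd.DataFrame(nurse_rows)
    if not nurse.empty:
        for p in Parameter:
            if p.value not in nurse.columns:
                nurse[p.value] = np.nan
        nurse = nurse.sort_values(["patient_id", "timestamp"]).reset_index(drop=True)
        cols = ["patient_id", "timestamp"] + [p.value for p in Parameter] + [
            "temp_adjusted"
        ]
        nurse = nurse[cols]

    truth = GroundTruth(
        missing_slot_mask=masks,
        artifact_locations=pd.DataFrame(
            artifact_rows,
            columns=["patient_id", "timestamp", "parameter", "rule", "value"],
        ),
        episode_windows=pd.DataFrame(
            window_rows,
            columns=["patient_id", "parameter", "direction", "cutoff", "start", "end"],
        ),
        true_labels=true_labels,
    )
    return device, nurse, episodes, truth
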