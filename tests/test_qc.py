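"""Artifact rules and completeness accounting."""

from datetime import datetime, timedelta

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from wardmon.core import MonitoringEpisode, Parameter, QCRuleConfig
from wardmon.qc import (
    apply_qc,
    completeness,
    flag_deviation,
    flag_range,
    flag_spo2_step,
)

T0 = datetime(2021, 3, 1, 8, 0, 0)
CFG = QCRuleConfig()


class TestRangeRule:
    def test_flags_value_above_limit(self):
        assert list(flag_range(np.array([80.0, 300.0, 82.0]), (5, 250))) == [1]

    def test_boundary_values_pass(self):
        # strict inequalities: exactly 20 mmHg systolic is not flagged
        assert list(flag_range(np.array([20.0, 300.0]), (20, 300))) == []

    def test_all_inside_no_flags(self):
        assert list(flag_range(np.array([60.0, 70.0, 80.0]), (5, 250))) == []


class TestDeviationRule:
    def test_confirmed_jump_is_genuine(self):
        # 62.5% jump confirmed by 128 (|128-130|/130 ~ 1.5% <= 25%)
        idx, _ = flag_deviation(np.array([80.0, 130.0, 128.0]), CFG)
        assert list(idx) == []

    def test_unconfirmed_jump_is_flagged(self):
        # |82-130|/130 ~ 37% > 25%: the 130 is an artifact
        idx, _ = flag_deviation(np.array([80.0, 130.0, 82.0]), CFG)
        assert list(idx) == [1]

    def test_candidate_at_series_end_is_flagged(self):
        idx, _ = flag_deviation(np.array([80.0, 130.0]), CFG)
        assert list(idx) == [1]

    def test_flagged_value_never_serves_as_prior(self):
        # after flagging 130, the prior for 84 is still 80 (5% change, clean)
        idx, _ = flag_deviation(np.array([80.0, 130.0, 84.0, 86.0]), CFG)
        assert list(idx) == [1]

    def test_recovery_semantics_option(self):
        cfg = QCRuleConfig(deviation_semantics="recovery")
        # genuine sustained rise: under recovery semantics it IS flagged
        idx, _ = flag_deviation(np.array([80.0, 130.0, 128.0]), cfg)
        assert list(idx) == []  # 128 does not return to baseline 80
        idx, _ = flag_deviation(np.array([80.0, 130.0, 82.0]), cfg)
        assert list(idx) == [1]  # returns to baseline -> spike

    def test_nonpositive_prior_skipped(self):
        idx, _ = flag_deviation(np.array([0.0, 10.0, 11.0]), CFG)
        assert list(idx) == []

    @given(
        values=st.lists(st.integers(min_value=8, max_value=200), min_size=2,
                        max_size=12),
        k=st.integers(min_value=-3, max_value=3),
    )
    @settings(max_examples=200, deadline=None, derandomize=True)
    def test_scale_invariance(self, values, k):
        # multiplying by a power of two (exact in floating point) must not
        # move any flag
        v = np.array(values, dtype=float)
        base, _ = flag_deviation(v, CFG)
        scaled, _ = flag_deviation(v * 2.0 ** k, CFG)
        assert list(base) == list(scaled)


class TestSpo2StepRule:
    def test_unconfirmed_drop_flagged(self):
        # 9-point drop, return jump of 9 >= 8 points: spike
        assert list(flag_spo2_step(np.array([96.0, 87.0, 96.0]), CFG)) == [1]

    def test_confirmed_drop_is_genuine(self):
        # 8-point drop confirmed by 89 (1 point away)
        assert list(flag_spo2_step(np.array([96.0, 88.0, 89.0]), CFG)) == []

    def test_small_changes_unflagged(self):
        assert list(flag_spo2_step(np.array([96.0, 95.0, 94.0]), CFG)) == []

    def test_flagged_value_not_used_as_baseline(self):
        # after flagging the 85, 95 is compared against 96 (1 point)
        assert list(flag_spo2_step(np.array([96.0, 85.0, 95.0, 94.0]), CFG)) == [1]


def _naive_rules(values: np.ndarray, cfg: QCRuleConfig, spo2: bool):
    """Brute-force reference: plain loops, re-deriving the prior each step."""
    flags = set()
    # deviation rule
    for i in range(len(values)):
        priors = [j for j in range(i) if j not in flags]
        if not priors:
            continue
        p = values[priors[-1]]
        if p <= 0:
            continue
        if abs(values[i] - p) / p > cfg.deviation_fraction:
            nxt = values[i + 1] if i + 1 < len(values) else None
            confirmed = (
                nxt is not None
                and values[i] != 0
                and abs(nxt - values[i]) / abs(values[i]) <= cfg.confirmation_fraction
            )
            if not confirmed:
                flags.add(i)
    step_flags = set()
    if spo2:
        for i in range(len(values)):
            priors = [j for j in range(i) if j not in step_flags]
            if not priors:
                continue
            p = values[priors[-1]]
            if abs(values[i] - p) >= cfg.spo2_step_points:
                nxt = values[i + 1] if i + 1 < len(values) else None
                confirmed = nxt is not None and abs(nxt - values[i]) < cfg.spo2_step_points
                if not confirmed:
                    step_flags.add(i)
    return sorted(flags), sorted(step_flags)


class TestOracleEquivalence:
    def test_production_rules_match_naive_loops_on_random_series(self):
        rng = np.random.default_rng(2024)
        for _ in range(1000):
            n = int(rng.integers(2, 20))
            values = np.round(rng.uniform(40, 160, n), 0)
            dev_idx, _ = flag_deviation(values, CFG)
            naive_dev, _ = _naive_rules(values, CFG, spo2=False)
            assert list(dev_idx) == naive_dev
        for _ in range(1000):
            n = int(rng.integers(2, 20))
            values = np.round(np.clip(rng.normal(92, 6, n), 50, 100), 0)
            step_idx = flag_spo2_step(values, CFG)
            _, naive_step = _naive_rules(values, CFG, spo2=True)
            assert list(step_idx) == naive_step


class TestApplyQC:
    def _device(self, pr):
        times = [T0 + i * timedelta(minutes=5) for i in range(len(pr))]
        return pd.DataFrame(
            {
                "patient_id": "P1",
                "timestamp": times,
                "PR": pr,
                "SPO2": np.nan,
                "MBP": np.nan,
                "RR": np.nan,
                "TEMP": np.nan,
            }
        )

    def test_flagged_values_removed_not_rows(self):
        device = self._device([80.0, 300.0, 82.0, 81.0])
        clean, flags, rates = apply_qc(device)
        assert len(clean) == len(device)
        assert np.isnan(clean.loc[1, "PR"])
        assert set(flags["rule"]) == {"range"}

    def test_artifact_free_cohort_has_zero_flags(self):
        device = self._device([80.0, 82.0, 81.0, 83.0])
        _, flags, _ = apply_qc(device)
        assert len(flags) == 0

    def test_double_rule_counted_once_in_removal_twice_in_tallies(self):
        # an SpO2 value that is both an unconfirmed deviation (>50%) and a
        # step (>=8 points): one removal, two rule tallies
        times = [T0 + i * timedelta(minutes=5) for i in range(3)]
        device = pd.DataFrame(
            {
                "patient_id": "P1",
                "timestamp": times,
                "SPO2": [90.0, 40.0, 91.0],
                "PR": np.nan,
                "MBP": np.nan,
                "RR": np.nan,
                "TEMP": np.nan,
            }
        )
        clean, flags, _ = apply_qc(device)
        assert len(flags) == 2
        assert set(flags["rule"]) == {"deviation", "spo2_step"}
        assert int(clean["SPO2"].isna().sum()) == 1

    def test_flags_are_subset_of_obtained_records(self, small_cohort):
        _, device, _, _, _ = small_cohort
        clean, flags, _ = apply_qc(device)
        assert len(clean) == len(device)
        merged = flags.merge(
            device, on=["patient_id", "timestamp"], how="left", indicator=True
        )
        assert (merged["_merge"] == "both").all()
        for _, f in flags.iterrows():
            sel = (device["patient_id"] == f["patient_id"]) & (
                device["timestamp"] == f["timestamp"]
            )
            assert device.loc[sel, f["parameter"]].notna().all()


class TestCompleteness:
    def test_small_arithmetic_example(self):
        # 2 patients x 13 slots, 6 slots lost -> missing fraction 23.1%
        episodes = [
            MonitoringEpisode("P1", T0, T0 + timedelta(minutes=60)),
            MonitoringEpisode("P2", T0, T0 + timedelta(minutes=60)),
        ]
        rows = []
        for pid in ("P1", "P2"):
            for i in range(13):
                rows.append(
                    {"patient_id": pid, "timestamp": T0 + i * timedelta(minutes=5),
                     "PR": 80.0, "MBP": 90.0, "RR": 16.0, "SPO2": 96.0, "TEMP": 37.0}
                )
        device = pd.DataFrame(rows).drop(index=[0, 1, 2, 13, 14, 15]).reset_index(
            drop=True
        )
        rep = completeness(device, episodes)
        assert rep.expected_slots == 26
        assert rep.missing_slots == 6
        assert round(100 * rep.missing_fraction, 1) == 23.1
        assert rep.complete_records == rep.obtained_slots  # all rows complete

    def test_record_outside_episode_excluded(self):
        episodes = [MonitoringEpisode("P1", T0, T0 + timedelta(minutes=60))]
        device = pd.DataFrame(
            {
                "patient_id": ["P1", "P1"],
                "timestamp": [T0, T0 + timedelta(hours=5)],
                "PR": [80.0, 81.0],
                "MBP": np.nan, "RR": np.nan, "SPO2": np.nan, "TEMP": np.nan,
            }
        )
        rep = completeness(device, episodes)
        assert rep.excluded_records == 1
        assert rep.obtained_slots == 1

    def test_invariant_expected_equals_obtained_plus_missing(self, small_cohort):
        _, device, _, episodes, _ = small_cohort
        rep = completeness(device, episodes)
        assert rep.expected_slots == rep.obtained_slots + rep.missing_slots
        assert rep.complete_records <= rep.obtained_slots
        for v in rep.parameter_absent.values():
            assert v <= rep.obtained_slots
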