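"""Abnormality detection, 2x2 tables, Cohen's kappa and McNemar tests."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from wardmon.concordance import (
    ConcordanceAnalysis,
    TwoByTwoTable,
    build_table,
    cohen_kappa,
    detect_abnormal,
    format_p,
    mcnemar,
)
from wardmon.core import AbnormalityThreshold, DEFAULT_THRESHOLDS, Parameter


def _th(param, direction, cutoff, strict=True, k=1):
    return AbnormalityThreshold(param, direction, cutoff, strict, k)


class TestDetectAbnormal:
    def test_single_dip_below_cutoff(self):
        assert detect_abnormal([72, 58, 75], _th(Parameter.MBP, "below", 60))

    def test_non_strict_threshold_includes_boundary(self):
        assert detect_abnormal([100], _th(Parameter.PR, "above", 100, strict=False))

    def test_strict_threshold_excludes_boundary(self):
        assert not detect_abnormal([60, 60], _th(Parameter.MBP, "below", 60))

    def test_empty_series_is_negative(self):
        assert not detect_abnormal([], _th(Parameter.MBP, "below", 60))
        assert not detect_abnormal([np.nan, np.nan], _th(Parameter.MBP, "below", 60))

    def test_consecutive_sample_requirement(self):
        th = _th(Parameter.MBP, "below", 60, k=2)
        assert not detect_abnormal([59, 70, 59], th)  # isolated dips
        assert detect_abnormal([70, 59, 58, 70], th)  # sustained
        # missing values between dips break the run
        assert not detect_abnormal([59, np.nan, 70, 59], th)


class TestBuildTable:
    def test_simple_tally(self):
        t = build_table({"P1": True, "P2": False}, {"P1": True, "P2": False})
        assert (t.a, t.b, t.c, t.d) == (1, 0, 0, 1)

    def test_nurse_only_positive(self):
        t = build_table({"P1": True}, {"P1": False})
        assert t.b == 1 and t.a == t.c == t.d == 0

    def test_mismatched_patient_sets_error(self):
        with pytest.raises(ValueError, match="P2"):
            build_table({"P1": True}, {"P1": True, "P2": False})

    def test_matches_brute_force_tally_on_synthetic_truth(self):
        rng = np.random.default_rng(9)
        pids = [f"P{i}" for i in range(60)]
        nf = {p: bool(rng.random() < 0.3) for p in pids}
        df_ = {p: bool(rng.random() < 0.5) for p in pids}
        t = build_table(nf, df_)
        assert t.a == sum(nf[p] and df_[p] for p in pids)
        assert t.b == sum(nf[p] and not df_[p] for p in pids)
        assert t.c == sum(df_[p] and not nf[p] for p in pids)
        assert t.n == 60


class TestCohenKappa:
    def test_published_cohort_mbp60_table(self):
        # 2x2 reconstructed from the published three-center postoperative
        # cohort: both-positive 2, nurse-only 1, device-only 7, both-negative 80
        kappa, lo, hi = cohen_kappa(TwoByTwoTable(2, 1, 7, 80))
        assert round(kappa, 2) == 0.30
        assert round(lo, 2) == -0.04
        assert round(hi, 2) == 0.64

    def test_perfect_agreement(self):
        kappa, lo, hi = cohen_kappa(TwoByTwoTable(5, 0, 0, 5))
        assert kappa == pytest.approx(1.0)

    def test_independence_gives_zero(self):
        kappa, *_ = cohen_kappa(TwoByTwoTable(1, 1, 1, 1))
        assert kappa == pytest.approx(0.0)

    def test_label_swap_symmetry(self):
        rng = np.random.default_rng(4)
        for _ in range(50):
            a, b, c, d = rng.integers(0, 30, 4)
            if a + b + c + d == 0:
                continue
            k1, *_ = cohen_kappa(TwoByTwoTable(int(a), int(b), int(c), int(d)))
            k2, *_ = cohen_kappa(TwoByTwoTable(int(d), int(c), int(b), int(a)))
            assert k1 == pytest.approx(k2)

    def test_degenerate_single_category(self):
        kappa, lo, hi = cohen_kappa(TwoByTwoTable(10, 0, 0, 0))
        assert kappa == 1.0

    def test_matches_statsmodels_oracle(self):
        from statsmodels.stats.inter_rater import cohens_kappa as sm_kappa

        rng = np.random.default_rng(12)
        for _ in range(25):
            a, b, c, d = (int(x) for x in rng.integers(1, 40, 4))
            ours, lo, hi = cohen_kappa(TwoByTwoTable(a, b, c, d))
            ref = sm_kappa(np.array([[a, b], [c, d]]), return_results=True)
            assert ours == pytest.approx(ref.kappa)
            # same standard error; CI quantile is 1.96 here vs 1.959964 there
            assert (hi - lo) / (2 * 1.96) == pytest.approx(
                np.sqrt(ref.var_kappa), abs=1e-9
            )
            assert lo == pytest.approx(ref.kappa_low, abs=1e-4)
            assert hi == pytest.approx(ref.kappa_upp, abs=1e-4)


def _exact_mcnemar_enumeration(b: int, c: int) -> float:
    """Brute-force two-sided exact p: enumerate the Binomial(b+c, 1/2) tail."""
    n = b + c
    if n == 0:
        return 1.0
    k = min(b, c)
    tail = sum(
        stats.binom.pmf(j, n, 0.5) for j in range(0, k + 1)
    )
    return min(1.0, 2.0 * tail)


class TestMcNemar:
    def test_exact_below_ten_discordants(self):
        p, method = mcnemar(TwoByTwoTable(0, 1, 7, 0))
        assert method == "exact"
        assert round(p, 3) == 0.070

    def test_corrected_at_ten_or_more(self):
        p, method = mcnemar(TwoByTwoTable(0, 2, 13, 0))
        assert method == "continuity_corrected"
        assert round(p, 3) == 0.010

    def test_no_discordants_gives_p_one(self):
        p, method = mcnemar(TwoByTwoTable(10, 0, 0, 10))
        assert p == 1.0 and method == "exact"

    def test_exact_matches_enumeration_oracle(self):
        for b in range(0, 13):
            for c in range(0, 13 - b):
                if b + c >= 10:
                    continue
                p, method = mcnemar(TwoByTwoTable(0, b, c, 0))
                assert method == "exact"
                assert p == pytest.approx(_exact_mcnemar_enumeration(b, c))

    def test_swapping_b_and_c_changes_nothing(self):
        rng = np.random.default_rng(8)
        for _ in range(100):
            b, c = (int(x) for x in rng.integers(0, 40, 2))
            assert mcnemar(TwoByTwoTable(0, b, c, 0)) == mcnemar(
                TwoByTwoTable(0, c, b, 0)
            )

    def test_matches_statsmodels_oracle(self):
        from statsmodels.stats.contingency_tables import mcnemar as sm_mcnemar

        rng = np.random.default_rng(13)
        for _ in range(25):
            a, b, c, d = (int(x) for x in rng.integers(0, 30, 4))
            p, method = mcnemar(TwoByTwoTable(a, b, c, d))
            exact = method == "exact"
            if b + c == 0:
                continue  # statsmodels exact is NaN there; ours is defined as 1
            ref = sm_mcnemar(
                np.array([[a, b], [c, d]]), exact=exact, correction=True
            ).pvalue
            assert p == pytest.approx(ref, abs=1e-9)


class TestFormatting:
    def test_p_rendering(self):
        assert format_p(0.0703) == "0.070"
        assert format_p(0.00049) == "<0.001"
        assert format_p(0.0005) == "0.001"


class TestSuite:
    def test_empty_cohort_is_error(self):
        empty = pd.DataFrame(columns=["patient_id", "timestamp"])
        with pytest.raises(ValueError, match="empty cohort"):
            ConcordanceAnalysis(empty, empty)

    def test_default_thresholds_produce_all_printed_rows(self, clean_small_cohort):
        _, clean, _, nurse, _, _ = clean_small_cohort
        results = ConcordanceAnalysis(clean, nurse).fit()
        assert len(results.results) == len(DEFAULT_THRESHOLDS) == 17
        for r in results.results:
            assert r.table.n + results.excluded[r.threshold.label] == 6
            assert -1.0 <= r.kappa <= 1.0
            assert 0.0 < r.mcnemar_p <= 1.0
            assert (r.mcnemar_method == "exact") == (r.table.discordant < 10)

    def test_device_side_matches_ground_truth_labels(self, clean_small_cohort):
        """Device detection on lossy data can only miss, never invent,
        latent-truth abnormalities."""
        cfg, clean, _, nurse, _, truth = clean_small_cohort
        for label, by_pid in truth.true_labels.items():
            parts = label.replace(">", " above ").replace("<", " below ").split()
            param, direction, cutoff = parts[0], parts[1], float(parts[2])
            th = _th(Parameter(param), direction, cutoff)
            for pid, true_pos in by_pid.items():
                series = clean.loc[clean["patient_id"] == pid, param]
                got = detect_abnormal(series, th)
                # the cleaned device stream is the (lossy, rounded) latent
                # trajectory, so a detection without latent truth is a bug
                assert true_pos or not got, (
                    f"device detected {label} for {pid} without latent truth"
                )

    def test_device_only_detections_grow_with_episode_rate(self):
        """Short hypotensive episodes between nurse visits are found by the
        device, not the nurse: c outgrows b as prevalence rises."""
        from wardmon.qc import apply_qc
        from wardmon.synth import EpisodeSpec, SynthConfig, generate_cohort

        th = _th(Parameter.MBP, "below", 60)

        def discordants(prevalence):
            cfg = SynthConfig(
                n_patients=30,
                seed=42,
                artifact_rates={},
                episode_specs=(
                    EpisodeSpec(Parameter.MBP, "below", 60.0, prevalence, 45.0, 6.0),
                ),
            )
            device, nurse, _, _ = generate_cohort(cfg)
            clean, _, _ = apply_qc(device)
            res = ConcordanceAnalysis(clean, nurse, (th,)).fit()
            t = res.results[0].table
            return t.b, t.c

        b_lo, c_lo = discordants(0.05)
        b_hi, c_hi = discordants(0.6)
        assert c_hi > c_lo  # device-only detections track the episode rate
        assert b_hi <= b_lo + 2  # nurse-only stays near its false-positive floor
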