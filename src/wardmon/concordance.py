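"""Per-patient abnormality concordance between the two monitoring sources.

For every abnormality threshold (e.g. MBP < 60 mmHg) each patient is
classified positive/negative independently from the nurse spot-checks and
from the artifact-filtered device stream; a patient is positive when at
least ``min_consecutive_samples`` consecutive obtained values satisfy the
directional comparison (default 1: any single exceedance).  The paired
binary classifications are summarised as a 2x2 table and tested with

* **Cohen's kappa** — chance-corrected agreement, with an asymptotic 95%
  confidence interval (Fleiss-Cohen-Everitt standard error);
* **McNemar's test** of marginal homogeneity on the discordant counts
  ``b`` (nurse-only) and ``c`` (device-only): exact two-sided binomial
  ``p = min(1, 2 * P[X <= min(b, c)])`` with ``X ~ Binomial(b+c, 1/2)``
  when ``b + c < 10``, otherwise the continuity-corrected chi-square
  ``(|b-c| - 1)^2 / (b+c)`` on 1 degree of freedom.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from decimal import Decimal, ROUND_HALF_UP

import numpy as np
import pandas as pd
from scipy import stats

from .core import AbnormalityThreshold, DEFAULT_THRESHOLDS, Parameter

__all__ = [
    "TwoByTwoTable",
    "ThresholdResult",
    "detect_abnormal",
    "build_table",
    "cohen_kappa",
    "mcnemar",
    "concordance_suite",
    "ConcordanceAnalysis",
    "ConcordanceResults",
    "format_p",
]

EXACT_DISCORDANT_LIMIT = 10  # below this, the exact binomial test is used


@dataclass(frozen=True)
class TwoByTwoTable:
    """Patient-level concordance counts for one threshold.

    a: both sources positive; b: nurse-only positive; c: device-only
    positive; d: both negative.
    """

    a: int
    b: int
    c: int
    d: int
    threshold: AbnormalityThreshold | None = None

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("counts must be non-negative")

    @property
    def n(self) -> int:
        return self.a + self.b + self.c + self.d

    @property
    def discordant(self) -> int:
        return self.b + self.c

    def swapped_sources(self) -> "TwoByTwoTable":
        return TwoByTwoTable(self.a, self.c, self.b, self.d, self.threshold)


def detect_abnormal(series, threshold: AbnormalityThreshold) -> bool:
    """Whether a patient's value sequence crosses the threshold.

    ``series`` holds one patient's obtained values (missing entries may be
    NaN and are dropped).  True iff at least ``min_consecutive_samples``
    consecutive obtained values satisfy the comparison.  An empty series is
    negative.
    """
    v = np.asarray(pd.Series(series).dropna(), dtype=float)
    if v.size == 0:
        return False
    hits = np.array([threshold.test(x) for x in v])
    need = threshold.min_consecutive_samples
    if need == 1:
        return bool(hits.any())
    run = 0
    for h in hits:
        run = run + 1 if h else 0
        if run >= need:
            return True
    return False


def build_table(
    nurse_flags: dict[str, bool],
    device_flags: dict[str, bool],
    threshold: AbnormalityThreshold | None = None,
) -> TwoByTwoTable:
    """Tally per-patient booleans from both sources into a 2x2 table."""
    if set(nurse_flags) != set(device_flags):
        diff = sorted(set(nurse_flags) ^ set(device_flags))
        raise ValueError(f"patient sets differ between sources: {diff}")
    a = b = c = d = 0
    for pid, nf in nurse_flags.items():
        df_ = device_flags[pid]
        if nf and df_:
            a += 1
        elif nf:
            b += 1
        elif df_:
            c += 1
        else:
            d += 1
    return TwoByTwoTable(a, b, c, d, threshold)


def cohen_kappa(table: TwoByTwoTable) -> tuple[float, float, float]:
    """Cohen's kappa with an asymptotic 95% confidence interval.

    Returns ``(kappa, ci_lower, ci_upper)``.  The standard error is the
    Fleiss-Cohen-Everitt large-sample formula.  In the degenerate
    single-category case (chance agreement 1) kappa is defined as 1 when
    observed agreement is also 1.
    """
    n = table.n
    if n == 0:
        raise ValueError("empty table")
    a, b, c, d = table.a, table.b, table.c, table.d
    po = (a + d) / n
    pe = ((a + b) * (a + c) + (c + d) * (b + d)) / (n * n)
    if pe == 1.0:
        kappa = 1.0 if po == 1.0 else 0.0
        return kappa, kappa, kappa

    kappa = (po - pe) / (1 - pe)

    # cell and marginal proportions (rows: nurse, cols: device)
    p = np.array([[a, b], [c, d]], dtype=float) / n
    pij = np.array([[p[0, 0], p[0, 1]], [p[1, 0], p[1, 1]]])
    row = pij.sum(axis=1)  # nurse marginals
    col = pij.sum(axis=0)  # device marginals
    term1 = sum(
        pij[i, i] * ((1 - pe) - (col[i] + row[i]) * (1 - po)) ** 2 for i in range(2)
    )
    term2 = (1 - po) ** 2 * sum(
        pij[i, j] * (col[i] + row[j]) ** 2
        for i in range(2)
        for j in range(2)
        if i != j
    )
    term3 = (po * pe - 2 * pe + po) ** 2
    var = (term1 + term2 - term3) / (n * (1 - pe) ** 4)
    se = math.sqrt(max(var, 0.0))
    return kappa, kappa - 1.96 * se, kappa + 1.96 * se


def mcnemar(table: TwoByTwoTable) -> tuple[float, str]:
    """McNemar test p-value and the method used.

    Exact binomial when the discordant total is below 10 (p = 1 when there
    are no discordant pairs); continuity-corrected chi-square otherwise.
    """
    b, c = table.b, table.c
    nd = b + c
    if nd < EXACT_DISCORDANT_LIMIT:
        if nd == 0:
            return 1.0, "exact"
        p = min(1.0, 2.0 * stats.binom.cdf(min(b, c), nd, 0.5))
        return float(p), "exact"
    chi2 = (abs(b - c) - 1.0) ** 2 / nd
    return float(stats.chi2.sf(chi2, df=1)), "continuity_corrected"


@dataclass
class ThresholdResult:
    """Concordance statistics for one abnormality threshold."""

    threshold: AbnormalityThreshold
    table: TwoByTwoTable
    kappa: float
    kappa_ci_lower: float
    kappa_ci_upper: float
    mcnemar_p: float
    mcnemar_method: str

    def to_dict(self) -> dict:
        t = self.table
        n = t.n
        return {
            "threshold": self.threshold.label,
            "n": n,
            "agreement": t.a + t.d,
            "agreement_pct": round(100.0 * (t.a + t.d) / n, 1) if n else 0.0,
            "nurse_only": t.b,
            "nurse_only_pct": round(100.0 * t.b / n, 1) if n else 0.0,
            "device_only": t.c,
            "device_only_pct": round(100.0 * t.c / n, 1) if n else 0.0,
            "kappa": round(self.kappa, 2),
            "kappa_ci": [round(self.kappa_ci_lower, 2), round(self.kappa_ci_upper, 2)],
            "mcnemar_p": format_p(self.mcnemar_p),
            "mcnemar_method": self.mcnemar_method,
        }


def format_p(p: float) -> str:
    """Render p at 3 decimals (half-up, as statistical software prints),
    '<0.001' below 0.0005."""
    if p < 0.0005:
        return "<0.001"
    q = Decimal(repr(float(p))).quantize(Decimal("0.001"), rounding=ROUND_HALF_UP)
    return str(q)


class ConcordanceAnalysis:
    """Per-patient abnormality concordance model.

    Built from the cleaned device table and the nurse observation table;
    ``fit`` detects abnormalities per patient and threshold for both
    sources, then computes the 2x2 table, kappa and McNemar p per
    threshold.  Patients lacking the parameter entirely in either source
    are excluded from that threshold's table (and counted).
    """

    def __init__(
        self,
        device_clean: pd.DataFrame,
        nurse: pd.DataFrame,
        thresholds: tuple[AbnormalityThreshold, ...] = DEFAULT_THRESHOLDS,
        patient_ids: list[str] | None = None,
    ):
        if device_clean.empty and nurse.empty:
            raise ValueError("empty cohort: no device records and no nurse observations")
        self.device = device_clean
        self.nurse = nurse
        self.thresholds = tuple(thresholds)
        if patient_ids is None:
            patient_ids = sorted(
                set(device_clean["patient_id"]) | set(nurse["patient_id"])
            )
        self.patient_ids = list(patient_ids)

    def _series(self, frame: pd.DataFrame, pid: str, param: Parameter) -> pd.Series:
        grp = frame.loc[frame["patient_id"] == pid]
        return grp.sort_values("timestamp")[param.value].dropna()

    def fit(self) -> "ConcordanceResults":
        results: list[ThresholdResult] = []
        excluded: dict[str, int] = {}
        dev_groups = {pid: g for pid, g in self.device.groupby("patient_id", sort=False)}
        nur_groups = {pid: g for pid, g in self.nurse.groupby("patient_id", sort=False)}
        for th in self.thresholds:
            col = th.parameter.value
            nurse_flags: dict[str, bool] = {}
            device_flags: dict[str, bool] = {}
            n_excl = 0
            for pid in self.patient_ids:
                dg = dev_groups.get(pid)
                ng = nur_groups.get(pid)
                dvals = (
                    dg.sort_values("timestamp")[col].dropna()
                    if dg is not None
                    else pd.Series(dtype=float)
                )
                nvals = (
                    ng.sort_values("timestamp")[col].dropna()
                    if ng is not None
                    else pd.Series(dtype=float)
                )
                if dvals.empty or nvals.empty:
                    n_excl += 1  # parameter unavailable from one source
                    continue
                device_flags[pid] = detect_abnormal(dvals, th)
                nurse_flags[pid] = detect_abnormal(nvals, th)
            table = build_table(nurse_flags, device_flags, th)
            kappa, lo, hi = cohen_kappa(table)
            p, method = mcnemar(table)
            excluded[th.label] = n_excl
            results.append(
                ThresholdResult(th, table, kappa, lo, hi, p, method)
            )
        return ConcordanceResults(results, excluded)


@dataclass
class ConcordanceResults:
    """Fitted concordance statistics for a set of thresholds."""

    results: list[ThresholdResult]
    excluded: dict[str, int]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([r.to_dict() for r in self.results])

    def to_dict(self) -> dict:
        return {
            "thresholds": [r.to_dict() for r in self.results],
            "excluded_patients": dict(self.excluded),
        }

    def summary(self) -> str:
        df = self.to_frame()
        cols = [
            "threshold", "n", "agreement", "nurse_only", "device_only",
            "kappa", "mcnemar_p", "mcnemar_method",
        ]
        return df[cols].to_string(index=False)


def concordance_suite(
    device_clean: pd.DataFrame,
    nurse: pd.DataFrame,
    thresholds: tuple[AbnormalityThreshold, ...] = DEFAULT_THRESHOLDS,
    patient_ids: list[str] | None = None,
) -> ConcordanceResults:
    """Functional wrapper over :class:`ConcordanceAnalysis`."""
    return ConcordanceAnalysis(device_clean, nurse, thresholds, patient_ids).fit()
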