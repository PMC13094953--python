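"""Continuous-scale agreement: repeated-measures Bland-Altman.

Differences are taken as ``device - nurse`` throughout, so underestimation
by the wearable appears as negative bias.  With repeated pairs per patient
the standard deviation entering the limits of agreement must account for
both within- and between-subject variation; this is done with a one-way
variance-components decomposition of the differences by subject, using the
unbalanced-design correction:

    MSW  = within-subject mean square of the differences
    MSB  = between-subject mean square
    n0   = (N - sum(m_i^2)/N) / (k - 1)      (effective group size)
    between = max(0, (MSB - MSW) / n0)
    total_sd = sqrt(MSW + between)
    LoA = bias +/- multiplier * total_sd

where ``m_i`` is the number of pairs for subject i, ``N = sum(m_i)`` and
``k`` the number of subjects.  When every subject contributes a single
pair the decomposition is undefined and the classic single-measurement
Bland-Altman (sample SD of the differences) is used instead.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import AgreementConfig

__all__ = ["RepeatedBlandAltman", "RepeatedBlandAltmanResults", "bland_altman_repeated"]


@dataclass
class RepeatedBlandAltmanResults:
    """Estimates from a repeated-measures Bland-Altman fit."""

    parameter: str
    n_pairs: int
    n_subjects: int
    bias: float
    within_subject_variance: float
    between_subject_variance: float
    total_sd: float
    loa_lower: float
    loa_upper: float
    loa_multiplier: float
    method: str  # "variance_components" | "classic"

    def to_dict(self) -> dict:
        return {
            "parameter": self.parameter,
            "n_pairs": self.n_pairs,
            "n_subjects": self.n_subjects,
            "bias": self.bias,
            "within_subject_variance": self.within_subject_variance,
            "between_subject_variance": self.between_subject_variance,
            "total_sd": self.total_sd,
            "loa_lower": self.loa_lower,
            "loa_upper": self.loa_upper,
            "loa_multiplier": self.loa_multiplier,
            "method": self.method,
        }

    def summary(self) -> str:
        r = self
        lines = [
            f"Repeated-measures Bland-Altman: {r.parameter}",
            f"  pairs / subjects : {r.n_pairs} / {r.n_subjects}",
            f"  bias (device - nurse) : {r.bias:.3f}",
            f"  within-subject var    : {r.within_subject_variance:.4f}",
            f"  between-subject var   : {r.between_subject_variance:.4f}",
            f"  total SD              : {r.total_sd:.4f}",
            f"  limits of agreement   : [{r.loa_lower:.3f}, {r.loa_upper:.3f}]"
            f"  (bias +/- {r.loa_multiplier:g} SD)",
            f"  method                : {r.method}",
        ]
        return "\n".join(lines)


class RepeatedBlandAltman:
    """Bland-Altman agreement model for repeated paired measurements.

    Parameters
    ----------
    subjects, device, nurse
        Aligned arrays: subject identifier and the two paired measurements.
    parameter
        Label carried into the results.
    subject_mean_bias
        When true, the bias is the mean of per-subject mean differences
        rather than the mean over all differences (default false).
    """

    def __init__(
        self,
        subjects,
        device,
        nurse,
        parameter: str = "",
        config: AgreementConfig | None = None,
        subject_mean_bias: bool = False,
    ):
        self.subjects = np.asarray(subjects)
        self.device = np.asarray(device, dtype=float)
        self.nurse = np.asarray(nurse, dtype=float)
        if not (len(self.subjects) == len(self.device) == len(self.nurse)):
            raise ValueError("subjects, device and nurse must be the same length")
        self.parameter = parameter
        self.config = config or AgreementConfig()
        self.subject_mean_bias = subject_mean_bias

    @classmethod
    def from_pairs(
        cls,
        pairs: pd.DataFrame,
        parameter: str,
        config: AgreementConfig | None = None,
        **kw,
    ) -> "RepeatedBlandAltman":
        """Build from a matched-pairs table (see :mod:`wardmon.pairing`)."""
        sub = pairs.loc[pairs["parameter"] == parameter]
        return cls(
            sub["patient_id"].to_numpy(),
            sub["device_value"].to_numpy(),
            sub["nurse_value"].to_numpy(),
            parameter=parameter,
            config=config,
            **kw,
        )

    def fit(self) -> RepeatedBlandAltmanResults:
        d = self.device - self.nurse
        subj = self.subjects
        uniq, inverse, m = np.unique(subj, return_inverse=True, return_counts=True)
        k = len(uniq)
        N = len(d)
        if k < 2:
            raise ValueError("repeated-measures Bland-Altman requires >= 2 subjects")

        group_sums = np.bincount(inverse, weights=d)
        group_means = group_sums / m
        grand = d.mean()
        bias = float(group_means.mean() if self.subject_mean_bias else grand)

        if np.all(m == 1):
            # degenerate design: classic single-measurement Bland-Altman
            sd = float(np.std(d, ddof=1))
            within, between, method = sd * sd, 0.0, "classic"
            total_sd = sd
        else:
            ssw = float(np.sum((d - group_means[inverse]) ** 2))
            msw = ssw / (N - k)
            ssb = float(np.sum(m * (group_means - grand) ** 2))
            msb = ssb / (k - 1)
            n0 = (N - np.sum(m.astype(float) ** 2) / N) / (k - 1)
            within = msw
            between = max(0.0, (msb - msw) / n0)
            total_sd = float(np.sqrt(within + between))
            method = "variance_components"

        mult = self.config.loa_multiplier
        return RepeatedBlandAltmanResults(
            parameter=self.parameter,
            n_pairs=N,
            n_subjects=k,
            bias=bias,
            within_subject_variance=float(within),
            between_subject_variance=float(between),
            total_sd=float(total_sd),
            loa_lower=bias - mult * total_sd,
            loa_upper=bias + mult * total_sd,
            loa_multiplier=mult,
            method=method,
        )


def bland_altman_repeated(
    pairs: pd.DataFrame, parameter: str, config: AgreementConfig | None = None
) -> RepeatedBlandAltmanResults:
    """Functional wrapper: fit the repeated-measures model for one parameter."""
    return RepeatedBlandAltman.from_pairs(pairs, parameter, config=config).fit()


def bland_altman_plot(results: RepeatedBlandAltmanResults, pairs: pd.DataFrame, ax=None):
    """Scatter of differences against means with bias and LoA lines."""
    import matplotlib.pyplot as plt

    sub = pairs.loc[pairs["parameter"] == results.parameter]
    mean = (sub["device_value"] + sub["nurse_value"]) / 2.0
    diff = sub["device_value"] - sub["nurse_value"]
    if ax is None:
        _, ax = plt.subplots()
    ax.scatter(mean, diff, s=12, alpha=0.6)
    ax.axhline(results.bias, color="k")
    for y in (results.loa_lower, results.loa_upper):
        ax.axhline(y, color="k", linestyle="--")
    ax.set_xlabel(f"mean of methods ({results.parameter})")
    ax.set_ylabel("device - nurse")
    ax.set_title(f"Bland-Altman: {results.parameter}")
    return ax
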