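"""Published reference contingency counts for cross-checking.

Per-threshold patient-level concordance counts from a published
three-center postoperative ward validation cohort (90 analysed patients;
89 for SpO2, where one patient had no paired oximetry data).  For each
abnormality threshold the published table reports the number of patients
on which the two monitoring sources agreed, the nurse-only positives (b)
and the device-only positives (c), together with the kappa coefficient
and McNemar p-value it printed.

These counts are *inputs* for validation: recomputing the statistics from
them with :mod:`wardmon.concordance` must reproduce the printed values
(except one printed p of 1.000 that is not reproducible from its own
discordant counts under the stated exact/corrected rule; see
``reproducible_p``).
"""

from __future__ import annotations

from dataclasses import dataclass

from .concordance import TwoByTwoTable

__all__ = ["ReferenceRow", "REFERENCE_ROWS", "MBP60_RECONSTRUCTED_TABLE"]


@dataclass(frozen=True)
class ReferenceRow:
    label: str
    n: int          # analysed patients
    agree: int      # both-positive + both-negative
    nurse_only: int  # b
    device_only: int  # c
    printed_p: str   # p-value as printed (3 dp or "<0.001")
    reproducible_p: bool  # printed p follows from (b, c) under the stated rule


REFERENCE_ROWS: tuple[ReferenceRow, ...] = (
    ReferenceRow("MBP<60", 90, 82, 1, 7, "0.070", True),
    ReferenceRow("MBP<65", 90, 75, 2, 13, "0.010", True),
    ReferenceRow("MBP<70", 90, 68, 11, 11, "1.000", False),
    ReferenceRow("MBP>100", 90, 51, 21, 18, "0.749", True),
    ReferenceRow("MBP>110", 90, 58, 18, 14, "0.596", True),
    ReferenceRow("MBP>120", 90, 76, 6, 8, "0.789", True),
    ReferenceRow("PR<=40", 90, 88, 0, 2, "0.500", True),
    ReferenceRow("PR>=100", 90, 46, 5, 39, "<0.001", True),
    ReferenceRow("RR<8", 90, 87, 0, 3, "0.250", True),
    ReferenceRow("RR>20", 90, 36, 4, 50, "<0.001", True),
    ReferenceRow("SPO2<95", 89, 46, 4, 39, "<0.001", True),
    ReferenceRow("SPO2<92", 89, 38, 0, 51, "<0.001", True),
    ReferenceRow("SPO2<90", 89, 55, 0, 34, "<0.001", True),
    ReferenceRow("SPO2<85", 89, 84, 0, 5, "0.063", True),
    ReferenceRow("TEMP<36.8", 90, 59, 30, 1, "<0.001", True),
    ReferenceRow("TEMP>38", 90, 34, 1, 55, "<0.001", True),
    ReferenceRow("TEMP>39", 90, 86, 0, 4, "0.125", True),
)

#: Full 2x2 table for the severe-hypotension threshold (MBP < 60 mmHg),
#: reconstructed from the published discordant counts (b=1, c=7) and the
#: published detection rates (device 10.0% and nurse 3.3% of 90 patients
#: => 9 device-positive, 3 nurse-positive => both-positive 2, both-negative
#: 80).  Printed kappa: 0.30 [-0.04; 0.64].
MBP60_RECONSTRUCTED_TABLE = TwoByTwoTable(a=2, b=1, c=7, d=80)
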