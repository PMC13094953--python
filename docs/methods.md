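# Methods

This note records the modelling assumptions, parameter choices and
numerical decisions behind `wardmon`, in the spirit of a statistical
package's model documentation. It states no empirical result that the
test suite or `scripts/acceptance.py` does not itself compute.

## Data model

A **monitoring episode** runs from ward admission to sensor removal
(1–200 h). The device is expected to deliver one multi-parameter record
per 5-minute slot; the slot grid is anchored at admission, so an episode
of duration `D` has `floor(D / 5 min) + 1` expected slots. Timestamps are
timezone-naive at second resolution; all interval arithmetic is in
seconds. Absent values are represented as missing (`NaN`), never as
sentinel numbers, because missingness itself is a primary outcome of this
kind of validation study.

Nurse observations carry the same parameters. Auricular temperature is
systematically adjusted by **+0.5 °C** to approximate core temperature;
the `temp_adjusted` flag tracks whether a value already carries the
correction, the adjustment refuses to run twice, and pairing on
temperature requires adjusted values. Input files may arrive pre- or
post-adjustment; a reader flag declares which, and the pipeline
normalises to adjusted.

## Artifact criteria

Three numerical rules, applied per patient and parameter to the sequence
of obtained values:

* **Range**: value strictly outside the configured physiological interval
  (defaults: PR [5, 250] bpm, SBP [20, 300] mmHg from the published
  criteria; MBP [10, 250] mmHg, RR [0, 80] /min, SpO2 [0, 100] %, TEMP
  [30, 45] °C as config-overridable plausibility bounds, echoed in output
  metadata). Boundary values pass (strict inequalities).
* **Deviation**: a value deviating from the *prior reading* by more than
  50 % is a spike candidate. The published wording — an artifact "unless
  followed by a ±25 % recovery value" — is ambiguous between two
  semantics. The default here is **confirmation**: the candidate is
  genuine only if the next obtained value lies within 25 % *of the
  candidate* (a sustained change is a real deterioration, not an
  artifact). The literal **recovery** reading (artifact only when the
  next value returns to within 25 % of the prior) is implemented behind
  `QCRuleConfig.deviation_semantics` because it labels genuine sustained
  deteriorations as artifacts. A candidate with no following value cannot
  be confirmed and is flagged (conservative). Flagged values never serve
  as the prior reading, so a single spike cannot cascade. The rule is
  applied across gaps of any length; the gap duration is recorded on each
  flag. For temperature in °C a 50 % deviation is physiologically
  impossible, so the rule is inert there and temperature artifacts arise
  from the range rule.
* **SpO2 step**: an absolute change of ≥ 8 percentage points between
  consecutive obtained readings marks the later reading as a candidate
  (absolute points, not relative 8 %, since SpO2 is already a
  percentage). The candidate is genuine only when the next obtained value
  stays strictly within 8 points of it: a return jump at least as large
  as the step threshold is precisely the signature of an isolated spike.
  Note this confirmation is in points, not the deviation rule's ±25 % —
  a 9-point drop from 96 to 87 followed by a return to 96 must be a
  spike, yet 96 is within 25 % of 87; the points criterion is the only
  internally consistent reading.

Rules are applied in order range → deviation → step, with range-flagged
values removed before the sequential rules. A record may be flagged by
several rules; it is removed once but tallied once per rule. Rates are
reported per parameter with the obtained measurements of that parameter
as denominator.

## Pairing

Each (nurse observation, parameter) is matched to the device record with
that parameter present minimising |Δt|, subject to |Δt| ≤ 5 min
(configurable). Nearest-in-time with an earlier-record tie-break is the
least-biased deterministic choice; a first-in-window option exists for
sensitivity analysis. A device record may serve two back-to-back nurse
checks when both fall within the window — repeated-measures agreement
tolerates this and the reuse is logged. Unmatched observations are logged
with a reason (no device data in window / parameter absent). Device
values are never interpolated to nurse timestamps.

## Repeated-measures Bland–Altman

Differences are fixed as **device − nurse** throughout, so
underestimation by the wearable appears as negative bias. The bias is the
mean over all differences (a subject-mean variant is available by flag).
Because patients contribute unequal numbers of pairs, the SD entering the
limits of agreement comes from a one-way variance decomposition of the
differences by subject with the unbalanced correction
`n0 = (N − Σ m_i²/N)/(k − 1)`; the between-subject component is clamped
at zero. When every subject contributes exactly one pair the
decomposition has no within-subject information and the classic
single-measurement formula (sample SD of the differences) is used — the
two coincide in that design, which is verified against an independent
oracle in the tests. The LoA multiplier defaults to the conventional
1.96. No confidence intervals are computed for the LoA; that is a
documented extension point.

## Clarke Error Grid

Zone geometry is declarative: each zone is a shapely polygon in the
(reference, measured) plane, serialisable to YAML, and every report
embeds the geometry used. The shipped defaults are built per parameter
from

* zone **A**: band around the identity line of half-width
  `max(rel · reference, abs)` — MBP/PR (10 %, 5 units), RR (10 %, 3),
  SpO2 (±3 points), TEMP (±0.5 °C). A ±5-unit band is meaningless for
  °C and far too wide for SpO2, hence the per-parameter adaptation;
* zone **B**: a wider band (MBP/PR 20 %/10, RR 25 %/5, SpO2 ±6, TEMP
  ±1.0) plus the regions where both readings are normal, or both
  abnormal in the same direction — large errors that would not change
  treatment;
* zones **C/D/E**: the remainder split by normal-range cutpoints (MBP
  60/110, PR 50/110, RR 8/20, SpO2 90, TEMP 36.0/38.5): measured
  abnormal with reference normal → C (overtreatment risk), reference
  abnormal with measured normal → D (dangerous miss), opposite-direction
  abnormality → E.

Because B–E are built by set differences from the domain rectangle, the
partition property holds by construction; `validate_zone_config`
additionally probes a 10⁴-point lattice for gaps and pairwise interior
overlaps, checks the identity line lies wholly in A, and reports area
shares. Boundary points are assigned to the more benign zone
(A > B > C > D > E) by classifying in benignity order with an inclusion
tolerance of 1e−9. Pairs outside the domain rectangle are clamped to it,
classified, and reported as clamped. These default boundaries are a
reasoned, provisional choice — published grids for vital signs draw them
by expert judgment and rarely print them — so zone percentages from the
defaults are not comparable across studies unless the geometry is shared.

## Abnormality concordance

A patient is positive at a threshold when at least
`min_consecutive_samples` consecutive obtained values satisfy the
directional comparison; the default is 1 (any single exceedance), since
validation studies of this design report no persistence criterion, and a
configurable run length is provided for sensitivity analyses. Strictness
follows the printed symbols: `<`/`>` strict, `≤`/`≥` inclusive. The same
rule is applied to both sources (any-reading, symmetric). Patients
lacking a parameter entirely in either source are excluded from that
threshold's table and counted.

Cohen's kappa uses `κ = (p_o − p_e)/(1 − p_e)` with the
Fleiss–Cohen–Everitt asymptotic standard error for the 95 % CI; the
degenerate single-category case (p_e = 1) defines κ = 1 when p_o = 1.
The implementation is cross-checked in the tests against
`statsmodels.stats.inter_rater.cohens_kappa`, which is never used as the
implementation. McNemar's test follows the published decision rule:
exact two-sided binomial when the discordant total `b + c` is below 10
(p = 1 when there are no discordants), continuity-corrected chi-square on
1 df otherwise, including when `b = c` (where the correction makes
p < 1; a printed value of exactly 1.000 in that situation is not
reproducible under this rule, and the rule as stated is what is
implemented). p-values are rendered at 3 decimals with half-up rounding
and as "<0.001" below 0.0005; kappa at 2 decimals.

## Synthetic cohort generator

The generator's defaults are the study conditions the analysis assumes:

* **Episodes**: duration uniform on 12–118 h; admission time jittered
  over the day so nurse visits align differently per patient.
* **Latent trajectories**: per-parameter AR(1) at the 5-minute lag with
  coefficient 0.9 and stationary centres/SDs MBP 89 ± 8 mmHg, PR 77 ± 10
  bpm, RR 16 ± 2 /min, SpO2 96 ± 1.5 % (clipped to [50, 100]), TEMP
  37.8 ± 0.3 °C — centred on the medians such monitoring reports.
* **Abnormality episodes**: per threshold, a configurable prevalence,
  duration and depth; the trajectory is pinned past the cutoff with a
  3-slot linear ramp in and out so that the *transition itself* never
  trips the deviation or step rules. Ground-truth labels are evaluated
  on the full latent grid, before any data loss.
* **Missingness**: alternating obtained/lost runs with geometric
  lengths (mean lost burst 6 slots = 30 min), tuned so the stationary
  lost fraction equals the configured 0.438. Burst structure, rather
  than independent Bernoulli slots, is what stresses the "prior
  reading" logic of the QC rules; the real gap-length distribution is
  unknown, and geometric bursts are a modelling choice. On top of slot
  loss, per-parameter dropout among obtained records defaults to SpO2
  16.1 %, MBP 2 %, RR 1.6 %, PR 0.02 %, TEMP 0.01 % — the relative
  ordering seen in such deployments, SpO2-dominated.
* **Artifacts**: injected as isolated spikes at per-record rates (PR
  0.04 %, MBP 0.04 %, RR 0.14 %, SpO2 0.31 %, TEMP 0.17 %), each
  violating exactly one rule: unconfirmed deviation spikes (≥ 175 % of
  the prior, neighbours within 15 % of each other) for PR/MBP/RR, range
  excursions for TEMP, ≥ 11-point steps for SpO2. The margins guarantee
  the spike remains detectable, and unconfirmed, after the device's
  integer rounding — so QC replay recovers every injection (sensitivity
  1 by construction, verified in tests).
* **Nurse visits**: 2 or 3 per day in morning/midday/evening windows
  (07–09, 12–14, 18–20 h) with uniform jitter; values are the latent
  truth at the visit slot plus noise (MBP 4, PR 3, RR 1.5, SpO2 1, TEMP
  0.2) and systematic offsets: nurse RR = latent + 3 breaths/min (the
  wearable underestimates RR) and nurse TEMP = latent − 0.4 °C (the
  wearable overestimates skin temperature). These offsets are free
  parameters chosen so Bland–Altman on synthetic data reproduces the
  qualitative directions such studies report; they are not claimed as
  measured biases.
* **Reproducibility**: each patient draws from a dedicated stream
  seeded by `(seed, patient_index)`, so cohorts are bit-identical for a
  seed and stable under parallel generation.

What the generator does **not** emulate: waveform-level PPG physics,
calibration drift of the cuff reference, motion-correlated missingness,
heavy-tailed measurement error, or charting delays in nurse timestamps.
Passing tests therefore demonstrate that the analysis chain is correct
and recovers planted structure under the stated statistical conditions —
not that any particular device is accurate on real wards.

## Problem sizes and tolerances

The test suite exercises cohorts of 6–40 patients; the acceptance script
and the parameter-recovery tests use 100 patients monitored 72 h each,
sizes at which the Monte-Carlo standard errors of the loss and dropout
fractions are small enough for 3-SE recovery checks while the full suite
runs in well under a minute of generator time. Convergence checks
compare realized fractions to configured values within three Monte-Carlo
standard errors estimated from the per-patient spread. Zone-partition
probing uses a 100 × 100 lattice with a gap tolerance of 1e−7 and an
overlap-area tolerance of 1e−6. The false-flag bound on artifact-free
AR(1) cohorts is ≤ 1 % of obtained measurements; at the default
autocorrelation the realized rate is essentially zero because the
confirmation clause absorbs genuine level shifts across data gaps.

## Known limitations

* The deviation rule's behaviour across multi-hour gaps follows the
  stated criteria literally; whether a prior reading hours earlier is a
  meaningful baseline is a clinical judgment the code only records (gap
  duration on each flag), not resolves.
* Kappa on rare abnormalities is unstable by construction (chance
  agreement near 1); the CI makes this visible but no continuity
  correction is applied.
* Expert visual trace review — the second artifact channel in such
  studies — is out of scope; the completeness report carries an optional
  field for externally supplied manual flag counts.
* Zone geometries are provisional defaults, not a published standard.
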