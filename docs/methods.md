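# Methods

This note documents the models, conventions and numerical choices behind
`morphokin`, in the order the pipeline applies them.

## Event model and record completeness

An event log is tidy: one row per observed transition, with time in hours
post-fertilization (time 0 = start of gamete co-incubation; the true
fertilization instant of an individual oocyte is unknown, so all times
inherit that shared offset). Cleavage events carry the blastomere count
*after* the division and an optional symmetry flag; stage events mark the
onsets of compaction (morula), cavitation (early blastocyst), expansion
onset (blastocyst) and full expansion.

A record is *complete* when its trace is unambiguous end to end. The
criterion is deliberately simple: at least one stage event, or an
explicit end-of-record marker at ≥ 190 h (the standard culture window).
Anything else — e.g. a record that stops mid-cleavage with no terminal
observation — is excluded by `filter_complete`, which logs the exclusion
count. "Unclear" is an annotation-level judgement we cannot reconstruct;
the boolean flag is the interface.

Symmetry is an annotation input, not computed from images. For pipelines
that measure blastomere diameters instead, `size_ratio_symmetry` maps a
diameter ratio to a flag with a configurable threshold (default 1.33);
this helper is an extension, not part of the classification rules proper.

## Cleavage-pattern classification

The classifier is a deterministic state machine over the ordered cell
counts (and symmetry flags), starting from an implicit 1-cell zygote.

**First-division window.** The top-level verdict is decided by the first
division and its immediately consequent events, up to (not including) the
first event that takes the embryo beyond 2 cells:

* first count ≥ 3 → *direct* (plus *unequal* if the division was also
  flagged unequal — direct takes precedence since the count is the
  stronger observable);
* first count 2 with unequal flag → *unequal*;
* any return to 1 cell inside the window → *reverse*;
* otherwise the record is *normal*.

More than one subtype in the window (e.g. unequal followed by reverse)
sets `multiple_abnormal`, preserving observation order. Count decreases
or more-than-doubling jumps *after* the window are recorded as
`later_reverse` / `later_direct` flags but do not change the top-level
class, which is defined on the first division.

**Normal subtyping.** A normal record is *synchronous* iff every
post-first-division count lies in {4, 8, 16}; otherwise *asynchronous*,
with the asynchrony count equal to the number of events whose resulting
count lies in {3, 5, 6, 7, 10, 12}. Counts outside both sets (e.g. 9) are
flagged per event and excluded from the tally — they make the record
asynchronous but contribute no event. Asynchrony classes are 1–4 and a
merged 5–6 (≥ 5 maps to the merged class; more than six events is not
biologically attainable under these count sets). Events are counted
through the last recorded cleavage; no cap at the 16-cell stage.

Correctness is checked two ways: worked examples for every rule, and
exhaustive agreement with an independent declarative rule checker
(membership tests instead of a state scan) over all count trajectories of
length ≤ 4 on counts 1..16 and all trajectories of length ≤ 6 on the
attainable alphabet {1, 2, 3, 4, 8, 16}, both symmetry options at every
2-cell event.

## Kinetics

Division rounds are defined so that asynchronous embryos remain
comparable to synchronous ones: the *i*-th cleavage time is the time of
the first count above 2^(i−1) cells (equivalently, round *i* ends at the
first attainment of more than 2^i cells). For a 2→3→4 trajectory the
second-cleavage time is therefore the 3-cell time. This is the
definition consistent with monotone counts and the synchronous special
case; the alternative (timing the 4-cell attainment) is not used.

Box summaries use linear-interpolation (type-7) percentiles, fixed for
reproducibility, with 10th/95th-percentile whiskers. Fourth-round
(16-cell) timings are computed but flagged `low_n` in the milestone
table, since few embryos have a clean 16-cell annotation in practice.

**Rank tests.** Both tests are implemented from first principles because
the exact small-sample path is part of the package's contract:

* *Wilcoxon rank-sum*: for pooled n ≤ 12 (default cutoff, chosen so the
  C(12,6) = 924-split enumeration stays well under a second), the
  two-sided p is the exact permutation tail of the rank sum over all
  C(n, n_x) assignments of the pooled midranks — exact under the
  permutation null even with ties. Above the cutoff, the normal
  approximation on U with tie correction and a 0.5 continuity
  correction. At n = 8–12 the null support is coarse, so the
  approximation can only agree with the exact p to about one support
  step (~0.07 worst case, concentrated near the null center); tests
  assert that bound plus exact agreement with scipy's asymptotic
  implementation in tie-free cases.
* *Kruskal–Wallis*: tie-corrected H with a χ²(k−1) reference. When every
  pooled value is identical the tie correction degenerates; H is defined
  as 0 with p = 1.

## Cohort statistics

**Run-level proportions.** The IVF run is the replicate. Percentages are
reported as raw mean ± SEM (sd/√n, ddof = 1) over runs; arcsin √p
versions of the per-run proportions are carried alongside and are what
the ANOVA/t pathway consumes. This reconciles presentation in percent
with variance-stabilized testing. Runs with an empty denominator are
excluded with a warning.

**Odds ratios.** The pattern–outcome association is the saturated
one-factor logistic model, whose ML odds ratios equal the per-level
cross-product ratios versus the reference — so `fit()` computes them in
closed form, with Wald 95% CIs on the log-odds scale (a test verifies
equality against an explicitly fitted logistic regression). Zero cells
get Haldane–Anscombe +0.5 on all four cells of the affected comparison
only, and the result is flagged rather than suppressed. The overall
association is the Pearson chi-square over the 2×K table (no continuity
correction, so the 2×2 statistic equals the squared two-proportion z);
2×2 tables additionally get the two-sided Fisher exact p (hypergeometric
tail sum, verified against full enumeration for small margins).

**Grade distributions** are compared by the overall chi-square over
groups × {good, fair, poor} plus, for every group pair and grade, a
Fisher exact test on the grade-vs-rest collapse. Pairwise tests are
reported unadjusted; no multiplicity correction is applied anywhere
beyond the FDR machinery of the transcript module, by design.

ANOVA is the classical one-way F (between/within mean squares; F = 0
when both variances vanish). Post-hoc pair comparisons use unadjusted
Student's t; the studentized-range (Tukey–Kramer) procedure is out of
scope. Correlation is plain product-moment r with constant input
rejected.

## Cohort simulator

The generator's defaults *are* the study conditions, not tuning knobs:

* design: 36 runs × 28 embryos (≈ 1,021 cleaved embryos);
* pattern frequencies: pooled category counts 431/271/193/95/27/4 over
  1,021 (synchronous/asynchronous/direct/unequal/reverse/multiple);
* pattern-conditional blastocyst probabilities: 65/431, 81/271, 24/193,
  4/95, 0, 0;
* timing template: 29.0/38.7/51.0 h (cleavages 1–3), 66.0 h (4th round —
  not reliably observed in the reference data; extrapolated from the
  ~12–13 h inter-division spacing), 113.0/130.5/159.5/166.5 h (morula
  through expanded blastocyst);
* asynchronous-event distribution: near-uniform on 1–4 events with 3%
  mass each on 5 and 6 (the reference source gives only a bar chart);
* noise: per-embryo lognormal tempo factor, log-scale SD 0.10, times a
  fixed template, plus per-event Gaussian jitter (SD 0.75 h), snapped to
  the 5-minute acquisition grid with strict monotonicity enforced.

Because the tempo has median 1 and the jitter median 0, every milestone's
cohort median equals the template up to grid rounding and sampling error
— this is what makes the simulator calibration checks meaningful rather
than circular: they verify the whole pipeline (generation → parsing →
classification → extraction → summaries) preserves the medians, not that
a number was copied through.

Asynchronous embryos with k events realize the counts
{2} ∪ {4, 8, 16} ∪ (k counts sampled from {3, 5, 6, 7, 10, 12}), in
increasing order; intermediate counts are timed by linear interpolation
on the log2(count) axis between the 2/4/8/16-cell anchors. Abnormal
embryos realize their defining first-division signature (direct: 1→3
with probability 0.7, else 1→4; reverse and multiple-abnormal records
end after the merge event). Blastocyst outcome is drawn per pattern;
non-developers arrest uniformly at random at one of {no stage event,
morula, early blastocyst}, with an explicit end-of-record marker at
190 h when no stage event is emitted, so every simulated record is
complete.

Reproducibility: one root integer seed; per-embryo substreams are spawned
from a single `SeedSequence`, so identical seeds give byte-identical
event logs.

**What the simulator does not emulate** — and hence what passing tests do
not show about real data: annotation error and missed frames (counts are
always observed exactly, so classifier agreement with truth is ~100% by
construction, not an accuracy estimate for real annotations); partial or
unclear records; correlation between tempo and outcome (developers and
non-developers share one timing distribution, whereas real
blastocyst-forming embryos cleave measurably earlier); run-level
heterogeneity in size and quality; morphology grades; and direct
cleavage at later divisions. The deterministic fixture generator shares
the trajectory code but removes all noise, realizing exact per-category
and per-outcome counts for round-trip tests.

## Transcript-list operations

Fold changes are signed magnitudes (−2.5 = 2.5-fold down), the convention
of array-era gene lists; log2 coordinates are derived where needed. The
DE gates are strict: |fold| > 2, p < 0.05, q < 0.05. BH adjustment is the
step-up q_(i) = min_{j≥i} p_(j)·m/j (delegated to statsmodels, verified
against a brute-force implementation of the definition). Venn partitions
are exact set operations. Volcano coordinates are (sign(fold)·log2|fold|,
−log10 p) with p = 0 capped at y = 300.

The per-gene p-values themselves are inputs (or simulated): the upstream
array preprocessing that produces them is explicitly out of scope, and no
raw expression data enters the package.

The synthetic DEG generator plants a chosen fraction of up/down genes
with |log2 fold| = 2 + |N(0, 0.5)| and log-uniform p = 10^−U(2.5, 8) —
the decreasing near-zero density a genuinely perturbed gene produces,
chosen so planted genes are detectable through the BH gate at array
scale (24,415 genes by default). Null genes draw p ~ U(0, 1) and small
symmetric log2 folds. The null-only configuration is what the FDR-control
check runs on: over 200 seeded tables, the fraction with any q < 0.05
discovery must stay ≤ 0.075.

**2^−ΔΔCt.** Per sample, ΔCt = Ct_target − mean(Ct of the reference
genes); the arithmetic mean in Ct space is exactly the geometric mean in
expression space, which is how dual-reference normalization is defined.
Replicate wells of a (sample, gene) pair are averaged in Ct space first.
ΔΔCt is the difference of group means; fold = 2^−ΔΔCt with the control
at 1. Significance is a two-sample t-test on the per-sample ΔCt values
(reported NaN when either group has a single sample). Reaction
efficiencies are assumed 100% (the method's standard assumption);
efficiency estimation is out of scope.

## Problem sizes and tolerances

The test suite runs the full classifier enumeration (~0.6 M
trajectories), a 10,000-embryo odds-ratio recovery simulation (10%
tolerance against the generating odds ratio), 200 null DEG tables of 400
genes for the FDR check, and the 1,021-record fixture round trip; the
acceptance script simulates one 431-embryo synchronous cohort and one
36×28 default cohort. These sizes keep the whole suite under a minute on
one CPU while leaving every stochastic check comfortably inside its
tolerance; they are the package's chosen reference scales, stated here so
results are reproducible.

## Known limitations

* The classifier consumes annotated symmetry; it cannot detect unequal
  cleavage from counts alone.
* The exact rank-sum path enumerates C(n, n_x) splits and is cut off at
  pooled n = 12; larger samples always use the approximation.
* Odds-ratio CIs are Wald; profile-likelihood intervals (which some
  statistical packages print) can differ in the second decimal for
  small groups.
* The simulator's arrest model is a uniform placeholder; arrest-stage
  distributions in real cohorts are not uniform.
* `multiple_abnormal` fixtures realize only the unequal-then-reverse
  signature, the one combination documented beyond doubt.
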