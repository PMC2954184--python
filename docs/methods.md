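# Methods

## Coordinate model

All interval arithmetic is done in 0-based half-open coordinates (BED
convention), so `length = end − start` with no off-by-one cases. Call
tables, catalogues and reported coordinates use the 1-based inclusive
convention of genome-browser displays; the I/O layer converts with the
exact bijection `(s, e)₁-based ↔ (s − 1, e)₀-based`. Chromosome labels are
normalized (leading `chr` stripped, case-insensitive) so catalogue and call
files in different dialects compare correctly. Genome builds (`hg18`,
`NCBI36`, …) are carried as labels only; no liftover is attempted, and a
build mismatch between callset and catalogue produces a warning, not an
error. CNVs are unstranded.

Union coverage merges abutting intervals: coverage is a measure over base
pairs, and a 0-bp gap is no gap.

## Filtering rules and boundaries

The retention thresholds follow the conservative post-processing scheme
used for Affymetrix 6.0 CNV calls: a call is kept when it is autosomal,
strictly larger than 100 kb, supported by at least 25 markers
(non-strict), and its mean inter-marker spacing is strictly below 10 kb.
The spacing denominator is the number of *gaps* (`n_markers − 1`), since
"average distance between markers" is a distance between adjacent markers;
a single-marker call has spacing +∞ and always fails the density rule. The
inequality directions are the literal reading of the protocol wording
("larger than", "at least", "lower than"); all individually reported calls
in the reference cohort pass under either gap- or marker-count
denominator, so the choice is testable but not discriminating there.

Rules are evaluated in the fixed order autosome → length → markers →
density, and each dropped call is charged to the first failing rule. The
retained set is order-independent (a call is kept iff it passes all
rules); only the audit attribution depends on the order.

Subject QC: a subject is excluded when contrast QC ≤ 0.4 or MAPD ≥ 0.4
(boundary values excluded exactly as those inequalities state); subjects
without metrics pass. Exclusion removes the subject's calls as well.

## Rarity classification

A call's `known_overlap_fraction` is the fraction of its length covered by
catalogue variants; `is_rare = fraction ≤ 0.8`, threshold inclusive. The
default coverage rule is the **union** over all overlapping catalogue
variants: a call tiled 90 % by two known variants is treated as known.
This is the conservative choice (fewer rare calls); the alternative
reading — the best overlap with any *single* catalogue variant — is kept
as `overlap_mode="best_single"` for sensitivity analysis, and the union
fraction never falls below the best-single fraction. Type-matched
classification (only catalogue variants of the call's own loss/gain type
count) is off by default because catalogue records of the relevant release
era frequently lack a type; when enabled, `Mixed` records match either
state and untyped records match neither. Rarity is evaluated per call, not
per merged per-subject region, so nested same-subject calls remain
distinct records.

Candidate-locus annotation lists every locus whose overlap covers at least
50 % (non-strict) of the call's length. Recurrence grouping uses
single-linkage clustering of same-state rare calls with ≥ 50 % reciprocal
overlap (both fractions); single linkage is a deliberate, documented
choice — chains A≈B≈C cluster together even when A and C do not meet the
threshold directly — because it matches the intuitive notion of "the same
variant seen in several subjects" without requiring a consensus interval.

## Statistics

* **Rates** — per-person call counts include zero-call subjects; group
  rates are the sample mean and SD (n − 1 denominator). A single-subject
  group reports SD 0 with an explicit `rate_sd_defined=False` flag.
* **t-test** — pooled-variance two-sample t with df = n₁ + n₂ − 2,
  computed from summary statistics so it applies identically to raw counts
  and to published mean ± SD ± n triples (the two agree exactly when the
  summaries come from the raw data). The `study` profile uses the
  one-tailed reading in the direction cases > controls, which is the
  convention that reproduces the reference cohort's printed rate p-value;
  the `generic` profile is two-tailed. The tail convention is always
  recorded in the result rather than silently assumed.
* **χ²** — Pearson on the 2×2 table, df = 1, **without** Yates continuity
  correction; with the correction the reference cohort's four printed
  p-values (0.09, 0.026, 0.022, 0.679) are not reproduced from its own
  counts. Zero margins raise an error (expected counts undefined). The
  rare deletion-frequency test treats each CNV as one observation, which
  is what makes the compared quantities the groups' deletion percentages.
* **Fisher** — one-tailed exact hypergeometric tail in the direction of
  enrichment in cell (1,1). The size-stratification test counts distinct
  carrier subjects (not calls) for the 2×2, with call-level counts
  reported alongside.
* Report printing mirrors the source tables — ratios to 2 decimals, rates
  to 1, p-values to 3 — while the JSON output carries full-precision
  doubles. No multiple-testing correction is applied; the report metadata
  states this.

## Synthetic cohorts

The generator emulates the *structure* of an array-called CNV cohort, not
the array itself (no intensities, probe maps, LD or relatedness):

| parameter | default | meaning |
|---|---|---|
| n_cases / n_controls | 172 / 160 | cohort sizes |
| rate_lambda (case/control) | 12.7 / 12.5 | Poisson mean calls/person |
| loss_prob (case/control) | 0.35 / 0.33 | P(call is a deletion) |
| length | log-normal, median 205 kb, log-sd 0.7 | truncated to > 100 kb |
| marker_density_bp | 1500 | mean spacing used for marker counts |
| frac_known | 0.957 | P(call copied from the catalogue) |
| catalogue_size | 4000 | simulated known variants |

Defaults are shaped after the reference cohort (≈ 12.5–12.7 calls/person,
rare fraction ≈ 179/4193 ≈ 4.3 %, median size ≈ 205 kb, maximum ≈ 2.5 Mb);
the length log-sd of 0.7 places the ~1/4000 upper quantile near 2.5 Mb.
"Known" calls are **exact** catalogue copies, so rarity ground truth is
unambiguous at any overlap threshold (a `jitter_bp` option shifts copies
for threshold-sensitivity experiments); "novel" calls are placed with zero
catalogue overlap by rejection sampling, erroring after a bounded number
of retries rather than looping forever on an infeasibly dense catalogue.
Marker counts are `max(25, round(length/1500) + 1)`, and lengths are
truncated above 100 kb, so every generated call passes the default filter
by construction — a filter pass over synthetic data dropping anything is a
bug, and is tested as such. All randomness flows from one
`numpy.random.Generator` seed; identical seeds give identical datasets.

What passing the synthetic tests does **not** show: real callsets have
segmentation artifacts (split/merged segments), partially overlapping
rather than exact catalogue matches, size-dependent deletion fractions and
batch structure — none of which the generator models. The synthetic suite
validates the pipeline's arithmetic and classification logic, not the
biology of any particular cohort.

## Problem sizes and numerical choices

The test suite and the acceptance script run full cohort-scale
simulations (332 subjects, ≈ 4200 calls) once or twice, and the detection
power check for the rare deletion excess (46.8 % vs 30.6 % at ≈ 179 rare
calls, 200 replicates) simulates only the rare stratum — generatively
identical to simulating the full cohort and keeping the rare calls, since
strata are independent given the per-stratum rates. Degenerate replicates
(a zero χ² margin) are counted as non-detections.

Fraction comparisons in classification use exact arithmetic on integers
divided once at the end, so threshold boundaries (≤ 0.8, ≥ 0.5) are exact
for exactly representable fractions; property tests compare against a
per-base counting oracle at 1e-12.

## Known limitations

* No liftover: callset and catalogue must share a build; the package only
  warns on mismatched labels.
* The candidate-locus list bundled as a default is a small convenience set
  of previously implicated regions; real analyses should supply their own
  BED.
* The χ² test is asymptotic; for very small rare strata the report still
  prints it (matching the reference analysis) rather than switching to an
  exact test automatically.
* Recurrence grouping is interval-based only; it does not use genotype or
  breakpoint evidence.
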