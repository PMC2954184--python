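# cnvburden

Case–control burden analysis for copy-number variations (CNVs) called from
SNP arrays. The package is aimed at statistical geneticists who have a table
of called CNV segments (deletions/duplications with probe support) for a
case and a control cohort and want to answer the standard burden questions:
do cases carry more CNVs per person, is their deletion/duplication mix
shifted, and does the shift concentrate in *rare* variants — calls that are
poorly covered by a population catalogue such as the Database of Genomic
Variants (DGV)?

## What it computes

Given calls, a subject manifest, a known-variant catalogue and an optional
set of previously implicated candidate loci, the pipeline runs:

1. **Call filtering** — retain autosomal calls with length > 100 kb,
   ≥ 25 supporting markers and mean inter-marker spacing < 10 kb
   (`length/(n_markers − 1)`); remove subjects failing array QC
   (contrast QC ≤ 0.4 or MAPD ≥ 0.4). Every drop is attributed to the first
   failing rule in an audit table.
2. **Rarity classification** — for each call, the fraction *f* of its length
   covered by catalogue variants (union coverage by default, best single
   variant as an alternative); the call is rare when *f* ≤ 0.8. Calls are
   also annotated with candidate loci covering ≥ 50 % of their length, and
   recurrent rare calls are grouped by ≥ 50 % reciprocal-overlap single
   linkage.
3. **Burden statistics** — per group: calls/person (mean ± SD), deletion and
   duplication counts, the deletion/duplication ratio, median and maximum
   size. Tests: pooled two-sample *t* on per-person rates; Pearson χ²
   (df = 1, **no** continuity correction) on the 2×2 loss/gain table, on the
   rare-stratum table, and on each group's overall-vs-rare composition
   shift; a one-tailed Fisher exact test on carriers of rare calls larger
   than 900 kb. No multiple-testing correction is applied (the report says
   so in its metadata).

A synthetic-cohort generator (`cnvburden.synthetic_data`) produces callsets
with known ground truth — Poisson per-person counts, group-specific
deletion probability, log-normal sizes, and an exact known/rare split
against a simulated catalogue — so the whole pipeline is testable without
any external data.

## Worked example

The package ships the printed summary tables of the schizophrenia
case–control cohort it was built around (172 cases / 160 controls, 4193
autosomal CNVs) as reference fixtures. `reproduce-study-stats` recomputes
every printed statistic from those printed inputs:

```
$ cnvburden reproduce-study-stats
statistic                              computed   printed match
overall_loss_gain_chi2_p                   0.09      0.09 yes
rare_deletion_freq_chi2_p                 0.026     0.026 yes
case_ratio_shift_chi2_p                   0.022     0.022 yes
control_ratio_shift_chi2_p                0.679     0.679 yes
overall_rate_t_one_tailed_p                0.31      0.31 yes
case_loss_gain_ratio                       0.54      0.54 yes
...
nrxn1_deletion_size_kb                    328.0       328 yes
largest_cnv_size_kb                      2566.0      2566 yes
gt900kb_carrier_fisher_one_tailed_p      0.0185         - -
```

Reading the first rows: the overall deletion/duplication mix does not
differ between groups (χ² p = 0.09) and neither does the overall CNV rate
(one-tailed pooled t, p = 0.31), but within the rare stratum deletions are
significantly more frequent in cases (46.8 % vs 30.6 %, p = 0.026), driven
by the case ratio shifting from 0.54 overall to 0.88 among rare calls
(p = 0.022) while the control ratio barely moves (0.49 → 0.44, p = 0.679).
The last row is the carrier-level Fisher test for rare calls > 900 kb
(6 case carriers, 0 controls → p ≈ 0.0185), which the source tables
describe but do not print as a number.

The same analysis runs end to end on synthetic data:

```
$ cnvburden simulate --out-dir sim --seed 7
$ cnvburden filter --calls sim/calls.tsv --manifest sim/manifest.tsv \
    --out-calls sim/filtered.tsv --out-audit sim/audit.tsv
$ cnvburden annotate --calls sim/filtered.tsv --manifest sim/manifest.tsv \
    --catalogue sim/catalogue.tsv --out sim/annotated.tsv
$ cnvburden burden --calls sim/annotated.tsv --manifest sim/manifest.tsv \
    --out-prefix sim/report
```

or in one shot from a YAML config with `cnvburden run --config config.yaml`.
All randomness sits behind a single seed; identical inputs give
byte-identical outputs.

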