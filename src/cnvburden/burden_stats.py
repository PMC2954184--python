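"""Group-level CNV burden summaries and hypothesis tests.

The burden analysis compares aggregate CNV load between cases and controls:

* per-person call rates, compared with a pooled-variance two-sample t-test
  (the ``study`` profile uses the one-tailed reading, direction cases >
  controls; the ``generic`` profile is two-tailed — the tail convention is
  always recorded in the result);
* the deletion/duplication composition, compared with the Pearson chi-square
  test on the 2x2 table *without* continuity correction;
* the same composition restricted to rare calls, including a within-group
  "ratio shift" test of rare vs overall composition;
* a size-stratified one-tailed Fisher exact test on carriers of calls above a
  size threshold (default 900 kb), where carriers are counted as distinct
  subjects.

Chi-square and Fisher p-values come from the standard scipy routines
(``chi2_contingency(correction=False)``, ``fisher_exact``); the t-test is the
textbook pooled form computed from summary statistics so that it applies both
to raw per-person counts and to published mean/SD/n triples.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from statistics import median
from typing import Sequence

import numpy as np
from scipy import stats

from .cnv_io import CnvDataset, CnvState, Group

__all__ = [
    "TestResult",
    "GroupSummary",
    "OverallComparison",
    "RareComparison",
    "SizeThresholdResult",
    "BurdenReport",
    "chi_square_2x2",
    "fisher_exact_one_tailed",
    "t_test_from_summary",
    "per_person_counts",
    "summarize_group",
    "compare_overall",
    "compare_rare",
    "size_threshold_test",
    "build_burden_report",
]


@dataclass(frozen=True, slots=True)
class TestResult:
    """One hypothesis-test outcome with its method and tail convention."""

    method: str  # pearson_chi2 | fisher_exact | t_pooled
    statistic: float
    df: float | None
    p_value: float
    tails: str  # "one" | "two"

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_value <= 1.0):
            raise ValueError(f"p-value {self.p_value} outside [0,1]")


def chi_square_2x2(a: int, b: int, c: int, d: int) -> TestResult:
    """Pearson chi-square on the table [[a, b], [c, d]], no continuity correction.

    df = 1, two-sided p. Raises on a zero margin (expected counts undefined).
    """
    if min(a, b, c, d) < 0:
        raise ValueError("counts must be non-negative")
    if (a + b) == 0 or (c + d) == 0 or (a + c) == 0 or (b + d) == 0:
        raise ValueError("chi-square undefined: zero row or column margin")
    res = stats.chi2_contingency([[a, b], [c, d]], correction=False)
    return TestResult("pearson_chi2", float(res.statistic), 1.0, float(res.pvalue), "two")


def fisher_exact_one_tailed(a: int, b: int, c: int, d: int) -> TestResult:
    """One-tailed Fisher exact test: enrichment of the first row's first cell.

    The p-value is the hypergeometric probability, at fixed margins, of
    tables with a count in cell (1,1) at least as large as observed.
    """
    if min(a, b, c, d) < 0:
        raise ValueError("counts must be non-negative")
    odds, p = stats.fisher_exact([[a, b], [c, d]], alternative="greater")
    return TestResult("fisher_exact", float(odds), None, float(p), "one")


def t_test_from_summary(mean1: float, sd1: float, n1: int,
                        mean2: float, sd2: float, n2: int,
                        tails: str = "two") -> TestResult:
    """Pooled-variance two-sample t-test from summary statistics.

    df = n1 + n2 - 2. One-tailed p is the upper tail in the direction
    mean1 > mean2. When both SDs are zero and the means equal, the statistic
    is 0 (p = 0.5 one-tailed, 1 two-tailed).
    """
    if n1 < 2 or n2 < 2:
        raise ValueError("each group needs n >= 2")
    if sd1 < 0 or sd2 < 0:
        raise ValueError("standard deviations must be non-negative")
    if tails not in ("one", "two"):
        raise ValueError(f"tails must be 'one' or 'two', got {tails!r}")
    df = n1 + n2 - 2
    sp2 = ((n1 - 1) * sd1 ** 2 + (n2 - 1) * sd2 ** 2) / df
    se = math.sqrt(sp2 * (1 / n1 + 1 / n2))
    if se == 0.0:
        if mean1 == mean2:
            t = 0.0
        else:
            t = math.inf if mean1 > mean2 else -math.inf
    else:
        t = (mean1 - mean2) / se
    if tails == "one":
        p = float(stats.t.sf(t, df))
    else:
        p = float(2.0 * stats.t.sf(abs(t), df))
    return TestResult("t_pooled", t, float(df), min(p, 1.0), tails)


def per_person_counts(ds: CnvDataset) -> dict[str, int]:
    """Calls per subject; subjects without calls appear with 0."""
    counts = {s.sample_id: 0 for s in ds.subjects}
    for c in ds.calls:
        counts[c.sample_id] += 1
    return counts


@dataclass(frozen=True, slots=True)
class GroupSummary:
    """Per-group burden summary: the machine-readable twin of a cohort table row."""

    group: Group
    n_subjects: int
    n_calls: int
    rate_mean: float
    rate_sd: float
    rate_sd_defined: bool
    n_loss: int
    n_gain: int
    loss_gain_ratio: float | None
    median_length_bp: float | None
    max_length_bp: int | None


def summarize_group(ds: CnvDataset, group: Group) -> GroupSummary:
    """Summarize one group's burden; errors on an empty group.

    ``rate_sd`` is the sample SD (n-1 denominator); for a single subject it
    is reported as 0 with ``rate_sd_defined=False``. ``loss_gain_ratio`` is
    kept at full precision (rounding happens only at reporting) and is None
    when the group has no gains.
    """
    subjects = ds.subjects_in(group)
    if not subjects:
        raise ValueError(f"no subjects in group {group.value}")
    counts = per_person_counts(ds)
    rates = np.array([counts[s.sample_id] for s in subjects], dtype=float)
    calls = ds.calls_in(group)
    n_loss = sum(1 for c in calls if c.state is CnvState.LOSS)
    n_gain = len(calls) - n_loss
    sd_defined = len(rates) > 1
    lengths = [c.length for c in calls]
    return GroupSummary(
        group=group,
        n_subjects=len(subjects),
        n_calls=len(calls),
        rate_mean=float(rates.mean()),
        rate_sd=float(rates.std(ddof=1)) if sd_defined else 0.0,
        rate_sd_defined=sd_defined,
        n_loss=n_loss,
        n_gain=n_gain,
        loss_gain_ratio=(n_loss / n_gain) if n_gain > 0 else None,
        median_length_bp=float(median(lengths)) if lengths else None,
        max_length_bp=max(lengths) if lengths else None,
    )


@dataclass(frozen=True, slots=True)
class OverallComparison:
    cases: GroupSummary
    controls: GroupSummary
    rate_test: TestResult
    loss_gain_test: TestResult


def compare_overall(ds: CnvDataset, tails: str = "two") -> OverallComparison:
    """Overall burden: per-person rate t-test + loss/gain chi-square across groups."""
    cases = summarize_group(ds, Group.CASE)
    controls = summarize_group(ds, Group.CONTROL)
    rate_test = t_test_from_summary(
        cases.rate_mean, cases.rate_sd, cases.n_subjects,
        controls.rate_mean, controls.rate_sd, controls.n_subjects,
        tails=tails,
    )
    lg = chi_square_2x2(cases.n_loss, cases.n_gain, controls.n_loss, controls.n_gain)
    return OverallComparison(cases, controls, rate_test, lg)


@dataclass(frozen=True, slots=True)
class RareComparison:
    cases: GroupSummary
    controls: GroupSummary
    deletion_freq_test: TestResult
    case_shift_test: TestResult
    control_shift_test: TestResult


def compare_rare(ds: CnvDataset) -> RareComparison:
    """Rare-call burden: deletion-frequency chi-square by group, plus the
    within-group shift of the rare loss/gain mix relative to the overall mix.

    The deletion-frequency test treats each CNV as one observation, so the
    compared quantities are the groups' rare deletion percentages.
    """
    rare = ds.rare_subset()
    cases_all = summarize_group(ds, Group.CASE)
    controls_all = summarize_group(ds, Group.CONTROL)
    cases_rare = summarize_group(rare, Group.CASE)
    controls_rare = summarize_group(rare, Group.CONTROL)
    del_freq = chi_square_2x2(cases_rare.n_loss, cases_rare.n_gain,
                              controls_rare.n_loss, controls_rare.n_gain)
    case_shift = chi_square_2x2(cases_all.n_loss, cases_all.n_gain,
                                cases_rare.n_loss, cases_rare.n_gain)
    control_shift = chi_square_2x2(controls_all.n_loss, controls_all.n_gain,
                                   controls_rare.n_loss, controls_rare.n_gain)
    return RareComparison(cases_rare, controls_rare, del_freq, case_shift, control_shift)


@dataclass(frozen=True, slots=True)
class SizeThresholdResult:
    threshold_bp: int
    rare_only: bool
    case_calls: int
    control_calls: int
    case_carriers: int
    control_carriers: int
    n_cases: int
    n_controls: int
    carrier_test: TestResult


def size_threshold_test(ds: CnvDataset, threshold_bp: int = 900_000,
                        rare_only: bool = True) -> SizeThresholdResult:
    """Count calls (and distinct carrier subjects) above a size threshold per
    group, and test carrier enrichment in cases with a one-tailed Fisher test.

    The 2x2 table is carriers vs non-carriers by group (subject-level);
    call-level counts are reported alongside.
    """
    sub = ds.rare_subset() if rare_only else ds
    big = [c for c in sub.calls if c.length > threshold_bp]
    gm = {s.sample_id: s.group for s in ds.subjects}
    case_calls = sum(1 for c in big if gm[c.sample_id] is Group.CASE)
    control_calls = len(big) - case_calls
    case_carriers = len({c.sample_id for c in big if gm[c.sample_id] is Group.CASE})
    control_carriers = len({c.sample_id for c in big if gm[c.sample_id] is Group.CONTROL})
    n_cases = len(ds.subjects_in(Group.CASE))
    n_controls = len(ds.subjects_in(Group.CONTROL))
    test = fisher_exact_one_tailed(case_carriers, n_cases - case_carriers,
                                   control_carriers, n_controls - control_carriers)
    return SizeThresholdResult(threshold_bp, rare_only, case_calls, control_calls,
                               case_carriers, control_carriers, n_cases, n_controls, test)


@dataclass(frozen=True)
class BurdenReport:
    """Full burden report: overall + rare comparisons + size stratification."""

    overall: OverallComparison
    rare: RareComparison | None
    size: SizeThresholdResult | None
    metadata: dict = field(default_factory=dict)

    def as_rows(self) -> list[tuple[str, str, object, str]]:
        """Flatten to (section, statistic, value, print-kind) rows for writers."""
        rows: list[tuple[str, str, object, str]] = []

        def summary_rows(section: str, s: GroupSummary) -> None:
            g = s.group.value
            rows.append((section, f"{g}.n_subjects", s.n_subjects, "count"))
            rows.append((section, f"{g}.n_calls", s.n_calls, "count"))
            rows.append((section, f"{g}.cnvs_per_person", s.rate_mean, "rate"))
            rows.append((section, f"{g}.cnvs_per_person_sd", s.rate_sd, "rate"))
            rows.append((section, f"{g}.n_deletions", s.n_loss, "count"))
            rows.append((section, f"{g}.n_duplications", s.n_gain, "count"))
            rows.append((section, f"{g}.loss_gain_ratio", s.loss_gain_ratio, "ratio"))
            rows.append((section, f"{g}.median_length_bp", s.median_length_bp, "count"))
            rows.append((section, f"{g}.max_length_bp", s.max_length_bp, "count"))

        summary_rows("overall", self.overall.cases)
        summary_rows("overall", self.overall.controls)
        rows.append(("overall", "rate_t_p", self.overall.rate_test.p_value, "p"))
        rows.append(("overall", "loss_gain_chi2_p", self.overall.loss_gain_test.p_value, "p"))
        if self.rare is not None:
            summary_rows("rare", self.rare.cases)
            summary_rows("rare", self.rare.controls)
            rows.append(("rare", "deletion_freq_chi2_p", self.rare.deletion_freq_test.p_value, "p"))
            rows.append(("rare", "case_shift_chi2_p", self.rare.case_shift_test.p_value, "p"))
            rows.append(("rare", "control_shift_chi2_p", self.rare.control_shift_test.p_value, "p"))
        if self.size is not None:
            rows.append(("size", "threshold_bp", self.size.threshold_bp, "count"))
            rows.append(("size", "case_calls_above", self.size.case_calls, "count"))
            rows.append(("size", "control_calls_above", self.size.control_calls, "count"))
            rows.append(("size", "case_carriers", self.size.case_carriers, "count"))
            rows.append(("size", "control_carriers", self.size.control_carriers, "count"))
            rows.append(("size", "carrier_fisher_one_tailed_p", self.size.carrier_test.p_value, "p"))
        return rows


def build_burden_report(ds: CnvDataset, profile: str = "study",
                        size_threshold_bp: int = 900_000) -> BurdenReport:
    """Run the full burden analysis on an annotated dataset.

    ``study`` profile: one-tailed rate t-test (the original study's
    convention); ``generic``: two-tailed. Rare sections are skipped when the
    dataset carries no rarity annotation. No multiple-testing correction is
    applied; the report metadata says so.
    """
    if profile not in ("study", "generic"):
        raise ValueError(f"unknown profile {profile!r}")
    tails = "one" if profile == "study" else "two"
    overall = compare_overall(ds, tails=tails)
    annotated = bool(ds.calls) and all(c.is_rare is not None for c in ds.calls)
    rare = None
    size = None
    if annotated:
        try:
            rare = compare_rare(ds)
        except ValueError:
            # degenerate rare counts (e.g. a zero chi-square margin): the
            # summaries are still useful, the tests are not
            rare = None
        size = size_threshold_test(ds, size_threshold_bp, rare_only=True)
    return BurdenReport(overall, rare, size, metadata={
        "profile": profile,
        "rate_test_tails": tails,
        "chi2_continuity_correction": False,
        "multiple_testing_correction": "none",
        "size_threshold_bp": size_threshold_bp,
    })
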