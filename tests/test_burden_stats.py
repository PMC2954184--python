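"""Burden statistics vs independent oracles and the study's printed values."""

import itertools
import math

import numpy as np
import pytest
from scipy import stats

from cnvburden import (
    CnvState,
    Group,
    annotate_rarity,
    build_burden_report,
    chi_square_2x2,
    compare_overall,
    compare_rare,
    fisher_exact_one_tailed,
    per_person_counts,
    size_threshold_test,
    summarize_group,
    t_test_from_summary,
)

from conftest import make_call, make_dataset


# --- independent oracles ---------------------------------------------------

def chi2_closed_form(a, b, c, d):
    """Pearson statistic from the 2x2 closed form n(ad-bc)^2 / (r1 r2 c1 c2)."""
    n = a + b + c + d
    return n * (a * d - b * c) ** 2 / ((a + b) * (c + d) * (a + c) * (b + d))


def fisher_upper_tail_enumeration(a, b, c, d):
    """P(X >= a) by exhaustive enumeration of tables at fixed margins."""
    r1, r2, c1 = a + b, c + d, a + c
    n = r1 + r2
    num = 0
    den = 0
    for x in range(max(0, c1 - r2), min(r1, c1) + 1):
        w = math.comb(r1, x) * math.comb(r2, c1 - x)
        den += w
        if x >= a:
            num += w
    return num / den


class TestChiSquare:
    @pytest.mark.parametrize("table,p_printed,ndigits", [
        ((771, 1418, 656, 1348), 0.09, 2),    # overall deletion/duplication mix
        ((44, 50, 26, 59), 0.026, 3),         # rare deletion frequency
        ((771, 1418, 44, 50), 0.022, 3),      # within-case ratio shift
        ((656, 1348, 26, 59), 0.679, 3),      # within-control ratio shift
    ])
    def test_printed_p_values(self, table, p_printed, ndigits):
        res = chi_square_2x2(*table)
        assert res.df == 1
        assert res.tails == "two"
        assert round(res.p_value, ndigits) == p_printed

    def test_overall_statistic_magnitude(self):
        assert chi_square_2x2(771, 1418, 656, 1348).statistic == pytest.approx(2.88, abs=0.01)

    def test_proportional_rows_give_zero(self):
        res = chi_square_2x2(10, 10, 10, 10)
        assert res.statistic == 0.0
        assert res.p_value == 1.0

    def test_zero_margin_rejected(self):
        with pytest.raises(ValueError):
            chi_square_2x2(0, 0, 5, 5)
        with pytest.raises(ValueError):
            chi_square_2x2(0, 5, 0, 5)

    def test_matches_closed_form_and_transpose(self):
        for a, b, c, d in itertools.product(range(1, 7), repeat=4):
            res = chi_square_2x2(a, b, c, d)
            assert res.statistic == pytest.approx(chi2_closed_form(a, b, c, d), abs=1e-10)
            assert res.p_value == pytest.approx(
                stats.chi2.sf(res.statistic, 1), abs=1e-12)
            assert chi_square_2x2(a, c, b, d).statistic == pytest.approx(res.statistic, abs=1e-10)


class TestFisherExact:
    def test_size_stratified_carrier_example(self):
        # 6 case carriers of >900 kb rare calls, none among controls
        res = fisher_exact_one_tailed(6, 166, 0, 160)
        assert res.tails == "one"
        assert res.p_value == pytest.approx(0.0185, abs=5e-4)

    def test_empty_first_column_gives_one(self):
        assert fisher_exact_one_tailed(0, 10, 0, 10).p_value == 1.0

    def test_matches_hypergeometric_enumeration(self):
        # exhaustive check over small tables, margins up to 24, zeros included
        for a, b, c, d in itertools.product(range(0, 7), repeat=4):
            if a + c == 0 or b + d == 0 or a + b == 0 or c + d == 0:
                continue
            res = fisher_exact_one_tailed(a, b, c, d)
            assert res.p_value == pytest.approx(
                fisher_upper_tail_enumeration(a, b, c, d), abs=1e-12)

    def test_random_tables_with_margins_to_thirty(self):
        rng = np.random.default_rng(19)
        for _ in range(300):
            a, b, c, d = (int(x) for x in rng.integers(0, 16, size=4))
            if min(a + b, c + d, a + c, b + d) == 0:
                continue
            assert fisher_exact_one_tailed(a, b, c, d).p_value == pytest.approx(
                fisher_upper_tail_enumeration(a, b, c, d), abs=1e-12)


class TestTTest:
    def test_printed_rate_comparison(self):
        res = t_test_from_summary(12.7, 3.7, 172, 12.5, 3.7, 160, tails="one")
        assert res.df == 330
        assert res.statistic == pytest.approx(0.492, abs=0.001)
        assert round(res.p_value, 2) == 0.31

    def test_rare_rates_not_different(self):
        res = t_test_from_summary(0.55, 0.83, 172, 0.53, 0.84, 160, tails="one")
        assert res.p_value > 0.05

    def test_equal_groups_give_half(self):
        assert t_test_from_summary(5.0, 1.0, 10, 5.0, 1.0, 10, tails="one").p_value == 0.5
        assert t_test_from_summary(5.0, 1.0, 10, 5.0, 1.0, 10, tails="two").p_value == 1.0

    def test_degenerate_zero_sds(self):
        res = t_test_from_summary(3.0, 0.0, 5, 3.0, 0.0, 5, tails="one")
        assert res.statistic == 0.0
        assert res.p_value == 0.5

    def test_summary_equals_raw_data_t(self):
        rng = np.random.default_rng(5)
        x = rng.poisson(12.0, size=40).astype(float)
        y = rng.poisson(11.0, size=35).astype(float)
        raw = stats.ttest_ind(x, y, equal_var=True)
        res = t_test_from_summary(x.mean(), x.std(ddof=1), len(x),
                                  y.mean(), y.std(ddof=1), len(y), tails="two")
        assert res.statistic == pytest.approx(raw.statistic, abs=1e-12)
        assert res.p_value == pytest.approx(raw.pvalue, abs=1e-12)

    def test_small_groups_rejected(self):
        with pytest.raises(ValueError):
            t_test_from_summary(1.0, 1.0, 1, 2.0, 1.0, 10)


class TestSummaries:
    def test_per_person_counts_include_zero_callers(self, small_dataset):
        counts = per_person_counts(small_dataset)
        assert counts == {"caseA": 2, "caseB": 1, "ctrlA": 2, "ctrlB": 1}
        shuffled = small_dataset.with_calls(tuple(reversed(small_dataset.calls)))
        assert per_person_counts(shuffled) == counts

    def test_group_summary_fields(self, small_dataset):
        s = summarize_group(small_dataset, Group.CASE)
        assert s.n_subjects == 2
        assert s.n_calls == 3
        assert s.n_loss == 1 and s.n_gain == 2
        assert s.loss_gain_ratio == pytest.approx(0.5)
        assert s.rate_mean == pytest.approx(1.5)
        assert s.rate_sd_defined

    def test_printed_ratios(self):
        # ratios round to the printed 0.54 (cases) and 0.49 (controls)
        assert round(771 / 1418, 2) == 0.54
        assert round(656 / 1348, 2) == 0.49

    def test_single_subject_sd_flagged(self):
        ds = make_dataset([make_call("only", "1", 0, 200_000)])
        s = summarize_group(ds, Group.CASE)
        assert s.rate_mean == 1.0
        assert s.rate_sd == 0.0
        assert not s.rate_sd_defined

    def test_empty_group_errors(self, small_dataset):
        ds = small_dataset.with_calls(())
        ds = ds.__class__(tuple(s for s in ds.subjects if s.group is Group.CASE), ())
        with pytest.raises(ValueError):
            summarize_group(ds, Group.CONTROL)


class TestComparisons:
    def test_overall_comparison(self, small_dataset):
        res = compare_overall(small_dataset, tails="two")
        assert res.rate_test.method == "t_pooled"
        assert res.loss_gain_test.method == "pearson_chi2"
        assert 0 <= res.rate_test.p_value <= 1

    def test_rare_equal_to_all_gives_zero_shift(self, small_dataset):
        # empty catalogue: every call rare, shift tables have identical rows
        ds = annotate_rarity(small_dataset, [])
        res = compare_rare(ds)
        assert res.case_shift_test.statistic == pytest.approx(0.0, abs=1e-12)
        assert res.case_shift_test.p_value == pytest.approx(1.0)
        assert res.control_shift_test.statistic == pytest.approx(0.0, abs=1e-12)

    def test_report_invariant_under_row_order(self, small_dataset):
        ds = annotate_rarity(small_dataset, [])
        r1 = build_burden_report(ds)
        r2 = build_burden_report(ds.with_calls(tuple(reversed(ds.calls))))
        assert [row[:3] for row in r1.as_rows()] == [row[:3] for row in r2.as_rows()]


class TestSizeThreshold:
    def make_annotated(self):
        calls = [make_call("case1", "1", 0, 1_000_000),
                 make_call("case1", "2", 0, 950_000),
                 make_call("case2", "3", 0, 500_000),
                 make_call("ctrl1", "4", 0, 400_000)]
        ds = make_dataset(calls, case_ids={"case1", "case2"}, control_ids={"ctrl1"})
        return annotate_rarity(ds, [])

    def test_counts_calls_and_carriers(self):
        res = size_threshold_test(self.make_annotated(), 900_000)
        assert res.case_calls == 2
        assert res.case_carriers == 1  # both large calls in the same subject
        assert res.control_calls == res.control_carriers == 0
        assert res.carrier_test.method == "fisher_exact"

    def test_threshold_above_max_gives_p_one(self):
        res = size_threshold_test(self.make_annotated(), 10_000_000)
        assert res.case_calls == res.control_calls == 0
        assert res.carrier_test.p_value == 1.0

    def test_lowering_threshold_never_decreases_counts(self):
        ds = self.make_annotated()
        prev = -1
        for thr in (2_000_000, 900_000, 400_000, 100_000):
            res = size_threshold_test(ds, thr)
            total = res.case_calls + res.control_calls
            assert total >= prev
            prev = total
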