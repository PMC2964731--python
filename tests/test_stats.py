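import datetime as dt
import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from registryqc.records import FieldValue, PatientRecord
from registryqc.simulate import GeneratorSpec, generate_cohort, generate_table1_cohort
from registryqc.stats import (
    RecordCategory,
    TraceEvent,
    classify_records,
    clopper_pearson_ci,
    cooccurrence_analysis,
    effectiveness_analysis,
    fisher_exact_2x2,
    hochberg_adjust,
    round_half_up,
    utilization_summary,
)

from conftest import make_record


# ---------------------------------------------------------------------------
# independent oracles

def cp_ci_by_tail_inversion(x, n, alpha=0.05, tol=1e-10):
    """Clopper-Pearson by direct bisection on the binomial tail sums."""
    def upper_tail(p):  # P(X >= x)
        return sum(math.comb(n, k) * p**k * (1 - p) ** (n - k) for k in range(x, n + 1))

    def lower_tail(p):  # P(X <= x)
        return sum(math.comb(n, k) * p**k * (1 - p) ** (n - k) for k in range(0, x + 1))

    def bisect(f, target, increasing):
        lo, hi = 0.0, 1.0
        for _ in range(200):
            mid = (lo + hi) / 2
            if (f(mid) < target) == increasing:
                lo = mid
            else:
                hi = mid
            if hi - lo < tol:
                break
        return (lo + hi) / 2

    low = 0.0 if x == 0 else bisect(upper_tail, alpha / 2, increasing=True)
    high = 1.0 if x == n else bisect(lower_tail, alpha / 2, increasing=False)
    return 100 * low, 100 * high


def fisher_p_by_enumeration(a, b, c, d):
    """Two-sided Fisher p by exhaustive enumeration over the hypergeometric
    support, summing probabilities <= the observed one (1e-7 slack)."""
    r1, r2, c1 = a + b, c + d, a + c

    def prob(k):
        return (
            math.comb(r1, k) * math.comb(r2, c1 - k) / math.comb(r1 + r2, c1)
        )

    lo, hi = max(0, c1 - r2), min(r1, c1)
    p_obs = prob(a)
    return sum(p for k in range(lo, hi + 1) if (p := prob(k)) <= p_obs * (1 + 1e-7))


def hochberg_by_formula(ps):
    """Direct evaluation of the step-up definition: sort descending,
    adj_i = min_{j<=i} (m-j+1) * p_(j), clipped at 1, back to input order."""
    m = len(ps)
    order = sorted(range(m), key=lambda i: -ps[i])
    adj = [0.0] * m
    running = math.inf
    for rank, i in enumerate(order):  # rank 0 = largest p, multiplier 1
        running = min(running, (rank + 1) * ps[i])
        adj[i] = min(1.0, running)
    return adj


# ---------------------------------------------------------------------------

class TestClopperPearson:
    @pytest.mark.parametrize("x,n,lo,hi", [
        (18, 226, 4.8, 12.3),
        (15, 226, 3.8, 10.7),
        (20, 226, 5.5, 13.3),
        (18, 118, 9.3, 23.0),
        (12, 118, 5.4, 17.1),
        (24, 118, 13.5, 28.7),
    ])
    def test_published_prevalence_intervals(self, x, n, lo, hi):
        """95% exact intervals for the six missing-field prevalences."""
        low, high = clopper_pearson_ci(x, n, 0.05)
        assert round_half_up(low, 1) == lo
        assert round_half_up(high, 1) == hi

    def test_zero_successes_lower_bound_exact(self):
        low, high = clopper_pearson_ci(0, 50, 0.05)
        assert low == 0.0 and 0 < high < 100

    def test_all_successes_upper_bound_exact(self):
        low, high = clopper_pearson_ci(50, 50, 0.05)
        assert high == 100.0 and 0 < low < 100

    @pytest.mark.parametrize("x,n", [(24, 118), (18, 226), (0, 30), (30, 30), (1, 7), (5, 9)])
    def test_matches_tail_inversion_oracle(self, x, n):
        got = clopper_pearson_ci(x, n, 0.05)
        want = cp_ci_by_tail_inversion(x, n, 0.05)
        assert got == pytest.approx(want, abs=1e-6)

    @pytest.mark.parametrize("x,n,alpha", [(-1, 5, 0.05), (6, 5, 0.05), (1, 0, 0.05),
                                           (1, 5, 0.0), (1, 5, 1.0)])
    def test_invalid_arguments(self, x, n, alpha):
        with pytest.raises(ValueError):
            clopper_pearson_ci(x, n, alpha)

    def test_coverage_is_conservative(self):
        """Exact intervals over-cover: >= 94% empirical coverage of p=0.1
        at n=118 over 10,000 simulated binomial draws."""
        rng = np.random.default_rng(42)
        n, p = 118, 0.1
        bounds = [clopper_pearson_ci(x, n, 0.05) for x in range(n + 1)]
        draws = rng.binomial(n, p, size=10_000)
        covered = sum(bounds[x][0] <= 100 * p <= bounds[x][1] for x in draws)
        assert covered / 10_000 >= 0.94


class TestFisherExact:
    def test_published_remission_table(self):
        """No missing relapse dates among the 86 summary-accessed records
        vs 5 of 78 others."""
        p = fisher_exact_2x2([[0, 86], [5, 73]])
        assert round(p, 3) == 0.023

    def test_published_correction_table(self):
        p = fisher_exact_2x2([[16, 446], [4, 690]])
        assert f"{p:.0e}" == "3e-04"

    def test_symmetric_table(self):
        assert fisher_exact_2x2([[1, 1], [1, 1]]) == 1.0

    def test_zero_margin_convention(self, caplog):
        with caplog.at_level("WARNING"):
            assert fisher_exact_2x2([[0, 0], [3, 4]]) == 1.0
        assert "degenerate" in caplog.text

    def test_rejects_negative_and_non_integer(self):
        with pytest.raises(ValueError):
            fisher_exact_2x2([[-1, 2], [3, 4]])
        with pytest.raises(ValueError):
            fisher_exact_2x2([[0.5, 2], [3, 4]])

    def test_matches_enumeration_oracle_small_tables(self):
        """Equality with exhaustive hypergeometric enumeration on all 2x2
        tables with every margin <= 8 (the full <=12 sweep runs in the
        acceptance suite)."""
        for a, b, c, d in itertools.product(range(9), repeat=4):
            if min(a + b, c + d, a + c, b + d) == 0:
                continue
            if max(a + b, c + d, a + c, b + d) > 8:
                continue
            assert fisher_exact_2x2([[a, b], [c, d]]) == pytest.approx(
                fisher_p_by_enumeration(a, b, c, d), abs=1e-9
            ), (a, b, c, d)


class TestHochberg:
    def test_single_p_unchanged(self):
        assert hochberg_adjust([0.037]) == [0.037]

    def test_three_p_example(self):
        ps = [0.01, 0.04, 0.03]
        assert hochberg_adjust(ps) == pytest.approx(hochberg_by_formula(ps))

    def test_all_equal_ties(self):
        ps = [0.02, 0.02, 0.02]
        got = hochberg_adjust(ps)
        assert got == pytest.approx(hochberg_by_formula(ps))
        # the largest p keeps multiplier 1, and ties propagate it
        assert got == pytest.approx([0.02, 0.02, 0.02])

    def test_monotone_in_raw_p(self):
        ps = [0.001, 0.2, 0.04, 0.9, 0.04]
        adj = hochberg_adjust(ps)
        for i, j in itertools.combinations(range(len(ps)), 2):
            if ps[i] <= ps[j]:
                assert adj[i] <= adj[j] + 1e-12

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            hochberg_adjust([0.5, 1.2])

    @given(st.lists(st.floats(min_value=0, max_value=1), min_size=1, max_size=8),
           st.randoms(use_true_random=False))
    @settings(max_examples=200, deadline=None)
    def test_matches_formula_and_permutation_invariant(self, ps, rnd):
        adj = hochberg_adjust(ps)
        assert adj == pytest.approx(hochberg_by_formula(ps))
        perm = list(range(len(ps)))
        rnd.shuffle(perm)
        adj_perm = hochberg_adjust([ps[i] for i in perm])
        assert adj_perm == pytest.approx([adj[i] for i in perm])


# ---------------------------------------------------------------------------

def _probe_cohort(n_complete, n_not_found, n_found, missing_counts_b, missing_counts_c):
    """Deterministic cohort with exact per-category probe-field missing counts."""
    from registryqc.records import ClinicalEvent, EventType

    records, review = [], {}
    probe = ["gender", "dob", "cancer_site"]
    k = 0

    def make(with_xrt, missing_fields):
        nonlocal k
        rec = make_record(f"C{k:05d}")
        if not with_xrt:
            rec.events = [e for e in rec.events
                          if e.event_type not in (EventType.XRT_START, EventType.XRT_END)]
        for f in missing_fields:
            setattr(rec, f, FieldValue.unknown())
        k += 1
        return rec

    for _ in range(n_complete):
        records.append(make(True, []))
    for cat_n, counts, found in ((n_not_found, missing_counts_b, False),
                                 (n_found, missing_counts_c, True)):
        for i in range(cat_n):
            missing = [f for f, cnt in zip(probe, counts) if i < cnt]
            rec = make(False, missing)
            records.append(rec)
            review[rec.record_id] = found
    return records, review


class TestClassifyRecords:
    def test_published_category_counts(self):
        """2,250 sarcoma records, 344 with no radiation start date, 118 of
        which were recovered on manual review."""
        records, review = _probe_cohort(1906, 226, 118, (0, 0, 0), (0, 0, 0))
        cats = classify_records(records, "xrt_start", review)
        counts = {c: sum(1 for v in cats.values() if v == c) for c in RecordCategory}
        assert counts[RecordCategory.NO_MISSING_INDEX] == 1906
        assert counts[RecordCategory.MISSING_NOT_FOUND] == 226
        assert counts[RecordCategory.MISSING_FOUND] == 118
        assert round_half_up(100 * 118 / 344, 1) == 34.3

    def test_no_missing_index(self):
        records, _ = _probe_cohort(5, 0, 0, (0, 0, 0), (0, 0, 0))
        cats = classify_records(records, "xrt_start", {})
        assert set(cats.values()) == {RecordCategory.NO_MISSING_INDEX}

    def test_review_for_present_index_rejected(self):
        records, review = _probe_cohort(2, 1, 0, (0, 0, 0), (0, 0, 0))
        review[records[0].record_id] = True  # record 0 has its index field
        with pytest.raises(ValueError, match="present"):
            classify_records(records, "xrt_start", review)

    def test_missing_review_rejected(self):
        records, _ = _probe_cohort(0, 1, 0, (0, 0, 0), (0, 0, 0))
        with pytest.raises(ValueError, match="no review result"):
            classify_records(records, "xrt_start", {})

    def test_generator_ground_truth_agrees(self):
        records, _, gtl = generate_cohort(GeneratorSpec(seed=5, n_records=400))
        cats = classify_records(records, "xrt_start", gtl.review_results)
        assert {k: v.value for k, v in cats.items()} == gtl.categories


class TestCooccurrence:
    def test_zero_missingness(self):
        records, review = _probe_cohort(10, 5, 5, (0, 0, 0), (0, 0, 0))
        table = cooccurrence_analysis(records, "xrt_start", review)
        for row in table.rows.values():
            for fs in row.fields.values():
                assert fs.missing == 0 and fs.percent == 0.0

    def test_empty_category_row(self):
        records, review = _probe_cohort(4, 2, 0, (0, 0, 0), (0, 0, 0))
        table = cooccurrence_analysis(records, "xrt_start", review)
        row = table.rows[RecordCategory.MISSING_FOUND]
        assert row.n == 0 and math.isnan(row.fields["gender"].percent)
        assert "-" in table.to_tsv()

    def test_any_missing_at_least_max_single_field(self):
        records, _, gtl = generate_cohort(GeneratorSpec(seed=9, n_records=600))
        table = cooccurrence_analysis(records, "xrt_start", gtl.review_results)
        for row in table.rows.values():
            if row.n == 0:
                continue
            assert row.any_missing.percent >= max(
                fs.percent for fs in row.fields.values()) - 1e-12

    def test_adjusted_pvalues_reported(self):
        records, review = _probe_cohort(50, 226, 118, (18, 15, 20), (18, 12, 24))
        table = cooccurrence_analysis(records, "xrt_start", review)
        assert set(table.pvalues_adjusted) == set(table.pvalues)
        for f in table.pvalues:
            assert table.pvalues_adjusted[f] >= table.pvalues[f] - 1e-12


# ---------------------------------------------------------------------------

T0 = dt.datetime(2008, 7, 10, 10, 0)


def _trace(kind, rid, minutes, field="", before="", after="", user="u1"):
    return TraceEvent(kind=kind, record_id=rid, user_id=user,
                      timestamp=T0 + dt.timedelta(minutes=minutes),
                      field=field, before=before, after=after)


class TestEffectiveness:
    def _records(self, n, prefix="E"):
        return [make_record(f"{prefix}{i:04d}") for i in range(n)]

    def test_no_traces(self):
        records = self._records(6)
        res = effectiveness_analysis(records, [])
        assert res.contingency == ((0, 0), (0, 6))
        assert res.fisher_p == 1.0
        assert res.window_attributed == 0

    def test_planted_latencies_window_attribution(self):
        """Accesses followed by edits at 5 and 15 minutes: only the 5-minute
        correction is attributed to the access under a 10-minute window."""
        records = self._records(3)
        traces = [
            _trace("summary_access", "E0000", 0),
            _trace("field_edit", "E0000", 5, "relapse_date", "", "2003-01-01"),
            _trace("summary_access", "E0001", 0),
            _trace("field_edit", "E0001", 15, "relapse_date", "", "2003-01-01"),
        ]
        res = effectiveness_analysis(records, traces, window_minutes=10)
        assert res.corrected_accessed == 2
        assert res.window_attributed == 1

    def test_latest_preceding_access_is_reference(self):
        records = self._records(1)
        traces = [
            _trace("summary_access", "E0000", 0),
            _trace("summary_access", "E0000", 30),
            _trace("field_edit", "E0000", 36, "relapse_date", "", "2003-01-01"),
        ]
        res = effectiveness_analysis(records, traces, window_minutes=10)
        assert res.window_attributed == 1

    def test_noop_edit_ignored(self, caplog):
        records = self._records(1)
        traces = [_trace("field_edit", "E0000", 1, "relapse_date", "", "")]
        with caplog.at_level("WARNING"):
            res = effectiveness_analysis(records, traces)
        assert res.corrected_not_accessed == 0
        assert "no-op" in caplog.text

    def test_revision_counted_separately(self):
        records = self._records(1)
        traces = [_trace("field_edit", "E0000", 1, "relapse_date",
                         "2002-01-01", "2003-01-01")]
        res = effectiveness_analysis(records, traces)
        assert res.revisions == 1
        assert res.corrected_not_accessed == 0

    def test_margins_conserve_n(self):
        records, traces, _ = generate_cohort(GeneratorSpec(seed=13, n_records=500))
        res = effectiveness_analysis(records, traces)
        assert sum(sum(r) for r in res.contingency) == 500
        assert res.n_accessed + res.n_not_accessed == 500

    def test_unknown_record_in_trace_rejected(self):
        with pytest.raises(ValueError, match="unknown record"):
            effectiveness_analysis(self._records(1), [_trace("summary_access", "ZZ", 0)])


class TestUtilization:
    def test_no_traces_all_zero(self):
        records = [make_record(f"U{i}") for i in range(4)]
        util = utilization_summary(records, [])
        assert util.overall_rate == 0.0
        assert util.histogram == {"0": 4, "1": 0, "2": 0, "3+": 0}

    def test_histogram_totals_record_count(self):
        records, traces, _ = generate_cohort(GeneratorSpec(seed=17, n_records=300))
        util = utilization_summary(records, traces)
        assert sum(util.histogram.values()) == 300

    def test_published_overall_rate(self):
        """462 of 1,156 updated records accessed plus 69.0% of 200 new ones:
        44.2% of all 1,356 records."""
        records = []
        traces = []
        for i in range(1156):
            rec = make_record(f"V{i:04d}")
            rec.is_new = False
            records.append(rec)
            if i < 462:
                traces.append(_trace("summary_access", rec.record_id, i))
        for i in range(200):
            rec = make_record(f"N{i:04d}")
            rec.is_new = True
            records.append(rec)
            if i < 138:  # 69.0% of 200
                traces.append(_trace("summary_access", rec.record_id, 3000 + i))
        util = utilization_summary(records, traces)
        assert round_half_up(util.overall_rate, 1) == 44.2
        assert round_half_up(util.new_rate, 1) == 69.0
        assert round_half_up(util.update_rate, 1) == 40.0
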