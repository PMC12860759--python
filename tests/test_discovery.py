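"""Optimised cutoffs, Benjamini-Hochberg control and marker selection."""

import numpy as np
import pandas as pd
import pytest

from texsurv.discovery import (
    BHTable,
    CutoffResult,
    MarkerDiscovery,
    adverse_mask,
    benjamini_hochberg,
    combine_markers,
    format_p,
    median_cutoff_check,
    optimize_cutoff,
    select_best_markers,
)
from texsurv.survival import binary_group_hr, logrank_test
from texsurv.synthetic import CohortSpec, gen_cohort


def brute_force_best_split(cohort, marker, min_group_size=2):
    """Independent exhaustive scan with the scalar log-rank test."""
    sub = cohort[cohort[marker].notna()]
    t = sub.time_months.to_numpy()
    e = sub.event.to_numpy(int)
    v = sub[marker].to_numpy()
    uniq = np.sort(np.unique(v))
    best = (np.inf, None)
    for c in (uniq[:-1] + uniq[1:]) / 2:
        below = v < c
        if min(below.sum(), (~below).sum()) < min_group_size:
            continue
        p = logrank_test(t, e, below).p
        if p < best[0]:
            best = (p, c)
    return best


class TestOptimizeCutoff:
    def test_equals_exhaustive_scan(self):
        """The returned p is the minimum over every admissible
        dichotomisation (brute-force oracle, n <= 30)."""
        for seed in range(5):
            c = gen_cohort(CohortSpec(seed=seed, n_subjects=24, n_events_target=10))
            res = optimize_cutoff(c, "marker_1")
            p_bf, _ = brute_force_best_split(c, "marker_1")
            assert res.p == pytest.approx(p_bf, rel=1e-10)

    def test_monotone_transform_invariance(self):
        c = gen_cohort(CohortSpec(seed=4, n_subjects=40, n_events_target=15))
        res1 = optimize_cutoff(c, "marker_1")
        c2 = c.copy()
        c2["marker_1"] = np.exp(c2["marker_1"] / 20.0)
        res2 = optimize_cutoff(c2, "marker_1")
        assert res2.p == pytest.approx(res1.p, rel=1e-10)
        assert (res2.n_poor, res2.n_good) == (res1.n_poor, res1.n_good)

    def test_direction_reports_worse_survival_side(self):
        c = gen_cohort(
            CohortSpec(seed=8, n_subjects=120, n_events_target=40, planted_hr=6.0,
                       marker_direction=">=")
        )
        res = optimize_cutoff(c, "marker_1")
        poor = adverse_mask(c.marker_1.to_numpy(), res)
        hr = binary_group_hr(c.time_months, c.event, poor)
        assert hr.hr > 1.0

    def test_group_size_floor_respected(self):
        c = gen_cohort(CohortSpec(seed=2, n_subjects=30, n_events_target=12))
        res = optimize_cutoff(c, "marker_1", min_group_size=5)
        assert min(res.n_poor, res.n_good) >= 5

    def test_constant_marker_rejected(self):
        c = gen_cohort(CohortSpec(seed=2, n_subjects=20, n_events_target=8))
        c["marker_1"] = 1.0
        with pytest.raises(ValueError, match="constant"):
            optimize_cutoff(c, "marker_1")

    def test_impossible_floor_rejected(self):
        c = gen_cohort(CohortSpec(seed=2, n_subjects=10, n_events_target=5))
        with pytest.raises(ValueError):
            optimize_cutoff(c, "marker_1", min_group_size=8)

    def test_missing_values_dropped_per_marker(self):
        c = gen_cohort(CohortSpec(seed=6, n_subjects=40, n_events_target=15))
        c.loc[:4, "marker_1"] = np.nan
        res = optimize_cutoff(c, "marker_1")
        assert res.n_poor + res.n_good == 35


class TestMedianCutoff:
    def test_median_split_convention_odd_n(self):
        """With an odd sample the subject at the median sits on the '>='
        side (poor group is '<' only for values strictly below)."""
        c = gen_cohort(CohortSpec(seed=1, n_subjects=11, n_events_target=5))
        res = median_cutoff_check(c, "marker_1")
        v = c.marker_1.to_numpy()
        below = v < np.median(v)
        assert {res.n_poor, res.n_good} == {int(below.sum()), int((~below).sum())}

    def test_equals_optimized_when_truth_at_median(self):
        """A strong effect whose cut sits at the sample median: the
        optimised search lands on the median split, so both p agree."""
        rng = np.random.default_rng(0)
        n = 60
        poor = np.arange(n) < n // 2
        time = np.where(poor, rng.exponential(5.0, n), rng.exponential(80.0, n))
        cohort = pd.DataFrame(
            {
                "time_months": np.round(time, 3) + 0.001,
                "event": 1,
                "marker_1": np.where(poor, 60.0, 40.0) + rng.normal(0, 1, n),
            }
        )
        res_opt = optimize_cutoff(cohort, "marker_1")
        res_med = median_cutoff_check(cohort, "marker_1")
        assert res_opt.p == pytest.approx(res_med.p, rel=1e-10)

    def test_optimized_never_worse_than_median_split(self):
        """The optimised minimum-p is <= the median-split p whenever the
        median split is admissible (superset of candidates)."""
        for seed in range(10):
            c = gen_cohort(CohortSpec(seed=seed))
            res_opt = optimize_cutoff(c, "marker_1")
            res_med = median_cutoff_check(c, "marker_1")
            assert res_opt.p <= res_med.p + 1e-12

    def test_constant_marker_rejected(self):
        c = gen_cohort(CohortSpec(seed=1, n_subjects=10, n_events_target=4))
        c["marker_1"] = 3.0
        with pytest.raises(ValueError, match="degenerate"):
            median_cutoff_check(c, "marker_1")


class TestBenjaminiHochberg:
    def test_critical_value_column_m45_q02(self):
        """45 tested markers at FDR 0.2: critical value is rank*0.2/45 —
        0.0044, 0.0222, 0.0444, 0.1600, 0.2000 at ranks 1, 5, 10, 36, 45."""
        p = np.linspace(0.001, 0.9, 45)
        bh = benjamini_hochberg(p, q=0.2)
        crit = bh.table.set_index("rank")["critical"]
        for rank, expected in [(1, 0.0044), (5, 0.0222), (10, 0.0444),
                               (36, 0.1600), (45, 0.2000)]:
            assert round(crit.loc[rank], 4) == expected

    def test_single_pvalue_critical_is_q(self):
        bh = benjamini_hochberg([0.03], q=0.2)
        assert bh.table.critical.iloc[0] == pytest.approx(0.2)
        assert bh.significant == ["m0"]

    def test_flags_match_step_up_oracle(self, rng):
        """Random p-vectors: flags equal the brute-force step-up rule
        (largest k with p_(k) <= k q/m; all smaller ranks flagged)."""
        for _ in range(50):
            m = rng.integers(1, 40)
            p = rng.random(m) ** 2
            bh = benjamini_hochberg(p, q=0.2)
            sp = np.sort(p)
            k = 0
            for i in range(1, m + 1):
                if sp[i - 1] <= i * 0.2 / m:
                    k = i
            expected = [rank <= k for rank in range(1, m + 1)]
            assert bh.table.significant.tolist() == expected

    def test_step_up_monotonicity_dropping_largest_p(self, rng):
        """Removing the largest p never de-flags a previously significant
        smaller p."""
        for _ in range(20):
            p = rng.random(15)
            before = benjamini_hochberg(p, q=0.2)
            sig_before = set(
                before.table.loc[before.table.significant, "p"].round(12)
            )
            reduced = np.delete(p, np.argmax(p))
            after = benjamini_hochberg(reduced, q=0.2)
            sig_after = set(after.table.loc[after.table.significant, "p"].round(12))
            assert sig_before <= sig_after

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            benjamini_hochberg([0.0, 0.5])
        with pytest.raises(ValueError):
            benjamini_hochberg([0.5], q=1.5)


def _cr(marker, p, n_poor, n_good, median_p=None):
    return CutoffResult(
        marker=marker, cutoff=1.0, direction="<", n_poor=n_poor, n_good=n_good,
        chi2=1.0, p=p, median_p=median_p,
    )


class TestSelection:
    def test_balance_breaks_p_ties(self):
        """At equal p (to 4 dp), a 27/39 split outranks a 6/60 split."""
        results = [_cr("a", 0.00009, 6, 60), _cr("b", 0.00008, 27, 39)]
        bh = benjamini_hochberg([r.p for r in results], q=0.2,
                                markers=[r.marker for r in results])
        short = select_best_markers(results, bh)
        assert [r.marker for r, _ in short] == ["b", "a"]

    def test_single_significant_marker(self):
        results = [_cr("a", 0.001, 10, 20)]
        bh = benjamini_hochberg([0.001], q=0.2, markers=["a"])
        short = select_best_markers(results, bh)
        assert len(short) == 1 and short[0][0].marker == "a"

    def test_order_invariance(self):
        results = [_cr("a", 0.003, 5, 40), _cr("b", 0.001, 20, 25),
                   _cr("c", 0.003, 22, 23)]
        bh = benjamini_hochberg([r.p for r in results], q=0.2,
                                markers=[r.marker for r in results])
        fwd = [r.marker for r, _ in select_best_markers(results, bh)]
        rev = [r.marker for r, _ in select_best_markers(results[::-1], bh)]
        assert fwd == rev == ["b", "c", "a"]

    def test_median_significance_filter(self):
        results = [_cr("a", 0.001, 10, 20, median_p=0.2),
                   _cr("b", 0.002, 10, 20, median_p=0.01)]
        bh = benjamini_hochberg([0.001, 0.002], q=0.2, markers=["a", "b"])
        short = select_best_markers(results, bh, require_median_significant=True)
        assert [r.marker for r, _ in short] == ["b"]

    def test_empty_input_gives_empty_shortlist(self):
        bh = benjamini_hochberg([0.9], q=0.2, markers=["x"])
        assert select_best_markers([], bh) == []


class TestCombineMarkers:
    def test_disjoint_adverse_sets_flagged(self):
        c = gen_cohort(CohortSpec(seed=1), n_null_markers=1)
        v = c.marker_1.to_numpy()
        lo, hi = np.quantile(v, [0.25, 0.75])
        ra = _cr("marker_1", 0.01, 10, 56)
        ra = CutoffResult(**{**ra.__dict__, "cutoff": lo, "direction": "<"})
        rb = CutoffResult(**{**ra.__dict__, "cutoff": hi, "direction": ">="})
        out = combine_markers(c, ra, rb)
        assert out.flagged_empty and out.hr is None

    def test_subset_adversity_equals_smaller_set(self):
        c = gen_cohort(CohortSpec(seed=2), n_linked_markers=2)
        va = c.marker_1.to_numpy()
        ra = _cr("marker_1", 0.01, 0, 0)
        ra = CutoffResult(**{**ra.__dict__, "cutoff": np.quantile(va, 0.8),
                             "direction": ">="})
        rb = CutoffResult(**{**ra.__dict__})
        rb = CutoffResult(**{**rb.__dict__, "marker": "marker_2",
                             "cutoff": c.marker_2.min() - 1.0})
        out = combine_markers(c, ra, rb)  # B adverse everywhere
        assert out.n_poor == int(adverse_mask(va, ra).sum())

    def test_combined_hr_exceeds_singles_on_planted_cohorts(self):
        """Two markers tagging the same high-hazard subgroup: the joint
        stratum's HR is at least each single-marker HR in >=80 of 100
        replicates."""
        wins = 0
        for seed in range(100):
            c = gen_cohort(
                CohortSpec(seed=seed, n_subjects=120, n_events_target=45,
                           planted_hr=3.0),
                n_linked_markers=2,
            )
            t, e = c.time_months.to_numpy(), c.event.to_numpy(int)
            singles = []
            strata = []
            for m in ("marker_1", "marker_2"):
                poor = c[m].to_numpy() >= 50.0
                singles.append(binary_group_hr(t, e, poor).hr)
                strata.append(poor)
            both = strata[0] & strata[1]
            if not both.any() or both.all():
                continue
            combined = binary_group_hr(t, e, both).hr
            wins += combined >= max(singles) - 1e-9
        assert wins >= 80

    def test_type_one_inflation_of_naive_optimised_search(self):
        """Global null, 45 independent markers, 66 subjects / ~19 events:
        the chance of at least one raw optimised p < 0.05 dwarfs the
        nominal 5% level — the reason BH control and cross-validation
        exist."""
        hits = 0
        n_rep = 25
        for seed in range(n_rep):
            c = gen_cohort(
                CohortSpec(seed=seed, planted_hr=1.0), n_null_markers=44
            )
            pmin = min(
                optimize_cutoff(c, f"marker_{i}").p for i in range(1, 46)
            )
            hits += pmin < 0.05
        assert hits / n_rep > 0.5


class TestModelObject:
    def test_fit_recovers_planted_marker(self, strong_cohort):
        res = MarkerDiscovery(strong_cohort).fit(seed=11)
        assert "marker_1" in res.bh.significant or "marker_2" in res.bh.significant
        table = res.summary()
        assert set(table.columns) >= {"marker", "cutoff (poor)", "n_poor",
                                      "n_good", "p", "BH critical", "significant"}
        assert len(table) == 6

    def test_requires_survival_columns(self):
        with pytest.raises(ValueError, match="time_months"):
            MarkerDiscovery(pd.DataFrame({"marker_1": [1.0, 2.0]}))

    def test_p_display_convention(self):
        assert format_p(5e-5) == "<0.0001"
        assert format_p(0.0123) == "0.0123"
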