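"""Kaplan-Meier, log-rank, median split and maximally selected cutpoints."""

import numpy as np
import pandas as pd
import pytest
from lifelines.statistics import logrank_test as ll_logrank

from cafsubsets import (
    SchemaError,
    assign_bulk_phenotype,
    generate_survival_cohort,
    km_estimate,
    logrank_test,
    max_selected_cutpoint,
    median_split,
    truncate_followup,
)
from cafsubsets.survival import CutpointResult, logrank_score

from conftest import make_survival_table


class TestKaplanMeier:
    def test_hand_product_limit_calculation(self):
        """times {1 event, 2 censored, 3 event}: S(1)=2/3, S(3)=0."""
        tbl = make_survival_table([1, 2, 3], [1, 0, 1])
        km = km_estimate(tbl)
        assert km.probability_at(1) == pytest.approx(2 / 3)
        assert km.probability_at(2) == pytest.approx(2 / 3)
        assert km.probability_at(3) == pytest.approx(0.0)

    def test_all_censored_curve_stays_at_1(self):
        tbl = make_survival_table([5, 10, 15], [0, 0, 0])
        km = km_estimate(tbl)
        assert np.allclose(km.survival, 1.0)

    def test_duplicating_cohort_leaves_curve_unchanged(self):
        tbl = make_survival_table([3, 5, 8, 11], [1, 0, 1, 1])
        double = pd.concat([tbl, tbl], ignore_index=True)
        a, b = km_estimate(tbl), km_estimate(double)
        assert np.allclose(a.times, b.times)
        assert np.allclose(a.survival, b.survival)

    def test_curve_nonincreasing_starts_at_most_1(self):
        tbl = generate_survival_cohort(n_patients=80, seed=5)
        km = km_estimate(tbl)
        assert km.survival[0] <= 1.0 + 1e-12
        assert (np.diff(km.survival) <= 1e-12).all()
        assert ((km.survival >= 0) & (km.survival <= 1)).all()

    def test_no_censoring_equals_empirical_survival(self):
        rng = np.random.default_rng(0)
        times = rng.exponential(100, 60).round(1)
        tbl = make_survival_table(times, np.ones(60))
        km = km_estimate(tbl)
        for t in np.quantile(times, [0.1, 0.5, 0.9]):
            assert km.probability_at(t) == pytest.approx((times > t).mean())

    def test_negative_time_rejected(self):
        with pytest.raises(SchemaError):
            km_estimate(make_survival_table([-1, 2], [1, 1]))


class TestLogrank:
    def test_identical_groups_statistic_zero_p_one(self):
        g = make_survival_table([1, 3, 5, 7], [1, 1, 0, 1])
        chi2, df, p = logrank_test([g, g.copy()])
        assert chi2 == pytest.approx(0.0, abs=1e-12)
        assert df == 1
        assert p == pytest.approx(1.0)

    def test_hand_hypergeometric_calculation(self):
        """A={1,2} events, B={3,4} events: U=7/6, V=17/36, chi2=49/17."""
        a = make_survival_table([1, 2], [1, 1])
        b = make_survival_table([3, 4], [1, 1])
        time = np.array([1, 2, 3, 4], dtype=float)
        event = np.ones(4, dtype=int)
        in_a = np.array([True, True, False, False])
        U, V = logrank_score(time, event, in_a)
        assert U == pytest.approx(7 / 6, abs=1e-9)
        assert V == pytest.approx(17 / 36, abs=1e-9)
        chi2, _, _ = logrank_test([a, b])
        assert chi2 == pytest.approx(49 / 17, abs=1e-9)

    def test_empty_group_rejected(self):
        g = make_survival_table([1, 2], [1, 1])
        with pytest.raises(ValueError):
            logrank_test([g, g.iloc[:0]])

    def test_invariance_under_monotone_time_transform(self):
        rng = np.random.default_rng(1)
        a = make_survival_table(rng.exponential(10, 40), rng.integers(0, 2, 40))
        b = make_survival_table(rng.exponential(14, 40), rng.integers(0, 2, 40))
        chi2, _, p = logrank_test([a, b])
        a2, b2 = a.copy(), b.copy()
        a2["time"] = np.sqrt(a2["time"])
        b2["time"] = np.sqrt(b2["time"])
        chi2_t, _, p_t = logrank_test([a2, b2])
        assert chi2 == pytest.approx(chi2_t, abs=1e-9)
        assert p == pytest.approx(p_t, abs=1e-12)

    def test_invariance_under_group_relabelling(self):
        rng = np.random.default_rng(2)
        a = make_survival_table(rng.exponential(10, 30), np.ones(30))
        b = make_survival_table(rng.exponential(20, 30), np.ones(30))
        assert logrank_test([a, b])[0] == pytest.approx(
            logrank_test([b, a])[0], abs=1e-9)


class TestMedianSplit:
    def test_even_n_direct_rule(self):
        tbl = make_survival_table([1, 2, 3, 4], [1, 1, 1, 1], cov=[1, 2, 3, 4])
        high, low = median_split(tbl, "cov")
        assert sorted(high["cov"]) == [3, 4]
        assert sorted(low["cov"]) == [1, 2]

    def test_value_at_median_goes_low(self):
        tbl = make_survival_table([1, 2, 3], [1, 1, 1], cov=[1, 2, 3])
        high, low = median_split(tbl, "cov")
        assert sorted(low["cov"]) == [1, 2]
        assert list(high["cov"]) == [3]

    def test_split_exhaustive_and_disjoint(self):
        tbl = generate_survival_cohort(n_patients=101, seed=9)
        high, low = median_split(tbl, "caf_abundance")
        assert len(high) + len(low) == 101
        assert not set(high["patient_id"]) & set(low["patient_id"])

    def test_constant_covariate_rejected(self):
        tbl = make_survival_table([1, 2], [1, 1], cov=[5.0, 5.0])
        with pytest.raises(ValueError):
            median_split(tbl, "cov")


def brute_force_cutpoint(tbl, covariate, minprop=0.1):
    """Independent oracle: per-candidate two-group log-rank via lifelines."""
    x = tbl[covariate].to_numpy(dtype=float)
    uniq = np.unique(x)
    n = len(tbl)
    best = None
    for c in (uniq[:-1] + uniq[1:]) / 2:
        hi = x > c
        if hi.sum() < minprop * n or (~hi).sum() < minprop * n:
            continue
        res = ll_logrank(tbl["time"][hi], tbl["time"][~hi],
                         tbl["event"][hi], tbl["event"][~hi])
        z = np.sqrt(max(res.test_statistic, 0.0))
        if best is None or z > best[1] + 1e-12:
            best = (float(c), float(z))
    return best


class TestMaxSelectedCutpoint:
    def test_matches_brute_force_on_random_cohorts(self):
        for seed in range(10):
            tbl = generate_survival_cohort(n_patients=60, hazard_ratio=1.8,
                                           seed=seed)
            got = max_selected_cutpoint(tbl, "caf_abundance")
            want_cut, want_z = brute_force_cutpoint(tbl, "caf_abundance")
            assert got.cutpoint == pytest.approx(want_cut)
            assert abs(got.statistic) == pytest.approx(want_z, rel=1e-9)

    def test_perfect_separation_forces_cutpoint_between_blocks(self):
        # covariate block [1..5] all dies at t=1, block [11..15] at t=100;
        # within-block survival is exchangeable so the block boundary is
        # the unique maximiser
        tbl = make_survival_table(
            [1, 1, 1, 1, 1, 100, 100, 100, 100, 100],
            [1] * 10,
            cov=[1, 2, 3, 4, 5, 11, 12, 13, 14, 15])
        cp = max_selected_cutpoint(tbl, "cov", minprop=0.1)
        assert 5 < cp.cutpoint < 11

    def test_minprop_half_restricts_to_median_cutpoint(self):
        rng = np.random.default_rng(3)
        tbl = make_survival_table(rng.exponential(10, 10), np.ones(10),
                                  cov=np.arange(10, dtype=float))
        cp = max_selected_cutpoint(tbl, "cov", minprop=0.5)
        assert cp.n_high == 5 and cp.n_low == 5

    def test_no_admissible_cutpoint_rejected(self):
        tbl = make_survival_table([1, 2, 3], [1, 1, 1], cov=[1.0, 1.0, 1.0])
        with pytest.raises(ValueError):
            max_selected_cutpoint(tbl, "cov")

    def test_group_sizes_respect_minprop(self):
        tbl = generate_survival_cohort(n_patients=80, seed=4)
        cp = max_selected_cutpoint(tbl, "caf_abundance", minprop=0.2)
        assert cp.n_high >= 16 and cp.n_low >= 16


class TestBulkPhenotype:
    def _cuts(self):
        return {m: CutpointResult(m, 10.0, 2.0, 5, 5, 0.1)
                for m in ("FAP", "PDPN", "aSMA")}

    def test_high_high_low_is_caf_s5(self):
        tbl = make_survival_table([1], [1], FAP=[20.0], PDPN=[20.0],
                                  aSMA=[5.0])
        assert assign_bulk_phenotype(tbl, self._cuts()).iloc[0] == "CAF-S5"

    def test_high_high_high_is_other(self):
        tbl = make_survival_table([1], [1], FAP=[20.0], PDPN=[20.0],
                                  aSMA=[20.0])
        assert assign_bulk_phenotype(tbl, self._cuts()).iloc[0] == "other"

    def test_missing_marker_schema_error(self):
        tbl = make_survival_table([1], [1], FAP=[20.0], PDPN=[20.0])
        with pytest.raises(SchemaError):
            assign_bulk_phenotype(tbl, self._cuts())

    def test_pipeline_recovers_planted_phenotype_effect(self):
        """Cutpoints + phenotype + log-rank detect a planted HR on one cohort."""
        tbl = generate_survival_cohort(n_patients=300,
                                       covariate="bulk_markers",
                                       hazard_ratio=2.5, seed=12)
        cuts = {m: max_selected_cutpoint(tbl, m) for m in ("FAP", "PDPN", "aSMA")}
        pheno = assign_bulk_phenotype(tbl, cuts)
        _, _, p = logrank_test([tbl[pheno == "CAF-S5"], tbl[pheno == "other"]])
        assert p < 0.05


class TestTruncation:
    def test_truncation_never_increases_events(self):
        tbl = generate_survival_cohort(n_patients=120, seed=8)
        cut = truncate_followup(tbl)
        assert cut["event"].sum() <= tbl["event"].sum()
        assert (cut["time"] <= 1826.0).all()

    def test_events_within_horizon_unchanged(self):
        tbl = make_survival_table([100, 2000, 1826], [1, 1, 1])
        cut = truncate_followup(tbl)
        assert list(cut["event"]) == [1, 0, 1]
        assert list(cut["time"]) == [100.0, 1826.0, 1826.0]
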