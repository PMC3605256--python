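"""Burden summaries, rank-sum, logistic fits, meta-combination, permutation."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest

from rarecnv.burden_stats import (
    BurdenFit,
    ScoreSet,
    combine_cohorts,
    compare_score_sets,
    geneset_burden,
    logistic_burden,
    order_score_sets,
    permutation_locus_test,
    ranksum_burden,
    summarize_burden,
)
from rarecnv.cnv_core import ConsensusCall, GenomicInterval, SampleSheet
from conftest import make_sheet


def ccall(sample, start, end, cls="loss", chrom="chr1"):
    return ConsensusCall(sample, GenomicInterval(chrom, start, end), cls, frozenset({"a", "b"}))


class TestSummarizeBurden:
    def test_additive_bp(self, small_sheet):
        s = small_sheet.sample_ids[0]
        calls = [ccall(s, 0, 100_000), ccall(s, 200_000, 268_000)]
        df = summarize_burden(calls, small_sheet, compartment="genome", cnv_class="loss")
        row = df.loc[df["sample_id"] == s].iloc[0]
        assert row["n_events"] == 2
        assert row["aneuploid_bp"] == 168_000

    def test_zero_filled(self, small_sheet):
        df = summarize_burden([], small_sheet)
        assert len(df) == small_sheet.n_samples
        assert (df["n_events"] == 0).all()
        assert (df["aneuploid_bp"] == 0).all()

    def test_order_invariance(self, small_sheet, rng):
        ids = small_sheet.sample_ids
        calls = [
            ccall(ids[int(rng.integers(len(ids)))], s := int(rng.integers(10_000)), s + 500)
            for _ in range(25)
        ]
        a = summarize_burden(calls, small_sheet)
        b = summarize_burden(calls[::-1], small_sheet)
        pd.testing.assert_frame_equal(a, b)

    def test_compartment_restriction(self, small_sheet):
        s = small_sheet.sample_ids[0]
        calls = [ccall(s, 0, 1000, chrom="chr1"), ccall(s, 0, 1000, chrom="chrX")]
        auto = summarize_burden(calls, small_sheet, compartment="autosome")
        assert auto.loc[auto["sample_id"] == s, "n_events"].iloc[0] == 1
        x = summarize_burden(calls, small_sheet, compartment="X")
        assert x.loc[x["sample_id"] == s, "n_events"].iloc[0] == 1


def enumeration_ranksum(x, y):
    """Exact two-sided rank-sum oracle by exhaustive relabelling (no ties)."""
    pooled = np.concatenate([x, y])
    n = len(x)
    ranks = pd.Series(pooled).rank().to_numpy()
    u_obs = ranks[:n].sum() - n * (n + 1) / 2
    m = len(pooled) - n
    us = []
    for combo in itertools.combinations(range(len(pooled)), n):
        u = ranks[list(combo)].sum() - n * (n + 1) / 2
        us.append(u)
    us = np.array(us)
    p_le = np.mean(us <= u_obs)
    p_ge = np.mean(us >= u_obs)
    return min(1.0, 2 * min(p_le, p_ge))


class TestRanksum:
    def test_identical_equal_values(self):
        assert ranksum_burden([1.0] * 20, [1.0] * 20) == 1.0

    def test_complete_separation_exact(self):
        p = ranksum_burden([6, 7, 8, 9, 10], [1, 2, 3, 4, 5])
        assert p == pytest.approx(2 / 252, rel=1e-9)

    @pytest.mark.parametrize("seed", range(6))
    def test_matches_enumeration_at_small_n(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(3, 9))
        m = int(rng.integers(3, 9))
        # continuous draws: ties almost surely absent
        x = rng.normal(0, 1, n)
        y = rng.normal(0.5, 1, m)
        assert ranksum_burden(x, y) == pytest.approx(enumeration_ranksum(x, y), rel=1e-9)

    def test_null_calibration(self):
        rng = np.random.default_rng(7)
        rej = 0
        reps = 400
        for _ in range(reps):
            x = rng.poisson(2.0, 60).astype(float)
            y = rng.poisson(2.0, 60).astype(float)
            if np.all(x == x[0]) and np.all(y == x[0]):
                continue
            if ranksum_burden(x, y) < 0.05:
                rej += 1
        # binomial 99% envelope around 0.05 at 400 reps
        assert rej / reps <= 0.05 + 2.58 * math.sqrt(0.05 * 0.95 / reps)


class TestLogisticBurden:
    def test_degenerate_all_zero_counts(self, small_sheet):
        with pytest.raises(ValueError):
            logistic_burden(np.zeros(15), small_sheet)

    def test_needs_both_statuses(self):
        sheet = make_sheet(5, 0)
        with pytest.raises(ValueError):
            logistic_burden(np.arange(5, dtype=float), sheet)

    def test_separation_flagged(self):
        sheet = make_sheet(20, 20)
        counts = np.r_[np.ones(20), np.zeros(20)]
        fit = logistic_burden(counts, sheet, covariates=False)
        assert fit.separation

    def test_firth_fallback_gives_finite_fit(self):
        sheet = make_sheet(20, 20)
        counts = np.r_[np.ones(20), np.zeros(20)]
        fit = logistic_burden(counts, sheet, covariates=False, firth_on_separation=True)
        assert not fit.separation
        assert np.isfinite(fit.beta) and np.isfinite(fit.se)

    def test_recovers_known_effect(self):
        rng = np.random.default_rng(11)
        beta = 0.6
        n = 2000
        counts = rng.poisson(1.5, n).astype(float)
        p = 1 / (1 + np.exp(-(-1.0 + beta * counts)))
        status = rng.random(n) < p
        df = pd.DataFrame({
            "sample_id": [f"s{i}" for i in range(n)],
            "status": np.where(status, "case", "control"),
            "cohort": "c1", "platform": "p1",
        })
        fit = logistic_burden(counts, SampleSheet(df), covariates=False)
        assert fit.beta == pytest.approx(beta, abs=3 * fit.se)
        assert fit.or_ == pytest.approx(math.exp(fit.beta))
        assert fit.ci_low < fit.or_ < fit.ci_high


class TestCombineCohorts:
    @staticmethod
    def fit(beta, se, n=100):
        return BurdenFit(beta=beta, se=se, or_=math.exp(beta),
                         ci_low=math.exp(beta - 1.96 * se), ci_high=math.exp(beta + 1.96 * se),
                         p=0.5, n_case=n, n_control=n)

    def test_identical_cohorts_halve_variance(self):
        f = self.fit(0.3, 0.2)
        combined = combine_cohorts([f, self.fit(0.3, 0.2)], method="fixed_iv")
        assert combined.beta == pytest.approx(0.3)
        assert combined.se**2 == pytest.approx(0.2**2 / 2)

    def test_single_cohort_passthrough_warns(self):
        with pytest.warns(UserWarning):
            combined = combine_cohorts([self.fit(0.4, 0.1)], method="fixed_iv")
        assert combined.beta == pytest.approx(0.4)

    def test_tau2_near_zero_under_homogeneity(self):
        rng = np.random.default_rng(3)
        taus = []
        for _ in range(100):
            fits = [self.fit(float(rng.normal(0.2, 0.1)), 0.1) for _ in range(3)]
            taus.append(combine_cohorts(fits, method="random_iv").tau2)
        assert np.median(taus) < 0.05

    def test_heterogeneity_widens_random_ci(self):
        fits = [self.fit(0.0, 0.1), self.fit(math.log(2.0), 0.1)]
        fixed = combine_cohorts(list(fits), method="fixed_iv")
        random = combine_cohorts(list(fits), method="random_iv")
        assert (random.ci_high - random.ci_low) > (fixed.ci_high - fixed.ci_low)

    def test_pooled_stratified(self):
        rng = np.random.default_rng(5)
        frames = []
        for k, cohort in enumerate(["u", "v"]):
            n = 300
            counts = rng.poisson(1.0, n).astype(float)
            p = 1 / (1 + np.exp(-(-0.5 + 0.4 * counts + 0.3 * k)))
            frames.append(pd.DataFrame({
                "sample_id": [f"{cohort}{i}" for i in range(n)],
                "status": np.where(rng.random(n) < p, "case", "control"),
                "cohort": cohort, "platform": cohort,
                "count": counts,
            }))
        df = pd.concat(frames, ignore_index=True)
        sheet = SampleSheet(df.drop(columns="count"))
        fit = combine_cohorts(None, method="pooled_stratified",
                              data=(df["count"].to_numpy(), sheet))
        assert fit.method == "pooled_stratified"
        assert fit.beta == pytest.approx(0.4, abs=3 * fit.se)


class TestPermutationLocusTest:
    def test_single_locus_corrected_equals_nominal(self):
        sheet = make_sheet(30, 30)
        rng = np.random.default_rng(0)
        X = pd.DataFrame({"locus1": rng.random(60) < 0.2}, index=sheet.sample_ids).astype(int)
        (res,) = permutation_locus_test(X, sheet, n_perm=500, seed=1)
        assert res.p_corrected == pytest.approx(res.p_nominal)

    def test_balanced_locus_has_large_p(self):
        sheet = make_sheet(40, 40)
        carriers = sheet.sample_ids[:8] + sheet.sample_ids[40:48]  # 8 case + 8 control
        X = pd.DataFrame({"locus1": [s in set(carriers) for s in sheet.sample_ids]},
                         index=sheet.sample_ids).astype(int)
        (res,) = permutation_locus_test(X, sheet, n_perm=1000, seed=2)
        assert res.p_nominal >= 0.5
        assert res.case_carriers == 8 and res.control_carriers == 8

    def test_corrected_dominates_nominal_and_monotone(self):
        sheet = make_sheet(50, 50)
        rng = np.random.default_rng(9)
        X = pd.DataFrame(
            (rng.random((100, 8)) < rng.uniform(0.05, 0.3, 8)).astype(int),
            index=sheet.sample_ids, columns=[f"l{k}" for k in range(8)],
        )
        results = permutation_locus_test(X, sheet, n_perm=300, seed=3)
        for r in results:
            assert r.p_corrected >= r.p_nominal
            assert 0 < r.p_nominal <= 1

    def test_deterministic_given_seed(self):
        sheet = make_sheet(25, 25)
        rng = np.random.default_rng(4)
        X = pd.DataFrame((rng.random((50, 3)) < 0.2).astype(int), index=sheet.sample_ids,
                         columns=list("abc"))
        r1 = permutation_locus_test(X, sheet, n_perm=200, seed=42)
        r2 = permutation_locus_test(X, sheet, n_perm=200, seed=42)
        assert [(r.p_nominal, r.p_corrected) for r in r1] == [
            (r.p_nominal, r.p_corrected) for r in r2
        ]

    def test_enriched_locus_detected(self):
        sheet = make_sheet(100, 100)
        carriers = set(sheet.sample_ids[:25]) | set(sheet.sample_ids[100:103])
        X = pd.DataFrame({"hit": [s in carriers for s in sheet.sample_ids]},
                         index=sheet.sample_ids).astype(int)
        (res,) = permutation_locus_test(X, sheet, n_perm=1000, seed=5)
        assert res.p_nominal < 0.01


class TestGenesetBurden:
    def test_counts_reproduced_from_input(self):
        sheet = make_sheet(30, 40, platform="p1")
        genes = [GenomicInterval("chr1", 1000, 2000)]
        carriers = sheet.sample_ids[:4] + sheet.sample_ids[30:33]
        calls = [ccall(s, 900, 2100) for s in carriers]
        table, res = geneset_burden(calls, sheet, genes, n_perm=500, seed=1)
        assert table.case_carriers == 4
        assert table.control_carriers == 3
        assert 0 < res.p_one_sided <= 1

    def test_zero_coverage_platform_excluded(self):
        import pandas as pd

        a = make_sheet(10, 10, cohort="a", platform="pA").df
        b = make_sheet(10, 10, cohort="b", platform="pB").df
        sheet = SampleSheet(pd.concat([a, b], ignore_index=True))
        genes = [GenomicInterval("chr1", 0, 1000)]
        calls = [ccall(sheet.sample_ids[0], 0, 500)]
        table, _ = geneset_burden(calls, sheet, genes,
                                  platform_coverage={"pA": 50, "pB": 0}, n_perm=200, seed=0)
        assert table.n_cases + table.n_controls == 20  # pB samples dropped

    def test_empty_gene_set_rejected(self, small_sheet):
        with pytest.raises(ValueError):
            geneset_burden([], small_sheet, [])


class TestScoreSets:
    def test_identical_sets(self):
        a = ScoreSet("x", "case", [1.0, 2.0, 3.0])
        b = ScoreSet("y", "control", [3.0, 2.0, 1.0])
        out = compare_score_sets(a, b)
        assert out["p"] == 1.0
        assert out["median_a"] == out["median_b"] == 2.0

    def test_shifted_distributions_detected(self):
        rng = np.random.default_rng(21)
        hits = 0
        for _ in range(40):
            a = ScoreSet("x", "case", rng.normal(1.0, 1.0, 100))
            b = ScoreSet("y", "control", rng.normal(0.0, 1.0, 100))
            if compare_score_sets(a, b)["p"] < 0.01:
                hits += 1
        assert hits >= 38  # >= 95% power at a 1-sigma shift

    def test_ordering_by_median(self):
        sets = [ScoreSet("a", "case", [5.0, 6.0]), ScoreSet("b", "case", [1.0, 2.0]),
                ScoreSet("c", "control", [3.0, 4.0])]
        assert [s.cohort for s in order_score_sets(sets)] == ["b", "c", "a"]
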