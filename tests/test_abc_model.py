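import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from cabc.abc_model import (
    CandidateElement,
    PowerlawFit,
    abc_scores,
    compare_enhancer_sets,
    contact_estimate,
    element_activity,
    enhancers_per_gene,
    fit_powerlaw,
    make_candidate_regions,
    quantile_normalize,
)
from cabc.genome_model import ContactMatrix, Gene, GenomicInterval, Peak


def mk_peak(start, summit_offset, pid, score=10.0, length=500):
    return Peak(GenomicInterval("chr1", start, start + length), pid,
                summit=summit_offset, score=score)


def mk_gene(tss, gid, length=5_000):
    return Gene(GenomicInterval("chr1", tss, tss + length, "+"), gid)


class TestCandidateRegions:
    def test_summit_extension(self):
        els = make_candidate_regions([mk_peak(10_000, 250, "p")], [], extend=250)
        (el,) = els
        s = 10_250
        assert (el.interval.start, el.interval.end) == (s - 250, s + 250)

    def test_nearby_summits_merge_and_resize(self):
        p1 = mk_peak(10_000, 250, "a")   # summit 10250
        p2 = mk_peak(10_300, 250, "b")   # summit 10550, regions overlap
        (el,) = make_candidate_regions([p1, p2], [])
        mid = (10_000 + 10_800) // 2
        assert el.interval.length == 500
        assert (el.interval.start, el.interval.end) == (mid - 250, mid + 250)

    def test_n_strongest_filter(self):
        p1 = mk_peak(10_000, 250, "weak", score=5)
        p2 = mk_peak(50_000, 250, "strong", score=9)
        els = make_candidate_regions([p1, p2], [], n_strongest=1)
        assert len(els) == 1
        assert els[0].interval.start == 50_000

    def test_promoter_elements_appended_and_deduplicated(self):
        g = mk_gene(30_000, "g1")
        els = make_candidate_regions([mk_peak(10_000, 250, "p")], [g])
        proms = [e for e in els if e.is_promoter]
        assert len(proms) == 1
        assert proms[0].promoter_gene_id == "g1"
        assert proms[0].interval.start == 29_750

    def test_peak_overlapping_promoter_window_dropped(self):
        g = mk_gene(10_300, "g1")  # promoter window [10050, 10550)
        els = make_candidate_regions([mk_peak(10_000, 250, "p")], [g])
        assert len(els) == 1 and els[0].is_promoter

    def test_missing_summit_rejected(self):
        p = Peak(GenomicInterval("chr1", 0, 500), "p")
        with pytest.raises(ValueError, match="summit"):
            make_candidate_regions([p], [])


class TestActivity:
    def test_geometric_mean(self):
        assert element_activity(4, 9) == pytest.approx(6.0)
        assert element_activity(0, 100) == 0.0

    def test_log_domain_oracle(self, rng):
        for _ in range(50):
            a, k = rng.uniform(0.1, 100, 2)
            expected = math.exp(0.5 * (math.log(a) + math.log(k)))
            assert element_activity(a, k) == pytest.approx(expected, rel=1e-12)

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            element_activity(-1, 5)


class TestQuantileNormalize:
    def test_own_sorted_values_is_identity(self, rng):
        x = rng.uniform(0, 50, 25)
        out = quantile_normalize(x, np.sort(x))
        np.testing.assert_allclose(out, x, atol=1e-10)

    def test_rank_map_example(self):
        out = quantile_normalize(np.array([1.0, 2, 3]), np.array([10.0, 20, 30]))
        np.testing.assert_allclose(out, [10, 20, 30])

    def test_matches_sort_interp_oracle_and_preserves_order(self, rng):
        for _ in range(20):
            x = rng.uniform(0, 100, 40)
            ref = np.sort(rng.uniform(0, 10, 60))
            out = quantile_normalize(x, ref)
            order = np.argsort(x, kind="stable")
            ranks = np.empty(len(x))
            ranks[order] = np.arange(len(x))
            oracle = np.interp(ranks / (len(x) - 1),
                               np.linspace(0, 1, len(ref)), ref)
            np.testing.assert_allclose(out, oracle, atol=1e-10)
            rho = stats.spearmanr(x, out).statistic
            assert rho == pytest.approx(1.0)

    def test_ties_share_mean(self):
        out = quantile_normalize(np.array([1.0, 1.0, 2.0]),
                                 np.array([0.0, 10.0, 20.0]))
        assert out[0] == out[1] == pytest.approx(5.0)
        assert out[2] == pytest.approx(20.0)

    def test_empty_reference_rejected(self):
        with pytest.raises(ValueError):
            quantile_normalize(np.array([1.0]), np.array([]))


def powerlaw_matrix(n, res, gamma, scale, noise_rng=None):
    d = np.abs(np.subtract.outer(np.arange(n), np.arange(n)))
    with np.errstate(divide="ignore"):
        exp = scale * np.maximum(d, 1) ** (-gamma * 1.0)
    if noise_rng is None:
        m = np.triu(exp)
    else:
        m = np.triu(noise_rng.poisson(exp))
    m = m + np.triu(m, 1).T
    np.fill_diagonal(m, exp[0, 0])
    return ContactMatrix("chr1", res, n, m)


class TestPowerlawFit:
    def test_exact_powerlaw_recovered(self):
        cm = powerlaw_matrix(300, 5_000, 1.0, 5e4)
        fit = fit_powerlaw(cm)
        assert fit.gamma == pytest.approx(1.0, abs=1e-6)

    def test_scaling_moves_intercept_not_gamma(self):
        cm1 = powerlaw_matrix(300, 5_000, 1.2, 5e4)
        cm2 = ContactMatrix("chr1", 5_000, 300, cm1.matrix * 2)
        f1, f2 = fit_powerlaw(cm1), fit_powerlaw(cm2)
        assert f2.gamma == pytest.approx(f1.gamma, abs=1e-9)
        assert f2.log_scale - f1.log_scale == pytest.approx(np.log(2), abs=1e-9)

    def test_too_few_points_rejected(self):
        cm = powerlaw_matrix(4, 5_000, 1.0, 100)
        with pytest.raises(ValueError):
            fit_powerlaw(cm)

    def test_expected_is_positive_decreasing(self):
        fit = PowerlawFit(gamma=1.0, log_scale=5.0, fit_range=(1e4, 1e6))
        ds = np.linspace(1e4, 1e6, 20)
        vals = [fit.expected(d) for d in ds]
        assert all(v > 0 for v in vals)
        assert all(a > b for a, b in zip(vals, vals[1:]))


class TestContactEstimate:
    def setup_method(self):
        rng = np.random.default_rng(0)
        self.cm = powerlaw_matrix(100, 5_000, 1.0, 1e3, noise_rng=rng)
        self.fit = fit_powerlaw(self.cm, fit_range=(5_000, 400_000))

    def test_symmetric_in_loci(self):
        a = contact_estimate(self.cm, self.fit, 12_500, 243_000)
        b = contact_estimate(self.cm, self.fit, 243_000, 12_500)
        assert a == b

    def test_zero_observed_returns_pseudocount_alone(self):
        n = 20
        m = np.zeros((n, n))
        m[0, 1] = m[1, 0] = 100.0  # keeps the matrix non-empty
        cm = ContactMatrix("chr1", 5_000, n, m)
        fit = PowerlawFit(gamma=1.0, log_scale=3.0, fit_range=(1e4, 1e5))
        d = 50_000
        got = contact_estimate(cm, fit, 2_500, 2_500 + d)
        depth_scale = cm.total / 1e6
        assert got == pytest.approx(fit.expected(d) / depth_scale)

    def test_matches_lookup_oracle(self, rng):
        for _ in range(50):
            i = int(rng.integers(0, 100))
            j = int(rng.integers(0, 100))
            pi, pj = i * 5_000 + 100, j * 5_000 + 4_000
            got = contact_estimate(self.cm, self.fit, pi, pj)
            depth_scale = self.cm.total / 1e6
            d = abs(pi - pj)
            if d < 5_000:
                oracle = self.fit.expected(5_000) / depth_scale
            else:
                oracle = (self.cm.toarray()[i, j] / depth_scale
                          + self.fit.expected(d) / depth_scale)
            assert got == pytest.approx(oracle, rel=1e-12)

    def test_locus_off_matrix_rejected(self):
        with pytest.raises(IndexError):
            contact_estimate(self.cm, self.fit, 10**9, 0)


def build_gene_with_elements(activities, offsets, tss=250_000):
    """One gene plus a promoter element and positioned enhancers."""
    gene = mk_gene(tss, "g")
    els = [CandidateElement(
        GenomicInterval("chr1", tss - 250, tss + 250), "prom",
        is_promoter=True, promoter_gene_id="g",
    )]
    for k, off in enumerate(offsets):
        s = tss + off - 250
        els.append(CandidateElement(GenomicInterval("chr1", s, s + 500), f"e{k}"))
    acts = np.array([activities[0]] + list(activities[1:]))
    return gene, els, acts


class TestAbcScores:
    def setup_method(self):
        rng = np.random.default_rng(1)
        self.cm = powerlaw_matrix(200, 5_000, 1.0, 1e3, noise_rng=rng)
        self.fit = fit_powerlaw(self.cm, fit_range=(5_000, 500_000))

    def test_single_active_element_scores_one(self):
        gene, els, _ = build_gene_with_elements([0.0, 5.0], [20_000])
        df = abc_scores(els, np.array([0.0, 5.0]), gene, self.fit, self.cm)
        e = df[df.element_id == "e0"].iloc[0]
        assert e.abc_score == pytest.approx(1.0)
        assert bool(e.predicted)

    def test_score_proportions(self):
        gene, els, _ = build_gene_with_elements([0.0, 1.0, 1.0],
                                                [20_000, -20_000])
        df = abc_scores(els, np.array([0.0, 1.0, 1.0]), gene, self.fit, self.cm)
        # same distance either side: contacts may differ by observed counts;
        # force equality by checking against recomputed numerators
        total = df.abc_numerator.sum()
        np.testing.assert_allclose(df.abc_score, df.abc_numerator / total)
        assert df.abc_score.sum() == pytest.approx(1.0, abs=1e-9)

    def test_below_threshold_not_predicted(self):
        gene, els, _ = build_gene_with_elements([100.0, 1.0], [20_000])
        df = abc_scores(els, np.array([100.0, 1.0]), gene, self.fit, self.cm)
        e = df[df.element_id == "e0"].iloc[0]
        assert e.abc_score < 0.02
        assert not bool(e.predicted)

    def test_promoter_never_predicted(self):
        gene, els, _ = build_gene_with_elements([10.0, 0.1], [20_000])
        df = abc_scores(els, np.array([10.0, 0.1]), gene, self.fit, self.cm)
        assert not df[df.is_promoter].predicted.any()

    def test_missing_promoter_rejected(self):
        gene = mk_gene(250_000, "g")
        el = CandidateElement(GenomicInterval("chr1", 100_000, 100_500), "e")
        with pytest.raises(ValueError, match="promoter"):
            abc_scores([el], np.array([1.0]), gene, self.fit, self.cm)

    def test_activity_monotonicity(self):
        gene, els, _ = build_gene_with_elements([2.0, 1.0, 1.0],
                                                [20_000, -30_000])
        base = abc_scores(els, np.array([2.0, 1.0, 1.0]), gene, self.fit, self.cm)
        boosted = abc_scores(els, np.array([2.0, 2.5, 1.0]), gene, self.fit, self.cm)
        def score(df, eid):
            return float(df.abc_score[df.element_id == eid].iloc[0])
        assert score(boosted, "e0") >= score(base, "e0")
        assert score(boosted, "e1") <= score(base, "e1")
        assert score(boosted, "prom") <= score(base, "prom")

    def test_threshold_monotone_subset(self):
        gene, els, _ = build_gene_with_elements(
            [5.0, 3.0, 1.0, 0.2], [15_000, -40_000, 70_000]
        )
        acts = np.array([5.0, 3.0, 1.0, 0.2])
        loose = abc_scores(els, acts, gene, self.fit, self.cm, threshold=0.02)
        tight = abc_scores(els, acts, gene, self.fit, self.cm, threshold=0.05)
        s_loose = set(loose.element_id[loose.predicted])
        s_tight = set(tight.element_id[tight.predicted])
        assert s_tight <= s_loose

    def test_all_zero_numerators_predict_nothing(self):
        gene, els, _ = build_gene_with_elements([0.0, 0.0], [20_000])
        df = abc_scores(els, np.array([0.0, 0.0]), gene, self.fit, self.cm)
        np.testing.assert_allclose(df.abc_score, 0.0)
        assert not df.predicted.any()


class TestEnhancersPerGene:
    def test_counts_and_conservation(self):
        pred = pd.DataFrame({
            "gene_id": ["g1", "g1", "g2", "g3"],
            "element_id": ["a", "b", "a", "c"],
            "predicted": [True, True, True, False],
            "is_promoter": [False] * 4,
        })
        counts, summary = enhancers_per_gene(pred)
        assert counts["g1"] == 2 and counts["g2"] == 1 and counts["g3"] == 0
        assert summary["total_links"] == counts.sum() == 3


class TestCompareEnhancerSets:
    def mk(self, predicted_ids, universe=("a", "b", "c")):
        return pd.DataFrame({
            "element_id": list(universe),
            "gene_id": ["g"] * len(universe),
            "predicted": [u in predicted_ids for u in universe],
            "distance": [5_000, 50_000, 2_000_000],
        })

    def test_identical_sets_fully_shared(self):
        out = compare_enhancer_sets(self.mk({"a", "b"}), self.mk({"a", "b"}))
        assert out["shared"] == 2 and out["unique_c1"] == out["unique_c2"] == 0
        assert out["shared_fraction"] == 1.0

    def test_disjoint_sets(self):
        out = compare_enhancer_sets(self.mk({"a"}), self.mk({"b"}))
        assert out["shared"] == 0
        assert out["unique_c1"] == out["unique_c2"] == 1

    def test_set_algebra_oracle(self, rng):
        universe = tuple(f"e{i}" for i in range(12))
        for _ in range(20):
            s1 = {u for u in universe if rng.random() < 0.4}
            s2 = {u for u in universe if rng.random() < 0.4}
            df1 = pd.DataFrame({
                "element_id": universe, "gene_id": ["g"] * 12,
                "predicted": [u in s1 for u in universe],
                "distance": rng.integers(1_000, 2_000_000, 12),
            })
            df2 = df1.copy()
            df2["predicted"] = [u in s2 for u in universe]
            out = compare_enhancer_sets(df1, df2)
            assert out["shared"] == len(s1 & s2)
            assert out["unique_c1"] == len(s1 - s2)
            assert out["unique_c2"] == len(s2 - s1)

    def test_mismatched_universe_rejected(self):
        with pytest.raises(ValueError):
            compare_enhancer_sets(self.mk({"a"}),
                                  self.mk({"a"}, universe=("a", "b")))
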