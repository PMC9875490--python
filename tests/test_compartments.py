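import numpy as np
import pytest

from cabc.compartments import (
    classify_switching,
    compartment_pc1,
    differential_insulation,
    insulation_scores,
    observed_expected,
)
from cabc.genome_model import ContactMatrix, GenomicInterval


def symmetric(rng, n, scale=10):
    upper = np.triu(rng.uniform(1, scale, (n, n)))
    return upper + np.triu(upper, 1).T


def oe_loop_oracle(obs):
    """Explicit per-diagonal loop, independent of the vectorized path."""
    n = obs.shape[0]
    out = np.zeros_like(obs, dtype=float)
    for i in range(n):
        for j in range(n):
            d = abs(i - j)
            vals = [obs[a, a + d] for a in range(n - d)]
            m = float(np.mean(vals))
            if m > 0:
                out[i, j] = obs[i, j] / m
    return out


class TestObservedExpected:
    def test_constant_diagonals_give_ones(self):
        n = 6
        obs = np.zeros((n, n))
        for d in range(n):
            idx = np.arange(n - d)
            obs[idx, idx + d] = d + 1.0
            obs[idx + d, idx] = d + 1.0
        cm = ContactMatrix("chr1", 1000, n, obs)
        oe = observed_expected(cm)
        np.testing.assert_allclose(oe, np.ones((n, n)))

    def test_matches_loop_oracle(self, rng):
        obs = symmetric(rng, 8)
        cm = ContactMatrix("chr1", 1000, 8, obs)
        np.testing.assert_allclose(observed_expected(cm), oe_loop_oracle(obs),
                                   atol=1e-12)

    def test_all_zero_matrix_rejected(self):
        cm = ContactMatrix("chr1", 1000, 4, np.zeros((4, 4)))
        with pytest.raises(ValueError, match="no contacts"):
            observed_expected(cm)


def checkerboard_oe(n=10, block=5, hi=2.0, lo=0.5):
    states = (np.arange(n) // block) % 2
    same = np.equal.outer(states, states)
    return np.where(same, hi, lo)


class TestCompartmentPC1:
    def test_two_block_checkerboard_separates_blocks(self):
        oe = checkerboard_oe()
        track = np.repeat([1.0, -1.0], 5)
        pc1 = compartment_pc1(oe, track)
        assert (pc1[:5] > 0).all() and (pc1[5:] < 0).all()

    def test_matches_dense_eigensolver_oracle(self):
        oe = checkerboard_oe() + np.diag(np.linspace(0, 0.5, 10))
        oe = (oe + oe.T) / 2
        track = np.repeat([1.0, -1.0], 5)
        pc1 = compartment_pc1(oe, track)
        # oracle: correlation matrix + scipy dense eigendecomposition
        import scipy.linalg

        corr = np.corrcoef(oe, rowvar=False)
        w, v = scipy.linalg.eigh(corr)
        lead = v[:, np.argmax(w)]
        if np.corrcoef(lead, pc1)[0, 1] < 0:
            lead = -lead
        np.testing.assert_allclose(pc1, lead, atol=1e-8)

    def test_negating_track_negates_output(self):
        oe = checkerboard_oe()
        track = np.repeat([1.0, -1.0], 5)
        a = compartment_pc1(oe, track)
        b = compartment_pc1(oe, -track)
        np.testing.assert_allclose(a, -b)

    def test_orthogonal_track_falls_back_to_loading_sign(self):
        oe = checkerboard_oe()
        pc1 = compartment_pc1(oe, np.zeros(10))
        nz = pc1[pc1 != 0]
        assert nz[0] > 0

    def test_low_coverage_bins_masked(self):
        oe = checkerboard_oe()
        totals = np.full(10, 100.0)
        totals[3] = 0.0
        pc1 = compartment_pc1(oe, np.repeat([1.0, -1.0], 5), bin_totals=totals)
        assert np.isnan(pc1[3]) and not np.isnan(pc1[4])

    def test_constant_columns_rejected(self):
        with pytest.raises(ValueError, match="no compartment signal"):
            compartment_pc1(np.ones((5, 5)), np.arange(5.0))

    def test_invariant_to_contact_scaling(self, rng):
        obs = symmetric(rng, 12)
        cm1 = ContactMatrix("chr1", 1000, 12, obs)
        cm2 = ContactMatrix("chr1", 1000, 12, obs * 7.5)
        track = rng.normal(size=12)
        a = compartment_pc1(observed_expected(cm1), track)
        b = compartment_pc1(observed_expected(cm2), track)
        np.testing.assert_allclose(a, b, atol=1e-10)


class TestClassifySwitching:
    def make_tracks(self, deltas, noise=0.01, reps=2, seed=0):
        rng = np.random.default_rng(seed)
        base = np.array(deltas, dtype=float)
        c1 = np.vstack([base[0] + rng.normal(0, noise, base.shape[1])
                        for _ in range(reps)])
        c2 = np.vstack([base[1] + rng.normal(0, noise, base.shape[1])
                        for _ in range(reps)])
        return c1, c2

    def test_sign_flip_with_support_is_switching(self):
        n = 40
        m1 = np.full(n, 0.85)
        m2 = np.full(n, 0.85)
        m1[:5], m2[:5] = 0.85, -0.75  # A -> B
        m1[5:10], m2[5:10] = -0.75, 0.85  # B -> A
        c1, c2 = self.make_tracks(np.vstack([m1, m2]))
        calls = classify_switching(c1, c2)
        assert (calls.switch_class[:5] == "A2B").all()
        assert (calls.switch_class[5:10] == "B2A").all()
        assert (calls.switch_class[10:] == "stable_A").all()
        assert (calls.fdr[:10] < 0.05).all()

    def test_no_sign_change_is_stable_even_when_significant(self):
        c1 = np.array([[0.8, 0.8], [0.9, 0.9]])
        c2 = np.array([[0.2, -0.7], [0.3, -0.8]])
        calls = classify_switching(c1, c2)
        assert calls.switch_class[0] == "stable_A"  # 0.8 -> 0.2, same sign
        assert calls.switch_class[1] in {"A2B", "stable_A"}

    def test_partition_of_classified_bins(self):
        n = 30
        m1 = np.where(np.arange(n) % 2 == 0, 0.5, -0.5)
        m2 = m1.copy()
        m2[:6] = -m2[:6]
        c1, c2 = self.make_tracks(np.vstack([m1, m2]), seed=2)
        calls = classify_switching(c1, c2)
        counted = calls.switch_class.isin(
            ["A2B", "B2A", "stable_A", "stable_B"]
        ).sum()
        counted += calls.switch_class.isin(["ambiguous", "unassigned"]).sum()
        assert counted == n

    def test_single_replicate_rejected(self):
        with pytest.raises(ValueError):
            classify_switching(np.ones((1, 5)), np.ones((2, 5)))


class TestInsulation:
    def domains(self, spans, res=1000):
        return [GenomicInterval("chr1", s * res, e * res) for s, e in spans]

    def test_uniform_matrix_scores_zero(self):
        cm = ContactMatrix("chr1", 1000, 12, np.ones((12, 12)))
        scores = insulation_scores(cm, self.domains([(2, 6), (6, 10)]))
        np.testing.assert_allclose(scores, 0.0, atol=1e-9)

    def test_block_diagonal_matches_loop_oracle(self):
        n = 12
        obs = np.zeros((n, n))
        obs[:6, :6] = 4.0
        obs[6:, 6:] = 4.0
        cm = ContactMatrix("chr1", 1000, n, obs)
        (score,) = insulation_scores(cm, self.domains([(0, 6)]))
        # oracle: recompute intra/inter means from the O/E matrix directly
        oe = observed_expected(cm)
        intra = oe[:6, :6][np.triu_indices(6, 1)].mean()
        inter = oe[6:12, 0:6].mean()
        expected = np.log2((intra + 1e-6) / (inter + 1e-6))
        assert score == pytest.approx(expected, abs=1e-12)
        assert score > 5  # strongly insulated

    def test_doubling_counts_leaves_scores_unchanged(self, rng):
        obs = np.triu(rng.uniform(1, 5, (10, 10)))
        obs = obs + np.triu(obs, 1).T
        doms = self.domains([(1, 4), (4, 8)])
        s1 = insulation_scores(ContactMatrix("chr1", 1000, 10, obs), doms)
        s2 = insulation_scores(ContactMatrix("chr1", 1000, 10, obs * 2), doms)
        np.testing.assert_allclose(s1, s2, atol=1e-9)

    def test_short_domain_skipped_with_warning(self):
        cm = ContactMatrix("chr1", 1000, 8, np.ones((8, 8)))
        with pytest.warns(UserWarning):
            scores = insulation_scores(cm, self.domains([(2, 3)]))
        assert np.isnan(scores[0])


class TestDifferentialInsulation:
    def test_threshold_and_fdr_rule(self):
        rng = np.random.default_rng(1)
        n = 20
        base = rng.normal(0, 0.02, n)
        s1 = np.vstack([base + rng.normal(0, 0.01, n) for _ in range(3)])
        delta = np.zeros(n)
        delta[0] = 0.30   # passes both
        delta[1] = 0.20   # fails |delta| > 0.25
        s2 = np.vstack([base + delta + rng.normal(0, 0.01, n) for _ in range(3)])
        doms = [GenomicInterval("chr1", i * 1000, (i + 1) * 1000) for i in range(n)]
        rec = differential_insulation(s1, s2, doms)
        assert bool(rec.differential[0])
        assert not bool(rec.differential[1])
        assert rec.padj[1] < 0.05  # significant but below the delta cutoff

    def test_identical_scores_not_differential(self):
        s = np.random.default_rng(0).normal(size=(2, 5))
        doms = [GenomicInterval("chr1", i * 1000, (i + 1) * 1000) for i in range(5)]
        rec = differential_insulation(s, s.copy(), doms)
        np.testing.assert_allclose(rec.delta, 0.0)
        assert not rec.differential.any()
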