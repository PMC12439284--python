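import itertools

import numpy as np
import pytest

import kinlagoon as kl
from kinlagoon.io import MISSING, GenotypeMatrix
from kinlagoon.relatedness import (
    NULL,
    LocusFrequencies,
    dyad_mode_likelihoods,
    dyad_relatedness,
    em_k_coefficients,
    estimate_frequencies_em,
    frequency_loglik,
    grid_k_coefficients,
    ml_relatedness,
    pair_log_likelihood,
    relatedness_from_k,
    remove_duplicates,
)
from kinlagoon.simulate import SimulationConfig, simulate_population

from conftest import make_gm
from oracles import enumerate_mode_probs


def biallelic(pa=0.5, p0=0.0, labels=(100, 104)):
    return LocusFrequencies(
        "L", np.array(labels), np.array([pa, 1 - pa - p0]) if p0 else
        np.array([pa, 1 - pa]), p0,
    )


class TestFrequencyEstimation:
    def test_monomorphic_counting_boundary(self):
        gm = make_gm(["a", "b"], ["L"], [[(100, 100)], [(100, 100)]])
        (lf,) = estimate_frequencies_em(gm, with_null=False)
        assert lf.alleles.tolist() == [100] and lf.freqs.tolist() == [1.0]

    def test_null_estimate_near_zero_without_excess(self):
        cfg = SimulationConfig(
            seed=31, n_loci=10, n_unrelated=400,
            null_rate_per_locus=0.0, missing_rate=0.0,
        )
        gm, _, _ = simulate_population(cfg)
        freqs = estimate_frequencies_em(gm, with_null=True)
        assert np.mean([lf.null_freq for lf in freqs]) < 0.03

    def test_em_matches_grid_search_of_same_likelihood(self):
        # one biallelic locus simulated at null frequency 0.2; the EM
        # solution must sit at the dense-grid maximiser of the identical
        # apparent-genotype likelihood
        lf_true = biallelic(pa=0.55, p0=0.2)
        rng = np.random.default_rng(77)
        labels = np.concatenate([lf_true.alleles, [NULL]])
        probs = np.concatenate([lf_true.freqs, [lf_true.null_freq]])
        true = rng.choice(labels, size=(400, 2), p=probs)
        from kinlagoon.simulate import _apparent

        gm = GenotypeMatrix(
            [f"i{k}" for k in range(400)], ["L"], _apparent(true)[:, None, :]
        )
        (lf_hat,) = estimate_frequencies_em(gm, with_null=True, tol=1e-10)

        # apparent-genotype category counts make the grid evaluation exact:
        # log L = nA*log(pa^2 + 2 pa p0) + nB*log(pb^2 + 2 pb p0)
        #         + nAB*log(2 pa pb)
        col = gm.alleles[:, 0, :]
        typed = col[col[:, 0] != 0]
        a_lab, b_lab = lf_true.alleles
        n_a = int(np.sum((typed[:, 0] == a_lab) & (typed[:, 1] == a_lab)))
        n_b = int(np.sum((typed[:, 0] == b_lab) & (typed[:, 1] == b_lab)))
        n_ab = len(typed) - n_a - n_b
        step = 0.002
        pa_grid_vals = np.arange(step, 1.0, step)
        p0_grid_vals = np.arange(0.0, 1.0, step)
        PA, P0 = np.meshgrid(pa_grid_vals, p0_grid_vals, indexing="ij")
        PB = 1.0 - PA - P0
        valid = PB > 0
        with np.errstate(divide="ignore", invalid="ignore"):
            LL = (
                n_a * np.log(PA**2 + 2 * PA * P0)
                + n_b * np.log(PB**2 + 2 * PB * P0)
                + n_ab * np.log(2 * PA * PB)
            )
        LL[~valid] = -np.inf
        flat = np.argmax(LL)
        pa_grid, p0_grid = PA.flat[flat], P0.flat[flat]
        ll_grid = LL.flat[flat]
        assert abs(lf_hat.freqs[0] - pa_grid) <= step
        assert abs(lf_hat.null_freq - p0_grid) <= step
        assert frequency_loglik(gm, 0, lf_hat) >= ll_grid - 1e-6


class TestDyadModeLikelihoods:
    def test_independence_mode_is_product_of_hwe_probs(self):
        lf = biallelic()
        a, _, _ = dyad_mode_likelihoods((100, 104), (100, 104), lf)
        assert a == pytest.approx(0.5 * 0.5)  # (2*.5*.5)^2

    def test_ibd2_forces_identity(self):
        lf = biallelic(pa=0.3)
        _, _, c = dyad_mode_likelihoods((100, 100), (100, 104), lf)
        assert c == 0.0
        _, _, c = dyad_mode_likelihoods((100, 100), (100, 100), lf)
        assert c == pytest.approx(0.3**2)

    def test_one_shared_allele_enumeration(self):
        lf = LocusFrequencies(
            "L", np.array([1, 2, 3]), np.array([0.5, 0.3, 0.2])
        )
        _, b, _ = dyad_mode_likelihoods((1, 1), (1, 2), lf)
        # shared IBD allele must be 1: p1 (shared) * p1 (other of hom) * p2
        assert b == pytest.approx(0.5 * 0.5 * 0.3)

    @pytest.mark.parametrize("n_alleles", [2, 3, 4])
    def test_matches_generative_enumeration(self, n_alleles, rng):
        p = rng.dirichlet(np.ones(n_alleles))
        labels = np.array(range(1, n_alleles + 1))
        lf = LocusFrequencies("L", labels, p)
        genotypes = [
            (i, j) for i, j in itertools.combinations_with_replacement(labels, 2)
        ]
        for g1, g2 in itertools.combinations_with_replacement(genotypes, 2):
            got = dyad_mode_likelihoods(g1, g2, lf)
            want = enumerate_mode_probs(g1, g2, labels, p)
            assert got == pytest.approx(want, abs=1e-12)

    def test_null_marginalisation_matches_enumeration(self, rng):
        p = np.array([0.45, 0.3, 0.1])
        lf = LocusFrequencies("L", np.array([1, 2, 3]), p, 0.15)
        labels = [1, 2, 3, NULL]
        probs = [0.45, 0.3, 0.1, 0.15]
        genotypes = [(1, 1), (1, 2), (2, 2), (2, 3), (3, 3)]
        for g1, g2 in itertools.combinations_with_replacement(genotypes, 2):
            got = dyad_mode_likelihoods(g1, g2, lf)
            want = enumerate_mode_probs(g1, g2, labels, probs, null_allele=NULL)
            assert got == pytest.approx(want, abs=1e-12)

    def test_unknown_allele_rejected(self):
        lf = biallelic()
        with pytest.raises(ValueError, match="absent"):
            dyad_mode_likelihoods((100, 999), (100, 104), lf)


class TestMaximumLikelihood:
    def _abc(self, g1, g2, freqs):
        return np.array(
            [dyad_mode_likelihoods(a, b, lf) for a, b, lf in zip(g1, g2, freqs)]
        )

    def test_unrelated_k_gives_product_of_genotype_probs(self, panel_freqs):
        g1, g2 = kl.simulate_dyads("FS", 1, panel_freqs, seed=8)
        abc = self._abc(
            [tuple(x) for x in g1[0]], [tuple(x) for x in g2[0]], panel_freqs
        )
        want = float(np.sum(np.log(abc[:, 0])))
        assert pair_log_likelihood(abc, (1.0, 0.0, 0.0)) == pytest.approx(want)

    def test_em_matches_dense_grid(self, panel_freqs):
        for rel, seed in (("U", 1), ("HS", 2), ("FS", 3), ("PO", 4)):
            g1, g2 = kl.simulate_dyads(rel, 8, panel_freqs, seed=seed)
            for d in range(8):
                abc = self._abc(
                    [tuple(x) for x in g1[d]], [tuple(x) for x in g2[d]],
                    panel_freqs,
                )
                r_em = relatedness_from_k(em_k_coefficients(abc))
                r_grid = relatedness_from_k(grid_k_coefficients(abc, 0.01))
                assert abs(r_em - r_grid) <= 0.02

    def test_identical_genotypes_estimate_near_one(self, panel_freqs):
        g1, _ = kl.simulate_dyads("U", 1, panel_freqs, seed=12)
        r = dyad_relatedness(g1, g1.copy(), panel_freqs)
        assert r[0] >= 0.95

    def test_matrix_symmetry_and_bounds(self):
        cfg = SimulationConfig(seed=41, n_loci=10, family_spec=(("FS", 3, 2),),
                               n_unrelated=20)
        gm, _, _ = simulate_population(cfg)
        freqs = estimate_frequencies_em(gm)
        rm = ml_relatedness(gm, freqs)
        assert np.array_equal(rm.r, rm.r.T, equal_nan=True)
        off = rm.r[~np.eye(rm.n, dtype=bool)]
        assert np.nanmin(off) >= 0 and np.nanmax(off) <= 1

    def test_more_loci_reduce_rmse(self, panel_freqs):
        g1, g2 = kl.simulate_dyads("FS", 300, panel_freqs, seed=6)
        r21 = dyad_relatedness(g1, g2, panel_freqs)
        r7 = dyad_relatedness(g1[:, :7], g2[:, :7], panel_freqs[:7])
        rmse = lambda r: float(np.sqrt(np.mean((r - 0.5) ** 2)))
        assert rmse(r21) < rmse(r7)


class TestDuplicateRemoval:
    def _rm(self, ids, pairs):
        n = len(ids)
        r = np.full((n, n), 0.01)
        np.fill_diagonal(r, np.nan)
        for i, j, v in pairs:
            r[i, j] = r[j, i] = v
        nl = np.full((n, n), 21)
        return kl.RelatednessMatrix(ids, r, nl)

    def _gm(self, ids, missing_counts=None):
        L = 4
        cells = []
        for k, _ in enumerate(ids):
            m = 0 if missing_counts is None else missing_counts[k]
            cells.append(
                [(MISSING, MISSING)] * m + [(100, 102)] * (L - m)
            )
        return make_gm(list(ids), [f"L{j}" for j in range(L)], cells)

    def test_nothing_above_threshold_keeps_all(self):
        ids = ["a", "b", "c"]
        rm = self._rm(ids, [(0, 1, 0.8)])
        retained, pairs = remove_duplicates(rm, self._gm(ids))
        assert retained == ids and pairs == []

    def test_single_pair_drops_exactly_one(self):
        ids = ["a", "b", "c"]
        rm = self._rm(ids, [(0, 1, 0.96)])
        retained, pairs = remove_duplicates(rm, self._gm(ids, [2, 0, 0]))
        assert retained == ["b", "c"]  # "a" has more missing loci
        assert len(pairs) == 1 and pairs[0][:2] == ("a", "b")

    def test_chain_collapses_to_one_survivor(self):
        ids = ["a", "b", "c", "d"]
        rm = self._rm(ids, [(0, 1, 0.97), (1, 2, 0.98)])
        retained, pairs = remove_duplicates(rm, self._gm(ids))
        # connected component {a,b,c}: ties on missingness resolve to "a"
        assert retained == ["a", "d"]
        assert len(pairs) == 2

    def test_exact_threshold_not_dropped(self):
        ids = ["a", "b"]
        rm = self._rm(ids, [(0, 1, 0.95)])
        retained, pairs = remove_duplicates(rm, self._gm(ids), threshold=0.95)
        assert retained == ids and pairs == []
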