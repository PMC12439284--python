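import itertools
import math

import numpy as np
import pandas as pd
import pytest

import kinlagoon as kl
from kinlagoon.families import FamilyAssignment
from kinlagoon.io import SampleMetadata
from kinlagoon.spatial import (
    EARTH_RADIUS_KM,
    RelatednessClassSpec,
    bootstrap_balanced_kw,
    class_counts,
    classify_pairs,
    dunn_posthoc,
    family_dispersion_test,
    kruskal_wallis,
    pairwise_distances,
)

from oracles import dunn_hand, kw_hand
from test_families import rm_from_matrix


def meta_from_coords(coords):
    ids = [f"i{k}" for k in range(len(coords))]
    return SampleMetadata(
        pd.DataFrame(
            {"lat": [c[0] for c in coords], "lon": [c[1] for c in coords]},
            index=pd.Index(ids, name="id"),
        )
    )


class TestPairwiseDistances:
    def test_identical_coordinates_zero(self):
        d = pairwise_distances(meta_from_coords([(-16.5, -151.7)] * 3))
        assert np.allclose(d, 0.0)

    def test_one_degree_latitude(self):
        d = pairwise_distances(meta_from_coords([(0.0, 10.0), (1.0, 10.0)]))
        assert d[0, 1] == pytest.approx(math.pi * EARTH_RADIUS_KM / 180, abs=1e-9)

    def test_matches_law_of_cosines(self, rng):
        coords = [
            (float(rng.uniform(-60, 60)), float(rng.uniform(-179, 179)))
            for _ in range(12)
        ]
        d = pairwise_distances(meta_from_coords(coords))
        for (i, (la1, lo1)), (j, (la2, lo2)) in itertools.combinations(
            enumerate(coords), 2
        ):
            p1, p2 = math.radians(la1), math.radians(la2)
            dl = math.radians(lo2 - lo1)
            want = EARTH_RADIUS_KM * math.acos(
                min(1.0, math.sin(p1) * math.sin(p2)
                    + math.cos(p1) * math.cos(p2) * math.cos(dl))
            )
            assert d[i, j] == pytest.approx(want, abs=1e-6)
        assert np.allclose(d, d.T) and np.all(np.diag(d) == 0)

    def test_triangle_inequality(self, rng):
        coords = [
            (float(rng.uniform(-16.6, -16.4)), float(rng.uniform(-151.8, -151.6)))
            for _ in range(8)
        ]
        d = pairwise_distances(meta_from_coords(coords))
        for i, j, k in itertools.permutations(range(8), 3):
            assert d[i, j] <= d[i, k] + d[k, j] + 1e-9


class TestClassifyPairs:
    def test_boundary_goes_to_upper_bin(self):
        spec = RelatednessClassSpec()
        assert spec.assign(np.array([0.75]))[0] == spec.n_classes - 1
        assert spec.assign(np.array([0.25]))[0] == 3
        assert spec.assign(np.array([1.0]))[0] == spec.n_classes - 1

    def test_single_bin_takes_everything(self, rng):
        rm = rm_from_matrix(rng.uniform(0, 1, (6, 6)))
        pairs = classify_pairs(rm, (0.0, 1.0))
        assert set(pairs["class_index"]) == {0}
        assert len(pairs) == 15

    def test_counts_match_brute_force(self, rng):
        rm = rm_from_matrix(rng.uniform(0, 1, (10, 10)))
        spec = RelatednessClassSpec()
        pairs = classify_pairs(rm, spec)
        counts = class_counts(pairs, spec)
        edges = spec.edges
        brute = [0] * spec.n_classes
        for i in range(10):
            for j in range(i + 1, 10):
                r = rm.r[i, j]
                for b in range(spec.n_classes):
                    hi_ok = r < edges[b + 1] or (
                        b == spec.n_classes - 1 and r <= edges[b + 1]
                    )
                    if edges[b] <= r and hi_ok:
                        brute[b] += 1
                        break
        assert counts.tolist() == brute

    def test_out_of_range_rejected(self):
        spec = RelatednessClassSpec()
        with pytest.raises(ValueError):
            spec.assign(np.array([1.2]))


class TestKruskalWallis:
    def test_identical_groups_give_floor(self):
        vals = np.array([1.0, 2, 3, 1, 2, 3])
        groups = np.array(list("aaabbb"))
        h, p = kruskal_wallis(vals, groups)
        assert p > 0.9

    def test_all_tied_values(self):
        h, p = kruskal_wallis(np.ones(6), np.array(list("aaabbb")))
        assert (h, p) == (0.0, 1.0)

    def test_single_group_rejected(self):
        with pytest.raises(ValueError):
            kruskal_wallis(np.arange(4.0), np.array(list("aaaa")))

    def test_matches_hand_formula(self, rng):
        vals = np.round(rng.random(18), 2)  # rounding forces ties
        groups = np.repeat(list("abc"), 6)
        h, _ = kruskal_wallis(vals, groups)
        assert h == pytest.approx(kw_hand(vals, groups))

    def test_type_one_error_rate(self, rng):
        reps, alpha, rejections = 500, 0.05, 0
        for _ in range(reps):
            vals = rng.normal(size=30)
            groups = np.repeat(list("abc"), 10)
            _, p = kruskal_wallis(vals, groups)
            rejections += p <= alpha
        rate = rejections / reps
        se = math.sqrt(alpha * (1 - alpha) / reps)
        assert abs(rate - alpha) < 3 * se


class TestDunn:
    def test_identical_groups_capped_at_one(self):
        vals = np.array([1.0, 2, 3, 1, 2, 3])
        groups = np.array(list("ababab"))
        out = dunn_posthoc(vals, groups)
        assert out.loc["a", "b"] == 1.0

    def test_matches_hand_formula(self, rng):
        vals = np.round(rng.random(21), 2)
        groups = np.repeat(list("abc"), 7)
        raw = dunn_posthoc(vals, groups, adjust="none")
        adj = dunn_posthoc(vals, groups)
        from scipy.stats import norm

        m = 3
        for g1, g2 in itertools.combinations("abc", 2):
            z = dunn_hand(vals, groups, g1, g2)
            want = 2 * norm.sf(abs(z))
            assert raw.loc[g1, g2] == pytest.approx(want)
            assert adj.loc[g1, g2] == pytest.approx(min(want * m, 1.0))
            assert adj.loc[g1, g2] >= raw.loc[g1, g2] - 1e-15


class TestBootstrapBalancedKW:
    def _scenario(self, rng, shift=0.0):
        # three classes of pair distances; class "c" optionally shifted
        vals = np.concatenate(
            [rng.normal(5, 1, 300), rng.normal(5, 1, 80), rng.normal(5, 1, 12) + shift]
        )
        groups = np.array(["a"] * 300 + ["b"] * 80 + ["c"] * 12)
        return vals, groups

    def test_single_iteration_degenerate(self, rng):
        vals, groups = self._scenario(rng)
        res = bootstrap_balanced_kw(vals, groups, R=1, seed=1, collect_dunn=False)
        assert res.p_values.shape == (1,) and res.median_p == res.p_values[0]
        assert res.min_class_size == 12

    def test_seed_reproducibility(self, rng):
        vals, groups = self._scenario(rng)
        r1 = bootstrap_balanced_kw(vals, groups, R=50, seed=9, collect_dunn=False)
        r2 = bootstrap_balanced_kw(vals, groups, R=50, seed=9, collect_dunn=False)
        assert np.array_equal(r1.p_values, r2.p_values)

    def test_null_declared_non_significant(self, rng):
        vals, groups = self._scenario(rng, shift=0.0)
        res = bootstrap_balanced_kw(vals, groups, R=200, seed=3, collect_dunn=False)
        assert not res.significant and res.median_p > 0.05

    def test_strong_shift_declared_significant(self, rng):
        vals, groups = self._scenario(rng, shift=-10.0)
        res = bootstrap_balanced_kw(vals, groups, R=200, seed=3)
        assert res.significant and res.median_p < 0.001
        assert res.dunn_median_p.loc["c", "a"] < 0.05

    def test_empty_class_rejected(self):
        with pytest.raises(ValueError):
            bootstrap_balanced_kw(np.arange(4.0), np.array(list("aaaa")), R=5)


class TestFamilyDispersion:
    def _dist(self, coords):
        return pairwise_distances(meta_from_coords(coords))

    def test_point_families_extreme_p(self, rng):
        # two families, each at one point; background far away
        coords = [(-16.50, -151.70)] * 3 + [(-16.46, -151.75)] * 3 + [
            (float(rng.uniform(-16.6, -16.4)), float(rng.uniform(-151.8, -151.6)))
            for _ in range(14)
        ]
        ids = [f"i{k}" for k in range(20)]
        fa = FamilyAssignment(
            {"F1": ids[:3], "F2": ids[3:6]}, ids[6:]
        )
        n_perm = 199
        obs, null_mean, p = family_dispersion_test(
            fa, self._dist(coords), ids, n_perm=n_perm, seed=4
        )
        assert obs == pytest.approx(0.0, abs=1e-9)
        assert p == pytest.approx(1 / (n_perm + 1))

    def test_random_labels_null_mean_matches_overall(self, rng):
        coords = [
            (float(rng.uniform(-16.6, -16.4)), float(rng.uniform(-151.8, -151.6)))
            for _ in range(16)
        ]
        ids = [f"i{k}" for k in range(16)]
        fa = FamilyAssignment({"F1": ids[:4], "F2": ids[4:8]}, ids[8:])
        d = self._dist(coords)
        _, null_mean, p = family_dispersion_test(fa, d, ids, n_perm=400, seed=8)
        iu = np.triu_indices(16, 1)
        assert null_mean == pytest.approx(float(d[iu].mean()), rel=0.05)
        assert p > 0.01

    def test_exhaustive_enumeration_on_five_individuals(self, rng):
        coords = [
            (float(rng.uniform(-16.6, -16.4)), float(rng.uniform(-151.8, -151.6)))
            for _ in range(5)
        ]
        ids = [f"i{k}" for k in range(5)]
        fa = FamilyAssignment({"F1": [ids[0], ids[1]]}, ids[2:])
        d = self._dist(coords)
        obs = d[0, 1]
        # exact null: the family pair is any of the 10 unordered pairs
        iu = np.triu_indices(5, 1)
        null_vals = d[iu]
        p_exact = np.mean(null_vals <= obs + 1e-12)
        n_perm = 4000
        _, _, p = family_dispersion_test(fa, d, ids, n_perm=n_perm, seed=2)
        se = math.sqrt(p_exact * (1 - p_exact) / n_perm)
        assert p == pytest.approx(p_exact, abs=3 * se + 2 / n_perm)

    def test_no_families_rejected(self):
        fa = FamilyAssignment({}, ["a", "b"])
        with pytest.raises(ValueError):
            family_dispersion_test(fa, np.zeros((2, 2)), ["a", "b"])


class TestClassSpecProperties:
    from hypothesis import given, settings
    from hypothesis import strategies as st

    @given(st.lists(st.floats(0.0, 1.0), min_size=1, max_size=50))
    @settings(deadline=None, derandomize=True, max_examples=200)
    def test_every_value_lands_in_exactly_its_bin(self, values):
        spec = RelatednessClassSpec()
        idx = spec.assign(np.array(values))
        for v, b in zip(values, idx):
            assert spec.edges[b] <= v
            if b < spec.n_classes - 1:
                assert v < spec.edges[b + 1]
            else:
                assert v <= spec.edges[b + 1]
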