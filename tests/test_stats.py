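from itertools import combinations

import numpy as np
import pytest

from piscape.errors import ValidationError
from piscape.spectrum import HabitatAggregate
from piscape.stats import (DistanceMatrix, bray_curtis, classify_habitat,
                           distance_matrix, pca_profiles, permanova)


class TestBrayCurtis:
    def test_identity_is_zero(self, rng):
        p = rng.dirichlet(np.ones(10))
        assert bray_curtis(p, p) == 0.0

    def test_disjoint_supports_are_maximally_dissimilar(self):
        assert bray_curtis([1.0, 0.0], [0.0, 2.0]) == 1.0

    def test_worked_example(self):
        assert bray_curtis([0.5, 0.5, 0.0], [0.0, 0.5, 0.5]) == \
            pytest.approx(0.5)

    def test_two_zero_vectors_defined_as_zero(self):
        assert bray_curtis([0.0, 0.0], [0.0, 0.0]) == 0.0

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValidationError):
            bray_curtis([0.1], [0.1, 0.2])

    def test_matches_scipy(self, rng):
        from scipy.spatial.distance import braycurtis as scipy_bc

        for _ in range(20):
            p = rng.uniform(0, 1, size=12)
            q = rng.uniform(0, 1, size=12)
            assert bray_curtis(p, q) == pytest.approx(scipy_bc(p, q), abs=1e-12)

    def test_half_l1_for_relative_frequencies(self, rng):
        p = rng.dirichlet(np.ones(20))
        q = rng.dirichlet(np.ones(20))
        assert bray_curtis(p, q) == pytest.approx(0.5 * np.abs(p - q).sum(),
                                                  abs=1e-12)


def toy_distance_matrix(rng, n=12, shift=0.0):
    pts = rng.normal(size=(n, 4))
    pts[n // 2:] += shift
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d[i, j] = d[j, i] = np.linalg.norm(pts[i] - pts[j])
    return DistanceMatrix(tuple(f"s{i}" for i in range(n)), d)


class TestPermanova:
    def test_duplicated_identical_points_give_r2_one(self):
        d = np.array([[0, 0, 1, 1],
                      [0, 0, 1, 1],
                      [1, 1, 0, 0],
                      [1, 1, 0, 0]], dtype=float)
        dm = DistanceMatrix(("a1", "a2", "b1", "b2"), d)
        res = permanova(dm, ["a", "a", "b", "b"], 99, 0)
        assert res.r_squared == pytest.approx(1.0)
        assert np.isinf(res.pseudo_F)

    def test_p_value_matches_exact_enumeration(self, rng):
        """Permutation p on N=6, two groups of 3, vs. all 20 assignments."""
        dm = toy_distance_matrix(rng, n=6, shift=2.0)
        groups = ["g1"] * 3 + ["g2"] * 3
        d2 = dm.d ** 2

        def f_stat(codes):
            codes = np.asarray(codes)
            sst = d2.sum() / 12.0
            ssw = sum(d2[np.ix_(np.flatnonzero(codes == g),
                                np.flatnonzero(codes == g))].sum() / 6.0
                      for g in (0, 1))
            return (sst - ssw) / (ssw / 4.0)

        f_obs = f_stat([0, 0, 0, 1, 1, 1])
        fs = [f_stat([0 if i in comb else 1 for i in range(6)])
              for comb in combinations(range(6), 3)]
        exact_p = np.mean([f >= f_obs - 1e-12 for f in fs])
        res = permanova(dm, groups, 9999, 7)
        assert res.p_value == pytest.approx(exact_p, abs=0.01)

    def test_matches_skbio_pseudo_f(self, rng):
        from skbio.stats.distance import DistanceMatrix as SkDM
        from skbio.stats.distance import permanova as sk_permanova

        dm = toy_distance_matrix(rng, n=10, shift=1.0)
        groups = ["a"] * 5 + ["b"] * 5
        ours = permanova(dm, groups, 99, 0)
        theirs = sk_permanova(SkDM(dm.d, ids=dm.labels), grouping=list(groups),
                              permutations=99)
        assert ours.pseudo_F == pytest.approx(theirs["test statistic"],
                                              rel=1e-10)

    def test_reproducible_given_seed(self, rng):
        dm = toy_distance_matrix(rng)
        groups = ["a"] * 6 + ["b"] * 6
        r1 = permanova(dm, groups, 199, 42)
        r2 = permanova(dm, groups, 199, 42)
        assert r1.p_value == r2.p_value

    def test_invariant_to_object_relabeling(self, rng):
        dm = toy_distance_matrix(rng, n=8, shift=1.0)
        groups = ["a", "a", "b", "a", "b", "b", "a", "b"]
        perm = rng.permutation(8)
        d_perm = dm.d[np.ix_(perm, perm)]
        dm2 = DistanceMatrix(tuple(dm.labels[i] for i in perm), d_perm)
        groups2 = [groups[i] for i in perm]
        r1 = permanova(dm, groups, 99, 0)
        r2 = permanova(dm2, groups2, 99, 0)
        assert r1.pseudo_F == pytest.approx(r2.pseudo_F, rel=1e-10)
        assert r1.r_squared == pytest.approx(r2.r_squared, rel=1e-10)

    def test_single_group_rejected(self, rng):
        dm = toy_distance_matrix(rng, n=4)
        with pytest.raises(ValidationError):
            permanova(dm, ["a"] * 4, 99, 0)

    def test_type_one_error_close_to_alpha(self, rng):
        """Random labels on structureless profiles reject ~5% of the time."""
        n_reps, alpha, n_obj = 200, 0.05, 14
        rejections = 0
        for rep in range(n_reps):
            local = np.random.default_rng(5000 + rep)
            profiles = local.dirichlet(np.ones(24), size=n_obj)
            dm = distance_matrix(profiles, [f"s{i}" for i in range(n_obj)])
            groups = ["a"] * (n_obj // 2) + ["b"] * (n_obj // 2)
            res = permanova(dm, groups, 199, rep)
            rejections += res.p_value <= alpha
        rate = rejections / n_reps
        se = np.sqrt(alpha * (1 - alpha) / n_reps)
        assert abs(rate - alpha) <= 3 * se


class TestPca:
    def test_collinear_points_fully_explained_by_first_component(self):
        x = np.outer(np.arange(5.0), [1.0, 2.0, -1.0])
        with pytest.warns(UserWarning):
            res = pca_profiles(x, n_components=2)
        assert res.explained_variance_ratio[0] == pytest.approx(1.0)

    def test_duplicated_rows_get_identical_scores(self, rng):
        x = rng.normal(size=(6, 5))
        doubled = np.vstack([x, x])
        res = pca_profiles(doubled, 2)
        assert res.scores[:6] == pytest.approx(res.scores[6:], abs=1e-10)

    def test_matches_sklearn_up_to_sign(self, rng):
        from sklearn.decomposition import PCA

        x = rng.normal(size=(10, 8))
        ours = pca_profiles(x, 3)
        theirs = PCA(n_components=3).fit(x)
        assert ours.explained_variance_ratio == pytest.approx(
            theirs.explained_variance_ratio_, abs=1e-10)
        assert np.abs(ours.scores) == pytest.approx(
            np.abs(theirs.transform(x)), abs=1e-8)


class TestClassifier:
    REFS = {
        "freshwater": [HabitatAggregate(0.25, 0.0, 0.75)],
        "marine": [HabitatAggregate(0.75, 0.0, 0.25)],
    }

    def test_profile_at_centroid_wins_with_margin(self):
        label, margin = classify_habitat(HabitatAggregate(0.75, 0.0, 0.25),
                                         self.REFS)
        assert label == "marine"
        assert margin > 0

    def test_equidistant_tie_breaks_lexicographically(self):
        # exactly representable coordinates so both distances are bit-equal
        mid = HabitatAggregate(0.5, 0.0, 0.5)
        label, margin = classify_habitat(mid, self.REFS)
        assert label == "freshwater"
        assert margin == pytest.approx(0.0, abs=1e-12)

    def test_empty_reference_set_rejected(self):
        with pytest.raises(ValidationError):
            classify_habitat(HabitatAggregate(0.4, 0.1, 0.4), {})

    def test_holdout_accuracy_on_synthetic_cohort(self):
        """Nearest-centroid calls >= 90% of held-out proteomes correctly."""
        import piscape as ps
        from piscape.spectrum import acid_neutral_basic, bin_spectrum

        specs = {"marine": ps.SyntheticSpec(n_proteins=150,
                                            acid_shift_delta=1.0),
                 "freshwater": ps.SyntheticSpec(n_proteins=150,
                                                basic_shift_delta=1.0)}
        train, train_meta = ps.generate_cohort(5, specs, seed=31)
        refs: dict[str, list] = {"marine": [], "freshwater": []}
        for meta in train_meta:
            pis = ps.isoelectric_points(
                [r.sequence for r in train[meta.proteome_id]])
            refs[meta.habitat].append(acid_neutral_basic(bin_spectrum(pis)))
        test, test_meta = ps.generate_cohort(10, specs, seed=32)
        hits = 0
        for meta in test_meta:
            pis = ps.isoelectric_points(
                [r.sequence for r in test[meta.proteome_id]])
            label, _ = classify_habitat(bin_spectrum(pis), refs)
            hits += label == meta.habitat
        assert hits / len(test_meta) >= 0.9
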