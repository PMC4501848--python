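"""Fuzzy c-means, fuzzifier estimation, MCD-based cluster-number selection."""

import math
import subprocess

import numpy as np
import pytest

from phosphodyn.clustering import (
    cmeans,
    estimate_fuzzifier,
    filter_by_membership,
    impute_missing,
    min_centroid_distance,
    select_cluster_number,
    standardize,
)
from phosphodyn.errors import InsufficientDataError, ParameterError
from phosphodyn.simulate import make_template
from phosphodyn.types import TIME_GRID


def two_groups(seed=0, n_per=20, sep=10.0, spread=0.05, dim=5):
    rng = np.random.default_rng(seed)
    a = rng.normal(0.0, spread, size=(n_per, dim))
    b = rng.normal(0.0, spread, size=(n_per, dim)) + sep
    return np.vstack([a, b])


class TestStandardize:
    def test_simple_case(self):
        np.testing.assert_allclose(standardize([0, 1, 2]), [-1, 0, 1], atol=1e-12)

    def test_moments_and_idempotence(self):
        rng = np.random.default_rng(1)
        v = rng.standard_normal(15) * 3 + 2
        s = standardize(v)
        assert np.mean(s) == pytest.approx(0.0, abs=1e-12)
        assert np.std(s, ddof=1) == pytest.approx(1.0, abs=1e-12)
        np.testing.assert_allclose(standardize(s), s, atol=1e-12)

    def test_constant_vector_rejected(self):
        with pytest.raises(InsufficientDataError):
            standardize([1.0] * 15)


class TestImputeMissing:
    def test_interior_gap_linear_midpoint(self):
        v = np.full(15, np.nan)
        v[1], v[3] = 0.0, 2.0  # t=2 and t=6, gap at t=4
        v[4:] = 2.0
        out = impute_missing(TIME_GRID, v)
        assert out[2] == pytest.approx(1.0)

    def test_leading_gap_nearest_carry(self):
        v = np.array([np.nan, 0.5] + [1.0] * 13)
        out = impute_missing(TIME_GRID, v)
        assert out[0] == pytest.approx(0.5)

    def test_complete_profile_unchanged(self):
        rng = np.random.default_rng(2)
        v = rng.standard_normal(15)
        np.testing.assert_array_equal(impute_missing(TIME_GRID, v), v)

    def test_observed_points_never_altered(self):
        rng = np.random.default_rng(3)
        v = rng.standard_normal(15)
        v[[0, 4, 9, 14]] = np.nan
        out = impute_missing(TIME_GRID, v)
        mask = np.isfinite(v)
        np.testing.assert_array_equal(out[mask], v[mask])


class TestEstimateFuzzifier:
    def test_independent_arithmetic_oracle(self):
        """Closed form re-evaluated step by step with math-module arithmetic."""
        N, D = 388, 15
        term1 = (1418.0 / N + 22.05) * D ** -2
        term2 = (12.33 / N + 0.243) * math.pow(
            D, -0.0406 * math.log(N) - 0.1134)
        assert estimate_fuzzifier(N, D) == pytest.approx(1.0 + term1 + term2,
                                                         abs=1e-12)

    def test_limit_toward_one(self):
        assert estimate_fuzzifier(10 ** 9, 10 ** 6) == pytest.approx(1.0, abs=1e-3)

    def test_monotone_decreasing_in_n_and_d(self):
        ns = np.unique(np.geomspace(100, 10000, 60).astype(int))
        ms = [estimate_fuzzifier(n, 15) for n in ns]
        assert all(b < a for a, b in zip(ms, ms[1:]))
        ds = range(3, 60)
        ms_d = [estimate_fuzzifier(388, d) for d in ds]
        assert all(b < a for a, b in zip(ms_d, ms_d[1:]))

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ParameterError):
            estimate_fuzzifier(1, 15)


class TestCMeans:
    def test_k1_closed_form(self):
        X = two_groups(seed=4)
        model = cmeans(X, k=1, m=1.2, seed=0)
        np.testing.assert_allclose(model.centroids[0], X.mean(axis=0), atol=1e-12)
        np.testing.assert_array_equal(model.memberships, np.ones((len(X), 1)))

    def test_membership_rows_sum_to_one(self):
        rng = np.random.default_rng(5)
        X = rng.standard_normal((60, 15))
        model = cmeans(X, k=5, m=1.25, seed=1, restarts=3)
        np.testing.assert_allclose(model.memberships.sum(axis=1), 1.0, atol=1e-9)
        assert np.all(model.memberships >= 0) and np.all(model.memberships <= 1)

    def test_well_separated_two_group_recovery(self):
        X = two_groups(seed=6, sep=10.0, spread=0.05)
        model = cmeans(X, k=2, m=1.2, seed=2, restarts=5)
        max_u = model.memberships.max(axis=1)
        assert np.all(max_u >= 0.99)
        got = np.sort(model.centroids[:, 0])
        want = np.sort([X[:20].mean(axis=0)[0], X[20:].mean(axis=0)[0]])
        np.testing.assert_allclose(got, want, atol=1e-3)

    def test_objective_nonincreasing_many_seeds(self):
        rng = np.random.default_rng(7)
        X = rng.standard_normal((40, 8))
        for seed in range(20):
            model = cmeans(X, k=4, m=1.3, seed=seed, restarts=1)
            trace = model.objective_trace
            assert np.all(np.diff(trace) <= 1e-9 * (1 + trace[:-1]))

    def test_coincident_vector_gets_unit_membership(self):
        X = two_groups(seed=8)
        model = cmeans(X, k=2, m=1.2, seed=3, restarts=3)
        probe = model.centroids[0]
        X2 = np.vstack([X, probe])
        model2 = cmeans(X2, k=2, m=1.2, seed=3, restarts=3)
        # the appended point sits (numerically) on a centroid; its max
        # membership must be essentially 1
        assert model2.memberships[-1].max() > 0.999

    def test_m_near_one_approaches_hard_kmeans(self):
        from sklearn.cluster import KMeans
        X = two_groups(seed=9, sep=6.0, spread=0.3)
        model = cmeans(X, k=2, m=1.0001, seed=4, restarts=5)
        km = KMeans(n_clusters=2, n_init=10, random_state=0).fit(X)
        # same partition up to label order
        ours = model.labels()
        theirs = km.labels_
        agree = max(np.mean(ours == theirs), np.mean(ours == 1 - theirs))
        assert agree == 1.0
        assert model.memberships.max(axis=1).min() > 0.999

    def test_row_permutation_equivariance(self):
        X = two_groups(seed=10)
        rng = np.random.default_rng(11)
        perm = rng.permutation(len(X))
        model = cmeans(X, k=2, m=1.2, seed=5, restarts=5)
        model_p = cmeans(X[perm], k=2, m=1.2, seed=5, restarts=5)
        # partitions match after undoing the permutation (up to relabeling)
        a = model.labels()[perm]
        b = model_p.labels()
        agree = max(np.mean(a == b), np.mean(a == 1 - b))
        assert agree == 1.0

    def test_k_not_less_than_n_rejected(self):
        with pytest.raises(ParameterError):
            cmeans(np.zeros((3, 2)), k=3, m=1.2)


class TestCrossCheckAgainstR:
    def test_matches_e1071_cmeans_on_separated_data(self, tmp_path):
        """Independent implementation check: R e1071's cmeans on the same
        well-separated data converges to the same centroids/objective."""
        X = two_groups(seed=12, sep=8.0, spread=0.1, dim=4)
        csv = tmp_path / "x.csv"
        np.savetxt(csv, X, delimiter=",")
        script = tmp_path / "run.R"
        script.write_text(
            'x <- as.matrix(read.csv("%s", header=FALSE));'
            'set.seed(1);'
            'fit <- e1071::cmeans(x, centers=2, m=1.2, iter.max=500);'
            'cat(sort(fit$centers[,1]), fit$withinerror, sep="\\n")' % csv)
        try:
            out = subprocess.run(["Rscript", "--vanilla", str(script)],
                                 capture_output=True, text=True, timeout=120)
        except FileNotFoundError:
            pytest.skip("Rscript not available")
        assert out.returncode == 0, out.stderr
        lines = [float(v) for v in out.stdout.strip().splitlines()]
        r_centers = np.array(lines[:2])
        model = cmeans(X, k=2, m=1.2, seed=6, restarts=5)
        ours = np.sort(model.centroids[:, 0])
        np.testing.assert_allclose(ours, r_centers, atol=1e-4)


class TestMCD:
    def test_three_four_five(self):
        model = cmeans(two_groups(seed=13), k=2, m=1.2, seed=0, restarts=2)
        model.centroids = np.array([[0.0, 0.0], [3.0, 4.0]])
        model.k = 2
        assert min_centroid_distance(model) == pytest.approx(5.0)

    def test_matches_brute_force_over_pairs(self):
        rng = np.random.default_rng(14)
        X = rng.standard_normal((50, 6))
        model = cmeans(X, k=5, m=1.3, seed=7, restarts=3)
        brute = min(np.linalg.norm(model.centroids[i] - model.centroids[j])
                    for i in range(5) for j in range(i + 1, 5))
        assert min_centroid_distance(model) == pytest.approx(brute, abs=1e-12)

    def test_duplicated_centroid_gives_zero(self):
        model = cmeans(two_groups(seed=15), k=2, m=1.2, seed=0, restarts=2)
        model.centroids = np.array([[1.0, 2.0], [1.0, 2.0]])
        assert min_centroid_distance(model) == 0.0

    def test_k1_rejected(self):
        model = cmeans(two_groups(seed=16), k=1, m=1.2)
        with pytest.raises(ParameterError):
            min_centroid_distance(model)


def planted_template_vectors(n_per=40, noise=0.05, seed=0):
    """Four well-separated standardized template shapes + small noise."""
    rng = np.random.default_rng(seed)
    shapes = [
        make_template("monotone", 1.0, 4.0),
        make_template("monotone", -1.0, 4.0),
        make_template("adaptation", 1.0, 8.0),
        make_template("adaptation", -1.0, 8.0),
    ]
    vectors, labels = [], []
    for lab, shape in enumerate(shapes):
        for _ in range(n_per):
            v = shape + rng.normal(0, noise, size=len(shape))
            vectors.append(standardize(v))
            labels.append(lab)
    return np.array(vectors), np.array(labels)


class TestClusterNumberSelection:
    def test_recovers_four_planted_templates(self):
        X, _ = planted_template_vectors()
        k_star, curve, _ = select_cluster_number(X, m=1.25, k_range=range(2, 11),
                                                 seed=0, restarts=5)
        assert k_star == 4
        assert np.all(curve.mcd >= 0)

    def test_mcd_decays_with_k(self):
        X, _ = planted_template_vectors(seed=1)
        _, curve, _ = select_cluster_number(X, m=1.25, k_range=range(2, 11),
                                            seed=1, restarts=5)
        # non-increasing up to small run-to-run jitter
        assert np.all(np.diff(curve.mcd) <= 0.15 * curve.mcd[:-1] + 1e-9)

    def test_manual_override_bypasses_rule(self):
        X, _ = planted_template_vectors(seed=2)
        k_star, _, models = select_cluster_number(X, m=1.25, k_range=range(2, 9),
                                                  seed=2, restarts=3, k_override=7)
        assert k_star == 7 and models[7].k == 7


class TestMembershipFilter:
    def _model_with_max(self, values):
        u = np.array([[v, 1 - v] for v in values])
        model = cmeans(two_groups(seed=17), k=2, m=1.2, seed=0, restarts=2)
        model.memberships = u
        return model

    def test_strict_inequality_at_threshold(self):
        model = self._model_with_max([0.71, 0.70, 0.5])
        kept = filter_by_membership(model, ["a", "b", "c"], threshold=0.7)
        assert list(kept["profile_id"]) == ["a"]
        assert list(kept["cluster"]) == [1]

    def test_uniform_memberships_dropped(self):
        model = self._model_with_max([0.5, 0.5])
        # only two ids needed to match the doctored membership matrix
        kept = filter_by_membership(model, ["a", "b"], threshold=0.7)
        assert len(kept) == 0
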