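"""Tests of Shannon, Bray-Curtis, PCoA, centroids and PERMANOVA, with
independent oracles (double-loop distances, brute-force sums of squares,
scikit-bio cross-checks)."""

import numpy as np
import pandas as pd
import pytest
from scipy.spatial.distance import pdist, squareform

from osagut import (
    DistanceMatrix,
    bray_curtis,
    group_centroids,
    pairwise_permanova,
    pcoa,
    permanova,
    shannon_index,
    shannon_table,
)


class TestShannon:
    def test_closed_forms(self):
        assert shannon_index(np.full(100, 0.01)) == pytest.approx(np.log(100), abs=1e-12)
        assert shannon_index([0.0, 1.0, 0.0]) == 0.0
        assert shannon_index([0.5, 0.5, 0.0]) == pytest.approx(np.log(2), abs=1e-12)

    def test_renormalization_invariance(self):
        assert shannon_index([2.0, 2.0]) == pytest.approx(shannon_index([0.5, 0.5]))

    def test_log2_flag(self):
        assert shannon_index([0.5, 0.5], base="2") == pytest.approx(1.0)

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError):
            shannon_index([0.0, 0.0])

    def test_table_matches_scalar(self, small_cohort):
        h = shannon_table(small_cohort.abundance)
        i = small_cohort.abundance.index[3]
        assert h[i] == pytest.approx(shannon_index(small_cohort.abundance.loc[i]))


class TestBrayCurtis:
    def test_hand_example(self):
        ab = pd.DataFrame([[0.6, 0.4], [0.2, 0.8]], index=["a", "b"])
        assert bray_curtis(ab).d[0, 1] == pytest.approx(0.4)

    def test_identical_and_disjoint(self):
        ab = pd.DataFrame([[0.5, 0.5, 0, 0], [0.5, 0.5, 0, 0], [0, 0, 0.3, 0.7]])
        d = bray_curtis(ab).d
        assert d[0, 1] == pytest.approx(0.0)
        assert d[0, 2] == pytest.approx(1.0)

    def test_matches_double_loop_oracle(self, rng):
        x = rng.random((20, 30))
        x[rng.random((20, 30)) < 0.4] = 0.0
        x[:, 0] += 0.01  # every row positive somewhere
        ab = pd.DataFrame(x)
        d = bray_curtis(ab).d
        for i in range(20):
            for j in range(20):
                expected = np.abs(x[i] - x[j]).sum() / (x[i] + x[j]).sum()
                assert d[i, j] == pytest.approx(expected, abs=1e-12)


class TestPcoa:
    def test_euclidean_reconstruction(self, rng):
        pts = rng.normal(size=(12, 2))
        dm = DistanceMatrix(ids=[str(i) for i in range(12)], d=squareform(pdist(pts)))
        ordn = pcoa(dm, n_axes=2)
        d2 = squareform(pdist(ordn.coordinates))
        assert np.abs(dm.d - d2).max() < 1e-8

    def test_three_equidistant_points(self):
        d = np.ones((3, 3)) - np.eye(3)
        ordn = pcoa(DistanceMatrix(ids=list("abc"), d=d))
        ev = ordn.eigenvalues[ordn.eigenvalues > 1e-10]
        assert len(ev) == 2
        assert ev[0] == pytest.approx(ev[1])

    def test_duplicate_rows_coincide(self):
        ab = pd.DataFrame([[0.5, 0.5], [0.5, 0.5], [0.1, 0.9]], index=list("abc"))
        ordn = pcoa(bray_curtis(ab))
        assert np.allclose(ordn.coordinates[0], ordn.coordinates[1], atol=1e-9)

    def test_explained_variance_bounded_and_sorted(self, small_cohort):
        dm = bray_curtis(small_cohort.abundance.iloc[:80])
        ordn = pcoa(dm, n_axes=5)
        assert ordn.explained_variance.sum() <= 1.0 + 1e-12
        assert (np.diff(ordn.explained_variance) <= 1e-12).all()
        assert np.abs(ordn.coordinates.mean(axis=0)).max() < 1e-8

    def test_axis_truncation_warns(self):
        d = np.ones((3, 3)) - np.eye(3)
        with pytest.warns(UserWarning):
            pcoa(DistanceMatrix(ids=list("abc"), d=d), n_axes=3)

    def test_matches_skbio(self, small_cohort):
        skbio = pytest.importorskip("skbio")
        dm = bray_curtis(small_cohort.abundance.iloc[:40])
        theirs = skbio.stats.ordination.pcoa(skbio.DistanceMatrix(dm.d, ids=dm.ids))
        ours = pcoa(dm, n_axes=3)
        assert np.allclose(
            ours.eigenvalues[:3], np.sort(theirs.eigvals.to_numpy())[::-1][:3], atol=1e-8
        )


class TestCentroids:
    def test_single_group_at_origin(self, rng):
        pts = rng.normal(size=(20, 3))
        dm = DistanceMatrix(ids=[str(i) for i in range(20)], d=squareform(pdist(pts)))
        ordn = pcoa(dm, n_axes=2)
        cent = group_centroids(ordn, pd.Series(["all"] * 20))
        assert abs(cent.loc["all", "mean_axis1"]) < 1e-8

    def test_mirrored_groups(self):
        coords = np.array([[1.0, 0], [2.0, 0], [-1.0, 0], [-2.0, 0]])
        from osagut.diversity import OrdinationResult

        ordn = OrdinationResult(
            ids=list("abcd"), coordinates=coords,
            eigenvalues=np.array([1.0, 0.0]), explained_variance=np.array([1.0, 0.0]),
        )
        cent = group_centroids(ordn, pd.Series(["p", "p", "m", "m"], index=list("abcd")))
        assert cent.loc["p", "mean_axis1"] == pytest.approx(-cent.loc["m", "mean_axis1"])

    def test_se_close_to_bootstrap_oracle(self, rng):
        coords = rng.normal(size=(60, 1))
        from osagut.diversity import OrdinationResult

        ids = [str(i) for i in range(60)]
        ordn = OrdinationResult(
            ids=ids, coordinates=coords, eigenvalues=np.array([1.0]),
            explained_variance=np.array([1.0]),
        )
        cent = group_centroids(ordn, pd.Series(["g"] * 60, index=ids))
        boots = [
            coords[rng.integers(0, 60, size=60), 0].mean() for _ in range(1000)
        ]
        assert cent.loc["g", "se_axis1"] == pytest.approx(np.std(boots, ddof=1), rel=0.15)

    def test_singleton_group_missing_se(self):
        from osagut.diversity import OrdinationResult

        ordn = OrdinationResult(
            ids=list("ab"), coordinates=np.array([[0.0], [1.0]]),
            eigenvalues=np.array([1.0]), explained_variance=np.array([1.0]),
        )
        cent = group_centroids(ordn, pd.Series(["x", "y"], index=list("ab")))
        assert np.isnan(cent.loc["x", "se_axis1"])


def _brute_force_f(d, labels):
    """One-way PERMANOVA pseudo-F from the classical SS partition on a
    distance matrix (Anderson's direct formula), no covariates."""
    n = len(labels)
    ss_total = (d[np.triu_indices(n, 1)] ** 2).sum() / n
    ss_within = 0.0
    for lv in np.unique(labels):
        idx = np.flatnonzero(labels == lv)
        sub = d[np.ix_(idx, idx)]
        ss_within += (sub[np.triu_indices(len(idx), 1)] ** 2).sum() / len(idx)
    a = len(np.unique(labels))
    ss_among = ss_total - ss_within
    return (ss_among / (a - 1)) / (ss_within / (n - a))


class TestPermanova:
    def test_matches_brute_force_partition(self, rng):
        pts = rng.normal(size=(6, 2))
        d = squareform(pdist(pts))
        labels = np.array(["a", "a", "a", "b", "b", "b"])
        dm = DistanceMatrix(ids=[str(i) for i in range(6)], d=d)
        res = permanova(dm, pd.Series(labels), n_permutations=99, seed=0)
        assert res.pseudo_f == pytest.approx(_brute_force_f(d, labels), abs=1e-10)

    def test_matches_skbio_unadjusted(self, rng):
        skbio = pytest.importorskip("skbio")
        x = rng.dirichlet(np.ones(15), size=24)
        ab = pd.DataFrame(x, index=[f"p{i}" for i in range(24)])
        labels = pd.Series(["a"] * 12 + ["b"] * 12)
        dm = bray_curtis(ab)
        ours = permanova(dm, labels, n_permutations=99, seed=0)
        theirs = skbio.stats.distance.permanova(
            skbio.DistanceMatrix(dm.d, ids=dm.ids), labels.to_numpy(), permutations=99
        )
        assert ours.pseudo_f == pytest.approx(theirs["test statistic"], abs=1e-10)

    def test_seeded_reproducibility(self, rng):
        x = rng.dirichlet(np.ones(10), size=20)
        dm = bray_curtis(pd.DataFrame(x))
        g = pd.Series(["a", "b"] * 10)
        r1 = permanova(dm, g, n_permutations=199, seed=5)
        r2 = permanova(dm, g, n_permutations=199, seed=5)
        assert r1.p == r2.p and r1.pseudo_f == r2.pseudo_f

    def test_null_p_uniformity(self, rng):
        # spec band: over 200 null runs the strict p<0.05 fraction sits in [0.02, 0.09]
        hits = 0
        for _ in range(200):
            x = rng.dirichlet(np.ones(8), size=24)
            dm = bray_curtis(pd.DataFrame(x))
            g = pd.Series(rng.permutation(["a"] * 12 + ["b"] * 12))
            res = permanova(dm, g, n_permutations=99, seed=int(rng.integers(2**31)))
            hits += res.p < 0.05
        assert 0.02 <= hits / 200 <= 0.09

    def test_mean_shift_reduces_p(self, rng):
        ps = {"null": [], "shift": []}
        for kind in ("null", "shift"):
            for _ in range(10):
                x = rng.dirichlet(np.ones(10), size=30)
                if kind == "shift":
                    x[:15, 0] += 0.3
                    x /= x.sum(axis=1, keepdims=True)
                dm = bray_curtis(pd.DataFrame(x))
                g = pd.Series(["a"] * 15 + ["b"] * 15)
                ps[kind].append(permanova(dm, g, n_permutations=99, seed=1).p)
        assert np.mean(ps["shift"]) < np.mean(ps["null"])

    def test_covariate_adjustment_changes_statistic(self, small_cohort):
        from osagut import assign_severity_groups, compute_parameters_table

        ab = small_cohort.abundance.iloc[:150]
        dm = bray_curtis(ab)
        params = compute_parameters_table(small_cohort.recordings, small_cohort.events)
        groups = assign_severity_groups(params).iloc[:150]
        cov = small_cohort.covariates.iloc[:150][["age", "sex", "bmi"]]
        r_adj = permanova(dm, groups.odi_group, cov, n_permutations=99, seed=2)
        r_raw = permanova(dm, groups.odi_group, None, n_permutations=99, seed=2)
        assert r_adj.pseudo_f != pytest.approx(r_raw.pseudo_f)
        assert r_adj.n == r_raw.n == 150

    def test_collinear_group_rejected(self):
        d = np.ones((6, 6)) - np.eye(6)
        dm = DistanceMatrix(ids=[str(i) for i in range(6)], d=d)
        g = pd.Series(["a", "a", "a", "b", "b", "b"])
        cov = pd.DataFrame({"dup": [0, 0, 0, 1, 1, 1]})
        with pytest.raises(ValueError):
            permanova(dm, g, cov, n_permutations=99, seed=0)

    def test_pairwise_covers_all_pairs(self, rng):
        x = rng.dirichlet(np.ones(8), size=30)
        dm = bray_curtis(pd.DataFrame(x))
        g = pd.Series(["a"] * 10 + ["b"] * 10 + ["c"] * 10)
        table = pairwise_permanova(dm, g, n_permutations=99, seed=0)
        assert set(map(tuple, table[["group_a", "group_b"]].values)) == {
            ("a", "b"), ("a", "c"), ("b", "c")
        }
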