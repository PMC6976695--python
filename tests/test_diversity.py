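"""Diversity statistics against hand values and independent oracles."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy.spatial.distance import pdist, squareform
from scipy.stats import f_oneway, rankdata
from skbio import DistanceMatrix
from skbio.stats.distance import anosim as skbio_anosim
from scipy.spatial import procrustes

import picodepth as pk
from picodepth import diversity as dv


class TestAlpha:
    @pytest.mark.parametrize(
        "vec,expected",
        [
            ([1, 1, 1, 1], np.log(4)),
            ([5], 0.0),
            ([0.5, 0.25, 0.25], 1.0397207708399179),
        ],
    )
    def test_shannon_values(self, vec, expected):
        assert dv.shannon(vec) == pytest.approx(expected, abs=1e-12)

    def test_shannon_rejects_all_zero(self):
        with pytest.raises(ValueError):
            dv.shannon([0, 0])

    def test_richness(self):
        assert dv.richness([0, 3, 0, 1]) == 2
        assert dv.richness([0, 0]) == 0

    def test_richness_never_increases_under_rarefaction(self):
        t = pk.OtuTable(
            pd.DataFrame({"s": [50, 30, 10, 5, 3, 2]},
                         index=[f"o{i}" for i in range(6)])
        )
        before = dv.richness(t.data["s"])
        for seed in range(5):
            out = pk.rarefy(t, depth=20, seed=seed)
            assert dv.richness(out.data["s"]) <= before


class TestBrayCurtis:
    def test_hand_values(self, tiny_table):
        dm = dv.bray_curtis(tiny_table)
        assert dm[("s1", "s2")] == pytest.approx(8 / 12)

    def test_identical_and_disjoint(self):
        df = pd.DataFrame({"a": [3, 1, 0], "b": [3, 1, 0], "c": [0, 0, 9]})
        dm = dv.bray_curtis(df)
        assert dm[("a", "b")] == 0.0
        assert dm[("a", "c")] == 1.0

    def test_invariant_to_otu_order(self, tiny_table):
        shuffled = pk.OtuTable(tiny_table.data.iloc[[2, 0, 1]])
        a = dv.bray_curtis(tiny_table)
        b = dv.bray_curtis(shuffled)
        assert np.allclose(a.data, b.data)

    def test_all_zero_sample_rejected(self):
        with pytest.raises(ValueError, match="all-zero"):
            dv.bray_curtis(pd.DataFrame({"a": [1, 2], "b": [0, 0]}))

    def test_range_symmetry_zero_diagonal(self):
        rng = np.random.default_rng(1)
        df = pd.DataFrame(rng.integers(0, 20, size=(10, 6)) + 0,
                          columns=[f"s{i}" for i in range(6)])
        df.iloc[0] += 1  # avoid all-zero columns
        dm = dv.bray_curtis(df)
        assert np.allclose(dm.data, dm.data.T)
        assert np.all(np.diag(dm.data) == 0)
        assert dm.data.min() >= 0 and dm.data.max() <= 1


def _anosim_brute_force(dm: DistanceMatrix, labels: np.ndarray) -> tuple[float, float]:
    """Exhaustive-relabeling oracle: R by direct double loop over pairs,
    p by enumerating every distinct assignment of labels to samples."""
    n = len(labels)

    def r_of(lab):
        within, between = [], []
        ranks = squareform(rankdata(dm.data[np.triu_indices(n, 1)]))
        for i, j in itertools.combinations(range(n), 2):
            (within if lab[i] == lab[j] else between).append(ranks[i, j])
        m = n * (n - 1) / 2
        return (np.mean(between) - np.mean(within)) / (m / 2)

    observed = r_of(labels)
    values = []
    idx_of_group1 = [i for i in itertools.combinations(range(n), int((labels == labels[0]).sum()))]
    for combo in idx_of_group1:
        lab = np.array(["g2"] * n)
        lab[list(combo)] = "g1"
        values.append(r_of(lab))
    values = np.array(values)
    p = (np.count_nonzero(values >= observed - 1e-12)) / len(values)
    return observed, p


class TestAnosim:
    def test_perfect_separation_gives_r_one(self):
        data = np.array([[0, .1, .8, .9], [.1, 0, .85, .8],
                         [.8, .85, 0, .05], [.9, .8, .05, 0]])
        dm = DistanceMatrix(data, ids=list("abcd"))
        res = dv.anosim(dm, ["g1", "g1", "g2", "g2"], n_perm=99, seed=0)
        assert res.statistic == pytest.approx(1.0)

    def test_matches_brute_force_oracle_on_six_samples(self):
        rng = np.random.default_rng(3)
        X = rng.normal(size=(6, 5))
        X[:3] += 1.5
        dm = DistanceMatrix(squareform(pdist(np.abs(X) + 0.1, "braycurtis")),
                            ids=list("abcdef"))
        labels = np.array(["g1"] * 3 + ["g2"] * 3)
        oracle_r, _ = _anosim_brute_force(dm, labels)
        res = dv.anosim(dm, labels, n_perm=500, seed=0)
        assert res.statistic == pytest.approx(oracle_r, abs=1e-12)

    def test_matches_skbio_statistic(self):
        rng = np.random.default_rng(8)
        X = np.abs(rng.normal(size=(9, 7))) + 0.05
        dm = DistanceMatrix(squareform(pdist(X, "braycurtis")),
                            ids=[f"s{i}" for i in range(9)])
        labels = ["a"] * 3 + ["b"] * 3 + ["c"] * 3
        ours = dv.anosim(dm, labels, n_perm=99, seed=0).statistic
        theirs = skbio_anosim(dm, list(labels), permutations=0)["test statistic"]
        assert ours == pytest.approx(theirs, abs=1e-12)

    def test_p_bounded_by_permutation_resolution(self):
        data = np.array([[0, .1, .8, .9], [.1, 0, .85, .8],
                         [.8, .85, 0, .05], [.9, .8, .05, 0]])
        dm = DistanceMatrix(data, ids=list("abcd"))
        res = dv.anosim(dm, ["g1", "g1", "g2", "g2"], n_perm=999, seed=0)
        assert res.p_value >= 1 / (999 + 1)
        assert -1 <= res.statistic <= 1

    def test_small_group_rejected(self):
        dm = DistanceMatrix(np.array([[0, .5, .4], [.5, 0, .3], [.4, .3, 0]]),
                            ids=list("abc"))
        with pytest.raises(ValueError, match="fewer than 2"):
            dv.anosim(dm, ["g1", "g2", "g2"], n_perm=9, seed=0)


class TestPermanova:
    def test_zero_within_dissimilarity_gives_full_r2(self):
        d = np.zeros((6, 6))
        d[:3, 3:] = 0.8
        d[3:, :3] = 0.8
        dm = DistanceMatrix(d, ids=list("abcdef"))
        res = dv.permanova(dm, pd.DataFrame({"g": ["x"] * 3 + ["y"] * 3}),
                           n_perm=99, seed=0)
        assert res.table.loc["g", "R2"] == pytest.approx(1.0)

    def test_univariate_euclidean_equals_anova_f(self):
        rng = np.random.default_rng(5)
        y = rng.normal(size=15)
        g = np.repeat(["a", "b", "c"], 5)
        dm = DistanceMatrix(squareform(pdist(y[:, None])),
                            ids=[str(i) for i in range(15)])
        res = dv.permanova(dm, pd.DataFrame({"g": g}), n_perm=99, seed=0)
        expected = f_oneway(y[:5], y[5:10], y[10:]).statistic
        assert res.table.loc["g", "pseudo_F"] == pytest.approx(expected, rel=1e-10)

    def test_null_pseudo_f_mean_near_one(self):
        rng = np.random.default_rng(7)
        fs = []
        g = np.repeat(["a", "b"], 15)
        for _ in range(300):
            X = rng.normal(size=(30, 10))
            dm = DistanceMatrix(squareform(pdist(X)),
                                ids=[str(i) for i in range(30)])
            res = dv.permanova(dm, pd.DataFrame({"g": g}), n_perm=0, seed=0)
            fs.append(res.table.loc["g", "pseudo_F"])
        assert np.mean(fs) == pytest.approx(1.0, abs=0.1)

    def test_r2_components_sum_to_one(self):
        rng = np.random.default_rng(2)
        X = np.abs(rng.normal(size=(12, 6))) + 0.01
        dm = DistanceMatrix(squareform(pdist(X, "braycurtis")),
                            ids=[str(i) for i in range(12)])
        terms = pd.DataFrame({
            "g": np.repeat(["a", "b", "c"], 4),
            "cov": rng.normal(size=12),
        })
        res = dv.permanova(dm, terms, n_perm=49, seed=1)
        r2 = res.table.drop(index="Total")["R2"]
        assert (r2 >= -1e-12).all()
        assert r2.sum() == pytest.approx(1.0, abs=1e-10)

    def test_constant_term_dropped(self):
        rng = np.random.default_rng(4)
        X = np.abs(rng.normal(size=(8, 4))) + 0.01
        dm = DistanceMatrix(squareform(pdist(X, "braycurtis")),
                            ids=[str(i) for i in range(8)])
        terms = pd.DataFrame({"const": ["z"] * 8, "g": np.repeat(["a", "b"], 4)})
        res = dv.permanova(dm, terms, n_perm=9, seed=0)
        assert res.dropped_terms == ["const"]
        assert list(res.table.index) == ["g", "Residual", "Total"]


class TestNmds:
    def _planar_dm(self, n=9, seed=0):
        rng = np.random.default_rng(seed)
        pts = rng.normal(size=(n, 2))
        return pts, DistanceMatrix(squareform(pdist(pts)),
                                   ids=[f"s{i}" for i in range(n)])

    def test_exactly_embeddable_configuration_has_near_zero_stress(self):
        _, dm = self._planar_dm()
        res = dv.nmds(dm, k=2, n_starts=4, seed=0)
        assert res.stress < 1e-3

    def test_stress_path_non_increasing(self):
        rng = np.random.default_rng(6)
        X = np.abs(rng.normal(size=(10, 8))) + 0.01
        dm = DistanceMatrix(squareform(pdist(X, "braycurtis")),
                            ids=[f"s{i}" for i in range(10)])
        res = dv.nmds(dm, k=2, n_starts=3, seed=0)
        path = np.array(res.stress_path)
        assert np.all(np.diff(path) <= 1e-12)

    def test_two_clusters_separate_in_embedding(self):
        d = np.full((8, 8), 0.9)
        within = 0.1
        d[:4, :4] = within
        d[4:, 4:] = within
        np.fill_diagonal(d, 0)
        dm = DistanceMatrix(d, ids=[f"s{i}" for i in range(8)])
        res = dv.nmds(dm, k=2, n_starts=8, seed=1)
        coords = res.coordinates.to_numpy()
        c1, c2 = coords[:4].mean(axis=0), coords[4:].mean(axis=0)
        spread = max(
            np.linalg.norm(coords[:4] - c1, axis=1).max(),
            np.linalg.norm(coords[4:] - c2, axis=1).max(),
        )
        assert np.linalg.norm(c1 - c2) > spread

    def test_invariant_to_sample_order_up_to_procrustes(self):
        pts, dm = self._planar_dm(n=8, seed=3)
        res1 = dv.nmds(dm, k=2, n_starts=2, seed=0, tol=1e-12, max_iter=2000)
        perm = [5, 2, 7, 0, 3, 6, 1, 4]
        ids = [dm.ids[i] for i in perm]
        dm2 = DistanceMatrix(dm.data[np.ix_(perm, perm)], ids=ids)
        res2 = dv.nmds(dm2, k=2, n_starts=2, seed=0, tol=1e-12, max_iter=2000)
        a = res1.coordinates.loc[ids].to_numpy()
        b = res2.coordinates.to_numpy()
        _, _, disparity = procrustes(a, b)
        assert disparity < 1e-6

    def test_k_must_be_below_sample_count(self):
        _, dm = self._planar_dm(n=4)
        with pytest.raises(ValueError):
            dv.nmds(dm, k=4, n_starts=1, seed=0)
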