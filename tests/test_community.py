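import numpy as np
import pandas as pd
import pytest
import scipy.spatial.distance as ssd
import scipy.stats as sstats

from bovibuccal.community import (
    DistanceMatrix,
    bray_curtis,
    correlation_display_order,
    dunnett,
    euclidean,
    pcoa,
    pearson_matrix,
    ward_cluster,
    welch_t,
)
from bovibuccal.tables import TaxonTable


def _table(cols: dict, taxa=None) -> TaxonTable:
    taxa = taxa or [f"t{i}" for i in range(len(next(iter(cols.values()))))]
    return TaxonTable(pd.DataFrame(cols, index=taxa))


class TestDistances:
    def test_identical_samples_zero(self):
        t = _table({"a": [5, 5], "b": [5, 5]})
        assert bray_curtis(t).values[0, 1] == 0.0
        assert euclidean(t).values[0, 1] == 0.0

    def test_disjoint_supports_one(self):
        t = _table({"a": [10, 0], "b": [0, 10]})
        assert bray_curtis(t).values[0, 1] == pytest.approx(1.0)

    def test_hand_calculation(self):
        # relabund u=(0.7,0.3,0), v=(0.3,0.3,0.4): 1 - 2*0.6/2 = 0.4
        t = _table({"u": [7, 3, 0], "v": [3, 3, 4]})
        assert bray_curtis(t).values[0, 1] == pytest.approx(0.4)

    def test_euclidean_closed_form(self):
        t = _table({"a": [1, 0], "b": [0, 1]})
        assert euclidean(t).values[0, 1] == pytest.approx(np.sqrt(2))

    def test_euclidean_matches_brute_force(self, rng):
        t = _table({f"s{i}": rng.integers(1, 100, 6) for i in range(5)})
        d = euclidean(t).values
        ra = t.relabund
        for i, a in enumerate(t.sample_ids):
            for j, b in enumerate(t.sample_ids):
                expected = np.sqrt(((ra[a] - ra[b]) ** 2).sum())
                assert d[i, j] == pytest.approx(expected)

    def test_zero_read_sample_rejected_for_braycurtis(self):
        t = _table({"a": [1, 1], "b": [0, 0]})
        with pytest.raises(ValueError, match="zero reads"):
            bray_curtis(t)

    def test_distance_axioms(self, rng):
        t = _table({f"s{i}": rng.integers(1, 50, 8) for i in range(6)})
        for d in (bray_curtis(t), euclidean(t)):
            v = d.values
            assert (v >= 0).all()
            assert np.allclose(v, v.T)
            assert np.allclose(np.diag(v), 0)
        assert (bray_curtis(t).values <= 1 + 1e-12).all()


class TestPcoa:
    def test_two_samples_forced_geometry(self):
        d = DistanceMatrix(("a", "b"), np.array([[0.0, 0.6], [0.6, 0.0]]))
        res = pcoa(d)
        assert sorted(res.coordinates[:, 0]) == pytest.approx([-0.3, 0.3])

    def test_round_trips_euclidean_embeddable_input(self, rng):
        pts = rng.normal(size=(7, 3))
        D = ssd.squareform(ssd.pdist(pts))
        res = pcoa(DistanceMatrix(tuple(f"s{i}" for i in range(7)), D))
        D2 = ssd.squareform(ssd.pdist(res.coordinates))
        assert np.abs(D - D2).max() < 1e-8
        assert res.coordinates.shape[1] <= 3

    def test_zero_matrix_all_zero_eigenvalues(self):
        d = DistanceMatrix(("a", "b", "c"), np.zeros((3, 3)))
        res = pcoa(d)
        assert np.allclose(res.eigenvalues, 0)
        assert res.coordinates.shape[1] == 0

    def test_eigenvalues_sorted_and_proportions(self, rng):
        pts = rng.normal(size=(6, 4))
        D = ssd.squareform(ssd.pdist(pts))
        res = pcoa(DistanceMatrix(tuple("abcdef"), D))
        assert (np.diff(res.eigenvalues) <= 1e-12).all()
        assert res.proportion_explained.sum() == pytest.approx(1.0)

    def test_matches_skbio_reference(self, rng):
        skbio = pytest.importorskip("skbio")
        t = _table({f"s{i}": rng.integers(1, 80, 10) for i in range(6)})
        d = bray_curtis(t)
        mine = pcoa(d)
        ref = skbio.stats.ordination.pcoa(
            skbio.DistanceMatrix(d.values, ids=list(d.ids)), method="eigh"
        )
        n_axes = mine.coordinates.shape[1]
        ref_coords = ref.samples.to_numpy()[:, :n_axes]
        # eigenvector sign is arbitrary; compare per-axis up to sign
        for k in range(n_axes):
            a, b = mine.coordinates[:, k], ref_coords[:, k]
            assert min(np.abs(a - b).max(), np.abs(a + b).max()) < 1e-8


class TestWardCluster:
    def test_two_blobs_recovered(self, rng):
        pts = np.vstack([rng.normal(0, 0.05, (5, 2)), rng.normal(3, 0.05, (4, 2))])
        D = ssd.squareform(ssd.pdist(pts))
        d = DistanceMatrix(tuple(f"s{i}" for i in range(9)), D)
        res = ward_cluster(d, k=2)
        assert len(set(res.labels[:5])) == 1
        assert len(set(res.labels[5:])) == 1
        assert res.labels[0] != res.labels[-1]

    def test_k_equals_n_singletons(self):
        D = ssd.squareform(ssd.pdist(np.arange(4, dtype=float)[:, None]))
        res = ward_cluster(DistanceMatrix(tuple("abcd"), D), k=4)
        assert sorted(res.labels) == [1, 2, 3, 4]

    def test_four_point_hand_computed_merge_heights(self):
        # 1-D points 0, 2, 9, 10; Lance-Williams Ward update on squared
        # distances gives merges at heights 1, 2, sqrt(578/4)
        D = ssd.squareform(ssd.pdist(np.array([0.0, 2.0, 9.0, 10.0])[:, None]))
        res = ward_cluster(DistanceMatrix(tuple("abcd"), D), k=2)
        heights = res.linkage[:, 2]
        assert heights == pytest.approx([1.0, 2.0, np.sqrt(578 / 4)])
        assert list(res.labels) == [1, 1, 2, 2] or list(res.labels) == [2, 2, 1, 1]

    def test_heights_non_decreasing_and_newick_valid(self, rng):
        dendropy = pytest.importorskip("dendropy")
        pts = rng.normal(size=(8, 3))
        D = ssd.squareform(ssd.pdist(pts))
        ids = tuple(f"s{i}" for i in range(8))
        res = ward_cluster(DistanceMatrix(ids, D), k=3)
        assert (np.diff(res.linkage[:, 2]) >= -1e-12).all()
        tree = dendropy.Tree.get(data=res.to_newick(), schema="newick")
        assert {l.taxon.label for l in tree.leaf_node_iter()} == set(ids)

    def test_ward_d_variant_matches_plain_recurrence(self):
        # for 2 points both variants merge at the input distance scale:
        # D2 height = d, D height = d (recurrence on d directly)
        D = np.array([[0.0, 3.0], [3.0, 0.0]])
        d = DistanceMatrix(("a", "b"), D)
        assert ward_cluster(d, 1, variant="D2").linkage[0, 2] == pytest.approx(3.0)
        assert ward_cluster(d, 1, variant="D").linkage[0, 2] == pytest.approx(3.0)

    def test_invalid_k(self):
        d = DistanceMatrix(("a", "b"), np.array([[0.0, 1.0], [1.0, 0.0]]))
        with pytest.raises(ValueError):
            ward_cluster(d, 0)


class TestPearson:
    def test_self_correlation_and_anticorrelation(self, rng):
        x = rng.integers(1, 50, 10)
        counts = pd.DataFrame(
            {f"s{i}": [x[i], 100 - x[i], 50] for i in range(10)},
            index=["up", "down", "flat"],
        )
        r, p, sig = pearson_matrix(TaxonTable(counts))
        assert r.loc["up", "up"] == pytest.approx(1.0)
        # up and down counts are complementary within a constant-total
        # composition: exact negative correlation
        assert r.loc["up", "down"] == pytest.approx(-1.0)
        assert p.loc["up", "down"] == pytest.approx(0.0, abs=1e-12)

    def test_zero_variance_taxon_reported_missing(self, rng):
        counts = pd.DataFrame(
            {f"s{i}": [int(v), 7] for i, v in enumerate(rng.integers(1, 99, 8))},
            index=["var", "const"],
        )
        # make 'const' truly constant in relative abundance: equal totals
        counts.loc["const"] = 100 - counts.loc["var"]
        counts.loc["flat"] = counts.sum(axis=0)  # 50% everywhere
        r, p, sig = pearson_matrix(TaxonTable(counts))
        assert np.isnan(r.loc["flat", "var"])
        assert np.isnan(p.loc["flat", "var"])

    def test_matches_textbook_formula(self, rng):
        counts = pd.DataFrame(
            rng.integers(1, 100, size=(5, 20)),
            index=[f"t{i}" for i in range(5)],
            columns=[f"s{i}" for i in range(20)],
        )
        t = TaxonTable(counts)
        r, p, sig = pearson_matrix(t)
        ra = t.relabund
        for a in t.taxa:
            for b in t.taxa:
                rr, pp = sstats.pearsonr(ra.loc[a], ra.loc[b])
                assert r.loc[a, b] == pytest.approx(rr, abs=1e-12)
                if a != b:
                    assert p.loc[a, b] == pytest.approx(pp, abs=1e-9)
        assert (sig == (p < 0.05)).all().all()

    def test_display_order_is_permutation(self, rng):
        counts = pd.DataFrame(
            rng.integers(1, 100, size=(6, 12)),
            index=[f"t{i}" for i in range(6)],
            columns=[f"s{i}" for i in range(12)],
        )
        r, _, _ = pearson_matrix(TaxonTable(counts))
        order = correlation_display_order(r)
        assert sorted(order) == sorted(r.index)


class TestWelch:
    def test_identical_groups(self):
        t, df, p = welch_t([1, 2, 3], [1, 2, 3])
        assert t == 0.0 and p == pytest.approx(1.0)

    def test_separated_groups(self):
        t, df, p = welch_t([1, 2, 3], [1001.0, 1002.0, 1003.0])
        assert p < 0.001

    def test_matches_direct_formula(self, rng):
        x = rng.normal(0, 1, 9)
        y = rng.normal(0.5, 2, 14)
        t, df, p = welch_t(x, y)
        vx, vy = x.var(ddof=1) / len(x), y.var(ddof=1) / len(y)
        t_direct = (x.mean() - y.mean()) / np.sqrt(vx + vy)
        df_direct = (vx + vy) ** 2 / (vx**2 / (len(x) - 1) + vy**2 / (len(y) - 1))
        p_direct = 2 * sstats.t.sf(abs(t_direct), df_direct)
        assert t == pytest.approx(t_direct)
        assert df == pytest.approx(df_direct)
        assert p == pytest.approx(p_direct)

    def test_insufficient_n(self):
        with pytest.raises(ValueError):
            welch_t([1.0], [1.0, 2.0])


class TestDunnett:
    def test_two_groups_reduces_to_pooled_t(self, rng):
        x = rng.normal(0, 1, 8)
        y = rng.normal(0.8, 1, 8)
        (adj,) = dunnett([x, y], control_index=0, mc_draws=400_000, seed=1)
        t, p = sstats.ttest_ind(y, x, equal_var=True)[:2]
        assert adj == pytest.approx(p, abs=0.005)

    def test_no_effect_gives_p_near_one(self):
        g = [1.0, 2.0, 3.0, 4.0]
        ps = dunnett([g, list(g), list(g)], mc_draws=50_000, seed=2)
        assert (ps > 0.99).all()

    def test_matches_scipy_reference(self, rng):
        ctrl = rng.normal(0, 1, 8)
        g1 = rng.normal(1.0, 1, 6)
        g2 = rng.normal(0.3, 1, 7)
        mine = dunnett([ctrl, g1, g2], control_index=0, mc_draws=400_000, seed=5)
        ref = sstats.dunnett(g1, g2, control=ctrl)
        np.testing.assert_allclose(mine, ref.pvalue, atol=0.01)

    def test_adjusted_at_least_unadjusted(self, rng):
        groups = [rng.normal(m, 1, 6) for m in (0, 0.5, 1.0, 1.5)]
        adj = dunnett(groups, mc_draws=100_000, seed=3)
        # per-comparison pooled-t p-values
        ctrl = groups[0]
        ns = [len(g) for g in groups]
        df = sum(ns) - len(groups)
        s2 = sum(((g - g.mean()) ** 2).sum() for g in groups) / df
        for a, g in zip(adj, groups[1:]):
            t = (g.mean() - ctrl.mean()) / np.sqrt(s2 * (1 / len(g) + 1 / len(ctrl)))
            p_un = 2 * sstats.t.sf(abs(t), df)
            assert a >= p_un - 0.005

    def test_deterministic_given_seed(self, rng):
        groups = [rng.normal(m, 1, 5) for m in (0, 1)]
        a = dunnett(groups, mc_draws=20_000, seed=9)
        b = dunnett(groups, mc_draws=20_000, seed=9)
        np.testing.assert_array_equal(a, b)
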