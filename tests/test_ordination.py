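import itertools

import numpy as np
import pandas as pd
import pytest
from scipy.spatial.distance import pdist, squareform
from scipy.stats import rankdata, spearmanr

from rarebiome.data_model import (
    DistanceMatrix,
    OTUTable,
    TableError,
    TaxonomyTable,
    bray_curtis,
)
from rarebiome.ordination import (
    anosim,
    build_design,
    dbrda,
    dbrda_by_rank,
    matrix_correlation,
    nmds,
    prune_vif,
    rda,
    vpa,
    _pcoa_coords,
)


def _dm(values, ids=None, metric="test"):
    values = np.asarray(values, dtype=float)
    return DistanceMatrix(ids or [f"s{i}" for i in range(len(values))], values, metric)


# ---------------------------------------------------------------------------
# NMDS


class TestNMDS:
    def test_equilateral_triangle_embeds_perfectly(self):
        d = np.full((3, 3), 1.0)
        np.fill_diagonal(d, 0.0)
        res = nmds(_dm(d), restarts=5, seed=0)
        assert res.stress < 1e-3

    def test_planar_configuration_recovered(self):
        rng = np.random.default_rng(2)
        X = rng.normal(size=(12, 2))
        res = nmds(_dm(squareform(pdist(X))), restarts=8, seed=1)
        assert res.stress < 0.01
        assert res.converged

    def test_best_of_restarts_no_worse_than_single(self):
        rng = np.random.default_rng(5)
        X = rng.normal(size=(10, 4))
        dm = _dm(squareform(pdist(X)))
        multi = nmds(dm, restarts=10, seed=3)
        single = nmds(dm, restarts=1, seed=3)
        assert multi.stress <= single.stress + 1e-12


# ---------------------------------------------------------------------------
# ANOSIM


def _anosim_oracle(dm: DistanceMatrix, labels: list) -> tuple:
    """Brute-force ANOSIM on <= 8 samples: direct R formula and exhaustive
    enumeration of distinct labelings (observed labeling contributes the
    add-one)."""
    n = len(labels)
    ranks = rankdata(dm.condensed())
    iu, ju = np.triu_indices(n, k=1)

    def r_stat(lab):
        lab = np.asarray(lab, dtype=object)
        within = lab[iu] == lab[ju]
        return (ranks[~within].mean() - ranks[within].mean()) / (n * (n - 1) / 4.0)

    obs = r_stat(labels)
    seen, n_ge, total, skipped = set(), 0, 0, False
    for perm in itertools.permutations(labels):
        if perm in seen:
            continue
        seen.add(perm)
        total += 1
        if not skipped and list(perm) == list(labels):
            skipped = True
            continue
        n_ge += r_stat(perm) >= obs - 1e-12
    return obs, (n_ge + 1) / (total + 1)


class TestAnosim:
    def test_complete_separation_r_one(self):
        d = np.array(
            [
                [0.0, 0.1, 0.9, 0.8],
                [0.1, 0.0, 0.85, 0.95],
                [0.9, 0.85, 0.0, 0.2],
                [0.8, 0.95, 0.2, 0.0],
            ]
        )
        res = anosim(_dm(d), pd.Series(["a", "a", "b", "b"], index=[f"s{i}" for i in range(4)]))
        assert res.R == pytest.approx(1.0)

    def test_all_equal_distances_r_zero(self):
        d = np.full((6, 6), 0.5)
        np.fill_diagonal(d, 0.0)
        grouping = pd.Series(["a"] * 3 + ["b"] * 3, index=[f"s{i}" for i in range(6)])
        res = anosim(_dm(d), grouping)
        assert res.R == pytest.approx(0.0)

    def test_matches_exhaustive_oracle(self):
        rng = np.random.default_rng(8)
        X = rng.normal(size=(6, 5))
        dm = _dm(squareform(pdist(X)))
        labels = ["a", "a", "a", "b", "b", "b"]
        grouping = pd.Series(labels, index=dm.ids)
        res = anosim(dm, grouping)
        r_ref, p_ref = _anosim_oracle(dm, labels)
        assert res.exhaustive
        assert res.R == pytest.approx(r_ref)
        assert res.p == pytest.approx(p_ref)

    def test_matches_skbio_r(self, small_community):
        skbio_anosim = pytest.importorskip("skbio.stats.distance").anosim
        from skbio import DistanceMatrix as SkbioDM

        table, _, meta, _ = small_community
        dm = bray_curtis(table)
        ours = anosim(dm, meta.habitat, n_perm=99, seed=0)
        ref = skbio_anosim(SkbioDM(dm.values, ids=dm.ids), meta.data, column="habitat",
                           permutations=0)
        assert ours.R == pytest.approx(ref["test statistic"], abs=1e-12)

    def test_monotone_transform_invariance(self):
        rng = np.random.default_rng(3)
        X = rng.normal(size=(8, 4))
        d = squareform(pdist(X))
        grouping = pd.Series(["a"] * 4 + ["b"] * 4, index=[f"s{i}" for i in range(8)])
        r1 = anosim(_dm(d), grouping, n_perm=9, seed=0).R
        r2 = anosim(_dm(np.sqrt(d)), grouping, n_perm=9, seed=0).R
        assert r1 == pytest.approx(r2)

    def test_singleton_group_rejected(self):
        d = np.full((3, 3), 0.5)
        np.fill_diagonal(d, 0.0)
        with pytest.raises(TableError, match="fewer than 2"):
            anosim(_dm(d), pd.Series(["a", "a", "b"], index=["s0", "s1", "s2"]))


# ---------------------------------------------------------------------------
# Mantel-style correlation


class TestMatrixCorrelation:
    def test_self_correlation_one(self):
        rng = np.random.default_rng(1)
        d = squareform(pdist(rng.normal(size=(6, 3))))
        res = matrix_correlation(_dm(d), _dm(d))
        assert res.rho == pytest.approx(1.0)

    def test_rank_reversal_minus_one(self):
        rng = np.random.default_rng(1)
        d = squareform(pdist(rng.normal(size=(6, 3))))
        rev = d.max() + d.min() - d
        np.fill_diagonal(rev, 0.0)
        res = matrix_correlation(_dm(d), _dm(rev))
        assert res.rho == pytest.approx(-1.0)

    def test_p_matches_exhaustive_permutation_oracle(self):
        rng = np.random.default_rng(4)
        d1 = squareform(pdist(rng.normal(size=(4, 3))))
        d2 = squareform(pdist(rng.normal(size=(4, 3))))
        res = matrix_correlation(_dm(d1), _dm(d2))
        assert res.exhaustive and res.n_perm == 24
        x = squareform(d1, checks=False)
        obs = abs(spearmanr(x, squareform(d2, checks=False)).statistic)
        n_ge, skipped = 0, False
        for perm in itertools.permutations(range(4)):
            if not skipped and perm == (0, 1, 2, 3):
                skipped = True
                continue
            y = squareform(d2[np.ix_(perm, perm)], checks=False)
            n_ge += abs(spearmanr(x, y).statistic) >= obs - 1e-12
        assert res.p == pytest.approx((n_ge + 1) / 25)

    def test_mismatched_ids_error(self):
        d = np.zeros((3, 3))
        with pytest.raises(TableError, match="ids"):
            matrix_correlation(_dm(d, ids=["a", "b", "c"]), _dm(d, ids=["a", "c", "b"]))


# ---------------------------------------------------------------------------
# RDA


class TestRDA:
    def test_single_response_equals_predictor(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=14)
        Y = pd.DataFrame({"y": x}, index=range(14))
        P = pd.DataFrame({"pH": x}, index=range(14))  # pH: no log transform
        res = rda(Y, P, n_perm=99, seed=0, forward_select=False)
        assert res.explained == pytest.approx(1.0)
        assert res.p == pytest.approx(0.01)

    def test_duplicated_predictor_dropped_by_vif(self):
        rng = np.random.default_rng(1)
        P = pd.DataFrame({"pH": rng.normal(7, 1, 12)})
        P["pH_copy"] = P["pH"]
        X = build_design(P)
        pruned, dropped = prune_vif(X, cut=20)
        assert len(dropped) == 1
        assert pruned.shape[1] == 1

    def test_explained_matches_least_squares_oracle(self):
        # RDA explained variance == sum of per-column OLS fitted SS / total SS
        rng = np.random.default_rng(2)
        n = 15
        P = pd.DataFrame({"pH": rng.normal(7, 1, n), "TC": rng.lognormal(1, 0.4, n)})
        Y = pd.DataFrame(rng.normal(size=(n, 4)), index=P.index)
        res = rda(Y, P, n_perm=9, seed=0, forward_select=False)
        X = build_design(P).to_numpy()
        Xc = X - X.mean(axis=0)
        Yc = Y.to_numpy() - Y.to_numpy().mean(axis=0)
        ss_fit = ss_tot = 0.0
        for j in range(Yc.shape[1]):
            beta, *_ = np.linalg.lstsq(Xc, Yc[:, j], rcond=None)
            ss_fit += ((Xc @ beta) ** 2).sum()
            ss_tot += (Yc[:, j] ** 2).sum()
        assert res.explained == pytest.approx(ss_fit / ss_tot)

    def test_axis_proportions_sum_to_explained(self):
        rng = np.random.default_rng(3)
        n = 12
        P = pd.DataFrame({"pH": rng.normal(7, 1, n), "TC": rng.lognormal(1, 0.4, n)})
        Y = pd.DataFrame(rng.normal(size=(n, 5)))
        res = rda(Y, P, n_perm=9, seed=0, forward_select=False)
        assert res.axis_proportions.sum() == pytest.approx(res.explained)
        assert ((res.axis_proportions >= 0) & (res.axis_proportions <= 1)).all()

    def test_orthogonal_predictor_type_i_error_controlled(self):
        # null predictor: permutation p should be ~uniform; rejection rate at
        # alpha=0.05 over 100 replicates inside the binomial 95% band {0..10}
        rng = np.random.default_rng(4)
        rejections = 0
        n = 10
        for _ in range(100):
            Y = pd.DataFrame(rng.normal(size=(n, 3)))
            P = pd.DataFrame({"pH": rng.normal(size=n)})
            res = rda(Y, P, n_perm=99, seed=int(rng.integers(2**31 - 1)),
                      forward_select=False)
            rejections += res.p < 0.05
        assert rejections <= 10

    def test_forward_selection_keeps_true_driver(self):
        rng = np.random.default_rng(5)
        n = 16
        signal = rng.normal(size=n)
        P = pd.DataFrame(
            {"pH": signal, "TC": rng.lognormal(1, 0.3, n), "TN": rng.lognormal(0, 0.3, n)}
        )
        Y = pd.DataFrame(
            {f"y{j}": signal * rng.normal(1, 0.1) + rng.normal(0, 0.05, n) for j in range(4)}
        )
        res = rda(Y, P, n_perm=199, seed=1, forward_select=True)
        assert "pH" in res.selected


# ---------------------------------------------------------------------------
# VPA


class TestVPA:
    def _orthogonal_case(self):
        # three mutually orthogonal numeric blocks driving disjoint response
        # structure; n chosen so the design stays far from saturation
        n = 48  # large enough that adjusted-R^2 penalties are small
        t = np.arange(n)
        # orthogonal two-level Walsh patterns, coded +-1 for the response
        e = np.where(t % 2 == 0, 1.0, -1.0)
        v = np.where((t // 2) % 2 == 0, 1.0, -1.0)
        s = np.where((t // 4) % 2 == 0, 1.0, -1.0)
        rng = np.random.default_rng(0)
        Y = pd.DataFrame(
            {
                "y1": 1.0 * e + rng.normal(0, 0.2, n),
                "y2": 0.8 * v + rng.normal(0, 0.2, n),
                "y3": 0.6 * s + rng.normal(0, 0.2, n),
            }
        )
        # two-level predictors stay orthogonal after log1p + standardization
        blocks = {
            "E": pd.DataFrame({"TC": e + 2.0}),
            "V": pd.DataFrame({"TN": v + 2.0}),
            "S": pd.DataFrame({"TS": s + 2.0}),
        }
        return Y, blocks

    def test_inclusion_exclusion_identity(self):
        Y, blocks = self._orthogonal_case()
        res = vpa(Y, blocks)
        total = sum(res.fractions.values()) + res.residual
        assert abs(total - 1.0) < 1e-10
        full = res.adj_r2[frozenset(("E", "V", "S"))]
        assert sum(res.fractions.values()) == pytest.approx(full, abs=1e-10)

    def test_orthogonal_blocks_have_no_shared_fractions(self):
        Y, blocks = self._orthogonal_case()
        res = vpa(Y, blocks)
        for name, frac in res.fractions.items():
            if name.startswith("shared"):
                assert abs(frac) < 0.05
        assert res.fractions["pure_E"] == pytest.approx(
            res.adj_r2[frozenset(["E"])], abs=0.05
        )

    def test_duplicated_block_shifts_to_shared(self):
        Y, blocks = self._orthogonal_case()
        blocks = dict(blocks)
        blocks["E"] = blocks["V"].rename(columns={"TN": "TC"})
        res = vpa(Y, blocks)
        assert abs(res.fractions["pure_E"]) < 0.05
        assert abs(res.fractions["pure_V"]) < 0.05
        assert res.fractions["shared_E&V"] > 0.1


# ---------------------------------------------------------------------------
# PCoA / dbRDA


class TestDbrda:
    def test_pcoa_matches_skbio(self):
        skbio_pcoa = pytest.importorskip("skbio.stats.ordination").pcoa
        rng = np.random.default_rng(6)
        d = squareform(pdist(rng.normal(size=(8, 4))))
        coords, eig = _pcoa_coords(d)
        ref = skbio_pcoa(d, number_of_dimensions=coords.shape[1])
        assert np.allclose(np.sort(eig)[::-1][: len(eig)],
                           ref.eigvals.to_numpy()[: len(eig)], atol=1e-8)

    def test_euclidean_equivalence_with_rda(self):
        rng = np.random.default_rng(7)
        n = 10
        Y = pd.DataFrame(rng.normal(size=(n, 5)), index=[f"s{i}" for i in range(n)])
        P = pd.DataFrame(
            {"pH": rng.normal(7, 1, n), "TC": rng.lognormal(1, 0.4, n)}, index=Y.index
        )
        plain = rda(Y, P, n_perm=9, seed=0, forward_select=False)
        dm = DistanceMatrix(list(Y.index), squareform(pdist(Y.to_numpy())), "euclidean")
        db = dbrda(dm, P)
        assert db["explained"] == pytest.approx(plain.explained, abs=1e-8)

    def test_rank_otu_reproduces_unaggregated(self, small_community):
        table, tax, meta, _ = small_community
        P = meta.data[["pH", "TC"]]
        grad = dbrda_by_rank(table, tax, P, ranks=("otu",))
        direct = dbrda(bray_curtis(table), P)
        assert grad.loc["otu", "explained"] == pytest.approx(direct["explained"])

    def test_phylum_level_signal_non_decreasing_toward_phylum(self):
        # habitat signal planted purely at the phylum level; intermediate
        # ranks share the phylum partition so explained variation must be
        # non-decreasing from otu to phylum
        rng = np.random.default_rng(9)
        n_samples, n_otus = 12, 60
        phylum = np.array(["P1"] * 30 + ["P2"] * 30)
        habitat = np.array(["a"] * 6 + ["b"] * 6)
        base = rng.dirichlet(np.ones(n_otus))
        rows = []
        for h in habitat:
            w = base * np.where(phylum == "P1", 4.0 if h == "a" else 1.0, 1.0)
            rows.append(rng.multinomial(4000, w / w.sum()))
        table = OTUTable(
            pd.DataFrame(rows, index=[f"s{i}" for i in range(n_samples)],
                         columns=[f"o{i}" for i in range(n_otus)])
        )
        lineages = pd.DataFrame(
            {
                "kingdom": "k",
                "phylum": phylum,
                "class": [f"{p}_c" for p in phylum],
                "order": [f"{p}_o" for p in phylum],
                "family": [f"{p}_f" for p in phylum],
                "genus": [f"{p}_g" for p in phylum],
                "species": [f"sp{i}" for i in range(n_otus)],
            },
            index=table.otu_ids,
        )
        tax = TaxonomyTable(lineages)
        P = pd.DataFrame({"pH": np.where(habitat == "a", 6.5, 7.5)}, index=table.sample_ids)
        grad = dbrda_by_rank(table, tax, P)
        vals = grad["explained"].to_numpy()
        assert (np.diff(vals) >= -1e-9).all()
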