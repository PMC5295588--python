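"""Spearman machinery, classical MDS, clustering, neighbour and FDR analyses."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats
from scipy.cluster import hierarchy

from ncrna.dynamics import (
    CorrelationResult,
    corr_fdr_pairs,
    dendrogram_newick,
    dim1_time_fit,
    hcluster,
    mds_embed,
    neighbor_correlations,
    sample_distance_matrix,
    spearman,
    zscore_rows,
    _exact_two_sided_p,
    _spearman_null_tail,
)
from ncrna.io_formats import GeneModel, GenomeAnnotation, GenomicInterval

from .test_classification import gene, iv


class TestSpearman:
    def test_monotone_transform_invariance(self):
        x = np.arange(10.0)
        rho, _ = spearman(x, np.exp(x))
        assert rho == pytest.approx(1.0)
        rho_rev, _ = spearman(x, x[::-1])
        assert rho_rev == pytest.approx(-1.0)

    def test_tied_ranks_match_hand_computation(self):
        x, y = [1, 2, 2, 3], [1, 3, 2, 4]
        # average ranks: x -> 1, 2.5, 2.5, 4 ; y -> 1, 3, 2, 4
        rx, ry = np.array([1, 2.5, 2.5, 4]), np.array([1.0, 3, 2, 4])
        expected = np.corrcoef(rx, ry)[0, 1]
        rho, p = spearman(x, y)
        assert rho == pytest.approx(expected)
        assert 0 <= p <= 1

    def test_constant_vector_is_missing(self):
        rho, p = spearman([1, 1, 1, 1], [1, 2, 3, 4])
        assert np.isnan(rho) and np.isnan(p)

    def test_exact_null_matches_enumeration(self):
        n = 6
        perms = np.array(list(itertools.permutations(range(n))))
        x = np.arange(n)
        rhos = np.array([np.corrcoef(x, p)[0, 1] for p in perms])
        for q in (1.0, 0.9, 0.6, 0.2):
            exact = np.mean(np.abs(rhos) >= q - 1e-9)
            assert _exact_two_sided_p(q, n) == pytest.approx(exact, abs=1e-12)

    def test_null_table_is_a_distribution(self):
        abs_vals, cum = _spearman_null_tail(11)
        assert cum[-1] == pytest.approx(1.0)
        assert (np.diff(abs_vals) <= 1e-12).all()


class TestMds:
    def test_equilateral_configuration(self):
        D = np.full((3, 3), 2.0)
        np.fill_diagonal(D, 0.0)
        coords, _ = mds_embed(D)
        dists = {
            np.linalg.norm(coords[i] - coords[j])
            for i, j in itertools.combinations(range(3), 2)
        }
        assert max(dists) - min(dists) < 1e-9

    def test_duplicate_samples_coincide(self):
        D = np.array(
            [[0, 0, 1.0], [0, 0, 1.0], [1.0, 1.0, 0]]
        )
        coords, _ = mds_embed(D)
        assert np.linalg.norm(coords[0] - coords[1]) < 1e-9

    def test_euclidean_round_trip_to_1e9(self):
        rng = np.random.default_rng(42)
        pts = rng.normal(size=(13, 2))
        D = np.linalg.norm(pts[:, None] - pts[None, :], axis=-1)
        coords, _ = mds_embed(D)
        D2 = np.linalg.norm(coords[:, None] - coords[None, :], axis=-1)
        assert np.abs(D - D2).max() < 1e-9

    def test_sign_fixed_by_time_order(self):
        rng = np.random.default_rng(0)
        pts = np.linspace(0, 1, 8)[:, None] + rng.normal(scale=0.01, size=(8, 2))
        D = np.linalg.norm(pts[:, None] - pts[None, :], axis=-1)
        coords, _ = mds_embed(D, order_hint=np.arange(8))
        assert np.corrcoef(coords[:, 0], np.arange(8))[0, 1] > 0

    def test_fit_extremes(self):
        coords = np.column_stack([np.arange(5.0), np.zeros(5)])
        _, _, r2 = dim1_time_fit(coords, np.arange(5.0))
        assert r2 == pytest.approx(1.0)
        flat = np.column_stack([np.ones(5), np.zeros(5)])
        _, _, r2_flat = dim1_time_fit(flat, np.arange(5.0))
        assert r2_flat == pytest.approx(0.0, abs=1e-12)


class TestHcluster:
    def test_two_tight_groups_recovered_at_top_split(self):
        n = 6
        D = np.zeros((n, n))
        for i, j in itertools.combinations(range(n), 2):
            same = (i < 3) == (j < 3)
            D[i, j] = D[j, i] = 0.1 if same else 5.0
        Z, order = hcluster(D, labels=[f"x{i}" for i in range(n)])
        clusters = hierarchy.fcluster(Z, t=2, criterion="maxclust")
        assert len(set(clusters[:3])) == 1 and len(set(clusters[3:])) == 1
        assert set(clusters) == {1, 2}

    def test_two_leaves_merge_at_their_distance(self):
        D = np.array([[0.0, 0.7], [0.7, 0.0]])
        Z, order = hcluster(D)
        assert Z.shape == (1, 4) and Z[0, 2] == pytest.approx(0.7)

    def test_complete_linkage_heights_monotone(self):
        rng = np.random.default_rng(3)
        pts = rng.normal(size=(12, 3))
        D = np.linalg.norm(pts[:, None] - pts[None, :], axis=-1)
        Z, _ = hcluster(D)
        assert (np.diff(Z[:, 2]) >= -1e-12).all()

    def test_newick_has_all_leaves(self):
        D = np.array([[0, 1, 2.0], [1, 0, 2.0], [2.0, 2.0, 0]])
        Z, _ = hcluster(D, labels=["a", "b", "c"])
        nwk = dendrogram_newick(Z, ["a", "b", "c"])
        assert nwk.endswith(";") and all(x in nwk for x in "abc")


def _profiles(rows, columns=10, seed=0):
    rng = np.random.default_rng(seed)
    return pd.DataFrame(
        rng.uniform(0, 50, size=(len(rows), columns)),
        index=rows,
        columns=[f"t{j}" for j in range(columns)],
    )


class TestNeighborCorrelations:
    def _annotation(self, n_genes=40, spacing=1500, length=600):
        genes = [
            gene(f"g{i}", iv(i * spacing, i * spacing + length,
                             "+" if i % 2 else "-"))
            for i in range(n_genes)
        ]
        return GenomeAnnotation(genes, {"chr1": n_genes * spacing + 1000})

    def test_shared_profile_gives_unit_correlation(self):
        ann = self._annotation(4)
        lnc = gene("L1", iv(700, 1100))
        profiles = _profiles([f"g{i}" for i in range(4)] + ["L1"])
        profiles.loc["L1"] = profiles.loc["g0"]
        out = neighbor_correlations([lnc], ann, profiles, n_random=50, seed=1)
        pair = out["pairs"]
        sc_with_g0 = pair[pair.neighbor == "g0"]["sc"].iloc[0]
        assert sc_with_g0 == pytest.approx(1.0)

    def test_independent_profiles_center_near_zero(self):
        ann = self._annotation(60)
        lncs = []
        for i in range(59):
            start = i * 1500 + 700
            lncs.append(gene(f"L{i}", iv(start, start + 300)))
        profiles = _profiles(
            [f"g{i}" for i in range(60)] + [l.gene_id for l in lncs], seed=5
        )
        out = neighbor_correlations(lncs, ann, profiles, n_random=300, seed=2)
        med = out["pairs"]["sc"].median()
        assert abs(med) < 0.1

    def test_planted_coupling_raises_converging_category(self):
        ann = self._annotation(40)
        rng = np.random.default_rng(9)
        lncs, planted = [], []
        for i in range(39):
            start = i * 1500 + 700
            lncs.append(gene(f"L{i}", iv(start, start + 300, "+")))
        profiles = _profiles(
            [f"g{i}" for i in range(40)] + [l.gene_id for l in lncs], seed=9
        )
        out0 = neighbor_correlations(lncs, ann, profiles, n_random=200, seed=3)
        # couple each lncRNA to its 5' co-oriented (converging) neighbour
        for _, row in out0["pairs"].iterrows():
            if row.category == "converging" and rng.random() < 0.5:
                profiles.loc[row.lncrna] = profiles.loc[row.neighbor] + rng.normal(
                    scale=0.5, size=profiles.shape[1]
                )
                planted.append(row.lncrna)
        assert planted
        out = neighbor_correlations(lncs, ann, profiles, n_random=200, seed=3)
        summary = out["summary"]
        assert summary["converging"]["median_sc"] > summary["diverging"]["median_sc"]

    def test_contig_edge_reports_missing_side(self):
        ann = self._annotation(3)
        lnc = gene("L0", iv(50, 250, "+"))  # nothing upstream of position 50
        profiles = _profiles(["g0", "g1", "g2", "L0"])
        out = neighbor_correlations([lnc], ann, profiles, n_random=10, seed=0)
        five_p = out["pairs"].query("side == '5p'")
        assert five_p["neighbor"].isna().all()


class TestCorrFdrPairs:
    def test_identical_row_reported_with_unit_sc(self):
        rng = np.random.default_rng(4)
        mrna = pd.DataFrame(
            rng.uniform(size=(20, 13)), index=[f"m{i}" for i in range(20)]
        )
        lnc = pd.DataFrame(
            rng.uniform(size=(5, 13)), index=[f"l{i}" for i in range(5)]
        )
        lnc.iloc[0] = mrna.iloc[3]
        lnc.columns = mrna.columns
        out = corr_fdr_pairs(lnc, mrna, fdr=0.01, min_abs_sc=0.85)
        pairs = {r.pair for r in out["pairs"]}
        assert ("l0", "m3") in pairs
        sc = next(r.sc for r in out["pairs"] if r.pair == ("l0", "m3"))
        assert sc == pytest.approx(1.0)

    def test_zscored_rows_standardised(self):
        df = pd.DataFrame([[1.0, 2, 3], [5, 5, 5]], index=["a", "b"])
        z, constant = zscore_rows(df)
        assert z.loc["a"].mean() == pytest.approx(0.0)
        assert z.loc["a"].std(ddof=1) == pytest.approx(1.0)
        assert (z.loc["b"] == 0).all() and bool(constant["b"])

    def test_bh_never_rejects_more_than_raw_threshold(self):
        rng = np.random.default_rng(8)
        lnc = pd.DataFrame(rng.normal(size=(30, 13)))
        mrna = pd.DataFrame(rng.normal(size=(40, 13)))
        # plant signal so some pairs are significant
        for k in range(5):
            mrna.iloc[k] = lnc.iloc[k] + rng.normal(scale=0.05, size=13)
        out = corr_fdr_pairs(lnc, mrna, fdr=0.01, min_abs_sc=0.0)
        praw = out["p_raw"].to_numpy()
        padj = out["p_adjusted"].to_numpy()
        n_bh = int(out["significant"].to_numpy().sum())
        n_raw = int(np.nansum(praw < 0.01))
        assert 0 < n_bh <= n_raw
        # BH adjustment is monotone: adjusted p never below raw p
        ok = np.isfinite(praw) & np.isfinite(padj)
        assert (padj[ok] >= praw[ok] - 1e-15).all()

    def test_mismatched_columns_rejected(self):
        a = pd.DataFrame(np.zeros((2, 3)), columns=["x", "y", "z"])
        b = pd.DataFrame(np.zeros((2, 3)), columns=["x", "y", "w"])
        with pytest.raises(ValueError, match="share sample columns"):
            corr_fdr_pairs(a, b)
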