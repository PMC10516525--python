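import numpy as np
import pytest
import scipy.sparse as sp
import scipy.stats

import cicada
from cicada.io_formats import CellExpressionMatrix
from cicada.separation import (
    SeparationParams,
    cluster_doublets,
    differential_expression,
    merge_and_filter,
    per_cluster_de,
)
from cicada.simulate import SimulationConfig, simulate_singlecell
from conftest import make_counts


def criterion_fixture(seed=1, n=200):
    """Planted doublets: n biological (20 interaction genes at 4x), n
    artifactual, n synthetic built from unique singleton pairs."""
    cfg = SimulationConfig(seed=seed, n_bio_doublets=n, n_art_doublets=n, cells_per_type=n)
    expr, _, truth = simulate_singlecell(cfg)
    lab = truth.labels
    sel = lambda q: lab.query(q)["cell_id"].to_numpy(object)
    sds = cicada.make_synthetic_doublets(
        expr,
        sel("kind=='singlet' and cell_type=='typeA'"),
        sel("kind=='singlet' and cell_type=='typeB'"),
        mode="unique",
        seed=seed,
    )
    idx = {c: i for i, c in enumerate(expr.cell_ids)}
    het_ids = np.concatenate([sel("kind=='bio_doublet'"), sel("kind=='art_doublet'")])
    het = expr.subset(cell_mask=np.array([idx[c] for c in het_ids]))
    merged, origin = merge_and_filter(het, sds)
    kind = lab.set_index("cell_id")["kind"].reindex(merged.cell_ids).fillna("synthetic")
    return merged, origin, kind, truth, sds


class TestMergeAndFilter:
    def test_gene_below_half_presence_dropped_per_object(self):
        rng = np.random.default_rng(0)
        x = rng.integers(1, 5, size=(6, 10))
        x[0, :6] = 0  # present in 40% of cells of this object
        a = CellExpressionMatrix(
            sp.csc_matrix(x),
            np.array([f"g{i}" for i in range(6)], dtype=object),
            np.array([f"a{j}" for j in range(10)], dtype=object),
        )
        b = make_counts(6, 10, seed=1, max_count=5)
        b.counts = sp.csc_matrix(np.abs(np.asarray(b.counts.todense())) + 1)
        p = SeparationParams(min_genes_per_cell=1)
        merged, origin = merge_and_filter(a, b, p)
        assert "g0" not in set(merged.gene_ids)
        assert list(origin) == ["experimental"] * 10 + ["synthetic"] * 10

    def test_mito_ribo_removed_after_merge(self):
        x = np.ones((4, 8), dtype=int)
        genes = np.array(["MT-Co1", "Rps3", "Actb", "Cd8a"], dtype=object)
        a = CellExpressionMatrix(sp.csc_matrix(x), genes, np.array([f"a{j}" for j in range(8)], dtype=object))
        b = CellExpressionMatrix(sp.csc_matrix(x), genes, np.array([f"b{j}" for j in range(8)], dtype=object))
        merged, _ = merge_and_filter(a, b, SeparationParams(min_genes_per_cell=1))
        assert set(merged.gene_ids) == {"Actb", "Cd8a"}

    def test_matches_index_algebra(self):
        """Merge equals brute-force set operations on indices."""
        rng = np.random.default_rng(2)

        def dense_counts(prefix, seed_shift):
            x = rng.integers(1, 5, size=(40, 30))
            x[rng.random(x.shape) < 0.35] = 0
            return CellExpressionMatrix(
                sp.csc_matrix(x),
                np.array([f"g{i}" for i in range(40)], dtype=object),
                np.array([f"{prefix}{j}" for j in range(30)], dtype=object),
            )

        a = dense_counts("c", 0)
        b = dense_counts("s", 1)
        p = SeparationParams(min_genes_per_cell=5)
        merged, origin = merge_and_filter(a, b, p)

        def brute(m):
            x = np.asarray(m.counts.todense())
            keep_c = (x > 0).sum(0) >= 5
            x = x[:, keep_c]
            keep_g = (x > 0).sum(1) / x.shape[1] >= 0.5
            return set(np.asarray(m.gene_ids)[keep_g]), list(np.asarray(m.cell_ids)[keep_c])

        ga, ca = brute(a)
        gb, cb = brute(b)
        assert set(merged.gene_ids) == (ga & gb)
        assert list(merged.cell_ids) == ca + cb

    def test_empty_intersection_raises(self):
        a = make_counts(5, 10, seed=4)
        b = make_counts(5, 10, seed=5)
        b.gene_ids = np.array([f"other{i}" for i in range(5)], dtype=object)
        with pytest.raises(ValueError, match="intersection"):
            merge_and_filter(a, b, SeparationParams(min_genes_per_cell=1))


class TestClusterDoublets:
    def test_planted_biological_doublets_recovered(self):
        """Biological doublets (interaction signature) separate from
        artifactual + synthetic ones."""
        merged, origin, kind, _, _ = criterion_fixture(seed=1)
        res = cluster_doublets(merged, origin)
        t = res.table.copy()
        t["kind"] = kind.values
        bio_rate = (t.loc[t["kind"] == "bio_doublet", "classification"] == "biological").mean()
        art_rate = (t.loc[t["kind"] == "art_doublet", "classification"] == "biological").mean()
        assert bio_rate >= 0.95
        assert art_rate <= 0.05

    def test_classification_partition_and_purity(self):
        merged, origin, _, _, _ = criterion_fixture(seed=2)
        res = cluster_doublets(merged, origin)
        t = res.table
        assert set(t["classification"]) <= {"biological", "artifactual", "synthetic"}
        assert (t.loc[t["origin"] == "synthetic", "classification"] == "synthetic").all()
        # biological <=> cluster has zero synthetic members
        for c, grp in t.groupby("cluster"):
            has_synth = (grp["origin"] == "synthetic").any()
            exp = grp[grp["origin"] == "experimental"]
            expected = "artifactual" if has_synth else "biological"
            assert (exp["classification"] == expected).all()

    def test_identical_cells_form_single_mixed_cluster(self):
        x = np.ones((50, 20), dtype=int) * 3
        m = CellExpressionMatrix(
            sp.csc_matrix(x),
            np.array([f"g{i}" for i in range(50)], dtype=object),
            np.array([f"c{j}" for j in range(20)], dtype=object),
        )
        origin = np.array(["experimental"] * 10 + ["synthetic"] * 10, dtype=object)
        with pytest.warns(UserWarning):  # n_pcs reduced
            res = cluster_doublets(m, origin, SeparationParams(min_genes_per_cell=1))
        assert res.table["cluster"].nunique() == 1
        assert not (res.table["classification"] == "biological").any()

    def test_higher_resolution_keeps_biological_calls(self):
        """Raising the clustering resolution splits clusters but does not
        merge synthetic cells into the biological ones."""
        merged, origin, kind, _, _ = criterion_fixture(seed=3)
        lo = cluster_doublets(merged, origin, SeparationParams(cluster_resolution=0.25))
        hi = cluster_doublets(merged, origin, SeparationParams(cluster_resolution=0.5))
        assert hi.table["cluster"].nunique() >= lo.table["cluster"].nunique()
        t = hi.table.copy()
        t["kind"] = kind.values
        bio_rate = (t.loc[t["kind"] == "bio_doublet", "classification"] == "biological").mean()
        assert bio_rate >= 0.95


class TestDifferentialExpression:
    def test_planted_genes_recovered(self):
        merged, origin, kind, truth, sds = criterion_fixture(seed=4)
        res = cluster_doublets(merged, origin)
        bio = res.biological_ids()
        syn = merged.cell_ids[np.asarray(origin) == "synthetic"]
        de = differential_expression(merged, bio, syn, ("biological", "synthetic"))
        sig = set(de.significant(0.05)["gene"])
        planted = set(truth.interaction_genes)
        assert len(planted & sig) / len(planted) >= 0.90
        # planted genes are upregulated in the biological group
        up = de.table.set_index("gene").loc[sorted(planted & sig), "log2FC"]
        assert (up > 0).all()

    def test_null_pvalues_uniform(self):
        """Label permutation of one population gives ~uniform adjusted p."""
        rng = np.random.default_rng(0)
        x = rng.negative_binomial(2, 2 / 7, size=(500, 200))
        m = CellExpressionMatrix(
            sp.csc_matrix(x),
            np.array([f"g{i}" for i in range(500)], dtype=object),
            np.array([f"c{j}" for j in range(200)], dtype=object),
        )
        perm = rng.permutation(200)
        de = differential_expression(m, m.cell_ids[perm[:100]], m.cell_ids[perm[100:]])
        frac_sig = (de.table["p_value"] < 0.05).mean()
        assert frac_sig <= 0.07
        ks = scipy.stats.kstest(de.table["p_value"], "uniform")
        assert ks.pvalue > 0.01

    def test_silent_gene_neutral(self):
        x = np.ones((3, 12), dtype=int)
        x[0] = 0  # expressed in neither group
        m = CellExpressionMatrix(
            sp.csc_matrix(x),
            np.array(["silent", "gb", "gc"], dtype=object),
            np.array([f"c{j}" for j in range(12)], dtype=object),
        )
        de = differential_expression(m, m.cell_ids[:6], m.cell_ids[6:])
        row = de.table.set_index("gene").loc["silent"]
        assert row["log2FC"] == 0 and row["p_value"] == 1

    def test_adjusted_p_dominates_raw(self):
        merged, origin, _, _, _ = criterion_fixture(seed=5, n=60)
        g1 = merged.cell_ids[:50]
        g2 = merged.cell_ids[-50:]
        de = differential_expression(merged, g1, g2)
        assert (de.table["adjusted_p"] >= de.table["p_value"] - 1e-12).all()
        assert de.table["adjusted_p"].between(0, 1).all()

    def test_tiny_group_warns(self):
        m = make_counts(10, 10, seed=6)
        m.counts = sp.csc_matrix(np.asarray(m.counts.todense()) + 1)
        with pytest.warns(UserWarning, match="unreliable"):
            differential_expression(m, m.cell_ids[:2], m.cell_ids[2:])


def test_per_cluster_de_runs_on_mixed_clusters():
    merged, origin, _, _, _ = criterion_fixture(seed=6, n=60)
    res = cluster_doublets(merged, origin)
    tables = per_cluster_de(merged, res)
    for c, de in tables.items():
        sub = res.table[res.table["cluster"] == c]
        assert (sub["origin"] == "synthetic").any()
        assert len(de.table) > 0
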