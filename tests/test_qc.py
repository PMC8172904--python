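"""QC metrics, threshold filtering, normalisation, and the four-criteria
multiplet screen."""

import warnings

import numpy as np
import pandas as pd
import pytest

import lineatlas as la
from lineatlas import qc, synthetic
from lineatlas import trajectory as tj


class TestBarcodeQC:
    def test_hand_computed_metrics(self, toy_counts):
        adata = toy_counts([[3, 0, 1]], mito=[False, False, True])
        t = qc.compute_barcode_qc(adata)
        assert t.loc["c0", "nFeature_RNA"] == 2
        assert t.loc["c0", "nCount_RNA"] == 4
        assert t.loc["c0", "percent_mt"] == 25.0

    def test_all_zero_barcode(self, toy_counts):
        adata = toy_counts([[0, 0, 0], [1, 1, 0]],
                           mito=[False, False, True])
        t = qc.compute_barcode_qc(adata)
        assert t.loc["c0"].tolist() == [0, 0, 0.0]

    def test_no_mito_genes_means_zero_percent(self, toy_counts):
        """References without mitochondrial transcripts give percent_mt = 0
        for every barcode."""
        adata = toy_counts([[5, 2], [1, 9]], mito=[False, False])
        assert (qc.compute_barcode_qc(adata)["percent_mt"] == 0).all()


class TestFilterBarcodes:
    def _qc(self, nf, nc, mt):
        return pd.DataFrame({"nFeature_RNA": nf, "nCount_RNA": nc,
                             "percent_mt": mt},
                            index=[f"b{i}" for i in range(len(nf))])

    def test_strict_below_threshold_removes(self):
        t = self._qc([499], [5000], [1.0])
        retained, reasons = qc.filter_barcodes(t)
        assert len(retained) == 0
        assert reasons.loc["b0", "low_nFeature"]

    def test_boundary_values_retained(self):
        t = self._qc([500], [1000], [5.0])
        retained, _ = qc.filter_barcodes(t)
        assert list(retained) == ["b0"]

    def test_per_dataset_mito_override(self):
        t = self._qc([600], [2000], [7.0])
        assert len(qc.filter_barcodes(t)[0]) == 0
        thr = qc.QCThresholds(max_percent_mt=10.0)
        assert list(qc.filter_barcodes(t, thr)[0]) == ["b0"]

    def test_idempotent(self, default_sim):
        adata, _ = default_sim
        t = qc.compute_barcode_qc(adata)
        r1, _ = qc.filter_barcodes(t)
        r2, _ = qc.filter_barcodes(t.loc[r1])
        assert list(r1) == list(r2)


class TestNormalizeAndScale:
    def test_zero_count_gene_maps_to_zero(self, toy_counts):
        adata = toy_counts([[0, 10], [5, 5]])
        out = qc.normalize_and_scale(adata)
        assert out.layers["lognorm"][0, 0] == 0.0

    def test_constant_gene_scales_to_zero(self, toy_counts):
        adata = toy_counts([[2, 2], [2, 2], [2, 2]])
        out = qc.normalize_and_scale(adata)
        assert np.allclose(out.layers["scaled"], 0.0)

    def test_hand_computed_z_scores(self, toy_counts):
        X = np.array([[1, 0], [2, 2], [3, 1]])
        adata = toy_counts(X)
        out = qc.normalize_and_scale(adata)
        lognorm = np.log1p(1e4 * X / X.sum(axis=1, keepdims=True))
        z = (lognorm - lognorm.mean(0)) / lognorm.std(0)
        np.testing.assert_allclose(out.layers["lognorm"], lognorm)
        np.testing.assert_allclose(out.layers["scaled"], z, atol=1e-12)

    def test_zero_depth_barcode_rejected(self, toy_counts):
        adata = toy_counts([[0, 0], [1, 2]])
        with pytest.raises(ValueError, match="zero counts"):
            qc.normalize_and_scale(adata)


class TestClusterProfiles:
    def test_singleton_cluster_equals_cell(self, toy_counts):
        adata = qc.normalize_and_scale(toy_counts([[1, 2], [5, 1]]))
        prof = qc.cluster_average_expression(
            adata, pd.Series(["a", "b"], index=adata.obs_names))
        np.testing.assert_allclose(prof.mean_expr.loc["a"],
                                   adata.layers["lognorm"][0])

    def test_two_cell_average(self):
        expr = pd.DataFrame([[1.0, 3.0], [3.0, 1.0]], index=["c0", "c1"],
                            columns=["g0", "g1"])
        import anndata as ad

        adata = ad.AnnData(X=np.ones((2, 2)),
                           obs=pd.DataFrame(index=expr.index),
                           var=pd.DataFrame(
                               {"is_mito": [False, False]},
                               index=expr.columns))
        adata.layers["lognorm"] = expr.to_numpy()
        prof = qc.cluster_average_expression(
            adata, pd.Series(["x", "x"], index=expr.index))
        np.testing.assert_allclose(prof.mean_expr.loc["x"], [2.0, 2.0])


class TestHypotheticalDoublet:
    def _profiles(self, rows):
        genes = [f"g{i}" for i in range(len(rows[0]))]
        expr = pd.DataFrame(rows, index=list("ABC")[: len(rows)],
                            columns=genes)
        n = pd.Series(1, index=expr.index)
        return qc.ClusterProfiles(expr, n, n.astype(float), n.astype(float))

    def test_exact_mixture_has_r_one(self):
        rng = np.random.default_rng(0)
        a = rng.uniform(0, 3, 60)
        b = rng.uniform(0, 3, 60)
        prof = self._profiles([a, b, (a + b) / 2])
        assert qc.hypothetical_doublet_test(prof, "C", ("A", "B")) == \
            pytest.approx(1.0)

    def test_orthogonal_target_has_r_zero(self):
        # centered target orthogonal to the centered hypothetical profile
        h = np.array([1.0, -1.0, 1.0, -1.0] * 15)
        t = np.array([1.0, 1.0, -1.0, -1.0] * 15)
        prof = self._profiles([2 * h, np.zeros(60), t])
        assert qc.hypothetical_doublet_test(prof, "C", ("A", "B")) == \
            pytest.approx(0.0, abs=1e-12)

    def test_target_in_pair_rejected(self):
        prof = self._profiles([np.arange(60.0)] * 3)
        with pytest.raises(ValueError, match="target"):
            qc.hypothetical_doublet_test(prof, "A", ("A", "B"))

    def test_constant_profile_is_error(self):
        prof = self._profiles([np.ones(60), np.arange(60.0),
                               np.arange(60.0)])
        with pytest.raises(ValueError, match="constant"):
            qc.hypothetical_doublet_test(prof, "A", ("B", "C"))


class TestDoubletRate:
    def test_worked_arithmetic(self):
        assert qc.estimate_doublet_rate(0.5, 0.5, 0.1) == \
            pytest.approx(0.2)

    def test_zero_mixed_cluster(self):
        assert qc.estimate_doublet_rate(0.3, 0.4, 0.0) == 0.0

    def test_symmetry_and_homogeneity(self):
        r = qc.estimate_doublet_rate
        assert r(0.2, 0.5, 0.08) == pytest.approx(r(0.5, 0.2, 0.08))
        assert r(0.2, 0.5, 0.16) == pytest.approx(2 * r(0.2, 0.5, 0.08))

    def test_zero_denominator_rejected(self):
        with pytest.raises(ValueError):
            qc.estimate_doublet_rate(0.0, 0.4, 0.1)

    def test_implausible_rate_warns(self):
        with pytest.warns(UserWarning, match="implausible"):
            assert qc.estimate_doublet_rate(0.1, 0.1, 0.1) > 1


def _crafted_clusters(with_doublets=True, with_prolif=False, seed=0):
    """Hand-built count matrix with three clean cell types, optionally a
    sum-constructed doublet cluster and a depth-elevated proliferating
    cluster carrying its own unique markers."""
    rng = np.random.default_rng(seed)
    p, per, nm = 3000, 250, 100
    base = rng.lognormal(0.0, 1.2, p)   # sparse counts: most genes rare

    def draw(mean_vec, n):
        return rng.poisson(np.tile(mean_vec * 0.35, (n, 1)))

    means = {}
    for i, name in enumerate(["A", "B", "C"]):
        m = base.copy()
        m[i * nm:(i + 1) * nm] *= 4.0
        means[name] = m
    blocks, labels = [], []
    for name, m in means.items():
        blocks.append(draw(m, per))
        labels += [name] * per
    if with_doublets:
        xa, xb = draw(means["A"], per // 2), draw(means["B"], per // 2)
        blocks.append(xa + xb)
        labels += ["D"] * (per // 2)
    if with_prolif:
        m = means["C"].copy() * 2.0          # elevated depth
        m[300:310] = base[300:310] * 10.0    # its own unique markers
        blocks.append(draw(m, per // 2))
        labels += ["P"] * (per // 2)
    X = np.vstack(blocks)
    import anndata as ad

    adata = ad.AnnData(
        X=X.astype(np.int32),
        obs=pd.DataFrame(index=[f"c{i}" for i in range(X.shape[0])]),
        var=pd.DataFrame({"is_mito": [False] * p},
                         index=[f"g{j}" for j in range(p)]))
    adata.obs["study"] = "s1"
    adata = qc.normalize_and_scale(adata)
    return adata, pd.Series(labels, index=adata.obs_names)


class TestMultipletDetection:
    def test_doublet_cluster_flagged(self):
        adata, labels = _crafted_clusters(with_doublets=True)
        rep = qc.detect_multiplet_clusters(adata, labels)
        assert rep.flagged == ["D"]
        row = rep.table.loc["D"]
        assert row["criterion4_mixture_correlation"] >= 0.99
        assert set(row["criterion4_pair"]) == {"A", "B"}
        assert np.isfinite(row["estimated_doublet_rate"])

    def test_no_doublets_no_flags(self):
        adata, labels = _crafted_clusters(with_doublets=False)
        rep = qc.detect_multiplet_clusters(adata, labels)
        assert rep.flagged == []

    def test_proliferating_cluster_spared_by_unique_markers(self):
        """A depth-elevated cluster with its own distinct markers (the
        Mki67-like case) must not be flagged: criterion 2 fails."""
        adata, labels = _crafted_clusters(with_doublets=True,
                                          with_prolif=True)
        rep = qc.detect_multiplet_clusters(adata, labels)
        assert "P" not in rep.flagged
        assert not rep.table.loc["P", "criterion2_no_exclusive_markers"]
        assert rep.table.loc["P", "criterion1_elevated_depth"]
        assert rep.flagged == ["D"]

    def test_fewer_than_three_clusters_rejected(self):
        adata, labels = _crafted_clusters(with_doublets=False)
        two = labels.map({"A": "A", "B": "B", "C": "B"})
        with pytest.raises(ValueError, match="3 clusters"):
            qc.detect_multiplet_clusters(adata, two)

    def test_external_flags_are_advisory(self):
        adata, labels = _crafted_clusters(with_doublets=True)
        ext = pd.Series(False, index=["A", "B", "C", "D"])
        rep = qc.detect_multiplet_clusters(adata, labels,
                                           external_flags=ext)
        # criterion 3 false does not veto the flag
        assert rep.flagged == ["D"]
        assert not rep.table.loc["D", "criterion3_external_flag"]


def test_end_to_end_screen_flags_injected_doublets():
    """Per-sample regime: injected Alv+Hor doublets form a cluster that the
    screen flags, and >=90% of the flagged cluster is injected."""
    adata, truth = la.simulate_atlas(synthetic.doublet_screen_config(seed=1))
    adata, truth = synthetic.inject_doublets(adata, truth, ("Alv", "Hor"),
                                             0.1, seed=11)
    qct = qc.compute_barcode_qc(adata)
    ret, _ = qc.filter_barcodes(qct)
    norm = qc.normalize_and_scale(adata[ret].copy())
    emb = tj.reduce_dimensions(norm, n_top_genes=1000)
    labels = pd.Series(tj.snn_cluster(emb, resolution=0.3, seed=0),
                       index=norm.obs_names)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        rep = qc.detect_multiplet_clusters(norm, labels, qct.loc[ret])
    assert len(rep.flagged) == 1
    members = labels.index[labels == rep.flagged[0]]
    frac_injected = truth.barcodes.loc[members, "is_doublet"].mean()
    assert frac_injected >= 0.9


class TestAnnotateClusters:
    def _profiles(self, expr):
        n = pd.Series(1, index=expr.index)
        return qc.ClusterProfiles(expr, n, n.astype(float), n.astype(float))

    def test_planted_markers_win(self):
        expr = pd.DataFrame(
            {"Krt14": [3.0, 0.1], "Acta2": [2.5, 0.2], "Csn3": [0.1, 3.0],
             "Elf5": [0.2, 2.8], "other": [1.0, 1.0]},
            index=["c1", "c2"])
        ann = qc.annotate_clusters(self._profiles(expr))
        assert ann["c1"] == "basal"
        assert ann["c2"] == "alveolar"

    def test_all_zero_profile_unassigned(self):
        expr = pd.DataFrame({"Krt14": [2.0, 0.0], "Csn3": [0.1, 0.0]},
                            index=["c1", "c2"])
        ann = qc.annotate_clusters(self._profiles(expr))
        assert ann["c2"] == "unassigned"

    def test_no_markers_present_is_error(self):
        expr = pd.DataFrame({"x": [1.0], "y": [2.0]}, index=["c1"])
        with pytest.raises(ValueError, match="no marker genes"):
            qc.annotate_clusters(self._profiles(expr))

    def test_simulated_clusters_get_truth_labels(self, analysis_chain):
        epi = analysis_chain["epi"]
        tb = analysis_chain["truth"]
        prof = qc.cluster_average_expression(
            epi, tb["branch"].astype(object))
        ann = qc.annotate_clusters(prof)
        expect = {"Basal": "basal", "Alv": "alveolar",
                  "Hor": "hormone-sensing"}
        hits = sum(ann.get(k) == v for k, v in expect.items())
        assert hits >= 3
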