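"""One-command pipeline driver: simulate/load -> QC -> trajectory ->
curation -> scoring -> pseudo-bulk titrations, with a run manifest.

Every stage writes its artifacts under the output directory as headered
TSV/GMT; the manifest records the configuration hash, the master seed, the
per-stage seeds fanned out from it, package versions, and a SHA-256 digest
of every written file, so that a rerun with the same seed can be checked
for bit-identical outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import bulk as bulk_mod
from . import curation, io, qc, scoring, synthetic, trajectory

logger = logging.getLogger(__name__)

#: canonical lineage markers used to anchor tree leaves to lineage names
LINEAGE_ANCHOR_MARKERS = {
    "Basal": ["Krt14", "Acta2"],
    "Alv": ["Csn3", "Elf5"],
    "Hor": ["Areg", "Esr1", "Ly6d"],
}
ROOT_ANCHOR_MARKERS = ["Mif"]
ANNOTATION_TO_LINEAGE = {"basal": "Basal", "alveolar": "Alv",
                         "hormone-sensing": "Hor"}
STROMAL_LABELS = {"fibroblast", "hematopoietic", "macrophage", "pericyte",
                  "endothelial"}


def lineage_pseudotime(
    adata,
    resolution: float = 1.0,
    n_pcs: int = 10,
    k_neighbors: int = 15,
    prune_frac: float = 0.2,
    cluster_seed: int = 0,
):
    """Normalised counts -> epithelial subset with leaf-anchored pseudotimes.

    Clusters the cells, drops clusters annotated as stromal by the bundled
    marker table, refits the embedding and the centroid-MST tree on the
    epithelial subset, anchors leaves to lineages by canonical markers and
    the root by the stem program, and returns a dict with the epithelial
    AnnData (``epi``), the pseudotime table (``pt``; columns Stem, Basal,
    Alv, Hor), the tree, the anchors and the cluster labels.
    """
    emb = trajectory.reduce_dimensions(adata, n_components=n_pcs)
    labels = pd.Series(
        trajectory.snn_cluster(emb, k_neighbors=k_neighbors,
                               resolution=resolution, seed=cluster_seed),
        index=adata.obs_names)
    profiles = qc.cluster_average_expression(adata, labels)
    annotation = qc.annotate_clusters(profiles)
    stromal = set(annotation.index[annotation.isin(STROMAL_LABELS)])
    keep = ~labels.isin(stromal)
    epi = adata[keep.to_numpy()].copy()
    epi_emb = trajectory.reduce_dimensions(epi, n_components=n_pcs)
    epi_labels = trajectory.snn_cluster(
        epi_emb, k_neighbors=k_neighbors, resolution=resolution,
        seed=cluster_seed)
    tree = trajectory.fit_tree(epi_emb, epi_labels,
                               cell_index=epi.obs_names,
                               prune_frac=prune_frac)
    anchors = trajectory.assign_leaf_states(
        tree, epi, LINEAGE_ANCHOR_MARKERS, root_markers=ROOT_ANCHOR_MARKERS)
    anchors = {("Stem" if k == "root" else k): v for k, v in anchors.items()}
    pt = trajectory.pseudotime_table(tree, anchors)
    return {"epi": epi, "pt": pt, "tree": tree, "anchors": anchors,
            "labels": labels, "annotation": annotation,
            "stroma_ids": adata.obs_names[labels.isin(stromal).to_numpy()]}


class PipelineError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage '{stage}' failed: {cause}")
        self.stage = stage


@dataclass
class PipelineConfig:
    outdir: str = "lineatlas_run"
    seed: int | None = None
    counts: str | None = None              # MTX dir or dense TSV
    simulate: dict = field(default_factory=dict)
    qc_thresholds: dict = field(default_factory=dict)
    trajectory: dict = field(default_factory=dict)  # n_pcs, k_neighbors, resolution, prune_frac
    curation: dict = field(default_factory=dict)    # grid, loess
    bulk: dict = field(default_factory=dict)        # sizes, reps, fracs, pool_size
    log_level: str = "INFO"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        cfg = cls(**raw)
        if cfg.seed is None:
            raise ValueError("config must set a seed")
        if cfg.counts is not None and not Path(cfg.counts).exists():
            raise FileNotFoundError(f"counts path {cfg.counts} not found")
        return cfg


def stage_seed(master: int, stage: str) -> int:
    """Fan a master seed out to independent per-stage seeds by stable
    hashing of the stage name."""
    h = hashlib.sha256(f"{master}:{stage}".encode()).digest()
    return int.from_bytes(h[:4], "big") % (2**31)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: PipelineConfig) -> Path:
    """Execute the full workflow; returns the output directory.

    A stage failure aborts with the stage name while keeping the artifacts
    of completed stages on disk.
    """
    if config.seed is None:
        raise ValueError("config must set a seed")
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    log_path = outdir / "run.log"
    handler = logging.FileHandler(log_path, mode="w")
    handler.setFormatter(logging.Formatter("%(levelname)s %(name)s %(message)s"))
    root = logging.getLogger("lineatlas")
    root.addHandler(handler)
    root.setLevel(config.log_level)
    artifacts: list[Path] = []
    stage = "load"
    try:
        # ---- load / simulate -------------------------------------------
        if config.counts:
            adata = io.read_counts(config.counts)
            truth = None
        else:
            sim_cfg = synthetic.AtlasConfig(
                **{"seed": stage_seed(config.seed, "simulate"),
                   **config.simulate})
            adata, truth = synthetic.simulate_atlas(sim_cfg)
            io.write_counts(adata, outdir / "counts")
            io.write_tsv(truth.barcodes, outdir / "truth.tsv",
                         index_label="barcode")
            artifacts += sorted((outdir / "counts").iterdir())
            artifacts.append(outdir / "truth.tsv")
        logger.info("loaded %d barcodes x %d genes", adata.n_obs, adata.n_vars)

        # ---- qc --------------------------------------------------------
        stage = "qc"
        thresholds = qc.QCThresholds(**config.qc_thresholds)
        qc_table = qc.compute_barcode_qc(adata)
        retained, reasons = qc.filter_barcodes(qc_table, thresholds)
        artifacts.append(io.write_tsv(qc_table, outdir / "qc_table.tsv",
                                      index_label="barcode"))
        artifacts.append(io.write_tsv(reasons, outdir / "qc_removed.tsv",
                                      index_label="barcode"))
        adata = adata[retained].copy()
        adata = qc.normalize_and_scale(adata)
        qc_table = qc_table.loc[retained]

        # ---- clustering + multiplet screen -----------------------------
        stage = "trajectory"
        tr = {"n_pcs": 10, "k_neighbors": 15, "resolution": 1.0,
              "prune_frac": 0.2, **config.trajectory}
        emb = trajectory.reduce_dimensions(adata, n_components=tr["n_pcs"])
        labels = trajectory.snn_cluster(
            emb, k_neighbors=tr["k_neighbors"], resolution=tr["resolution"],
            seed=stage_seed(config.seed, "cluster"))
        labels = pd.Series(labels, index=adata.obs_names, name="cluster")
        report = qc.detect_multiplet_clusters(adata, labels, qc_table)
        artifacts.append(io.write_tsv(report.table,
                                      outdir / "multiplet_report.tsv"))
        profiles = qc.cluster_average_expression(adata, labels, qc_table)
        annotation = qc.annotate_clusters(profiles)
        artifacts.append(io.write_tsv(annotation.to_frame(),
                                      outdir / "cluster_annotation.tsv",
                                      index_label="cluster"))
        stromal_clusters = set(
            annotation.index[annotation.isin(STROMAL_LABELS)])
        drop = set(report.flagged) | stromal_clusters
        keep_cells = ~labels.isin(drop)
        logger.info("dropping clusters %s (multiplet/stromal); %d cells kept",
                    sorted(drop), int(keep_cells.sum()))
        stroma_ids = adata.obs_names[labels.isin(stromal_clusters)]
        epi = adata[keep_cells.to_numpy()].copy()
        epi_labels = labels[keep_cells]

        # ---- tree + pseudotime -----------------------------------------
        epi_emb = trajectory.reduce_dimensions(epi, n_components=tr["n_pcs"])
        epi_clusters = trajectory.snn_cluster(
            epi_emb, k_neighbors=tr["k_neighbors"],
            resolution=tr["resolution"],
            seed=stage_seed(config.seed, "cluster2"))
        tree = trajectory.fit_tree(epi_emb, epi_clusters,
                                   cell_index=epi.obs_names,
                                   prune_frac=tr["prune_frac"])
        anchors = trajectory.assign_leaf_states(
            tree, epi, LINEAGE_ANCHOR_MARKERS,
            root_markers=ROOT_ANCHOR_MARKERS)
        anchors = {("Stem" if k == "root" else k): v
                   for k, v in anchors.items()}
        pt = trajectory.pseudotime_table(tree, anchors)
        artifacts.append(io.write_tsv(pt, outdir / "pseudotime.tsv",
                                      index_label="barcode"))
        edge_df = pd.DataFrame(tree.edges,
                               columns=["node_a", "node_b", "length"])
        artifacts.append(io.write_tsv(edge_df, outdir / "tree_edges.tsv"))

        # ---- curation --------------------------------------------------
        stage = "curation"
        grid = config.curation.get("grid") or curation.default_grid()
        selected_sets = []
        for leaf_name in anchors:
            ranked = curation.rank_genes_by_pseudotime(
                epi, pt[leaf_name], leaf_name)
            artifacts.append(io.write_tsv(
                ranked, outdir / f"ranked_{leaf_name}.tsv",
                index_label="gene"))
            sets = curation.build_incremental_sets(ranked, grid)
            curve = curation.evaluate_selection_curve(
                epi, sets, pt[leaf_name],
                loess=bool(config.curation.get("loess", False)))
            artifacts.append(io.write_tsv(
                curve.table, outdir / f"selection_curve_{leaf_name}.tsv"))
            chosen = next(s for s in sets if s.size == curve.k_star)
            selected_sets.append(curation.GeneSet(
                name=leaf_name, genes=chosen.genes, leaf=leaf_name,
                description=f"top {curve.k_star} genes for {leaf_name}"))
            logger.info("leaf %s: k* = %d", leaf_name, curve.k_star)
        gmt_path = io.write_gmt(selected_sets, outdir / "lineage_sets.gmt")
        artifacts.append(gmt_path)
        genesets = {s.name: s.genes for s in selected_sets}

        # ---- scoring ---------------------------------------------------
        stage = "scoring"
        frames = []
        for study, idx in epi.obs.groupby("study", observed=True).groups.items():
            pos = epi.obs_names.get_indexer(idx)
            expr = pd.DataFrame(epi.layers["scaled"][pos], index=idx,
                                columns=epi.var_names)
            frames.append(scoring.enrichment_scores(expr, genesets))
        scores = pd.concat(frames).reindex(epi.obs_names)
        lineage_cols = [c for c in ("Basal", "Alv", "Hor")
                        if c in scores.columns]
        tern = scoring.ternary_coordinates(scores[lineage_cols])
        artifacts.append(io.write_tsv(scores, outdir / "scores.tsv",
                                      index_label="barcode"))
        artifacts.append(io.write_tsv(tern, outdir / "ternary.tsv",
                                      index_label="barcode"))

        # ---- pseudo-bulk titrations ------------------------------------
        stage = "bulk"
        lineage_labels = epi_labels.map(
            {cl: ANNOTATION_TO_LINEAGE[a]
             for cl, a in annotation.items()
             if a in ANNOTATION_TO_LINEAGE})
        bk = {"sizes": (10, 30, 100, 300, 1000), "reps": 5,
              "fracs": (0.5, 0.6, 0.7, 0.8, 0.9, 1.0), "pool_size": 100,
              **config.bulk}
        if lineage_labels.notna().sum() >= 3 * 10:
            titr = bulk_mod.sampling_robustness(
                epi, lineage_labels, genesets, sizes=tuple(bk["sizes"]),
                reps=int(bk["reps"]),
                seed=stage_seed(config.seed, "sampling"))
            artifacts.append(io.write_tsv(
                titr, outdir / "sampling_titration.tsv"))
            if len(stroma_ids) >= 50:
                cont = bulk_mod.contamination_titration(
                    adata, lineage_labels, stroma_ids, genesets,
                    epithelial_fracs=tuple(bk["fracs"]),
                    pool_size=int(bk["pool_size"]), reps=int(bk["reps"]),
                    seed=stage_seed(config.seed, "contamination"))
                artifacts.append(io.write_tsv(
                    cont, outdir / "contamination_titration.tsv"))
            else:
                logger.info("too few stromal cells; contamination "
                            "titration skipped")
        else:
            logger.info("lineage clusters too small; titrations skipped")

        # ---- manifest --------------------------------------------------
        stage = "manifest"
        import anndata
        import scipy
        import sklearn

        cfg_dict = asdict(config)
        manifest = {
            "config": cfg_dict,
            # hash of the scientific configuration (output location aside)
            "config_hash": hashlib.sha256(json.dumps(
                {k: v for k, v in cfg_dict.items() if k != "outdir"},
                sort_keys=True).encode()).hexdigest(),
            "seed": config.seed,
            "stage_seeds": {s: stage_seed(config.seed, s)
                            for s in ("simulate", "cluster", "cluster2",
                                      "sampling", "contamination")},
            "versions": {"numpy": np.__version__, "scipy": scipy.__version__,
                         "pandas": pd.__version__,
                         "anndata": anndata.__version__,
                         "sklearn": sklearn.__version__},
            "artifacts": {p.name: _sha256(p) for p in artifacts},
        }
        (outdir / "manifest.json").write_text(
            json.dumps(manifest, indent=2, sort_keys=True) + "\n")
        (outdir / "config_used.yaml").write_text(
            yaml.safe_dump(cfg_dict, sort_keys=True))
    except Exception as err:  # noqa: BLE001 - annotate with the stage
        raise PipelineError(stage, err) from err
    finally:
        root.removeHandler(handler)
        handler.close()
    return outdir
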