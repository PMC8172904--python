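"""Barcode-level quality control and cluster-level multiplet detection.

Droplet scRNA-seq barcodes are screened on three basic characteristics —
genes detected (nFeature_RNA), total UMI counts (nCount_RNA) and the
percentage of mitochondrial-gene counts (percent_mt).  After clustering,
putative multiplet clusters are identified by four criteria:

1. elevated sequencing depth (median nCount and nFeature above a multiple
   of the overall medians), the signature of >1 cell per droplet;
2. no exclusive marker genes — a true cell type separates from the others
   by at least one marker of its own, a doublet cluster does not;
3. an (optional, advisory) external doublet-caller flag;
4. a near-perfect correlation between the cluster's average expression
   profile and a hypothetical doublet profile built by averaging two other
   clusters' profiles.

A cluster is flagged when criteria 1, 2 and 4 all hold; the correlation
threshold defaults to r >= 0.99.  The implied doublet rate is estimated
from cluster frequencies as f_AB / (2 f_A f_B), the random-pairing
inversion.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from itertools import combinations

import anndata as ad
import numpy as np
import pandas as pd
from scipy import sparse, stats

logger = logging.getLogger(__name__)

#: Representative markers used to categorise mammary clusters.
DEFAULT_MARKER_TABLE: dict[str, list[str]] = {
    "epithelial": ["Epcam"],
    "basal": ["Krt14", "Acta2"],
    "luminal": ["Krt18"],
    "hormone-sensing": ["Areg", "Esr1", "Ly6d"],
    "alveolar": ["Csn3", "Elf5"],
    "proliferating": ["Mki67"],
    "stressed": ["Fosb"],
    "fibroblast": ["Col1a1", "Vim"],
    "hematopoietic": ["Ptprc"],
    "macrophage": ["Cd52"],
    "pericyte": ["Des"],
    "endothelial": ["Cdh5"],
}


@dataclass(frozen=True)
class QCThresholds:
    """Retention thresholds; a barcode is kept iff nFeature >= min_nFeature,
    nCount >= min_nCount and percent_mt <= max_percent_mt (boundaries
    inclusive on the retained side)."""

    min_nFeature: int = 500
    min_nCount: int = 1000
    max_percent_mt: float = 5.0

    def __post_init__(self) -> None:
        if min(self.min_nFeature, self.min_nCount, self.max_percent_mt) <= 0:
            raise ValueError("thresholds must be positive")


@dataclass
class ClusterProfiles:
    """Per-cluster average log-normalised expression with QC medians."""

    mean_expr: pd.DataFrame          # clusters x genes
    n_cells: pd.Series
    median_nFeature: pd.Series
    median_nCount: pd.Series


@dataclass
class MultipletReport:
    table: pd.DataFrame              # one row per cluster
    marker_lists: dict = field(default_factory=dict)

    @property
    def flagged(self) -> list:
        return list(self.table.index[self.table["flagged"]])


def _counts_matrix(adata: ad.AnnData) -> sparse.csr_matrix:
    X = adata.X
    return X.tocsr() if sparse.issparse(X) else sparse.csr_matrix(X)


def compute_barcode_qc(adata: ad.AnnData) -> pd.DataFrame:
    """Per-barcode nFeature_RNA, nCount_RNA and percent_mt from raw counts.

    percent_mt is defined as 0 for all-zero barcodes and is identically 0
    when the gene table carries no mitochondrial flags (e.g. references
    without mitochondrial transcripts).
    """
    if "is_mito" not in adata.var:
        raise ValueError("gene table must carry an 'is_mito' column")
    X = _counts_matrix(adata)
    n_count = np.asarray(X.sum(axis=1)).ravel()
    n_feature = X.getnnz(axis=1)
    mito = adata.var["is_mito"].to_numpy()
    mito_counts = np.asarray(X[:, mito].sum(axis=1)).ravel() if mito.any() \
        else np.zeros_like(n_count)
    with np.errstate(invalid="ignore", divide="ignore"):
        pct = np.where(n_count > 0, 100.0 * mito_counts / n_count, 0.0)
    return pd.DataFrame(
        {"nFeature_RNA": n_feature, "nCount_RNA": n_count.astype(np.int64),
         "percent_mt": pct},
        index=adata.obs_names,
    )


def filter_barcodes(
    qc: pd.DataFrame, thresholds: QCThresholds = QCThresholds()
) -> tuple[pd.Index, pd.DataFrame]:
    """Apply the retention thresholds; returns (retained index, reasons).

    ``reasons`` has one boolean column per failed criterion for every
    removed barcode.
    """
    low_feat = qc["nFeature_RNA"] < thresholds.min_nFeature
    low_count = qc["nCount_RNA"] < thresholds.min_nCount
    high_mt = qc["percent_mt"] > thresholds.max_percent_mt
    removed = low_feat | low_count | high_mt
    reasons = pd.DataFrame(
        {"low_nFeature": low_feat, "low_nCount": low_count,
         "high_percent_mt": high_mt}
    ).loc[removed]
    retained = qc.index[~removed]
    if len(retained) == 0:
        warnings.warn("no barcodes survive QC thresholds", stacklevel=2)
    logger.info("QC filter: %d/%d barcodes retained", len(retained), len(qc))
    return retained, reasons


def normalize_and_scale(adata: ad.AnnData) -> ad.AnnData:
    """Attach 'lognorm' and 'scaled' layers.

    lognorm = ln(1 + 1e4 * count / nCount) per barcode; scaled = per-gene
    z-score of lognorm across barcodes, with zero-variance genes set to 0.
    """
    X = _counts_matrix(adata)
    n_count = np.asarray(X.sum(axis=1)).ravel()
    if (n_count == 0).any():
        raise ValueError("barcodes with zero counts must be filtered first")
    lognorm = np.log1p(1e4 * X.toarray() / n_count[:, None])
    mu = lognorm.mean(axis=0)
    sd = lognorm.std(axis=0)
    sd_safe = np.where(sd > 0, sd, 1.0)
    scaled = (lognorm - mu) / sd_safe
    out = adata.copy()
    out.layers["lognorm"] = lognorm
    out.layers["scaled"] = scaled
    return out


def cluster_average_expression(
    adata: ad.AnnData, labels: pd.Series, qc: pd.DataFrame | None = None
) -> ClusterProfiles:
    """Arithmetic mean of the lognorm layer per cluster, with median QC
    metrics attached.  Empty clusters are dropped with a warning."""
    labels = pd.Series(labels, index=adata.obs_names)
    lognorm = adata.layers["lognorm"]
    if qc is None:
        qc = compute_barcode_qc(adata)
    groups, means, n_cells, med_f, med_c = [], [], [], [], []
    for g, idx in labels.groupby(labels).groups.items():
        if len(idx) == 0:  # pragma: no cover - groupby drops empties
            warnings.warn(f"cluster {g} is empty; excluded", stacklevel=2)
            continue
        pos = adata.obs_names.get_indexer(idx)
        groups.append(g)
        means.append(lognorm[pos].mean(axis=0))
        n_cells.append(len(pos))
        med_f.append(float(qc["nFeature_RNA"].iloc[pos].median()))
        med_c.append(float(qc["nCount_RNA"].iloc[pos].median()))
    mean_expr = pd.DataFrame(np.vstack(means), index=groups,
                             columns=adata.var_names)
    return ClusterProfiles(
        mean_expr=mean_expr,
        n_cells=pd.Series(n_cells, index=groups),
        median_nFeature=pd.Series(med_f, index=groups),
        median_nCount=pd.Series(med_c, index=groups),
    )


def hypothetical_doublet_test(
    profiles: ClusterProfiles, target, pair: tuple
) -> float:
    """Pearson r between a cluster profile and a hypothetical doublet built
    by averaging two other clusters' profiles gene-wise."""
    a, b = pair
    if target in pair:
        raise ValueError("target cluster cannot be part of the pair")
    expr = profiles.mean_expr
    if expr.shape[1] < 50:
        raise ValueError("need >= 50 genes in common for the correlation")
    hypo = (expr.loc[a].to_numpy() + expr.loc[b].to_numpy()) / 2.0
    tgt = expr.loc[target].to_numpy()
    if np.std(tgt) == 0 or np.std(hypo) == 0:
        raise ValueError("constant profile: correlation undefined")
    return float(np.corrcoef(tgt, hypo)[0, 1])


def find_cluster_markers(
    adata: ad.AnnData,
    labels: pd.Series,
    lfc_min: float = np.log(2.0),
    alpha: float = 0.05,
) -> dict[str, list[str]]:
    """One-vs-rest Wilcoxon rank-sum markers per cluster.

    A gene is a marker of a cluster when its BH-adjusted rank-sum p-value
    is below ``alpha`` and its mean lognorm expression exceeds the rest by
    at least ``lfc_min`` (natural-log scale).
    """
    labels = pd.Series(labels, index=adata.obs_names)
    lognorm = adata.layers["lognorm"]
    out: dict[str, list[str]] = {}
    for g in labels.unique():
        mask = (labels == g).to_numpy()
        x, y = lognorm[mask], lognorm[~mask]
        lfc = x.mean(axis=0) - y.mean(axis=0)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            p = stats.ranksums(x, y, axis=0).pvalue
        p_adj = stats.false_discovery_control(np.nan_to_num(p, nan=1.0))
        hit = (p_adj < alpha) & (lfc >= lfc_min)
        out[g] = list(adata.var_names[hit])
    return out


def detect_multiplet_clusters(
    adata: ad.AnnData,
    labels: pd.Series,
    qc: pd.DataFrame | None = None,
    r_threshold: float = 0.99,
    depth_factor: float = 1.4,
    lfc_min: float = np.log(2.0),
    max_exclusive_markers: int = 2,
    external_flags: pd.Series | None = None,
) -> MultipletReport:
    """Evaluate the four multiplet criteria for every cluster.

    A cluster is flagged iff criterion 1 (elevated depth), criterion 2
    (no distinct exclusive markers, operationalised as at most
    ``max_exclusive_markers`` genes unique to the cluster's one-vs-rest
    marker list) and criterion 4 (best mixture correlation >=
    ``r_threshold``) hold; criterion 3 (an external caller's verdict,
    passed as ``external_flags``) is reported but not required.  The
    doublet rate implied by cluster frequencies is attached to flagged rows.
    """
    labels = pd.Series(labels, index=adata.obs_names)
    if labels.nunique() < 3:
        raise ValueError("need >= 3 clusters to build a hypothetical doublet")
    if qc is None:
        qc = compute_barcode_qc(adata)
    profiles = cluster_average_expression(adata, labels, qc)
    clusters = list(profiles.mean_expr.index)
    overall_f = float(qc["nFeature_RNA"].median())
    overall_c = float(qc["nCount_RNA"].median())
    markers = find_cluster_markers(adata, labels, lfc_min=lfc_min)
    freq = profiles.n_cells / profiles.n_cells.sum()

    rows = []
    for g in clusters:
        c1 = (profiles.median_nCount[g] > depth_factor * overall_c
              and profiles.median_nFeature[g] > depth_factor * overall_f)
        own = set(markers.get(g, []))
        others = set().union(*(markers[h] for h in clusters if h != g))
        exclusive = own - others
        c2 = len(exclusive) <= max_exclusive_markers
        best_r, best_pair = -np.inf, None
        for a, b in combinations([h for h in clusters if h != g], 2):
            try:
                r = hypothetical_doublet_test(profiles, g, (a, b))
            except ValueError:
                continue
            if r > best_r:
                best_r, best_pair = r, (a, b)
        c3 = bool(external_flags[g]) if external_flags is not None else None
        flag = bool(c1 and c2 and best_r >= r_threshold)
        rate = np.nan
        if flag and best_pair is not None:
            rate = estimate_doublet_rate(
                freq[best_pair[0]], freq[best_pair[1]], freq[g])
        rows.append(
            {"cluster": g, "criterion1_elevated_depth": c1,
             "criterion2_no_exclusive_markers": c2,
             "criterion3_external_flag": c3,
             "criterion4_mixture_correlation": best_r,
             "criterion4_pair": best_pair, "flagged": flag,
             "estimated_doublet_rate": rate})
    table = pd.DataFrame(rows).set_index("cluster")
    return MultipletReport(table=table, marker_lists=markers)


def estimate_doublet_rate(fA: float, fB: float, fAB: float) -> float:
    """Doublet rate implied by random pairing: fAB / (2 fA fB).

    ``fA``/``fB`` are the frequencies of the parent clusters, ``fAB`` of
    the mixed cluster.  Values above 1 are implausible and trigger a
    warning but are returned as computed.
    """
    if fA <= 0 or fB <= 0:
        raise ValueError("parent cluster frequencies must be positive")
    rate = fAB / (2.0 * fA * fB)
    if rate > 1.0:
        warnings.warn(f"implausible doublet rate {rate:.3f} > 1", stacklevel=2)
    return rate


def annotate_clusters(
    profiles: ClusterProfiles,
    marker_table: dict[str, list[str]] | None = None,
    min_score: float = 0.5,
    min_range: float = 0.5,
) -> pd.Series:
    """Assign each cluster the label whose markers have the highest mean
    scaled (cross-cluster z-scored) expression in its profile; ties, flat
    profiles and clusters whose best score stays below ``min_score`` give
    'unassigned'.

    A label is only eligible when at least one of its markers is actually
    differential in the data — its cluster-mean lognorm spans a range of
    at least ``min_range`` (0.5 ~ a 1.6-fold change).  This keeps cell
    types that are absent from a dataset (e.g. stroma in a sorted
    epithelial sample) from being assigned on amplified noise.
    """
    if marker_table is None:
        marker_table = DEFAULT_MARKER_TABLE
    expr = profiles.mean_expr
    present = {lab: [g for g in genes if g in expr.columns]
               for lab, genes in marker_table.items()}
    rng_ = expr.max(axis=0) - expr.min(axis=0)
    present = {
        lab: genes for lab, genes in present.items()
        if genes and max(rng_[g] for g in genes) >= min_range}
    if not present:
        raise ValueError("no marker genes found in the expression matrix")
    sd = expr.std(axis=0, ddof=0).replace(0.0, 1.0)
    z = (expr - expr.mean(axis=0)) / sd
    out = {}
    for cl in expr.index:
        if not expr.loc[cl].to_numpy().any():
            out[cl] = "unassigned"
            continue
        scores = {lab: float(z.loc[cl, genes].mean())
                  for lab, genes in present.items()}
        ordered = sorted(scores.items(), key=lambda kv: -kv[1])
        if len(ordered) > 1 and np.isclose(ordered[0][1], ordered[1][1]):
            out[cl] = "unassigned"
        elif not np.isfinite(ordered[0][1]) or ordered[0][1] < min_score:
            out[cl] = "unassigned"
        else:
            out[cl] = ordered[0][0]
    return pd.Series(out, name="annotation")
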