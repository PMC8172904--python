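"""Pseudotime-anchored gene ranking and incremental gene-set curation.

For each terminal lineage state, genes are ranked by how specifically they
mark that state: within every study separately, Spearman's rank
correlation is computed between expression and the cell's distance from
the leaf along the trajectory, and the per-study coefficients are averaged
— cross-study averaging absorbs batch effects no single study can.  The
stored "leaf affinity" is the negated distance correlation, so rank 1 is
the gene most enriched toward the leaf.

Gene sets are then grown incrementally down the ranking (every size up to
100, then steps of 20 up to 1000), each candidate set is scored per cell
with the single-sample enrichment score, and the set size maximising the
cross-study mean score–pseudotime correlation is selected.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import anndata as ad
import numpy as np
import pandas as pd
from scipy import stats

from .scoring import enrichment_scores


@dataclass
class GeneSet:
    """An ordered gene set cut from a leaf-state ranking."""

    name: str
    genes: list[str]
    leaf: str | None = None
    description: str = ""

    @property
    def size(self) -> int:
        return len(self.genes)


def default_grid() -> list[int]:
    """Set-size grid: every size 1..100, then 120..1000 in steps of 20."""
    return list(range(1, 101)) + list(range(120, 1001, 20))


def _spearman_columns(X: np.ndarray, t: np.ndarray) -> np.ndarray:
    """Spearman rho of every column of X against t; NaN for constant
    columns."""
    rt = stats.rankdata(t)
    rt = (rt - rt.mean()) / rt.std()
    rX = stats.rankdata(X, axis=0)
    sd = rX.std(axis=0)
    mu = rX.mean(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        rho = (rX - mu).T @ rt / len(t) / sd
    rho[sd == 0] = np.nan
    return rho


def rank_genes_by_pseudotime(
    adata: ad.AnnData,
    pseudotime: pd.Series,
    leaf: str,
    layer: str = "scaled",
    study_key: str = "study",
    min_studies: int = 2,
) -> pd.DataFrame:
    """Cross-study-averaged Spearman ranking of genes against a leaf's
    pseudotime.

    ``pseudotime`` is distance-from-leaf per cell.  The returned table has
    one per-study rho column (leaf affinity, i.e. -rho(distance)), the
    cross-study mean, and ranks (1 = most leaf-enriched; ties broken by
    gene symbol).  Genes with a defined coefficient in fewer than
    ``min_studies`` studies are dropped; studies with constant pseudotime
    are excluded with a warning.
    """
    pt = pseudotime.reindex(adata.obs_names)
    cols = {}
    for study, idx in adata.obs.groupby(study_key, observed=True).groups.items():
        pos = adata.obs_names.get_indexer(idx)
        t = pt.iloc[pos].to_numpy(dtype=float)
        if np.ptp(t) == 0 or len(t) < 3:
            warnings.warn(f"pseudotime constant in study {study}; excluded",
                          stacklevel=2)
            continue
        X = adata.layers[layer][pos]
        cols[f"rho_{study}"] = -_spearman_columns(X, t)  # leaf affinity
    table = pd.DataFrame(cols, index=adata.var_names)
    n_valid = table.notna().sum(axis=1)
    table = table[n_valid >= min_studies].copy()
    table["mean_rho"] = table.mean(axis=1)
    table["leaf"] = leaf
    # rank 1 = most leaf-enriched; ties broken by gene symbol
    order = np.lexsort((table.index.to_numpy(), -table["mean_rho"].to_numpy()))
    table = table.iloc[order]
    table["rank"] = np.arange(1, len(table) + 1)
    return table


def build_incremental_sets(
    ranked: pd.DataFrame, grid: list[int] | None = None
) -> list[GeneSet]:
    """Nested prefix sets of the ranking at each grid size."""
    if grid is None:
        grid = default_grid()
    leaf = str(ranked["leaf"].iloc[0]) if "leaf" in ranked else "set"
    genes = list(ranked.index)
    usable = [k for k in grid if k <= len(genes)]
    if len(usable) < len(grid):
        warnings.warn("grid sizes exceeding the ranking length were dropped",
                      stacklevel=2)
    return [GeneSet(name=f"{leaf}_top{k}", genes=genes[:k], leaf=leaf)
            for k in usable]


@dataclass
class SelectionCurve:
    """Per-size score–pseudotime correlations and the selected size."""

    table: pd.DataFrame          # index size k; per-study + mean columns
    k_star: int
    k_star_loess: int | None = None
    leaf: str | None = None


def evaluate_selection_curve(
    adata: ad.AnnData,
    sets: list[GeneSet],
    pseudotime: pd.Series,
    layer: str = "scaled",
    study_key: str = "study",
    loess: bool = False,
    loess_frac: float = 0.3,
    max_cells_per_study: int | None = 300,
    subsample_seed: int = 0,
) -> SelectionCurve:
    """Score every candidate set per cell and correlate with pseudotime.

    For each study, each set's per-cell enrichment score is computed
    (cohort = the study's cells) and Spearman-correlated with the leaf
    affinity orientation of pseudotime (-distance).  The curve is the
    cross-study mean; the selected size k* is its argmax, with a
    LOESS-smoothed argmax reported alongside when requested.  Scoring is
    evaluated on at most ``max_cells_per_study`` cells per study (the
    ranking itself always uses every cell).
    """
    pt = pseudotime.reindex(adata.obs_names)
    genesets = {s.name: s.genes for s in sets}
    sizes = [s.size for s in sets]
    rng = np.random.default_rng(subsample_seed)
    per_study = {}
    for study, idx in adata.obs.groupby(study_key, observed=True).groups.items():
        if max_cells_per_study is not None and len(idx) > max_cells_per_study:
            idx = pd.Index(rng.choice(idx, max_cells_per_study,
                                      replace=False))
        pos = adata.obs_names.get_indexer(idx)
        t = pt.iloc[pos].to_numpy(dtype=float)
        if np.ptp(t) == 0:
            continue
        expr = pd.DataFrame(adata.layers[layer][pos],
                            index=idx, columns=adata.var_names)
        scores = enrichment_scores(expr, genesets)
        rhos = []
        for s in sets:
            sc = scores[s.name].to_numpy()
            if np.isnan(sc).all() or np.ptp(sc[~np.isnan(sc)]) == 0:
                rhos.append(np.nan)
            else:
                rhos.append(-stats.spearmanr(sc, t).statistic)
        per_study[f"rho_{study}"] = rhos
    table = pd.DataFrame(per_study, index=pd.Index(sizes, name="size"))
    table["mean_rho"] = table.mean(axis=1)
    k_star = int(table["mean_rho"].idxmax())
    k_loess = None
    if loess:
        from statsmodels.nonparametric.smoothers_lowess import lowess

        sm = lowess(table["mean_rho"].to_numpy(),
                    np.asarray(sizes, dtype=float), frac=loess_frac)
        k_loess = int(sizes[int(np.argmax(sm[:, 1]))])
    leaf = sets[0].leaf if sets else None
    return SelectionCurve(table=table, k_star=k_star, k_star_loess=k_loess,
                          leaf=leaf)


def benchmark_features(
    features: pd.DataFrame,
    pseudotime: pd.Series,
    study: pd.Series,
    n_per_study: int = 1000,
    seed: int = 0,
) -> pd.DataFrame:
    """Rank arbitrary per-cell features by cross-study mean Spearman
    correlation with a leaf pseudotime (leaf-affinity orientation).

    Cells are subsampled per study (default 1000) before correlating;
    features constant within every study are reported as missing.
    """
    rng = np.random.default_rng(seed)
    pt = pseudotime.reindex(features.index)
    study = study.reindex(features.index)
    rows = {}
    for st in study.dropna().unique():
        idx = features.index[study == st]
        if len(idx) > n_per_study:
            idx = pd.Index(rng.choice(idx, n_per_study, replace=False))
        t = pt.loc[idx].to_numpy(dtype=float)
        if np.ptp(t) == 0:
            continue
        rows[f"rho_{st}"] = -_spearman_columns(
            features.loc[idx].to_numpy(dtype=float), t)
    out = pd.DataFrame(rows, index=features.columns)
    out["mean_rho"] = out.mean(axis=1)
    return out.sort_values("mean_rho", ascending=False)
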