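"""Pseudo-bulk construction, robustness titrations, and bulk lineage calls.

Bulk RNA-seq of a tissue averages over its cell mixture; whether the
lineage gene sets still resolve the cell of origin there is probed by two
simulations built from single cells with known labels:

* sampling robustness — pseudo-bulk pools of 10..1000 cells drawn from one
  lineage cluster (or from an even "Mixture" pool) are scored and placed
  on the ternary simplex; calls should not depend on pool size;
* stromal contamination — fixed-size pools with the epithelial fraction
  titrated from 100% down to 50% (remainder stromal cells); calls should
  survive realistic contamination.

Pseudo-bulk profiles are arithmetic means of the log-normalised layer,
matching standard cluster-average pseudo-RNA-seq.  All replicate pools in
a run are scored jointly, the pools forming the scoring cohort.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import anndata as ad
import numpy as np
import pandas as pd

from .scoring import enrichment_scores, nearest_vertex, ternary_coordinates

MIXTURE = "Mixture"


@dataclass
class PseudoBulkProfile:
    """Mean lognorm expression over a pooled cell set plus its recipe."""

    profile: pd.Series
    composition: dict = field(default_factory=dict)
    n_cells: int = 0


def pseudobulk(
    adata: ad.AnnData, cell_ids, composition: dict | None = None
) -> PseudoBulkProfile:
    """Average the lognorm layer over ``cell_ids``."""
    cell_ids = pd.Index(cell_ids)
    if len(cell_ids) == 0:
        raise ValueError("empty pool")
    pos = adata.obs_names.get_indexer(cell_ids)
    if (pos < 0).any():
        raise KeyError("unknown cell ids in pool")
    prof = pd.Series(adata.layers["lognorm"][pos].mean(axis=0),
                     index=adata.var_names)
    return PseudoBulkProfile(profile=prof, composition=dict(composition or {}),
                             n_cells=len(cell_ids))


def _sample_pool(rng: np.random.Generator, ids: pd.Index, size: int
                 ) -> tuple[pd.Index, bool]:
    capped = size > len(ids)
    if capped:
        warnings.warn(f"pool size {size} capped to {len(ids)} cells",
                      stacklevel=3)
    take = min(size, len(ids))
    return pd.Index(rng.choice(ids, take, replace=False)), capped


def _score_pools(
    pools: list[tuple[dict, pd.Series]],
    genesets: dict[str, list[str]],
    lineage_sets: list[str],
) -> pd.DataFrame:
    meta = pd.DataFrame([m for m, _ in pools])
    expr = pd.DataFrame([p.to_numpy() for _, p in pools],
                        columns=pools[0][1].index)
    scores = enrichment_scores(expr, genesets)
    tern = ternary_coordinates(scores[lineage_sets])
    calls = nearest_vertex(tern)
    tern = tern.add_prefix("tern_")
    return pd.concat(
        [meta.reset_index(drop=True), scores.reset_index(drop=True),
         tern.reset_index(drop=True),
         calls.reset_index(drop=True).rename("call")], axis=1)


def sampling_robustness(
    adata: ad.AnnData,
    labels: pd.Series,
    genesets: dict[str, list[str]],
    sizes: tuple[int, ...] = (10, 30, 100, 300, 1000),
    reps: int = 5,
    seed: int = 0,
    mixture_per_cluster: int = 500,
) -> pd.DataFrame:
    """Pseudo-bulk pools of varying size from each lineage cluster and from
    an even mixture pool, scored and placed on the simplex.

    ``labels`` assigns lineage-cluster names to cells (cells with NA are
    ignored); ``genesets`` must contain one set per lineage cluster, named
    after it.  Replicate seeds derive deterministically from ``seed`` and
    the condition index.
    """
    labels = labels.reindex(adata.obs_names)
    clusters = sorted(labels.dropna().unique())
    lineage_sets = [c for c in clusters if c in genesets]
    by_cluster = {c: adata.obs_names[(labels == c).to_numpy()]
                  for c in clusters}
    pools = []
    cond = 0
    for source in clusters + [MIXTURE]:
        for size in sizes:
            for rep in range(reps):
                rng = np.random.default_rng([seed, cond, rep])
                if source == MIXTURE:
                    base = []
                    for c in clusters:
                        take, _ = _sample_pool(
                            rng, by_cluster[c],
                            min(mixture_per_cluster, len(by_cluster[c])))
                        base.append(take)
                    pool_ids, capped = _sample_pool(
                        rng, pd.Index(np.concatenate(base)), size)
                else:
                    pool_ids, capped = _sample_pool(
                        rng, by_cluster[source], size)
                pb = pseudobulk(adata, pool_ids,
                                {"source": source, "size": size})
                pools.append(({"source": source, "size": size, "rep": rep,
                               "n_cells": pb.n_cells, "capped": capped},
                              pb.profile))
            cond += 1
    return _score_pools(pools, genesets, lineage_sets)


def contamination_titration(
    adata: ad.AnnData,
    labels: pd.Series,
    stroma_ids: pd.Index,
    genesets: dict[str, list[str]],
    epithelial_fracs: tuple[float, ...] = (0.5, 0.6, 0.7, 0.8, 0.9, 1.0),
    pool_size: int = 100,
    reps: int = 10,
    seed: int = 0,
) -> pd.DataFrame:
    """Titrate stromal contamination into fixed-size pseudo-bulk pools.

    For each epithelial source (every lineage cluster plus an even Mixture)
    and each epithelial fraction, pools of ``pool_size`` cells are drawn
    with the stated fraction epithelial and the remainder stromal, fully
    resampled per replicate.  The returned table adds ``drift``: the
    ternary distance of each pool from its source's mean position at
    fraction 1.0.
    """
    if len(stroma_ids) == 0:
        raise ValueError("no stromal cells supplied")
    labels = labels.reindex(adata.obs_names)
    clusters = sorted(labels.dropna().unique())
    lineage_sets = [c for c in clusters if c in genesets]
    by_cluster = {c: adata.obs_names[(labels == c).to_numpy()]
                  for c in clusters}
    pools = []
    cond = 0
    for source in clusters + [MIXTURE]:
        for frac in epithelial_fracs:
            n_epi = round(frac * pool_size)
            for rep in range(reps):
                rng = np.random.default_rng([seed, 1000 + cond, rep])
                if source == MIXTURE:
                    per = [n_epi // len(clusters)] * len(clusters)
                    for i in range(n_epi - sum(per)):
                        per[i] += 1
                    epi = np.concatenate([
                        _sample_pool(rng, by_cluster[c], k)[0]
                        for c, k in zip(clusters, per)])
                else:
                    epi = _sample_pool(rng, by_cluster[source], n_epi)[0]
                stro = _sample_pool(rng, pd.Index(stroma_ids),
                                    pool_size - n_epi)[0]
                ids = pd.Index(np.concatenate([np.asarray(epi),
                                               np.asarray(stro)]))
                pb = pseudobulk(adata, ids, {"source": source, "frac": frac})
                pools.append(({"source": source, "epithelial_frac": frac,
                               "rep": rep, "n_cells": pb.n_cells},
                              pb.profile))
            cond += 1
    table = _score_pools(pools, genesets, lineage_sets)
    tern_cols = [c for c in table.columns if c.startswith("tern_")]
    drift = np.full(len(table), np.nan)
    for source in table["source"].unique():
        ref = table[(table["source"] == source)
                    & (table["epithelial_frac"] == 1.0)][tern_cols].mean()
        sel = table["source"] == source
        drift[sel.to_numpy()] = np.linalg.norm(
            table.loc[sel, tern_cols].to_numpy() - ref.to_numpy(), axis=1)
    table["drift"] = drift
    return table


def infer_bulk_lineage(
    bulk_expr: pd.DataFrame,
    genesets: dict[str, list[str]],
    lineage_sets: tuple[str, ...] = ("Basal", "Alv", "Hor"),
) -> pd.DataFrame:
    """Score bulk transcriptomes (samples x genes, log expression) against
    the lineage sets and call each sample's nearest simplex vertex."""
    if bulk_expr.shape[0] < 3:
        raise ValueError("need >= 3 bulk samples for the scoring cohort")
    scores = enrichment_scores(bulk_expr, genesets)
    present = [s for s in lineage_sets if s in scores.columns]
    if len(present) != 3:
        raise ValueError("three differentiation sets are required")
    tern = ternary_coordinates(scores[present])
    out = pd.concat([scores, tern.add_prefix("tern_")], axis=1)
    out["call"] = nearest_vertex(tern)
    return out
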