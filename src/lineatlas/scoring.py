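"""Single-sample gene-set enrichment scoring and lineage coordinates.

The enrichment score is a rank-based random-walk statistic (the GSVA
family) quantifying how coordinately a gene set is up-ranked within one
unit (cell or bulk sample) relative to the cohort:

1. per gene, each unit's expression is replaced by its empirical CDF
   across units (average-rank ties, divided by n);
2. per unit, genes are ordered by decreasing CDF; the gene at position
   r in {1..p} carries weight w_r = |p/2 - r|, emphasising extremes;
3. a random walk accumulates w_r (normalised by the set's total weight)
   on set genes and 1/(p - |S|) on non-set genes:
       nu(l) = sum_{r<=l, g_r in S} w_r / W_S  -  #{r<=l, g_r not in S}/(p-|S|)
4. the score is max_l nu(l) + min_l nu(l), the signed difference of the
   walk's two extreme deviations, in [-1, 1].

Ties in the CDF are broken by matrix gene order (stable sort), making the
score fully deterministic.  Because only cross-unit ranks enter, the score
is invariant to any strictly monotone per-gene transform.

Also provided: the simplex (ternary) projection of three lineage scores,
2-D summarisation of score space, and the Cliff's delta effect size with
its companion Wilcoxon rank-sum test.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.decomposition import PCA


def _as_frame(expr) -> pd.DataFrame:
    if isinstance(expr, pd.DataFrame):
        return expr
    raise TypeError("expression must be a units x genes DataFrame")


def enrichment_scores(
    expr: pd.DataFrame,
    genesets: dict[str, list[str]],
    min_genes: int = 2,
) -> pd.DataFrame:
    """Score every unit (row) against every gene set.

    ``expr`` is units x genes — scaled expression for cells, log expression
    for bulk samples.  Sets with fewer than ``min_genes`` members present
    in the matrix get NaN; a set covering every gene leaves no background
    for the walk and is rejected.
    """
    expr = _as_frame(expr)
    n, p = expr.shape
    if n < 3:
        raise ValueError("need >= 3 units for a cross-unit ECDF")
    X = expr.to_numpy(dtype=float)
    cdf = stats.rankdata(X, axis=0) / n
    order = np.argsort(-cdf, axis=1, kind="stable")
    pos_w = np.abs(p / 2.0 - np.arange(1, p + 1))

    col_idx = {g: i for i, g in enumerate(expr.columns)}
    out = {}
    for name, genes in genesets.items():
        present = [col_idx[g] for g in dict.fromkeys(genes) if g in col_idx]
        k = len(present)
        if k >= p:
            raise ValueError(f"gene set '{name}' covers all genes; "
                             "no background remains")
        if k < min_genes:
            out[name] = np.full(n, np.nan)
            continue
        member = np.zeros(p, dtype=bool)
        member[present] = True
        M = member[order]                                  # units x p
        wm = M * pos_w[None, :]
        walk_in = np.cumsum(wm, axis=1) / wm.sum(axis=1, keepdims=True)
        walk_out = np.cumsum(~M, axis=1) / (p - k)
        nu = walk_in - walk_out
        out[name] = nu.max(axis=1) + nu.min(axis=1)
    return pd.DataFrame(out, index=expr.index)


def ternary_coordinates(scores3: pd.DataFrame) -> pd.DataFrame:
    """Project three lineage scores onto the probability simplex.

    Each column is min-max rescaled to [0, 1] across units (enrichment
    scores can be negative), then rows are closed to sum to 1.  Constant
    columns rescale to 0.5 with a warning; all-zero rows map to the
    centroid.
    """
    if scores3.shape[1] != 3:
        raise ValueError("exactly three score columns required")
    if scores3.shape[0] < 2:
        raise ValueError("need >= 2 units to rescale")
    lo, hi = scores3.min(axis=0), scores3.max(axis=0)
    span = hi - lo
    const = span == 0
    if const.any():
        warnings.warn(
            f"constant score column(s) {list(scores3.columns[const])}; "
            "rescaled to 0.5", stacklevel=2)
    span = span.replace(0, 1.0)
    scaled = (scores3 - lo) / span
    scaled.loc[:, const[const].index] = 0.5
    total = scaled.sum(axis=1)
    zero = total == 0
    scaled.loc[zero] = 1.0 / 3.0
    total[zero] = 1.0
    return scaled.div(total, axis=0)


def nearest_vertex(ternary: pd.DataFrame) -> pd.Series:
    """Lineage call per unit: the simplex vertex with the largest
    coordinate; exact ties give 'ambiguous'."""
    arr = ternary.to_numpy()
    best = arr.argmax(axis=1)
    top = arr.max(axis=1)
    tied = (arr == top[:, None]).sum(axis=1) > 1
    calls = pd.Series(ternary.columns.to_numpy()[best], index=ternary.index,
                      name="call", dtype=object)
    calls[tied] = "ambiguous"
    return calls


class ScoreEmbedding:
    """2-D summary of score space, fit on a reference cohort and able to
    project further units onto the same coordinates."""

    def __init__(self, method: str = "pca", seed: int = 0):
        if method not in {"pca", "umap"}:
            raise ValueError("method must be 'pca' or 'umap'")
        self.method = method
        self.seed = seed
        self._model = None

    def fit(self, scores: pd.DataFrame) -> "ScoreEmbedding":
        if scores.shape[0] < 3:
            raise ValueError("need >= 3 units")
        if self.method == "pca":
            self._model = PCA(n_components=2, svd_solver="full")
            self._model.fit(scores.to_numpy())
        else:
            import umap

            self._model = umap.UMAP(n_components=2, random_state=self.seed)
            self._model.fit(scores.to_numpy())
        return self

    def transform(self, scores: pd.DataFrame) -> pd.DataFrame:
        coords = self._model.transform(scores.to_numpy())
        return pd.DataFrame(coords, index=scores.index,
                            columns=["dim1", "dim2"])


def summarize_score_space(
    scores: pd.DataFrame,
    method: str = "pca",
    reference: pd.Index | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Embed units in 2-D from their lineage scores; when ``reference`` is
    given the embedding is fit on those units only and the rest are
    projected onto it."""
    emb = ScoreEmbedding(method=method, seed=seed)
    emb.fit(scores.loc[reference] if reference is not None else scores)
    return emb.transform(scores)


def cliffs_delta(x, y) -> float:
    """Cliff's delta effect size.

    delta = (#{x_i > y_j} - #{x_i < y_j}) / (|x| |y|), in [-1, 1];
    positive when x stochastically dominates y.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    diff = np.sign(x[:, None] - y[None, :])
    return float(diff.sum() / (x.size * y.size))


def compare_groups(x, y) -> tuple[float, float]:
    """Effect size and significance for a two-sample comparison:
    (Cliff's delta, two-sided Wilcoxon rank-sum p-value)."""
    delta = cliffs_delta(x, y)
    p = float(stats.mannwhitneyu(x, y, alternative="two-sided").pvalue)
    return delta, p
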