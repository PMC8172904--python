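"""Independent brute-force oracles, written from the definitions with
plain loops; deliberately naive so they cannot share bugs with the
vectorised implementations they check."""

from __future__ import annotations

import numpy as np


def ecdf_average_rank(column):
    """Empirical CDF values of one gene across units: average rank / n."""
    column = list(column)
    n = len(column)
    out = []
    for v in column:
        less = sum(1 for w in column if w < v)
        equal = sum(1 for w in column if w == v)
        avg_rank = (2 * less + equal + 1) / 2.0   # mean rank of tied block
        out.append(avg_rank / n)
    return out


def gsva_walk_score(values, in_set):
    """Score one unit: values per gene already converted to ECDF, in_set a
    boolean list.  Genes ordered by decreasing ECDF, ties by gene index;
    walk accumulates |p/2 - r| weights on set genes and 1/(p-k) off-set;
    score = max deviation + min deviation of the walk."""
    p = len(values)
    order = sorted(range(p), key=lambda j: (-values[j], j))
    k = sum(in_set)
    w_total = 0.0
    for r, j in enumerate(order, start=1):
        if in_set[j]:
            w_total += abs(p / 2.0 - r)
    nu, best_max, best_min = 0.0, -np.inf, np.inf
    for r, j in enumerate(order, start=1):
        if in_set[j]:
            nu += abs(p / 2.0 - r) / w_total
        else:
            nu -= 1.0 / (p - k)
        best_max = max(best_max, nu)
        best_min = min(best_min, nu)
    return best_max + best_min


def enrichment_scores_bruteforce(expr_df, genes):
    """Full oracle: expr_df units x genes DataFrame, genes a list."""
    n, p = expr_df.shape
    cdf = np.column_stack([ecdf_average_rank(expr_df.iloc[:, j])
                           for j in range(p)])
    in_set = [g in set(genes) for g in expr_df.columns]
    return np.array([gsva_walk_score(list(cdf[i]), in_set)
                     for i in range(n)])


def cliffs_delta_bruteforce(x, y):
    more = sum(1 for a in x for b in y if a > b)
    less = sum(1 for a in x for b in y if a < b)
    return (more - less) / (len(x) * len(y))
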