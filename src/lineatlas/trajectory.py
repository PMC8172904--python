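"""Tree trajectory and leaf-anchored pseudotime.

The lineage trajectory is modelled as a minimum spanning tree over cluster
centroids in PCA space, with every cell orthogonally projected onto its
nearest tree edge.  Pseudotime from any anchor node is the geodesic
distance along the tree from that node to the cell's projected point;
anchoring at each terminal (leaf) state yields the per-lineage pseudotimes
(Stem, Basal, Alv, Hor) that gene-set curation consumes.  The tree is the
minimal structure supporting the one contract downstream code relies on:
cell–cell and cell–leaf distances on a branching trajectory.
"""

from __future__ import annotations

from dataclasses import dataclass

import anndata as ad
import igraph
import leidenalg
import networkx as nx
import numpy as np
import pandas as pd
from scipy import sparse
from scipy.optimize import linear_sum_assignment
from scipy.sparse.csgraph import minimum_spanning_tree
from sklearn.decomposition import PCA
from sklearn.neighbors import NearestNeighbors


def reduce_dimensions(
    adata: ad.AnnData, n_components: int = 10,
    n_top_genes: int | None = None,
) -> np.ndarray:
    """PCA of the scaled layer restricted to the most variable genes.

    Genes are ranked by normalised dispersion of the lognorm layer (the
    standard mean-binned excess-variance criterion); the top
    ``n_top_genes`` enter the PCA.  When None, roughly the top tenth of
    the transcriptome is used (clamped to [300, 2000], i.e. the customary
    2000 for a full-size matrix).  Component signs are fixed by making
    each loading's largest-magnitude entry positive, so the embedding is
    fully deterministic.  The result is stored in ``obsm['X_pca']`` and
    returned.
    """
    if n_components < 2:
        raise ValueError("n_components must be >= 2")
    if n_components > min(adata.n_obs, adata.n_vars):
        raise ValueError("n_components exceeds matrix rank")
    if n_top_genes is None:
        n_top_genes = min(2000, max(300, adata.n_vars // 10))
    import scanpy as sc

    tmp = ad.AnnData(X=np.asarray(adata.layers["lognorm"]))
    if n_top_genes < adata.n_vars:
        sc.pp.highly_variable_genes(tmp, n_top_genes=n_top_genes,
                                    flavor="seurat")
        top = np.flatnonzero(tmp.var["highly_variable"].to_numpy())
    else:
        top = np.arange(adata.n_vars)
    X = adata.layers["scaled"][:, top]
    pca = PCA(n_components=n_components, svd_solver="full")
    emb = pca.fit_transform(X)
    # sign convention: largest-|loading| entry of each component positive
    flip = np.sign(pca.components_[
        np.arange(n_components),
        np.abs(pca.components_).argmax(axis=1)])
    flip[flip == 0] = 1.0
    emb = emb * flip
    adata.obsm["X_pca"] = emb
    adata.uns["pca_variance_ratio"] = pca.explained_variance_ratio_
    return emb


def snn_cluster(
    embedding: np.ndarray,
    k_neighbors: int = 15,
    resolution: float = 0.5,
    seed: int = 0,
) -> np.ndarray:
    """Leiden community detection on a Jaccard-weighted shared-nearest-
    neighbor graph, the standard single-cell clustering construction."""
    n = embedding.shape[0]
    if k_neighbors >= n:
        raise ValueError("k_neighbors must be < number of cells")
    nn = NearestNeighbors(n_neighbors=k_neighbors).fit(embedding)
    knn = nn.kneighbors(return_distance=False)
    rows = np.repeat(np.arange(n), k_neighbors)
    A = sparse.csr_matrix(
        (np.ones(rows.size), (rows, knn.ravel())), shape=(n, n))
    A = A + sparse.eye(n, format="csr")          # include self
    shared = (A @ A.T).tocoo()
    k1 = k_neighbors + 1
    mask = shared.row < shared.col
    r, c, s = shared.row[mask], shared.col[mask], shared.data[mask]
    jac = s / (2 * k1 - s)
    keep = jac > 1.0 / 15.0                      # prune weak SNN edges
    g = igraph.Graph(n=n, edges=list(zip(r[keep], c[keep])),
                     edge_attrs={"weight": jac[keep]})
    part = leidenalg.find_partition(
        g, leidenalg.RBConfigurationVertexPartition,
        weights="weight", resolution_parameter=resolution, seed=int(seed))
    return np.asarray(part.membership).astype(str)


@dataclass
class TreeTrajectory:
    """MST over cluster centroids with per-cell edge projections.

    ``cell_edge[i]`` indexes ``edges``; ``cell_offset[i]`` in [0, 1] is the
    position along that edge from its first node.
    """

    nodes: np.ndarray                    # n_nodes x dim centroids
    edges: list[tuple[int, int, float]]  # (u, v, length)
    graph: nx.Graph
    cell_edge: np.ndarray
    cell_offset: np.ndarray
    cell_index: pd.Index

    @property
    def leaves(self) -> list[int]:
        return sorted(n for n in self.graph.nodes if self.graph.degree(n) == 1)

    def node_distances(self, node: int) -> dict[int, float]:
        return nx.single_source_dijkstra_path_length(
            self.graph, node, weight="length")


def _project_cells(
    emb: np.ndarray, nodes: np.ndarray, edges: list[tuple[int, int, float]]
) -> tuple[np.ndarray, np.ndarray]:
    """Orthogonal projection of each cell onto its nearest tree edge."""
    best_d = np.full(emb.shape[0], np.inf)
    cell_edge = np.zeros(emb.shape[0], dtype=int)
    cell_off = np.zeros(emb.shape[0])
    for ei, (u, v, length) in enumerate(edges):
        a, b = nodes[u], nodes[v]
        ab = b - a
        t = np.clip((emb - a) @ ab / (length**2), 0.0, 1.0)
        d = np.linalg.norm(emb - (a + t[:, None] * ab), axis=1)
        better = d < best_d
        best_d[better] = d[better]
        cell_edge[better] = ei
        cell_off[better] = t[better]
    return cell_edge, cell_off


def fit_tree(
    embedding: np.ndarray,
    labels: np.ndarray,
    cell_index: pd.Index | None = None,
    prune_frac: float = 0.2,
) -> TreeTrajectory:
    """Fit the centroid-MST trajectory and project every cell onto it.

    Leaf branches shorter than ``prune_frac`` times the median edge length
    are collapsed into their neighbour, removing spurious terminal states
    produced by over-clustering.
    """
    labels = np.asarray(labels)
    uniq = sorted(pd.unique(labels), key=str)
    if len(uniq) < 3:
        raise ValueError("need >= 3 clusters to fit a branching tree")
    centroids = np.vstack([embedding[labels == g].mean(axis=0) for g in uniq])
    D = np.linalg.norm(centroids[:, None] - centroids[None, :], axis=2)
    if np.any(D[np.triu_indices_from(D, 1)] == 0):
        raise ValueError("identical cluster centroids")
    mst = minimum_spanning_tree(D).tocoo()
    G = nx.Graph()
    G.add_nodes_from(range(len(uniq)))
    for u, v, w in zip(mst.row, mst.col, mst.data):
        a, b = (int(u), int(v)) if u < v else (int(v), int(u))
        G.add_edge(a, b, length=float(w))

    # prune spuriously short terminal branches
    lengths = [d["length"] for _, _, d in G.edges(data=True)]
    cutoff = prune_frac * float(np.median(lengths))
    changed = True
    while changed and G.number_of_nodes() > 2:
        changed = False
        for node in sorted(G.nodes):
            if G.degree(node) == 1:
                (nbr,) = G.neighbors(node)
                if G[node][nbr]["length"] < cutoff and G.degree(nbr) > 1:
                    G.remove_node(node)
                    changed = True
                    break

    edges = [(u, v, G[u][v]["length"]) for u, v in sorted(G.edges)]
    cell_edge, cell_off = _project_cells(embedding, centroids, edges)
    if cell_index is None:
        cell_index = pd.RangeIndex(embedding.shape[0])
    return TreeTrajectory(nodes=centroids, edges=edges, graph=G,
                          cell_edge=cell_edge, cell_offset=cell_off,
                          cell_index=pd.Index(cell_index))


def compute_pseudotime(
    tree: TreeTrajectory, anchor: int, allow_internal: bool = False
) -> pd.Series:
    """Geodesic distance along the tree from an anchor node to every cell's
    projected point.  The anchor must be a leaf unless ``allow_internal``
    (used for root states that sit at the trifurcation centre)."""
    if anchor not in tree.graph:
        raise ValueError(f"node {anchor} not in tree")
    if not allow_internal and anchor not in tree.leaves:
        raise ValueError(f"node {anchor} is not a leaf")
    nd = tree.node_distances(anchor)
    out = np.empty(len(tree.cell_index))
    for i, (ei, off) in enumerate(zip(tree.cell_edge, tree.cell_offset)):
        u, v, length = tree.edges[ei]
        out[i] = min(nd[u] + off * length, nd[v] + (1 - off) * length)
    return pd.Series(out, index=tree.cell_index, name=f"pt_from_{anchor}")


def cell_cell_distance(tree: TreeTrajectory, i: int, j: int) -> float:
    """Tree distance between the projected points of two cells (by
    positional index)."""
    ei, ej = tree.cell_edge[i], tree.cell_edge[j]
    oi, oj = tree.cell_offset[i], tree.cell_offset[j]
    ui, vi, li = tree.edges[ei]
    uj, vj, lj = tree.edges[ej]
    if ei == ej:
        return abs(oi - oj) * li
    nd = tree.node_distances(ui)
    d_ui_uj = nd[uj]
    d_ui_vj = nd[vj]
    ndv = tree.node_distances(vi)
    cands = [
        oi * li + min(d_ui_uj + oj * lj, d_ui_vj + (1 - oj) * lj),
        (1 - oi) * li + min(ndv[uj] + oj * lj, ndv[vj] + (1 - oj) * lj),
    ]
    return min(cands)


def nearest_node(tree: TreeTrajectory) -> np.ndarray:
    """Tree node nearest to each cell's projection (by edge side)."""
    out = np.empty(len(tree.cell_index), dtype=int)
    for i, (ei, off) in enumerate(zip(tree.cell_edge, tree.cell_offset)):
        u, v, _ = tree.edges[ei]
        out[i] = u if off < 0.5 else v
    return out


def assign_leaf_states(
    tree: TreeTrajectory,
    adata: ad.AnnData,
    lineage_markers: dict[str, list[str]],
    root_markers: list[str] | None = None,
    layer: str = "scaled",
) -> dict[str, int]:
    """Map lineage names to tree nodes by planted/known marker programs.

    Each differentiation lineage is assigned the leaf whose adjacent cells
    (cells projecting nearest to it) have the highest mean marker score,
    via an optimal one-to-one assignment.  The root/stem state is the node
    — possibly internal, since the stem sits at the trifurcation centre —
    maximising the root-marker score.
    """
    near = nearest_node(tree)
    expr = adata.layers[layer]
    var_idx = {g: i for i, g in enumerate(adata.var_names)}

    def mean_score(node: int, genes: list[str]) -> float:
        cols = [var_idx[g] for g in genes if g in var_idx]
        cells = near == node
        if not cols or not cells.any():
            return -np.inf
        return float(expr[np.ix_(cells, cols)].mean())

    leaves = tree.leaves
    lineages = list(lineage_markers)
    score = np.array([[mean_score(leaf, lineage_markers[lin])
                       for leaf in leaves] for lin in lineages])
    ri, ci = linear_sum_assignment(-score)
    anchors = {lineages[r]: leaves[c] for r, c in zip(ri, ci)}
    if root_markers is not None:
        nodes = sorted(tree.graph.nodes)
        root_scores = [mean_score(nd, root_markers) for nd in nodes]
        anchors["root"] = nodes[int(np.argmax(root_scores))]
    return anchors


def pseudotime_table(
    tree: TreeTrajectory, anchors: dict[str, int]
) -> pd.DataFrame:
    """Distance-from-anchor for every cell and every anchored state."""
    cols = {}
    for name, node in anchors.items():
        cols[name] = compute_pseudotime(tree, node, allow_internal=True)
    return pd.DataFrame(cols)
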