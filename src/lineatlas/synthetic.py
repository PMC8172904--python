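"""Synthetic trifurcating-lineage scRNA-seq data with known ground truth.

The generator emulates the structure of a multi-study mammary-epithelium
atlas: a single stem/root state that differentiates into three epithelial
lineages (basal, luminal alveolar, luminal hormone-sensing), each with its
own marker program rising monotonically along pseudotime; a shared stem
program decaying from the root outward on every branch; stromal cell types
with an independent program; multiplicative gene-by-study batch effects;
mitochondrial-gene count fractions; and optionally injected same-droplet
doublets whose count vectors are exact sums of two singlet parents.

Counts are negative-binomial with variance ``mu + mu**2 / dispersion``,
the standard overdispersed noise model for UMI data.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import anndata as ad
import numpy as np
import pandas as pd
from scipy import sparse

BRANCHES = ("Basal", "Alv", "Hor")
ROOT = "Stem"
STROMA = "Stroma"

# pan-epithelial and pan-luminal markers: constant (t-independent) factors
# over the cell classes that express them, so cluster annotation can tell
# epithelium from stroma and luminal from basal
_PAN = {"Epcam": "epithelial", "Krt18": "luminal"}

# canonical mammary markers planted at the head of each lineage program so
# that marker-table annotation works on simulated data
_CANONICAL = {
    "Stem": ["Mif"],
    "Basal": ["Krt14", "Acta2"],
    "Alv": ["Csn3", "Elf5"],
    "Hor": ["Areg", "Esr1", "Ly6d"],
    "Stroma": ["Col1a1", "Vim", "Des", "Cdh5", "Ptprc", "Cd52"],
}


@dataclass(frozen=True)
class AtlasConfig:
    """Parameters of the simulated atlas.

    Defaults give ~1.1k epithelial cells across three studies with 100
    planted markers per lineage program — large enough that the planted
    structure is recoverable by the downstream pipeline, small enough to
    iterate on quickly.
    """

    n_genes: int = 3000
    n_marker_genes_per_lineage: int = 100
    n_cells_per_branch: int = 800
    n_root_cells: int = 400
    n_studies: int = 3
    branch_names: tuple[str, ...] = BRANCHES
    root_name: str = ROOT
    nb_dispersion: float = 2.0
    base_mean: float = 0.8
    marker_fold_change: float = 8.0
    batch_sd: float = 0.3
    abundance_sd: float = 1.4
    cell_size_sd: float = 0.25
    #: branch cells draw pseudotime uniformly from this interval; a range
    #: like (0.55, 1.0) yields discrete differentiated populations (the
    #: adult-tissue regime in which cluster-level multiplet detection
    #: operates) instead of a continuum
    pseudotime_range: tuple[float, float] = (0.0, 1.0)
    doublet_fraction: float = 0.0
    stroma_fraction: float = 0.15
    mito_gene_fraction: float = 0.01
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.branch_names) != 3:
            raise ValueError("exactly three branch names required")
        for name in ("n_genes", "n_marker_genes_per_lineage",
                     "n_cells_per_branch", "n_root_cells", "n_studies"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        for name in ("doublet_fraction", "stroma_fraction",
                     "mito_gene_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v < 1.0:
                raise ValueError(f"{name} must be in [0, 1)")
        n_programs = 5  # stem + three lineages + stroma
        n_mito = max(1, round(self.mito_gene_fraction * self.n_genes))
        n_pan = len(_PAN)
        if (n_programs * self.n_marker_genes_per_lineage + n_mito + n_pan
                > self.n_genes):
            raise ValueError("marker programs and mito genes exceed n_genes")


@dataclass
class SimulationTruth:
    """Ground truth emitted alongside the counts.

    ``barcodes`` has one row per barcode: branch (Stem/Basal/Alv/Hor/Stroma,
    NA for doublets), true_pseudotime in [0, 1] from the root (NaN for
    stroma/doublets), arm (which branch a root cell sits at the base of),
    is_doublet, doublet_parents, study.  ``markers`` maps each program name
    to its planted ordered gene list.
    """

    barcodes: pd.DataFrame
    markers: dict[str, list[str]] = field(default_factory=dict)


def _nb_counts(rng: np.random.Generator, mean: np.ndarray,
               dispersion: float) -> np.ndarray:
    """NB(mean, dispersion) via the gamma–Poisson mixture."""
    lam = rng.gamma(shape=dispersion, scale=mean / dispersion)
    return rng.poisson(lam).astype(np.int32)


def _gene_table(config: AtlasConfig) -> tuple[pd.DataFrame, dict[str, list[str]]]:
    m = config.n_marker_genes_per_lineage
    n_mito = max(1, round(config.mito_gene_fraction * config.n_genes))
    programs = [config.root_name, *config.branch_names, STROMA]
    symbols: list[str] = []
    markers: dict[str, list[str]] = {}
    for prog in programs:
        canon = _CANONICAL.get(prog, [])[:m]
        generic = [f"{prog.lower()[:3]}-g{i:03d}" for i in range(m - len(canon))]
        markers[prog] = canon + generic
        symbols.extend(markers[prog])
    symbols.extend(_PAN)
    symbols.extend(f"mt-g{i:02d}" for i in range(n_mito))
    n_bg = config.n_genes - len(symbols)
    symbols.extend(f"g{i:04d}" for i in range(n_bg))
    var = pd.DataFrame(index=pd.Index(symbols, name="symbol"))
    var["is_mito"] = [s.startswith("mt-") for s in symbols]
    return var, markers


def simulate_atlas(config: AtlasConfig) -> tuple[ad.AnnData, SimulationTruth]:
    """Generate a count matrix plus ground truth for the configured atlas.

    Each singlet epithelial barcode gets an arm (one of the three branches)
    and a pseudotime ``t``; root cells sit near t=0 and carry the branch
    label of the root state.  The expected count of gene *g* in a cell is
    ``base_mean * batch(g, study) * lineage(g, arm, t)`` where the lineage
    factor rises log-linearly from 1 to ``marker_fold_change`` along t for
    the arm's own markers, stays at 1 for off-arm markers, and decays from
    ``marker_fold_change`` to 1 with t for the shared stem program.
    Deterministic given ``config.seed``.
    """
    rng = np.random.default_rng(config.seed)
    var, markers = _gene_table(config)
    n_genes = config.n_genes
    sym_to_idx = {s: i for i, s in enumerate(var.index)}

    # --- cells -----------------------------------------------------------
    arms: list[str] = []
    branches: list[str] = []
    ts: list[float] = []
    for b in config.branch_names:
        arms += [b] * config.n_cells_per_branch
        branches += [b] * config.n_cells_per_branch
        lo, hi = config.pseudotime_range
        ts += list(rng.uniform(lo, hi, config.n_cells_per_branch))
    root_arms = rng.choice(config.branch_names, config.n_root_cells)
    arms += list(root_arms)
    branches += [config.root_name] * config.n_root_cells
    ts += list(rng.uniform(0.0, 0.1, config.n_root_cells))
    n_epi = len(arms)
    n_stroma = round(config.stroma_fraction / (1 - config.stroma_fraction) * n_epi)
    arms += [STROMA] * n_stroma
    branches += [STROMA] * n_stroma
    ts += [np.nan] * n_stroma
    n_cells = len(arms)
    studies = rng.choice([f"study{i + 1}" for i in range(config.n_studies)],
                         n_cells)

    # --- expected counts -------------------------------------------------
    # gene-level base abundances: mildly variable for program genes,
    # broadly lognormal for the background transcriptome
    is_marker = np.zeros(n_genes, dtype=bool)
    is_marker[[sym_to_idx[s] for s in _PAN]] = True
    for prog_genes in markers.values():
        is_marker[[sym_to_idx[s] for s in prog_genes]] = True
    abundance = np.exp(rng.normal(0.0, config.abundance_sd, n_genes))
    abundance[is_marker] = np.exp(
        rng.normal(0.0, 0.5, int(is_marker.sum())))
    study_idx = pd.Categorical(studies).codes
    batch = np.exp(rng.normal(0.0, config.batch_sd,
                              (config.n_studies, n_genes)))
    mean = abundance[None, :] * batch[study_idx]

    t_arr = np.asarray(ts)
    arm_arr = np.asarray(arms)
    log_fc = np.log(config.marker_fold_change)
    stem_idx = [sym_to_idx[s] for s in markers[config.root_name]]
    stroma_idx = [sym_to_idx[s] for s in markers[STROMA]]
    epi = arm_arr != STROMA
    mean[np.ix_(epi, stem_idx)] *= np.exp(
        log_fc * (1.0 - t_arr[epi]))[:, None]
    for b in config.branch_names:
        on = arm_arr == b
        b_idx = [sym_to_idx[s] for s in markers[b]]
        mean[np.ix_(on, b_idx)] *= np.exp(log_fc * t_arr[on])[:, None]
    mean[np.ix_(~epi, stroma_idx)] *= config.marker_fold_change
    # pan markers: Epcam in every epithelial cell, Krt18 on the two
    # luminal arms, independent of pseudotime
    mean[epi, sym_to_idx["Epcam"]] *= config.marker_fold_change
    luminal = np.isin(arm_arr, ["Alv", "Hor"])
    mean[luminal, sym_to_idx["Krt18"]] *= config.marker_fold_change

    # library size is independent of lineage state: expected depth is
    # normalised per cell, then a lognormal cell-size factor is applied
    target = config.base_mean * n_genes
    mean *= (target / mean.sum(axis=1))[:, None]
    mean *= np.exp(rng.normal(0.0, config.cell_size_sd, n_cells))[:, None]

    # mitochondrial counts: per-cell fraction ~ Beta, centred near 3% with
    # a tail crossing the 5% QC threshold
    mito_mask = var["is_mito"].to_numpy()
    phi = rng.beta(2.5, 80.0, n_cells)
    non_mito_total = mean[:, ~mito_mask].sum(axis=1)
    mean[:, mito_mask] = (phi / (1 - phi) * non_mito_total
                          / mito_mask.sum())[:, None]

    counts = _nb_counts(rng, mean, config.nb_dispersion)

    obs = pd.DataFrame(
        {"study": studies, "sample": studies},
        index=pd.Index([f"BC{i:05d}" for i in range(n_cells)], name="barcode"),
    )
    adata = ad.AnnData(X=sparse.csr_matrix(counts), obs=obs, var=var.copy())
    truth_df = pd.DataFrame(
        {
            "branch": branches,
            "arm": arms,
            "true_pseudotime": t_arr,
            "is_doublet": False,
            "doublet_parents": pd.Series([None] * n_cells, dtype=object,
                                         index=obs.index),
            "study": studies,
        },
        index=obs.index,
    )
    truth = SimulationTruth(barcodes=truth_df, markers=markers)

    if config.doublet_fraction > 0:
        adata, truth = inject_doublets(
            adata, truth, pair=None, fraction=config.doublet_fraction,
            seed=int(rng.integers(2**31)))
    return adata, truth


def inject_doublets(
    adata: ad.AnnData,
    truth: SimulationTruth,
    pair: tuple[str, str] | None,
    fraction: float,
    seed: int,
) -> tuple[ad.AnnData, SimulationTruth]:
    """Append sum-constructed doublet barcodes.

    ``round(fraction * n_barcodes)`` new barcodes are added; each is the
    elementwise count sum of two distinct singlet parents drawn from the
    two branches in ``pair`` (or any two epithelial singlets when ``pair``
    is None), constrained to share a study — doublets form within one
    droplet run.  No library-size rescaling is applied, so the doubled
    depth remains detectable downstream.
    """
    if not 0.0 <= fraction < 1.0:
        raise ValueError("fraction must be in [0, 1)")
    if fraction == 0.0:
        return adata, truth
    rng = np.random.default_rng(seed)
    tb = truth.barcodes
    singlet = ~tb["is_doublet"].to_numpy()
    epithelial = tb["branch"].isin([ROOT, *BRANCHES]).to_numpy()
    if pair is None:
        pool_a = pool_b = tb.index[singlet & epithelial]
    else:
        pool_a = tb.index[singlet & (tb["branch"] == pair[0]).to_numpy()]
        pool_b = tb.index[singlet & (tb["branch"] == pair[1]).to_numpy()]
    if len(pool_a) < 2 or len(pool_b) < 2:
        raise ValueError("need >= 2 singlet cells on each branch of the pair")

    n_new = round(fraction * adata.n_obs)
    study = tb["study"]
    X = adata.X.tocsr() if sparse.issparse(adata.X) else sparse.csr_matrix(adata.X)
    rows, parents, new_names, new_study = [], [], [], []
    i = 0
    while len(rows) < n_new:
        a = pool_a[rng.integers(len(pool_a))]
        b = pool_b[rng.integers(len(pool_b))]
        if a == b or study[a] != study[b]:
            continue
        ia, ib = adata.obs_names.get_loc(a), adata.obs_names.get_loc(b)
        rows.append(X[ia] + X[ib])
        parents.append((a, b))
        new_names.append(f"DBL{i:05d}")
        new_study.append(study[a])
        i += 1

    X_new = sparse.vstack([X] + rows).tocsr()
    obs_new = pd.DataFrame(
        {"study": new_study, "sample": new_study},
        index=pd.Index(new_names, name=adata.obs.index.name),
    )
    obs = pd.concat([adata.obs, obs_new])
    out = ad.AnnData(X=X_new, obs=obs, var=adata.var.copy())

    add = pd.DataFrame(
        {
            "branch": pd.array([pd.NA] * n_new, dtype=object),
            "arm": pd.array([pd.NA] * n_new, dtype=object),
            "true_pseudotime": np.nan,
            "is_doublet": True,
            "doublet_parents": pd.Series(parents, dtype=object,
                                         index=obs_new.index),
            "study": new_study,
        },
        index=obs_new.index,
    )
    truth_out = SimulationTruth(
        barcodes=pd.concat([tb, add]), markers=dict(truth.markers))
    return out, truth_out


def doublet_screen_config(**overrides) -> AtlasConfig:
    """Config variant emulating one droplet run of adult tissue, the regime
    in which the per-sample multiplet screen operates: a single study and
    discrete differentiated populations (branch pseudotime in the upper
    range) instead of a continuum, at single-sample size."""
    base = AtlasConfig(n_studies=1, n_cells_per_branch=250, n_root_cells=150,
                       pseudotime_range=(0.55, 1.0))
    return replace(base, **overrides)


def low_noise_config(**overrides) -> AtlasConfig:
    """Config variant with the stochastic nuisances turned down: large NB
    dispersion (variance ~ mean), no batch effect, no stroma."""
    base = AtlasConfig(nb_dispersion=50.0, batch_sd=0.0, base_mean=4.0,
                       stroma_fraction=0.0)
    return replace(base, **overrides)
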