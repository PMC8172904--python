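"""Shared fixtures: simulated atlases and the analysis chain on them.

Session-scoped where generation is expensive; tests must not mutate the
shared objects (copy first).
"""

from __future__ import annotations

import anndata as ad
import numpy as np
import pandas as pd
import pytest
from scipy import sparse

import lineatlas as la
from lineatlas import pipeline, qc


@pytest.fixture(scope="session")
def default_sim():
    """Default atlas simulation (three studies, stroma included), seed 1."""
    adata, truth = la.simulate_atlas(la.AtlasConfig(seed=1))
    return adata, truth


@pytest.fixture(scope="session")
def normalized_sim(default_sim):
    """QC-filtered and normalised view of the default simulation."""
    adata, truth = default_sim
    retained, _ = qc.filter_barcodes(qc.compute_barcode_qc(adata))
    norm = qc.normalize_and_scale(adata[retained].copy())
    return norm, truth.barcodes.loc[retained], truth.markers


@pytest.fixture(scope="session")
def analysis_chain(normalized_sim):
    """Trajectory stage on the default simulation: epithelial subset plus
    leaf-anchored pseudotime table."""
    norm, tb, markers = normalized_sim
    res = pipeline.lineage_pseudotime(norm)
    res["truth"] = tb.loc[res["epi"].obs_names]
    res["markers"] = markers
    return res


def make_counts(X, mito=None, study=None, genes=None, barcodes=None):
    """Small AnnData count matrix for hand-built examples (cells x genes)."""
    X = np.asarray(X)
    n, p = X.shape
    genes = list(genes) if genes is not None else [f"g{j}" for j in range(p)]
    barcodes = (list(barcodes) if barcodes is not None
                else [f"c{i}" for i in range(n)])
    var = pd.DataFrame(index=pd.Index(genes, name="symbol"))
    var["is_mito"] = (list(mito) if mito is not None else [False] * p)
    obs = pd.DataFrame(index=pd.Index(barcodes, name="barcode"))
    obs["study"] = list(study) if study is not None else ["s1"] * n
    obs["sample"] = obs["study"]
    return ad.AnnData(X=sparse.csr_matrix(X.astype(np.int32)), obs=obs,
                      var=var)


@pytest.fixture
def toy_counts():
    return make_counts
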