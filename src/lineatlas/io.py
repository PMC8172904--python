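"""Readers and writers for the pipeline's interchange formats.

Counts travel as a CellRanger-dialect MatrixMarket triplet (genes x
barcodes ``matrix.mtx`` with ``genes.tsv``/``barcodes.tsv`` sidecars) or
as a dense genes x barcodes TSV; per-barcode metadata and every tabular
artifact are TSV with headers; gene sets are GMT.
"""

from __future__ import annotations

import warnings
from pathlib import Path

import anndata as ad
import numpy as np
import pandas as pd
from scipy import io as scio
from scipy import sparse

from .curation import GeneSet

MITO_PREFIXES = ("mt-", "MT-", "Mt-")


def mito_flag(symbols, prefixes: tuple[str, ...] = MITO_PREFIXES) -> np.ndarray:
    """True for symbols carrying a mitochondrial prefix (the prefix ends
    with '-', so 'mt-Nd1' is flagged while 'Mtor' is not)."""
    return np.array([any(s.startswith(p) for p in prefixes)
                     for s in symbols])


def write_counts(adata: ad.AnnData, outdir: str | Path) -> Path:
    """Write counts as matrix.mtx (genes x barcodes) + genes.tsv +
    barcodes.tsv + metadata.tsv."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    X = adata.X if sparse.issparse(adata.X) else sparse.csr_matrix(adata.X)
    scio.mmwrite(outdir / "matrix.mtx", X.T.astype(np.int64).tocoo())
    genes = pd.DataFrame({"gene_id": adata.var_names,
                          "symbol": adata.var_names})
    genes.to_csv(outdir / "genes.tsv", sep="\t", header=False, index=False)
    pd.Series(adata.obs_names).to_csv(outdir / "barcodes.tsv", sep="\t",
                                      header=False, index=False)
    adata.obs.to_csv(outdir / "metadata.tsv", sep="\t",
                     index_label="barcode")
    return outdir


def read_counts(
    path: str | Path,
    mito_prefixes: tuple[str, ...] = MITO_PREFIXES,
) -> ad.AnnData:
    """Read a CountMatrix from an MTX triplet directory or a dense genes x
    barcodes TSV; mitochondrial flags are assigned by symbol prefix."""
    path = Path(path)
    if path.is_dir():
        X = scio.mmread(path / "matrix.mtx").tocsr()
        genes = pd.read_csv(path / "genes.tsv", sep="\t", header=None)
        symbols = genes.iloc[:, -1].astype(str).tolist()
        barcodes = pd.read_csv(path / "barcodes.tsv", sep="\t",
                               header=None)[0].astype(str).tolist()
        if X.shape[0] != len(symbols) or X.shape[1] != len(barcodes):
            raise ValueError(
                f"dimension mismatch: matrix is {X.shape[0]} genes x "
                f"{X.shape[1]} barcodes but sidecars list {len(symbols)} "
                f"genes and {len(barcodes)} barcodes")
        obs = pd.DataFrame(index=pd.Index(barcodes, name="barcode"))
        meta_path = path / "metadata.tsv"
        if meta_path.exists():
            obs = pd.read_csv(meta_path, sep="\t", index_col=0)
            obs.index = obs.index.astype(str)
    else:
        dense = pd.read_csv(path, sep="\t", index_col=0)
        symbols = dense.index.astype(str).tolist()
        X = sparse.csr_matrix(dense.to_numpy())  # genes x barcodes
        obs = pd.DataFrame(
            index=pd.Index(dense.columns.astype(str), name="barcode"))
    var = pd.DataFrame(index=pd.Index(symbols, name="symbol"))
    if var.index.has_duplicates:
        raise ValueError("duplicate gene symbols in input")
    var["is_mito"] = mito_flag(symbols, mito_prefixes)
    adata = ad.AnnData(X=sparse.csr_matrix(X.T).astype(np.int32),
                       obs=obs, var=var)
    if (adata.X.data < 0).any():
        raise ValueError("negative counts in input")
    return adata


def read_gmt(path: str | Path) -> list[GeneSet]:
    """Parse a GMT file (name, description, tab-separated genes); duplicate
    genes within a set are collapsed order-preservingly with a warning."""
    sets = []
    for ln, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip():
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) < 3:
            raise ValueError(f"{path}:{ln}: GMT line has {len(fields)} "
                             "fields, need name, description and >= 1 gene")
        name, desc, genes = fields[0], fields[1], fields[2:]
        unique = list(dict.fromkeys(genes))
        if len(unique) < len(genes):
            warnings.warn(f"{path}:{ln}: duplicate genes in set '{name}' "
                          "collapsed", stacklevel=2)
        sets.append(GeneSet(name=name, genes=unique, description=desc))
    return sets


def write_gmt(sets: list[GeneSet], path: str | Path) -> Path:
    path = Path(path)
    lines = ["\t".join([s.name, s.description or s.name, *s.genes])
             for s in sets]
    path.write_text("\n".join(lines) + "\n")
    return path


def read_marker_table(path: str | Path) -> dict[str, list[str]]:
    """Two-column TSV: label, comma-separated genes."""
    out = {}
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    for _, (label, genes) in df.iloc[:, :2].iterrows():
        out[str(label)] = [g.strip() for g in str(genes).split(",")]
    return out


def write_marker_table(table: dict[str, list[str]], path: str | Path) -> Path:
    path = Path(path)
    lines = [f"{label}\t{','.join(genes)}" for label, genes in table.items()]
    path.write_text("\n".join(lines) + "\n")
    return path


def write_tsv(df: pd.DataFrame, path: str | Path, index_label=None) -> Path:
    path = Path(path)
    df.to_csv(path, sep="\t", index_label=index_label)
    return path
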