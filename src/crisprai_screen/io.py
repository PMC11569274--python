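"""Plain-text readers/writers for the pipeline's interchange formats.

Matrices travel as MTX triplets (matrix.mtx + barcodes.tsv + features.tsv,
the 10x convention); tables as TSV; genomic tracks as 4-column bedGraph and
elements as BED6. Everything round-trips through pandas / scipy.io.
"""

from __future__ import annotations

import os

import anndata as ad
import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

BEDGRAPH_COLS = ["chrom", "start", "end", "value"]
BED6_COLS = ["chrom", "start", "end", "name", "score", "strand"]


def write_mtx(adata: ad.AnnData, prefix: str) -> None:
    """Write an AnnData as ``<prefix>matrix.mtx`` + barcodes/features TSVs.

    The matrix is stored features x cells (MTX/10x orientation).
    """
    os.makedirs(os.path.dirname(prefix) or ".", exist_ok=True)
    x = adata.X
    if not sp.issparse(x):
        x = sp.csr_matrix(x)
    scipy.io.mmwrite(prefix + "matrix.mtx", x.T.tocoo())
    pd.Series(adata.obs_names).to_csv(
        prefix + "barcodes.tsv", sep="\t", index=False, header=False
    )
    pd.Series(adata.var_names).to_csv(
        prefix + "features.tsv", sep="\t", index=False, header=False
    )


def read_mtx(prefix: str) -> ad.AnnData:
    """Read an MTX triplet written by :func:`write_mtx` into AnnData."""
    x = scipy.io.mmread(prefix + "matrix.mtx").tocsr().T.tocsr()
    barcodes = pd.read_csv(prefix + "barcodes.tsv", sep="\t", header=None)[0]
    features = pd.read_csv(prefix + "features.tsv", sep="\t", header=None)[0]
    adata = ad.AnnData(X=x)
    adata.obs_names = barcodes.astype(str).to_list()
    adata.var_names = features.astype(str).to_list()
    return adata


def write_bedgraph(track: pd.DataFrame, path: str) -> None:
    track[BEDGRAPH_COLS].to_csv(path, sep="\t", index=False, header=False)


def read_bedgraph(path: str) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", header=None, names=BEDGRAPH_COLS)
    df["start"] = df["start"].astype(np.int64)
    df["end"] = df["end"].astype(np.int64)
    return df


def write_bed6(elements: pd.DataFrame, path: str) -> None:
    """Write elements (chrom/start/end/name, optional score/strand) as BED6."""
    df = elements.copy()
    if "score" not in df.columns:
        df["score"] = 0
    if "strand" not in df.columns:
        df["strand"] = "."
    df[BED6_COLS].to_csv(path, sep="\t", index=False, header=False)


def read_bed6(path: str) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", header=None)
    df.columns = BED6_COLS[: df.shape[1]]
    return df


def write_table(df: pd.DataFrame, path: str, header_comment: str | None = None) -> None:
    """Write a TSV, optionally preceded by '#'-prefixed provenance lines."""
    os.makedirs(os.path.dirname(path) or ".", exist_ok=True)
    with open(path, "w") as fh:
        if header_comment:
            for line in header_comment.splitlines():
                fh.write(f"# {line}\n")
        df.to_csv(fh, sep="\t", index=False)


def read_table(path: str) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#")
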