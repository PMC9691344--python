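"""Readers and writers for the plain-text formats used across the pipeline.

Expression matrices travel as the 10x triplet dialect: a MatrixMarket
coordinate file of integer UMI counts (genes x cells) plus ``features.tsv``
and ``barcodes.tsv`` without headers.  Gene-set collections travel as GMT.
All functions round-trip exactly for integer data.
"""

from __future__ import annotations

import os
from typing import Dict, List, Tuple

import anndata as ad
import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp


def write_10x_mtx(adata: ad.AnnData, outdir: str) -> None:
    """Write an AnnData (cells x genes) as a 10x-style MTX triplet.

    ``matrix.mtx`` holds the genes x cells integer coordinate matrix;
    ``features.tsv`` has columns (gene_id, gene_name, feature_type) and
    ``barcodes.tsv`` one barcode per line, both headerless and tab-separated.
    """
    os.makedirs(outdir, exist_ok=True)
    X = adata.X
    if not sp.issparse(X):
        X = sp.csr_matrix(X)
    mat = sp.coo_matrix(X.T)  # genes x cells on disk
    scipy.io.mmwrite(os.path.join(outdir, "matrix.mtx"), mat, field="integer")
    features = pd.DataFrame(
        {
            "gene_id": adata.var_names,
            "gene_name": adata.var_names,
            "feature_type": "Gene Expression",
        }
    )
    features.to_csv(
        os.path.join(outdir, "features.tsv"), sep="\t", header=False, index=False
    )
    pd.Series(adata.obs_names).to_csv(
        os.path.join(outdir, "barcodes.tsv"), sep="\t", header=False, index=False
    )


def read_10x_mtx(indir: str) -> ad.AnnData:
    """Read a 10x-style MTX triplet back into an AnnData (cells x genes)."""
    mat = scipy.io.mmread(os.path.join(indir, "matrix.mtx"))
    X = sp.csr_matrix(mat.T)

    def _read_column(path: str) -> List[str]:
        if os.path.getsize(path) == 0:
            return []
        return pd.read_csv(path, sep="\t", header=None, dtype=str)[0].tolist()

    var_names = _read_column(os.path.join(indir, "features.tsv"))
    obs_names = _read_column(os.path.join(indir, "barcodes.tsv"))
    adata = ad.AnnData(
        X=X,
        obs=pd.DataFrame(index=pd.Index(obs_names, name="barcode")),
        var=pd.DataFrame(index=pd.Index(var_names, name="gene")),
    )
    return adata


def read_gmt(path: str) -> Dict[str, Tuple[str, List[str]]]:
    """Read a GMT file: term_id -> (description, gene list)."""
    terms: Dict[str, Tuple[str, List[str]]] = {}
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"malformed GMT line: {line[:80]!r}")
            term, desc, genes = parts[0], parts[1], [g for g in parts[2:] if g]
            terms[term] = (desc, genes)
    return terms


def write_gmt(terms: Dict[str, Tuple[str, List[str]]], path: str) -> None:
    with open(path, "w") as fh:
        for term, (desc, genes) in terms.items():
            fh.write("\t".join([term, desc, *genes]) + "\n")
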