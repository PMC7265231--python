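"""Reading and writing droplet count matrices and bulk count tables.

Count matrices travel as 10x-style triplet directories: ``matrix.mtx``
(Matrix Market integer coordinate, genes x cells, 1-based indices),
``features.tsv`` (gene_id, symbol, length, mito), ``barcodes.tsv``, and an
optional ``cell_metadata.tsv``.  In memory a matrix is an
:class:`anndata.AnnData` with cells as ``obs`` and genes as ``var``.

Bulk RNA-seq counts travel as a TSV with columns ``gene_id``, ``length_bp``
and one column per sample, held in :class:`BulkCounts`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import anndata as ad
import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

CELL_META_COLUMNS = ("sample", "condition", "replicate", "chemistry", "modality")


@dataclass
class BulkCounts:
    """Bulk RNA-seq gene counts with gene lengths.

    Attributes
    ----------
    counts : DataFrame, genes x samples, nonnegative integers.
    lengths : Series of gene lengths in bp, indexed like ``counts``.
    normalized : DataFrame of GeTMM-normalized values once computed.
    factors : Series of per-sample TMM scaling factors once computed.
    """

    counts: pd.DataFrame
    lengths: pd.Series
    normalized: pd.DataFrame | None = None
    factors: pd.Series | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.lengths = self.lengths.reindex(self.counts.index)
        if self.lengths.isna().any():
            missing = self.lengths.index[self.lengths.isna()][:5].tolist()
            raise ValueError(f"gene lengths missing for {missing}")
        if (self.lengths <= 0).any():
            raise ValueError("gene lengths must be positive")
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("bulk counts must be nonnegative")

    @property
    def samples(self) -> list[str]:
        return list(self.counts.columns)


def write_10x_triplet(adata: ad.AnnData, path: str | Path) -> None:
    """Write ``adata`` as a triplet directory (genes x cells, 1-based MTX)."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    X = sp.coo_matrix(adata.X.T)  # genes x cells on disk
    X = X.astype(np.int64)
    scipy.io.mmwrite(path / "matrix.mtx", X, field="integer")
    var = adata.var
    features = pd.DataFrame({"gene_id": adata.var_names})
    features["symbol"] = var["symbol"].to_numpy() if "symbol" in var else adata.var_names
    features["length"] = var["length"].to_numpy() if "length" in var else 1000
    features["mito"] = var["mito"].to_numpy().astype(int) if "mito" in var else 0
    features.to_csv(path / "features.tsv", sep="\t", header=False, index=False)
    pd.Series(adata.obs_names).to_csv(
        path / "barcodes.tsv", sep="\t", header=False, index=False
    )
    meta_cols = [c for c in (*CELL_META_COLUMNS, "true_type", "label") if c in adata.obs]
    meta = adata.obs[meta_cols].copy()
    meta.insert(0, "barcode", adata.obs_names)
    meta.to_csv(path / "cell_metadata.tsv", sep="\t", index=False)


def read_10x_triplet(path: str | Path) -> ad.AnnData:
    """Read a triplet directory written by :func:`write_10x_triplet`.

    Raises
    ------
    ValueError
        On dimension mismatches between the matrix and the identifier files,
        or non-integer matrix entries.
    FileNotFoundError
        If any of the three required files is absent.
    """
    path = Path(path)
    for name in ("matrix.mtx", "features.tsv", "barcodes.tsv"):
        if not (path / name).exists():
            raise FileNotFoundError(path / name)
    M = scipy.io.mmread(path / "matrix.mtx")
    dense_vals = M.data if sp.issparse(M) else np.asarray(M).ravel()
    if not np.allclose(dense_vals, np.round(dense_vals)):
        raise ValueError("matrix.mtx contains non-integer entries")
    M = sp.csr_matrix(M.T).astype(np.int64)  # cells x genes in memory
    features = pd.read_csv(path / "features.tsv", sep="\t", header=None)
    features.columns = ["gene_id", "symbol", "length", "mito"][: features.shape[1]]
    barcodes = pd.read_csv(path / "barcodes.tsv", sep="\t", header=None)[0].astype(str)
    if len(features) != M.shape[1]:
        raise ValueError(
            f"features.tsv has {len(features)} rows but matrix has {M.shape[1]} genes"
        )
    if len(barcodes) != M.shape[0]:
        raise ValueError(
            f"barcodes.tsv has {len(barcodes)} rows but matrix has {M.shape[0]} cells"
        )
    var = features.set_index("gene_id")
    if "mito" in var and not var["mito"].isna().any():
        var["mito"] = var["mito"].astype(bool)
    else:
        var["mito"] = var.index.str.lower().str.startswith("mt-")
    adata = ad.AnnData(X=M, var=var, obs=pd.DataFrame(index=barcodes.to_numpy()))
    meta_path = path / "cell_metadata.tsv"
    if meta_path.exists():
        meta = pd.read_csv(meta_path, sep="\t", dtype={"barcode": str})
        meta = meta.set_index("barcode").reindex(adata.obs_names)
        for col in meta.columns:
            adata.obs[col] = meta[col].to_numpy()
    if adata.obs_names.duplicated().any():
        raise ValueError("duplicate barcodes in barcodes.tsv")
    return adata


def write_bulk_tsv(bulk: BulkCounts, path: str | Path) -> None:
    out = pd.DataFrame({"gene_id": bulk.counts.index, "length_bp": bulk.lengths.to_numpy()})
    for s in bulk.samples:
        out[s] = bulk.counts[s].to_numpy()
    out.to_csv(path, sep="\t", index=False)


def read_bulk_tsv(path: str | Path) -> BulkCounts:
    df = pd.read_csv(path, sep="\t")
    if "gene_id" not in df or "length_bp" not in df:
        raise ValueError("bulk TSV requires gene_id and length_bp columns")
    df = df.set_index("gene_id")
    lengths = df.pop("length_bp")
    return BulkCounts(counts=df, lengths=lengths)
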