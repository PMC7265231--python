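"""Quality-control filters and log-normalization for droplet count matrices.

Filter order is genes first (detection in a minimum number of cells,
computed on the input matrix), then cells (detected-gene range,
mitochondrial fraction, and for nuclei libraries a per-chemistry minimum
UMI count with mitochondrial genes dropped).  A one-sided MAD filter
removes cells with an outlying UMI-to-gene ratio.  Normalization divides
by the cell total, scales by 10,000 and natural-log transforms.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import anndata as ad
import numpy as np
import pandas as pd
import scipy.sparse as sp

from ._utils import as_csr

DEFAULT_MIN_UMI = {"v2": 450, "v3": 900}


@dataclass
class QCReport:
    """Bookkeeping of one filtering step."""

    n_cells_in: int
    n_cells_out: int
    n_genes_in: int
    n_genes_out: int
    removed: dict[str, int] = field(default_factory=dict)
    thresholds: dict = field(default_factory=dict)
    notes: list[str] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            ("n_cells_in", self.n_cells_in),
            ("n_cells_out", self.n_cells_out),
            ("n_genes_in", self.n_genes_in),
            ("n_genes_out", self.n_genes_out),
            *((f"removed_{k}", v) for k, v in self.removed.items()),
        ]
        return pd.DataFrame(rows, columns=["metric", "value"])

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


def _detected_per_gene(X: sp.csr_matrix) -> np.ndarray:
    return np.asarray((X > 0).sum(axis=0)).ravel()


def _detected_per_cell(X: sp.csr_matrix) -> np.ndarray:
    return np.asarray((X > 0).sum(axis=1)).ravel()


def filter_matrix(
    adata: ad.AnnData,
    min_cells_per_gene: int = 10,
    gene_range: tuple[int, int] = (200, 3000),
    max_mito_frac: float = 0.5,
    min_umi: dict[str, int] | None = None,
    drop_mito_for_nuclei: bool = True,
    mito_genes: list[str] | None = None,
) -> tuple[ad.AnnData, QCReport]:
    """Apply the standard droplet QC filters.

    Gene-range bounds are inclusive, the mitochondrial bound is exclusive
    ("under" the threshold).  The UMI floor applies only to nuclei
    (``obs['modality'] == 'nucleus'``), per 10x chemistry, and for all-nuclei
    matrices the mitochondrial genes themselves are dropped.
    """
    if min_umi is None:
        min_umi = dict(DEFAULT_MIN_UMI)
    X = as_csr(adata.X)
    n_cells_in, n_genes_in = X.shape
    report = QCReport(
        n_cells_in=n_cells_in,
        n_cells_out=0,
        n_genes_in=n_genes_in,
        n_genes_out=0,
        thresholds={
            "min_cells_per_gene": min_cells_per_gene,
            "gene_range": gene_range,
            "max_mito_frac": max_mito_frac,
            "min_umi": dict(min_umi),
        },
    )

    if mito_genes is not None:
        mito_mask = adata.var_names.isin(mito_genes)
    elif "mito" in adata.var:
        mito_mask = adata.var["mito"].to_numpy(dtype=bool)
    else:
        mito_mask = adata.var_names.str.lower().str.startswith("mt-").to_numpy()

    # 1) gene filter, on the full input droplet set
    keep_gene = _detected_per_gene(X) >= min_cells_per_gene
    report.removed["genes_low_detection"] = int((~keep_gene).sum())
    X = X[:, keep_gene]
    mito_mask = mito_mask[keep_gene]

    # 2) cell filters, on the gene-filtered matrix
    n_detected = _detected_per_cell(X)
    lo, hi = gene_range
    keep_cell = (n_detected >= lo) & (n_detected <= hi)
    report.removed["cells_gene_range"] = int((~keep_cell).sum())

    totals = np.asarray(X.sum(axis=1)).ravel()
    mito_counts = np.asarray(X[:, mito_mask].sum(axis=1)).ravel()
    with np.errstate(invalid="ignore", divide="ignore"):
        mito_frac = np.where(totals > 0, mito_counts / np.maximum(totals, 1), 0.0)
    mito_ok = mito_frac < max_mito_frac
    report.removed["cells_mito"] = int((keep_cell & ~mito_ok).sum())
    keep_cell &= mito_ok

    modality = (
        adata.obs["modality"].to_numpy(dtype=object)
        if "modality" in adata.obs
        else np.full(n_cells_in, "cell", dtype=object)
    )
    chemistry = (
        adata.obs["chemistry"].to_numpy(dtype=object)
        if "chemistry" in adata.obs
        else np.full(n_cells_in, "v2", dtype=object)
    )
    is_nucleus = modality == "nucleus"
    umi_floor = np.zeros(n_cells_in)
    for chem, floor in min_umi.items():
        umi_floor[is_nucleus & (chemistry == chem)] = floor
    umi_ok = totals >= umi_floor
    report.removed["cells_low_umi"] = int((keep_cell & ~umi_ok).sum())
    keep_cell &= umi_ok

    out = adata[keep_cell, keep_gene].copy()
    if drop_mito_for_nuclei and is_nucleus.all() and n_cells_in > 0:
        keep_nonmito = ~mito_mask
        report.removed["genes_mito_dropped"] = int(mito_mask.sum())
        out = out[:, keep_nonmito].copy()

    report.n_cells_out, report.n_genes_out = out.shape
    if out.n_obs == 0:
        report.notes.append("all cells removed")
    return out, report


def remove_ratio_outliers(adata: ad.AnnData, n_mads: float = 3.0) -> tuple[ad.AnnData, QCReport]:
    """Drop cells whose UMI/gene ratio is > median + n_mads * MAD.

    One-sided (high ratios only) with an unscaled MAD; a degenerate MAD of 0
    removes only cells strictly above the median.
    """
    if adata.n_obs < 1:
        raise ValueError("remove_ratio_outliers requires at least one cell")
    X = as_csr(adata.X)
    totals = np.asarray(X.sum(axis=1)).ravel()
    detected = np.maximum(_detected_per_cell(X), 1)
    ratio = totals / detected
    med = np.median(ratio)
    mad = np.median(np.abs(ratio - med))
    keep = ~(ratio > med + n_mads * mad)
    report = QCReport(
        n_cells_in=adata.n_obs,
        n_cells_out=int(keep.sum()),
        n_genes_in=adata.n_vars,
        n_genes_out=adata.n_vars,
        removed={"cells_ratio_outlier": int((~keep).sum())},
        thresholds={"n_mads": n_mads, "median": float(med), "mad": float(mad)},
    )
    return adata[keep].copy(), report


def lognormalize(adata: ad.AnnData, scale: float = 10_000.0) -> ad.AnnData:
    """ln(1 + count / cell_total * scale); zeros stay zero.

    Raw counts are kept in ``layers['counts']``.  A zero-total cell is an
    error naming the offending barcode.
    """
    X = as_csr(adata.X).astype(np.float64)
    totals = np.asarray(X.sum(axis=1)).ravel()
    if (totals == 0).any():
        bad = adata.obs_names[totals == 0][0]
        raise ValueError(f"cell {bad!r} has zero total count; filter before normalizing")
    norm = X.multiply(scale / totals[:, None]).tocsr()
    norm.data = np.log1p(norm.data)
    out = adata.copy()
    out.layers["counts"] = X
    out.X = norm
    out.uns["normalization"] = {"scale": scale, "log": "natural"}
    return out
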