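"""Statistical comparisons for protocol-bias assessment.

Covers per-type Wilcoxon differential expression with detection-rate and
fold-change thresholds, Monte-Carlo-calibrated stress scoring, cell-cycle
phase assignment, per-type composition chi-square tests, GeTMM bulk
normalization (gene-length-corrected trimmed mean of M-values), and
marker-based bulk deconvolution by nonnegative least squares.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import anndata as ad
import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.optimize import nnls
from scipy.stats import chi2
from statsmodels.stats.multitest import multipletests

from . import genesets
from ._utils import as_csr, as_dense, substream
from .annotation import (
    _group_stats,
    _log_fold_change,
    bin_genes,
    derive_signatures,
    draw_null_sets,
    module_score,
    montecarlo_p,
    score_sets,
    wilcoxon_rank_sum,
)
from .io import BulkCounts

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# Wilcoxon differential expression


def wilcoxon_de(
    adata: ad.AnnData,
    group1_cells,
    group2_cells,
    logfc_min: float = 0.5,
    min_pct: float = 0.5,
    fdr: float = 0.05,
) -> pd.DataFrame:
    """Two-group differential expression on log-normalized values.

    Genes are pre-filtered to ``|logFC| >= logfc_min`` and
    ``max(pct1, pct2) >= min_pct``, then tested two-sided by tie-corrected
    rank-sum with BH correction over the tested genes.  Positive logFC
    means higher in group 1; both directions are reported.
    """
    g1 = pd.Index(group1_cells)
    g2 = pd.Index(group2_cells)
    if len(g1.intersection(g2)) > 0:
        raise ValueError("groups overlap")
    if len(g1) < 3 or len(g2) < 3:
        raise ValueError("both groups need >= 3 cells")
    X = as_csr(adata.X)
    mask1 = adata.obs_names.isin(g1)
    mask2 = adata.obs_names.isin(g2)
    pct1, mean1 = _group_stats(X, mask1)
    pct2, mean2 = _group_stats(X, mask2)
    logfc = _log_fold_change(mean1, mean2)
    cand = (np.abs(logfc) >= logfc_min) & (np.maximum(pct1, pct2) >= min_pct)
    idx = np.flatnonzero(cand)
    out = pd.DataFrame(
        {
            "gene": adata.var_names[idx],
            "logfc": logfc[idx],
            "pct1": pct1[idx],
            "pct2": pct2[idx],
        }
    )
    if idx.size:
        X1 = as_dense(X[mask1][:, idx])
        X2 = as_dense(X[mask2][:, idx])
        p = wilcoxon_rank_sum(X1, X2)
        out["p"] = p
        out["q"] = multipletests(p, method="fdr_bh")[1]
    else:
        out["p"] = np.empty(0)
        out["q"] = np.empty(0)
    out["direction"] = np.where(out["logfc"] > 0, "up_group1", "up_group2")
    out = out[out["q"] < fdr].reset_index(drop=True)
    out.attrs["thresholds"] = {"logfc_min": logfc_min, "min_pct": min_pct, "fdr": fdr}
    return out


def wilcoxon_de_by_type(
    adata: ad.AnnData,
    labels,
    conditions,
    pair: tuple[str, str],
    min_group: int = 3,
    **kwargs,
) -> dict[str, pd.DataFrame]:
    """Per-cell-type DE between two conditions; small types skipped."""
    labels = pd.Series(np.asarray(labels, dtype=object), index=adata.obs_names)
    conditions = pd.Series(np.asarray(conditions, dtype=object), index=adata.obs_names)
    results = {}
    for t in sorted(labels.dropna().unique()):
        cells1 = adata.obs_names[(labels == t) & (conditions == pair[0])]
        cells2 = adata.obs_names[(labels == t) & (conditions == pair[1])]
        if len(cells1) < min_group or len(cells2) < min_group:
            logger.info("DE: type %s skipped (too few cells)", t)
            continue
        results[t] = wilcoxon_de(adata, cells1, cells2, **kwargs)
    return results


def filter_de_table(
    table: pd.DataFrame,
    logfc_min: float = 2.0,
    fdr: float = 0.05,
    logfc_col: str = "logfc",
    fdr_col: str = "q",
) -> pd.DataFrame:
    """Threshold filter for an externally computed bulk DE table.

    The bulk exact-test engine itself is not reimplemented; this applies the
    printed ``|logFC| >= logfc_min``, ``FDR < fdr`` rule to its output (or to
    the Wilcoxon substitute's output).
    """
    keep = (table[logfc_col].abs() >= logfc_min) & (table[fdr_col] < fdr)
    return table[keep].reset_index(drop=True)


# ---------------------------------------------------------------------------
# Stress scoring


def stress_score_by_type(
    adata: ad.AnnData,
    labels,
    stress_genes=genesets.STRESS_GENES,
    n_iter: int = 1000,
    alpha: float = 0.01,
    n_bins: int = 25,
    n_ctrl: int = 100,
    min_cells: int = 3,
    seed: int = 0,
) -> pd.DataFrame:
    """Per-type mean stress score with Monte-Carlo significance.

    Per-cell binned-control module scores over the stress set are averaged
    within each type; each type's p-value is the upper-tail Monte-Carlo
    probability against the type-averaged scores of ``n_iter`` random
    same-size gene sets.  Because the score is linear in expression, the
    type average of per-cell null scores equals the null score of the
    per-type mean expression profile, which is what is computed.  BH is
    applied across types; the significance flag is ``p < alpha``.
    """
    labels = pd.Series(np.asarray(labels, dtype=object), index=adata.obs_names)
    present = [g for g in stress_genes if g in adata.var_names]
    if not present:
        raise ValueError("stress gene set is disjoint from the matrix genes")
    rng = substream(seed, "stress_score")
    cell_scores = module_score(adata, present, n_bins=n_bins, n_ctrl=n_ctrl, rng=rng)
    cell_scores = pd.Series(cell_scores, index=adata.obs_names)

    counts = labels.value_counts()
    types = [t for t in sorted(counts.index) if counts[t] >= min_cells]
    skipped = [t for t in sorted(counts.index) if counts[t] < min_cells]
    for t in skipped:
        logger.info("stress score: type %s skipped (< %d cells)", t, min_cells)

    X = as_csr(adata.X)
    type_means = np.vstack(
        [np.asarray(X[(labels == t).to_numpy()].mean(axis=0)).ravel() for t in types]
    )
    avg = np.asarray(X.mean(axis=0)).ravel()
    bins = bin_genes(avg, n_bins)
    lookup = {g: i for i, g in enumerate(adata.var_names)}
    set_idx = np.array([lookup[g] for g in present], dtype=int)
    universe = np.setdiff1d(np.arange(X.shape[1]), set_idx)
    null_sets = draw_null_sets(rng, n_iter, universe, set_idx.size)
    null_scores = score_sets(type_means, null_sets, bins, n_ctrl, rng)  # types x n_iter

    obs = np.array([cell_scores[(labels == t)].mean() for t in types])
    p = montecarlo_p(obs, null_scores.T)
    q = multipletests(p, method="fdr_bh")[1] if len(types) else np.empty(0)
    out = pd.DataFrame(
        {
            "type": types,
            "n_cells": [int(counts[t]) for t in types],
            "mean_score": obs,
            "p": p,
            "q": q,
            "significant": p < alpha,
        }
    )
    out.attrs["alpha"] = alpha
    out.attrs["skipped_types"] = skipped
    return out


# ---------------------------------------------------------------------------
# Cell cycle


def cell_cycle_phase(
    adata: ad.AnnData,
    s_genes=genesets.S_GENES,
    g2m_genes=genesets.G2M_GENES,
    seed: int = 0,
    n_bins: int = 25,
    n_ctrl: int = 100,
) -> pd.DataFrame:
    """Assign S / G2M / G1 per cell from the two phase module scores.

    Phase is the argmax of the S and G2M scores when that score is
    positive; otherwise the cell defaults to G1.
    """
    s_present = [g for g in s_genes if g in adata.var_names]
    g2m_present = [g for g in g2m_genes if g in adata.var_names]
    if not s_present and not g2m_present:
        raise ValueError("neither cell-cycle gene list overlaps the matrix genes")
    rng = substream(seed, "cell_cycle")
    s_score = (
        module_score(adata, s_present, n_bins=n_bins, n_ctrl=n_ctrl, rng=rng)
        if s_present
        else np.full(adata.n_obs, -np.inf)
    )
    g2m_score = (
        module_score(adata, g2m_present, n_bins=n_bins, n_ctrl=n_ctrl, rng=rng)
        if g2m_present
        else np.full(adata.n_obs, -np.inf)
    )
    phase = np.where(
        (s_score <= 0) & (g2m_score <= 0),
        "G1",
        np.where(s_score >= g2m_score, "S", "G2M"),
    )
    return pd.DataFrame(
        {"phase": phase, "s_score": s_score, "g2m_score": g2m_score},
        index=adata.obs_names,
    )


# ---------------------------------------------------------------------------
# Composition chi-square


@dataclass
class CompositionTable:
    """Per-type counts/percentages per condition with chi-square results."""

    table: pd.DataFrame  # index type; count_<cond>, pct_<cond>, chi2, p, significant
    conditions: tuple[str, str]
    alpha: float
    skipped_types: tuple[str, ...] = ()
    excluded_types: tuple[str, ...] = ()

    def to_tsv(self, path) -> None:
        out = self.table.copy()
        out.insert(0, "type", out.index)
        out.to_csv(path, sep="\t", index=False)


def chi_square_2x2(a: int, b: int, c: int, d: int, yates: bool = False) -> tuple[float, float]:
    """Pearson chi-square for the 2x2 table [[a, b], [c, d]], two-sided p."""
    obs = np.array([[a, b], [c, d]], dtype=float)
    total = obs.sum()
    if total == 0:
        return 0.0, 1.0
    expected = np.outer(obs.sum(axis=1), obs.sum(axis=0)) / total
    if (expected == 0).any():
        return 0.0, 1.0
    diff = np.abs(obs - expected)
    if yates:
        diff = np.maximum(diff - 0.5, 0.0)
    stat = float((diff**2 / expected).sum())
    return stat, float(chi2.sf(stat, df=1))


def composition_from_counts(
    counts: pd.DataFrame,
    alpha: float = 0.001,
    yates: bool = False,
) -> CompositionTable:
    """Chi-square composition test from a types x 2-conditions count table.

    Each type is tested in a 2x2 table (type vs. all other types, condition
    A vs. B) with a two-sided Pearson chi-square (no continuity correction
    by default).  Percentages are per condition and sum to 100.
    """
    if counts.shape[1] != 2:
        raise ValueError("composition test requires exactly 2 conditions")
    cond_a, cond_b = counts.columns
    totals = counts.sum(axis=0)
    if (totals == 0).any():
        raise ValueError("a condition has zero cells")
    rows = []
    skipped = []
    for t, row in counts.iterrows():
        if row.sum() == 0:
            skipped.append(t)
            continue
        a, b = int(row[cond_a]), int(row[cond_b])
        stat, p = chi_square_2x2(a, b, int(totals[cond_a] - a), int(totals[cond_b] - b), yates)
        rows.append(
            {
                "type": t,
                f"count_{cond_a}": a,
                f"count_{cond_b}": b,
                f"pct_{cond_a}": 100.0 * a / totals[cond_a],
                f"pct_{cond_b}": 100.0 * b / totals[cond_b],
                "chi2": stat,
                "p": p,
                "significant": p < alpha,
            }
        )
    table = pd.DataFrame(rows).set_index("type")
    return CompositionTable(
        table=table,
        conditions=(str(cond_a), str(cond_b)),
        alpha=alpha,
        skipped_types=tuple(skipped),
    )


def composition_table(
    labels,
    conditions,
    alpha: float = 0.001,
    exclude_types=None,
    yates: bool = False,
) -> CompositionTable:
    """Composition test from per-cell labels and conditions (pooled replicates).

    ``exclude_types`` removes those cells before computing proportions
    (e.g., recompute relative to all non-PT cells).
    """
    labels = pd.Series(np.asarray(labels, dtype=object))
    conditions = pd.Series(np.asarray(conditions, dtype=object))
    if labels.shape != conditions.shape:
        raise ValueError("labels and conditions must align")
    if conditions.nunique() != 2:
        raise ValueError("composition test requires exactly 2 conditions")
    excluded = tuple(exclude_types) if exclude_types else ()
    keep = ~labels.isin(excluded)
    counts = pd.crosstab(labels[keep], conditions[keep])
    counts = counts[sorted(counts.columns)]
    result = composition_from_counts(counts, alpha=alpha, yates=yates)
    result.excluded_types = excluded
    return result


# ---------------------------------------------------------------------------
# GeTMM normalization


def _tmm_factor(
    rpk_obs: np.ndarray,
    rpk_ref: np.ndarray,
    trim_m: float,
    trim_a: float,
) -> float:
    """Weighted trimmed mean of M-values between one library and the reference.

    M = log2 ratio of relative RPK, A = average log2 abundance, computed on
    genes expressed in both; the top/bottom ``trim_m`` of M and ``trim_a``
    of A are trimmed by rank, and the remaining M are averaged with
    inverse-asymptotic-variance (delta method) weights.
    """
    n_obs, n_ref = rpk_obs.sum(), rpk_ref.sum()
    both = (rpk_obs > 0) & (rpk_ref > 0)
    o, r = rpk_obs[both], rpk_ref[both]
    m = np.log2((o / n_obs) / (r / n_ref))
    a = 0.5 * np.log2((o / n_obs) * (r / n_ref))
    v = (n_obs - o) / (n_obs * o) + (n_ref - r) / (n_ref * r)
    if m.size == 0 or np.allclose(m, 0, atol=1e-10):
        return 1.0
    n = m.size
    lo_m = np.floor(n * trim_m) + 1
    hi_m = n + 1 - lo_m
    lo_a = np.floor(n * trim_a) + 1
    hi_a = n + 1 - lo_a
    rank_m = pd.Series(m).rank().to_numpy()
    rank_a = pd.Series(a).rank().to_numpy()
    keep = (rank_m >= lo_m) & (rank_m <= hi_m) & (rank_a >= lo_a) & (rank_a <= hi_a)
    if not keep.any():
        return 1.0
    f = np.sum(m[keep] / v[keep]) / np.sum(1.0 / v[keep])
    if not np.isfinite(f):
        return 1.0
    return float(2.0**f)


def getmm(bulk: BulkCounts, trim_m: float = 0.3, trim_a: float = 0.05) -> BulkCounts:
    """Gene-length-corrected TMM normalization of a bulk count table.

    Counts become reads-per-kilobase (RPK), TMM scaling factors are computed
    on the RPK matrix against a reference sample (the one whose
    upper-quartile RPK fraction is closest to the mean), factors are scaled
    to geometric mean 1, and the normalized value is
    ``RPK / (library RPK total x factor) x 1e6``.
    """
    if bulk.counts.shape[1] < 2:
        raise ValueError("GeTMM requires >= 2 samples")
    counts = bulk.counts.to_numpy(dtype=float)
    if (counts.sum(axis=0) == 0).any():
        bad = bulk.counts.columns[counts.sum(axis=0) == 0].tolist()
        raise ValueError(f"samples with all-zero counts: {bad}")
    rpk = counts / (bulk.lengths.to_numpy(dtype=float)[:, None] / 1000.0)
    totals = rpk.sum(axis=0)
    uq = np.array(
        [np.percentile(rpk[:, j], 75) / totals[j] for j in range(rpk.shape[1])]
    )
    ref = int(np.argmin(np.abs(uq - uq.mean())))
    factors = np.array(
        [
            1.0 if j == ref else _tmm_factor(rpk[:, j], rpk[:, ref], trim_m, trim_a)
            for j in range(rpk.shape[1])
        ]
    )
    factors /= np.exp(np.mean(np.log(factors)))
    normalized = rpk / (totals * factors)[None, :] * 1e6
    return BulkCounts(
        counts=bulk.counts,
        lengths=bulk.lengths,
        normalized=pd.DataFrame(normalized, index=bulk.counts.index, columns=bulk.counts.columns),
        factors=pd.Series(factors, index=bulk.counts.columns, name="tmm_factor"),
        meta={**bulk.meta, "reference_sample": str(bulk.counts.columns[ref])},
    )


# ---------------------------------------------------------------------------
# Deconvolution


@dataclass
class DeconvolutionResult:
    """Estimated cell-type proportions per bulk sample (simplex rows)."""

    proportions: pd.DataFrame  # samples x types
    markers: tuple[str, ...]
    residuals: pd.Series = field(default_factory=lambda: pd.Series(dtype=float))

    def to_tsv(self, path) -> None:
        out = self.proportions.copy()
        out.insert(0, "sample", out.index)
        out.to_csv(path, sep="\t", index=False)


def select_deconvolution_markers(
    adata: ad.AnnData,
    labels,
    marker_logfc: float = 1.5,
    marker_min_pct: float = 0.5,
    fdr: float = 0.05,
    min_cells: int = 10,
) -> dict[str, list[str]]:
    """Positive-only per-type markers, unique to a single type.

    Genes identified in more than one cell type are removed entirely.
    """
    sigs = derive_signatures(
        adata,
        labels,
        logfc_min=marker_logfc,
        min_pct=marker_min_pct,
        fdr=fdr,
        min_cells=min_cells,
        max_memberships=1,
        only_pos=True,
    )
    return sigs.gene_sets()


def deconvolve(
    bulk: BulkCounts,
    adata: ad.AnnData,
    labels,
    marker_logfc: float = 1.5,
    marker_min_pct: float = 0.5,
    exclude_labels=("unknown",),
) -> DeconvolutionResult:
    """Marker-based bulk deconvolution via nonnegative least squares.

    The signature basis is each type's mean linear-scale normalized
    expression over the union of its unique markers; each bulk sample's
    marker vector (normalized to sum 1) is regressed onto the basis and the
    nonnegative coefficients are renormalized to the simplex.
    """
    labels = pd.Series(np.asarray(labels, dtype=object), index=adata.obs_names)
    keep = ~labels.isin(tuple(exclude_labels))
    sub = adata[keep.to_numpy()]
    sub_labels = labels[keep]
    marker_map = select_deconvolution_markers(
        sub, sub_labels, marker_logfc=marker_logfc, marker_min_pct=marker_min_pct
    )
    marker_map = {t: g for t, g in marker_map.items() if g}
    if len(marker_map) < 2:
        raise ValueError("need >= 2 types with at least one unique marker each")
    markers = sorted({g for genes in marker_map.values() for g in genes})
    markers = [g for g in markers if g in bulk.counts.index]
    if not markers:
        raise ValueError("no marker genes present in the bulk table")

    X = as_csr(sub.X)
    linear = X.copy()
    linear.data = np.expm1(linear.data)
    types = sorted(marker_map)
    gene_pos = {g: i for i, g in enumerate(sub.var_names)}
    midx = [gene_pos[g] for g in markers]
    basis = np.vstack(
        [
            np.asarray(linear[(sub_labels == t).to_numpy()].mean(axis=0)).ravel()[midx]
            for t in types
        ]
    ).T  # markers x types
    rank = np.linalg.matrix_rank(basis)
    if rank < len(types):
        corr = np.corrcoef(basis.T)
        collinear = [
            (types[i], types[j])
            for i in range(len(types))
            for j in range(i + 1, len(types))
            if corr[i, j] > 0.999
        ]
        raise ValueError(f"rank-deficient signature basis; collinear types: {collinear}")

    props = {}
    residuals = {}
    for s in bulk.samples:
        b = bulk.counts.loc[markers, s].to_numpy(dtype=float)
        if b.sum() == 0:
            raise ValueError(f"bulk sample {s} has zero counts on the marker genes")
        b = b / b.sum()
        coef, resid = nnls(basis, b)
        if coef.sum() == 0:
            raise ValueError(f"deconvolution of sample {s} collapsed to zero")
        props[s] = coef / coef.sum()
        residuals[s] = resid
    proportions = pd.DataFrame(props, index=types).T
    return DeconvolutionResult(
        proportions=proportions,
        markers=tuple(markers),
        residuals=pd.Series(residuals, name="residual_norm"),
    )
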