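"""Two-iteration reference-plus-signature cell-identity inference.

The procedure labels droplet cells in six steps:

1. build per-type reference expression vectors from labelled data
   (library-size-normalized means), pruning vectors uncorrelated with all
   others;
2. match each query cell to its best reference vector by Spearman
   correlation over shared genes (ties kept, zeros included);
3. derive per-type marker gene signatures from the matched labels by
   one-vs-rest Wilcoxon rank-sum with detection-rate and log-fold-change
   thresholds, excluding promiscuous genes found in more than two
   signatures;
4. score every cell for every signature with a binned-control module score
   (mean signature expression minus the mean of expression-matched random
   control genes);
5. assess each score against a Monte-Carlo null of random same-size gene
   sets and assign the top-scoring type when positive and significant after
   Benjamini-Hochberg correction;
6. append the newly inferred type profiles to the reference and repeat once;
   cells never assigned are labelled ``"unknown"``.

A subcluster refinement step recovers a confusable type (e.g., connecting
tubule among other distal segments) by k-means clustering of the implicated
cells and re-scoring with the marker-bearing cluster as a candidate type.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace

import anndata as ad
import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.stats import mannwhitneyu, rankdata
from sklearn.cluster import KMeans
from sklearn.decomposition import PCA
from statsmodels.stats.multitest import multipletests

from ._utils import as_csr, as_dense, substream

logger = logging.getLogger(__name__)

UNKNOWN_LABEL = "unknown"


# ---------------------------------------------------------------------------
# Reference profiles


@dataclass
class ReferenceProfileSet:
    """Per-type mean expression vectors used for correlation matching.

    ``profiles`` is genes x types with library-size-normalized (counts per
    total, x 1e4) means.  ``retained`` flags vectors kept after outlier
    pruning; ``provenance`` records where each vector came from.
    """

    profiles: pd.DataFrame
    retained: pd.Series
    provenance: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.profiles.columns.duplicated().any():
            raise ValueError("reference type names must be unique")
        if (self.profiles.to_numpy() < 0).any():
            raise ValueError("reference vectors must be nonnegative")
        retained_cols = self.profiles.loc[:, self.retained.reindex(self.profiles.columns)]
        if (retained_cols.to_numpy().sum(axis=0) == 0).any():
            raise ValueError("retained reference vectors must have a nonzero entry")

    @property
    def type_names(self) -> list[str]:
        return list(self.profiles.columns)

    def retained_profiles(self) -> pd.DataFrame:
        keep = [c for c in self.profiles.columns if self.retained[c]]
        return self.profiles[keep]

    def append(self, profiles: pd.DataFrame, provenance: str) -> "ReferenceProfileSet":
        """Return a new set with extra per-type vectors (genes x types)."""
        merged = self.profiles.join(profiles, how="outer").fillna(0.0)
        retained = pd.concat(
            [self.retained, pd.Series(True, index=profiles.columns)]
        )
        prov = dict(self.provenance)
        prov.update({c: provenance for c in profiles.columns})
        return ReferenceProfileSet(profiles=merged, retained=retained, provenance=prov)

    def to_tsv(self, path) -> None:
        self.profiles.to_csv(path, sep="\t")


def _type_mean_normalized(adata: ad.AnnData, labels: pd.Series, scale: float = 1e4) -> pd.DataFrame:
    """Per-type mean of library-size-normalized raw counts (linear scale)."""
    X = as_csr(adata.layers["counts"] if "counts" in adata.layers else adata.X)
    totals = np.asarray(X.sum(axis=1)).ravel()
    totals[totals == 0] = 1.0
    norm = X.multiply(scale / totals[:, None]).tocsr()
    out = {}
    labels = pd.Series(np.asarray(labels, dtype=object), index=adata.obs_names)
    for t in sorted(labels.dropna().unique()):
        mask = (labels == t).to_numpy()
        out[t] = np.asarray(norm[mask].mean(axis=0)).ravel()
    return pd.DataFrame(out, index=adata.var_names)


def build_reference(
    labelled_matrices: list[ad.AnnData],
    outlier_min_rho: float = 0.3,
    label_key: str = "label",
) -> ReferenceProfileSet:
    """Average library-size-normalized counts within each labelled type.

    Vectors whose maximum Spearman correlation to every other vector falls
    below ``outlier_min_rho`` are flagged as not retained (outliers); with a
    single vector nothing is pruned.
    """
    frames = []
    for i, adata in enumerate(labelled_matrices):
        if label_key not in adata.obs:
            raise ValueError(f"matrix {i} has no obs[{label_key!r}] labels")
        frames.append((i, adata))
    if not frames:
        raise ValueError("no labelled matrices provided")

    pieces = []
    prov: dict[str, str] = {}
    for i, adata in frames:
        piece = _type_mean_normalized(adata, adata.obs[label_key])
        # same type appearing in several matrices: pool cells by averaging
        pieces.append(piece)
        for c in piece.columns:
            prov.setdefault(c, f"matrix_{i}")
    profiles = pd.concat(pieces, axis=1).fillna(0.0)
    profiles = profiles.T.groupby(level=0).mean().T  # merge duplicate type names

    retained = pd.Series(True, index=profiles.columns)
    if profiles.shape[1] > 1:
        ranks = np.apply_along_axis(rankdata, 0, profiles.to_numpy())
        rho = np.corrcoef(ranks.T)
        np.fill_diagonal(rho, -np.inf)
        max_rho = rho.max(axis=1)
        retained[:] = max_rho >= outlier_min_rho
        for name, keep in retained.items():
            if not keep:
                logger.info("reference vector %s pruned (max rho < %.2f)", name, outlier_min_rho)
    return ReferenceProfileSet(profiles=profiles, retained=retained, provenance=prov)


# ---------------------------------------------------------------------------
# Correlation matching


def correlation_match(query: ad.AnnData, reference: ReferenceProfileSet) -> pd.DataFrame:
    """Best reference type per cell by Spearman rho over shared genes.

    Zeros are kept as values and ties receive average ranks.  A cell with a
    constant expression vector has undefined rho and is returned unmatched
    with a reason.  Exact rho ties are broken by the lexicographically
    smallest type name (logged).
    """
    ref = reference.retained_profiles()
    shared = query.var_names.intersection(ref.index)
    if len(shared) < 20:
        raise ValueError(f"only {len(shared)} genes shared between query and reference (< 20)")
    Xq = as_dense(query[:, shared].X)
    Xr = ref.loc[shared].to_numpy()

    rq = np.apply_along_axis(rankdata, 1, Xq)
    rr = np.apply_along_axis(rankdata, 0, Xr)
    rq_c = rq - rq.mean(axis=1, keepdims=True)
    rr_c = rr - rr.mean(axis=0, keepdims=True)
    sq = np.sqrt((rq_c**2).sum(axis=1))
    sr = np.sqrt((rr_c**2).sum(axis=0))
    constant = sq == 0
    sq_safe = np.where(constant, 1.0, sq)
    rho = (rq_c @ rr_c) / (sq_safe[:, None] * sr[None, :])

    best_idx = np.argmax(rho, axis=1)
    names = np.array(ref.columns, dtype=object)
    best_type = names[best_idx].copy()
    best_rho = rho[np.arange(len(best_idx)), best_idx]
    max_rho = rho.max(axis=1)
    for i in range(rho.shape[0]):
        tied = np.flatnonzero(rho[i] == max_rho[i])
        if len(tied) > 1:
            best_type[i] = min(names[tied])
            logger.info("cell %s: correlation tie among %s, picked %s",
                        query.obs_names[i], list(names[tied]), best_type[i])
    reason = np.where(constant, "constant expression vector", "")
    best_type = np.where(constant, None, best_type)
    best_rho = np.where(constant, np.nan, best_rho)
    return pd.DataFrame(
        {"type": best_type, "rho": best_rho, "reason": reason}, index=query.obs_names
    )


# ---------------------------------------------------------------------------
# Signatures


@dataclass
class SignatureSet:
    """Per-type marker genes with effect sizes and adjusted p-values.

    ``markers`` is a long table (type, gene, logfc, pct_in, pct_out, q);
    ``excluded`` lists genes dropped for appearing in more than
    ``max_memberships`` signatures.
    """

    markers: pd.DataFrame
    excluded: tuple[str, ...] = ()
    skipped_types: tuple[str, ...] = ()
    thresholds: dict = field(default_factory=dict)

    def gene_sets(self) -> dict[str, list[str]]:
        return {
            t: list(sub["gene"]) for t, sub in self.markers.groupby("type", sort=True)
        }

    def to_tsv(self, path) -> None:
        self.markers.to_csv(path, sep="\t", index=False)


def _group_stats(X: sp.csr_matrix, mask: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """(detection rate, mean of de-logged normalized expression) per gene."""
    sub = X[mask]
    pct = np.asarray((sub > 0).sum(axis=0)).ravel() / max(sub.shape[0], 1)
    linear = sub.copy()
    linear.data = np.expm1(linear.data)
    mean_linear = np.asarray(linear.mean(axis=0)).ravel()
    return pct, mean_linear


def _log_fold_change(mean1: np.ndarray, mean2: np.ndarray) -> np.ndarray:
    """Natural-log fold change of de-logged means, pseudo-count 1.

    This is the Seurat-v2-era convention; a threshold of "logFC = 1" refers
    to this scale.
    """
    return np.log(mean1 + 1.0) - np.log(mean2 + 1.0)


_EXACT_MAX_COMBINATIONS = 20_000


def _exact_rank_sum_p(X1: np.ndarray, X2: np.ndarray) -> np.ndarray:
    """Exact two-sided permutation p of the rank sum, per column.

    Enumerates every assignment of group labels to the pooled observations
    and counts rank-sum deviations from the permutation mean at least as
    large as observed.  Correct under arbitrary ties.
    """
    from itertools import combinations

    n1, n2 = X1.shape[0], X2.shape[0]
    n = n1 + n2
    combos = np.array(list(combinations(range(n), n1)))
    pooled = np.vstack([X1, X2])
    ranks = np.apply_along_axis(rankdata, 0, pooled)
    mean_sum = n1 * (n + 1) / 2.0
    obs_dev = np.abs(ranks[:n1].sum(axis=0) - mean_sum)
    pvals = np.empty(pooled.shape[1])
    for j in range(pooled.shape[1]):
        sums = ranks[:, j][combos].sum(axis=1)
        pvals[j] = np.mean(np.abs(sums - mean_sum) >= obs_dev[j] - 1e-12)
    return pvals


def wilcoxon_rank_sum(X1: np.ndarray, X2: np.ndarray) -> np.ndarray:
    """Two-sided rank-sum p per column (gene).

    Small groups get the exact permutation distribution (enumerated, valid
    under ties); larger groups use the tie-corrected normal approximation.
    """
    if X1.shape[1] == 0:
        return np.empty(0)
    from math import comb

    if comb(X1.shape[0] + X2.shape[0], X1.shape[0]) <= _EXACT_MAX_COMBINATIONS:
        return _exact_rank_sum_p(X1, X2)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        res = mannwhitneyu(X1, X2, alternative="two-sided", method="asymptotic", axis=0)
    return np.atleast_1d(res.pvalue)


def derive_signatures(
    adata: ad.AnnData,
    labels,
    logfc_min: float = 1.0,
    min_pct: float = 0.5,
    fdr: float = 0.05,
    min_cells: int = 10,
    max_memberships: int = 2,
    only_pos: bool = True,
) -> SignatureSet:
    """One-vs-rest marker signatures on log-normalized expression.

    Genes are pre-filtered per type to detection rate >= ``min_pct`` within
    the type and log fold change >= ``logfc_min``, then tested by Wilcoxon
    rank-sum with BH correction within the tested set.  Types with fewer
    than ``min_cells`` cells are skipped (recorded).  Genes attributed to
    more than ``max_memberships`` signatures are moved to the exclusion
    list and removed from every signature.
    """
    labels = pd.Series(np.asarray(labels, dtype=object), index=adata.obs_names)
    counts = labels.value_counts()
    eligible = [t for t in sorted(counts.index) if counts[t] >= min_cells]
    skipped = tuple(t for t in sorted(counts.index) if counts[t] < min_cells)
    if len(eligible) < 2:
        raise ValueError("need >= 2 label classes with enough cells to derive signatures")

    X = as_csr(adata.X)
    rows = []
    for t in eligible:
        mask = (labels == t).to_numpy()
        pct1, mean1 = _group_stats(X, mask)
        pct2, mean2 = _group_stats(X, ~mask)
        logfc = _log_fold_change(mean1, mean2)
        cand = (pct1 >= min_pct) & (logfc >= logfc_min)
        if not only_pos:
            cand |= (pct2 >= min_pct) & (-logfc >= logfc_min)
        idx = np.flatnonzero(cand)
        if idx.size == 0:
            continue
        X1 = as_dense(X[mask][:, idx])
        X2 = as_dense(X[~mask][:, idx])
        p = wilcoxon_rank_sum(X1, X2)
        q = multipletests(p, method="fdr_bh")[1]
        for pos in np.flatnonzero(q < fdr):
            j = idx[pos]
            rows.append((t, adata.var_names[j], logfc[j], pct1[j], pct2[j], q[pos]))
    markers = pd.DataFrame(rows, columns=["type", "gene", "logfc", "pct_in", "pct_out", "q"])

    membership = markers.groupby("gene")["type"].nunique()
    excluded = tuple(sorted(membership.index[membership > max_memberships]))
    markers = markers[~markers["gene"].isin(excluded)].reset_index(drop=True)
    return SignatureSet(
        markers=markers,
        excluded=excluded,
        skipped_types=skipped,
        thresholds={
            "logfc_min": logfc_min,
            "min_pct": min_pct,
            "fdr": fdr,
            "min_cells": min_cells,
            "max_memberships": max_memberships,
        },
    )


# ---------------------------------------------------------------------------
# Module scoring with binned controls


def bin_genes(avg_expr: np.ndarray, n_bins: int) -> np.ndarray:
    """Assign genes to ``n_bins`` near-equal-size bins of average expression."""
    order = rankdata(avg_expr, method="ordinal") - 1
    return (order * n_bins // len(avg_expr)).astype(int)


class _BinSampler:
    """Vectorised sampling of control genes from average-expression bins."""

    def __init__(self, bins: np.ndarray):
        self.bins = bins
        self.order = np.argsort(bins, kind="stable")
        n_bins = int(bins.max()) + 1
        self.count = np.bincount(bins, minlength=n_bins)
        self.start = np.concatenate([[0], np.cumsum(self.count)[:-1]])

    def draw(self, set_idx: np.ndarray, n_ctrl: int, rng: np.random.Generator) -> np.ndarray:
        """n_ctrl controls per set gene from that gene's bin, flattened.

        Without replacement when the bin holds at least n_ctrl genes, with
        replacement otherwise.
        """
        b = self.bins[set_idx]
        sizes = self.count[b]
        small = sizes < n_ctrl
        out = np.empty((set_idx.size, n_ctrl), dtype=int)
        if small.any():
            offs = np.floor(
                rng.random((int(small.sum()), n_ctrl)) * sizes[small][:, None]
            ).astype(int)
            out[small] = self.order[self.start[b[small]][:, None] + offs]
        for i in np.flatnonzero(~small):
            perm = rng.permutation(sizes[i])[:n_ctrl]
            out[i] = self.order[self.start[b[i]] + perm]
        return out.ravel()


def _score_weight_matrix(
    sets: list[np.ndarray],
    bins: np.ndarray,
    n_ctrl: int,
    rng: np.random.Generator,
    n_genes: int,
) -> sp.csc_matrix:
    """Sparse genes x n_sets weights so that scores = X @ W."""
    sampler = _BinSampler(bins)
    sizes = np.array([s.size for s in sets])
    all_set = np.concatenate(sets)
    ctrl = sampler.draw(all_set, n_ctrl, rng)  # row-major: n_ctrl per set gene
    set_cols = np.repeat(np.arange(len(sets)), sizes)
    rows = np.concatenate([all_set, ctrl])
    cols = np.concatenate([set_cols, np.repeat(set_cols, n_ctrl)])
    data = np.concatenate(
        [np.repeat(1.0 / sizes, sizes), np.repeat(-1.0 / (sizes * n_ctrl), sizes * n_ctrl)]
    )
    W = sp.coo_matrix((data, (rows, cols)), shape=(n_genes, len(sets)))
    return W.tocsc()


def score_sets(
    X,
    sets: list[np.ndarray],
    bins: np.ndarray,
    n_ctrl: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """Binned-control module scores (cells x sets) for many gene sets."""
    W = _score_weight_matrix(sets, bins, n_ctrl, rng, X.shape[1])
    res = X @ W
    if sp.issparse(res):
        res = res.todense()
    return np.asarray(res)


def module_score(
    adata: ad.AnnData,
    gene_set,
    n_bins: int = 25,
    n_ctrl: int = 100,
    seed: int = 0,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Per-cell module score for one gene set.

    Mean normalized expression of the set minus the mean over control genes
    drawn from each set gene's average-expression bin (``n_ctrl`` controls
    per set gene).  Deterministic under ``seed``.
    """
    present = [g for g in gene_set if g in adata.var_names]
    if not present:
        raise ValueError("gene_set is disjoint from the matrix genes")
    X = as_csr(adata.X)
    avg = np.asarray(X.mean(axis=0)).ravel()
    bins = bin_genes(avg, n_bins)
    lookup = {g: i for i, g in enumerate(adata.var_names)}
    set_idx = np.array([lookup[g] for g in present], dtype=int)
    if rng is None:
        rng = substream(seed, "module_score")
    return score_sets(X, [set_idx], bins, n_ctrl, rng)[:, 0]


# ---------------------------------------------------------------------------
# Monte-Carlo significance


def montecarlo_p(observed, null_scores) -> np.ndarray | float:
    """Add-one upper-tail Monte-Carlo p: (1 + #{null >= obs}) / (1 + n).

    ``null_scores`` may be a vector (shared null) or a matrix of shape
    (n_iter, n_obs) with one null column per observation.
    """
    obs = np.atleast_1d(np.asarray(observed, dtype=float))
    nulls = np.asarray(null_scores, dtype=float)
    if nulls.ndim == 1:
        counts = (nulls[:, None] >= obs[None, :]).sum(axis=0)
        n = nulls.shape[0]
    else:
        if nulls.shape[1] != obs.shape[0]:
            raise ValueError("null matrix columns must match observations")
        counts = (nulls >= obs[None, :]).sum(axis=0)
        n = nulls.shape[0]
    p = (1.0 + counts) / (1.0 + n)
    return float(p[0]) if np.isscalar(observed) or np.asarray(observed).ndim == 0 else p


def draw_null_sets(
    rng: np.random.Generator,
    n_iter: int,
    universe: np.ndarray,
    size: int,
) -> list[np.ndarray]:
    """Random same-size gene sets drawn uniformly from ``universe``.

    Implemented as the top-``size`` entries of i.i.d. random keys per row,
    which is uniform sampling without replacement.
    """
    keys = rng.random((n_iter, universe.size))
    idx = np.argpartition(keys, size - 1, axis=1)[:, :size]
    return [universe[row] for row in idx]


def null_score_matrix(
    X,
    bins: np.ndarray,
    set_idx: np.ndarray,
    n_iter: int,
    n_ctrl: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """Null module scores (n_iter x cells) for random sets of the same size.

    Null sets are drawn from all analyzed genes excluding the observed set.
    """
    universe = np.setdiff1d(np.arange(X.shape[1]), set_idx)
    sets = draw_null_sets(rng, n_iter, universe, set_idx.size)
    return score_sets(X, sets, bins, n_ctrl, rng).T


# ---------------------------------------------------------------------------
# Assignment


@dataclass
class ScoreTable:
    """Per-cell x per-type module scores with Monte-Carlo p and BH q."""

    scores: pd.DataFrame
    pvals: pd.DataFrame
    qvals: pd.DataFrame | None = None


def assign_types(score_table: ScoreTable, fdr: float = 0.05) -> pd.DataFrame:
    """Label each cell with its top-scoring significant type.

    BH is applied across each cell's candidate-type p-values; a cell is
    assigned iff its maximal score is positive, unique, and has q < fdr.
    Exact score ties leave the cell unannotated (logged).
    """
    scores = score_table.scores
    pvals = score_table.pvals.reindex(columns=scores.columns)
    q = pd.DataFrame(
        np.vstack([multipletests(row, method="fdr_bh")[1] for row in pvals.to_numpy()]),
        index=pvals.index,
        columns=pvals.columns,
    )
    score_table.qvals = q
    S = scores.to_numpy()
    best = np.argmax(S, axis=1)
    max_score = S[np.arange(len(S)), best]
    n_ties = (S == max_score[:, None]).sum(axis=1)
    best_q = q.to_numpy()[np.arange(len(S)), best]
    assigned = (max_score > 0) & (best_q < fdr) & (n_ties == 1)
    labels = np.where(assigned, np.array(scores.columns, dtype=object)[best], None)
    tied = (n_ties > 1) & (max_score > 0)
    for i in np.flatnonzero(tied):
        logger.info("cell %s: score tie, left unannotated", scores.index[i])
    return pd.DataFrame(
        {"label": labels, "score": max_score, "q": best_q, "tie": n_ties > 1},
        index=scores.index,
    )


# ---------------------------------------------------------------------------
# Full pipeline


@dataclass(frozen=True)
class AnnotationConfig:
    fdr: float = 0.05
    n_iter: int = 1000
    n_bins: int = 25
    n_ctrl: int = 100
    logfc_min: float = 1.0
    min_pct: float = 0.5
    min_cells: int = 10
    max_memberships: int = 2
    max_signature_genes: int = 50
    seed: int = 0


@dataclass
class AnnotationResult:
    """Final per-cell labels with provenance of the assigning stage."""

    table: pd.DataFrame  # index barcode; columns label, stage, rho, score
    signatures: SignatureSet | None = None
    reference: ReferenceProfileSet | None = None
    warnings: list[str] = field(default_factory=list)

    def to_tsv(self, path) -> None:
        out = self.table.copy()
        out.insert(0, "barcode", out.index)
        out.to_csv(path, sep="\t", index=False)


def _strip_query_suffix(name: str | None) -> str | None:
    if name is None:
        return None
    return name.split("__query", 1)[0]


def _signature_pass(
    norm: ad.AnnData,
    prelim_labels: pd.Series,
    cfg: AnnotationConfig,
    rng: np.random.Generator,
):
    """Signature derivation, scoring, Monte-Carlo p and assignment."""
    sigs = derive_signatures(
        norm,
        prelim_labels,
        logfc_min=cfg.logfc_min,
        min_pct=cfg.min_pct,
        fdr=cfg.fdr,
        min_cells=cfg.min_cells,
        max_memberships=cfg.max_memberships,
    )
    gene_sets = sigs.gene_sets()
    if not gene_sets:
        raise ValueError("no signatures passed the derivation thresholds")
    X = as_csr(norm.X)
    avg = np.asarray(X.mean(axis=0)).ravel()
    bins = bin_genes(avg, cfg.n_bins)
    lookup = {g: i for i, g in enumerate(norm.var_names)}

    score_cols, p_cols = {}, {}
    for t, genes in gene_sets.items():
        if cfg.max_signature_genes and len(genes) > cfg.max_signature_genes:
            top = (
                sigs.markers[sigs.markers["type"] == t]
                .nlargest(cfg.max_signature_genes, "logfc")["gene"]
                .tolist()
            )
            genes = top
        set_idx = np.array([lookup[g] for g in genes], dtype=int)
        obs = score_sets(X, [set_idx], bins, cfg.n_ctrl, rng)[:, 0]
        nulls = null_score_matrix(X, bins, set_idx, cfg.n_iter, cfg.n_ctrl, rng)
        p = montecarlo_p(obs, nulls)
        score_cols[t] = obs
        p_cols[t] = p
    table = ScoreTable(
        scores=pd.DataFrame(score_cols, index=norm.obs_names),
        pvals=pd.DataFrame(p_cols, index=norm.obs_names),
    )
    return assign_types(table, fdr=cfg.fdr), sigs, table


def annotate(
    query: ad.AnnData,
    reference: ReferenceProfileSet,
    config: AnnotationConfig | None = None,
) -> AnnotationResult:
    """Run the full two-iteration annotation pipeline on a query matrix.

    ``query`` must be log-normalized (see :func:`dbk.qc.lognormalize`) with
    raw counts in ``layers['counts']``.
    """
    cfg = config or AnnotationConfig()
    if not reference.type_names:
        raise ValueError("reference is empty")
    rng = substream(cfg.seed, "annotate")

    # iteration 1
    cm1 = correlation_match(query, reference)
    prelim1 = cm1["type"].map(_strip_query_suffix)
    assign1, sigs1, _ = _signature_pass(query, prelim1, cfg, rng)

    labels = assign1["label"].copy()
    stages = pd.Series(
        np.where(labels.notna(), "signature_iter1", None), index=labels.index, dtype=object
    )
    scores = assign1["score"].copy()
    rhos = cm1["rho"]
    warnings_list: list[str] = []
    sigs, ref2 = sigs1, reference

    if labels.isna().any():
        # iteration 2: augment the reference with the inferred type profiles
        assigned_mask = labels.notna()
        if assigned_mask.any():
            new_profiles = _type_mean_normalized(
                query[assigned_mask.to_numpy()], labels[assigned_mask]
            )
            new_profiles.columns = [f"{c}__query" for c in new_profiles.columns]
            ref2 = reference.append(new_profiles, provenance="query_iter1")
        cm2 = correlation_match(query, ref2)
        prelim2 = cm2["type"].map(_strip_query_suffix)
        assign2, sigs2, _ = _signature_pass(query, prelim2, cfg, rng)
        newly = assign2["label"].notna() & labels.isna()
        labels[newly] = assign2.loc[newly, "label"]
        stages[newly] = "signature_iter2"
        scores[newly] = assign2.loc[newly, "score"]
        sigs = sigs2

    unknown = labels.isna()
    labels[unknown] = UNKNOWN_LABEL
    stages[unknown] = UNKNOWN_LABEL
    if unknown.any():
        warnings_list.append(f"{int(unknown.sum())} cells labelled unknown")

    table = pd.DataFrame(
        {"label": labels, "stage": stages, "rho": rhos, "score": scores},
        index=query.obs_names,
    )
    return AnnotationResult(table=table, signatures=sigs, reference=ref2, warnings=warnings_list)


def refine_confusable(
    result: AnnotationResult,
    adata: ad.AnnData,
    confusable_types: list[str],
    marker_genes: list[str],
    n_clusters: int = 2,
    seed: int = 0,
    new_type: str = "refined_type",
    config: AnnotationConfig | None = None,
) -> AnnotationResult:
    """Recover a confusable type by subclustering and re-scoring.

    Cells labelled with any of ``confusable_types`` are clustered (k-means
    on the top-50-PC embedding of scaled normalized values).  The candidate
    cluster must exceed every other cluster in the mean expression of each
    marker gene (strict); its cells are re-scored with the candidate
    signature added and relabelled where assigned.
    """
    cfg = config or AnnotationConfig(seed=seed)
    missing = [t for t in confusable_types if t not in set(result.table["label"])]
    if missing:
        raise ValueError(f"confusable types absent from result: {missing}")
    present_markers = [g for g in marker_genes if g in adata.var_names]
    if not present_markers:
        warnings.warn("refine_confusable: no marker genes in matrix; result unchanged")
        return result

    mask = result.table["label"].isin(confusable_types).to_numpy()
    sub = adata[mask].copy()
    if n_clusters < 2 or sub.n_obs < n_clusters:
        warnings.warn("refine_confusable: no competing cluster; result unchanged")
        return result

    X = as_dense(sub.X)
    mu, sd = X.mean(axis=0), X.std(axis=0)
    sd[sd == 0] = 1.0
    Z = np.clip((X - mu) / sd, -10, 10)
    n_pc = min(50, Z.shape[0] - 1, Z.shape[1])
    emb = PCA(n_components=n_pc, random_state=int(seed) & 0x7FFFFFFF).fit_transform(Z)
    km = KMeans(n_clusters=n_clusters, n_init=10, random_state=int(seed) & 0x7FFFFFFF)
    clusters = km.fit_predict(emb)

    marker_idx = [list(sub.var_names).index(g) for g in present_markers]
    means = np.vstack([X[clusters == c][:, marker_idx].mean(axis=0) for c in range(n_clusters)])
    candidate = None
    for c in range(n_clusters):
        others = np.delete(np.arange(n_clusters), c)
        if np.all(means[c][None, :] > means[others]):
            candidate = c
            break
    if candidate is None:
        warnings.warn("refine_confusable: no cluster overexpresses all markers; result unchanged")
        return result

    sub_labels = result.table.loc[sub.obs_names, "label"].copy()
    sub_labels[clusters == candidate] = new_type
    rng = substream(cfg.seed, "refine")
    min_cells = min(cfg.min_cells, max(3, int((clusters == candidate).sum())))
    sub_cfg = replace(cfg, min_cells=min(cfg.min_cells, min_cells))
    assign, sigs, _ = _signature_pass(sub, sub_labels, sub_cfg, rng)

    new_table = result.table.copy()
    relabelled = assign["label"].notna()
    new_table.loc[assign.index[relabelled], "label"] = assign.loc[relabelled, "label"]
    new_table.loc[assign.index[relabelled], "stage"] = "refined"
    new_table.loc[assign.index[relabelled], "score"] = assign.loc[relabelled, "score"]
    return AnnotationResult(
        table=new_table,
        signatures=sigs,
        reference=result.reference,
        warnings=list(result.warnings),
    )
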