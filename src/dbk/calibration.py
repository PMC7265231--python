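"""Null-calibration utilities for the Monte-Carlo scoring machinery.

These generate exchangeable-null expression matrices (every gene i.i.d.
from one distribution) and measure how well the Monte-Carlo p-values and
the per-type stress flags keep their nominal error rates.  Used by the
test suite and the acceptance script; the quantities are recomputed from
scratch each run.
"""

from __future__ import annotations

import anndata as ad
import numpy as np
import pandas as pd
import scipy.sparse as sp

from . import genesets
from ._utils import substream
from .annotation import bin_genes, draw_null_sets, montecarlo_p, score_sets
from .qc import lognormalize
from .stats import stress_score_by_type


def exchangeable_null_matrix(
    n_cells: int,
    n_genes: int,
    seed: int,
    rate: float = 1.0,
    include_stress_names: bool = True,
) -> ad.AnnData:
    """Counts with every gene i.i.d. Poisson(rate): no structure at all.

    The first 17 genes carry the stress-set names (so the stress score can
    be computed) but are statistically identical to every other gene.
    """
    rng = substream(seed, "null_matrix")
    counts = rng.poisson(rate, size=(n_cells, n_genes))
    names = [f"null_gene{i + 1:05d}" for i in range(n_genes)]
    if include_stress_names:
        names[: len(genesets.STRESS_GENES)] = list(genesets.STRESS_GENES)
    adata = ad.AnnData(
        X=sp.csr_matrix(counts),
        obs=pd.DataFrame(index=[f"cell{i + 1:05d}" for i in range(n_cells)]),
        var=pd.DataFrame(index=pd.Index(names, name="gene_id")),
    )
    totals = np.asarray(adata.X.sum(axis=1)).ravel()
    adata = adata[totals > 0].copy()
    return lognormalize(adata)


def mc_pvalue_sample(
    adata: ad.AnnData,
    set_size: int = 17,
    n_reps: int = 2000,
    n_iter: int = 199,
    n_bins: int = 25,
    n_ctrl: int = 100,
    seed: int = 0,
) -> np.ndarray:
    """Monte-Carlo p-values for random observed sets under the null.

    Each replicate draws a random observed gene set, computes its
    cell-averaged module score, and compares it with a fresh null of
    ``n_iter`` random same-size sets.  Under exchangeability the returned
    p-values should be (discretely) uniform.

    Cell-averaged scoring is computed on the mean expression profile —
    identical to averaging per-cell scores, since the score is linear in
    expression.
    """
    X = adata.X
    mu = np.asarray(X.mean(axis=0)).reshape(1, -1)
    bins = bin_genes(mu.ravel(), n_bins)
    n_genes = mu.shape[1]
    rng = substream(seed, "mc_calibration")
    pvals = np.empty(n_reps)
    all_genes = np.arange(n_genes)
    for r in range(n_reps):
        obs_set = rng.choice(all_genes, size=set_size, replace=False)
        universe = np.setdiff1d(all_genes, obs_set)
        sets = [obs_set] + draw_null_sets(rng, n_iter, universe, set_size)
        scores = score_sets(mu, sets, bins, n_ctrl, rng)[0]
        pvals[r] = montecarlo_p(scores[0], scores[1:])
    return pvals


def ks_uniform_distance(pvals: np.ndarray) -> float:
    """Kolmogorov-Smirnov distance of a p-value sample from Uniform(0,1)."""
    from scipy.stats import kstest

    return float(kstest(pvals, "uniform").statistic)


def stress_flag_rate(
    n_reps: int = 2000,
    n_cells: int = 200,
    n_genes: int = 600,
    n_types: int = 4,
    n_iter: int = 999,
    alpha: float = 0.01,
    n_ctrl: int = 25,
    seed: int = 0,
) -> float:
    """Empirical per-type false-flag rate of the stress score under the null.

    Each replicate is a fresh exchangeable matrix with random type labels;
    the rate is the fraction of (replicate, type) pairs flagged at
    ``alpha`` and should be close to ``alpha``.  ``n_iter`` must be large
    enough that p-values below ``alpha`` are reachable (the Monte-Carlo p
    is quantized at 1/(n_iter+1)); 999 draws give a 0.001 grid.  The
    control count only affects score variance, not calibration, so a
    smaller ``n_ctrl`` keeps the study fast.
    """
    rng = substream(seed, "stress_flag_rate")
    n_flags = 0
    n_tests = 0
    for r in range(n_reps):
        sub_seed = int(rng.integers(2**31))
        adata = exchangeable_null_matrix(n_cells, n_genes, seed=sub_seed)
        labels = pd.Series(
            rng.integers(n_types, size=adata.n_obs).astype(str), index=adata.obs_names
        )
        table = stress_score_by_type(
            adata, labels, n_iter=n_iter, alpha=alpha, n_ctrl=n_ctrl, seed=sub_seed
        )
        n_flags += int(table["significant"].sum())
        n_tests += len(table)
    return n_flags / n_tests
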