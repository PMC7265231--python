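"""Internal helpers: seeded substreams and matrix coercion."""

from __future__ import annotations

import hashlib

import numpy as np
import scipy.sparse as sp


def substream(seed: int, stage: str) -> np.random.Generator:
    """Independent random generator for *stage*, derived from one root seed.

    Every stochastic stage draws from its own substream keyed by a stable
    hash of the stage name, so adding randomness to one stage never perturbs
    another and the whole pipeline is reproducible from a single seed.
    """
    digest = hashlib.blake2b(stage.encode(), digest_size=4).digest()
    key = int.from_bytes(digest, "little")
    return np.random.default_rng(np.random.SeedSequence([int(seed) & 0x7FFFFFFF, key]))


def as_dense(X) -> np.ndarray:
    """Return ``X`` as a dense float64 ndarray (cells x genes)."""
    if sp.issparse(X):
        return np.asarray(X.todense(), dtype=np.float64)
    return np.asarray(X, dtype=np.float64)


def as_csr(X) -> sp.csr_matrix:
    if sp.issparse(X):
        return X.tocsr()
    return sp.csr_matrix(np.asarray(X))
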