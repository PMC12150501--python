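"""Shared helpers: seed streams and symmetric-matrix packing."""

from __future__ import annotations

import numpy as np

# Fixed per-stage offsets so that one master seed yields independent,
# reproducible streams for every stage of the pipeline.
_STAGE_OFFSETS = {
    "panel": 11,
    "genotypes": 23,
    "effects": 37,
    "environment": 41,
    "cohorts": 53,
    "gwas": 61,
    "subsample": 71,
    "target": 83,
    "misc": 97,
}


def stage_rng(seed: int, stage: str, extra: int = 0) -> np.random.Generator:
    """Generator for a named pipeline stage derived from one master seed."""
    if stage not in _STAGE_OFFSETS:
        raise KeyError(f"unknown seed stage {stage!r}")
    ss = np.random.SeedSequence(entropy=int(seed), spawn_key=(_STAGE_OFFSETS[stage], int(extra)))
    return np.random.default_rng(ss)


def triu_index(k: int):
    """Row/column indices of the k(k+1)/2 unique elements, diagonal first ordering
    not required -- we use numpy's row-major upper triangle throughout."""
    return np.triu_indices(k)


def vech(mat: np.ndarray) -> np.ndarray:
    """Upper-triangle (incl. diagonal) of a symmetric matrix as a vector."""
    i, j = np.triu_indices(mat.shape[0])
    return np.asarray(mat)[i, j]


def unvech(v: np.ndarray, k: int) -> np.ndarray:
    """Inverse of :func:`vech`."""
    out = np.zeros((k, k), dtype=float)
    i, j = np.triu_indices(k)
    out[i, j] = v
    out[j, i] = v
    return out
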