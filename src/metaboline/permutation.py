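"""Permutation machinery: label-adjacency clustering score with a permuted
null, and cross-dataset per-feature concordance against a permuted-line
null. Small label multisets are enumerated exhaustively for exact p-values;
Monte-Carlo p-values carry +1 smoothing so they never reach zero.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sympy.utilities.iterables import multiset_permutations

from .activity import bh_adjust
from .types import FeatureMatrix, PreconditionError

__all__ = [
    "PermutationResult",
    "tissue_adjacency_score",
    "permutation_pvalue",
    "dataset_concordance",
]


@dataclass
class PermutationResult:
    observed: float
    p: float
    n_perm: int
    seed: int | None
    exhaustive: bool
    null_samples: np.ndarray | None = None


def tissue_adjacency_score(ordered_labels) -> int:
    """Number of adjacent positions holding the same label."""
    labels = list(ordered_labels)
    if len(labels) < 2:
        raise PreconditionError("need at least two labels")
    return sum(a == b for a, b in zip(labels, labels[1:]))


def _n_multiset_perms(labels) -> int:
    counts = Counter(labels)
    n = math.factorial(len(labels))
    for c in counts.values():
        n //= math.factorial(c)
    return n


def permutation_pvalue(
    observed_order,
    n_perm: int = 10_000,
    seed: int = 0,
    exhaustive_limit: int = 8,
) -> PermutationResult:
    """Upper-tail p of the adjacency score under label shuffling.

    All distinct multiset orderings are enumerated when their count is at
    most factorial(exhaustive_limit) (exact fraction); otherwise Monte
    Carlo with +1 smoothing.
    """
    labels = list(observed_order)
    if n_perm < 1:
        raise PreconditionError("n_perm must be >= 1")
    observed = tissue_adjacency_score(labels)
    if len(set(labels)) == 1:
        return PermutationResult(observed, 1.0, 0, seed, True)
    if _n_multiset_perms(labels) <= math.factorial(exhaustive_limit):
        null = np.array([tissue_adjacency_score(p) for p in multiset_permutations(sorted(labels))])
        p = float((null >= observed).mean())
        return PermutationResult(observed, p, len(null), None, True, null)
    rng = np.random.default_rng(int(seed))
    arr = np.array(labels, dtype=object)
    null = np.array([
        tissue_adjacency_score(rng.permutation(arr)) for _ in range(int(n_perm))
    ])
    p = (int((null >= observed).sum()) + 1) / (int(n_perm) + 1)
    return PermutationResult(observed, p, int(n_perm), int(seed), False, null)


def dataset_concordance(
    matrix_a: FeatureMatrix,
    matrix_b: FeatureMatrix,
    n_perm: int = 1000,
    seed: int = 0,
) -> pd.DataFrame:
    """Per-feature Pearson concordance between two cell-line-averaged matrices.

    The null permutes the cell-line assignment of the second matrix; the
    upper-tail p carries +1 smoothing and is BH-adjusted across features.
    """
    shared_lines = [l for l in matrix_a.sample_ids if l in set(matrix_b.sample_ids)]
    if len(shared_lines) < 5:
        raise PreconditionError("need >= 5 shared cell lines")
    shared_feats = [f for f in matrix_a.feature_ids if f in set(matrix_b.feature_ids)]
    if not shared_feats:
        raise PreconditionError("no shared features")
    A = matrix_a.data.loc[shared_lines, shared_feats].to_numpy(dtype=float)
    B = matrix_b.data.loc[shared_lines, shared_feats].to_numpy(dtype=float)

    def standardize(X: np.ndarray) -> np.ndarray:
        sd = X.std(axis=0, ddof=0)
        sd[sd == 0.0] = np.nan
        return (X - X.mean(axis=0)) / sd

    Za, Zb = standardize(A), standardize(B)
    n = len(shared_lines)
    observed = (Za * Zb).sum(axis=0) / n

    rng = np.random.default_rng(int(seed))
    exceed = np.zeros(len(shared_feats))
    for _ in range(int(n_perm)):
        perm = rng.permutation(n)
        null_r = (Za * Zb[perm]).sum(axis=0) / n
        exceed += null_r >= observed
    p = (exceed + 1.0) / (int(n_perm) + 1.0)
    out = pd.DataFrame({"r": observed, "p": p}, index=shared_feats)
    ok = out["r"].notna()
    out = out.loc[ok]
    out["p_adjusted"] = bh_adjust(out["p"].tolist())
    out.attrs["n_perm"] = int(n_perm)
    out.attrs["seed"] = int(seed)
    return out
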