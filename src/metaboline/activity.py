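"""Rank-based pathway activity statistics.

A cell line's pathway activity is summarized by the change in rank of the
pathway's member features between the line and the bulk (dataset-average)
ordering. Significance uses a minimum-hypergeometric (mHG) statistic over
ranked-list prefixes, calibrated by permutation (exact enumeration on
small instances) or a Bonferroni bound; over-representation analysis and
Benjamini-Hochberg adjustment live here too.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass
from functools import lru_cache

import numpy as np
import pandas as pd
from scipy.stats import hypergeom, linregress, rankdata

from .types import FeatureMatrix, PathwayDB, PreconditionError

logger = logging.getLogger(__name__)

__all__ = [
    "RankProfile",
    "ActivityMatrix",
    "EnrichmentResult",
    "compute_rank_profile",
    "scaled_rank_sum_threshold",
    "mhg_statistic",
    "min_hypergeometric",
    "pathway_activity",
    "doubling_time_regression",
    "ora",
    "bh_adjust",
]

#: enumerate the exact null whenever C(N, K) is at most this
EXHAUSTIVE_LIMIT = 20_000

_REL_TOL = 1.0 + 1e-9  # float slack when counting null stats <= observed


@dataclass
class RankProfile:
    bulk_rank: pd.Series  # feature -> rank, 1 = highest mean level
    per_sample_rank: pd.DataFrame  # cell line x feature
    delta: pd.DataFrame  # bulk_rank - per-sample rank


@dataclass
class ActivityMatrix:
    rank_sum_change: pd.DataFrame  # cell line x pathway
    pvalue: pd.DataFrame
    direction: pd.DataFrame  # "increased" | "decreased" | "none"
    flagged_pathways: list[str]
    n_features: int


@dataclass
class EnrichmentResult:
    pathway: str
    statistic: float  # -log10(p) x direction sign
    p_raw: float
    p_adjusted: float
    k_at_min: int
    direction: str = "none"


def scaled_rank_sum_threshold(
    n_features: int, base: float = 350.0, reference_n_features: int = 1099
) -> float:
    """Direction-coloring cutoff, scaled linearly from its reference feature count."""
    return base * n_features / reference_n_features


def compute_rank_profile(matrix: FeatureMatrix) -> RankProfile:
    """Bulk and per-cell-line descending ranks (average ranks on ties)."""
    if matrix.n_features < 2:
        raise PreconditionError("rank profile needs at least two features")
    vals = matrix.data.astype(float)
    bulk = pd.Series(rankdata(-vals.mean(axis=0)), index=vals.columns)
    per = pd.DataFrame(
        rankdata(-vals.to_numpy(), axis=1), index=vals.index, columns=vals.columns
    )
    if (per.nunique(axis=1) == 1).any():
        logger.warning("cell line with all-tied feature values: average ranks used")
    delta = per.rsub(bulk, axis=1)  # bulk_rank - per-sample rank
    return RankProfile(bulk_rank=bulk, per_sample_rank=per, delta=delta)


@lru_cache(maxsize=256)
def _tail_table(N: int, K: int) -> np.ndarray:
    """T[j-1, n-1] = P(X >= j) for X ~ Hypergeom(N, K, n)."""
    j = np.arange(1, K + 1)[:, None]
    n = np.arange(1, N + 1)[None, :]
    return hypergeom.sf(j - 1, N, K, n)


def _stat_from_positions(positions: np.ndarray, table: np.ndarray) -> np.ndarray:
    """mHG statistic for sorted member positions (1-based), vectorized.

    ``positions`` has shape (..., K); the statistic is the minimum over j of
    the hypergeometric tail at prefix length positions[j].
    """
    K = positions.shape[-1]
    jidx = np.arange(K)
    return table[jidx, positions - 1].min(axis=-1)


def mhg_statistic(ranked_flags) -> tuple[float, int]:
    """Minimum over prefixes of the hypergeometric upper tail; returns (s, k_at_min)."""
    flags = np.asarray(ranked_flags, dtype=bool)
    N, K = flags.size, int(flags.sum())
    if K == 0:
        raise PreconditionError("no member flags in the ranked list")
    table = _tail_table(N, K)
    positions = np.flatnonzero(flags) + 1
    vals = table[np.arange(K), positions - 1]
    jmin = int(np.argmin(vals))
    return float(vals[jmin]), int(positions[jmin])


def min_hypergeometric(
    ranked_flags,
    calibration: str = "permutation",
    n_perm: int = 1000,
    seed: int = 0,
) -> tuple[float, float]:
    """mHG statistic plus a calibrated p-value.

    ``permutation``: share of random K-subsets of ranks attaining s' <= s
    (+1 smoothing; exact enumeration when C(N, K) <= EXHAUSTIVE_LIMIT).
    ``bonferroni``: min(1, s x number of informative prefixes).
    """
    flags = np.asarray(ranked_flags, dtype=bool)
    if flags.size == 0:
        raise PreconditionError("empty ranked list")
    N, K = flags.size, int(flags.sum())
    if K == 0:
        raise PreconditionError("pathway has no members in the ranked list")
    s, _ = mhg_statistic(flags)
    if K == N:
        return s, 1.0
    if calibration == "bonferroni":
        return s, min(1.0, s * K)
    if calibration != "permutation":
        raise ValueError(f"unknown calibration {calibration!r}")
    table = _tail_table(N, K)
    if math.comb(N, K) <= EXHAUSTIVE_LIMIT:
        hits = total = 0
        for combo in itertools.combinations(range(1, N + 1), K):
            total += 1
            if _stat_from_positions(np.array(combo), table) <= s * _REL_TOL:
                hits += 1
        return s, hits / total
    rng = np.random.default_rng(int(seed))
    # random K-subsets of 1..N via partial permutations
    draws = rng.random((int(n_perm), N)).argpartition(K - 1, axis=1)[:, :K]
    draws = np.sort(draws, axis=1) + 1
    null = _stat_from_positions(draws, table)
    hits = int((null <= s * _REL_TOL).sum())
    return s, (hits + 1) / (int(n_perm) + 1)


def _direction_pvalue(
    delta_row: pd.Series,
    member_mask: np.ndarray,
    calibration: str,
    n_perm: int,
    seed: int,
) -> tuple[float, str]:
    """Smaller of the increase/decrease mHG p-values with its direction."""
    order_inc = np.argsort(-delta_row.to_numpy(), kind="stable")
    flags_inc = member_mask[order_inc]
    _, p_inc = min_hypergeometric(flags_inc, calibration, n_perm, seed)
    _, p_dec = min_hypergeometric(flags_inc[::-1], calibration, n_perm, seed + 1)
    if p_inc <= p_dec:
        return p_inc, "increased"
    return p_dec, "decreased"


def pathway_activity(
    matrix: FeatureMatrix,
    db: PathwayDB,
    alpha: float = 0.05,
    min_frac_significant: float = 0.40,
    rank_sum_threshold: float = 350.0,
    reference_n_features: int = 1099,
    calibration: str = "permutation",
    n_perm: int = 300,
    seed: int = 0,
) -> ActivityMatrix:
    """Per (cell line, pathway) rank-sum change, p-value and direction.

    The direction-coloring cutoff ``rank_sum_threshold`` is calibrated to a
    reference feature count and scaled linearly to the measured one.
    """
    profile = compute_rank_profile(matrix)
    measured = set(matrix.feature_ids)
    usable = db.restricted(measured, min_size=3)
    for name in set(db.pathways) - set(usable.pathways):
        logger.info("dropped_pathway pathway=%s reason=fewer_than_3_measured_members", name)
    if not usable.pathways:
        raise PreconditionError("no pathway retains >= 3 measured members")

    features = list(matrix.feature_ids)
    col_index = {f: i for i, f in enumerate(features)}
    masks = {
        name: np.isin(np.arange(len(features)), [col_index[m] for m in members])
        for name, members in usable.pathways.items()
    }
    lines = matrix.sample_ids
    names = list(usable.pathways)
    rsc = pd.DataFrame(0.0, index=lines, columns=names)
    pvals = pd.DataFrame(1.0, index=lines, columns=names)
    dirs = pd.DataFrame("none", index=lines, columns=names, dtype=object)

    threshold = scaled_rank_sum_threshold(matrix.n_features, rank_sum_threshold, reference_n_features)
    for i, line in enumerate(lines):
        drow = profile.delta.loc[line]
        dvals = drow.to_numpy()
        for name in names:
            mask = masks[name]
            rsc.at[line, name] = float(dvals[mask].sum())
            p, direction = _direction_pvalue(
                drow, mask, calibration, n_perm, seed + 7919 * i
            )
            pvals.at[line, name] = p
            if p < alpha and abs(rsc.at[line, name]) > threshold:
                dirs.at[line, name] = direction

    frac_sig = (pvals < alpha).mean(axis=0)
    flagged = sorted(frac_sig.index[frac_sig >= min_frac_significant])
    return ActivityMatrix(
        rank_sum_change=rsc,
        pvalue=pvals,
        direction=dirs,
        flagged_pathways=flagged,
        n_features=matrix.n_features,
    )


def doubling_time_regression(activity: ActivityMatrix, meta: pd.DataFrame) -> pd.DataFrame:
    """OLS of doubling time on rank-sum change, per pathway, BH-adjusted."""
    dt = meta.groupby("cell_line")["doubling_time"].first()
    lines = [l for l in activity.rank_sum_change.index if l in dt.index and np.isfinite(dt[l])]
    if len(lines) < 5:
        raise PreconditionError("need >= 5 cell lines with doubling times")
    y = dt.loc[lines].to_numpy(dtype=float)
    rows = {}
    for pw in activity.rank_sum_change.columns:
        x = activity.rank_sum_change.loc[lines, pw].to_numpy(dtype=float)
        if np.ptp(x) == 0.0:
            logger.info("skipped_pathway pathway=%s reason=constant_rank_sum_change", pw)
            continue
        fit = linregress(x, y)
        p = fit.pvalue if fit.pvalue > 0 else np.nextafter(0.0, 1.0)
        rows[pw] = dict(slope=fit.slope, r=fit.rvalue, p=p)
    out = pd.DataFrame(rows).T
    if out.empty:
        return out
    out["p_adjusted"] = bh_adjust(out["p"].tolist())
    return out.sort_values("p", kind="stable")


def ora(selection, db: PathwayDB, universe) -> list[EnrichmentResult]:
    """Hypergeometric over-representation of a selection against each pathway."""
    selection = set(selection)
    universe = set(universe)
    if not selection:
        raise PreconditionError("empty selection")
    if not selection <= universe:
        raise PreconditionError("selection must be a subset of the universe")
    N, n = len(universe), len(selection)
    results = []
    for name, members in db.pathways.items():
        mem = set(members) & universe
        if not mem:
            continue
        K, k = len(mem), len(mem & selection)
        p = float(hypergeom.sf(k - 1, N, K, n))
        p = min(max(p, np.nextafter(0.0, 1.0)), 1.0)
        results.append(EnrichmentResult(name, -math.log10(p), p, p, k))
    results.sort(key=lambda r: (r.p_raw, r.pathway))
    adj = bh_adjust([r.p_raw for r in results])
    for r, a in zip(results, adj):
        r.p_adjusted = a
    return results


def bh_adjust(pvalues) -> list[float]:
    """Benjamini-Hochberg step-up adjustment, capped at 1."""
    p = np.asarray(list(pvalues), dtype=float)
    if p.size == 0:
        return []
    if np.any((p <= 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in (0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    scaled = p[order] * m / np.arange(1, m + 1)
    adjusted = np.minimum.accumulate(scaled[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(adjusted, 1.0)
    return out.tolist()
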