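"""Score-metabolite correlation and pathway enrichment.

Continuous per-cell-line scores (transcriptional-program activity, TF
activity, drug ln IC50) are correlated with metabolite levels; pathways
are tested by ranking features on |r| and applying the minimum
hypergeometric statistic, signed by the mean member correlation. Drug
profiles over pathways support anticorrelation ranking and overlay with
known synergies.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .activity import EnrichmentResult, bh_adjust, min_hypergeometric
from .types import FeatureMatrix, PathwayDB, PreconditionError

logger = logging.getLogger(__name__)

__all__ = [
    "DrugPathwayProfile",
    "metabolite_score_correlation",
    "pathway_score_enrichment",
    "drug_pathway_profiles",
    "drug_pair_anticorrelation",
    "synergy_overlay",
]


@dataclass
class DrugPathwayProfile:
    signed_stat: pd.DataFrame  # drug x pathway, -log10(p_adjusted) x direction
    p_adjusted: pd.DataFrame


def metabolite_score_correlation(
    matrix: FeatureMatrix, scores: pd.DataFrame, score_name: str, min_lines: int = 5
) -> pd.Series:
    """Pearson r of each feature against one score over overlapping lines."""
    if score_name not in scores.columns:
        raise PreconditionError(f"unknown score {score_name!r}")
    s = scores[score_name].dropna()
    shared = [l for l in matrix.sample_ids if l in s.index]
    if len(shared) < min_lines:
        raise PreconditionError(f"fewer than {min_lines} overlapping cell lines")
    sv = s.loc[shared].to_numpy(dtype=float)
    if np.ptp(sv) == 0.0:
        raise PreconditionError("constant score")
    X = matrix.data.loc[shared].to_numpy(dtype=float)
    xc = X - X.mean(axis=0)
    sc = sv - sv.mean()
    denom = np.sqrt((xc**2).sum(axis=0) * (sc**2).sum())
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (xc * sc[:, None]).sum(axis=0) / denom
    out = pd.Series(r, index=matrix.feature_ids)
    dropped = out.index[~np.isfinite(out)]
    for f in dropped:
        logger.info("skipped_feature feature=%s reason=zero_variance", f)
    return out.dropna()


def pathway_score_enrichment(
    correlations: pd.Series,
    db: PathwayDB,
    calibration: str = "permutation",
    n_perm: int = 1000,
    seed: int = 0,
) -> list[EnrichmentResult]:
    """Rank features by |r| descending and score each pathway by mHG.

    The direction is the sign of the mean member correlation; the reported
    statistic is -log10(p_adjusted) x that sign.
    """
    usable = db.restricted(set(correlations.index), min_size=3)
    if not usable.pathways:
        raise PreconditionError("no pathway with >= 3 measured members")
    absr = correlations.abs()
    order = sorted(correlations.index, key=lambda f: (-absr[f], f))
    pos = {f: i for i, f in enumerate(order)}
    all_zero = bool((absr == 0.0).all())

    results = []
    for i, (name, members) in enumerate(sorted(usable.pathways.items())):
        mean_r = float(correlations[list(members)].mean())
        sign = 1.0 if mean_r > 0 else (-1.0 if mean_r < 0 else 0.0)
        if all_zero:
            results.append(EnrichmentResult(name, 0.0, 1.0, 1.0, 0, "none"))
            continue
        flags = np.zeros(len(order), dtype=bool)
        flags[[pos[m] for m in members]] = True
        _, p = min_hypergeometric(flags, calibration, n_perm, seed + i)
        results.append(EnrichmentResult(name, 0.0, p, p, int(flags.sum()), _dir(sign)))
    adj = bh_adjust([r.p_raw for r in results])
    for r, a in zip(results, adj):
        r.p_adjusted = a
        s = 1.0 if r.direction == "increased" else (-1.0 if r.direction == "decreased" else 0.0)
        r.statistic = -math.log10(max(a, np.nextafter(0.0, 1.0))) * s
    results.sort(key=lambda r: (r.p_raw, r.pathway))
    return results


def _dir(sign: float) -> str:
    return "increased" if sign > 0 else ("decreased" if sign < 0 else "none")


def drug_pathway_profiles(
    matrix: FeatureMatrix,
    drugs: pd.DataFrame,
    db: PathwayDB,
    calibration: str = "permutation",
    n_perm: int = 1000,
    seed: int = 0,
    min_lines: int = 5,
) -> DrugPathwayProfile:
    """Signed pathway-association profile per drug.

    Positive signed statistics mean higher pathway member levels associate
    with higher ln(IC50), i.e. resistance; negative with sensitivity.
    """
    stat_rows, p_rows = {}, {}
    for drug in drugs.columns:
        try:
            corr = metabolite_score_correlation(matrix, drugs, drug, min_lines=min_lines)
        except PreconditionError as exc:
            logger.info("skipped_drug drug=%s reason=%s", drug, exc)
            continue
        # common random numbers across drugs: identical |r| rankings give
        # identical calibrated p-values (keeps negated-drug profiles exact mirrors)
        enr = pathway_score_enrichment(corr, db, calibration, n_perm, seed)
        stat_rows[drug] = {r.pathway: r.statistic for r in enr}
        p_rows[drug] = {r.pathway: r.p_adjusted for r in enr}
    if not stat_rows:
        raise PreconditionError("no drug could be profiled")
    return DrugPathwayProfile(
        signed_stat=pd.DataFrame(stat_rows).T.sort_index(),
        p_adjusted=pd.DataFrame(p_rows).T.sort_index(),
    )


def drug_pair_anticorrelation(profiles: DrugPathwayProfile) -> pd.DataFrame:
    """Pearson r between drugs' signed pathway vectors, most anticorrelated first."""
    mat = profiles.signed_stat
    if mat.shape[1] < 3:
        raise PreconditionError("need >= 3 shared pathways")
    keep = [d for d in mat.index if np.ptp(mat.loc[d].to_numpy(dtype=float)) > 0.0]
    for d in set(mat.index) - set(keep):
        logger.info("skipped_drug drug=%s reason=constant_profile", d)
    rows = []
    for i, a in enumerate(keep):
        for b in keep[i + 1:]:
            r = float(np.corrcoef(mat.loc[a], mat.loc[b])[0, 1])
            rows.append((a, b, r))
    out = pd.DataFrame(rows, columns=["drug_a", "drug_b", "profile_r"])
    return out.sort_values(["profile_r", "drug_a", "drug_b"], kind="stable").reset_index(drop=True)


def synergy_overlay(
    anticorrelations: pd.DataFrame,
    synergies: pd.DataFrame,
    calibration: str = "permutation",
    n_perm: int = 2000,
    seed: int = 0,
) -> tuple[pd.DataFrame, float]:
    """Join known synergies onto profiled pairs; mHG enrichment of synergy
    flags down the ascending-correlation ranking (strict ZIP > 0 rule)."""
    known = {}
    for _, row in synergies.iterrows():
        known[frozenset((row["drug_a"], row["drug_b"]))] = float(row["zip_score"])
    table = anticorrelations.copy()
    zips = [known.get(frozenset((a, b))) for a, b in zip(table["drug_a"], table["drug_b"])]
    table["zip_score"] = zips
    table["known_synergy"] = [z is not None and z > 0 for z in zips]
    if not any(z is not None for z in zips):
        raise PreconditionError("no overlap between synergy table and profiled drug pairs")
    flags = table["known_synergy"].to_numpy(dtype=bool)
    if not flags.any():
        return table, 1.0
    _, p = min_hypergeometric(flags, calibration, n_perm, seed)
    return table, p
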