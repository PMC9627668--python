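"""Normalization and quality control.

The chain mirrors a replicate-structured untargeted metabolomics workflow:
replicate-ROC reproducibility metric, per-feature Lowess injection-order
correction, removal of low-intensity injections, confluency correction of
total intensity, an ANOVA-driven batch/plate feature filter tuned by the
replicate AUC, z-scoring, and biological-replicate averaging.

Corrections operate on natural-log intensities and are exponentiated back;
ROC distances use log10 intensities.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist
from scipy.stats import f_oneway, rankdata
from statsmodels.nonparametric.smoothers_lowess import lowess

from .types import FeatureMatrix, PreconditionError, Stage, meta_for

logger = logging.getLogger(__name__)

__all__ = [
    "QCReport",
    "replicate_roc_auc",
    "correct_injection_drift",
    "drop_low_intensity_injections",
    "correct_confluency",
    "batch_plate_filter",
    "zscore_features",
    "average_biological_replicates",
    "normalize_pipeline",
]


@dataclass
class QCReport:
    auc_technical: float = float("nan")
    auc_biological: float = float("nan")
    removed_injections: list = field(default_factory=list)
    removed_features: list = field(default_factory=list)
    anova_pvalues: pd.DataFrame | None = None
    sweep_curve: list = field(default_factory=list)  # (n_removed, auc_biological)


def _pair_labels(meta: pd.DataFrame, level: str) -> tuple[np.ndarray, np.ndarray]:
    """Condensed-form boolean masks (positive pairs, negative pairs).

    Positive pairs are replicate pairs at the requested level; negative
    pairs are samples of different cell lines.
    """
    line = meta["cell_line"].to_numpy()
    bio = meta["bio_rep"].to_numpy()
    n = len(line)
    iu, ju = np.triu_indices(n, k=1)
    same_line = line[iu] == line[ju]
    same_bio = bio[iu] == bio[ju]
    if level == "technical":
        pos = same_line & same_bio
    elif level == "biological":
        pos = same_line & ~same_bio
    else:
        raise ValueError(f"unknown replicate level {level!r}")
    neg = ~same_line
    return pos, neg


def replicate_roc_auc(matrix: FeatureMatrix, meta: pd.DataFrame, level: str) -> float:
    """AUC of "smaller Euclidean distance => replicate pair" at the given level.

    Distances are computed on log10 intensities; tied distances contribute
    0.5, i.e. the Mann-Whitney AUC.
    """
    if matrix.n_samples < 2:
        raise PreconditionError("need at least two samples")
    m = meta_for(meta, matrix)
    pos, neg = _pair_labels(m, level)
    if not pos.any() or not neg.any():
        raise PreconditionError(f"no {'positive' if not pos.any() else 'negative'} pairs at level {level!r}")
    d = pdist(np.log10(matrix.data.to_numpy(dtype=float)))
    dp, dn = d[pos], d[neg]
    # AUC = P(dp < dn) + 0.5 P(dp == dn) via midranks
    ranks = rankdata(np.concatenate([dp, dn]))
    n1, n2 = len(dp), len(dn)
    u = n1 * n2 + n1 * (n1 + 1) / 2.0 - ranks[:n1].sum()
    return float(u / (n1 * n2))


def _lowess_fit(y: np.ndarray, x: np.ndarray, span: float, it: int = 2) -> np.ndarray:
    """Lowess fitted values aligned to the input order (x need not be sorted)."""
    fitted = lowess(y, x, frac=span, it=it, return_sorted=False)
    return np.asarray(fitted, dtype=float)


def correct_injection_drift(matrix: FeatureMatrix, meta: pd.DataFrame, span: float = 0.3) -> FeatureMatrix:
    """Remove the injection-order trend of each feature independently.

    Per feature, a Lowess curve of log-intensity vs injection index is
    subtracted and the feature re-centered to its pre-correction mean.
    """
    if matrix.n_samples < 10:
        raise PreconditionError("fewer than 10 injections: trend not estimable")
    if not 0 < span <= 1:
        raise ValueError("span must lie in (0, 1]")
    m = meta_for(meta, matrix)
    x = m["injection_index"].to_numpy(dtype=float)
    logv = matrix.log().to_numpy()
    out = np.empty_like(logv)
    for j in range(logv.shape[1]):
        y = logv[:, j]
        if np.ptp(y) == 0.0:
            out[:, j] = y  # constant feature: nothing to correct
            continue
        fitted = _lowess_fit(y, x, span)
        out[:, j] = y - fitted + y.mean()
    return matrix.with_data(
        pd.DataFrame(np.exp(out), index=matrix.data.index, columns=matrix.data.columns),
        Stage.drift_corrected,
    )


def drop_low_intensity_injections(
    matrix: FeatureMatrix, threshold_log2_sum: float = 25.0
) -> tuple[FeatureMatrix, list]:
    """Drop samples whose log2 total ion intensity falls below the threshold."""
    if matrix.stage not in (Stage.raw, Stage.drift_corrected):
        raise PreconditionError("expects a raw or drift-corrected matrix")
    totals = matrix.data.sum(axis=1)
    low = totals[np.log2(totals) < threshold_log2_sum].index.tolist()
    if len(low) == matrix.n_samples:
        raise PreconditionError("threshold removes every sample")
    kept = matrix.data.drop(index=low)
    for s in low:
        logger.info("dropped_injection sample=%s reason=low_total_intensity", s)
    return matrix.with_data(kept), low


def correct_confluency(matrix: FeatureMatrix, meta: pd.DataFrame, span: float = 0.6) -> FeatureMatrix:
    """Rescale each sample so total intensity is confluency-independent.

    A Lowess fit of per-sample log total intensity vs confluency provides a
    multiplicative factor that is divided out (total-intensity geometric
    mean preserved).
    """
    if matrix.n_samples < 5:
        raise PreconditionError("too few samples for confluency smoothing")
    m = meta_for(meta, matrix)
    conf = m["confluency"].to_numpy(dtype=float)
    if np.ptp(conf) == 0.0:
        logger.warning("constant confluency: correction is the identity")
        return matrix.with_data(matrix.data.copy(), Stage.confluency_corrected)
    log_total = np.log(matrix.data.sum(axis=1).to_numpy(dtype=float))
    fitted = _lowess_fit(log_total, conf, span)
    factor = fitted - fitted.mean()
    corrected = matrix.data.to_numpy(dtype=float) * np.exp(-factor)[:, None]
    return matrix.with_data(
        pd.DataFrame(corrected, index=matrix.data.index, columns=matrix.data.columns),
        Stage.confluency_corrected,
    )


def _anova_pvalues(matrix: FeatureMatrix, meta: pd.DataFrame) -> pd.DataFrame:
    m = meta_for(meta, matrix)
    logv = matrix.log()
    out = {}
    for effect in ("batch", "plate"):
        groups = m[effect].to_numpy()
        uniq = np.unique(groups)
        if len(uniq) < 2:
            out[f"p_{effect}"] = np.ones(matrix.n_features)
            continue
        chunks = [logv.to_numpy()[groups == g] for g in uniq]
        with np.errstate(invalid="ignore", divide="ignore"):
            stat = f_oneway(*chunks, axis=0)
        p = np.asarray(stat.pvalue, dtype=float)
        out[f"p_{effect}"] = np.where(np.isfinite(p), p, 1.0)
    return pd.DataFrame(out, index=matrix.feature_ids)


def _sweep_grid(max_remove: int, dense_to: int = 50, step: int = 5) -> list[int]:
    grid = list(range(0, min(dense_to, max_remove) + 1))
    grid += list(range(dense_to + step, max_remove + 1, step))
    if grid[-1] != max_remove:
        grid.append(max_remove)
    return grid


def batch_plate_filter(
    matrix: FeatureMatrix, meta: pd.DataFrame, max_remove: int
) -> tuple[FeatureMatrix, QCReport]:
    """Remove the batch/plate-associated features that maximize biological AUC.

    Features are ranked by min(ANOVA p for batch, ANOVA p for plate)
    ascending; candidate removal counts on a fixed grid are scored by the
    biological replicate AUC of the reduced matrix; the AUC-maximizing
    count wins (ties -> smallest count).
    """
    if max_remove >= matrix.n_features:
        raise PreconditionError("max_remove must be smaller than the feature count")
    m = meta_for(meta, matrix)
    if m["batch"].nunique() < 2 and m["plate"].nunique() < 2:
        raise PreconditionError("need at least 2 batches or 2 plates")
    pvals = _anova_pvalues(matrix, meta)
    order = pvals.min(axis=1).sort_values(kind="stable").index.tolist()

    sweep = []
    best_auc, best_count = -np.inf, 0
    for count in _sweep_grid(int(max_remove)):
        reduced = matrix.with_data(matrix.data.drop(columns=order[:count]))
        auc = replicate_roc_auc(reduced, meta, "biological")
        sweep.append((count, auc))
        if auc > best_auc:
            best_auc, best_count = auc, count

    removed = order[:best_count]
    filtered = matrix.with_data(matrix.data.drop(columns=removed), Stage.filtered)
    report = QCReport(
        auc_technical=replicate_roc_auc(filtered, meta, "technical"),
        auc_biological=best_auc,
        removed_features=removed,
        anova_pvalues=pvals,
        sweep_curve=sweep,
    )
    for f in removed:
        logger.info("dropped_feature feature=%s reason=batch_plate_anova", f)
    return filtered, report


def zscore_features(matrix: FeatureMatrix) -> FeatureMatrix:
    """Per-feature z-score (sample SD, ddof=1); zero-variance features dropped."""
    if matrix.n_samples < 2:
        raise PreconditionError("z-scoring needs at least two samples")
    vals = matrix.data.astype(float)
    sd = vals.std(axis=0, ddof=1)
    dropped = sd.index[sd == 0.0].tolist()
    for f in dropped:
        logger.warning("dropped_feature feature=%s reason=zero_variance", f)
    keep = sd.index[sd > 0.0]
    z = (vals[keep] - vals[keep].mean(axis=0)) / sd[keep]
    return matrix.with_data(z, Stage.zscored)


def average_biological_replicates(matrix: FeatureMatrix, meta: pd.DataFrame) -> FeatureMatrix:
    """Collapse to one row per cell line: tech reps averaged within bio rep,
    then bio reps averaged with equal weight."""
    m = meta_for(meta, matrix)
    joined = matrix.data.join(m[["cell_line", "bio_rep"]])
    per_bio = joined.groupby(["cell_line", "bio_rep"], sort=True).mean(numeric_only=True)
    per_line = per_bio.groupby(level="cell_line", sort=True).mean()
    per_line = per_line[matrix.data.columns]
    return matrix.with_data(per_line, Stage.cellline_avg)


def normalize_pipeline(
    matrix: FeatureMatrix,
    meta: pd.DataFrame,
    drift_span: float = 0.3,
    confluency_span: float = 0.6,
    low_intensity_threshold: float = 25.0,
    max_remove: int | None = None,
) -> tuple[FeatureMatrix, QCReport]:
    """Full chain: drift -> low-intensity removal -> confluency -> batch filter."""
    m1 = correct_injection_drift(matrix, meta, span=drift_span)
    m2, removed_inj = drop_low_intensity_injections(m1, low_intensity_threshold)
    m3 = correct_confluency(m2, meta, span=confluency_span)
    if max_remove is None:
        max_remove = min(50, matrix.n_features - 1)
    m4, report = batch_plate_filter(m3, meta, max_remove=max_remove)
    report.removed_injections = removed_inj
    return m4, report
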