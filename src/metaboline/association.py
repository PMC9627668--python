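"""Mutation-metabolite association with tissue control.

Per (gene, feature) pair, an ordinary-least-squares fit of the z-scored
feature level on a mutation indicator plus one-hot tissue covariates (one
reference tissue dropped) yields the mutation coefficient's T-statistic.
Fits are vectorized across features for each gene's design matrix.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .activity import bh_adjust
from .types import FeatureMatrix, MutationTable, PreconditionError, MISSING, MUTANT, WT

logger = logging.getLogger(__name__)

__all__ = [
    "AssociationMatrix",
    "association_tstats",
    "tissue_specific_tstats",
    "cross_tissue_heterogeneity",
    "differential_metabolites",
    "rank_genes_for_metabolite",
]


@dataclass
class AssociationMatrix:
    tstat: pd.DataFrame  # gene x feature
    pvalue: pd.DataFrame
    n_mut: pd.Series
    n_wt: pd.Series
    scope: str = "all tissues"
    skipped: dict[str, str] = field(default_factory=dict)


def _fit_gene(
    y: np.ndarray, mut: np.ndarray, tissue_dummies: np.ndarray | None
) -> tuple[np.ndarray, np.ndarray] | None:
    """T and p of the mutation coefficient for every feature column of ``y``.

    Returns None when the design is rank deficient (mutation collinear with
    a tissue dummy, or a constant column).
    """
    n = y.shape[0]
    cols = [np.ones(n), mut.astype(float)]
    if tissue_dummies is not None and tissue_dummies.size:
        cols.extend(tissue_dummies.T)
    X = np.column_stack(cols)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        return None
    df = n - X.shape[1]
    if df < 1:
        return None
    xtx_inv = np.linalg.inv(X.T @ X)
    beta = xtx_inv @ (X.T @ y)
    resid = y - X @ beta
    sigma2 = (resid**2).sum(axis=0) / df
    with np.errstate(divide="ignore", invalid="ignore"):
        se = np.sqrt(sigma2 * xtx_inv[1, 1])
        t = beta[1] / se
    t = np.where(np.isfinite(t), t, np.nan)
    p = 2.0 * stats.t.sf(np.abs(t), df)
    return t, p


def association_tstats(
    matrix: FeatureMatrix,
    muts: MutationTable,
    meta: pd.DataFrame,
    gene_list=None,
    min_group: int = 3,
    include_tissue: bool = True,
    scope: str = "all tissues",
) -> AssociationMatrix:
    """Covariate-adjusted mutation T-statistics for every (gene, feature).

    Cell lines with missing mutation status are excluded per gene; genes
    with fewer than ``min_group`` mutant or wild-type lines are skipped.
    ``include_tissue=False`` omits the tissue dummies (single-tissue fits).
    """
    lines = [l for l in matrix.sample_ids if l in muts.status.index]
    if len(lines) < 2 * min_group:
        raise PreconditionError("too few cell lines with mutation calls")
    genes = list(gene_list) if gene_list is not None else muts.genes
    line_tissue = meta.groupby("cell_line")["tissue"].first().reindex(lines)
    Y_all = matrix.data.loc[lines].to_numpy(dtype=float)
    features = matrix.feature_ids

    tstat, pval, nmut, nwt, skipped = {}, {}, {}, {}, {}
    for gene in genes:
        calls = muts.status[gene].reindex(lines)
        keep = (calls == MUTANT) | (calls == WT)
        mut = (calls[keep] == MUTANT).to_numpy()
        n_mut, n_wt = int(mut.sum()), int((~mut).sum())
        if n_mut < min_group or n_wt < min_group:
            skipped[gene] = "group_size"
            logger.info("skipped_gene gene=%s reason=group_size n_mut=%d n_wt=%d", gene, n_mut, n_wt)
            continue
        idx = np.flatnonzero(keep.to_numpy())
        dummies = None
        if include_tissue:
            tis = line_tissue.iloc[idx]
            levels = sorted(tis.unique())
            dummies = np.column_stack(
                [(tis == lv).to_numpy(dtype=float) for lv in levels[1:]]
            ) if len(levels) > 1 else None
        fit = _fit_gene(Y_all[idx], mut, dummies)
        if fit is None:
            skipped[gene] = "collinear"
            logger.info("skipped_gene gene=%s reason=collinear_design", gene)
            continue
        tstat[gene], pval[gene] = fit
        nmut[gene], nwt[gene] = n_mut, n_wt

    return AssociationMatrix(
        tstat=pd.DataFrame(tstat, index=features).T,
        pvalue=pd.DataFrame(pval, index=features).T,
        n_mut=pd.Series(nmut, dtype=int),
        n_wt=pd.Series(nwt, dtype=int),
        scope=scope,
        skipped=skipped,
    )


def tissue_specific_tstats(
    matrix: FeatureMatrix,
    muts: MutationTable,
    meta: pd.DataFrame,
    tissue: str,
    gene_list=None,
    min_group: int = 3,
) -> AssociationMatrix:
    """Association fit restricted to one tissue (no tissue covariates)."""
    line_tissue = meta.groupby("cell_line")["tissue"].first()
    lines = [l for l in matrix.sample_ids if line_tissue.get(l) == tissue]
    if not lines:
        raise PreconditionError(f"tissue {tissue!r} absent from the dataset")
    sub = matrix.with_data(matrix.data.loc[lines])
    return association_tstats(
        sub, muts, meta, gene_list=gene_list, min_group=min_group,
        include_tissue=False, scope=tissue,
    )


def cross_tissue_heterogeneity(per_tissue: list[AssociationMatrix]) -> pd.Series:
    """Per gene, the mean pairwise Spearman rho between tissue T-vectors."""
    if len(per_tissue) < 2:
        raise PreconditionError("need association matrices for >= 2 tissues")
    out = {}
    genes = set().union(*[set(a.tstat.index) for a in per_tissue])
    for gene in sorted(genes):
        mats = [a for a in per_tissue if gene in a.tstat.index]
        if len(mats) < 2:
            continue
        rhos = []
        for i in range(len(mats)):
            for j in range(i + 1, len(mats)):
                a = mats[i].tstat.loc[gene]
                b = mats[j].tstat.loc[gene]
                shared = a.index.intersection(b.index)
                av, bv = a[shared], b[shared]
                ok = av.notna() & bv.notna()
                if ok.sum() >= 3:
                    rhos.append(stats.spearmanr(av[ok], bv[ok]).statistic)
        if rhos:
            out[gene] = float(np.mean(rhos))
    return pd.Series(out, dtype=float)


def differential_metabolites(
    matrix: FeatureMatrix, group_labels: pd.Series, alpha: float = 0.05
) -> pd.DataFrame:
    """Two-sample pooled-variance T-test per feature with BH adjustment.

    ``group_labels`` is boolean (True = case) aligned to the matrix rows.
    ``mean_level`` is the mean log10 level (volcano x-axis) when the matrix
    is on the intensity scale, else the plain mean.
    """
    labels = group_labels.reindex(matrix.sample_ids).astype(bool)
    a = matrix.data.loc[labels[labels].index]
    b = matrix.data.loc[labels[~labels].index]
    if len(a) < 3 or len(b) < 3:
        raise PreconditionError("need >= 3 samples per group")
    res = stats.ttest_ind(a.to_numpy(float), b.to_numpy(float), axis=0, equal_var=True)
    t = np.asarray(res.statistic, dtype=float)
    p = np.asarray(res.pvalue, dtype=float)
    ok = np.isfinite(t)
    for f in matrix.data.columns[~ok]:
        logger.info("skipped_feature feature=%s reason=zero_variance_both_groups", f)
    vals = matrix.data.to_numpy(float)
    mean_level = np.log10(vals).mean(axis=0) if (vals > 0).all() else vals.mean(axis=0)
    out = pd.DataFrame(
        {"tstat": t, "p_raw": p, "mean_level": mean_level}, index=matrix.data.columns
    ).loc[matrix.data.columns[ok]]
    out["p_adjusted"] = bh_adjust(out["p_raw"].tolist())
    out["significant"] = out["p_adjusted"] < alpha
    return out


def rank_genes_for_metabolite(assoc: AssociationMatrix, feature: str) -> pd.Series:
    """Genes ordered by T ascending (ties broken by name)."""
    if feature not in assoc.tstat.columns:
        raise PreconditionError(f"feature {feature!r} absent from the association matrix")
    t = assoc.tstat[feature].dropna()
    order = sorted(t.index, key=lambda g: (t[g], g))
    return t.loc[order]
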