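"""Driver-mutation subtype analysis.

Covers three operations used for TP53-style questions: overlap between a
driver gene's differential metabolites and those of downstream genes,
Fisher-exact association between mutation classes (e.g. DNA-contact vs
conformation) and pathway membership of differential metabolites, and an
average-linkage pathway-similarity tree emitted as Newick text.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import linkage, to_tree
from scipy.stats import fisher_exact

from .activity import ActivityMatrix, bh_adjust
from .association import differential_metabolites
from .types import FeatureMatrix, MutationTable, PreconditionError, MISSING, MUTANT, WT

logger = logging.getLogger(__name__)

__all__ = [
    "MutationClassMap",
    "downstream_overlap",
    "class_pathway_association",
    "pathway_similarity_tree",
]


@dataclass
class MutationClassMap:
    """Maps a gene's protein-change strings to structural mutation classes."""

    gene: str
    class_of: dict[str, str] = field(default_factory=dict)

    def line_class(self, muts: MutationTable, line: str) -> str | None:
        """Class for a mutant line, 'unclassified' if the change is unknown,
        None for non-mutant lines."""
        if muts.status.at[line, self.gene] != MUTANT:
            return None
        det = muts.detail.get((line, self.gene))
        if det is None:
            return "unclassified"
        return self.class_of.get(det[0], "unclassified")


def _gene_differential(
    matrix: FeatureMatrix, muts: MutationTable, gene: str, alpha: float, min_group: int
) -> set[str] | None:
    calls = muts.status[gene].reindex(matrix.sample_ids)
    keep = calls.isin([MUTANT, WT])
    lines = calls.index[keep]
    labels = calls.loc[lines] == MUTANT
    if labels.sum() < min_group or (~labels).sum() < min_group:
        logger.info("skipped_gene gene=%s reason=group_size", gene)
        return None
    sub = matrix.with_data(matrix.data.loc[lines])
    table = differential_metabolites(sub, labels, alpha=alpha)
    return set(table.index[table["significant"]])


def downstream_overlap(
    matrix: FeatureMatrix,
    muts: MutationTable,
    driver_gene: str,
    downstream_genes,
    alpha: float = 0.05,
    min_group: int = 3,
) -> pd.DataFrame:
    """Share of the driver's differential metabolites recovered per downstream gene."""
    driver_set = _gene_differential(matrix, muts, driver_gene, alpha, min_group)
    if driver_set is None:
        raise PreconditionError(f"driver {driver_gene!r} fails the group-size precondition")
    if not driver_set:
        logger.warning("driver %s has an empty differential set", driver_gene)
    rows = {}
    for gene in downstream_genes:
        dset = _gene_differential(matrix, muts, gene, alpha, min_group)
        if dset is None:
            continue
        shared = sorted(driver_set & dset)
        pct = 100.0 * len(shared) / len(driver_set) if driver_set else 0.0
        rows[gene] = dict(n_shared=len(shared), pct_of_driver_set=pct, shared=shared)
    out = pd.DataFrame(rows).T
    out.attrs["driver_set"] = sorted(driver_set)
    return out


def class_pathway_association(
    matrix: FeatureMatrix,
    muts: MutationTable,
    class_map: MutationClassMap,
    db,
    alpha: float = 0.05,
    min_group: int = 3,
) -> pd.DataFrame:
    """Fisher-exact association of each mutation class with each pathway.

    Per class, the differential metabolite set vs WT is intersected with
    pathway membership over the measured universe in a 2x2 table
    (differential x member); two-sided p-values are BH-adjusted across all
    (class, pathway) pairs. Unclassified mutants are excluded.
    """
    gene = class_map.gene
    calls = muts.status[gene].reindex(matrix.sample_ids)
    wt_lines = list(calls.index[calls == WT])
    if len(wt_lines) < min_group:
        raise PreconditionError("too few WT lines")
    classes: dict[str, list[str]] = {}
    for line in calls.index[calls == MUTANT]:
        cls = class_map.line_class(muts, line)
        if cls and cls != "unclassified":
            classes.setdefault(cls, []).append(line)

    universe = set(matrix.feature_ids)
    usable = db.restricted(universe, min_size=1)
    rows = []
    for cls, lines in sorted(classes.items()):
        if len(lines) < min_group:
            logger.info("skipped_class class=%s reason=group_size", cls)
            continue
        sub_lines = lines + wt_lines
        sub = matrix.with_data(matrix.data.loc[sub_lines])
        labels = pd.Series([True] * len(lines) + [False] * len(wt_lines), index=sub_lines)
        table = differential_metabolites(sub, labels, alpha=alpha)
        diff = set(table.index[table["significant"]])
        for name, members in sorted(usable.pathways.items()):
            mem = set(members)
            a = len(diff & mem)
            b = len(diff - mem)
            c = len(mem - diff)
            d = len(universe) - a - b - c
            odds, p = fisher_exact([[a, b], [c, d]], alternative="two-sided")
            rows.append(dict(mutation_class=cls, pathway=name, odds_ratio=odds, p_raw=p,
                             n_differential=len(diff), n_overlap=a))
    out = pd.DataFrame(rows)
    if out.empty:
        return out
    out["p_adjusted"] = bh_adjust(out["p_raw"].clip(lower=np.nextafter(0.0, 1.0), upper=1.0).tolist())
    return out.sort_values(["p_raw", "mutation_class", "pathway"], kind="stable").reset_index(drop=True)


def pathway_similarity_tree(activity: ActivityMatrix) -> str:
    """Average-linkage tree over pathways, distance 1 - Pearson r of their
    rank-sum-change vectors across cell lines; Newick with merge-height
    branch lengths."""
    mat = activity.rank_sum_change
    keep = []
    for pw in sorted(mat.columns):
        if np.ptp(mat[pw].to_numpy(dtype=float)) == 0.0:
            logger.info("dropped_pathway pathway=%s reason=constant_vector", pw)
        else:
            keep.append(pw)
    if len(keep) < 3:
        raise PreconditionError("need >= 3 non-constant pathways")
    X = mat[keep].to_numpy(dtype=float)
    r = np.corrcoef(X, rowvar=False)
    dist = 1.0 - r
    iu, ju = np.triu_indices(len(keep), k=1)
    condensed = np.maximum(dist[iu, ju], 0.0)
    Z = linkage(condensed, method="average")
    root = to_tree(Z)

    def newick(node, parent_height: float) -> str:
        length = max(parent_height - node.dist, 0.0) if parent_height is not None else 0.0
        if node.is_leaf():
            return f"{keep[node.id]}:{length:.6g}"
        left = newick(node.left, node.dist)
        right = newick(node.right, node.dist)
        return f"({left},{right}):{length:.6g}"

    return newick(root, None).rsplit(":", 1)[0] + ";"
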