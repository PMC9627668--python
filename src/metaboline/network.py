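"""Thresholded gene-metabolite correlation network.

Pearson correlations between all pairs of (log-transformed) expression
columns and metabolite features over shared cell lines define an
undirected graph; size-filtered connected components are extracted and
each component's typed members tested by over-representation.
"""

from __future__ import annotations

import logging

import networkx as nx
import numpy as np
import pandas as pd

from .activity import EnrichmentResult, ora
from .types import FeatureMatrix, PathwayDB, PreconditionError

logger = logging.getLogger(__name__)

__all__ = ["build_correlation_graph", "components", "component_ora"]


def build_correlation_graph(
    expr: pd.DataFrame,
    metab: FeatureMatrix,
    threshold: float = 0.8,
    absolute: bool = False,
    max_nodes: int | None = None,
) -> nx.Graph:
    """Graph over genes and metabolites linked when Pearson r exceeds the threshold.

    Expression is log(x+1)-transformed; the metabolite matrix is used as
    given (cell-line averaged). The edge rule is signed ``r > threshold``
    unless ``absolute`` is set. ``max_nodes`` keeps only the
    highest-variance columns of each input (quadratic cost guard).
    """
    if not 0.0 < threshold < 1.0:
        raise PreconditionError("threshold must lie in (0, 1)")
    shared = [l for l in metab.sample_ids if l in expr.index]
    if len(shared) < 5:
        raise PreconditionError("need >= 5 shared cell lines")
    e = np.log1p(expr.loc[shared].astype(float))
    m = metab.data.loc[shared].astype(float)

    def trim(df: pd.DataFrame) -> pd.DataFrame:
        sd = df.std(axis=0, ddof=1)
        keep = sd.index[sd > 0.0]
        for c in df.columns.difference(keep):
            logger.info("dropped_node node=%s reason=zero_variance", c)
        df = df[keep]
        if max_nodes is not None and df.shape[1] > max_nodes:
            top = sd[keep].nlargest(max_nodes).index
            df = df[top]
        return df

    e, m = trim(e), trim(m)
    cols = list(e.columns) + list(m.columns)
    types = ["gene"] * e.shape[1] + ["metabolite"] * m.shape[1]
    X = np.column_stack([e.to_numpy(), m.to_numpy()])
    r = np.corrcoef(X, rowvar=False)

    g = nx.Graph(threshold=threshold, absolute=absolute)
    for c, t in zip(cols, types):
        g.add_node(c, kind=t)
    iu, ju = np.triu_indices(len(cols), k=1)
    vals = np.abs(r[iu, ju]) if absolute else r[iu, ju]
    hits = np.flatnonzero(vals > threshold)
    for h in hits:
        a, b = cols[iu[h]], cols[ju[h]]
        g.add_edge(a, b, weight=float(r[iu[h], ju[h]]))
    return g


def components(graph: nx.Graph, min_size: int = 10) -> list[set]:
    """Connected components with >= min_size nodes, largest first."""
    comps = [set(c) for c in nx.connected_components(graph) if len(c) >= min_size]
    comps.sort(key=lambda c: (-len(c), sorted(c)))
    return comps


def component_ora(
    component: set,
    graph: nx.Graph,
    metab_db: PathwayDB | None = None,
    gene_db: PathwayDB | None = None,
) -> tuple[list[EnrichmentResult], list[EnrichmentResult]]:
    """ORA of a component's metabolite and gene members.

    Universes are all graph nodes of the respective type. Returns
    (metabolite results, gene results); an empty typed subset yields an
    empty list on that side.
    """
    kinds = nx.get_node_attributes(graph, "kind")
    out = []
    for db, kind in ((metab_db, "metabolite"), (gene_db, "gene")):
        universe = {n for n, k in kinds.items() if k == kind}
        selection = {n for n in component if kinds.get(n) == kind}
        if db is None or not selection:
            if not selection:
                logger.info("component has no %s members", kind)
            out.append([])
            continue
        out.append(ora(selection, db, universe))
    return out[0], out[1]
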