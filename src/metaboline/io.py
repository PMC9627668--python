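"""File formats: TSV matrices/tables with a schema-version header, GMT
pathway sets, mutation tables, and JSON ground truth / manifests.

All text is UTF-8; matrices are samples-as-rows; missing values are empty
cells. Every writer prefixes a single ``#``-comment schema line.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import pandas as pd

from .types import ConfigurationError, FeatureMatrix, MutationTable, PathwayDB, Stage

logger = logging.getLogger(__name__)

SCHEMA = "metaboline/v1"

__all__ = [
    "read_matrix", "write_matrix",
    "read_meta", "write_meta",
    "read_gmt", "write_gmt",
    "read_mutations", "write_mutations",
    "read_table", "write_table",
    "write_json", "read_json",
]


def _header(kind: str, **fields) -> str:
    extra = " ".join(f"{k}={v}" for k, v in fields.items())
    return f"# {SCHEMA} {kind}" + (f" {extra}" if extra else "")


def write_matrix(matrix: FeatureMatrix, path) -> None:
    path = Path(path)
    with path.open("w", encoding="utf-8") as fh:
        fh.write(_header("matrix", stage=matrix.stage.value) + "\n")
        out = matrix.data.copy()
        out.index.name = "sample_id"
        out.to_csv(fh, sep="\t")


def read_matrix(path) -> FeatureMatrix:
    path = Path(path)
    stage = Stage.raw
    with path.open(encoding="utf-8") as fh:
        first = fh.readline()
        if first.startswith("#"):
            for token in first.split():
                if token.startswith("stage="):
                    stage = Stage(token.split("=", 1)[1])
        else:
            fh.seek(0)
        df = pd.read_csv(fh, sep="\t", index_col=0)
    df.index.name = None
    df.columns.name = None
    return FeatureMatrix(df, stage)


def write_meta(meta: pd.DataFrame, path) -> None:
    with Path(path).open("w", encoding="utf-8") as fh:
        fh.write(_header("metadata") + "\n")
        out = meta.copy()
        out.index.name = "sample_id"
        out.to_csv(fh, sep="\t")


def read_meta(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0, comment="#")


def write_table(df: pd.DataFrame, path, kind: str = "table", index: bool = True) -> None:
    with Path(path).open("w", encoding="utf-8") as fh:
        fh.write(_header(kind) + "\n")
        df.to_csv(fh, sep="\t", index=index)


def read_table(path, index_col=0) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=index_col, comment="#")


def write_gmt(db: PathwayDB, path) -> None:
    with Path(path).open("w", encoding="utf-8") as fh:
        for name, members in db.pathways.items():
            desc = db.descriptions.get(name, "na")
            fh.write("\t".join([name, desc, *members]) + "\n")


def read_gmt(path, universe=None) -> PathwayDB:
    """Parse a GMT file (name, description, members...).

    Duplicate pathway names raise; duplicate members within a pathway are
    dropped with a warning. The universe defaults to the union of members.
    """
    pathways: dict[str, tuple[str, ...]] = {}
    descriptions: dict[str, str] = {}
    for lineno, line in enumerate(Path(path).read_text(encoding="utf-8").splitlines(), start=1):
        if not line.strip() or line.startswith("#"):
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) < 3:
            raise ConfigurationError(f"{path}:{lineno}: GMT line needs name, description and >= 1 member")
        name, desc, *members = fields
        if name in pathways:
            raise ConfigurationError(f"{path}:{lineno}: duplicate pathway name {name!r}")
        uniq = tuple(dict.fromkeys(m for m in members if m))
        if len(uniq) != len([m for m in members if m]):
            logger.warning("pathway %s: duplicate members deduplicated", name)
        pathways[name] = uniq
        descriptions[name] = desc
    if universe is None:
        universe = set().union(*pathways.values()) if pathways else set()
    return PathwayDB(pathways, frozenset(universe), descriptions)


def write_mutations(muts: MutationTable, path) -> None:
    rows = []
    for line in muts.status.index:
        for gene in muts.status.columns:
            det = muts.detail.get((line, gene), ("", ""))
            rows.append((line, gene, muts.status.at[line, gene], det[0], det[1]))
    df = pd.DataFrame(rows, columns=["cell_line", "gene", "status", "protein_change", "mutation_class"])
    write_table(df, path, kind="mutations", index=False)


def read_mutations(path) -> MutationTable:
    df = pd.read_csv(path, sep="\t", comment="#", keep_default_na=False)
    status = df.pivot(index="cell_line", columns="gene", values="status")
    detail = {}
    for _, row in df.iterrows():
        if row.get("protein_change"):
            detail[(row["cell_line"], row["gene"])] = (row["protein_change"], row.get("mutation_class", ""))
    return MutationTable(status, detail)


def write_json(obj, path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True, default=str) + "\n", encoding="utf-8")


def read_json(path):
    return json.loads(Path(path).read_text(encoding="utf-8"))
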