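"""Core containers shared by every pipeline stage.

Matrices are pandas DataFrames wrapped in :class:`FeatureMatrix` so that the
processing stage travels with the values; metadata is a plain DataFrame
validated by :func:`validate_meta`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

__all__ = [
    "Stage",
    "FeatureMatrix",
    "PathwayDB",
    "MutationTable",
    "ConfigurationError",
    "PreconditionError",
    "validate_meta",
    "META_COLUMNS",
]


class ConfigurationError(ValueError):
    """Invalid configuration (bad dimensions, missing seed, bad paths)."""


class PreconditionError(ValueError):
    """An operation's stated precondition is not met by the inputs."""


class Stage(str, Enum):
    raw = "raw"
    drift_corrected = "drift_corrected"
    confluency_corrected = "confluency_corrected"
    filtered = "filtered"
    zscored = "zscored"
    cellline_avg = "cellline_avg"


#: required metadata columns (doubling_time is optional)
META_COLUMNS = (
    "cell_line",
    "tissue",
    "bio_rep",
    "tech_rep",
    "injection_index",
    "confluency",
    "batch",
    "plate",
)


@dataclass
class FeatureMatrix:
    """Samples x metabolite-features intensity table.

    ``data`` is indexed by sample id (or cell line at the averaged stage)
    with one column per feature id. Intensity stages hold strictly positive
    values; the z-scored stage holds reals.
    """

    data: pd.DataFrame
    stage: Stage = Stage.raw

    def __post_init__(self) -> None:
        self.stage = Stage(self.stage)
        if self.data.index.has_duplicates:
            raise ConfigurationError("duplicated sample ids")
        if self.data.columns.has_duplicates:
            raise ConfigurationError("duplicated feature ids")
        if self.stage in (Stage.raw, Stage.drift_corrected, Stage.confluency_corrected, Stage.filtered):
            vals = self.data.to_numpy(dtype=float)
            if np.any(vals < 0) or not np.all(np.isfinite(vals)):
                raise ConfigurationError(f"{self.stage.value}-stage intensities must be finite and >= 0")

    @property
    def sample_ids(self) -> list:
        return list(self.data.index)

    @property
    def feature_ids(self) -> list:
        return list(self.data.columns)

    @property
    def n_samples(self) -> int:
        return self.data.shape[0]

    @property
    def n_features(self) -> int:
        return self.data.shape[1]

    def log(self) -> pd.DataFrame:
        """Natural-log intensities (positive stages only)."""
        if self.stage in (Stage.zscored,):
            raise PreconditionError("log of a z-scored matrix is undefined")
        return np.log(self.data)

    def with_data(self, data: pd.DataFrame, stage: Stage | str | None = None) -> "FeatureMatrix":
        return FeatureMatrix(data, Stage(stage) if stage is not None else self.stage)

    def copy(self) -> "FeatureMatrix":
        return FeatureMatrix(self.data.copy(), self.stage)


@dataclass
class PathwayDB:
    """Named member-id sets over a declared universe (GMT-serializable)."""

    pathways: dict[str, tuple[str, ...]]
    universe: frozenset[str]
    descriptions: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.universe = frozenset(self.universe)
        clean: dict[str, tuple[str, ...]] = {}
        for name, members in self.pathways.items():
            uniq = tuple(dict.fromkeys(members))
            if not uniq:
                raise ConfigurationError(f"pathway {name!r} is empty")
            missing = set(uniq) - self.universe
            if missing:
                raise ConfigurationError(f"pathway {name!r} has members outside the universe: {sorted(missing)[:5]}")
            clean[name] = uniq
        self.pathways = clean

    def __len__(self) -> int:
        return len(self.pathways)

    def __iter__(self):
        return iter(self.pathways)

    def members(self, name: str) -> tuple[str, ...]:
        return self.pathways[name]

    def restricted(self, measured: Iterable[str], min_size: int = 1) -> "PathwayDB":
        """Drop members absent from ``measured``; drop pathways below ``min_size``."""
        measured = set(measured)
        kept = {}
        for name, members in self.pathways.items():
            m = tuple(x for x in members if x in measured)
            if len(m) >= min_size:
                kept[name] = m
        return PathwayDB(kept, frozenset(self.universe & measured), dict(self.descriptions))


# mutation status levels
WT, MUTANT, MISSING = "WT", "mutant", "missing"


@dataclass
class MutationTable:
    """Cell line x gene mutation status plus optional per-line mutation detail.

    ``status`` values are one of ``WT``, ``mutant``, ``missing``.
    ``detail`` maps (cell_line, gene) -> (protein_change, class_label) for
    mutant entries that carry a recorded protein change.
    """

    status: pd.DataFrame
    detail: dict[tuple[str, str], tuple[str, str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        bad = set(np.unique(self.status.to_numpy(dtype=object))) - {WT, MUTANT, MISSING}
        if bad:
            raise ConfigurationError(f"unknown mutation status values: {sorted(bad)}")
        for (line, gene) in self.detail:
            if self.status.at[line, gene] != MUTANT:
                raise ConfigurationError(f"mutation detail on non-mutant entry ({line}, {gene})")

    @property
    def genes(self) -> list[str]:
        return list(self.status.columns)

    @property
    def cell_lines(self) -> list[str]:
        return list(self.status.index)

    def calls(self, gene: str) -> pd.Series:
        return self.status[gene]


def validate_meta(meta: pd.DataFrame, matrix: FeatureMatrix | None = None) -> pd.DataFrame:
    """Check the metadata contract; returns ``meta`` unchanged on success."""
    missing = [c for c in META_COLUMNS if c not in meta.columns]
    if missing:
        raise ConfigurationError(f"metadata missing columns: {missing}")
    if meta.index.has_duplicates:
        raise ConfigurationError("duplicated sample ids in metadata")
    idx = meta["injection_index"]
    if idx.duplicated().any():
        raise ConfigurationError("injection_index values must be unique")
    conf = meta["confluency"].astype(float)
    if ((conf <= 0) | (conf > 1)).any():
        raise ConfigurationError("confluency must lie in (0, 1]")
    if matrix is not None:
        unknown = set(matrix.sample_ids) - set(meta.index)
        if unknown:
            raise ConfigurationError(f"samples absent from metadata: {sorted(unknown)[:5]}")
    return meta


def meta_for(meta: pd.DataFrame, matrix: FeatureMatrix) -> pd.DataFrame:
    """Metadata rows aligned to the matrix sample order."""
    validate_meta(meta, matrix)
    return meta.loc[matrix.sample_ids]
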