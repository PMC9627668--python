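"""Synthetic study generator.

Produces a complete replicate-structured metabolomics study — intensities,
sample metadata, pathway sets, planted mutation effects, score/drug
couplings — together with a machine-readable ground-truth record, so every
downstream stage can be tested without external data.

All randomness flows from a single seeded :class:`numpy.random.Generator`
per call; identical seeds give bit-identical outputs.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .types import (
    ConfigurationError,
    FeatureMatrix,
    MutationTable,
    PathwayDB,
    Stage,
    MISSING,
    MUTANT,
    WT,
)

__all__ = [
    "StudyConfig",
    "DriftModel",
    "PlantedGeneEffect",
    "Coupling",
    "GroundTruth",
    "generate_study",
    "generate_pathways",
    "plant_mutation_effects",
    "generate_scores_and_drugs",
]


@dataclass(frozen=True)
class StudyConfig:
    """Parameters of the simulated study.

    The replicate-noise hierarchy must satisfy
    ``noise_sd_tech <= noise_sd_bio <= between_line_sd`` so that technical
    replicates are tighter than biological ones, which are tighter than
    between-line differences.
    """

    n_cell_lines: int = 20
    n_tissues: int = 4
    n_bio_reps: int = 3
    n_tech_reps: int = 2
    n_features: int = 300
    seed: int = None  # type: ignore[assignment]  # mandatory, checked below
    base_log_mean: float = 18.0
    base_log_sd: float = 1.0
    tissue_sd: float = 0.3
    between_line_sd: float = 0.5
    noise_sd_bio: float = 0.15
    noise_sd_tech: float = 0.05
    global_bio_sd: float = 0.4
    global_tech_sd: float = 0.02
    drift_amplitude: float = 0.3
    drift_linear: float = 2.0
    confluency_effect: float = 1.0
    batch_frac: float = 0.10
    batch_effect_sd: float = 0.5
    n_batches: int = 3
    n_plates: int = 4
    doubling_time_frac: float = 1.0

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ConfigurationError("seed is mandatory (reproducibility)")
        if int(self.seed) < 0:
            raise ConfigurationError("seed must be non-negative")
        for name in ("n_cell_lines", "n_tissues", "n_bio_reps", "n_tech_reps", "n_features", "n_batches", "n_plates"):
            if int(getattr(self, name)) <= 0:
                raise ConfigurationError(f"{name} must be positive")
        if self.n_tissues > self.n_cell_lines:
            raise ConfigurationError("n_tissues cannot exceed n_cell_lines")
        sds = {
            "base_log_sd": self.base_log_sd,
            "tissue_sd": self.tissue_sd,
            "between_line_sd": self.between_line_sd,
            "noise_sd_bio": self.noise_sd_bio,
            "noise_sd_tech": self.noise_sd_tech,
            "global_bio_sd": self.global_bio_sd,
            "global_tech_sd": self.global_tech_sd,
            "drift_amplitude": self.drift_amplitude,
            "confluency_effect": self.confluency_effect,
            "batch_effect_sd": self.batch_effect_sd,
        }
        for name, v in sds.items():
            if not np.isfinite(v) or v < 0:
                raise ConfigurationError(f"{name} must be finite and >= 0")
        if not (self.noise_sd_tech <= self.noise_sd_bio <= self.between_line_sd):
            raise ConfigurationError(
                "replicate noise ordering violated: need noise_sd_tech <= noise_sd_bio <= between_line_sd"
            )
        if not 0.0 <= self.batch_frac <= 1.0:
            raise ConfigurationError("batch_frac must lie in [0, 1]")

    @property
    def n_samples(self) -> int:
        return self.n_cell_lines * self.n_bio_reps * self.n_tech_reps


@dataclass
class DriftModel:
    """Injection-order drift: shared sinusoid + linear trend, scaled per feature."""

    amplitude: float
    period: float
    linear_coef: float
    n_injections: int
    feature_scale: dict[str, float]

    def base(self, injection: np.ndarray | float) -> np.ndarray | float:
        i = np.asarray(injection, dtype=float)
        n = self.n_injections
        out = np.sin(2.0 * np.pi * i / self.period) + self.linear_coef * (i - (n + 1) / 2.0) / n
        return out if out.ndim else float(out)

    def log_offset(self, feature: str, injection) -> float:
        return self.amplitude * self.feature_scale[feature] * self.base(injection)

    def to_dict(self) -> dict:
        return {
            "amplitude": self.amplitude,
            "period": self.period,
            "linear_coef": self.linear_coef,
            "n_injections": self.n_injections,
            "feature_scale": dict(self.feature_scale),
        }


@dataclass(frozen=True)
class PlantedGeneEffect:
    gene: str
    features: tuple[str, ...]
    effect_size: float  # in units of per-feature log-intensity SD
    tissue: str = "all"
    mutant_frac: float = 0.3
    protein_changes: tuple[tuple[str, str], ...] = ()  # (change, class) choices for mutant lines


@dataclass(frozen=True)
class Coupling:
    name: str
    pathway: str
    sign: int
    strength: float


@dataclass
class GroundTruth:
    """Record of every planted component of a synthetic study."""

    drift: DriftModel | None = None
    batch_features: tuple[str, ...] = ()
    planted_gene_effects: list[PlantedGeneEffect] = field(default_factory=list)
    planted_score_couplings: list[Coupling] = field(default_factory=list)
    planted_drug_couplings: list[Coupling] = field(default_factory=list)
    synergy_pairs: list[tuple[str, str]] = field(default_factory=list)
    warnings: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "drift": self.drift.to_dict() if self.drift is not None else None,
            "batch_features": list(self.batch_features),
            "planted_gene_effects": [dataclasses.asdict(e) for e in self.planted_gene_effects],
            "planted_score_couplings": [dataclasses.asdict(c) for c in self.planted_score_couplings],
            "planted_drug_couplings": [dataclasses.asdict(c) for c in self.planted_drug_couplings],
            "synergy_pairs": [list(p) for p in self.synergy_pairs],
            "warnings": list(self.warnings),
        }


def generate_study(config: StudyConfig) -> tuple[FeatureMatrix, pd.DataFrame, GroundTruth]:
    """Simulate the raw study matrix plus metadata and ground truth.

    Per-sample log-intensity of feature f decomposes additively into:
    feature baseline + tissue effect + cell-line effect + bio-rep noise +
    tech-rep noise + injection drift + confluency term + batch offset
    (batch subset only). Values are exponentiated to the intensity scale.
    """
    rng = np.random.default_rng(int(config.seed))
    nl, nt = config.n_cell_lines, config.n_tissues
    nb, nk, nf = config.n_bio_reps, config.n_tech_reps, config.n_features
    n = config.n_samples

    lines = [f"CL{i + 1:03d}" for i in range(nl)]
    tissues = [f"T{i + 1}" for i in range(nt)]
    features = [f"F{i + 1:04d}" for i in range(nf)]
    line_tissue = {ln: tissues[i % nt] for i, ln in enumerate(lines)}

    baseline = rng.normal(config.base_log_mean, config.base_log_sd, size=nf)
    tissue_eff = rng.normal(0.0, config.tissue_sd, size=(nt, nf))
    line_eff = rng.normal(0.0, config.between_line_sd, size=(nl, nf))
    bio_eff = rng.normal(0.0, config.noise_sd_bio, size=(nl, nb, nf))
    # per-culture and per-injection global log offsets (sample-amount variation)
    bio_global = rng.normal(0.0, config.global_bio_sd, size=(nl, nb))
    tech_global = rng.normal(0.0, config.global_tech_sd, size=n)

    # technical replicates of a culture are injected consecutively; cultures
    # themselves enter the sequence in random order
    n_groups = nl * nb
    group_order = rng.permutation(n_groups)
    group_slot = np.empty(n_groups, dtype=int)
    group_slot[group_order] = np.arange(n_groups)
    confluency_group = rng.uniform(0.3, 1.0, size=n_groups)
    plate_group = rng.integers(0, config.n_plates, size=n_groups)

    drift = DriftModel(
        amplitude=config.drift_amplitude,
        period=max(4.0, n / 2.5),
        linear_coef=config.drift_linear,
        n_injections=n,
        feature_scale={f: s for f, s in zip(features, rng.uniform(0.5, 1.5, size=nf))},
    )
    fscale = np.array([drift.feature_scale[f] for f in features])

    n_batch_feats = int(round(config.batch_frac * nf))
    batch_features = tuple(sorted(rng.choice(features, size=n_batch_feats, replace=False))) if n_batch_feats else ()
    batch_mask = np.isin(np.array(features), np.array(batch_features, dtype=object))
    # across-batch offsets standardized per feature so every planted feature
    # carries exactly batch_effect_sd of between-batch spread
    raw_off = rng.normal(size=(config.n_batches, nf))
    if config.n_batches > 1:
        raw_off = raw_off - raw_off.mean(axis=0)
        sd0 = raw_off.std(axis=0, ddof=0)
        raw_off = raw_off / np.where(sd0 > 0, sd0, 1.0)
    batch_offsets = config.batch_effect_sd * raw_off * batch_mask

    rows, sample_ids, meta_rows = [], [], []
    s = 0
    for li, line in enumerate(lines):
        t = tissues.index(line_tissue[line])
        for b in range(nb):
            g = li * nb + b
            for k in range(nk):
                inj = int(group_slot[g] * nk + k + 1)
                # batch follows injection-order blocks
                batch = min((inj - 1) * config.n_batches // n, config.n_batches - 1)
                log_row = (
                    baseline
                    + tissue_eff[t]
                    + line_eff[li]
                    + bio_eff[li, b]
                    + bio_global[li, b]
                    + rng.normal(0.0, config.noise_sd_tech, size=nf)
                    + tech_global[s]
                    + config.drift_amplitude * fscale * drift.base(inj)
                    + config.confluency_effect * np.log(confluency_group[g])
                    + batch_offsets[batch]
                )
                sid = f"S{s + 1:04d}"
                sample_ids.append(sid)
                rows.append(np.exp(log_row))
                meta_rows.append(
                    dict(
                        sample_id=sid,
                        cell_line=line,
                        tissue=line_tissue[line],
                        bio_rep=b + 1,
                        tech_rep=k + 1,
                        injection_index=inj,
                        confluency=float(confluency_group[g]),
                        batch=f"B{batch + 1}",
                        plate=f"P{plate_group[g] + 1}",
                    )
                )
                s += 1

    # doubling times are a per-line covariate, optionally missing
    dts = 20.0 + 40.0 * rng.random(nl)
    have_dt = rng.random(nl) < config.doubling_time_frac
    line_dt = {ln: (float(dt) if ok else np.nan) for ln, dt, ok in zip(lines, dts, have_dt)}

    meta = pd.DataFrame(meta_rows).set_index("sample_id")
    meta["doubling_time"] = meta["cell_line"].map(line_dt)
    matrix = FeatureMatrix(pd.DataFrame(rows, index=sample_ids, columns=features), Stage.raw)
    truth = GroundTruth(drift=drift, batch_features=batch_features)
    return matrix, meta, truth


def generate_pathways(
    n_pathways: int,
    size_range: tuple[int, int],
    universe: Sequence[str],
    seed: int,
) -> PathwayDB:
    """Random named subsets of ``universe`` (overlaps allowed)."""
    universe = list(dict.fromkeys(universe))
    if not universe:
        raise ConfigurationError("empty universe")
    lo, hi = int(size_range[0]), int(size_range[1])
    if lo < 1 or hi < lo:
        raise ConfigurationError("invalid size_range")
    if hi > len(universe):
        raise ConfigurationError("max pathway size exceeds universe size")
    rng = np.random.default_rng(int(seed))
    pathways = {}
    for i in range(int(n_pathways)):
        size = int(rng.integers(lo, hi + 1))
        members = tuple(sorted(rng.choice(universe, size=size, replace=False)))
        pathways[f"PW{i + 1:03d}"] = members
    return PathwayDB(pathways, frozenset(universe))


def plant_mutation_effects(
    matrix: FeatureMatrix,
    meta: pd.DataFrame,
    effects: Sequence[PlantedGeneEffect],
    seed: int,
    missing_frac: float = 0.0,
    truth: GroundTruth | None = None,
) -> tuple[FeatureMatrix, MutationTable, GroundTruth]:
    """Assign per-line mutation status and shift target features for mutants.

    The shift is ``effect_size x per-feature log-intensity SD`` (SD taken
    across all samples before shifting; unit fallback when the feature is
    constant). Tissue-scoped effects only move samples of that tissue.
    """
    rng = np.random.default_rng(int(seed))
    truth = truth if truth is not None else GroundTruth()
    lines = list(dict.fromkeys(meta.loc[matrix.sample_ids, "cell_line"]))
    line_tissue = meta.groupby("cell_line")["tissue"].first()

    logv = matrix.log()
    feat_sd = logv.std(axis=0, ddof=0)

    genes = list(dict.fromkeys(e.gene for e in effects))
    status = pd.DataFrame(WT, index=lines, columns=genes, dtype=object)
    detail: dict[tuple[str, str], tuple[str, str]] = {}
    out = logv.copy()

    for eff in effects:
        if eff.tissue != "all" and eff.tissue not in set(meta["tissue"]):
            raise ConfigurationError(f"effect tissue {eff.tissue!r} absent from metadata")
        missing_feats = [f for f in eff.features if f not in out.columns]
        if missing_feats:
            raise ConfigurationError(f"planted features absent from matrix: {missing_feats[:5]}")
        n_mut = int(round(eff.mutant_frac * len(lines)))
        mut_lines = set(rng.choice(lines, size=n_mut, replace=False)) if n_mut else set()
        for ln in mut_lines:
            status.at[ln, eff.gene] = MUTANT
            if eff.protein_changes:
                change, cls = eff.protein_changes[int(rng.integers(len(eff.protein_changes)))]
                detail[(ln, eff.gene)] = (change, cls)
        scope_lines = {
            ln for ln in mut_lines if eff.tissue == "all" or line_tissue[ln] == eff.tissue
        }
        if not scope_lines:
            truth.warnings.append(f"gene {eff.gene}: zero mutant lines in scope {eff.tissue!r}")
        scope_samples = [
            s for s in out.index if meta.at[s, "cell_line"] in scope_lines
        ]
        if eff.effect_size != 0.0 and scope_samples:
            for f in eff.features:
                sd = float(feat_sd[f])
                if sd == 0.0:
                    truth.warnings.append(f"feature {f}: zero SD, unit fallback for planted shift")
                    sd = 1.0
                out.loc[scope_samples, f] += eff.effect_size * sd
        truth.planted_gene_effects.append(eff)

    if missing_frac > 0.0:
        for g in genes:
            drop = rng.random(len(lines)) < missing_frac
            for ln, d in zip(lines, drop):
                if d:
                    status.at[ln, g] = MISSING
                    detail.pop((ln, g), None)

    shifted = matrix.with_data(np.exp(out))
    return shifted, MutationTable(status, detail), truth


def _pathway_mean_z(matrix: FeatureMatrix, members: Sequence[str]) -> pd.Series:
    vals = matrix.log() if matrix.stage != Stage.zscored else matrix.data
    z = (vals - vals.mean(axis=0)) / vals.std(axis=0, ddof=1).replace(0.0, np.nan)
    cols = [m for m in members if m in z.columns]
    if not cols:
        raise ConfigurationError("coupling to a pathway with no measured members")
    return z[cols].mean(axis=1)


def generate_scores_and_drugs(
    matrix: FeatureMatrix,
    pathways: PathwayDB,
    score_couplings: Sequence[Coupling] = (),
    drug_couplings: Sequence[Coupling] = (),
    seed: int = 0,
    noise_sd: float = 0.2,
    n_null_scores: int = 0,
    n_null_drugs: int = 0,
    truth: GroundTruth | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame, GroundTruth]:
    """Per-cell-line score and ln(IC50) tables coupled to pathway mean z.

    Each coupled value is ``sign x strength x mean(z of pathway members)``
    plus Gaussian noise; uncoupled columns are pure noise. Drug pairs with
    opposite-signed couplings to the same pathway enter the synergy table
    with a positive ZIP score.
    """
    rng = np.random.default_rng(int(seed))
    truth = truth if truth is not None else GroundTruth()
    lines = matrix.sample_ids
    n = len(lines)

    def build(couplings: Sequence[Coupling], n_null: int, prefix: str) -> pd.DataFrame:
        cols = {}
        for c in couplings:
            if c.pathway not in pathways.pathways:
                raise ConfigurationError(f"coupling to unknown pathway {c.pathway!r}")
            pmz = _pathway_mean_z(matrix, pathways.members(c.pathway))
            cols[c.name] = c.sign * c.strength * pmz.to_numpy() + rng.normal(0.0, noise_sd, size=n)
        for i in range(n_null):
            cols[f"{prefix}{i + 1:03d}"] = rng.normal(0.0, 1.0, size=n)
        return pd.DataFrame(cols, index=lines)

    scores = build(score_couplings, n_null_scores, "null_score_")
    drugs = build(drug_couplings, n_null_drugs, "null_drug_")

    truth.planted_score_couplings.extend(score_couplings)
    truth.planted_drug_couplings.extend(drug_couplings)

    pairs = []
    dlist = list(drug_couplings)
    for i, a in enumerate(dlist):
        for b in dlist[i + 1:]:
            if a.pathway == b.pathway and a.sign * b.sign < 0:
                pairs.append((a.name, b.name, float(rng.uniform(0.5, 5.0))))
                truth.synergy_pairs.append((a.name, b.name))
    synergy = pd.DataFrame(pairs, columns=["drug_a", "drug_b", "zip_score"])
    return scores, drugs, synergy, truth
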