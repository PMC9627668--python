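"""End-to-end orchestration with deterministic artifact naming.

``run_pipeline`` executes the fixed stage order
qc -> activity -> association -> enrichment -> network -> subtype ->
permutation on a simulated study (or pre-simulated inputs written by the
``simulate`` stage), writing every intermediate artifact plus a manifest
holding parameters, seeds and output checksums.
"""

from __future__ import annotations

import hashlib
import logging
import platform
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from . import io as mio
from .activity import doubling_time_regression, pathway_activity
from .association import association_tstats, rank_genes_for_metabolite
from .network import build_correlation_graph, components, component_ora
from .permutation import permutation_pvalue
from .qc import average_biological_replicates, normalize_pipeline, zscore_features
from .scorecorr import (
    drug_pair_anticorrelation,
    drug_pathway_profiles,
    synergy_overlay,
)
from .subtype import MutationClassMap, class_pathway_association, pathway_similarity_tree
from .synthetic import (
    Coupling,
    PlantedGeneEffect,
    StudyConfig,
    generate_pathways,
    generate_scores_and_drugs,
    generate_study,
    plant_mutation_effects,
)
from .types import ConfigurationError, FeatureMatrix, Stage

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "run_pipeline", "simulate_study_files"]


@dataclass
class PipelineConfig:
    outdir: str = "metaboline_run"
    seed: int = 0
    study: dict = field(default_factory=dict)  # StudyConfig overrides
    n_pathways: int = 15
    pathway_size: tuple[int, int] = (5, 20)
    drift_span: float = 0.3
    confluency_span: float = 0.6
    low_intensity_threshold: float = 25.0
    max_remove: int | None = None
    alpha: float = 0.05
    n_perm: int = 2000
    mhg_n_perm: int = 300
    network_threshold: float = 0.8

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(d) - known
        if unknown:
            raise ConfigurationError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def simulate_study_files(config: PipelineConfig, outdir: Path) -> dict:
    """Generate the full synthetic study and write every input artifact."""
    seed = int(config.seed)
    study_cfg = StudyConfig(**{"seed": seed, **config.study})
    matrix, meta, truth = generate_study(study_cfg)
    db = generate_pathways(
        config.n_pathways, config.pathway_size, matrix.feature_ids, seed=seed + 1
    )
    rng = np.random.default_rng(seed + 2)
    pw_names = list(db.pathways)
    effects = [
        PlantedGeneEffect("GENE1", tuple(db.members(pw_names[0])[:6]), 1.5,
                          protein_changes=(("p.C1A", "DNA_contact"), ("p.C2B", "conformation"))),
        PlantedGeneEffect("GENE2", tuple(db.members(pw_names[1 % len(pw_names)])[:6]), -1.0,
                          tissue=meta["tissue"].iloc[0]),
    ]
    matrix, muts, truth = plant_mutation_effects(
        matrix, meta, effects, seed=seed + 3, missing_frac=0.05, truth=truth
    )
    avg_for_scores = average_biological_replicates(matrix, meta)
    log_avg = avg_for_scores.with_data(np.log(avg_for_scores.data), Stage.cellline_avg)
    score_couplings = [Coupling("PROG1", pw_names[0], +1, 1.0)]
    drug_couplings = [
        Coupling("drugA", pw_names[0], +1, 1.0),
        Coupling("drugB", pw_names[0], -1, 1.0),
        Coupling("drugC", pw_names[1 % len(pw_names)], +1, 0.8),
    ]
    scores, drugs, synergy, truth = generate_scores_and_drugs(
        log_avg, db, score_couplings, drug_couplings,
        seed=seed + 4, noise_sd=0.2, n_null_scores=2, n_null_drugs=2, truth=truth,
    )
    # pseudo expression matrix: pathway-coupled latent plus noise, intensity scale
    expr_couplings = [
        Coupling(f"G{i + 1:03d}", pw_names[i % len(pw_names)], 1 if i % 2 == 0 else -1, 1.0)
        for i in range(20)
    ]
    expr_z, _, _, _ = generate_scores_and_drugs(
        log_avg, db, expr_couplings, (), seed=seed + 5, noise_sd=0.5,
    )
    expr = np.exp(expr_z + 5.0)

    mio.write_matrix(matrix, outdir / "intensities.tsv")
    mio.write_meta(meta, outdir / "metadata.tsv")
    mio.write_gmt(db, outdir / "pathways.gmt")
    mio.write_mutations(muts, outdir / "mutations.tsv")
    mio.write_table(scores, outdir / "scores.tsv", kind="scores")
    mio.write_table(drugs, outdir / "drugs.tsv", kind="drugs")
    mio.write_table(synergy, outdir / "synergy.tsv", kind="synergy", index=False)
    mio.write_table(expr, outdir / "expression.tsv", kind="expression")
    mio.write_json(truth.to_dict(), outdir / "ground_truth.json")
    return {"matrix": matrix, "meta": meta, "db": db, "muts": muts,
            "scores": scores, "drugs": drugs, "synergy": synergy,
            "expr": expr, "truth": truth}


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every stage on a synthetic study; returns the manifest dict."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    seed = int(config.seed)
    manifest: dict = {
        "tool": f"metaboline {__version__}",
        "python": platform.python_version(),
        "seed": seed,
        "parameters": {k: getattr(config, k) for k in config.__dataclass_fields__},
        "stages": [],
        "artifacts": {},
    }

    inputs = simulate_study_files(config, outdir)
    manifest["stages"].append("simulate")

    # qc
    normalized, report = normalize_pipeline(
        inputs["matrix"], inputs["meta"],
        drift_span=config.drift_span, confluency_span=config.confluency_span,
        low_intensity_threshold=config.low_intensity_threshold,
        max_remove=config.max_remove,
    )
    avg = average_biological_replicates(normalized, inputs["meta"])
    log_avg = avg.with_data(np.log(avg.data), Stage.cellline_avg)
    z = zscore_features(log_avg)
    mio.write_matrix(normalized, outdir / "normalized.tsv")
    mio.write_matrix(avg, outdir / "cellline_avg.tsv")
    mio.write_matrix(z, outdir / "zscored.tsv")
    mio.write_json(
        {
            "auc_technical": report.auc_technical,
            "auc_biological": report.auc_biological,
            "removed_injections": report.removed_injections,
            "removed_features": report.removed_features,
            "sweep_curve": report.sweep_curve,
        },
        outdir / "qc_report.json",
    )
    manifest["stages"].append("qc")

    # activity
    act = pathway_activity(
        avg, inputs["db"], alpha=config.alpha,
        calibration="permutation", n_perm=config.mhg_n_perm, seed=seed + 10,
    )
    mio.write_table(act.rank_sum_change, outdir / "activity_rank_sum.tsv", kind="activity")
    mio.write_table(act.pvalue, outdir / "activity_pvalues.tsv", kind="activity")
    dtreg = doubling_time_regression(act, inputs["meta"])
    mio.write_table(dtreg, outdir / "doubling_time_regression.tsv", kind="regression")
    manifest["stages"].append("activity")

    # association
    assoc = association_tstats(z, inputs["muts"], inputs["meta"])
    mio.write_table(assoc.tstat, outdir / "association_tstats.tsv", kind="association")
    mio.write_table(assoc.pvalue, outdir / "association_pvalues.tsv", kind="association")
    manifest["stages"].append("association")

    # enrichment: drug x pathway profiles + synergy overlay
    profiles = drug_pathway_profiles(
        z, inputs["drugs"], inputs["db"],
        calibration="permutation", n_perm=config.mhg_n_perm, seed=seed + 20,
    )
    mio.write_table(profiles.signed_stat, outdir / "drug_pathway_signed.tsv", kind="profiles")
    anti = drug_pair_anticorrelation(profiles)
    overlay, synergy_p = synergy_overlay(
        anti, inputs["synergy"], calibration="permutation",
        n_perm=config.n_perm, seed=seed + 21,
    )
    mio.write_table(overlay, outdir / "drug_pair_anticorrelation.tsv", kind="pairs", index=False)
    manifest["synergy_enrichment_p"] = synergy_p
    manifest["stages"].append("enrichment")

    # network
    graph = build_correlation_graph(inputs["expr"], z, threshold=config.network_threshold)
    comps = components(graph, min_size=10)
    comp_rows = []
    for i, comp in enumerate(comps):
        metab_res, gene_res = component_ora(comp, graph, metab_db=inputs["db"])
        comp_rows.append({
            "component": i + 1,
            "size": len(comp),
            "members": ";".join(sorted(comp)),
            "top_metab_pathway": metab_res[0].pathway if metab_res else "",
        })
    mio.write_table(pd.DataFrame(comp_rows), outdir / "network_components.tsv",
                    kind="network", index=False)
    manifest["stages"].append("network")

    # subtype
    cmap = MutationClassMap("GENE1", {"p.C1A": "DNA_contact", "p.C2B": "conformation"})
    cpa = class_pathway_association(z, inputs["muts"], cmap, inputs["db"], alpha=config.alpha)
    mio.write_table(cpa, outdir / "class_pathway_association.tsv", kind="subtype", index=False)
    newick = pathway_similarity_tree(act)
    (outdir / "pathway_tree.nwk").write_text(newick + "\n", encoding="utf-8")
    manifest["stages"].append("subtype")

    # permutation: tissue adjacency of the line ordering induced by clustering
    from scipy.cluster.hierarchy import leaves_list, linkage

    X = z.data.to_numpy(dtype=float)
    Z = linkage(X, method="average")
    order = leaves_list(Z)
    tissue_of = inputs["meta"].groupby("cell_line")["tissue"].first()
    labels = [tissue_of[z.sample_ids[i]] for i in order]
    perm = permutation_pvalue(labels, n_perm=config.n_perm, seed=seed + 30)
    mio.write_json(
        {"observed": perm.observed, "p": perm.p, "n_perm": perm.n_perm,
         "exhaustive": perm.exhaustive},
        outdir / "tissue_clustering_permutation.json",
    )
    manifest["stages"].append("permutation")

    for p in sorted(outdir.iterdir()):
        if p.is_file() and p.name != "manifest.json":
            manifest["artifacts"][p.name] = _sha256(p)
    mio.write_json(manifest, outdir / "manifest.json")
    return manifest
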