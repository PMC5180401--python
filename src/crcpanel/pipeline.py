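"""End-to-end orchestration of the cohort analysis.

``run_pipeline`` chains the seven analysis stages — simulate (or load),
filter, burden, signatures, cluster, associate, survival — writing each
stage's tables to the output directory plus a run manifest (config hash,
seeds, per-stage row counts).  The pipeline is a pure function of
(inputs, config): a rerun with the same config is byte-identical, and no
stage mutates another stage's outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__
from .association import cluster_associations, fisher_power
from .burden import RocExperimentConfig, compute_burden, random_panel_experiment
from .clustering import (
    GeneSet,
    build_similarity,
    hierarchical_cluster,
    model_select,
    pairwise_distance,
)
from .filtering import FilterConfig, apply_filters
from .io import (
    PanelDefinition,
    VariantClass,
    write_clinical,
    write_maf,
    write_survival,
)
from .signatures import build_context_matrix, deconvolve, extract_signatures, reference_catalog
from .simulate import ClusterProfile, CohortSpec, default_panel, simulate_cohort
from .survival import filter_stage4_chain, km_estimate, logrank_test, waterfall_data

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "run_pipeline", "demo_config"]


@dataclass
class PipelineConfig:
    out_dir: str = "results/pipeline"
    seed: int = 0
    cohort: CohortSpec = field(default_factory=CohortSpec)
    filter_config: FilterConfig = field(default_factory=FilterConfig)
    roc_config: RocExperimentConfig = field(default_factory=RocExperimentConfig)
    gene_set: GeneSet | None = None
    k_range: tuple[int, ...] = (2, 3, 4, 5, 6)
    distances: tuple[str, ...] = ("euclidean", "manhattan")
    linkages: tuple[str, ...] = ("ward.D", "complete", "average")
    nmf_k: int = 2
    alpha: float = 0.05
    panel: PanelDefinition = field(default_factory=default_panel)

    def config_hash(self) -> str:
        def encode(obj):
            if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
                return {
                    f.name: encode(getattr(obj, f.name))
                    for f in dataclasses.fields(obj)
                    if f.name != "out_dir"  # where outputs land is not analysis identity
                }
            if isinstance(obj, (frozenset, set)):
                return sorted(obj)
            if isinstance(obj, (list, tuple)):
                return [encode(x) for x in obj]
            if isinstance(obj, dict):
                return {str(k): encode(v) for k, v in sorted(obj.items())}
            if obj is None or isinstance(obj, (str, int, float, bool)):
                return obj
            return repr(obj)

        blob = json.dumps(encode(self), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def demo_config(out_dir: str = "results/demo", seed: int = 0) -> PipelineConfig:
    """A self-contained demo: synthetic cohort with three planted clusters."""
    profiles = (
        ClusterProfile("RAS_cluster", ("KRAS", "PIK3CA"), 0.30,
                       clinical_odds={"N": 1.5}, hazard_multiplier=2.0),
        ClusterProfile("APC_TP53_cluster", ("APC", "TP53"), 0.30,
                       clinical_odds={"M": 0.5}, hazard_multiplier=1.0),
        ClusterProfile("PTEN_cluster", ("PTEN", "ERBB2"), 0.20,
                       clinical_odds={"vascular_invasion": 2.0}, hazard_multiplier=1.5),
    )
    return PipelineConfig(
        out_dir=out_dir,
        seed=seed,
        cohort=CohortSpec(seed=seed, cluster_profiles=profiles),
        roc_config=RocExperimentConfig(panel_sizes=(400, 200, 50), n_reps=20, seed=seed),
        gene_set=GeneSet("actionable", ("KRAS", "NRAS", "BRAF", "PIK3CA", "PTEN",
                                        "ERBB2", "RNF43", "APC", "TP53")),
        k_range=(2, 3, 4, 5),
        distances=("euclidean",),
        linkages=("ward.D", "average"),
    )


def run_pipeline(config: PipelineConfig) -> dict:
    """Run all stages in dependency order; returns the manifest dict."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "version": __version__,
        "stages": {},
    }

    # 1. simulate -----------------------------------------------------------
    cohort = simulate_cohort(config.cohort)
    write_maf(cohort.variants, out / "variants.tsv")
    write_clinical(cohort.clinical, out / "clinical.tsv")
    write_survival(cohort.survival, out / "survival.tsv")
    cohort.truth.to_csv(out / "truth.tsv", sep="\t", index=False)
    manifest["stages"]["simulate"] = {
        "variants": len(cohort.variants),
        "donors": len(cohort.clinical),
    }

    # 2. filter -------------------------------------------------------------
    filtered = apply_filters(cohort.variants, config=config.filter_config)
    write_maf(filtered.variants, out / "variants_somatic.tsv")
    manifest["stages"]["filter"] = {
        "kept": len(filtered.variants),
        **{f"removed_{k}": v for k, v in filtered.counts.items()},
    }

    # 3. burden -------------------------------------------------------------
    donors = list(cohort.truth["donor_id"])
    burdens = compute_burden(filtered.variants, config.panel, donors=donors)
    pd.DataFrame([dataclasses.asdict(b) for b in burdens]).to_csv(
        out / "burden.tsv", sep="\t", index=False
    )
    hyper_calls = {b.donor_id: b.hypermutated for b in burdens}
    truth_labels = dict(zip(cohort.truth["donor_id"], cohort.truth["hypermutated"]))
    roc = random_panel_experiment(
        filtered.variants, truth_labels, sorted(config.cohort.gene_weights),
        config.roc_config,
        universe_footprint_mb=config.cohort.footprint_mb
        * len(config.cohort.gene_weights) / len(config.panel.genes),
    )
    roc.curves.to_csv(out / "panel_roc_curves.tsv", sep="\t", index=False)
    roc.summary.to_csv(out / "panel_roc_summary.tsv", sep="\t", index=False)
    manifest["stages"]["burden"] = {
        "n_hypermutated": int(sum(hyper_calls.values())),
        "roc_sizes": list(map(int, roc.summary["panel_size"])),
    }

    # 4. signatures ---------------------------------------------------------
    ctx = build_context_matrix(filtered.variants, donors=donors)
    nmf = extract_signatures(ctx, k=config.nmf_k, n_restarts=3, seed=config.seed)
    pd.DataFrame(
        nmf.signatures, columns=[f"denovo_{i+1}" for i in range(config.nmf_k)]
    ).to_csv(out / "signatures_denovo.tsv", sep="\t", index=False)
    catalog = reference_catalog()
    exposures = []
    for i, donor in enumerate(ctx.donors):
        if ctx.counts[i].sum() == 0:
            continue
        res = deconvolve(ctx.counts[i], catalog, donor_id=donor)
        exposures.append({"donor_id": donor, **res.weights, "unassigned": res.unassigned})
    pd.DataFrame(exposures).to_csv(out / "signature_exposures.tsv", sep="\t", index=False)
    manifest["stages"]["signatures"] = {
        "classifiable_donors": len(exposures),
        "unclassifiable_snvs": ctx.n_unclassifiable,
    }

    # 5. cluster ------------------------------------------------------------
    gene_set = config.gene_set or GeneSet(
        "default", tuple(sorted(config.cohort.gene_weights))
    )
    non_hyper = [d for d in donors if not hyper_calls.get(d)]
    profiles = {d: set() for d in non_hyper}
    for v in filtered.variants:
        if v.donor_id in profiles and v.variant_class is not VariantClass.SILENT:
            profiles[v.donor_id].add(v.gene)
    sim = build_similarity(profiles, gene_set)
    selection = model_select(
        sim.values, config.k_range, config.distances, config.linkages
    )
    dist_name, linkage, k = selection.selected
    clustering = hierarchical_cluster(
        pairwise_distance(sim.values, dist_name), linkage, k,
        donors=sim.donors, distance_name=dist_name,
    )
    labels = clustering.labels_by_donor()
    selection.grid.to_csv(out / "stability_grid.tsv", sep="\t", index=False)
    pd.DataFrame(
        {"donor_id": sim.donors, "cluster": clustering.labels}
    ).to_csv(out / "cluster_labels.tsv", sep="\t", index=False)
    pd.DataFrame(
        clustering.merge_history, columns=["left", "right", "height"]
    ).to_csv(out / "merge_history.tsv", sep="\t", index=False)
    manifest["stages"]["cluster"] = {
        "selected": list(selection.selected), "n_donors": len(non_hyper),
    }

    # 6. associate ----------------------------------------------------------
    all_labels: dict[str, object] = dict(labels)
    for d in donors:
        if hyper_calls.get(d):
            all_labels[d] = "hypermutated"
    assoc = cluster_associations(all_labels, cohort.clinical)
    assoc_rows = []
    for r in assoc:
        row = {
            "cluster": r.unit, "category": r.category,
            "a": r.table.a, "b": r.table.b, "c": r.table.c, "d": r.table.d,
            "odds_ratio": r.odds_ratio, "p_value": r.p_value,
        }
        if r.p_value < config.alpha:
            est = fisher_power(r.table, r.table.total, alpha=config.alpha,
                               n_sims=200, seed=config.seed)
            row["power"] = est.power
        assoc_rows.append(row)
    pd.DataFrame(assoc_rows).to_csv(out / "cluster_associations.tsv", sep="\t", index=False)
    manifest["stages"]["associate"] = {
        "tests": len(assoc_rows),
        "significant": int(sum(1 for r in assoc if r.p_value < config.alpha)),
    }

    # 7. survival -----------------------------------------------------------
    sets = filter_stage4_chain(cohort.survival, cohort.clinical, labels=all_labels)
    pd.DataFrame(sets.trace.steps, columns=["step", "n"]).to_csv(
        out / "exclusion_trace.tsv", sep="\t", index=False
    )
    km_groups: dict[str, tuple[list[float], list[bool]]] = {}
    for r in sets.km_set:
        key = str(all_labels.get(r.donor_id, "unlabeled"))
        km_groups.setdefault(key, ([], []))
        km_groups[key][0].append(r.pfs_days)
        km_groups[key][1].append(r.event)
    km_rows = []
    for name, (ts, evs) in sorted(km_groups.items()):
        curve = km_estimate(ts, evs)
        for t, s in zip(curve.times, curve.survival):
            km_rows.append({"group": name, "time": t, "survival": s})
    pd.DataFrame(km_rows).to_csv(out / "km_curves.tsv", sep="\t", index=False)
    logrank_p = None
    usable = {k: v for k, v in km_groups.items() if len(v[0]) >= 2}
    if len(usable) >= 2:
        logrank_p = logrank_test(usable).p_value
    wf = waterfall_data(
        {r.donor_id: r.best_response_pct for r in sets.waterfall_set}, labels=all_labels
    )
    wf.to_csv(out / "waterfall.tsv", sep="\t", index=False)
    manifest["stages"]["survival"] = {
        "trace": sets.trace.counts(),
        "logrank_p": logrank_p,
        "waterfall_donors": len(wf),
    }

    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest
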