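"""Synthetic cohort generator.

Emulates the statistical structure of a targeted-panel colorectal-cancer
cohort: ~200 donors of whom ~8% are hypermutated (background 5 mut/Mb,
hypermutated 30 mut/Mb by default), gene-level mutation propensities
concentrated in CRC driver genes, SNVs drawn from mixtures of reference
trinucleotide signatures (hypermutated donors lean on MMR/POLE-like
components), optional planted co-mutation clusters that shift clinical
odds and progression hazards, correlated clinical covariates, and
exponential progression-free survival with uniform censoring.

Determinism: every donor draws from its own substream keyed by
``(seed, donor index, stream tag)``, so enlarging the cohort never perturbs
earlier donors and a fixed seed reproduces output byte-identically.
"""

from __future__ import annotations

from dataclasses import dataclass, field
import numpy as np
import pandas as pd

from .io import (
    ClinicalRecord,
    PanelDefinition,
    SurvivalRecord,
    VariantClass,
    VariantRecord,
    VariantType,
)
from .signatures import SignatureCatalog, channel_to_snv, reference_catalog

__all__ = [
    "ClusterProfile",
    "CohortSpec",
    "SimulatedCohort",
    "simulate_cohort",
    "simulate_wes_panel_pair",
    "PairedCohort",
    "planted_cluster_profiles",
    "default_gene_weights",
    "default_panel",
]

_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}

#: CRC driver genes and relative mutation propensities (weight 1 = background)
_DRIVER_WEIGHTS = {
    "APC": 40.0, "TP53": 35.0, "KRAS": 25.0, "PIK3CA": 12.0, "SMAD4": 8.0,
    "FBXW7": 7.0, "BRAF": 6.0, "RNF43": 5.0, "PTEN": 5.0, "ERBB2": 4.0,
    "NRAS": 4.0, "SOX9": 4.0, "ARID1A": 4.0, "AMER1": 3.0, "TCF7L2": 3.0,
    "ATM": 3.0, "BRCA2": 3.0, "POLE": 2.0, "SMAD2": 2.0, "CTNNB1": 2.0,
    "SRC": 1.5, "TGFB2": 1.5, "MSH2": 1.5, "MSH6": 1.5, "MLH1": 1.5,
    "PMS2": 1.5, "CDKN2A": 1.5, "MYC": 1.5, "EGFR": 1.5, "NF1": 1.5,
}

_N_FILLER_GENES = 400


def default_gene_weights() -> dict[str, float]:
    """Driver-weighted gene universe: 30 named CRC genes + 400 filler genes."""
    weights = dict(_DRIVER_WEIGHTS)
    for i in range(1, _N_FILLER_GENES + 1):
        weights[f"GENE{i:03d}"] = 1.0
    return weights


def default_panel(footprint_mb: float = 1.6) -> PanelDefinition:
    """A 415-gene panel over the default universe (all 30 drivers + 385 fillers)."""
    genes = list(_DRIVER_WEIGHTS) + [f"GENE{i:03d}" for i in range(1, 386)]
    return PanelDefinition(name="panel415", genes=frozenset(genes), footprint_mb=footprint_mb)


@dataclass(frozen=True)
class ClusterProfile:
    """A planted co-mutation cluster.

    Members carry every gene in ``genes`` as a mutation; ``clinical_odds``
    multiplies the odds of the aggressive level of the named dichotomous
    clinical variables; ``hazard_multiplier`` scales the PFS hazard.
    """

    name: str
    genes: tuple[str, ...]
    prevalence: float
    clinical_odds: dict[str, float] = field(default_factory=dict)
    hazard_multiplier: float = 1.0


@dataclass
class CohortSpec:
    """Study conditions for the synthetic cohort."""

    n_donors: int = 200
    hyper_fraction: float = 0.08
    background_rate_per_mb: float = 5.0
    hyper_rate_per_mb: float = 30.0
    footprint_mb: float = 1.6
    gene_weights: dict[str, float] = field(default_factory=default_gene_weights)
    signature_weights_normal: tuple[float, ...] = (0.55, 0.10, 0.0, 0.15, 0.20)
    signature_weights_hyper: tuple[float, ...] = (0.10, 0.50, 0.25, 0.05, 0.10)
    cluster_profiles: tuple[ClusterProfile, ...] = ()
    germline_contam_rate: float = 2.0   # spurious germline calls per donor (tumor-only noise)
    seed: int = 0
    catalog: SignatureCatalog | None = None

    def __post_init__(self) -> None:
        if self.background_rate_per_mb <= 0 or self.hyper_rate_per_mb <= 0:
            raise ValueError("rates must be positive")
        if self.hyper_rate_per_mb <= self.background_rate_per_mb:
            raise ValueError("hyper rate must exceed background rate")
        if not 0.0 <= self.hyper_fraction <= 1.0:
            raise ValueError("hyper_fraction must be in [0, 1]")
        for name in ("signature_weights_normal", "signature_weights_hyper"):
            w = np.asarray(getattr(self, name), dtype=float)
            if abs(w.sum() - 1.0) > 1e-9 or (w < 0).any():
                raise ValueError(f"{name} must be nonnegative and sum to 1")
        if self.hyper_rate_per_mb * self.footprint_mb > 1e6:
            raise ValueError("expected per-donor mutation count exceeds 1e6 guard")
        total_prev = sum(p.prevalence for p in self.cluster_profiles)
        if total_prev > 1.0 + 1e-9:
            raise ValueError("cluster prevalences sum above 1")


@dataclass
class SimulatedCohort:
    variants: list[VariantRecord]
    clinical: list[ClinicalRecord]
    survival: list[SurvivalRecord]
    truth: pd.DataFrame  # donor_id, hypermutated, cluster, n_snvs_true, signature_group


def _rng(seed: int, donor: int, stream: int) -> np.random.Generator:
    return np.random.default_rng([seed, donor, stream])


_STREAM_LABEL, _STREAM_MUT, _STREAM_CLIN, _STREAM_SURV, _STREAM_CONTAM = range(5)


def _draw_snv(
    rng: np.random.Generator,
    donor_id: str,
    gene: str,
    gene_index: int,
    channel_cdf: np.ndarray,
    allelic_fraction: float,
) -> VariantRecord:
    channel = int(np.searchsorted(channel_cdf, rng.random(), side="right"))
    ref, alt, ctx = channel_to_snv(min(channel, 95))
    if rng.random() < 0.5:  # report on the purine strand to exercise folding
        ref, alt = _COMPLEMENT[ref], _COMPLEMENT[alt]
        ctx = "".join(_COMPLEMENT[b] for b in reversed(ctx))
    u = rng.random()
    if u < 0.65:
        vclass = VariantClass.MISSENSE
    elif u < 0.90:
        vclass = VariantClass.SILENT
    elif u < 0.97:
        vclass = VariantClass.NONSENSE
    else:
        vclass = VariantClass.SPLICE
    return VariantRecord(
        donor_id=donor_id,
        gene=gene,
        chrom=f"chr{1 + gene_index % 22}",
        pos=int(rng.integers(1, 10_000_000)),
        ref=ref,
        alt=alt,
        variant_class=vclass,
        variant_type=VariantType.SNP,
        allelic_fraction=round(float(allelic_fraction), 4),
        context3=ctx,
    )


def _draw_indel(
    rng: np.random.Generator, donor_id: str, gene: str, gene_index: int,
    allelic_fraction: float,
) -> VariantRecord:
    ins = rng.random() < 0.5
    vclass = VariantClass.FRAMESHIFT if rng.random() < 0.8 else VariantClass.INFRAME_INDEL
    return VariantRecord(
        donor_id=donor_id,
        gene=gene,
        chrom=f"chr{1 + gene_index % 22}",
        pos=int(rng.integers(1, 10_000_000)),
        ref="-" if ins else "ACT",
        alt="ACT" if ins else "-",
        variant_class=vclass,
        variant_type=VariantType.INS if ins else VariantType.DEL,
        allelic_fraction=round(float(allelic_fraction), 4),
        context3=None,
    )


def _somatic_af(rng: np.random.Generator) -> float:
    # tumor purity ~60% -> somatic AF centered near 0.3
    return float(np.clip(rng.beta(6.0, 14.0), 0.01, 0.95))


def simulate_cohort(spec: CohortSpec) -> SimulatedCohort:
    """Generate a full synthetic cohort (variants, clinical, survival, truth)."""
    catalog = spec.catalog or reference_catalog()
    genes = sorted(spec.gene_weights)
    gene_index = {g: i for i, g in enumerate(genes)}
    weights = np.array([spec.gene_weights[g] for g in genes], dtype=float)
    gene_cdf = np.cumsum(weights / weights.sum())
    mix_normal = catalog.matrix @ np.asarray(spec.signature_weights_normal)
    mix_hyper = catalog.matrix @ np.asarray(spec.signature_weights_hyper)
    cdf_normal = np.cumsum(mix_normal / mix_normal.sum())
    cdf_hyper = np.cumsum(mix_hyper / mix_hyper.sum())

    cluster_names = [p.name for p in spec.cluster_profiles]
    prevalences = np.array([p.prevalence for p in spec.cluster_profiles])

    variants: list[VariantRecord] = []
    clinical: list[ClinicalRecord] = []
    survival: list[SurvivalRecord] = []
    truth_rows = []

    for d in range(spec.n_donors):
        donor_id = f"D{d + 1:04d}"
        rng_label = _rng(spec.seed, d, _STREAM_LABEL)
        hyper = bool(rng_label.random() < spec.hyper_fraction)
        cluster = "none"
        profile: ClusterProfile | None = None
        if spec.cluster_profiles and not hyper:
            u = rng_label.random()
            acc = 0.0
            for name, prev, prof in zip(cluster_names, prevalences, spec.cluster_profiles):
                acc += prev
                if u < acc:
                    cluster, profile = name, prof
                    break
        if hyper:
            cluster = "hypermutated"

        # --- mutations ---------------------------------------------------
        rng_mut = _rng(spec.seed, d, _STREAM_MUT)
        rate = spec.hyper_rate_per_mb if hyper else spec.background_rate_per_mb
        n_mut = int(rng_mut.poisson(rate * spec.footprint_mb))
        channel_cdf = cdf_hyper if hyper else cdf_normal
        for _ in range(n_mut):
            gene = genes[int(np.searchsorted(gene_cdf, rng_mut.random(), side="right"))]
            af = _somatic_af(rng_mut)
            if rng_mut.random() < 0.92:
                variants.append(
                    _draw_snv(rng_mut, donor_id, gene, gene_index[gene], channel_cdf, af)
                )
            else:
                variants.append(
                    _draw_indel(rng_mut, donor_id, gene, gene_index[gene], af)
                )
        if profile is not None:
            for gene in profile.genes:
                variants.append(
                    _draw_snv(
                        rng_mut, donor_id, gene,
                        gene_index.get(gene, 0), channel_cdf, _somatic_af(rng_mut),
                    )
                )
        # tumor-only germline contamination: het-like AF, high population AF
        rng_contam = _rng(spec.seed, d, _STREAM_CONTAM)
        for _ in range(int(rng_contam.poisson(spec.germline_contam_rate))):
            gene = genes[int(np.searchsorted(gene_cdf, rng_contam.random(), side="right"))]
            rec = _draw_snv(
                rng_contam, donor_id, gene, gene_index[gene], channel_cdf,
                float(np.clip(rng_contam.normal(0.5, 0.05), 0.05, 0.95)),
            )
            pop = round(float(rng_contam.uniform(0.011, 0.4)), 4)
            variants.append(
                VariantRecord(
                    **{**rec.__dict__, "pop_af": {"dbSNP": pop, "ExAC": pop}}
                )
            )

        # --- clinical -----------------------------------------------------
        rng_clin = _rng(spec.seed, d, _STREAM_CLIN)
        odds_mult = (profile.clinical_odds if profile else {})
        base_p = 0.35

        def aggressive(var: str) -> bool:
            odds = base_p / (1 - base_p) * odds_mult.get(var, 1.0)
            return bool(rng_clin.random() < odds / (1 + odds))

        site = "colon" if rng_clin.random() < 0.7 else "rectum"
        if site == "rectum":
            side = "left"
        else:
            side = "right" if rng_clin.random() < 0.5 else "left"
        m1 = aggressive("M")
        n_pos = aggressive("N")
        t_high = aggressive("T")
        stage = "IV" if m1 else ("III" if n_pos else ("II" if t_high else "I"))
        clinical.append(
            ClinicalRecord(
                donor_id=donor_id,
                sex="M" if rng_clin.random() < 0.55 else "F",
                age=float(np.clip(round(rng_clin.normal(66, 10), 1), 25, 95)),
                site=site,
                side=side,
                lymphatic_invasion="presence" if aggressive("lymphatic_invasion") else "absence",
                vascular_invasion="presence" if aggressive("vascular_invasion") else "absence",
                grade="G3" if aggressive("grade") else ("G2" if rng_clin.random() < 0.6 else "G1"),
                T="T3" if t_high and rng_clin.random() < 0.7 else ("T4" if t_high else ("T2" if rng_clin.random() < 0.6 else "T1")),
                N=("N1" if rng_clin.random() < 0.6 else "N2") if n_pos else "N0",
                M="M1" if m1 else "M0",
                stage=stage,
                diameter_mm=float(np.clip(round(rng_clin.lognormal(3.7, 0.4), 1), 5, 200)),
            )
        )

        # --- survival (Stage IV donors) ----------------------------------
        if stage == "IV":
            rng_surv = _rng(spec.seed, d, _STREAM_SURV)
            base_hazard = np.log(2) / 300.0  # median PFS ~300 days
            hazard = base_hazard * (profile.hazard_multiplier if profile else 1.0)
            t_event = float(rng_surv.exponential(1.0 / hazard))
            t_censor = float(rng_surv.uniform(200.0, 1200.0))
            observed = t_event <= t_censor
            has_ras = profile is not None and any(g in ("KRAS", "NRAS", "RAS") for g in profile.genes)
            anti_egfr = bool(rng_surv.random() < (0.15 if has_ras else 0.75))
            early_prog = bool(observed and t_event < 60 and rng_surv.random() < 0.6)
            survival.append(
                SurvivalRecord(
                    donor_id=donor_id,
                    pfs_days=round(min(t_event, t_censor), 1),
                    event=observed,
                    anti_egfr=anti_egfr,
                    surgical_resection=bool(rng_surv.random() < 0.15),
                    progressed_before_first_assessment=early_prog,
                    best_response_pct=None if early_prog else round(float(rng_surv.normal(-25, 35)), 1),
                )
            )

        truth_rows.append({
            "donor_id": donor_id,
            "hypermutated": hyper,
            "cluster": cluster,
            "n_snvs_true": n_mut,
            "signature_group": "hyper" if hyper else "normal",
        })

    return SimulatedCohort(variants, clinical, survival, pd.DataFrame(truth_rows))


def planted_cluster_profiles(
    seed: int,
    n_blocks: int = 3,
    donors_per_block: int = 8,
    genes_per_block: int = 3,
) -> tuple[dict[str, set[str]], dict[str, int]]:
    """Mutated-gene profiles with planted, well-separated co-mutation clusters,
    for validating similarity clustering and stability-based model selection.

    Each block of donors shares a disjoint set of always-mutated signature
    genes.  Noise is added along a seeded Hamiltonian cycle that alternates
    blocks: each consecutive donor pair on the cycle shares one private noise
    gene, so every donor carries exactly two noise genes, each shared with
    one donor of another block.  By construction the blocks have no internal
    substructure and no outliers (all within-block donor pairs are exactly
    exchangeable), so the only stable partition is the planted one:
    over-splitting a block keys on which cross-block noise columns survive
    and is unstable under feature deletion, while the k = ``n_blocks``
    partition is deletion-invariant.

    Returns ``(profiles, truth)`` with truth mapping donor -> block index.
    """
    rng = np.random.default_rng(seed)
    profiles: dict[str, set[str]] = {}
    truth: dict[str, int] = {}
    blocks: list[list[str]] = []
    i = 0
    for block in range(n_blocks):
        signature = {f"BLK{block}_G{g}" for g in range(genes_per_block)}
        ids = []
        for _ in range(donors_per_block):
            donor = f"d{i:03d}"
            profiles[donor] = set(signature)
            truth[donor] = block
            ids.append(donor)
            i += 1
        rng.shuffle(ids)
        blocks.append(ids)
    cycle = [
        blocks[r % n_blocks][j]
        for j in range(donors_per_block)
        for r in range(n_blocks)
    ]
    for gene in range(len(cycle)):
        a, b = cycle[gene], cycle[(gene + 1) % len(cycle)]
        profiles[a].add(f"NOISE{gene}")
        profiles[b].add(f"NOISE{gene}")
    return profiles, truth


@dataclass
class PairedCohort:
    exome_variants: list[VariantRecord]
    panel_variants: list[VariantRecord]
    truth: pd.DataFrame
    burdens: pd.DataFrame  # donor_id, wes_burden, panel_burden


def simulate_wes_panel_pair(
    spec: CohortSpec, panel: PanelDefinition, exome_mb: float
) -> PairedCohort:
    """Simulate an exome-wide cohort and its restriction to a panel.

    The panel list is exactly the exome list filtered to panel genes;
    per-donor burdens (non-silent SNVs / footprint) are computed on the
    respective footprints.
    """
    universe = {g.upper() for g in spec.gene_weights}
    missing = set(panel.genes) - universe
    if missing:
        raise ValueError(f"panel genes absent from simulated universe: {sorted(missing)[:5]}")
    if exome_mb <= panel.footprint_mb:
        raise ValueError("exome_mb must exceed the panel footprint")
    from dataclasses import replace

    wes_spec = replace(spec, footprint_mb=exome_mb)
    cohort = simulate_cohort(wes_spec)
    exome_variants = cohort.variants
    panel_variants = [v for v in exome_variants if v.gene in panel.genes]

    def burden(vlist: list[VariantRecord], mb: float) -> dict[str, float]:
        counts: dict[str, int] = {d: 0 for d in cohort.truth["donor_id"]}
        for v in vlist:
            if v.variant_type is VariantType.SNP and v.variant_class is not VariantClass.SILENT:
                counts[v.donor_id] += 1
        return {d: c / mb for d, c in counts.items()}

    wes_b = burden(exome_variants, exome_mb)
    panel_b = burden(panel_variants, panel.footprint_mb)
    burdens = pd.DataFrame({
        "donor_id": list(cohort.truth["donor_id"]),
        "wes_burden": [wes_b[d] for d in cohort.truth["donor_id"]],
        "panel_burden": [panel_b[d] for d in cohort.truth["donor_id"]],
    })
    return PairedCohort(exome_variants, panel_variants, cohort.truth, burdens)
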