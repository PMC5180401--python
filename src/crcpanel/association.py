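"""Fisher-exact association of clusters and genes with clinical variables,
with simulation-based power estimation and minimum-sample-size prediction,
plus pathway-level alteration comparison across cohorts.

The two-tailed Fisher p value follows the probability-mass ordering
convention: with margins fixed, it sums the hypergeometric probability of
every table at most as probable as the observed one (within relative
tolerance 1e-7).  No multiple-testing correction is applied by default
(raw p < 0.05 throughout); a Benjamini-Hochberg option exists but changes
the analysis away from its reference behavior and is off by default.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import hypergeom

from .io import ClinicalRecord, CopyNumberRecord, VariantClass, VariantRecord
from .clustering import hierarchical_cluster, pairwise_distance

logger = logging.getLogger(__name__)

__all__ = [
    "ContingencyTable2x2",
    "AssociationResult",
    "DichotomizationRules",
    "fisher_exact_2x2",
    "cluster_associations",
    "fisher_power",
    "PowerEstimate",
    "predict_required_n",
    "RequiredNResult",
    "gene_associations",
    "GeneAssociationResult",
    "pathway_alteration_summary",
    "Cohort",
    "DEFAULT_PATHWAYS",
    "benjamini_hochberg",
]

_REL_TOL = 1e-7


@dataclass(frozen=True)
class ContingencyTable2x2:
    """Counts (a, b | c, d): rows = group in/out, columns = category level."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("counts must be nonnegative")
        if self.total == 0:
            raise ValueError("table total must be positive")

    @property
    def total(self) -> int:
        return self.a + self.b + self.c + self.d

    def as_array(self) -> np.ndarray:
        return np.array([[self.a, self.b], [self.c, self.d]])


def fisher_exact_2x2(table: ContingencyTable2x2) -> tuple[float, float]:
    """Two-tailed Fisher exact test: ``(p_two_tailed, odds_ratio)``.

    The p value sums hypergeometric probabilities of all tables with the
    observed margins whose probability is <= the observed table's (relative
    tolerance 1e-7).  The odds ratio is the sample value ad/bc, with +inf
    when bc = 0 (and ad > 0), -- a zero margin makes the test degenerate and
    returns p = 1 with an undefined (NaN) odds ratio.
    """
    a, b, c, d = table.a, table.b, table.c, table.d
    row1, col1, n = a + b, a + c, table.total
    if row1 == 0 or row1 == n or col1 == 0 or col1 == n:
        return 1.0, float("nan")
    lo, hi = max(0, col1 - (n - row1)), min(row1, col1)
    support = np.arange(lo, hi + 1)
    pmf = hypergeom.pmf(support, n, col1, row1)
    p_obs = pmf[a - lo]
    p = float(pmf[pmf <= p_obs * (1.0 + _REL_TOL)].sum())
    if b * c == 0:
        odds = float("inf") if a * d > 0 else float("nan")
    else:
        odds = (a * d) / (b * c)
    if p >= 1.0 - 1e-12:  # full support summed; absorb float rounding
        p = 1.0
    return p, odds


@dataclass(frozen=True)
class DichotomizationRules:
    """Less- vs more-aggressive splits of the seven ordinal clinical variables."""

    rules: Mapping[str, tuple[tuple[str, ...], tuple[str, ...]]] = field(
        default_factory=lambda: {
            "lymphatic_invasion": (("absence",), ("presence",)),
            "vascular_invasion": (("absence",), ("presence",)),
            "grade": (("G1", "G2"), ("G3",)),
            "T": (("T1", "T2"), ("T3", "T4")),
            "N": (("N0",), ("N1", "N2")),
            "M": (("M0",), ("M1",)),
            "stage": (("I", "II"), ("III", "IV")),
        }
    )

    def variables(self) -> list[str]:
        return list(self.rules)

    def is_aggressive(self, record: ClinicalRecord, variable: str) -> bool | None:
        """True = more aggressive, False = less, None = missing value."""
        value = getattr(record, variable)
        if value is None:
            return None
        less, more = self.rules[variable]
        if value in more:
            return True
        if value in less:
            return False
        raise ValueError(f"{variable}={value!r} not covered by dichotomization rule")


#: two-level variables tested as given (no dichotomization needed)
_BINARY_VARIABLES = {"sex": "M", "site": "colon", "side": "left"}


@dataclass
class AssociationResult:
    unit: str                 # cluster id or gene symbol
    category: str             # clinical variable name
    table: ContingencyTable2x2
    odds_ratio: float
    p_value: float
    power: float | None = None
    n_required: int | None = None


def _category_indicator(
    record: ClinicalRecord, category: str, rules: DichotomizationRules
) -> bool | None:
    if category in _BINARY_VARIABLES:
        value = getattr(record, category)
        return None if value is None else value == _BINARY_VARIABLES[category]
    return rules.is_aggressive(record, category)


def cluster_associations(
    labels: Mapping[str, int | str],
    clinical: Sequence[ClinicalRecord],
    rules: DichotomizationRules | None = None,
    reference_donors: Sequence[str] | None = None,
) -> list[AssociationResult]:
    """Per-cluster x per-category two-tailed Fisher tests.

    Each cluster is compared against the reference set — by default all
    labeled donors in the other clusters (so a hypermutated group is tested
    against every non-hypermutated donor and vice versa).  Donors missing a
    variable are excluded pairwise.  Empty clusters are skipped with a
    warning.
    """
    rules = rules or DichotomizationRules()
    by_donor = {c.donor_id: c for c in clinical}
    categories = list(_BINARY_VARIABLES) + rules.variables()
    clusters = sorted({str(v) for v in labels.values()})
    results = []
    for cluster in clusters:
        members = [d for d, c in labels.items() if str(c) == cluster and d in by_donor]
        if reference_donors is not None:
            others = [d for d in reference_donors if d in by_donor and str(labels.get(d)) != cluster]
        else:
            others = [d for d, c in labels.items() if str(c) != cluster and d in by_donor]
        if not members:
            logger.warning("cluster %s has no donors with clinical data; skipped", cluster)
            continue
        for category in categories:
            def count(donors: Sequence[str]) -> tuple[int, int]:
                yes = no = 0
                for d in donors:
                    flag = _category_indicator(by_donor[d], category, rules)
                    if flag is True:
                        yes += 1
                    elif flag is False:
                        no += 1
                return yes, no
            a, b = count(members)
            c, d = count(others)
            if a + b + c + d == 0:
                continue
            table = ContingencyTable2x2(a, b, c, d)
            p, odds = fisher_exact_2x2(table)
            results.append(AssociationResult(cluster, category, table, odds, p))
    return results


# ---------------------------------------------------------------------------
# Power simulation and sample-size prediction
# ---------------------------------------------------------------------------

@dataclass
class PowerEstimate:
    power: float
    mc_se: float
    n_sims: int
    alpha: float


def fisher_power(
    table: ContingencyTable2x2,
    n: int,
    alpha: float = 0.05,
    n_sims: int = 1000,
    seed: int = 0,
) -> PowerEstimate:
    """Monte-Carlo power of the two-tailed Fisher test at total sample size n.

    The two group sizes are fixed at the observed row split of ``n``; each
    group's outcomes are drawn binomially at the group's observed cell
    probability.  Power is the fraction of simulated tables with p < alpha;
    the binomial Monte-Carlo standard error is reported alongside.
    """
    row1 = table.a + table.b
    row2 = table.c + table.d
    if row1 == 0 or row2 == 0:
        raise ValueError("both groups must be nonempty")
    n1 = max(1, round(n * row1 / table.total))
    n2 = max(1, n - n1)
    p1 = table.a / row1
    p2 = table.c / row2
    rng = np.random.default_rng(seed)
    a_draws = rng.binomial(n1, p1, size=n_sims)
    c_draws = rng.binomial(n2, p2, size=n_sims)
    cache: dict[tuple[int, int], float] = {}
    hits = 0
    for a_sim, c_sim in zip(a_draws, c_draws):
        key = (int(a_sim), int(c_sim))
        if key not in cache:
            cache[key] = fisher_exact_2x2(
                ContingencyTable2x2(key[0], n1 - key[0], key[1], n2 - key[1])
            )[0]
        hits += cache[key] < alpha
    power = hits / n_sims
    return PowerEstimate(power, float(np.sqrt(power * (1 - power) / n_sims)), n_sims, alpha)


@dataclass
class RequiredNResult:
    n_required: int | None    # None = "not reached" on the grid
    trace: pd.DataFrame       # n, power, mc_se


def predict_required_n(
    observed_table: ContingencyTable2x2,
    alpha: float = 0.05,
    power_target: float = 0.8,
    n_grid: Sequence[int] = tuple(range(20, 501, 10)),
    n_sims: int = 1000,
    seed: int = 0,
) -> RequiredNResult:
    """Smallest grid sample size at which the test reaches the target power.

    Hypothetical cohorts keep the observed cell percentages; each grid n is
    simulated ``n_sims`` times.  Returns the minimum n with estimated power
    >= ``power_target`` (None when the grid never reaches it) plus the full
    (n, power) trace.
    """
    rows = []
    n_required = None
    for i, n in enumerate(n_grid):
        est = fisher_power(observed_table, n, alpha=alpha, n_sims=n_sims, seed=seed + i)
        rows.append({"n": n, "power": est.power, "mc_se": est.mc_se})
        if n_required is None and est.power >= power_target:
            n_required = n
    return RequiredNResult(n_required, pd.DataFrame(rows))


# ---------------------------------------------------------------------------
# Gene-level association
# ---------------------------------------------------------------------------

#: pseudonumber replacing +-infinite log odds ratios in the clustered matrix
LOG_ODDS_CLAMP = 4.0


@dataclass
class GeneAssociationResult:
    significant_genes: list[str]
    log_odds: pd.DataFrame        # genes x categories, finite after clamping
    results: list[AssociationResult]
    gene_clusters: dict[str, int] | None = None


def gene_associations(
    profiles: Mapping[str, set[str]],
    clinical: Sequence[ClinicalRecord],
    rules: DichotomizationRules | None = None,
    alpha: float = 0.05,
    cluster_k: int = 2,
) -> GeneAssociationResult:
    """Per-gene Fisher tests against the seven dichotomized variables.

    For each gene, mutated-vs-wild-type donors are crossed with
    aggressive-vs-not per category.  Genes significant in at least one
    category (p < alpha) are kept; their natural-log odds-ratio matrix
    (infinite values replaced by the +-4 pseudonumbers) is clustered with
    Euclidean distance and Ward linkage.
    """
    rules = rules or DichotomizationRules()
    by_donor = {c.donor_id: c for c in clinical}
    donors = [d for d in profiles if d in by_donor]
    genes = sorted({g for d in donors for g in profiles[d]})
    results: list[AssociationResult] = []
    log_odds_rows: dict[str, dict[str, float]] = {}
    significant: list[str] = []
    for gene in genes:
        any_sig = False
        row = {}
        for category in rules.variables():
            a = b = c = d = 0
            for donor in donors:
                flag = rules.is_aggressive(by_donor[donor], category)
                if flag is None:
                    continue
                mutated = gene in profiles[donor]
                if mutated and flag:
                    a += 1
                elif mutated:
                    b += 1
                elif flag:
                    c += 1
                else:
                    d += 1
            if a + b + c + d == 0:
                row[category] = 0.0
                continue
            table = ContingencyTable2x2(a, b, c, d)
            p, odds = fisher_exact_2x2(table)
            results.append(AssociationResult(gene, category, table, odds, p))
            if p < alpha:
                any_sig = True
            if np.isnan(odds):
                row[category] = 0.0
            elif np.isinf(odds):
                row[category] = LOG_ODDS_CLAMP
            elif odds == 0.0:
                row[category] = -LOG_ODDS_CLAMP
            else:
                row[category] = float(np.log(odds))
        if any_sig:
            significant.append(gene)
            log_odds_rows[gene] = row
    matrix = pd.DataFrame.from_dict(log_odds_rows, orient="index").reindex(
        columns=rules.variables()
    )
    gene_clusters = None
    if len(significant) >= 2:
        k = min(cluster_k, len(significant))
        result = hierarchical_cluster(
            pairwise_distance(matrix.to_numpy(), "euclidean"), "ward.D", k,
            donors=significant, distance_name="euclidean",
        )
        gene_clusters = result.labels_by_donor()
    return GeneAssociationResult(significant, matrix, results, gene_clusters)


# ---------------------------------------------------------------------------
# Pathway-level alteration comparison
# ---------------------------------------------------------------------------

DEFAULT_PATHWAYS: dict[str, tuple[str, ...]] = {
    "WNT": ("APC", "CTNNB1", "RNF43", "AMER1", "TCF7L2", "SOX9"),
    "RAS_RAF": ("KRAS", "NRAS", "BRAF", "NF1", "EGFR", "ERBB2"),
    "PI3K": ("PIK3CA", "PTEN", "AKT1"),
    "cell_cycle": ("TP53", "CDKN2A", "MYC", "RB1"),
    "dsDNA_break_repair": ("BRCA2", "BRCA1", "ATM", "BAP1", "FANCD2"),
}


@dataclass
class Cohort:
    """A labeled call set for cross-cohort pathway comparison."""

    name: str
    variants: Sequence[VariantRecord]
    cnvs: Sequence[CopyNumberRecord]
    donors: Sequence[str]


def pathway_alteration_summary(
    cohorts: Sequence[Cohort],
    pathway_defs: Mapping[str, Sequence[str]] | None = None,
    gain_threshold: float = 2.5,
    loss_threshold: float = 0.5,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Unique-altered-donor counts per pathway and pairwise Fisher comparisons.

    A donor counts once per pathway no matter how many member genes are
    altered; alteration = any non-silent variant, or a CNV beyond the
    gain/loss thresholds, in a member gene.  Returns ``(summary, tests)``:
    per-cohort counts/fractions, and per-pathway 2x2 Fisher p for every
    cohort pair.
    """
    if len(cohorts) < 2:
        raise ValueError("need at least two cohorts to compare")
    pathway_defs = pathway_defs or DEFAULT_PATHWAYS
    altered: dict[tuple[str, str], set[str]] = {}
    for cohort in cohorts:
        for pathway, genes in pathway_defs.items():
            geneset = {g.upper() for g in genes}
            hit: set[str] = set()
            for v in cohort.variants:
                if v.variant_class is not VariantClass.SILENT and v.gene in geneset:
                    hit.add(v.donor_id)
            for c in cohort.cnvs:
                if c.gene.upper() in geneset and (
                    c.fold_change > gain_threshold or c.fold_change < loss_threshold
                ):
                    hit.add(c.donor_id)
            altered[(cohort.name, pathway)] = hit & set(cohort.donors)
    summary_rows = []
    for cohort in cohorts:
        for pathway in pathway_defs:
            n_alt = len(altered[(cohort.name, pathway)])
            n = len(cohort.donors)
            summary_rows.append({
                "cohort": cohort.name, "pathway": pathway,
                "n_altered": n_alt, "n_donors": n,
                "fraction": n_alt / n if n else 0.0,
            })
    test_rows = []
    for i in range(len(cohorts)):
        for j in range(i + 1, len(cohorts)):
            ci, cj = cohorts[i], cohorts[j]
            for pathway in pathway_defs:
                ai = len(altered[(ci.name, pathway)])
                aj = len(altered[(cj.name, pathway)])
                table = ContingencyTable2x2(
                    ai, len(ci.donors) - ai, aj, len(cj.donors) - aj
                )
                p, odds = fisher_exact_2x2(table)
                test_rows.append({
                    "pathway": pathway, "cohort_1": ci.name, "cohort_2": cj.name,
                    "p_value": p, "odds_ratio": odds,
                })
    return pd.DataFrame(summary_rows), pd.DataFrame(test_rows)


def benjamini_hochberg(p_values: Sequence[float]) -> np.ndarray:
    """BH-adjusted p values (optional; raw p values are the default analysis)."""
    p = np.asarray(p_values, dtype=float)
    order = np.argsort(p)
    ranked = p[order] * len(p) / (np.arange(len(p)) + 1)
    adjusted = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty_like(p)
    out[order] = np.clip(adjusted, 0, 1)
    return out
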