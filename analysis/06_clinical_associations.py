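"""Cluster- and gene-level clinical association with power prediction.

Runs per-cluster two-tailed Fisher tests against all other donors (sex,
site, side, plus the seven dichotomized aggressiveness variables), estimates
the power of significant tests by simulation, predicts the minimum cohort
size reaching 80% power on the 20-500 grid, extracts genes associated with
aggressiveness (log-odds matrix with +-4 pseudonumbers), and compares
pathway alteration fractions against an independent synthetic cohort.

Reads results/clustering/, results/cohort/; writes results/associations/.
"""

from pathlib import Path

import pandas as pd

from crcpanel.association import (
    Cohort,
    cluster_associations,
    fisher_power,
    gene_associations,
    pathway_alteration_summary,
    predict_required_n,
)
from crcpanel.io import VariantClass, read_clinical, read_maf
from crcpanel.simulate import CohortSpec, simulate_cohort

OUT = Path("results/associations")
ALPHA = 0.05


def main() -> None:
    clinical = read_clinical("results/cohort/clinical.tsv")
    labels_df = pd.read_csv("results/clustering/cluster_labels.tsv", sep="\t")
    labels = dict(zip(labels_df["donor_id"], labels_df["cluster"]))
    burden = pd.read_csv("results/burden/burden.tsv", sep="\t")
    for donor in burden.loc[burden["hypermutated"], "donor_id"]:
        labels[donor] = "hypermutated"

    results = cluster_associations(labels, clinical)
    rows = []
    n_sig = 0
    for r in results:
        row = {"cluster": r.unit, "category": r.category,
               "a": r.table.a, "b": r.table.b, "c": r.table.c, "d": r.table.d,
               "odds_ratio": r.odds_ratio, "p_value": r.p_value}
        if r.p_value < ALPHA:
            n_sig += 1
            est = fisher_power(r.table, r.table.total, n_sims=1000, seed=0)
            row["power"] = est.power
            if est.power < 0.8:
                req = predict_required_n(r.table, n_sims=200, seed=1)
                row["n_required"] = req.n_required
        rows.append(row)
    OUT.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(rows).to_csv(OUT / "cluster_associations.tsv", sep="\t", index=False)
    print(f"{n_sig}/{len(rows)} cluster x category tests significant at p < {ALPHA}")

    variants, _ = read_maf("results/filtering/variants_somatic.tsv", dialect="minimal_tsv")
    profiles: dict[str, set] = {}
    for v in variants:
        if v.variant_class is not VariantClass.SILENT:
            profiles.setdefault(v.donor_id, set()).add(v.gene)
    gene_res = gene_associations(profiles, clinical)
    gene_res.log_odds.to_csv(OUT / "gene_log_odds.tsv", sep="\t", index_label="gene")
    print(f"{len(gene_res.significant_genes)} genes associated with at least one "
          f"aggressiveness category: {sorted(gene_res.significant_genes)[:8]} ...")

    # pathway comparison against an independent cohort simulated at US-like size
    other = simulate_cohort(CohortSpec(n_donors=108, seed=99))
    cohorts = [
        Cohort("primary", variants, [], [c.donor_id for c in clinical]),
        Cohort("replication", other.variants, [], list(other.truth["donor_id"])),
    ]
    summary, tests = pathway_alteration_summary(cohorts)
    summary.to_csv(OUT / "pathway_summary.tsv", sep="\t", index=False)
    tests.to_csv(OUT / "pathway_tests.tsv", sep="\t", index=False)
    frac = summary[summary["cohort"] == "primary"].set_index("pathway")["fraction"]
    print("pathway alteration fractions (primary cohort): "
          + ", ".join(f"{p}={f:.2f}" for p, f in frac.items()))


if __name__ == "__main__":
    main()
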