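"""Donor-similarity clustering of non-hypermutated donors with
stability-based model selection.

Builds the 1/(c_ij+1) similarity matrix over the actionable gene set
(KRAS/NRAS merged into RAS), evaluates APN/AD/ADM/FOM over a
distance x linkage x k grid, selects the most stable setting, cuts the
dendrogram, and annotates each cluster with a therapy recommendation.

Reads results/burden/ and results/filtering/; writes results/clustering/.
"""

from pathlib import Path

import pandas as pd

from crcpanel.clustering import (
    GeneSet,
    annotate_therapy,
    build_similarity,
    hierarchical_cluster,
    model_select,
    pairwise_distance,
)
from crcpanel.io import VariantClass, read_maf

OUT = Path("results/clustering")

ACTIONABLE = GeneSet(
    "actionable",
    ("KRAS", "NRAS", "BRAF", "PIK3CA", "PTEN", "ERBB2", "RNF43", "APC", "TP53"),
)


def main() -> None:
    variants, _ = read_maf("results/filtering/variants_somatic.tsv", dialect="minimal_tsv")
    burden = pd.read_csv("results/burden/burden.tsv", sep="\t")
    non_hyper = list(burden.loc[~burden["hypermutated"], "donor_id"])
    profiles = {d: set() for d in non_hyper}
    for v in variants:
        if v.donor_id in profiles and v.variant_class is not VariantClass.SILENT:
            profiles[v.donor_id].add(v.gene)

    sim = build_similarity(profiles, ACTIONABLE)
    selection = model_select(
        sim.values, k_range=range(2, 7),
        distances=("euclidean",), linkages=("ward.D", "average"),
    )
    dist_name, linkage, k = selection.selected
    print(f"selected distance={dist_name} linkage={linkage} k={k} "
          f"over a {len(selection.grid)}-setting grid")
    clustering = hierarchical_cluster(
        pairwise_distance(sim.values, dist_name), linkage, k,
        donors=sim.donors, distance_name=dist_name,
    )
    OUT.mkdir(parents=True, exist_ok=True)
    selection.grid.to_csv(OUT / "stability_grid.tsv", sep="\t", index=False)
    labels = clustering.labels_by_donor()
    pd.DataFrame({"donor_id": sim.donors, "cluster": clustering.labels}).to_csv(
        OUT / "cluster_labels.tsv", sep="\t", index=False
    )

    # tag each cluster by its most enriched gene (all-wild-type if none)
    cluster_driver = {}
    for cluster in sorted(set(labels.values())):
        members = [d for d, c in labels.items() if c == cluster]
        gene_counts: dict[str, int] = {}
        for d in members:
            for g in ACTIONABLE.apply(profiles[d]):
                gene_counts[g] = gene_counts.get(g, 0) + 1
        if not gene_counts:
            cluster_driver[cluster] = "all_wt"
        else:
            top = max(gene_counts, key=gene_counts.get)
            cluster_driver[cluster] = top if gene_counts[top] > len(members) / 2 else "all_wt"
        print(f"  cluster {cluster}: n={len(members)} driver={cluster_driver[cluster]}")
    therapy = annotate_therapy(labels, cluster_driver)
    pd.DataFrame(
        [{"donor_id": d, "cluster": labels[d], "therapy": t} for d, t in therapy.items()]
    ).to_csv(OUT / "therapy_annotation.tsv", sep="\t", index=False)


if __name__ == "__main__":
    main()
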