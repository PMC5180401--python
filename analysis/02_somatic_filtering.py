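"""Tumor-only somatic filtering of the simulated call set.

Applies the population-frequency filter (any database AF > 1% deprioritized),
the 10% allelic-fraction calling floor, and the two-component germline/somatic
allele-fraction model, reporting removal counts by reason.

Reads results/cohort/variants.tsv; writes results/filtering/.
"""

from pathlib import Path

import pandas as pd

from crcpanel.filtering import apply_filters
from crcpanel.io import read_maf, write_maf

IN = Path("results/cohort")
OUT = Path("results/filtering")


def main() -> None:
    variants, problems = read_maf(IN / "variants.tsv", dialect="minimal_tsv")
    assert not problems
    result = apply_filters(variants)
    OUT.mkdir(parents=True, exist_ok=True)
    write_maf(result.variants, OUT / "variants_somatic.tsv")
    pd.DataFrame(
        [{"reason": k, "removed": v} for k, v in result.counts.items()]
    ).to_csv(OUT / "removal_counts.tsv", sep="\t", index=False)
    print(f"kept {len(result.variants)} of {len(variants)} calls as putatively somatic")
    for reason, n in result.counts.items():
        print(f"  removed {n:4d}  ({reason})")


if __name__ == "__main__":
    main()
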