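import numpy as np
import pytest

from crcpanel.io import VariantClass, VariantRecord, VariantType


def make_snv(
    donor="D1",
    gene="TP53",
    pos=100,
    ref="C",
    alt="T",
    vclass=VariantClass.MISSENSE,
    af=0.3,
    pop_af=None,
    context3=None,
):
    return VariantRecord(
        donor_id=donor,
        gene=gene,
        chrom="chr1",
        pos=pos,
        ref=ref,
        alt=alt,
        variant_class=vclass,
        variant_type=VariantType.SNP,
        allelic_fraction=af,
        pop_af=pop_af,
        context3=context3,
    )


def make_indel(donor="D1", gene="APC", pos=200, vclass=VariantClass.FRAMESHIFT, af=0.3):
    return VariantRecord(
        donor_id=donor,
        gene=gene,
        chrom="chr1",
        pos=pos,
        ref="-",
        alt="ACT",
        variant_class=vclass,
        variant_type=VariantType.INS,
        allelic_fraction=af,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(0)
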