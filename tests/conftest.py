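import numpy as np
import pytest

from dnmprior.core_io import Cohort, DnmRecord, VariantClass


def make_record(
    gene="GENE1",
    sample_id="case_00001",
    variant_class=VariantClass.MISSENSE,
    damaging_votes=10,
    max_maf=0.0,
    cohort=Cohort.CASE,
    pos=100,
):
    if variant_class is not VariantClass.MISSENSE:
        damaging_votes = None
    return DnmRecord(
        sample_id=sample_id,
        cohort=cohort,
        gene=gene,
        chrom="chr1",
        pos=pos,
        ref="A",
        alt="T",
        variant_class=variant_class,
        damaging_votes=damaging_votes,
        max_maf=max_maf,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
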