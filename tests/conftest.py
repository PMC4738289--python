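import numpy as np
import pytest

from famvar.pedigree import Individual, Pedigree, Sex
from famvar.segregation import (
    Annotation,
    Consequence,
    GenotypeCall,
    RegionClass,
    VariantSite,
    Zygosity,
)
from famvar.simulate import SEQUENCED_SAMPLES, family_pedigree

AFFECTED = ("II.3", "III.3")
UNAFFECTED_SEQUENCED = ("II.4", "III.1", "III.2", "III.4")


@pytest.fixture
def family():
    """The six-exome study pedigree with its ungenotyped connectors."""
    return family_pedigree()


@pytest.fixture
def sequenced_family():
    """A pedigree containing only the six sequenced members (founder
    parents collapsed), as a PED file would usually encode it."""
    return Pedigree(
        [
            Individual("II.3", sex=Sex.MALE, affected=True),
            Individual("II.4", sex=Sex.FEMALE),
            Individual("III.1", sex=Sex.FEMALE),
            Individual("III.2", sex=Sex.MALE),
            Individual("III.3", father_id="II.3", mother_id="II.4", sex=Sex.FEMALE, affected=True),
            Individual("III.4", father_id="II.3", mother_id="II.4", sex=Sex.FEMALE),
        ],
        name="FAM1",
    )


def make_variant(pattern, chrom="chr1", pos=100, ref="A", alt="G", site_pass=True):
    """Build a VariantSite from {sample: 'het'|'hom_ref'|'hom_alt'|'missing'}."""
    genotypes = {
        s: GenotypeCall(s, Zygosity(pattern.get(s, "hom_ref")))
        for s in SEQUENCED_SAMPLES
    }
    return VariantSite(
        chrom=chrom, pos=pos, ref=ref, alt=alt, site_pass=site_pass, genotypes=genotypes
    )


def make_annotation(
    region="exonic",
    consequence="nonsynonymous_snv",
    gene="GENE00001",
    phylop=1.0,
    sift=0.5,
    polyphen=0.5,
    aa_change=None,
):
    return Annotation(
        gene=gene,
        region_class=RegionClass(region),
        consequence=Consequence(consequence),
        phylop=phylop,
        sift=sift,
        polyphen_hdiv=polyphen,
        aa_change=aa_change,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(2024)
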