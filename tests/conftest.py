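import pytest

from haplobank.model import (
    DonorRecord,
    Haplotype,
    HaplotypeFrequencyRecord,
    LocusGenotype,
    ResolutionLevel,
    parse_allele,
)

SIX = ("A", "B", "C", "DRB1", "DQA1", "DQB1")


def allele(text, gene=None):
    return parse_allele(text, gene_hint=gene)


def genotype(gene, a1, a2, pp=None):
    return LocusGenotype(
        gene=gene,
        allele_1=parse_allele(a1, gene_hint=gene),
        allele_2=parse_allele(a2, gene_hint=gene),
        posterior_probability=pp,
    )


def donor(donor_id, allele_pairs, pp=None):
    """Build a donor from {gene: (a1, a2)} with field-only allele strings."""
    return DonorRecord(
        donor_id=donor_id,
        genotypes={g: genotype(g, a1, a2, pp) for g, (a1, a2) in allele_pairs.items()},
    )


def homozygous_donor(donor_id, hap_alleles, pp=None):
    """Donor homozygous for {gene: allele} at every given locus."""
    return donor(donor_id, {g: (a, a) for g, a in hap_alleles.items()}, pp)


HAP_COMMON = {
    "A": "03:01", "B": "35:01", "C": "04:01",
    "DRB1": "01:01", "DQA1": "01:01", "DQB1": "05:01",
}
HAP_OTHER = {
    "A": "01:01", "B": "08:01", "C": "07:01",
    "DRB1": "03:01", "DQA1": "05:01", "DQB1": "02:01",
}


def pool(freq_by_hapstring, resolution=ResolutionLevel.HIGH):
    """Frequency records from {'A*03:01~B*35:01~...': f}."""
    return tuple(
        HaplotypeFrequencyRecord(
            haplotype=Haplotype.parse(text, resolution), frequency=f
        )
        for text, f in freq_by_hapstring.items()
    )


@pytest.fixture
def toy_cohort():
    """Five donors: two homozygous for the common haplotype, one for the
    other, one heterozygous at a single locus, one fully heterozygous."""
    nearly = {g: (HAP_COMMON[g], HAP_COMMON[g]) for g in SIX}
    nearly["B"] = ("35:01", "07:02")
    mixed = {g: (HAP_COMMON[g], HAP_OTHER[g]) for g in SIX}
    return [
        homozygous_donor("d1", HAP_COMMON, pp=0.99),
        homozygous_donor("d2", HAP_COMMON, pp=0.97),
        homozygous_donor("d3", HAP_OTHER, pp=0.95),
        donor("d4", nearly, pp=0.98),
        donor("d5", mixed, pp=0.90),
    ]


@pytest.fixture
def two_hap_pool():
    return pool(
        {
            "~".join(f"{g}*{HAP_COMMON[g]}" for g in SIX): 0.10,
            "~".join(f"{g}*{HAP_OTHER[g]}" for g in SIX): 0.05,
        }
    )
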