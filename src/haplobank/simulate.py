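"""Synthetic cohort generator.

Real imputed-genotype cohorts are biobank-restricted, so every downstream
stage is exercised on synthetic cohorts with the statistical structure the
analysis assumes:

* a haplotype pool with specified frequencies, the residual mass assigned to
  a catch-all pool of unique singleton haplotypes (a conservative null: the
  residual never produces spurious homozygotes, at any resolution);
* diploid Hardy-Weinberg sampling — each donor is two independent haplotype
  draws, so a haplotype of frequency p yields homozygotes at rate p^2;
* haplotype-linked DNA markers in an MHC window: each haplotype carries a
  fixed binary marker vector, a donor is heterozygous at a marker iff its
  two haplotypes differ there, plus a small per-marker noise rate that flips
  homozygous states to heterozygous (residual within-haplotype variation);
* imputation noise: allele calls are substituted at a configured rate, with
  posterior probabilities drawn from a high-confidence distribution for
  correct calls and a degraded one for erroneous calls.

A single global seed feeds separate deterministic streams for haplotype
sampling, markers and imputation noise, so regenerating one layer leaves
the others untouched.
"""

from __future__ import annotations

import copy
import math
from dataclasses import dataclass, field as dc_field
from typing import Optional, Sequence

import numpy as np

from .datasets import FINNISH_COHORT_SIZE, finnish_six_locus_homozygotes
from .frequencies import frequency_from_expected
from .heterozygosity import WINDOWS
from .model import (
    DonorRecord,
    GenomicWindow,
    Haplotype,
    HaplotypeFrequencyRecord,
    HLAAllele,
    LocusGenotype,
    MarkerGenotype,
    MarkerState,
    ResolutionLevel,
    validate_frequency_table,
)

#: Truth table: donor_id -> the labels of the donor's two drawn haplotypes.
TruthTable = dict[str, tuple[str, str]]


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for one synthetic cohort.

    Rate defaults sit inside the ranges reported for imputed Finnish
    blood-donor data: a 1% marker noise rate (observed per-haplotype MHC
    heterozygosity spans ~0.01-2%) and a 2.3% allele-call error rate
    (reported per-locus imputation error rates span 0-4.6%).  Posterior
    probabilities for correct calls follow Beta(49, 1) (mean 0.98) and for
    erroneous calls Beta(8, 8) (mean 0.5), reproducing the observation that
    nearly all homozygote PPs exceed 0.5 with isolated values just below.
    """

    haplotype_frequencies: tuple[HaplotypeFrequencyRecord, ...]
    n_donors: int
    seed: int = 0
    n_markers: int = 0
    marker_window: GenomicWindow = dc_field(default_factory=lambda: WINDOWS["mhc_a_dqb1"])
    marker_noise_rate: float = 0.01
    imputation_error_rate: float = 0.023
    pp_correct: tuple[float, float] = (49.0, 1.0)  # Beta(a, b), mean 0.98
    pp_error: tuple[float, float] = (8.0, 8.0)  # Beta(a, b), mean 0.5

    def __post_init__(self) -> None:
        if self.n_donors < 0:
            raise ValueError("n_donors must be non-negative")
        if self.n_markers < 0:
            raise ValueError("n_markers must be non-negative")
        for name in ("marker_noise_rate", "imputation_error_rate"):
            rate = getattr(self, name)
            if not (0.0 <= rate <= 1.0):
                raise ValueError(f"{name}={rate} outside [0, 1]")
        object.__setattr__(
            self, "haplotype_frequencies", tuple(self.haplotype_frequencies)
        )
        validate_frequency_table(self.haplotype_frequencies)

    @property
    def panel(self) -> tuple[str, ...]:
        return self.haplotype_frequencies[0].haplotype.panel

    @property
    def resolution(self) -> ResolutionLevel:
        return self.haplotype_frequencies[0].haplotype.resolution

    def streams(self) -> tuple[np.random.Generator, ...]:
        """(haplotype, marker, imputation) generators from the global seed."""
        children = np.random.SeedSequence(self.seed).spawn(3)
        return tuple(np.random.default_rng(c) for c in children)


def finnish_study_pool() -> tuple[HaplotypeFrequencyRecord, ...]:
    """The 41 published six-locus haplotypes with registry frequencies
    recovered as the square roots of their printed expected (p^2) values."""
    table = finnish_six_locus_homozygotes()
    records = []
    for _, row in table.iterrows():
        hap = Haplotype.parse(row["haplotype"], ResolutionLevel.HIGH)
        records.append(
            HaplotypeFrequencyRecord(
                haplotype=hap,
                frequency=frequency_from_expected(float(row["expected_frequency"])),
                population_label="FIN",
            )
        )
    return tuple(records)


def finnish_study_config(seed: int = 0, **overrides) -> SimulationConfig:
    """Study-scale configuration: the published Finnish pool and 20,737 donors."""
    defaults = dict(
        haplotype_frequencies=finnish_study_pool(),
        n_donors=FINNISH_COHORT_SIZE,
        seed=seed,
    )
    defaults.update(overrides)
    return SimulationConfig(**defaults)


def _singleton_haplotype(panel: Sequence[str], index: int) -> tuple[str, tuple[HLAAllele, ...]]:
    """A unique catch-all haplotype for the residual frequency mass.

    The first nomenclature field is unique per singleton so two distinct
    singletons never match even after truncation to low resolution.
    """
    alleles = tuple(
        HLAAllele(gene=g, fields=(str(9_000_000 + index), "01")) for g in panel
    )
    return f"other:{index}", alleles


def sample_cohort(config: SimulationConfig) -> tuple[list[DonorRecord], TruthTable]:
    """Draw a diploid Hardy-Weinberg cohort from the configured pool.

    Each donor is two independent haplotype draws; per-locus genotypes are
    the unordered allele pairs of the two drawn haplotypes.  Posterior
    probabilities are left unset until :func:`apply_imputation_noise`.
    Deterministic given ``config.seed``.
    """
    rng_hap, _, _ = config.streams()
    n = config.n_donors
    if n == 0:
        return [], {}
    pool = config.haplotype_frequencies
    panel = config.panel
    freqs = np.array([rec.frequency for rec in pool], dtype=float)
    residual = max(0.0, 1.0 - freqs.sum())
    probs = np.append(freqs, residual)
    probs = probs / probs.sum()  # guard tiny rounding in printed frequencies
    draws = rng_hap.choice(len(pool) + 1, size=2 * n, p=probs)

    named_labels = [str(rec.haplotype) for rec in pool]
    named_alleles = [rec.haplotype.alleles for rec in pool]
    cohort: list[DonorRecord] = []
    truth: TruthTable = {}
    singleton_counter = 0
    width = max(6, len(str(n)))
    for i in range(n):
        pair = []
        for j in (2 * i, 2 * i + 1):
            idx = int(draws[j])
            if idx < len(pool):
                pair.append((named_labels[idx], named_alleles[idx]))
            else:
                pair.append(_singleton_haplotype(panel, singleton_counter))
                singleton_counter += 1
        (label1, alleles1), (label2, alleles2) = pair
        donor_id = f"D{i:0{width}d}"
        genotypes = {
            gene: LocusGenotype(gene=gene, allele_1=a1, allele_2=a2)
            for gene, a1, a2 in zip(panel, alleles1, alleles2)
        }
        cohort.append(DonorRecord(donor_id=donor_id, genotypes=genotypes))
        truth[donor_id] = (label1, label2)
    return cohort, truth


def attach_markers(
    cohort: Sequence[DonorRecord], truth: TruthTable, config: SimulationConfig
) -> np.ndarray:
    """Attach haplotype-linked marker genotypes to a cohort in place.

    Each haplotype label carries a fixed random binary vector at
    ``n_markers`` distinct positions uniformly placed in the marker window;
    a donor is heterozygous where its two vectors differ, homozygous
    elsewhere, and each homozygous state flips to heterozygous with
    ``marker_noise_rate``.  Returns the sorted marker positions.
    """
    if config.n_markers <= 0:
        raise ValueError("attach_markers requires n_markers > 0")
    window = config.marker_window
    if window.length < config.n_markers:
        raise ValueError(
            f"window of {window.length} bp cannot host {config.n_markers} distinct positions"
        )
    _, rng_mark, _ = config.streams()
    positions = np.sort(
        rng_mark.choice(
            np.arange(window.start_bp, window.end_bp + 1),
            size=config.n_markers,
            replace=False,
        )
    )
    labels = sorted({label for pair in truth.values() for label in pair})
    vectors = {
        label: rng_mark.integers(0, 2, size=config.n_markers, dtype=np.int8)
        for label in labels
    }
    state_of = {0: MarkerState.HOM_REF, 1: MarkerState.HET, 2: MarkerState.HOM_ALT}
    for donor in cohort:
        label1, label2 = truth[donor.donor_id]
        v1, v2 = vectors[label1], vectors[label2]
        dosage = v1 + v2  # 0 hom-ref, 1 het, 2 hom-alt
        if config.marker_noise_rate > 0:
            flip = rng_mark.random(config.n_markers) < config.marker_noise_rate
            dosage = np.where(flip & (dosage != 1), 1, dosage)
        donor.markers = [
            MarkerGenotype(int(pos), state_of[int(d)]) for pos, d in zip(positions, dosage)
        ]
    return positions


@dataclass
class ImputationNoiseLog:
    n_calls: int = 0
    n_errors: int = 0
    n_skipped_monoallelic: int = 0


def apply_imputation_noise(
    cohort: Sequence[DonorRecord], config: SimulationConfig
) -> tuple[list[DonorRecord], dict[tuple[str, str], tuple[HLAAllele, HLAAllele]], ImputationNoiseLog]:
    """Corrupt allele calls at the configured rate and assign posteriors.

    Each allele call is independently replaced, with probability
    ``imputation_error_rate``, by a *different* allele drawn uniformly from
    that locus's allele universe in the cohort; the locus posterior
    probability is drawn from the correct-call Beta family when both calls
    survived and from the degraded family otherwise.  Returns the noisy
    cohort, the untouched truth as a clinical-typing table keyed by
    (donor_id, gene), and a log of calls/errors/skips.  Loci whose universe
    holds a single allele cannot host an error and are skipped (counted).
    """
    _, _, rng_imp = config.streams()
    universe: dict[str, list[HLAAllele]] = {}
    for donor in cohort:
        for gene in donor.genotypes:
            universe.setdefault(gene, [])
    for gene in universe:
        seen = {
            str(a): a
            for d in cohort
            if gene in d.genotypes
            for a in d.genotypes[gene].alleles
        }
        universe[gene] = [seen[k] for k in sorted(seen)]

    log = ImputationNoiseLog()
    truth: dict[tuple[str, str], tuple[HLAAllele, HLAAllele]] = {}
    noisy: list[DonorRecord] = []
    a_c, b_c = config.pp_correct
    a_e, b_e = config.pp_error
    rate = config.imputation_error_rate
    for donor in cohort:
        new_genotypes: dict[str, LocusGenotype] = {}
        for gene, gt in donor.genotypes.items():
            truth[(donor.donor_id, gene)] = gt.alleles
            alleles = list(gt.alleles)
            erred = False
            for k in range(2):
                log.n_calls += 1
                if rate > 0 and rng_imp.random() < rate:
                    choices = [a for a in universe[gene] if a != alleles[k]]
                    if not choices:
                        log.n_skipped_monoallelic += 1
                        continue
                    alleles[k] = choices[rng_imp.integers(len(choices))]
                    erred = True
                    log.n_errors += 1
            pp = float(rng_imp.beta(a_e, b_e) if erred else rng_imp.beta(a_c, b_c))
            new_genotypes[gene] = LocusGenotype(
                gene=gene,
                allele_1=alleles[0],
                allele_2=alleles[1],
                posterior_probability=pp,
            )
        noisy.append(
            DonorRecord(
                donor_id=donor.donor_id,
                genotypes=new_genotypes,
                markers=copy.copy(donor.markers),
            )
        )
    return noisy, truth, log


def clinical_table_from_truth(
    truth: dict[tuple[str, str], tuple[HLAAllele, HLAAllele]],
    donor_ids: Optional[set[str]] = None,
) -> dict[tuple[str, str], tuple[HLAAllele, HLAAllele]]:
    """Restrict a truth table to a donor subset, as a clinical-typing table."""
    if donor_ids is None:
        return dict(truth)
    return {k: v for k, v in truth.items() if k[0] in donor_ids}
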