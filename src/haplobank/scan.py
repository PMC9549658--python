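"""Homozygote screening.

A donor is called homozygous for a panel (e.g. A..DQB1 at high resolution,
or A-B at low resolution) when, at every panel locus, its two allele calls
agree after truncation to the requested resolution.  For such a donor phase
is trivial, so the shared per-locus alleles assemble directly into the
donor's (doubled) haplotype.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Optional, Sequence

from .model import (
    DonorRecord,
    GENES,
    Haplotype,
    InsufficientResolutionError,
    LocusGenotype,
    ResolutionLevel,
    SIX_LOCUS_PANEL,
)


class MissingLocusPolicy(enum.Enum):
    """What to do with a donor lacking a genotype at a panel locus."""

    EXCLUDE_DONOR = "exclude_donor"
    TREAT_AS_HETEROZYGOUS = "treat_as_heterozygous"


@dataclass(frozen=True)
class ScanConfig:
    """Parameters of a homozygote scan.

    ``pp_threshold`` is off by default: the posterior-probability cutoff is
    reported descriptively (``min_pp`` on each call) rather than used as an
    exclusion gate; pass a threshold to filter.
    """

    panel: tuple[str, ...] = SIX_LOCUS_PANEL
    resolution: ResolutionLevel = ResolutionLevel.HIGH
    pp_threshold: Optional[float] = None
    missing_locus_policy: MissingLocusPolicy = MissingLocusPolicy.EXCLUDE_DONOR

    def __post_init__(self) -> None:
        if not self.panel:
            raise ValueError("scan panel must be non-empty")
        if len(set(self.panel)) != len(self.panel):
            raise ValueError(f"duplicate genes in panel {self.panel}")
        unknown = [g for g in self.panel if g not in GENES]
        if unknown:
            raise ValueError(f"unknown genes in panel: {unknown}")
        if self.pp_threshold is not None and not (0.0 <= self.pp_threshold <= 1.0):
            raise ValueError(f"pp_threshold {self.pp_threshold} outside [0, 1]")


@dataclass(frozen=True)
class HomozygoteCall:
    """One donor called homozygous for ``haplotype`` across the scanned panel.

    ``min_pp`` is the smallest imputation posterior probability across the
    panel loci, or ``None`` when any locus lacks one.
    """

    donor_id: str
    haplotype: Haplotype
    min_pp: Optional[float]


@dataclass
class ScanResult:
    """Calls plus the bookkeeping of everything that was dropped en route."""

    calls: list[HomozygoteCall]
    n_donors: int
    n_missing_locus: int = 0
    n_below_pp_threshold: int = 0
    n_ambiguous_resolution: int = 0
    config: Optional[ScanConfig] = field(default=None, repr=False)

    def __iter__(self):
        return iter(self.calls)

    def __len__(self) -> int:
        return len(self.calls)

    @property
    def proportion_pct(self) -> float:
        """Homozygote proportion of the scanned cohort, in percent."""
        return 100.0 * len(self.calls) / self.n_donors if self.n_donors else 0.0


def is_locus_homozygous(genotype: LocusGenotype, level: ResolutionLevel) -> bool:
    """True iff both allele calls agree after truncation to *level*."""
    return genotype.is_homozygous(level)


def scan_homozygotes(cohort: Sequence[DonorRecord], config: ScanConfig) -> ScanResult:
    """Scan a cohort for donors homozygous at every panel locus.

    Output is deterministic, ordered by donor_id.  Donors missing a panel
    locus are handled per ``missing_locus_policy`` and counted; donors with
    any panel posterior probability below ``pp_threshold`` (when set) are
    dropped and counted.
    """
    calls: list[HomozygoteCall] = []
    n_missing = 0
    n_below_pp = 0
    n_ambiguous = 0
    for donor in sorted(cohort, key=lambda d: d.donor_id):
        genotypes = []
        missing = False
        for gene in config.panel:
            gt = donor.genotype(gene)
            if gt is None:
                missing = True
                break
            genotypes.append(gt)
        if missing:
            n_missing += 1
            continue  # both policies drop the donor from the call set
        try:
            homozygous = all(
                is_locus_homozygous(gt, config.resolution) for gt in genotypes
            )
        except InsufficientResolutionError:
            # a coarse call that cannot be decided at this resolution:
            # not callable as homozygous, counted rather than silently dropped
            n_ambiguous += 1
            continue
        if not homozygous:
            continue
        pps = [gt.posterior_probability for gt in genotypes]
        min_pp = None if any(p is None for p in pps) else min(pps)
        if config.pp_threshold is not None:
            if min_pp is None or min_pp < config.pp_threshold:
                n_below_pp += 1
                continue
        # from_alleles truncates leniently, keeping already-coarse calls
        haplotype = Haplotype.from_alleles(
            [gt.allele_1 for gt in genotypes], config.resolution, panel=config.panel
        )
        calls.append(HomozygoteCall(donor_id=donor.donor_id, haplotype=haplotype, min_pp=min_pp))
    return ScanResult(
        calls=calls,
        n_donors=len(cohort),
        n_missing_locus=n_missing,
        n_below_pp_threshold=n_below_pp,
        n_ambiguous_resolution=n_ambiguous,
        config=config,
    )


def count_single_locus_homozygotes(
    cohort: Sequence[DonorRecord], gene: str, level: ResolutionLevel
) -> int:
    """Count donors homozygous at one locus (a 1-gene panel scan)."""
    if gene not in GENES:
        raise ValueError(f"unknown HLA gene {gene!r}")
    return len(
        scan_homozygotes(cohort, ScanConfig(panel=(gene,), resolution=level)).calls
    )
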