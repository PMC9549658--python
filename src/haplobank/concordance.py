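"""Imputation-vs-clinical typing concordance QC.

Compares imputed HLA calls against clinical-grade typings (the gold
standard), reporting per-locus error rates, and flags imputed homozygote
calls whose clinical typing is heterozygous at any panel locus — such
donors are excluded from downstream homozygote analyses.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

from .model import DonorRecord, HLAAllele, ResolutionLevel, truncate_at_most
from .scan import HomozygoteCall

ClinicalTable = Mapping[tuple[str, str], tuple[HLAAllele, HLAAllele]]


@dataclass(frozen=True)
class LocusConcordance:
    n_typings: int
    n_errors: int

    @property
    def error_pct(self) -> float:
        return 100.0 * self.n_errors / self.n_typings if self.n_typings else 0.0


@dataclass
class ConcordanceReport:
    """Per-locus comparison summary plus the skipped-pair bookkeeping."""

    per_locus: dict[str, LocusConcordance]
    overall_n: int
    n_skipped: int = 0
    resolution: ResolutionLevel = ResolutionLevel.HIGH
    discordant_pairs: list[tuple[str, str]] = field(default_factory=list)

    @property
    def overall_errors(self) -> int:
        return sum(lc.n_errors for lc in self.per_locus.values())

    @property
    def error_range_pct(self) -> tuple[float, float]:
        """(min, max) per-locus error percentage across compared loci."""
        pcts = [lc.error_pct for lc in self.per_locus.values() if lc.n_typings]
        return (min(pcts), max(pcts)) if pcts else (0.0, 0.0)


def compare_typings(
    cohort: Sequence[DonorRecord],
    clinical: ClinicalTable,
    level: ResolutionLevel = ResolutionLevel.HIGH,
    allele_level: bool = False,
) -> ConcordanceReport:
    """Per-locus error rates of imputed calls against clinical typings.

    One comparison per (donor, locus) present in both sources; an error is
    any mismatch of the unordered, resolution-truncated allele pairs.
    ``allele_level=True`` instead counts mismatched alleles (0, 1 or 2 per
    typing) with the denominator doubled accordingly.  Pairs present in
    only one source are skipped and counted.
    """
    by_id = {d.donor_id: d for d in cohort}
    per_locus_n: dict[str, int] = {}
    per_locus_err: dict[str, int] = {}
    discordant: list[tuple[str, str]] = []
    n_skipped = 0
    for (donor_id, gene), (c1, c2) in clinical.items():
        donor = by_id.get(donor_id)
        gt = donor.genotype(gene) if donor is not None else None
        if gt is None:
            n_skipped += 1
            continue
        imp = sorted(str(truncate_at_most(a, level)) for a in gt.alleles)
        cli = sorted(str(truncate_at_most(a, level)) for a in (c1, c2))
        if allele_level:
            per_locus_n[gene] = per_locus_n.get(gene, 0) + 2
            # greedy multiset intersection gives the matched-allele count
            matched = 0
            pool = list(cli)
            for a in imp:
                if a in pool:
                    pool.remove(a)
                    matched += 1
            n_err = 2 - matched
        else:
            per_locus_n[gene] = per_locus_n.get(gene, 0) + 1
            n_err = 0 if imp == cli else 1
        if n_err:
            per_locus_err[gene] = per_locus_err.get(gene, 0) + n_err
            discordant.append((donor_id, gene))
    n_skipped += sum(
        1
        for d in cohort
        for g in d.genotypes
        if (d.donor_id, g) not in clinical
    )
    per_locus = {
        gene: LocusConcordance(n_typings=per_locus_n[gene], n_errors=per_locus_err.get(gene, 0))
        for gene in sorted(per_locus_n)
    }
    return ConcordanceReport(
        per_locus=per_locus,
        overall_n=sum(per_locus_n.values()),
        n_skipped=n_skipped,
        resolution=level,
        discordant_pairs=discordant,
    )


@dataclass(frozen=True)
class ExcludedCall:
    call: HomozygoteCall
    reason: str  # discordant locus name, or "unverified"


def flag_discordant_homozygotes(
    calls: Sequence[HomozygoteCall],
    clinical: ClinicalTable,
    level: ResolutionLevel = ResolutionLevel.HIGH,
) -> tuple[list[HomozygoteCall], list[ExcludedCall], list[HomozygoteCall]]:
    """Partition homozygote calls by clinical verification.

    Returns ``(retained, excluded, unverified)``: a call is excluded when
    its clinical typing is heterozygous at any panel locus (the first such
    locus is recorded as the reason); calls without any clinical data are
    retained but also listed as unverified.  ``len(retained) +
    len(excluded) == len(calls)`` always.
    """
    retained: list[HomozygoteCall] = []
    excluded: list[ExcludedCall] = []
    unverified: list[HomozygoteCall] = []
    for call in calls:
        reason: Optional[str] = None
        seen_any = False
        for gene in call.haplotype.panel:
            typing = clinical.get((call.donor_id, gene))
            if typing is None:
                continue
            seen_any = True
            c1, c2 = typing
            het = truncate_at_most(c1, level) != truncate_at_most(c2, level)
            if het:
                reason = gene
                break
        if reason is not None:
            excluded.append(ExcludedCall(call=call, reason=reason))
        else:
            retained.append(call)
            if not seen_any:
                unverified.append(call)
    return retained, excluded, unverified
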