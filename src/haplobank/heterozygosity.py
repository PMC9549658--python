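"""Genomic verification of HLA homozygosity via MHC marker heterozygosity.

A donor truly homozygous for an entire MHC haplotype should be homozygous
at (almost) every DNA polymorphism marker inside the region, so the
percentage of heterozygous markers within a window is a genome-level check
on an imputed homozygote call.  Two built-in hg38 windows are provided: the
HLA-A-to-DQB1 segment and the extended MHC segment reaching past DPB1.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

from .model import DonorRecord, GenomicWindow, MarkerGenotype, MarkerState
from .scan import HomozygoteCall

#: Built-in windows (1-based inclusive hg38 coordinates).
WINDOWS: dict[str, GenomicWindow] = {
    "mhc_a_dqb1": GenomicWindow(start_bp=29_942_470, end_bp=32_666_689),
    "mhc_extended": GenomicWindow(start_bp=28_510_120, end_bp=33_480_577),
}


@dataclass(frozen=True)
class HeterozygosityResult:
    """Per-donor marker heterozygosity within one window.

    ``het_pct`` is 100 * n_het / n_non_missing, or ``None`` (undefined, not
    zero) when the window contains no non-missing markers.
    """

    donor_id: str
    window: GenomicWindow
    n_markers_in_window: int
    n_non_missing: int
    n_het: int

    @property
    def het_pct(self) -> Optional[float]:
        if self.n_non_missing == 0:
            return None
        return 100.0 * self.n_het / self.n_non_missing


def window_markers(
    markers: Sequence[MarkerGenotype], window: GenomicWindow
) -> list[MarkerGenotype]:
    """Markers with start <= position <= end (both boundaries inclusive)."""
    return [m for m in markers if m.position in window]


def donor_het_pct(donor: DonorRecord, window: GenomicWindow) -> HeterozygosityResult:
    """Heterozygous-marker percentage for one donor in one window.

    Missing genotypes are excluded from the denominator so that no-calls
    cannot deflate the apparent heterozygosity.
    """
    if donor.markers is None:
        raise ValueError(f"donor {donor.donor_id!r} has no marker genotypes")
    in_window = window_markers(donor.markers, window)
    non_missing = [m for m in in_window if m.state is not MarkerState.MISSING]
    n_het = sum(1 for m in non_missing if m.state is MarkerState.HET)
    return HeterozygosityResult(
        donor_id=donor.donor_id,
        window=window,
        n_markers_in_window=len(in_window),
        n_non_missing=len(non_missing),
        n_het=n_het,
    )


@dataclass(frozen=True)
class HaplotypeHeterozygosity:
    """Mean heterozygosity of the donors homozygous for one haplotype."""

    haplotype: str
    n_donors: int
    mean_het_pct: Optional[float]


def haplotype_mean_het(
    calls: Sequence[HomozygoteCall],
    cohort: Sequence[DonorRecord],
    window: GenomicWindow,
    pooled: bool = False,
) -> Mapping[str, HaplotypeHeterozygosity]:
    """Average marker heterozygosity per homozygous haplotype group.

    Default is the per-donor mean of het percentages; ``pooled=True``
    instead pools het / non-missing marker counts across the group's
    donors before taking the percentage.  Groups whose donors carry no
    usable markers are flagged with ``mean_het_pct=None``.
    """
    by_id = {d.donor_id: d for d in cohort}
    groups: dict[str, list[HeterozygosityResult]] = {}
    for call in calls:
        donor = by_id.get(call.donor_id)
        if donor is None or donor.markers is None:
            continue
        groups.setdefault(str(call.haplotype), []).append(donor_het_pct(donor, window))
    out: dict[str, HaplotypeHeterozygosity] = {}
    for call in calls:
        key = str(call.haplotype)
        if key in out:
            continue
        results = [r for r in groups.get(key, []) if r.n_non_missing > 0]
        if not results:
            out[key] = HaplotypeHeterozygosity(key, 0, None)
        elif pooled:
            total_het = sum(r.n_het for r in results)
            total = sum(r.n_non_missing for r in results)
            out[key] = HaplotypeHeterozygosity(key, len(results), 100.0 * total_het / total)
        else:
            pcts = [r.het_pct for r in results]
            out[key] = HaplotypeHeterozygosity(key, len(results), sum(pcts) / len(pcts))
    return out
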