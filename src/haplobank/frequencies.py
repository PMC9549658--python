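"""Homozygote frequency tables and allele-frequency QC.

Under Hardy-Weinberg equilibrium a haplotype with population frequency p
yields homozygotes at frequency p^2, so the observed homozygote frequency of
a haplotype in a cohort can be compared directly against the square of its
registry frequency (the "expected frequency"), and a registry frequency can
be recovered from a published expected frequency as its square root.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd
from scipy import stats

from .model import DonorRecord, GENES
from .scan import HomozygoteCall

TABLE_COLUMNS = [
    "haplotype",
    "n_homozygotes",
    "observed_frequency",
    "expected_frequency",
    "mean_het_pct",
]


def observed_frequency(n: int, cohort_size: int) -> float:
    """Observed homozygote frequency n / cohort_size (full precision)."""
    if cohort_size <= 0:
        raise ValueError("cohort_size must be positive")
    if not (0 <= n <= cohort_size):
        raise ValueError(f"count {n} outside [0, {cohort_size}]")
    return n / cohort_size


def expected_homozygote_frequency(p: float) -> float:
    """HWE expected homozygote frequency p^2 for haplotype frequency p."""
    if not (0.0 <= p <= 1.0):
        raise ValueError(f"haplotype frequency {p} outside [0, 1]")
    return p * p


def frequency_from_expected(e: float) -> float:
    """Recover a haplotype frequency from its expected homozygote frequency
    (sqrt inversion; used when only published p^2 values are available)."""
    if not (0.0 <= e <= 1.0):
        raise ValueError(f"expected frequency {e} outside [0, 1]")
    return math.sqrt(e)


def build_homozygote_table(
    calls: Iterable[HomozygoteCall],
    cohort_size: int,
    reference_frequencies: Optional[Mapping[str, float]] = None,
) -> pd.DataFrame:
    """Aggregate homozygote calls into a per-haplotype summary table.

    Expected frequencies are the squares of the external reference
    (registry) frequencies, never in-cohort estimates; haplotypes absent
    from the reference get NaN (missing), not zero.  Rows are ordered by
    descending homozygote count, ties by descending expected frequency,
    then by haplotype string.  ``mean_het_pct`` is left NaN here and filled
    by the MHC heterozygosity stage.
    """
    counts: dict[str, int] = {}
    for call in calls:
        key = str(call.haplotype)
        counts[key] = counts.get(key, 0) + 1
    rows = []
    for hap, n in counts.items():
        p = reference_frequencies.get(hap) if reference_frequencies else None
        rows.append(
            {
                "haplotype": hap,
                "n_homozygotes": n,
                "observed_frequency": observed_frequency(n, cohort_size),
                "expected_frequency": (
                    expected_homozygote_frequency(p) if p is not None else math.nan
                ),
                "mean_het_pct": math.nan,
            }
        )
    df = pd.DataFrame(rows, columns=TABLE_COLUMNS)
    if df.empty:
        return df
    df = df.sort_values(
        by=["n_homozygotes", "expected_frequency", "haplotype"],
        ascending=[False, False, True],
        na_position="last",
        kind="mergesort",
    ).reset_index(drop=True)
    return df


def allele_frequencies(cohort: Sequence[DonorRecord], gene: str) -> pd.DataFrame:
    """Per-allele counts and frequencies at one locus.

    Each donor contributes two allele occurrences (homozygotes contribute
    two of the same); frequencies are counts / (2 x donors typed at the
    locus) and sum to 1.  Donors missing the locus are skipped; the skip
    count is in ``df.attrs["n_skipped"]``.
    """
    if gene not in GENES:
        raise ValueError(f"unknown HLA gene {gene!r}")
    counts: dict[str, int] = {}
    n_typed = 0
    n_skipped = 0
    for donor in cohort:
        gt = donor.genotype(gene)
        if gt is None:
            n_skipped += 1
            continue
        n_typed += 1
        for allele in gt.alleles:
            key = str(allele)
            counts[key] = counts.get(key, 0) + 1
    total = 2 * n_typed
    df = pd.DataFrame(
        {
            "gene": gene,
            "allele": sorted(counts),
            "count": [counts[a] for a in sorted(counts)],
        }
    )
    df["frequency"] = df["count"] / total if total else 0.0
    df.attrs["n_skipped"] = n_skipped
    return df


@dataclass(frozen=True)
class CorrelationResult:
    """Pearson product-moment correlation of imputed vs reference allele
    frequencies, with the alleles that had to be excluded."""

    r: float
    n_pairs: int
    excluded: tuple[str, ...]


def correlate_with_reference(
    observed: Mapping[str, float],
    reference: Mapping[str, float],
    exclusions: Iterable[str] = (),
) -> CorrelationResult:
    """Pearson r between observed and reference allele frequencies.

    Alleles listed in *exclusions* or lacking a reference value are excluded
    and reported; at least 3 shared pairs and non-zero variance in both
    vectors are required.
    """
    excl = set(exclusions)
    excluded = sorted(excl | (set(observed) - set(reference)))
    shared = sorted(set(observed) & set(reference) - excl)
    if len(shared) < 3:
        raise ValueError(f"only {len(shared)} shared alleles after exclusions; need >= 3")
    x = [observed[a] for a in shared]
    y = [reference[a] for a in shared]
    if len(set(x)) == 1 or len(set(y)) == 1:
        raise ValueError("zero variance in a frequency vector; correlation undefined")
    r = float(stats.pearsonr(x, y).statistic)
    return CorrelationResult(r=r, n_pairs=len(shared), excluded=tuple(excluded))
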