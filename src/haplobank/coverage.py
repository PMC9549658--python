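"""Population coverage of a set of homozygous haplotypes.

Under Hardy-Weinberg equilibrium an individual drawing two haplotypes at
random carries a set S of haplotypes with total frequency F = sum(p_i) with
probability

    coverage(S) = 1 - (1 - F)^2

i.e. one minus the probability that neither chromosome carries a set member.
For a single haplotype this is the carrier probability 2p - p^2.  The
quadratic expansion 2F - F^2 makes the overlap correction explicit: summing
per-haplotype carrier probabilities double-counts individuals compatible
with more than one haplotype in the set, and the F^2-type cross terms
subtract exactly that overlap.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Optional, Sequence

import pandas as pd

_SLACK = 1e-9  # tolerance for accumulated rounding of printed frequencies


def round_half_up(x: float, ndigits: int = 1) -> float:
    """Decimal round-half-up (report style, e.g. 30.35 -> 30.4)."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


def carrier_probability(p: float) -> float:
    """Probability a diploid individual carries >= 1 copy: 1-(1-p)^2."""
    if not (-_SLACK <= p <= 1.0 + _SLACK):
        raise ValueError(f"haplotype frequency {p} outside [0, 1]")
    p = min(max(p, 0.0), 1.0)
    return 1.0 - (1.0 - p) ** 2


@dataclass(frozen=True)
class CoverageResult:
    """Coverage of one haplotype set."""

    frequencies: tuple[float, ...]
    summed_frequency: float
    coverage: float
    per_haplotype_carrier: tuple[float, ...]

    @property
    def coverage_pct(self) -> float:
        """Coverage as a percentage rounded to one decimal (report style)."""
        return round_half_up(100.0 * self.coverage, 1)

    @property
    def overlap(self) -> float:
        """Population fraction compatible with more than one set member:
        the gap between summed carrier probabilities and the coverage."""
        return sum(self.per_haplotype_carrier) - self.coverage


@dataclass(frozen=True)
class CoverageCurve:
    """Cumulative coverage after each prefix of a ranked haplotype list."""

    frequencies: tuple[float, ...]
    cumulative: tuple[float, ...]

    @property
    def final(self) -> float:
        return self.cumulative[-1] if self.cumulative else 0.0

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "k": range(1, len(self.cumulative) + 1),
                "frequency": self.frequencies,
                "cumulative_coverage": self.cumulative,
                "cumulative_coverage_pct": [
                    round_half_up(100.0 * c, 1) for c in self.cumulative
                ],
            }
        )


def set_coverage(frequencies: Sequence[float]) -> CoverageResult:
    """Coverage 1-(1-F)^2 of a haplotype set with frequencies p_i, F = sum p_i.

    Equals the probability that a random HWE diploid carries at least one
    set member; requires all p_i >= 0 and F <= 1 (+1e-9 printed-value slack).
    """
    freqs = tuple(float(p) for p in frequencies)
    for p in freqs:
        if p < 0.0 or p > 1.0 + _SLACK:
            raise ValueError(f"haplotype frequency {p} outside [0, 1]")
    total = sum(freqs)
    if total > 1.0 + _SLACK:
        raise ValueError(f"summed frequency {total:.6g} exceeds 1")
    total = min(total, 1.0)
    return CoverageResult(
        frequencies=freqs,
        summed_frequency=total,
        coverage=1.0 - (1.0 - total) ** 2,
        per_haplotype_carrier=tuple(carrier_probability(p) for p in freqs),
    )


def cumulative_coverage(frequencies: Sequence[float]) -> CoverageCurve:
    """Prefix-wise set coverage of a ranked haplotype list (non-decreasing)."""
    freqs = tuple(float(p) for p in frequencies)
    set_coverage(freqs)  # validates the full set once
    running = 0.0
    cumulative = []
    for p in freqs:
        running = min(running + p, 1.0)
        cumulative.append(1.0 - (1.0 - running) ** 2)
    return CoverageCurve(frequencies=freqs, cumulative=tuple(cumulative))


def rank_haplotypes(
    table: pd.DataFrame,
    key: str = "observed_n",
    k: Optional[int] = None,
) -> pd.DataFrame:
    """Rank a homozygote table by observed count or reference frequency.

    ``key`` is ``"observed_n"`` (the published-table ordering: number of
    homozygous individuals identified) or ``"reference_frequency"``.  The
    sort is stable and fully deterministic: descending by the key, ties by
    the other key descending, then by haplotype string.  ``k`` returns the
    top-k prefix; k larger than the table returns the whole table.
    """
    if table.empty:
        return table.iloc[0:0] if k != 0 else table.iloc[0:0]
    columns = {
        "observed_n": "n_homozygotes",
        "reference_frequency": "expected_frequency",
    }
    if key not in columns:
        raise ValueError(f"unknown rank key {key!r}; expected one of {sorted(columns)}")
    primary = columns[key]
    secondary = columns["reference_frequency" if key == "observed_n" else "observed_n"]
    ranked = table.sort_values(
        by=[primary, secondary, "haplotype"],
        ascending=[False, False, True],
        na_position="last",
        kind="mergesort",
    ).reset_index(drop=True)
    if k is not None:
        if k < 0:
            raise ValueError("k must be non-negative")
        ranked = ranked.head(k)
    return ranked
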