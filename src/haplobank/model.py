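"""HLA nomenclature data model.

Alleles, per-locus genotypes, haplotypes and the resolution handling that
every other stage of the pipeline consumes.  HLA alleles are written
``GENE*F1:F2[:F3[:F4]]`` where the colon-separated numeric fields encode
increasingly fine typing resolution: the first field is the allele family
(two-digit / "low" resolution, the level used for HLA-matched platelets),
the first two fields identify the protein ("four-digit" / high resolution,
the level at which imputation calls and clinical typings are compared).
Expression suffixes (N, L, S, Q, ...) are accepted and preserved in ``raw``
but ignored for matching.
"""

from __future__ import annotations

import enum
import re
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

#: The seven classical loci handled by the pipeline, in serialization order.
GENES: tuple[str, ...] = ("A", "B", "C", "DRB1", "DQA1", "DQB1", "DPB1")

#: Default six-locus panel (A..DQB1) used for high-resolution homozygote scans.
SIX_LOCUS_PANEL: tuple[str, ...] = ("A", "B", "C", "DRB1", "DQA1", "DQB1")

#: Two-locus panel used for low-resolution platelet-donor matching.
AB_PANEL: tuple[str, ...] = ("A", "B")


class HLAParseError(ValueError):
    """Raised when an allele string cannot be interpreted."""


class InsufficientResolutionError(ValueError):
    """Raised when an allele lacks the fields required for a resolution."""


class ResolutionLevel(enum.Enum):
    """Typing resolution: ``LOW`` keeps the first nomenclature field (allele
    family), ``HIGH`` keeps the first two (protein-level allele)."""

    LOW = "low"
    HIGH = "high"

    @property
    def n_fields(self) -> int:
        return 1 if self is ResolutionLevel.LOW else 2

    @classmethod
    def from_string(cls, text: str) -> "ResolutionLevel":
        try:
            return cls(text.lower())
        except ValueError:
            raise ValueError(f"unknown resolution level {text!r}; expected 'low' or 'high'")


_FIELD_RE = re.compile(r"^(\d+)([NLSCAQ]?)$")


@dataclass(frozen=True, order=True)
class HLAAllele:
    """A parsed HLA allele.

    Equality and ordering use ``gene`` and ``fields`` only, so two spellings
    of the same allele (with/without an expression suffix) compare equal at
    the represented resolution.
    """

    gene: str
    fields: tuple[str, ...]
    raw: str = field(default="", compare=False, repr=False)

    def __post_init__(self) -> None:
        if self.gene not in GENES:
            raise HLAParseError(f"unknown HLA gene {self.gene!r}")
        if not self.fields:
            raise HLAParseError(f"allele {self.raw!r} has no numeric fields")
        for f in self.fields:
            if not f or not f.isdigit():
                raise HLAParseError(f"non-numeric field {f!r} in allele {self.raw!r}")

    def __str__(self) -> str:
        return f"{self.gene}*{':'.join(self.fields)}"

    @property
    def resolution_fields(self) -> int:
        return len(self.fields)

    def truncate(self, level: ResolutionLevel) -> "HLAAllele":
        return truncate_allele(self, level)


def parse_allele(text: str, gene_hint: Optional[str] = None) -> HLAAllele:
    """Parse an allele string such as ``"A*03:01"`` or bare ``"03:01"``.

    A bare field string (no ``GENE*`` prefix) requires *gene_hint*.  An
    expression suffix on the last field (e.g. ``"15:01N"``) is stripped for
    matching but retained in ``raw``.
    """
    raw = text.strip()
    if not raw:
        raise HLAParseError("empty allele string")
    body = raw
    gene = gene_hint
    if "*" in raw:
        gene_token, _, body = raw.partition("*")
        gene = gene_token.strip().upper().removeprefix("HLA-").removeprefix("HLA")
        gene = gene or gene_hint
    if gene is None:
        raise HLAParseError(f"allele {raw!r} has no gene prefix and no gene_hint was given")
    if gene not in GENES:
        raise HLAParseError(f"unknown HLA gene {gene!r} in allele {raw!r}")
    parts = body.split(":")
    fields: list[str] = []
    for i, part in enumerate(parts):
        part = part.strip()
        m = _FIELD_RE.match(part) if i == len(parts) - 1 else None
        if m:
            part = m.group(1)
        if not part or not part.isdigit():
            raise HLAParseError(f"invalid field {parts[i]!r} in allele {raw!r}")
        fields.append(part)
    return HLAAllele(gene=gene, fields=tuple(fields), raw=raw)


def truncate_allele(allele: HLAAllele, level: ResolutionLevel) -> HLAAllele:
    """Truncate an allele to the requested resolution.

    Low keeps the first field; high keeps the first two and raises
    :class:`InsufficientResolutionError` for a one-field allele, because a
    family-level call cannot be promoted to a protein-level one.
    """
    n = level.n_fields
    if len(allele.fields) < n:
        raise InsufficientResolutionError(
            f"allele {allele} has {len(allele.fields)} field(s); "
            f"{level.value} resolution needs {n}"
        )
    if len(allele.fields) == n:
        return allele
    return HLAAllele(gene=allele.gene, fields=allele.fields[:n], raw=allele.raw)


def truncate_at_most(allele: HLAAllele, level: ResolutionLevel) -> HLAAllele:
    """Lenient truncation: keep an already-coarser allele unchanged instead
    of raising (used when comparing typings that may mix resolutions)."""
    if len(allele.fields) <= level.n_fields:
        return allele
    return truncate_allele(allele, level)


@dataclass(frozen=True)
class LocusGenotype:
    """Unphased allele pair at one locus, with the imputation posterior
    probability when available.  The pair is unordered: alleles are stored in
    canonical (lexicographic field-vector) order."""

    gene: str
    allele_1: HLAAllele
    allele_2: HLAAllele
    posterior_probability: Optional[float] = None

    def __post_init__(self) -> None:
        if self.allele_1.gene != self.gene or self.allele_2.gene != self.gene:
            raise ValueError(
                f"genotype gene {self.gene} does not match alleles "
                f"{self.allele_1}/{self.allele_2}"
            )
        pp = self.posterior_probability
        if pp is not None and not (0.0 <= pp <= 1.0):
            raise ValueError(f"posterior probability {pp} outside [0, 1]")
        if self.allele_2 < self.allele_1:
            a1, a2 = self.allele_2, self.allele_1
            object.__setattr__(self, "allele_1", a1)
            object.__setattr__(self, "allele_2", a2)

    @property
    def alleles(self) -> tuple[HLAAllele, HLAAllele]:
        return (self.allele_1, self.allele_2)

    def is_homozygous(self, level: ResolutionLevel) -> bool:
        """True iff both allele calls agree after truncation to *level*.

        Identical calls are homozygous at any level.  Distinct calls whose
        common prefix already differs are definitively heterozygous even if
        one call is coarse; a coarse call whose prefix matches the other
        allele cannot be decided at the requested level and raises
        :class:`InsufficientResolutionError`.
        """
        a1, a2 = self.allele_1, self.allele_2
        if a1 == a2:
            return True
        n = level.n_fields
        if a1.fields[:n] != a2.fields[:n]:
            return False
        if len(a1.fields) < n or len(a2.fields) < n:
            raise InsufficientResolutionError(
                f"cannot decide {level.value}-resolution homozygosity of "
                f"{a1}/{a2}: a call has too few fields"
            )
        return True


class MarkerState(enum.Enum):
    """Diploid state of a biallelic DNA marker."""

    HOM_REF = "hom_ref"
    HET = "het"
    HOM_ALT = "hom_alt"
    MISSING = "missing"

    @classmethod
    def from_code(cls, code: str) -> "MarkerState":
        """Map the 0/1/2/. dosage coding of the marker matrix format."""
        table = {"0": cls.HOM_REF, "1": cls.HET, "2": cls.HOM_ALT, ".": cls.MISSING}
        try:
            return table[code]
        except KeyError:
            raise ValueError(f"unknown marker genotype code {code!r}") from None

    @property
    def code(self) -> str:
        return {"hom_ref": "0", "het": "1", "hom_alt": "2", "missing": "."}[self.value]


@dataclass(frozen=True)
class MarkerGenotype:
    """One donor's state at one DNA marker (1-based hg38 position)."""

    position: int
    state: MarkerState

    def __post_init__(self) -> None:
        if self.position <= 0:
            raise ValueError(f"marker position must be positive, got {self.position}")


@dataclass(frozen=True)
class GenomicWindow:
    """A 1-based, inclusive-both-ends genomic interval (chromosome 6 MHC)."""

    start_bp: int
    end_bp: int
    assembly: str = "hg38"

    def __post_init__(self) -> None:
        if not (0 < self.start_bp <= self.end_bp):
            raise ValueError(f"invalid window [{self.start_bp}, {self.end_bp}]")

    def __contains__(self, position: int) -> bool:
        return self.start_bp <= position <= self.end_bp

    @property
    def length(self) -> int:
        return self.end_bp - self.start_bp + 1


@dataclass
class DonorRecord:
    """One donor: per-locus genotypes plus optional MHC marker genotypes."""

    donor_id: str
    genotypes: dict[str, LocusGenotype]
    markers: Optional[list[MarkerGenotype]] = None

    def genotype(self, gene: str) -> Optional[LocusGenotype]:
        return self.genotypes.get(gene)


@dataclass(frozen=True)
class Haplotype:
    """An ordered tuple of alleles, one per panel gene, at a fixed resolution.

    Haplotypes are only ever asserted for fully homozygous donors, where
    phase is trivial; the pipeline never phases heterozygotes.
    """

    panel: tuple[str, ...]
    alleles: tuple[HLAAllele, ...]
    resolution: ResolutionLevel

    def __post_init__(self) -> None:
        if len(self.panel) != len(self.alleles):
            raise ValueError("panel and alleles must align 1:1")
        for gene, allele in zip(self.panel, self.alleles):
            if allele.gene != gene:
                raise ValueError(f"allele {allele} out of place in panel {self.panel}")
            # an allele may be *coarser* than the stated resolution (published
            # tables contain the occasional family-level call) but never finer
            if len(allele.fields) > self.resolution.n_fields:
                raise ValueError(
                    f"allele {allele} not truncated to {self.resolution.value} resolution"
                )

    def __str__(self) -> str:
        return "~".join(str(a) for a in self.alleles)

    @classmethod
    def from_alleles(
        cls,
        alleles: Sequence[HLAAllele],
        resolution: ResolutionLevel,
        panel: Optional[Sequence[str]] = None,
    ) -> "Haplotype":
        """Build a haplotype, truncating each allele to *resolution* (alleles
        already coarser than the resolution are kept as-is)."""
        truncated = tuple(
            truncate_allele(a, resolution) if len(a.fields) >= resolution.n_fields else a
            for a in alleles
        )
        genes = tuple(panel) if panel is not None else tuple(a.gene for a in truncated)
        return cls(panel=genes, alleles=truncated, resolution=resolution)

    @classmethod
    def parse(
        cls, text: str, resolution: ResolutionLevel, panel: Optional[Sequence[str]] = None
    ) -> "Haplotype":
        """Parse a ``~``-joined haplotype string such as ``"A*03:01~B*35:01"``."""
        tokens = [t for t in text.split("~") if t]
        genes = list(panel) if panel is not None else [None] * len(tokens)
        alleles = [parse_allele(tok, gene_hint=g) for tok, g in zip(tokens, genes)]
        return cls.from_alleles(alleles, resolution, panel=panel)


@dataclass(frozen=True)
class HaplotypeFrequencyRecord:
    """Reference (registry) frequency of one haplotype in one population."""

    haplotype: Haplotype
    frequency: float
    population_label: str = ""

    def __post_init__(self) -> None:
        if not (0.0 <= self.frequency <= 1.0):
            raise ValueError(f"frequency {self.frequency} outside [0, 1]")


def validate_frequency_table(records: Iterable[HaplotypeFrequencyRecord]) -> None:
    """Check haplotype-key uniqueness and total mass <= 1 (+1e-9 slack)."""
    seen: set[str] = set()
    total = 0.0
    for rec in records:
        key = str(rec.haplotype)
        if key in seen:
            raise ValueError(f"duplicate haplotype {key} in frequency table")
        seen.add(key)
        total += rec.frequency
    if total > 1.0 + 1e-9:
        raise ValueError(f"frequencies sum to {total:.6g} > 1")


def frequency_map(records: Iterable[HaplotypeFrequencyRecord]) -> Mapping[str, float]:
    """Index a frequency table by serialized haplotype string."""
    return {str(rec.haplotype): rec.frequency for rec in records}
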