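"""Readers and writers for the pipeline's tabular formats.

All files are UTF-8 TSV/CSV with a header (delimiter chosen by extension:
``.csv`` -> comma, anything else -> tab).

* cohort table: ``donor_id, gene, allele_1, allele_2, posterior_probability``
  — one row per donor x locus, emulating the long-format output of
  SNP-based HLA imputation (HIBAG-style calls with posterior probabilities).
* haplotype frequency table: ``haplotype, frequency[, population]`` with the
  haplotype serialized as gene-ordered ``~``-joined alleles.
* marker matrix: ``donor_id`` column then one column per hg38 position,
  genotypes coded ``0`` (hom-ref), ``1`` (het), ``2`` (hom-alt), ``.``
  (missing).  A VCF path (``.vcf``/``.vcf.gz``) is accepted instead when
  cyvcf2 is available; diploid GT fields are mapped to the same states.
* clinical typing table: ``donor_id, gene, allele_1, allele_2``.
"""

from __future__ import annotations

import math
from pathlib import Path
from typing import Optional, Sequence, Union

import pandas as pd

from .model import (
    DonorRecord,
    GenomicWindow,
    Haplotype,
    HaplotypeFrequencyRecord,
    HLAParseError,
    LocusGenotype,
    MarkerGenotype,
    MarkerState,
    ResolutionLevel,
    parse_allele,
    validate_frequency_table,
)

PathLike = Union[str, Path]

COHORT_COLUMNS = ["donor_id", "gene", "allele_1", "allele_2", "posterior_probability"]


def _sep(path: PathLike) -> str:
    return "," if str(path).endswith(".csv") else "\t"


def read_cohort(path: PathLike) -> list[DonorRecord]:
    """Read a long-format cohort table into one record per donor.

    Row count is conserved (one genotype per input row); duplicate
    (donor, gene) rows are rejected.
    """
    df = pd.read_csv(path, sep=_sep(path), dtype=str, keep_default_na=False)
    missing = [c for c in COHORT_COLUMNS[:4] if c not in df.columns]
    if missing:
        raise ValueError(f"cohort table {path} lacks columns {missing}")
    donors: dict[str, DonorRecord] = {}
    for idx, row in enumerate(df.itertuples(index=False)):
        donor_id = str(row.donor_id)
        gene = str(row.gene).upper().removeprefix("HLA-")
        try:
            a1 = parse_allele(str(row.allele_1), gene_hint=gene)
            a2 = parse_allele(str(row.allele_2), gene_hint=gene)
        except HLAParseError as exc:
            raise HLAParseError(f"{path} row {idx + 2}: {exc}") from exc
        pp_text = str(getattr(row, "posterior_probability", "")).strip()
        pp: Optional[float] = None
        if pp_text not in ("", ".", "NA", "nan"):
            pp = float(pp_text)
            if not (0.0 <= pp <= 1.0) or math.isnan(pp):
                raise ValueError(f"{path} row {idx + 2}: posterior probability {pp} outside [0, 1]")
        rec = donors.setdefault(donor_id, DonorRecord(donor_id=donor_id, genotypes={}))
        if gene in rec.genotypes:
            raise ValueError(f"{path}: duplicate row for donor {donor_id!r}, locus {gene}")
        rec.genotypes[gene] = LocusGenotype(
            gene=gene, allele_1=a1, allele_2=a2, posterior_probability=pp
        )
    return list(donors.values())


def write_cohort(cohort: Sequence[DonorRecord], path: PathLike) -> None:
    """Write a cohort back to the long-format table (canonical allele order)."""
    rows = []
    for donor in cohort:
        for gene, gt in donor.genotypes.items():
            pp = gt.posterior_probability
            rows.append(
                {
                    "donor_id": donor.donor_id,
                    "gene": gene,
                    "allele_1": str(gt.allele_1),
                    "allele_2": str(gt.allele_2),
                    "posterior_probability": "" if pp is None else f"{pp:.6g}",
                }
            )
    pd.DataFrame(rows, columns=COHORT_COLUMNS).to_csv(path, sep=_sep(path), index=False)


def read_frequency_table(
    path: PathLike,
    resolution: ResolutionLevel,
    panel: Optional[Sequence[str]] = None,
    population_label: str = "",
) -> list[HaplotypeFrequencyRecord]:
    """Read a reference haplotype-frequency table."""
    df = pd.read_csv(path, sep=_sep(path), dtype=str, keep_default_na=False)
    if "haplotype" not in df.columns or "frequency" not in df.columns:
        raise ValueError(f"frequency table {path} needs 'haplotype' and 'frequency' columns")
    records = []
    for row in df.itertuples(index=False):
        hap = Haplotype.parse(str(row.haplotype), resolution, panel=panel)
        label = str(getattr(row, "population", population_label))
        records.append(
            HaplotypeFrequencyRecord(
                haplotype=hap, frequency=float(row.frequency), population_label=label
            )
        )
    validate_frequency_table(records)
    return records


def write_frequency_table(records: Sequence[HaplotypeFrequencyRecord], path: PathLike) -> None:
    df = pd.DataFrame(
        {
            "haplotype": [str(r.haplotype) for r in records],
            "frequency": [r.frequency for r in records],
            "population": [r.population_label for r in records],
        }
    )
    df.to_csv(path, sep=_sep(path), index=False)


def read_marker_matrix(
    path: PathLike, cohort: Sequence[DonorRecord], zero_based: bool = False
) -> int:
    """Attach marker genotypes from a donor x position matrix to a cohort.

    Columns after ``donor_id`` are bp positions (hg38).  ``zero_based=True``
    shifts half-open/0-based positions (BED-style exports) to the 1-based
    inclusive convention used throughout.  Returns the number of donors that
    received markers; donors absent from the matrix keep ``markers=None``.
    """
    df = pd.read_csv(path, sep=_sep(path), dtype=str, keep_default_na=False)
    if df.columns[0] != "donor_id":
        raise ValueError(f"marker matrix {path} must start with a 'donor_id' column")
    shift = 1 if zero_based else 0
    positions = [int(c) + shift for c in df.columns[1:]]
    by_id = {d.donor_id: d for d in cohort}
    n_attached = 0
    for row in df.itertuples(index=False):
        donor = by_id.get(str(row.donor_id))
        if donor is None:
            continue
        states = [MarkerState.from_code(code) for code in row[1:]]
        markers = [MarkerGenotype(p, s) for p, s in zip(positions, states)]
        markers.sort(key=lambda m: m.position)
        donor.markers = markers
        n_attached += 1
    return n_attached


def write_marker_matrix(cohort: Sequence[DonorRecord], path: PathLike) -> None:
    """Write attached markers as a donor x position matrix (0/1/2/. codes)."""
    with_markers = [d for d in cohort if d.markers is not None]
    positions = sorted({m.position for d in with_markers for m in d.markers})
    rows = []
    for donor in with_markers:
        by_pos = {m.position: m.state.code for m in donor.markers}
        rows.append([donor.donor_id] + [by_pos.get(p, ".") for p in positions])
    df = pd.DataFrame(rows, columns=["donor_id"] + [str(p) for p in positions])
    df.to_csv(path, sep=_sep(path), index=False)


def read_markers_vcf(
    path: PathLike, cohort: Sequence[DonorRecord], window: Optional[GenomicWindow] = None
) -> int:
    """Attach marker genotypes from a diploid VCF (requires cyvcf2)."""
    from cyvcf2 import VCF  # deferred: optional dependency

    vcf = VCF(str(path))
    samples = vcf.samples
    by_id = {d.donor_id: d for d in cohort}
    collected: dict[str, list[MarkerGenotype]] = {s: [] for s in samples if s in by_id}
    for variant in vcf:
        pos = variant.POS
        if window is not None and pos not in window:
            continue
        # gt_types: 0=hom-ref, 1=het, 2=unknown, 3=hom-alt
        state_map = {0: MarkerState.HOM_REF, 1: MarkerState.HET,
                     3: MarkerState.HOM_ALT, 2: MarkerState.MISSING}
        for sample, gt_type in zip(samples, variant.gt_types):
            if sample in collected:
                collected[sample].append(MarkerGenotype(pos, state_map[int(gt_type)]))
    for sample, markers in collected.items():
        markers.sort(key=lambda m: m.position)
        by_id[sample].markers = markers
    return len(collected)


def read_clinical_table(path: PathLike) -> dict[tuple[str, str], tuple]:
    """Read clinical typings keyed by (donor_id, gene); duplicates rejected."""
    df = pd.read_csv(path, sep=_sep(path), dtype=str, keep_default_na=False)
    needed = ["donor_id", "gene", "allele_1", "allele_2"]
    missing = [c for c in needed if c not in df.columns]
    if missing:
        raise ValueError(f"clinical table {path} lacks columns {missing}")
    typings: dict[tuple[str, str], tuple] = {}
    for row in df.itertuples(index=False):
        gene = str(row.gene).upper().removeprefix("HLA-")
        key = (str(row.donor_id), gene)
        if key in typings:
            raise ValueError(f"{path}: duplicate clinical typing for {key}")
        typings[key] = (
            parse_allele(str(row.allele_1), gene_hint=gene),
            parse_allele(str(row.allele_2), gene_hint=gene),
        )
    return typings
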