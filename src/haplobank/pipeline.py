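"""End-to-end orchestration: scan -> tabulate -> coverage -> heterozygosity
-> concordance, with fixed report formats.

Reports mirror the published summary layouts: the six-locus style table
carries 8-decimal frequencies and 2-decimal heterozygosity percentages, the
low-resolution style table 6-decimal frequencies, and coverage percentages
are printed to one decimal (round-half-up).  Everything dropped or flagged
at any stage is counted in the run summary; no stage filters silently.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Sequence

import pandas as pd

from . import io as hio
from .concordance import ConcordanceReport, compare_typings, flag_discordant_homozygotes
from .coverage import CoverageCurve, cumulative_coverage, rank_haplotypes, round_half_up
from .frequencies import build_homozygote_table, frequency_from_expected
from .heterozygosity import WINDOWS, haplotype_mean_het
from .model import DonorRecord, GenomicWindow, ResolutionLevel, frequency_map
from .scan import ScanConfig, ScanResult, scan_homozygotes

logger = logging.getLogger("haplobank")


@dataclass
class PipelineConfig:
    """Inputs and options for one full pipeline run."""

    cohort_path: Optional[str] = None
    frequency_path: Optional[str] = None
    marker_path: Optional[str] = None
    clinical_path: Optional[str] = None
    scan: ScanConfig = field(default_factory=ScanConfig)
    rank_key: str = "observed_n"
    top_k: tuple[int, ...] = (3, 10)
    window_name: str = "mhc_a_dqb1"
    output_dir: Optional[str] = None
    seed: int = 0

    def __post_init__(self) -> None:
        if any(k <= 0 for k in self.top_k):
            raise ValueError("top_k values must be positive")
        if self.window_name not in WINDOWS:
            raise ValueError(f"unknown window {self.window_name!r}; options: {sorted(WINDOWS)}")


@dataclass
class RunSummary:
    """Headline numbers of one pipeline run."""

    cohort_size: int
    n_homozygotes: int
    n_haplotypes: int
    coverage_final_pct: Optional[float]
    coverage_top_k_pct: dict[int, float]
    exclusions: dict[str, int]
    error_range_pct: Optional[tuple[float, float]] = None

    @property
    def proportion_pct(self) -> float:
        """Homozygote share of the cohort, percent, 1 decimal half-up."""
        if self.cohort_size == 0:
            return 0.0
        return round_half_up(100.0 * self.n_homozygotes / self.cohort_size, 1)


def run_pipeline(
    cohort: Sequence[DonorRecord],
    config: PipelineConfig,
    reference_frequencies: Optional[Mapping[str, float]] = None,
    clinical=None,
) -> tuple[RunSummary, dict]:
    """Run scan -> tabulate -> coverage (-> het -> concordance) in memory.

    Returns the summary plus a dict of intermediate artifacts (scan result,
    homozygote table, coverage curve, heterozygosity map, concordance
    report).  Deterministic given inputs; writes no files (see
    :func:`render_reports`).
    """
    artifacts: dict = {}
    exclusions: dict[str, int] = {}

    result: ScanResult = scan_homozygotes(cohort, config.scan)
    artifacts["scan"] = result
    exclusions["missing_locus"] = result.n_missing_locus
    exclusions["below_pp_threshold"] = result.n_below_pp_threshold
    exclusions["ambiguous_resolution"] = result.n_ambiguous_resolution

    calls = list(result.calls)
    report: Optional[ConcordanceReport] = None
    if clinical:
        report = compare_typings(cohort, clinical, level=config.scan.resolution)
        retained, excluded, unverified = flag_discordant_homozygotes(
            calls, clinical, level=config.scan.resolution
        )
        exclusions["clinically_discordant"] = len(excluded)
        exclusions["clinically_unverified"] = len(unverified)
        artifacts["concordance"] = report
        artifacts["excluded_calls"] = excluded
        calls = retained

    table = build_homozygote_table(calls, len(cohort), reference_frequencies)
    if any(d.markers is not None for d in cohort) and calls:
        window = WINDOWS[config.window_name]
        het = haplotype_mean_het(calls, cohort, window)
        artifacts["heterozygosity"] = het
        table["mean_het_pct"] = [
            het[h].mean_het_pct if h in het and het[h].mean_het_pct is not None else math.nan
            for h in table["haplotype"]
        ]
    artifacts["table"] = table

    curve: Optional[CoverageCurve] = None
    top_k_pct: dict[int, float] = {}
    if reference_frequencies is not None and not table.empty:
        ranked = rank_haplotypes(table, key=config.rank_key)
        known = ranked.dropna(subset=["expected_frequency"])
        exclusions["no_reference_frequency"] = len(ranked) - len(known)
        freqs = [frequency_from_expected(e) for e in known["expected_frequency"]]
        curve = cumulative_coverage(freqs)
        artifacts["coverage"] = curve
        for k in config.top_k:
            if k <= len(curve.cumulative):
                top_k_pct[k] = round_half_up(100.0 * curve.cumulative[k - 1], 1)

    summary = RunSummary(
        cohort_size=len(cohort),
        n_homozygotes=len(calls),
        n_haplotypes=int(table["haplotype"].nunique()) if not table.empty else 0,
        coverage_final_pct=(
            round_half_up(100.0 * curve.final, 1) if curve is not None else None
        ),
        coverage_top_k_pct=top_k_pct,
        exclusions=exclusions,
        error_range_pct=report.error_range_pct if report is not None else None,
    )
    artifacts["summary"] = summary
    for name, count in exclusions.items():
        if count:
            logger.info("pipeline: %d donor(s)/call(s) flagged as %s", count, name)
    return summary, artifacts


def run_pipeline_from_files(config: PipelineConfig) -> tuple[RunSummary, dict]:
    """File-based front end over :func:`run_pipeline`."""
    if config.cohort_path is None:
        raise ValueError("cohort_path is required")
    cohort = hio.read_cohort(config.cohort_path)
    reference = None
    if config.frequency_path:
        records = hio.read_frequency_table(
            config.frequency_path, config.scan.resolution, panel=config.scan.panel
        )
        reference = frequency_map(records)
    if config.marker_path:
        hio.read_marker_matrix(config.marker_path, cohort)
    clinical = hio.read_clinical_table(config.clinical_path) if config.clinical_path else None
    summary, artifacts = run_pipeline(cohort, config, reference, clinical)
    if config.output_dir:
        render_reports(artifacts, config.output_dir)
    return summary, artifacts


def format_homozygote_table(table: pd.DataFrame, frequency_decimals: int = 8) -> pd.DataFrame:
    """Fixed-precision report view of a homozygote table (round-half-even
    on frequencies, as printed tables do; heterozygosity to 2 decimals)."""
    out = table.copy()
    for col in ("observed_frequency", "expected_frequency"):
        out[col] = [
            "" if (isinstance(v, float) and math.isnan(v)) else f"{round(v, frequency_decimals):.{frequency_decimals}f}"
            for v in out[col]
        ]
    out["mean_het_pct"] = [
        "" if (isinstance(v, float) and math.isnan(v)) else f"{v:.2f}"
        for v in out["mean_het_pct"]
    ]
    return out


def render_reports(artifacts: dict, output_dir) -> list[Path]:
    """Write TSV/JSON reports for the computed stages; returns paths."""
    out = Path(output_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    table = artifacts.get("table")
    if table is not None:
        decimals = 8 if artifacts["scan"].config.resolution is ResolutionLevel.HIGH else 6
        path = out / "homozygote_table.tsv"
        format_homozygote_table(table, decimals).to_csv(path, sep="\t", index=False)
        written.append(path)

    curve = artifacts.get("coverage")
    if curve is not None:
        path = out / "coverage_curve.tsv"
        curve.to_frame().to_csv(path, sep="\t", index=False, float_format="%.10g")
        written.append(path)

    report = artifacts.get("concordance")
    if report is not None:
        path = out / "concordance.tsv"
        pd.DataFrame(
            [
                {
                    "gene": gene,
                    "n_typings": lc.n_typings,
                    "n_errors": lc.n_errors,
                    "error_pct": f"{lc.error_pct:.2f}",
                }
                for gene, lc in report.per_locus.items()
            ]
        ).to_csv(path, sep="\t", index=False)
        written.append(path)

    summary = artifacts.get("summary")
    if summary is not None:
        path = out / "summary.json"
        payload = {
            "cohort_size": summary.cohort_size,
            "n_homozygotes": summary.n_homozygotes,
            "n_haplotypes": summary.n_haplotypes,
            "proportion_pct": summary.proportion_pct,
            "coverage_final_pct": summary.coverage_final_pct,
            "coverage_top_k_pct": {str(k): v for k, v in summary.coverage_top_k_pct.items()},
            "exclusions": summary.exclusions,
            "error_range_pct": (
                list(summary.error_range_pct) if summary.error_range_pct else None
            ),
        }
        path.write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")
        written.append(path)
    return written
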