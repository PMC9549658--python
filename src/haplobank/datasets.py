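"""Published Finnish blood-donor homozygote summary tables.

Two summary tables published for a cohort of 20,737 genotyped Finnish blood
donors ship with the package as plain TSV:

* :func:`finnish_six_locus_homozygotes` — the 41 haplotypes found
  homozygous for HLA-A, -B, -C, -DRB1, -DQA1 and -DQB1 at high resolution
  (317 donors), with observed homozygote frequencies, the Hardy-Weinberg
  expected frequencies p^2 computed from registry haplotype frequencies,
  and the mean percentage of heterozygous MHC markers per haplotype.
* :func:`finnish_a_b_homozygotes` — the 49 low-resolution HLA-A~B
  haplotypes found homozygous (platelet-matching resolution).

The registry haplotype frequencies themselves are unpublished; they are
recoverable from the printed expected frequencies as sqrt(p^2), which is
how the worked coverage examples and the acceptance computations use these
tables.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

#: Size of the genotyped donor cohort the published tables summarize.
FINNISH_COHORT_SIZE = 20_737

#: Donors found homozygous for the six-locus panel / the low-resolution A~B panel.
FINNISH_SIX_LOCUS_HOMOZYGOTES = 317
FINNISH_A_B_HOMOZYGOTES = 741

_SIX_LOCUS_GENES = ["A", "B", "C", "DRB1", "DQA1", "DQB1"]


def _load(name: str) -> pd.DataFrame:
    with resources.files("haplobank.data").joinpath(name).open("r", encoding="utf-8") as fh:
        return pd.read_csv(fh, sep="\t", dtype={g: str for g in _SIX_LOCUS_GENES})


def finnish_six_locus_homozygotes() -> pd.DataFrame:
    """The 41 published six-locus (A..DQB1) homozygous haplotypes.

    Columns: rank (table order = descending homozygote count), the six
    allele columns (two-field strings), ``n_homozygotes``,
    ``observed_frequency``, ``expected_frequency`` (registry p^2),
    ``het_pct`` (mean % heterozygous markers in the A..DQB1 MHC window),
    ``fer`` (haplotype enriched in Finland but rare elsewhere) and
    ``confirmed`` (homozygosity confirmed by clinical-grade typing), plus a
    serialized ``haplotype`` string.
    """
    df = _load("finnish_a_dqb1_homozygotes.tsv")
    df["haplotype"] = [
        "~".join(f"{g}*{row[g]}" for g in _SIX_LOCUS_GENES) for _, row in df.iterrows()
    ]
    return df


def finnish_a_b_homozygotes() -> pd.DataFrame:
    """The 49 published low-resolution HLA-A~B homozygous haplotypes."""
    df = _load("finnish_a_b_homozygotes.tsv")
    df["haplotype"] = [f"A*{a}~B*{b}" for a, b in zip(df["A"], df["B"])]
    return df
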