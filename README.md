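# haplobank

Screening imputed HLA genotypes for fully homozygous donors, and estimating
how much of a population those donors could serve.

## The problem

Allogeneic therapeutic cells (iPS-derived lines, mesenchymal stromal cells,
HLA-typed platelets) are rejected when they display HLA alleles the
recipient lacks. Donors **homozygous** across the classical HLA loci
sidestep much of this: their cells present a single haplotype, so every
recipient carrying at least one copy of that haplotype is compatible. A
blood-donor biobank with SNP-array genotypes and statistical HLA imputation
is a cheap way to find such donors — but the raw screening output needs a
reproducible analysis: which donors are homozygous, at which resolution,
how do the counts compare with Hardy–Weinberg expectation, how much of the
population do the found haplotypes cover, and can the imputed calls be
trusted?

`haplobank` implements that analysis as a tested library + CLI:

* **scan** — call donors homozygous across a configurable locus panel
  (e.g. HLA-A…DQB1 at high / "4-digit" resolution, or HLA-A~B at low /
  "2-digit" resolution for platelet matching), with posterior-probability
  bookkeeping;
* **tabulate** — per-haplotype homozygote counts, observed frequencies
  *n/N*, and Hardy–Weinberg expected frequencies *p²* from registry
  haplotype frequencies;
* **coverage** — population coverage of a haplotype set *S* under HWE,
  `1 − (1 − F)²` with `F = Σ_{i∈S} p_i`, which corrects for the overlap of
  individuals compatible with more than one haplotype; cumulative curves
  over ranked haplotypes;
* **hetscan** — genomic verification: percentage of heterozygous DNA
  markers per donor inside the MHC (hg38 windows 29,942,470–32,666,689 and
  28,510,120–33,480,577) — a true HLA homozygote should be nearly
  marker-homozygous across the whole segment;
* **concordance** — per-locus error rates of imputed calls against
  clinical-grade typings, and exclusion of imputed homozygotes whose
  clinical typing is heterozygous anywhere;
* **simulate** — a synthetic-cohort generator (haplotype pool → diploid
  HWE sampling → haplotype-linked markers → imputation noise with degraded
  posteriors) so the full pipeline is testable although the real biobank
  data are access-restricted.

Two published summary tables for 20,737 Finnish blood donors ship with the
package (`haplobank.datasets`); the registry haplotype frequencies behind
them are recovered as √(expected frequency) wherever needed.

## Worked example

```python
import haplobank as hb

cfg = hb.finnish_study_config(seed=42)          # published pool, 20,737 donors
cohort, truth = hb.sample_cohort(cfg)
result = hb.scan_homozygotes(cohort, hb.ScanConfig())
print(f"{len(result)} of {result.n_donors} donors homozygous "
      f"for the six-locus panel ({result.proportion_pct:.1f}%)")

reference = hb.frequency_map(cfg.haplotype_frequencies)
table = hb.build_homozygote_table(result.calls, len(cohort), reference)
print(table.head(3)[["haplotype", "n_homozygotes", "observed_frequency",
                     "expected_frequency"]].to_string(index=False))

ranked = hb.rank_haplotypes(table, key="reference_frequency")
freqs = [hb.frequency_from_expected(e)
         for e in ranked["expected_frequency"].dropna()]
print(f"top-3 coverage: {hb.set_coverage(freqs[:3]).coverage_pct}%   "
      f"all {len(freqs)} haplotypes: {hb.set_coverage(freqs).coverage_pct}%")
```

prints

```
272 of 20737 donors homozygous for the six-locus panel (1.3%)
                                               haplotype  n_homozygotes  observed_frequency  expected_frequency
A*03:01~B*35:01~C*04:01~DRB1*01:01~DQA1*01:01~DQB1*05:01            134            0.006462            0.006908
A*01:01~B*08:01~C*07:01~DRB1*03:01~DQA1*05:01~DQB1*02:01             45            0.002170            0.002421
A*03:01~B*07:02~C*07:02~DRB1*15:01~DQA1*01:02~DQB1*06:02             20            0.000964            0.001133
top-3 coverage: 30.4%   all 21 haplotypes: 62.0%
```

One synthetic draw of the study: 272 donors (1.3% of the cohort) are
homozygous at all six loci, the observed per-haplotype frequencies sit on
their Hardy–Weinberg expectations *p²*, and the three most frequent
homozygous haplotypes would already cover 30.4% of the population. (Only 21
of the 41 pool haplotypes happened to produce a homozygote in this draw,
so the full-set coverage, 62.0%, is below the 69.3% attainable with all
41.) The same stages are available from the shell:

```bash
haplobank simulate --n-donors 2000 --seed 7 --out-dir sim/
haplobank scan --cohort sim/cohort.tsv --out calls.tsv
haplobank run-all --cohort sim/cohort.tsv --out-dir report/
```

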