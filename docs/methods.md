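# Methods

## Model

The pipeline treats a genotyped donor cohort as a random-mating
(Hardy–Weinberg) sample of diploid HLA haplotypes. For a haplotype *h*
with population frequency *p*:

* homozygote frequency: *P(hom for h) = p²* — the basis for the expected
  column of the homozygote tables;
* carrier probability: *P(≥1 copy of h) = 1 − (1 − p)² = 2p − p²*;
* coverage of a haplotype set *S* with total frequency *F = Σ_{h∈S} p_h*:
  *C(S) = 1 − (1 − F)²*. Expanding, *C(S) = Σ 2p_h − F²*: summing carrier
  probabilities double-counts individuals compatible with more than one
  member of *S*, and the quadratic term subtracts exactly that overlap.
  Haplotypes are mutually exclusive on a chromosome, so no inclusion–
  exclusion beyond the two-chromosome level is needed.

A recipient is "covered" by a homozygous donor when at least one of the
recipient's two haplotypes equals the donor's haplotype, i.e. the donor's
alleles are a subset of the recipient's. Nothing beyond carriage is
modelled (no permissive mismatching, no DPB1 T-cell-epitope groups).

Registry haplotype frequencies are external inputs and are never estimated
from the cohort itself. When only published expected homozygote
frequencies (*p²*) exist, frequencies are recovered as their square roots;
this is an exact inversion, limited only by the precision the table was
printed at.

## Homozygosity and resolution

Imputation yields unphased per-locus genotypes. Haplotypes are asserted
only for donors homozygous at every panel locus, where phase is trivial;
no phasing or EM frequency estimation is performed on heterozygotes.
Resolution is handled by field truncation of the allele nomenclature: low
= first field (allele family, the platelet-matching level), high = first
two fields (protein level). Truncation never invents precision — deciding
high-resolution homozygosity for a genotype like `DQA1*03 / DQA1*03:01`
(one coarse call with a matching family) is impossible and is surfaced as
an explicit "insufficient resolution" condition; the scanner counts such
donors separately instead of guessing. Identical calls are homozygous at
any level, and calls whose first fields already differ are heterozygous at
any level, so the ambiguity only arises for mixed-resolution pairs. One
published haplotype contains such a family-level call (a formatting
ambiguity in the source table); it is stored as printed.

Expression suffixes (N, L, Q, …) are parsed, preserved in the raw string
and ignored for matching. Allele pairs are stored in canonical
lexicographic order, so genotype equality is order-insensitive.

## Synthetic cohorts

The generator's default conditions mirror the study the published tables
come from:

| parameter | default | rationale |
|---|---|---|
| pool | 41 six-locus haplotypes, *p* = √(printed *p²*) | the registry frequencies behind the published table |
| `n_donors` | 20,737 | the genotyped cohort size |
| `marker_noise_rate` | 0.01 | per-marker hom→het flip; published per-haplotype MHC heterozygosity spans ~0.01–2% |
| `imputation_error_rate` | 0.023 | per allele call; published per-locus error rates span 0–4.6% at genotype level (a 2.3% allele rate gives 1−(1−0.023)² ≈ 4.6%) |
| `pp_correct` | Beta(49, 1), mean 0.98 | imputation posteriors of correct calls cluster near 1 |
| `pp_error` | Beta(8, 8), mean 0.5 | erroneous calls sit near the nominal 0.5 cut-off, occasionally below |

Residual frequency mass becomes unique singleton haplotypes whose first
nomenclature field is unique per draw, so the residual pool can never
produce a homozygote at any resolution — a conservative null for
homozygote-count statistics. Markers are perfect haplotype tags: each
haplotype label carries a fixed random binary vector at positions drawn
uniformly within the MHC window; a donor is heterozygous exactly where its
two vectors differ, plus the noise flips. One global seed spawns separate
sub-streams for haplotype sampling, markers and imputation noise, so
regenerating one layer leaves the others bit-identical.

What the generator does **not** emulate: linkage-disequilibrium decay and
recombination inside the MHC (markers are in perfect LD with the
haplotype), allele-frequency correlation structure between loci beyond the
pool haplotypes, array intensity artefacts, genotype missingness, and
population substructure. Passing tests therefore demonstrate that the
*analysis* is correct under the model the analysis itself assumes — not
that real biobank data meet those assumptions.

## Numerical and reporting choices

* Observed frequencies are exact ratios kept at full precision; report
  serialization rounds to 8 decimals (six-locus style) or 6 decimals
  (low-resolution style), round-half-even.
* Coverage percentages are printed to one decimal, round-half-up, matching
  the style of the published figures; summary proportions likewise.
* Frequency tables must sum to ≤ 1 with 1e-9 slack for accumulated
  rounding of printed values.
* Ranking is fully deterministic: descending key, ties by the secondary
  key, then lexicographic haplotype string.
* Marker heterozygosity excludes missing genotypes from the denominator
  (no-calls must not deflate heterozygosity); a window with zero informative
  markers yields an explicitly undefined result, not 0%.
* Genomic coordinates are 1-based and inclusive at both ends; BED-style
  half-open inputs are shifted at the reader behind an explicit flag.
* Per-haplotype heterozygosity averages over donors by default; pooled
  (marker-weighted) averaging is available behind a flag, as the published
  tables do not state which was used.
* Concordance counts one comparison per (donor, locus) and an error as any
  genotype-level mismatch; allele-level counting (0–2 errors per typing,
  doubled denominator) is available behind a flag, since the published
  0–4.6% range does not state its granularity.

## Design decisions taken where the source was open

* The posterior-probability cut-off (0.5) is descriptive, not an exclusion
  gate: scans report each call's minimum posterior and filtering is
  opt-in. The published analysis used the threshold the same way.
* Donors missing a panel locus are excluded and counted (the published
  cohort was complete, so no behaviour was specified).
* A two-locus DQA1/DQB1 ordering and the published column order fix
  haplotype serialization.
* Coverage input source (registry frequencies vs √expected) is an explicit
  flag, never inferred silently.
* The published top-10 coverage values reproduce from the printed tables
  only when the ten haplotypes are ranked by reference frequency; ranking
  by observed homozygote count (the tables' row order) selects a slightly
  different ten. Both rankings are available; the regression test pins the
  frequency ranking.

## Problem sizes used in the test suite

Statistical tests run at sizes chosen to make 3–4 SD bands narrow enough
to be meaningful while keeping the suite quick: Hardy–Weinberg recovery
and goodness-of-fit on 50,000-donor cohorts, coverage vs Monte-Carlo
diploid sampling at 10⁶ draws × 50 random sets, imputation-noise recovery
on 27,588 allele calls, marker-noise recovery on 10⁴–10⁵ marker draws, and
a full study-scale run (20,737 donors) for the end-to-end recovery checks.
Marker counts are scaled to hundreds per donor (the real windows hold
36,161 and 60,808 markers); heterozygosity percentages are scale-free, so
this only widens the binomial error bands accounted for in the tests.

## Known limitations

* No G/P-group or serological-split handling; low resolution is first-field
  truncation.
* No confidence intervals on frequencies or coverage.
* The concordance module compares unordered genotypes after truncation; it
  does not model typing ambiguity strings.
* Coverage assumes a single well-mixed population; multi-population pooling
  is out of scope.
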