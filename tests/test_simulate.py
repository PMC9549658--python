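"""The synthetic cohort generator: HWE structure, markers, imputation noise."""

import math

import numpy as np
import pytest

from haplobank.heterozygosity import WINDOWS, donor_het_pct
from haplobank.io import write_cohort
from haplobank.model import MarkerState, ResolutionLevel
from haplobank.simulate import (
    SimulationConfig,
    apply_imputation_noise,
    attach_markers,
    finnish_study_config,
    finnish_study_pool,
    sample_cohort,
)

from conftest import pool


def _cohort_text(cohort, tmp_path, name):
    path = tmp_path / name
    write_cohort(cohort, path)
    return path.read_bytes()


def test_same_seed_bit_identical(tmp_path, two_hap_pool):
    cfg = SimulationConfig(haplotype_frequencies=two_hap_pool, n_donors=500, seed=7)
    c1, t1 = sample_cohort(cfg)
    c2, t2 = sample_cohort(cfg)
    assert t1 == t2
    assert _cohort_text(c1, tmp_path, "a.tsv") == _cohort_text(c2, tmp_path, "b.tsv")
    c3, t3 = sample_cohort(
        SimulationConfig(haplotype_frequencies=two_hap_pool, n_donors=500, seed=8)
    )
    assert t3 != t1


def test_empty_cohort(two_hap_pool):
    cohort, truth = sample_cohort(
        SimulationConfig(haplotype_frequencies=two_hap_pool, n_donors=0, seed=1)
    )
    assert cohort == [] and truth == {}


def test_degenerate_distribution():
    """A single haplotype with f=1 makes every donor homozygous everywhere."""
    p = pool({"A*01:01~B*08:01": 1.0})
    cohort, truth = sample_cohort(
        SimulationConfig(haplotype_frequencies=p, n_donors=100, seed=3)
    )
    assert len(cohort) == 100
    for d in cohort:
        assert all(
            gt.is_homozygous(ResolutionLevel.HIGH) for gt in d.genotypes.values()
        )
    assert all(a == b for a, b in truth.values())


def test_homozygote_count_binomial():
    """The most frequent haplotype (f~0.0831) yields ~n*f^2 homozygotes in a
    study-sized cohort, within 4 binomial SD."""
    cfg = finnish_study_config(seed=11)
    _, truth = sample_cohort(cfg)
    target = str(cfg.haplotype_frequencies[0].haplotype)
    f = cfg.haplotype_frequencies[0].frequency
    n = cfg.n_donors
    count = sum(1 for a, b in truth.values() if a == b == target)
    expected = n * f * f
    sd = math.sqrt(n * f * f * (1 - f * f))
    assert abs(count - expected) < 4 * sd
    assert abs(expected - 143.2) < 1  # printed-value sanity: 20737 * 0.00690815


def test_haplotype_frequency_convergence():
    """Empirical chromosome frequencies converge to configured f (n=50,000)."""
    p = pool({"A*01:01~B*08:01": 0.12, "A*03:01~B*07:02": 0.05, "A*02:01~B*44:02": 0.01})
    cfg = SimulationConfig(haplotype_frequencies=p, n_donors=50_000, seed=5)
    _, truth = sample_cohort(cfg)
    labels = [lab for pair in truth.values() for lab in pair]
    n_chrom = len(labels)
    for rec in p:
        f = rec.frequency
        obs = labels.count(str(rec.haplotype)) / n_chrom
        sd = math.sqrt(f * (1 - f) / n_chrom)
        assert abs(obs - f) < 4 * sd


def test_frequency_sum_validation():
    with pytest.raises(ValueError):
        SimulationConfig(
            haplotype_frequencies=pool({"A*01:01~B*08:01": 0.7, "A*03:01~B*07:02": 0.4}),
            n_donors=10,
        )


class TestMarkers:
    def test_noise_free_homozygote_scores_zero(self, two_hap_pool):
        cfg = SimulationConfig(
            haplotype_frequencies=two_hap_pool,
            n_donors=300,
            n_markers=50,
            marker_noise_rate=0.0,
            seed=9,
        )
        cohort, truth = sample_cohort(cfg)
        positions = attach_markers(cohort, truth, cfg)
        assert len(positions) == 50
        window = cfg.marker_window
        assert all(int(p) in window for p in positions)
        hom = [d for d in cohort if truth[d.donor_id][0] == truth[d.donor_id][1]]
        assert hom, "seeded cohort should contain homozygotes"
        for d in hom:
            assert donor_het_pct(d, window).het_pct == 0.0

    def test_distinct_haplotypes_differ(self, two_hap_pool):
        """With noise off, a donor's het markers are exactly where its two
        haplotype vectors differ — so two distinct named haplotypes give a
        positive het fraction near 50% for random vectors."""
        cfg = SimulationConfig(
            haplotype_frequencies=two_hap_pool,
            n_donors=400,
            n_markers=100,
            marker_noise_rate=0.0,
            seed=13,
        )
        cohort, truth = sample_cohort(cfg)
        attach_markers(cohort, truth, cfg)
        names = {str(r.haplotype) for r in two_hap_pool}
        mixed = [
            d
            for d in cohort
            if truth[d.donor_id][0] != truth[d.donor_id][1]
            and set(truth[d.donor_id]) <= names
        ]
        assert mixed, "seeded cohort should contain named-heterozygous donors"
        for d in mixed:
            pct = donor_het_pct(d, cfg.marker_window).het_pct
            assert pct > 0.0

    def test_noise_rate_recovered(self):
        """On all-homozygous donors every het marker is noise: the mean het
        fraction estimates the flip rate within binomial error."""
        p = pool({"A*01:01~B*08:01": 1.0})
        cfg = SimulationConfig(
            haplotype_frequencies=p,
            n_donors=200,
            n_markers=500,
            marker_noise_rate=0.02,
            seed=17,
        )
        cohort, truth = sample_cohort(cfg)
        attach_markers(cohort, truth, cfg)
        n_total = 200 * 500
        n_het = sum(
            1 for d in cohort for m in d.markers if m.state is MarkerState.HET
        )
        sd = math.sqrt(0.02 * 0.98 / n_total)
        assert abs(n_het / n_total - 0.02) < 4 * sd

    def test_window_too_small(self, two_hap_pool):
        from haplobank.model import GenomicWindow

        cfg = SimulationConfig(
            haplotype_frequencies=two_hap_pool,
            n_donors=5,
            n_markers=100,
            marker_window=GenomicWindow(start_bp=100, end_bp=150),
            seed=1,
        )
        cohort, truth = sample_cohort(cfg)
        with pytest.raises(ValueError, match="window"):
            attach_markers(cohort, truth, cfg)


class TestImputationNoise:
    def test_rate_zero_is_identity(self, two_hap_pool):
        cfg = SimulationConfig(
            haplotype_frequencies=two_hap_pool,
            n_donors=100,
            imputation_error_rate=0.0,
            seed=21,
        )
        cohort, _ = sample_cohort(cfg)
        noisy, truth, log = apply_imputation_noise(cohort, cfg)
        assert log.n_errors == 0
        for before, after in zip(cohort, noisy):
            for gene in before.genotypes:
                assert before.genotypes[gene].alleles == after.genotypes[gene].alleles
                assert truth[(before.donor_id, gene)] == before.genotypes[gene].alleles

    def test_rate_one_binary_universe_flips_everything(self):
        p = pool({"A*01:01": 0.5, "A*02:01": 0.5})
        cfg = SimulationConfig(
            haplotype_frequencies=p, n_donors=50, imputation_error_rate=1.0, seed=23
        )
        cohort, _ = sample_cohort(cfg)
        noisy, truth, log = apply_imputation_noise(cohort, cfg)
        assert log.n_errors == log.n_calls == 100
        for before, after in zip(cohort, noisy):
            b = before.genotypes["A"]
            a = after.genotypes["A"]
            # every call flipped to the only other allele of the universe
            assert sorted(map(str, a.alleles)) == sorted(
                "A*01:01" if str(x) == "A*02:01" else "A*02:01" for x in b.alleles
            )

    def test_error_fraction_recovered(self, two_hap_pool):
        """Error fraction on ~27,588 allele calls recovers the configured
        2.3% rate within 3 binomial SD."""
        cfg = SimulationConfig(
            haplotype_frequencies=two_hap_pool,
            n_donors=2299,  # x 6 loci x 2 calls = 27,588 calls
            imputation_error_rate=0.023,
            seed=29,
        )
        cohort, _ = sample_cohort(cfg)
        _, _, log = apply_imputation_noise(cohort, cfg)
        assert log.n_calls == 27_588
        rate = log.n_errors / log.n_calls
        sd = math.sqrt(0.023 * 0.977 / log.n_calls)
        assert abs(rate - 0.023) < 3 * sd

    def test_posterior_probability_families(self, two_hap_pool):
        """Correct calls get high PPs, erroneous loci degraded ones."""
        cfg = SimulationConfig(
            haplotype_frequencies=two_hap_pool,
            n_donors=500,
            imputation_error_rate=0.05,
            seed=31,
        )
        cohort, _ = sample_cohort(cfg)
        noisy, truth, _ = apply_imputation_noise(cohort, cfg)
        correct_pp, error_pp = [], []
        for d in noisy:
            for gene, gt in d.genotypes.items():
                (error_pp if gt.alleles != truth[(d.donor_id, gene)] else correct_pp).append(
                    gt.posterior_probability
                )
        assert error_pp and correct_pp
        assert np.mean(correct_pp) > 0.95
        assert 0.3 < np.mean(error_pp) < 0.7


def test_study_pool_matches_published_table():
    recs = finnish_study_pool()
    assert len(recs) == 41
    assert abs(recs[0].frequency - math.sqrt(0.00690815)) < 1e-12
    freqs = [r.frequency for r in recs]
    assert sum(freqs) <= 1.0
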