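"""Frequency arithmetic, homozygote tables, allele-frequency QC."""

import math

import numpy as np
import pytest
from scipy import stats

from haplobank.frequencies import (
    allele_frequencies,
    build_homozygote_table,
    correlate_with_reference,
    expected_homozygote_frequency,
    frequency_from_expected,
    observed_frequency,
)
from haplobank.model import frequency_map
from haplobank.scan import ScanConfig, scan_homozygotes
from haplobank.simulate import SimulationConfig, sample_cohort

from conftest import donor, pool


@pytest.mark.parametrize(
    "n, size, expected",
    [(149, 20_737, 0.00718522), (48, 20_737, 0.00231470), (0, 20_737, 0.0)],
)
def test_observed_frequency_printed_precision(n, size, expected):
    assert round(observed_frequency(n, size), 8) == expected


def test_observed_frequency_errors():
    with pytest.raises(ValueError):
        observed_frequency(1, 0)
    with pytest.raises(ValueError):
        observed_frequency(5, 4)


@pytest.mark.parametrize("p, e", [(0.0, 0.0), (1.0, 1.0), (0.5, 0.25)])
def test_expected_frequency_trivial(p, e):
    assert expected_homozygote_frequency(p) == e
    assert frequency_from_expected(e) == p


def test_expected_frequency_square_root_round_trip():
    """sqrt inversion reproduces the registry frequency behind a printed
    p^2 value to full precision."""
    p = frequency_from_expected(0.00690815)
    assert abs(p - 0.0831153) < 5e-8
    assert abs(expected_homozygote_frequency(p) - 0.00690815) < 1e-15


@pytest.mark.parametrize("bad", [-0.1, 1.1])
def test_frequency_domain_checks(bad):
    with pytest.raises(ValueError):
        expected_homozygote_frequency(bad)
    with pytest.raises(ValueError):
        frequency_from_expected(bad)


class TestAlleleFrequencies:
    def test_homozygotes_contribute_two(self):
        cohort = [
            donor("d1", {"A": ("03:01", "03:01")}),
            donor("d2", {"A": ("03:01", "03:01")}),
        ]
        df = allele_frequencies(cohort, "A")
        assert df["count"].tolist() == [4]
        assert df["frequency"].tolist() == [1.0]

    def test_heterozygote_split(self):
        df = allele_frequencies([donor("d1", {"A": ("01:01", "02:01")})], "A")
        assert df["frequency"].tolist() == [0.5, 0.5]

    def test_missing_locus_skipped_and_counted(self):
        cohort = [
            donor("d1", {"A": ("01:01", "02:01")}),
            donor("d2", {"B": ("07:02", "07:02")}),
        ]
        df = allele_frequencies(cohort, "A")
        assert df.attrs["n_skipped"] == 1
        assert df["frequency"].sum() == pytest.approx(1.0)

    def test_matches_haplotype_marginals(self):
        """Sampled allele frequencies match the pool's marginal allele
        frequencies within 4 SD (multinomial sampling error)."""
        p = pool(
            {
                "A*01:01~B*08:01": 0.3,
                "A*01:01~B*07:02": 0.2,
                "A*03:01~B*07:02": 0.5,
            }
        )
        cfg = SimulationConfig(haplotype_frequencies=p, n_donors=20_000, seed=43)
        cohort, _ = sample_cohort(cfg)
        df = allele_frequencies(cohort, "A")
        marginal = {"A*01:01": 0.5, "A*03:01": 0.5}
        n_chrom = 2 * len(cohort)
        for _, row in df.iterrows():
            f = marginal[row["allele"]]
            sd = math.sqrt(f * (1 - f) / n_chrom)
            assert abs(row["frequency"] - f) < 4 * sd


class TestHomozygoteTable:
    def _table(self, toy_cohort, reference=None):
        calls = scan_homozygotes(toy_cohort, ScanConfig()).calls
        return build_homozygote_table(calls, len(toy_cohort), reference)

    def test_counts_and_observed(self, toy_cohort, two_hap_pool):
        table = self._table(toy_cohort, frequency_map(two_hap_pool))
        assert table["n_homozygotes"].tolist() == [2, 1]
        assert table["observed_frequency"].tolist() == [0.4, 0.2]
        assert table["expected_frequency"].tolist() == pytest.approx([0.01, 0.0025])

    def test_sum_property(self, toy_cohort):
        table = self._table(toy_cohort)
        total = table["observed_frequency"].sum() * len(toy_cohort)
        assert total == pytest.approx(3)  # three homozygote calls

    def test_missing_reference_flagged_nan_not_zero(self, toy_cohort):
        table = self._table(toy_cohort, {"no~such~haplotype": 0.1})
        assert table["expected_frequency"].isna().all()

    def test_sort_order(self):
        from haplobank.model import Haplotype, ResolutionLevel
        from haplobank.scan import HomozygoteCall

        def call(d, text):
            return HomozygoteCall(
                d, Haplotype.parse(text, ResolutionLevel.HIGH), None
            )

        calls = (
            [call(f"a{i}", "A*01:01") for i in range(2)]
            + [call(f"b{i}", "A*02:01") for i in range(2)]
            + [call("c0", "A*03:01")]
        )
        ref = {"A*01:01": 0.05, "A*02:01": 0.2, "A*03:01": 0.5}
        table = build_homozygote_table(calls, 100, ref)
        # ties on count broken by descending expected frequency
        assert table["haplotype"].tolist() == ["A*02:01", "A*01:01", "A*03:01"]


class TestCorrelation:
    def test_identity_gives_r_one(self):
        freqs = {f"A*{i:02d}:01": 0.1 * i for i in range(1, 11)}
        res = correlate_with_reference(freqs, dict(freqs))
        assert res.r == pytest.approx(1.0)
        assert res.n_pairs == 10

    def test_perfect_negative(self):
        obs = {f"A*{i:02d}:01": float(i) for i in range(1, 6)}
        ref = {k: 1.0 - 0.1 * v for k, v in obs.items()}
        assert correlate_with_reference(obs, ref).r == pytest.approx(-1.0)

    def test_matches_product_moment_formula(self):
        """scipy's r equals a direct implementation of the product-moment
        formula to 1e-12 on random 20-pair vectors."""
        rng = np.random.default_rng(47)
        x, y = rng.random(20), rng.random(20)
        keys = [f"B*{i:02d}:01" for i in range(20)]
        res = correlate_with_reference(dict(zip(keys, x)), dict(zip(keys, y)))
        xm, ym = x - x.mean(), y - y.mean()
        manual = float((xm * ym).sum() / math.sqrt((xm**2).sum() * (ym**2).sum()))
        assert abs(res.r - manual) < 1e-12

    def test_exclusions_reported(self):
        obs = {"A*01:01": 0.1, "A*02:01": 0.2, "A*03:01": 0.3, "C*17:03": 0.4}
        ref = {"A*01:01": 0.1, "A*02:01": 0.25, "A*03:01": 0.28}
        res = correlate_with_reference(obs, ref)
        assert res.excluded == ("C*17:03",)
        assert res.n_pairs == 3

    def test_too_few_pairs(self):
        with pytest.raises(ValueError, match="shared"):
            correlate_with_reference({"A*01:01": 0.1}, {"A*01:01": 0.1})

    def test_zero_variance(self):
        obs = {f"A*{i:02d}:01": 0.5 for i in range(1, 5)}
        ref = {k: 0.1 * i for i, k in enumerate(obs)}
        with pytest.raises(ValueError, match="variance"):
            correlate_with_reference(obs, ref)


def test_hwe_goodness_of_fit():
    """Observed homozygote counts per haplotype fit the Binomial(n, p^2)
    expectation on a 50,000-donor HWE cohort (chi-square p > 0.001)."""
    p = pool(
        {
            "A*01:01~B*08:01": 0.10,
            "A*03:01~B*07:02": 0.07,
            "A*02:01~B*44:02": 0.05,
            "A*24:02~B*15:01": 0.03,
        }
    )
    cfg = SimulationConfig(haplotype_frequencies=p, n_donors=50_000, seed=53)
    _, truth = sample_cohort(cfg)
    labels = [str(r.haplotype) for r in p]
    observed = []
    expected = []
    for rec, label in zip(p, labels):
        count = sum(1 for a, b in truth.values() if a == b == label)
        observed.append(count)
        expected.append(cfg.n_donors * rec.frequency**2)
    observed.append(cfg.n_donors - sum(observed))
    expected.append(cfg.n_donors - sum(expected))
    result = stats.chisquare(observed, expected)
    assert result.pvalue > 0.001
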