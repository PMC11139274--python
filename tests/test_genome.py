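"""Genome layout, founding genotypes, mutation, and Mendelian transmission."""

import numpy as np
import pytest
from scipy import stats as sps

from genrescue import (
    ALT,
    MUT,
    REF,
    ConfigurationError,
    GenomeSpec,
    draw_founding_frequencies,
    init_genotypes,
    mendelian_offspring,
    mutate,
)
from genrescue.genome import (
    SOURCE_ALLELE,
    count_conserved,
    count_deleterious,
    write_genotypes_csv,
    write_vcf,
)


class TestGenomeSpec:
    def test_defaults_give_1200_loci_and_derived_conserved_rate(self):
        spec = GenomeSpec()
        assert spec.n_loci == 1200
        assert spec.mu_conserved == pytest.approx(spec.mu_neutral * spec.constraint_u)
        assert spec.mu_conserved == pytest.approx(4.84e-9)

    @pytest.mark.parametrize(
        "kwargs",
        [
            dict(n_neutral=0),
            dict(maf_range_recipient=(0.0, 0.1)),
            dict(maf_range_recipient=(0.2, 0.1)),
            dict(maf_range_source=(0.1, 0.55)),
            dict(mu_neutral=-1e-9),
        ],
    )
    def test_invalid_parameters_rejected(self, kwargs):
        with pytest.raises(ConfigurationError):
            GenomeSpec(**kwargs)


class TestFoundingFrequencies:
    def test_draws_stay_inside_the_configured_interval(self, rng):
        spec = GenomeSpec(maf_range_recipient=(0.05, 0.15), maf_range_source=(0.05, 0.15))
        freqs = draw_founding_frequencies(spec, rng)
        neutral = freqs.recipient[spec.neutral_slice]
        assert np.all((neutral >= 0.05) & (neutral <= 0.15))

    def test_degenerate_interval_is_a_point_mass(self, rng):
        spec = GenomeSpec(maf_range_recipient=(0.1, 0.1), maf_range_source=(0.1, 0.1))
        freqs = draw_founding_frequencies(spec, rng)
        assert np.all(freqs.recipient[spec.neutral_slice] == 0.1)

    def test_mean_of_uniform_draws_matches_interval_midpoint(self, rng):
        spec = GenomeSpec(maf_range_recipient=(0.40, 0.50), maf_range_source=(0.40, 0.50))
        freqs = draw_founding_frequencies(spec, rng)
        # SE of the mean of 1000 U(0.40, 0.50) draws is ~9e-4
        assert freqs.recipient[spec.neutral_slice].mean() == pytest.approx(0.45, abs=0.005)

    def test_equal_ranges_share_one_draw_and_unequal_ranges_do_not(self, rng):
        shared = draw_founding_frequencies(GenomeSpec(), rng)
        assert shared.shared
        np.testing.assert_array_equal(shared.recipient, shared.source)
        crossed_spec = GenomeSpec(
            maf_range_recipient=(0.05, 0.15), maf_range_source=(0.40, 0.50)
        )
        crossed = draw_founding_frequencies(crossed_spec, rng)
        assert not crossed.shared
        assert np.all(crossed.source[crossed_spec.neutral_slice] >= 0.40)
        assert np.all(crossed.recipient[crossed_spec.neutral_slice] <= 0.15)

    def test_diagnostic_and_conserved_classes_are_fixed(self, rng):
        spec = GenomeSpec()
        freqs = draw_founding_frequencies(spec, rng)
        assert np.all(freqs.recipient[spec.migrant_slice] == 1.0)
        assert np.all(freqs.recipient[spec.conserved_slice] == 0.0)


class TestInitGenotypes:
    def test_zero_frequency_locus_is_monomorphic_reference(self, small_spec, rng):
        freqs = np.zeros(small_spec.n_loci)
        geno = init_genotypes(small_spec, 50, "recipient", freqs, rng)
        assert np.all(geno[:, small_spec.neutral_slice, :] == REF)

    def test_founding_heterozygosity_matches_hardy_weinberg(self, rng):
        spec = GenomeSpec(n_neutral=1000, n_migrant=1, n_conserved=1)
        freqs = np.full(spec.n_loci, 0.1)
        geno = init_genotypes(spec, 1000, "recipient", freqs, rng)
        block = geno[:, spec.neutral_slice, :]
        het = (block[:, :, 0] != block[:, :, 1]).mean()
        # expectation 2p(1-p) = 0.18; SE over 1e6 draws ~ 4e-4
        assert het == pytest.approx(0.18, abs=0.005)

    def test_source_founders_fixed_for_their_diagnostic_allele(self, small_spec, rng):
        freqs = draw_founding_frequencies(small_spec, rng)
        geno = init_genotypes(small_spec, 30, "source", freqs.source, rng)
        assert np.all(geno[:, small_spec.migrant_slice, :] == SOURCE_ALLELE)
        recip = init_genotypes(small_spec, 30, "recipient", freqs.recipient, rng)
        assert np.all(recip[:, small_spec.migrant_slice, :] != SOURCE_ALLELE)

    def test_realized_founding_frequency_within_binomial_error(self, rng):
        spec = GenomeSpec(n_neutral=1000, n_migrant=1, n_conserved=1)
        freqs = draw_founding_frequencies(spec, rng)
        geno = init_genotypes(spec, 1000, "recipient", freqs.recipient, rng)
        realized = (geno[:, spec.neutral_slice, :] == ALT).mean(axis=(0, 2))
        p = freqs.recipient[spec.neutral_slice]
        se = np.sqrt(p * (1 - p) / 2000)
        assert np.all(np.abs(realized - p) < 5 * se + 1e-12)


class TestMutation:
    def test_zero_rate_leaves_table_unchanged(self, small_spec, rng):
        spec = GenomeSpec(n_neutral=20, n_migrant=10, n_conserved=10, mu_neutral=0.0)
        geno = init_genotypes(spec, 20, "recipient", np.full(spec.n_loci, 0.3), rng)
        before = geno.copy()
        events = mutate(geno, spec, rng)
        np.testing.assert_array_equal(geno, before)
        assert events.rows.size == 0

    def test_rate_one_converts_every_copy_to_mutant(self, rng):
        spec = GenomeSpec(n_neutral=5, n_migrant=2, n_conserved=3, mu_neutral=1.0, constraint_u=1.0)
        geno = init_genotypes(spec, 10, "recipient", np.full(spec.n_loci, 0.3), rng)
        mutate(geno, spec, rng)
        assert np.all(geno == MUT)

    def test_event_count_matches_bernoulli_expectation(self, rng):
        spec = GenomeSpec(n_neutral=500, n_migrant=1, n_conserved=1, mu_neutral=1e-3)
        geno = np.zeros((100, spec.n_loci, 2), dtype=np.uint8)
        total = sum(mutate(geno.copy(), spec, rng).rows.size for _ in range(50))
        n_slots = 100 * (spec.n_neutral + spec.n_migrant) * 2
        expected = 50 * n_slots * 1e-3
        assert abs(total - expected) < 4 * np.sqrt(expected)

    def test_mutant_state_is_absorbing(self, small_spec, rng):
        spec = GenomeSpec(n_neutral=20, n_migrant=10, n_conserved=10, mu_neutral=0.2)
        geno = init_genotypes(spec, 30, "recipient", np.full(spec.n_loci, 0.3), rng)
        counts = []
        for _ in range(10):
            mutate(geno, spec, rng)
            counts.append(int((geno == MUT).sum()))
        assert all(b >= a for a, b in zip(counts, counts[1:]))


class TestConservedCounting:
    def test_founders_carry_no_mutations(self, small_spec, rng):
        freqs = draw_founding_frequencies(small_spec, rng)
        geno = init_genotypes(small_spec, 10, "recipient", freqs.recipient, rng)
        m, d = count_conserved(geno, small_spec)
        assert np.all(m == 0) and np.all(d == 0)

    def test_single_mutant_copy_is_not_deleterious(self, small_spec, rng):
        freqs = draw_founding_frequencies(small_spec, rng)
        geno = init_genotypes(small_spec, 3, "recipient", freqs.recipient, rng)
        first_cons = small_spec.conserved_slice.start
        geno[0, first_cons, 0] = MUT
        assert count_deleterious(geno, small_spec, 0) == (0, 1)

    def test_homozygous_mutant_loci_are_counted(self, small_spec, rng):
        freqs = draw_founding_frequencies(small_spec, rng)
        geno = init_genotypes(small_spec, 3, "recipient", freqs.recipient, rng)
        start = small_spec.conserved_slice.start
        geno[1, start, :] = MUT
        geno[1, start + 1, :] = MUT
        geno[1, start + 2, 0] = MUT
        d, m = count_deleterious(geno, small_spec, 1)
        assert (d, m) == (2, 5)


class TestMendelianTransmission:
    def _fixed_genotypes(self, spec, pairs):
        geno = np.zeros((len(pairs), spec.n_loci, 2), dtype=np.uint8)
        for i, (a1, a2) in enumerate(pairs):
            geno[i, :, 0] = a1
            geno[i, :, 1] = a2
        return geno

    def test_homozygous_cross_outcomes(self, small_spec, rng):
        geno = self._fixed_genotypes(small_spec, [(REF, REF), (REF, REF), (ALT, ALT)])
        off = mendelian_offspring(geno, [0], [1], rng)
        assert np.all(off == REF)
        off = mendelian_offspring(geno, [0], [2], rng)  # AA x aa
        assert np.all(off[:, :, 0] == REF) and np.all(off[:, :, 1] == ALT)

    def test_heterozygous_cross_segregates_1_2_1(self, rng):
        spec = GenomeSpec(n_neutral=1, n_migrant=1, n_conserved=1)
        geno = self._fixed_genotypes(spec, [(REF, ALT), (REF, ALT)])
        off = mendelian_offspring(geno, np.zeros(10_000, int), np.ones(10_000, int), rng)
        dosage = (off[:, 0, :] == ALT).sum(axis=1)
        observed = np.bincount(dosage, minlength=3)
        result = sps.chisquare(observed, f_exp=[2500, 5000, 2500])
        assert result.pvalue > 0.001

    def test_diagnostic_alleles_are_conserved_in_transmission(self, small_spec, rng):
        freqs = draw_founding_frequencies(small_spec, rng)
        recip = init_genotypes(small_spec, 5, "recipient", freqs.recipient, rng)
        src = init_genotypes(small_spec, 5, "source", freqs.source, rng)
        geno = np.concatenate([recip, src])
        off = mendelian_offspring(geno, [0], [5], rng)  # resident x migrant F1
        mig = off[:, small_spec.migrant_slice, :]
        # exactly one source-diagnostic allele per migrant-associated locus
        assert np.all((mig == SOURCE_ALLELE).sum(axis=2) == 1)

    def test_mismatched_parent_arrays_rejected(self, small_spec, rng):
        geno = self._fixed_genotypes(small_spec, [(REF, REF), (REF, REF)])
        with pytest.raises(ValueError):
            mendelian_offspring(geno, [0, 1], [0], rng)


class TestWriters:
    def test_csv_round_trip(self, small_spec, rng, tmp_path):
        import pandas as pd

        freqs = draw_founding_frequencies(small_spec, rng)
        geno = init_genotypes(small_spec, 4, "recipient", freqs.recipient, rng)
        path = tmp_path / "geno.csv"
        write_genotypes_csv(path, geno, ids=[10, 11, 12, 13])
        df = pd.read_csv(path)
        assert len(df) == 4 * small_spec.n_loci
        back = df[df.individual_id == 12].sort_values("locus")
        np.testing.assert_array_equal(back["allele1"].to_numpy(), geno[2, :, 0])
        np.testing.assert_array_equal(back["allele2"].to_numpy(), geno[2, :, 1])

    def test_vcf_records_are_well_formed(self, small_spec, rng, tmp_path):
        freqs = draw_founding_frequencies(small_spec, rng)
        geno = init_genotypes(small_spec, 3, "source", freqs.source, rng)
        path = tmp_path / "geno.vcf"
        write_vcf(path, geno, small_spec)
        lines = path.read_text().splitlines()
        body = [ln for ln in lines if not ln.startswith("#")]
        assert lines[0] == "##fileformat=VCFv4.2"
        assert len(body) == small_spec.n_loci
        first = body[0].split("\t")
        assert first[3] == "A" and first[4] == "C,T"
        # source founders are 1/1 at migrant-associated loci
        mig_record = body[small_spec.migrant_slice.start].split("\t")
        assert mig_record[2].startswith("mig_")
        assert mig_record[9:] == ["1/1", "1/1", "1/1"]
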