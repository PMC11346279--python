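import numpy as np
import pytest

from alleletally.core import InheritanceMode, PopulationSpec
from alleletally.synth import (
    SpectrumSpec,
    default_fixture_table,
    default_population_specs,
    draw_truth,
    sample_table,
)

POPS = ["A", "B", "C"]


class TestSpectrumSpec:
    def test_invalid_bounds(self):
        with pytest.raises(ValueError):
            SpectrumSpec.log_uniform(1e-3, 1e-6)
        with pytest.raises(ValueError):
            SpectrumSpec.log_uniform(0.0, 1e-3)
        with pytest.raises(ValueError):
            SpectrumSpec.point_mass(0.0)
        with pytest.raises(ValueError):
            SpectrumSpec.point_mass(1.5)

    def test_log_uniform_mean_log10(self):
        # uniform on log10 in [-6, -4]: mean -5, sd (b-a)/sqrt(12)
        spec = SpectrumSpec.log_uniform(1e-6, 1e-4)
        draws = spec.sample(10_000, np.random.default_rng(7))
        se = (2 / np.sqrt(12)) / np.sqrt(10_000)
        assert np.mean(np.log10(draws)) == pytest.approx(-5.0, abs=3 * se)

    def test_draws_within_bounds(self):
        for spec in [
            SpectrumSpec.log_uniform(1e-6, 1e-3),
            SpectrumSpec.constraint_skewed(1e-6, 1e-3, skew=1.0),
        ]:
            draws = spec.sample(5_000, np.random.default_rng(0))
            assert draws.min() >= 1e-6 * (1 - 1e-12)
            assert draws.max() <= 1e-3 * (1 + 1e-12)

    def test_skew_shifts_mass_toward_rare(self):
        rng1, rng2 = np.random.default_rng(0), np.random.default_rng(0)
        base = SpectrumSpec.log_uniform(1e-6, 1e-2).sample(20_000, rng1)
        skewed = SpectrumSpec.constraint_skewed(1e-6, 1e-2, skew=1.0).sample(20_000, rng2)
        assert np.mean(np.log10(skewed)) < np.mean(np.log10(base)) - 0.5


class TestDrawTruth:
    def test_point_mass_all_equal(self):
        truth = draw_truth(SpectrumSpec.point_mass(1e-5), 131, POPS, shared=True, seed=0)
        assert truth.freqs.shape == (131, 3)
        assert np.all(truth.freqs == 1e-5)

    def test_empty_truth(self):
        truth = draw_truth(SpectrumSpec.point_mass(0.5), 0, POPS, seed=0)
        assert truth.freqs.shape == (0, 3)
        assert truth.variant_ids == []

    def test_shared_copies_one_draw(self):
        truth = draw_truth(
            SpectrumSpec.log_uniform(1e-6, 1e-3), 20, POPS, shared=True, seed=3
        )
        assert np.all(truth.freqs == truth.freqs[:, [0]])

    def test_unshared_differs_across_populations(self):
        truth = draw_truth(
            SpectrumSpec.log_uniform(1e-6, 1e-3), 20, POPS, shared=False, seed=3
        )
        assert not np.all(truth.freqs == truth.freqs[:, [0]])

    def test_deterministic_given_seed(self):
        a = draw_truth(SpectrumSpec.log_uniform(1e-6, 1e-3), 10, POPS, seed=5)
        b = draw_truth(SpectrumSpec.log_uniform(1e-6, 1e-3), 10, POPS, seed=5)
        assert np.array_equal(a.freqs, b.freqs)

    def test_negative_n_variants(self):
        with pytest.raises(ValueError):
            draw_truth(SpectrumSpec.point_mass(0.5), -1, POPS, seed=0)


def _specs(n=1000):
    return [PopulationSpec.half_half(p, n) for p in POPS]


class TestSampleTable:
    def test_zero_frequency_gives_zero_counts(self):
        truth = draw_truth(SpectrumSpec.point_mass(1e-9), 5, POPS, seed=0)
        truth.freqs[:] = 0.0
        table = sample_table(truth, _specs(), seed=1)
        assert all(c.ac == 0 for r in table for c in r.counts.values())

    def test_unit_frequency_saturates(self):
        truth = draw_truth(SpectrumSpec.point_mass(1.0), 5, POPS, seed=0)
        table = sample_table(truth, _specs(), seed=1)
        assert all(c.ac == c.an for r in table for c in r.counts.values())

    def test_allele_numbers_respect_mode(self):
        specs = [PopulationSpec("A", 300, 200), PopulationSpec("B", 10, 0),
                 PopulationSpec("C", 0, 7)]
        for mode, expected in [
            (InheritanceMode.AUTOSOMAL, {"A": 1000, "B": 20, "C": 14}),
            (InheritanceMode.X_LINKED, {"A": 800, "B": 20, "C": 7}),
        ]:
            truth = draw_truth(
                SpectrumSpec.point_mass(0.5), 2, POPS, seed=0, inheritance_mode=mode
            )
            table = sample_table(truth, specs, seed=1)
            for rec in table:
                assert {p: c.an for p, c in rec.counts.items()} == expected

    def test_binomial_mean_recovery(self):
        # 500 point-mass variants at p=0.01 over an=20000: matches spec's
        # 500-replicate mean tolerance 3*sqrt(p(1-p)/an/500)
        p, an_people = 0.01, 10_000
        truth = draw_truth(SpectrumSpec.point_mass(p), 500, ["A"], seed=2)
        table = sample_table(truth, [PopulationSpec.half_half("A", an_people)], seed=3)
        freqs = [r.counts["A"].ac / r.counts["A"].an for r in table]
        tol = 3 * np.sqrt(p * (1 - p) / 20_000 / 500)
        assert np.mean(freqs) == pytest.approx(p, abs=tol)

    def test_law_of_large_numbers(self):
        p = 0.003
        truth = draw_truth(SpectrumSpec.point_mass(p), 1, ["A"], seed=4)
        table = sample_table(truth, [PopulationSpec.half_half("A", 500_000)], seed=5)
        an = table.records[0].counts["A"].an
        assert an == 1_000_000
        tol = 3 * np.sqrt(p * (1 - p) / an)
        assert table.records[0].counts["A"].ac / an == pytest.approx(p, abs=tol)

    def test_seed_determinism_and_divergence(self):
        truth = draw_truth(SpectrumSpec.point_mass(0.01), 50, POPS, seed=0)
        t1 = sample_table(truth, _specs(), seed=9)
        t2 = sample_table(truth, _specs(), seed=9)
        t3 = sample_table(truth, _specs(), seed=10)
        acs = lambda t: [c.ac for r in t for c in r.counts.values()]
        assert acs(t1) == acs(t2)
        assert acs(t1) != acs(t3)

    def test_label_mismatch_rejected(self):
        truth = draw_truth(SpectrumSpec.point_mass(0.5), 2, POPS, seed=0)
        with pytest.raises(ValueError, match="labels"):
            sample_table(truth, [PopulationSpec.half_half("X", 10)], seed=0)


class TestDefaultFixture:
    def test_shape(self):
        table = default_fixture_table(seed=0)
        assert len(table) == 131
        assert len(table.populations) == 9
        assert sorted(table.genes()) == ["ACE2LIKE", "TMPRSS2LIKE"]

    def test_anchored_person_counts(self):
        by_label = {ps.label: ps.n_individuals for ps in default_population_specs()}
        assert by_label["EUR"] == 36_000
        assert by_label["AFR"] == 23_000
        assert by_label["AMI"] == 450
        assert by_label["ASH"] == 1_662
        assert by_label["EAS"] == 1_567

    def test_x_gene_has_smaller_an(self):
        table = default_fixture_table(seed=0)
        x_rec = next(r for r in table if r.gene == "ACE2LIKE")
        a_rec = next(r for r in table if r.gene == "TMPRSS2LIKE")
        for pop in table.populations:
            assert x_rec.counts[pop].an < a_rec.counts[pop].an
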