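"""Simulator behaviour: drift limits, sampling laws, block maps, missingness."""

import numpy as np
import pandas as pd
import pytest

from breedmix.fst import one_vs_rest_tables, wc_fst
from breedmix.simulate import (
    HaplotypeBlockMap,
    SimulationConfig,
    apply_depth_missingness,
    draw_breed_freq_panel,
    random_two_breed_scenario,
    sample_admixed_individual,
    sample_purebred_cohort,
    simulate_reference,
)


class TestConfig:
    def test_rejects_out_of_range_drift(self):
        with pytest.raises(ValueError):
            SimulationConfig(breed_drift=0.0)
        with pytest.raises(ValueError):
            SimulationConfig(breed_drift=1.0)  # needs allow_fixation
        SimulationConfig(breed_drift=1.0, allow_fixation=True)

    def test_rejects_bad_probabilities(self):
        with pytest.raises(ValueError):
            SimulationConfig(missing_base_rate=1.5)
        with pytest.raises(ValueError):
            SimulationConfig(ancestral_freq_range=(0.0, 0.9))


class TestFreqPanel:
    def test_zero_drift_limit_tracks_ancestral(self):
        cfg = SimulationConfig(n_breeds=3, n_sites=500, breed_drift=1e-8, seed=3)
        panel = draw_breed_freq_panel(cfg)
        dev = np.abs(panel.freqs - panel.ancestral[:, None])
        assert dev.max() < 1e-3

    def test_fixation_limit_gives_zero_or_one(self):
        cfg = SimulationConfig(
            n_breeds=3, n_sites=500, breed_drift=1.0, allow_fixation=True, seed=3
        )
        panel = draw_breed_freq_panel(cfg)
        assert np.isin(panel.freqs, (0.0, 1.0)).all()

    def test_realized_fst_matches_configured_drift(self):
        # Balding-Nichols calibration: realized multi-breed WC theta ~ F.
        # (The one-vs-rest per-site median is structurally much smaller:
        # WC's n-weighted 1:19 pooling dilutes the between-group variance.)
        cfg = SimulationConfig(
            n_breeds=20, n_sites=5000, samples_per_breed=20, breed_drift=0.2, seed=5
        )
        panel, G, labels = simulate_reference(cfg)
        assert abs(np.nanmedian(wc_fst(G, labels).fst) - 0.2) < 0.05

    def test_realized_fst_monotone_in_drift(self):
        global_medians, ovr_medians = [], []
        for F in (0.05, 0.2, 0.4):
            cfg = SimulationConfig(
                n_breeds=6, n_sites=2000, samples_per_breed=15, breed_drift=F, seed=9
            )
            _, G, labels = simulate_reference(cfg)
            global_medians.append(np.nanmedian(wc_fst(G, labels).fst))
            tables = one_vs_rest_tables(G, labels)
            ovr_medians.append(np.median([np.nanmedian(t.fst) for t in tables.values()]))
        assert global_medians[0] < global_medians[1] < global_medians[2]
        assert ovr_medians[0] < ovr_medians[1] < ovr_medians[2]


class TestPurebredCohort:
    def test_degenerate_frequencies_give_constant_dosage(self, rng):
        cfg = SimulationConfig(n_breeds=2, n_sites=50, breed_drift=0.2, seed=1)
        panel = draw_breed_freq_panel(cfg)
        panel.freqs[:, 0] = 0.0
        G, _ = sample_purebred_cohort(panel, {panel.breeds[0]: 5}, rng)
        assert (G.dosages == 0.0).all()

    def test_mean_dosage_matches_binomial_expectation(self, rng):
        cfg = SimulationConfig(n_breeds=2, n_sites=200, breed_drift=0.2, seed=1)
        panel = draw_breed_freq_panel(cfg)
        panel.freqs[:, 0] = 0.5
        G, _ = sample_purebred_cohort(panel, {panel.breeds[0]: 1000}, rng)
        assert 0.95 < G.dosages.mean() < 1.05

    def test_cohort_shape_supports_349_samples_over_65_breeds(self, rng):
        # the reference study design: 349 dogs spanning 65 breeds
        cfg = SimulationConfig(n_breeds=65, n_sites=20, breed_drift=0.2, seed=1)
        panel = draw_breed_freq_panel(cfg)
        counts = {b: 5 for b in panel.breeds}
        for b in panel.breeds[:24]:
            counts[b] = 6  # 41*5 + 24*6 = 349
        G, labels = sample_purebred_cohort(panel, counts, rng)
        assert G.n_samples == 349
        assert len(set(labels.labels.values())) == 65

    def test_unknown_breed_rejected(self, rng):
        cfg = SimulationConfig(n_breeds=2, n_sites=10, seed=1)
        panel = draw_breed_freq_panel(cfg)
        with pytest.raises(KeyError):
            sample_purebred_cohort(panel, {"poodle": 3}, rng)

    def test_realized_frequencies_converge_to_panel(self, rng):
        cfg = SimulationConfig(n_breeds=2, n_sites=300, breed_drift=0.2, seed=2)
        panel = draw_breed_freq_panel(cfg)
        G, _ = sample_purebred_cohort(panel, {panel.breeds[0]: 1000}, rng)
        realized = G.dosages.mean(axis=0) / 2.0
        assert np.abs(realized - panel.freqs[:, 0]).mean() < 0.03


class TestAdmixedIndividual:
    def test_pure_scenario_blocks_all_one_breed(self, rng):
        cfg = SimulationConfig(n_breeds=3, n_sites=500, seed=4)
        panel = draw_breed_freq_panel(cfg)
        q = np.array([0.0, 1.0, 0.0])
        _, bm = sample_admixed_individual(panel, q, cfg, rng)
        fracs = bm.origin_site_fractions()
        assert fracs[panel.breeds[1]] == 1.0

    def test_pure_scenario_matches_purebred_law(self, rng):
        # marginal allele frequencies of q = e_k draws match purebred draws
        cfg = SimulationConfig(n_breeds=3, n_sites=400, breed_drift=0.3, seed=4)
        panel = draw_breed_freq_panel(cfg)
        q = np.array([1.0, 0.0, 0.0])
        rows = [sample_admixed_individual(panel, q, cfg, rng)[0] for _ in range(500)]
        realized = np.mean(rows, axis=0) / 2.0
        assert np.abs(realized - panel.freqs[:, 0]).mean() < 0.03

    def test_half_half_origin_fraction_converges(self, rng):
        cfg = SimulationConfig(
            n_breeds=2, n_sites=2000, block_length_morgans=0.02, seed=4
        )
        panel = draw_breed_freq_panel(cfg)
        q = np.array([0.5, 0.5])
        total = pd.Series(0.0, index=panel.breeds)
        n_blocks = 0
        sites = 0
        for _ in range(60):
            _, bm = sample_admixed_individual(panel, q, cfg, rng)
            for hap in bm.haplotypes:
                n_blocks += len(hap)
                for _, s, e, breed in hap:
                    total[breed] += e - s
                    sites += e - s
        assert n_blocks >= 10_000
        assert 0.48 <= total[panel.breeds[0]] / sites <= 0.52

    def test_off_simplex_rejected(self, rng):
        cfg = SimulationConfig(n_breeds=2, n_sites=20, seed=4)
        panel = draw_breed_freq_panel(cfg)
        with pytest.raises(ValueError):
            sample_admixed_individual(panel, np.array([0.7, 0.7]), cfg, rng)

    def test_block_map_validates_tiling(self):
        with pytest.raises(ValueError):
            HaplotypeBlockMap([[("1", 0, 5, "a"), ("1", 6, 10, "a")]], 10, ["a"])
        with pytest.raises(ValueError):
            HaplotypeBlockMap([[("1", 0, 10, "zzz")]], 10, ["a"])


class TestTwoBreedScenario:
    def test_two_nonzero_entries_summing_to_one(self, rng):
        q = random_two_breed_scenario(["a", "b", "c", "d"], rng)
        assert (q > 0).sum() == 2
        assert q.sum() == pytest.approx(1.0)

    def test_same_seed_same_scenario(self):
        q1 = random_two_breed_scenario(["a", "b", "c"], np.random.default_rng(7))
        q2 = random_two_breed_scenario(["a", "b", "c"], np.random.default_rng(7))
        pd.testing.assert_series_equal(q1, q2)

    def test_minor_proportion_mean_matches_uniform_law(self, rng):
        # E[min(U, 1-U)] = 1/4 for U ~ Uniform(0, 1)
        minors = []
        for _ in range(10_000):
            q = random_two_breed_scenario(["a", "b"], rng)
            minors.append(q[q > 0].min())
        assert 0.24 <= np.mean(minors) <= 0.26

    def test_needs_two_breeds(self, rng):
        with pytest.raises(ValueError):
            random_two_breed_scenario(["only"], rng)


class TestDepthMissingness:
    def test_zero_reads_loses_everything(self, small_cohort, rng):
        _, _, G, _ = small_cohort
        out = apply_depth_missingness(G, 0.0, rng)
        assert np.isnan(out.dosages).all()

    def test_call_rate_monotone_in_read_fraction(self, small_cohort):
        _, _, G, _ = small_cohort
        rates = []
        for frac in (0.05, 0.10, 0.25, 0.5, 0.75, 1.0):
            out = apply_depth_missingness(G, frac, np.random.default_rng(3))
            rates.append(out.called.mean())
        assert all(a <= b for a, b in zip(rates, rates[1:]))

    def test_existing_missingness_preserved(self, rng):
        cfg = SimulationConfig(n_breeds=2, n_sites=200, missing_base_rate=0.3, seed=8)
        _, G, _ = simulate_reference(cfg)
        before = np.isnan(G.dosages)
        out = apply_depth_missingness(G, 0.9, rng)
        assert np.isnan(out.dosages)[before].all()

    def test_rejects_bad_fraction(self, small_cohort, rng):
        _, _, G, _ = small_cohort
        with pytest.raises(ValueError):
            apply_depth_missingness(G, 1.5, rng)


def test_generators_bit_reproducible():
    cfg = SimulationConfig(n_breeds=3, n_sites=300, samples_per_breed=4, seed=21)
    p1, g1, _ = simulate_reference(cfg)
    p2, g2, _ = simulate_reference(cfg)
    assert np.array_equal(p1.freqs, p2.freqs)
    assert np.array_equal(g1.dosages, g2.dosages, equal_nan=True)
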