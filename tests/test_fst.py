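"""Weir-Cockerham estimator against an independent transcription, plus
panel selection and stratified frequencies."""

import numpy as np
import pandas as pd
import pytest

from breedmix.fst import (
    AlleleFreqPanel,
    BreedAssignment,
    PanelSelection,
    breed_allele_freqs,
    one_vs_rest_tables,
    select_panel,
    wc_fst,
)
from breedmix.simulate import SimulationConfig, draw_breed_freq_panel, simulate_reference

from .conftest import geno
from .oracles import wc_fst_site

nan = np.nan


def two_pop_cohort(pop1, pop2):
    G = geno([[v] for v in pop1 + pop2])
    labels = BreedAssignment(
        {f"s{i + 1}": ("A" if i < len(pop1) else "B") for i in range(len(pop1) + len(pop2))}
    )
    return G, labels


class TestBreedAssignment:
    def test_one_vs_rest_relabels_without_touching_original(self):
        ba = BreedAssignment({"a": "pug", "b": "lab", "c": "lab"})
        view = ba.one_vs_rest("pug")
        assert view.labels == {"a": "pug", "b": "NOT_pug", "c": "NOT_pug"}
        assert ba.labels["b"] == "lab"

    def test_one_vs_rest_unknown_breed(self):
        ba = BreedAssignment({"a": "pug"})
        with pytest.raises(KeyError):
            ba.one_vs_rest("lab")

    def test_cluster_file_round_trip(self, tmp_path):
        ba = BreedAssignment({"a": "pug", "b": "lab"}, families={"a": "f1", "b": "f2"})
        path = tmp_path / "clusters.tsv"
        ba.write_cluster_file(path)
        back = BreedAssignment.read_cluster_file(path)
        assert back.labels == ba.labels
        assert back.families == {"a": "f1", "b": "f2"}

    def test_cluster_file_header_and_comments_skipped(self, tmp_path):
        path = tmp_path / "clusters.tsv"
        path.write_text("#comment\nFID IID CLUSTER\nf1 a pug\nf2 b lab\n")
        ba = BreedAssignment.read_cluster_file(path)
        assert ba.labels == {"a": "pug", "b": "lab"}


class TestWcFst:
    def test_fixed_difference_gives_exactly_one(self):
        G, labels = two_pop_cohort([0.0] * 10, [2.0] * 10)
        tab = wc_fst(G, labels)
        assert tab.fst[0] == 1.0

    def test_identical_pops_give_nonpositive_theta(self):
        # same genotype counts in both pops at an 0.5-frequency site
        pop = [0.0, 0.0, 1.0] * 2 + [1.0, 2.0, 2.0, 1.0]
        G, labels = two_pop_cohort(pop, list(pop))
        tab = wc_fst(G, labels)
        assert tab.table["defined"][0]
        assert tab.fst[0] <= 0.0

    def test_hwe_two_pop_case_matches_transcription(self):
        # pop1 alt freq 0.8, pop2 alt freq 0.2, near-HWE genotype counts
        pop1 = [2.0] * 6 + [1.0] * 4  # freq 0.8
        pop2 = [0.0] * 6 + [1.0] * 4  # freq 0.2
        G, labels = two_pop_cohort(pop1, pop2)
        tab = wc_fst(G, labels)
        a, b, c, theta = wc_fst_site([np.array(pop1), np.array(pop2)])
        assert tab.table["a"][0] == pytest.approx(a, abs=1e-12)
        assert tab.table["b"][0] == pytest.approx(b, abs=1e-12)
        assert tab.table["c"][0] == pytest.approx(c, abs=1e-12)
        assert tab.fst[0] == pytest.approx(theta, abs=1e-12)

    def test_single_population_rejected(self):
        G = geno([[0], [1]])
        with pytest.raises(ValueError):
            wc_fst(G, BreedAssignment({"s1": "A", "s2": "A"}))

    def test_random_sites_match_transcription(self, rng):
        # 1000 random multi-pop sites, with missingness, against the oracle
        n_pops = 4
        sizes = [7, 12, 5, 9]
        cols, expected = [], []
        for _ in range(1000):
            pops = []
            for n in sizes:
                p = rng.uniform(0.02, 0.98)
                d = rng.binomial(2, p, n).astype(float)
                d[rng.random(n) < 0.1] = nan
                pops.append(d)
            cols.append(np.concatenate(pops))
            expected.append(wc_fst_site(pops))
        G = geno(np.column_stack(cols))
        lab = {}
        i = 0
        for k, n in enumerate(sizes):
            for _ in range(n):
                lab[f"s{i + 1}"] = f"pop{k}"
                i += 1
        tab = wc_fst(G, BreedAssignment(lab))
        for m, (a, b, c, theta) in enumerate(expected):
            if np.isnan(theta):
                assert not tab.table["defined"][m]
            else:
                assert tab.fst[m] == pytest.approx(theta, abs=1e-10)

    def test_components_consistent_and_bounded(self, small_cohort):
        _, _, G, labels = small_cohort
        tab = wc_fst(G, labels)
        df = tab.table[tab.table["defined"]]
        recon = df["a"] / (df["a"] + df["b"] + df["c"])
        assert np.allclose(df["fst"], recon, atol=1e-12)
        assert (df["fst"] <= 1.0 + 1e-12).all()

    def test_pooled_identical_populations_near_zero(self, rng):
        # null: both "breeds" drawn from one frequency vector
        p = rng.uniform(0.1, 0.9, 2000)
        G = geno(rng.binomial(2, p, (100, 2000)).astype(float))
        lab = {f"s{i + 1}": ("A" if i < 50 else "B") for i in range(100)}
        tab = wc_fst(G, BreedAssignment(lab))
        assert abs(np.nanmedian(tab.fst)) < 0.02


class TestOneVsRest:
    def test_two_breeds_reduce_to_plain_two_pop_fst(self, rng):
        G = geno(rng.binomial(2, 0.4, (12, 50)).astype(float))
        lab = BreedAssignment({f"s{i + 1}": ("A" if i < 6 else "B") for i in range(12)})
        tables = one_vs_rest_tables(G, lab)
        direct = wc_fst(G, lab)
        for t in tables.values():
            assert np.allclose(t.fst, direct.fst, atol=1e-12, equal_nan=True)

    def test_undifferentiated_breed_near_zero(self, rng):
        # breed whose frequencies equal the pooled rest: |theta| small
        p = rng.uniform(0.1, 0.9, 2000)
        G = geno(rng.binomial(2, p, (50, 2000)).astype(float))
        lab = BreedAssignment(
            {f"s{i + 1}": ("target" if i < 10 else f"other{i % 4}") for i in range(50)}
        )
        tab = one_vs_rest_tables(G, lab)["target"]
        assert abs(np.nanmedian(tab.fst)) < 0.02


class TestSelectPanel:
    def _tables(self, fst_by_breed, pos=None):
        tables = {}
        n = len(next(iter(fst_by_breed.values())))
        pos = pos if pos is not None else np.arange(1, n + 1) * 1000
        from breedmix.fst import SiteFstTable

        for breed, fst in fst_by_breed.items():
            fst = np.asarray(fst, dtype=float)
            tables[breed] = SiteFstTable(
                pd.DataFrame(
                    {
                        "id": [f"site{m}" for m in range(n)],
                        "chrom": "1",
                        "pos": pos,
                        "a": fst,
                        "b": 0.0,
                        "c": 1.0 - fst,
                        "fst": fst,
                        "defined": ~np.isnan(fst),
                    }
                ),
                scheme=breed,
            )
        return tables

    def test_top_k_covering_all_defined_sites(self):
        tables = self._tables({"A": [0.1, nan, 0.3]})
        sel = select_panel(tables, None, top_k=10, global_threshold=0.35)
        assert sel.site_ids == ["site0", "site2"]  # undefined never selected

    def test_shared_site_has_multiple_provenance_tags(self):
        tables = self._tables({"A": [0.9, 0.1, 0.1], "B": [0.8, 0.2, 0.1]})
        sel = select_panel(tables, None, top_k=1, global_threshold=0.35)
        assert sel.site_ids == ["site0"]
        assert set(sel.provenance["site0"]) == {"top_k:A", "top_k:B"}

    def test_global_threshold_union_and_provenance_partition(self):
        tables = self._tables({"A": [0.9, 0.1, 0.2]})
        glob = self._tables({"g": [0.1, 0.6, 0.2]})["g"]
        sel = select_panel(tables, glob, top_k=1, global_threshold=0.35)
        assert sel.site_ids == ["site0", "site1"]
        assert sel.provenance["site1"] == ["global"]
        # dropping the global rule yields a subset
        sub = select_panel(tables, None, top_k=1, global_threshold=0.35)
        assert set(sub.site_ids) <= set(sel.site_ids)

    def test_ties_break_by_genomic_order(self):
        tables = self._tables({"A": [0.5, 0.5, 0.5]})
        sel = select_panel(tables, None, top_k=2, global_threshold=0.35)
        assert sel.site_ids == ["site0", "site1"]

    def test_invalid_parameters_rejected(self):
        tables = self._tables({"A": [0.5]})
        with pytest.raises(ValueError):
            select_panel(tables, None, top_k=-1)
        with pytest.raises(ValueError):
            select_panel(tables, tables["A"], top_k=1, global_threshold=1.5)

    def test_duplicate_panel_ids_rejected(self):
        with pytest.raises(ValueError):
            PanelSelection(["x", "x"], {"x": ["global"]})


class TestBreedAlleleFreqs:
    def test_single_sample_breed_frequency_is_half_dosage(self):
        G = geno([[0, 1, 2], [2, 2, 0]])
        lab = BreedAssignment({"s1": "A", "s2": "B"})
        panel = breed_allele_freqs(G, lab)
        assert np.allclose(panel.freqs[:, 0], [0.0, 0.5, 1.0])
        assert np.allclose(panel.freqs[:, 1], [1.0, 1.0, 0.0])

    def test_missing_excluded_from_denominator(self):
        G = geno([[2.0], [nan], [0.0], [0.0]])
        lab = BreedAssignment({f"s{i + 1}": "A" for i in range(4)})
        lab.labels["s4"] = "B"
        panel = breed_allele_freqs(G, lab)
        assert panel.freqs[0, 0] == pytest.approx(0.5)  # 2 alt over 4 alleles

    def test_zero_call_breed_imputed_from_pool(self):
        G = geno([[1.0], [nan]])
        lab = BreedAssignment({"s1": "A", "s2": "B"})
        panel = breed_allele_freqs(G, lab, on_empty="impute")
        assert panel.freqs[0, 1] == pytest.approx(0.5)  # pooled frequency
        panel_nan = breed_allele_freqs(G, lab, on_empty="nan")
        assert np.isnan(panel_nan.freqs[0, 1])  # alternative: leave the hole visible

    def test_recovers_generating_frequencies(self):
        cfg = SimulationConfig(
            n_breeds=3, n_sites=400, samples_per_breed=200, breed_drift=0.2, seed=17
        )
        true_panel, G, labels = simulate_reference(cfg)
        est = breed_allele_freqs(G, labels)
        assert np.abs(est.freqs - true_panel.freqs).max() < 0.2
        assert np.abs(est.freqs - true_panel.freqs).mean() < 0.05

    def test_orientation_metadata_constant(self, small_cohort):
        _, _, G, labels = small_cohort
        panel = breed_allele_freqs(G, labels)
        assert panel.oriented_to == "alt"

    def test_freq_panel_tsv_round_trip(self, tmp_path, small_cohort):
        _, _, G, labels = small_cohort
        panel = breed_allele_freqs(G, labels)
        path = tmp_path / "freqs.tsv"
        panel.write_tsv(path)
        back = AlleleFreqPanel.read_tsv(path)
        assert back.breeds == panel.breeds
        assert np.allclose(back.freqs, panel.freqs, atol=1e-6)
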