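"""End-to-end experiment recipes over the library primitives.

These functions wire simulator -> panel selection -> supervised estimation
into the three study designs the package is organised around:

* purebred recovery — re-estimate every reference individual against a
  panel built from its own cohort and ask how often the own-breed
  proportion dominates;
* synthetic-admixture recovery — estimate two-breed admixed individuals
  with known truth and score per-sample RMSE / Pearson r;
* downsampling robustness — repeat the recovery on the same queries under
  increasing genotype missingness that emulates read downsampling.

Every recipe is deterministic given its seed and sized to run on a single
CPU in minutes.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .admixture import AdmixtureFit, estimate_q_matrix, recovery_metrics
from .fst import (
    AlleleFreqPanel,
    BreedAssignment,
    PanelSelection,
    breed_allele_freqs,
    one_vs_rest_tables,
    select_panel,
    wc_fst,
)
from .genotypes import GenotypeMatrix
from .simulate import (
    SimulationConfig,
    apply_depth_missingness,
    simulate_admixed_cohort,
    simulate_reference,
)

PAPER_READ_FRACTIONS = (1.0, 0.75, 0.5, 0.25, 0.10, 0.05)


def twin_simulation_config(
    seed: int,
    n_breeds: int = 20,
    n_sites: int = 20_000,
    samples_per_breed: int = 8,
    drift_range: tuple[float, float] = (0.1, 0.3),
) -> SimulationConfig:
    """Scaled-down study cohort: 20 moderately drifted breeds, 8 dogs each.

    Per-breed drift F is drawn once, uniformly on ``drift_range``, from a
    generator seeded independently of the cohort draw, mimicking the wide
    spread of breed differentiation in real panels.
    """
    drift_rng = np.random.default_rng([seed, 0xD81F])
    F = drift_rng.uniform(*drift_range, size=n_breeds)
    return SimulationConfig(
        n_breeds=n_breeds,
        n_sites=n_sites,
        samples_per_breed=samples_per_breed,
        breed_drift=F,
        seed=seed,
    )


def build_reference_panel(
    G_ref: GenotypeMatrix,
    labels: BreedAssignment,
    top_k: int = 10_000,
    global_threshold: float = 0.350,
) -> tuple[PanelSelection, AlleleFreqPanel]:
    """One-vs-rest + global FST panel and its stratified frequencies."""
    per_breed = one_vs_rest_tables(G_ref, labels)
    global_table = wc_fst(G_ref, labels)
    selection = select_panel(per_breed, global_table, top_k=top_k, global_threshold=global_threshold)
    freqs = breed_allele_freqs(G_ref, labels, selection)
    return selection, freqs


def harmonized_query_panel(
    G_ref: GenotypeMatrix,
    labels: BreedAssignment,
    G_query: GenotypeMatrix,
    breed_panel: PanelSelection,
    global_threshold: float = 0.350,
) -> tuple[list[str], AlleleFreqPanel]:
    """Query-side panel harmonization recipe.

    Intersect the query's genotyped sites with the reference, re-derive
    the global high-FST sites on the shared set, concatenate with the
    stored breed-specific sites, and return the final site list with
    reference frequencies restricted to it.
    """
    shared = [s for s in G_ref.site_ids() if s in set(G_query.site_ids())]
    G_shared = G_ref.subset_site_ids(shared)
    global_table = wc_fst(G_shared, labels)
    hits = global_table.table[
        global_table.table["defined"] & (global_table.table["fst"] > global_threshold)
    ]["id"].tolist()
    shared_set = set(shared)
    breed_sites = [s for s in breed_panel.site_ids if s in shared_set]
    order = {s: i for i, s in enumerate(G_ref.site_ids())}
    final = sorted(set(hits) | set(breed_sites), key=order.__getitem__)
    freqs = breed_allele_freqs(G_ref.subset_site_ids(final), labels)
    return final, freqs


def purebred_recovery_experiment(
    config: SimulationConfig,
    top_k: int = 500,
    global_threshold: float = 0.350,
) -> dict:
    """Re-estimate every simulated reference sample against its own panel.

    Returns the fit plus each sample's estimated own-breed proportion.
    """
    panel_truth, G_ref, labels = simulate_reference(config)
    selection, freqs = build_reference_panel(
        G_ref, labels, top_k=top_k, global_threshold=global_threshold
    )
    fit = estimate_q_matrix(freqs, G_ref.subset_site_ids(selection.site_ids))
    lab = labels.label_vector(G_ref.samples)
    own = pd.Series(
        [fit.q.loc[s, b] for s, b in zip(G_ref.samples, lab)],
        index=fit.q.index,
        name="own_breed_proportion",
    )
    return {
        "panel_truth": panel_truth,
        "reference": G_ref,
        "labels": labels,
        "selection": selection,
        "freqs": freqs,
        "fit": fit,
        "own_breed": own,
    }


def synthetic_recovery_experiment(
    config: SimulationConfig,
    n_queries: int = 50,
    top_k: int = 500,
    global_threshold: float = 0.350,
    query_seed: int | None = None,
) -> dict:
    """Scaled twin of the synthetic-admixture recovery experiment.

    Simulates the reference, builds the marker panel, draws ``n_queries``
    two-breed admixed individuals with uniform random proportions, and
    scores per-sample RMSE and Pearson r against the truth.
    """
    rng = config.rng()
    panel_truth, G_ref, labels = simulate_reference(config, rng)
    selection, freqs = build_reference_panel(
        G_ref, labels, top_k=top_k, global_threshold=global_threshold
    )
    query_rng = rng if query_seed is None else np.random.default_rng([query_seed, 0xAD])
    G_query, truth, block_maps = simulate_admixed_cohort(
        panel_truth, n_queries, config, query_rng
    )
    G_query_panel = G_query.subset_site_ids(selection.site_ids)
    fit = estimate_q_matrix(freqs, G_query_panel)
    metrics = recovery_metrics(fit.q, truth)
    return {
        "panel_truth": panel_truth,
        "reference": G_ref,
        "labels": labels,
        "selection": selection,
        "freqs": freqs,
        "query": G_query,
        "query_panel": G_query_panel,
        "truth": truth,
        "block_maps": block_maps,
        "fit": fit,
        "metrics": metrics,
    }


def downsampling_experiment(
    freqs: AlleleFreqPanel,
    G_query_panel: GenotypeMatrix,
    truth: pd.DataFrame,
    seed: int,
    read_fractions: tuple[float, ...] = PAPER_READ_FRACTIONS,
    full_depth: float = 2.5,
) -> pd.DataFrame:
    """Re-estimate the same queries under coverage-dependent missingness.

    For each read fraction the query genotypes are thinned with the
    Poisson zero-coverage model at ``full_depth`` x baseline and
    re-estimated; returns one row per fraction with mean RMSE, mean and
    10th-percentile Pearson r, and the mean surviving call rate.
    """
    rng = np.random.default_rng([seed, 0xD0])
    rows = []
    for frac in read_fractions:
        G_d = apply_depth_missingness(G_query_panel, frac, rng, full_depth=full_depth)
        fit = estimate_q_matrix(freqs, G_d)
        metrics = recovery_metrics(fit.q, truth)
        rows.append(
            {
                "read_fraction": frac,
                "mean_rmse": float(metrics["rmse"].mean()),
                "mean_pearson_r": float(metrics["pearson_r"].mean()),
                "p10_pearson_r": float(np.percentile(metrics["pearson_r"], 10)),
                "mean_call_rate": float(G_d.called.mean()),
            }
        )
    return pd.DataFrame(rows)


def solver_grid_instances(
    n_instances: int = 100,
    n_sites: int = 200,
    max_breeds: int = 3,
    seed: int = 0,
) -> list[dict]:
    """Random small supervised-estimation instances for grid-oracle checks."""
    rng = np.random.default_rng([seed, 0x501])
    out = []
    for _ in range(n_instances):
        K = int(rng.integers(2, max_breeds + 1))
        P = rng.uniform(0.02, 0.98, size=(n_sites, K))
        q = rng.dirichlet(np.ones(K))
        x = P @ q + rng.normal(0, 0.05, size=n_sites)
        g = np.clip(np.round(2 * np.clip(x, 0, 1)), 0, 2)
        out.append({"P": P, "q_true": q, "g": g})
    return out
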