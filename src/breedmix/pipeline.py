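"""Staged pipeline: configuration, artifact writing, and the manifest.

A run executes simulate? -> filter -> panel -> freqs -> estimate
(-> bootstrap / structure / evaluate as requested), writing every product
as plain text (VCF, TSV, site lists) plus a JSON manifest recording the
parameters, seed and artifact list so any output can be regenerated.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .admixture import bootstrap_reference, estimate_q_matrix, recovery_metrics
from .experiments import build_reference_panel, harmonized_query_panel
from .filtering import FilterReport, filter_sites, ld_prune
from .fst import BreedAssignment, breed_allele_freqs
from .genotypes import GenotypeMatrix
from .simulate import SimulationConfig, simulate_admixed_cohort, simulate_reference
from .structure import (
    centroid_distance_score,
    hamming_distance_matrix,
    neighbor_joining,
    pca_embedding,
    standardized_grm,
)
from .vcfio import read_genotypes_vcf, read_truth_table, write_genotypes_vcf, write_truth_table

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """All stage parameters, defaulted to the reference study's values."""

    # site filters
    maf_min: float = 0.01
    min_call_rate: float = 0.20
    # LD pruning
    window_kb: float = 250.0
    window_ct: int = 50
    r2_max: float = 0.8
    step_ct: int = 1
    # panel selection
    top_k: int = 10_000
    global_fst_threshold: float = 0.350
    # solver
    solver_tol: float = 1e-8
    # bootstrap
    bootstrap_n_remove: int = 6
    bootstrap_iters: int = 100
    # synthetic cohorts
    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    n_queries: int = 50
    seed: int = 0

    def to_yaml(self, path) -> None:
        d = asdict(self)
        sim = d.pop("simulation")
        drift = sim["breed_drift"]
        if isinstance(drift, np.ndarray):
            sim["breed_drift"] = drift.tolist()
        sim["ancestral_freq_range"] = list(sim["ancestral_freq_range"])
        d["simulation"] = sim
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh)
        sim = d.pop("simulation", {})
        if "ancestral_freq_range" in sim:
            sim["ancestral_freq_range"] = tuple(sim["ancestral_freq_range"])
        if isinstance(sim.get("breed_drift"), list):
            sim["breed_drift"] = np.asarray(sim["breed_drift"])
        return cls(simulation=SimulationConfig(**sim), **d)

    def with_seed(self, seed: int) -> "PipelineConfig":
        return replace(self, seed=seed, simulation=replace(self.simulation, seed=seed))


class PipelineError(RuntimeError):
    """Stage failure with a machine-readable record."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"stage {stage!r} failed: {message}")
        self.record = {"stage": stage, "error": message}


def run_pipeline(
    config: PipelineConfig,
    outdir,
    reference_vcf=None,
    cluster_file=None,
    query_vcf=None,
    truth_table=None,
    do_filter: bool = True,
    do_bootstrap: bool = False,
    do_structure: bool = False,
) -> dict:
    """Execute the staged pipeline and write an artifact bundle.

    Inputs are either a reference VCF + cluster file (plus optional query
    VCF and truth table), or — when ``reference_vcf`` is None — cohorts
    simulated from ``config.simulation``. Returns the manifest dict.
    """
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "version": __version__,
        "seed": config.seed,
        "artifacts": {},
        "stages": [],
    }

    def _save(name: str, filename: str, writer) -> None:
        path = out / filename
        writer(path)
        manifest["artifacts"][name] = filename

    stage = "inputs"
    try:
        truth = None
        if reference_vcf is None:
            stage = "simulate"
            sim = config.simulation
            rng = np.random.default_rng(config.seed)
            panel_truth, G_ref, labels = simulate_reference(sim, rng)
            if query_vcf is None and config.n_queries > 0:
                G_query, truth, _maps = simulate_admixed_cohort(
                    panel_truth, config.n_queries, sim, rng
                )
                _save("query_vcf", "query.vcf", lambda p: write_genotypes_vcf(G_query, p))
                _save("truth", "truth.tsv", lambda p: write_truth_table(truth, p))
            else:
                G_query = read_genotypes_vcf(query_vcf) if query_vcf else None
            _save("reference_vcf", "reference.vcf", lambda p: write_genotypes_vcf(G_ref, p))
            _save("cluster_file", "reference.clusters.tsv", labels.write_cluster_file)
            manifest["stages"].append({"name": "simulate", "params": {"seed": config.seed}})
        else:
            G_ref = read_genotypes_vcf(reference_vcf)
            if cluster_file is None:
                raise PipelineError("inputs", "a cluster file is required with a reference VCF")
            labels = BreedAssignment.read_cluster_file(cluster_file)
            G_query = read_genotypes_vcf(query_vcf) if query_vcf else None
            if truth_table:
                truth = read_truth_table(truth_table)

        if do_filter:
            stage = "filter"
            report = FilterReport()
            G_ref, report = filter_sites(
                G_ref, config.maf_min, config.min_call_rate, report=report
            )
            kept = ld_prune(
                G_ref,
                window_kb=config.window_kb,
                window_ct=config.window_ct,
                r2_max=config.r2_max,
                step_ct=config.step_ct,
                report=report,
            )
            G_ref = G_ref.take_sites(kept)
            _save(
                "filter_report",
                "filter_report.json",
                lambda p: Path(p).write_text(json.dumps(report.to_dict(), indent=2)),
            )
            manifest["stages"].append({"name": "filter", "params": report.to_dict()})

        stage = "panel"
        selection, freqs = build_reference_panel(
            G_ref, labels, top_k=config.top_k, global_threshold=config.global_fst_threshold
        )
        _save("panel_sites", "panel_sites.txt", selection.write_site_list)
        _save("allele_freqs", "breed_freqs.tsv", freqs.write_tsv)
        manifest["stages"].append(
            {
                "name": "panel",
                "params": {
                    "top_k": config.top_k,
                    "global_fst_threshold": config.global_fst_threshold,
                    "panel_size": len(selection),
                },
            }
        )

        if G_query is not None:
            stage = "estimate"
            shared = set(G_query.site_ids())
            dropped = len([s for s in selection.site_ids if s not in shared])
            if dropped:
                logger.info("query lacks %d panel sites; harmonizing", dropped)
                sites, freqs_q = harmonized_query_panel(
                    G_ref, labels, G_query, selection,
                    global_threshold=config.global_fst_threshold,
                )
            else:
                sites, freqs_q = selection.site_ids, freqs
            manifest["stages"].append(
                {"name": "estimate", "params": {"panel_sites_dropped_in_query": dropped,
                                                "panel_sites_used": len(sites)}}
            )
            fit = estimate_q_matrix(freqs_q, G_query.subset_site_ids(sites), tol=config.solver_tol)
            _save("q_matrix", "Q.tsv", fit.write_tsv)

            if truth is not None:
                stage = "evaluate"
                metrics = recovery_metrics(fit.q, truth)
                _save(
                    "metrics",
                    "recovery_metrics.tsv",
                    lambda p: metrics.to_csv(p, sep="\t", index_label="sample"),
                )

            if do_bootstrap:
                stage = "bootstrap"
                summary = bootstrap_reference(
                    G_ref,
                    labels,
                    G_query.subset_site_ids(sites),
                    sites,
                    np.random.default_rng([config.seed, 0xB0]),
                    n_remove=config.bootstrap_n_remove,
                    iters=config.bootstrap_iters,
                    tol=config.solver_tol,
                )
                _save(
                    "bootstrap_sd",
                    "bootstrap_sd.tsv",
                    lambda p: summary.sd.to_csv(p, sep="\t", index_label="sample"),
                )

        if do_structure:
            stage = "structure"
            G_panel = G_ref.subset_site_ids(selection.site_ids)
            grm = standardized_grm(G_panel)
            _save("grm", "grm.tsv", grm.write_tsv)
            ham = hamming_distance_matrix(G_panel)
            _save("hamming", "hamming.tsv", ham.write_tsv)
            tree = neighbor_joining(ham)
            _save("nj_tree", "nj_tree.nwk", lambda p: Path(p).write_text(str(tree)))
            coords = pca_embedding(G_panel, n_components=2)
            _save("pca", "pca.tsv", lambda p: coords.to_csv(p, sep="\t"))
            score = centroid_distance_score(coords, labels)
            manifest["stages"].append(
                {"name": "structure", "params": {"centroid_global_mean": score.global_mean}}
            )

    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError(stage, str(exc)) from exc

    config.to_yaml(out / "config.yaml")
    manifest["artifacts"]["config"] = "config.yaml"
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest
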