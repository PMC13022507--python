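"""Breed-structured cohort simulator with known admixture truth.

Breeds are modelled as populations drifted from a common ancestor under
the Balding-Nichols model: at each site the ancestral frequency p is drawn
uniformly from a configured range, and breed k's frequency is

    p_k ~ Beta(p (1 - F_k) / F_k,  (1 - p) (1 - F_k) / F_k),

so the expected differentiation of breed k from the ancestor is ~F_k. A
per-breed F emulates the wide spread of breed-specific FST seen across
real dog breeds (some barely drifted, some near fixation).

Admixed individuals are built haplotype by haplotype: each of the two
haplotypes is tiled with ancestry blocks whose genetic lengths are
exponential (a single genome-wide recombination rate on a flat 1 cM/Mb
map), block origins drawn i.i.d. from the individual's true proportion
vector q, and alleles drawn Bernoulli from the origin breed's frequency.
The block map is returned as ground truth for local-origin bookkeeping.

Low-coverage genotyping is emulated at the genotype level: a call is lost
with the Poisson zero-coverage probability exp(-depth), where depth scales
with the retained read fraction. There is no genotype-error model.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .fst import AlleleFreqPanel, BreedAssignment
from .genotypes import GenotypeMatrix, make_site_table

MORGAN_PER_BP_PER_CM_MB = 1e-8  # 1 cM/Mb == 1e-8 Morgan per bp


@dataclass
class SimulationConfig:
    """Study-design knobs for the synthetic cohorts.

    Attributes
    ----------
    n_breeds, n_sites
        Cohort dimensions.
    samples_per_breed
        Purebred reference individuals per breed (int, or one count per breed).
    ancestral_freq_range
        Uniform support for the ancestral allele frequency at each site.
    breed_drift
        Balding-Nichols F per breed (scalar broadcast, or length-n_breeds);
        strictly inside (0, 1) unless ``allow_fixation`` and F == 1.
    block_length_morgans
        Mean genetic length of an ancestry block in admixed individuals
        (0.1 Morgan by default, i.e. roughly ten generations of mixing).
    missing_base_rate
        Baseline probability that any genotype is missing.
    site_spacing_bp / cm_per_mb
        Sites sit on one synthetic chromosome at uniform physical spacing;
        the flat map converts physical to genetic distance.
    """

    n_breeds: int = 20
    n_sites: int = 20_000
    samples_per_breed: int | list[int] = 8
    ancestral_freq_range: tuple[float, float] = (0.05, 0.95)
    breed_drift: float | np.ndarray = 0.2
    block_length_morgans: float = 0.1
    missing_base_rate: float = 0.0
    site_spacing_bp: int = 100_000
    cm_per_mb: float = 1.0
    seed: int = 0
    allow_fixation: bool = False
    chrom: str = "1"

    def __post_init__(self) -> None:
        if self.n_breeds < 1 or self.n_sites < 1:
            raise ValueError("n_breeds and n_sites must be positive")
        lo, hi = self.ancestral_freq_range
        if not (0.0 < lo <= hi < 1.0):
            raise ValueError("ancestral_freq_range must lie inside (0, 1)")
        if not 0.0 <= self.missing_base_rate <= 1.0:
            raise ValueError("missing_base_rate must be a probability")
        if self.block_length_morgans <= 0:
            raise ValueError("block_length_morgans must be positive")
        counts = self.per_breed_counts()
        if any(c < 1 for c in counts):
            raise ValueError("samples_per_breed counts must be positive")
        F = self.drift_vector()
        bad = (F <= 0.0) | (F > 1.0) | ((F == 1.0) & (not self.allow_fixation))
        if bad.any():
            raise ValueError(
                "breed_drift must be in (0, 1); F == 1 requires allow_fixation"
            )

    def drift_vector(self) -> np.ndarray:
        F = np.asarray(self.breed_drift, dtype=float)
        if F.ndim == 0:
            F = np.full(self.n_breeds, float(F))
        if F.shape != (self.n_breeds,):
            raise ValueError("breed_drift must be scalar or one value per breed")
        return F

    def per_breed_counts(self) -> list[int]:
        if isinstance(self.samples_per_breed, int):
            return [self.samples_per_breed] * self.n_breeds
        counts = list(self.samples_per_breed)
        if len(counts) != self.n_breeds:
            raise ValueError("samples_per_breed list must have one entry per breed")
        return counts

    def breed_names(self) -> list[str]:
        width = len(str(self.n_breeds))
        return [f"breed{str(i + 1).zfill(width)}" for i in range(self.n_breeds)]

    def positions(self) -> np.ndarray:
        return (np.arange(self.n_sites, dtype=np.int64) + 1) * self.site_spacing_bp

    def genetic_positions(self) -> np.ndarray:
        """Site genetic positions in Morgans on the flat map."""
        return self.positions() * MORGAN_PER_BP_PER_CM_MB * self.cm_per_mb

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)


@dataclass
class HaplotypeBlockMap:
    """Ground-truth breed-of-origin segments for one diploid individual.

    Each haplotype is a list of ``(chrom, start, end, breed)`` segments in
    site-index coordinates, half-open ``[start, end)``, tiling ``[0,
    n_sites)`` without overlap.
    """

    haplotypes: list[list[tuple[str, int, int, str]]]
    n_sites: int
    breeds: list[str] = field(repr=False)

    def __post_init__(self) -> None:
        known = set(self.breeds)
        for hap in self.haplotypes:
            cursor = 0
            for _, start, end, breed in hap:
                if start != cursor or end <= start:
                    raise ValueError("segments must tile the site range without overlap")
                if breed not in known:
                    raise ValueError(f"unknown breed label {breed!r} in block map")
                cursor = end
            if cursor != self.n_sites:
                raise ValueError("segments do not cover all sites")

    def origin_site_fractions(self) -> pd.Series:
        """Fraction of (haplotype, site) slots originating from each breed."""
        counts = dict.fromkeys(self.breeds, 0)
        for hap in self.haplotypes:
            for _, start, end, breed in hap:
                counts[breed] += end - start
        total = sum(counts.values())
        return pd.Series({b: c / total for b, c in counts.items()})

    def to_frame(self, sample_id: str = "sample") -> pd.DataFrame:
        rows = [
            (sample_id, hap_i, chrom, start, end, breed)
            for hap_i, hap in enumerate(self.haplotypes)
            for chrom, start, end, breed in hap
        ]
        return pd.DataFrame(
            rows, columns=["sample", "haplotype", "chrom", "start", "end", "breed"]
        )


def validate_simplex(q: np.ndarray, atol: float = 1e-9) -> np.ndarray:
    q = np.asarray(q, dtype=float)
    if q.ndim != 1 or np.any(q < -atol) or abs(q.sum() - 1.0) > atol:
        raise ValueError("proportion vector is not on the simplex")
    return np.clip(q, 0.0, None)


# ---------------------------------------------------------------------------
# Generators
# ---------------------------------------------------------------------------


def draw_breed_freq_panel(
    config: SimulationConfig, rng: np.random.Generator | None = None
) -> AlleleFreqPanel:
    """Draw per-breed allele frequencies under the Balding-Nichols model."""
    rng = config.rng() if rng is None else rng
    lo, hi = config.ancestral_freq_range
    p = rng.uniform(lo, hi, size=config.n_sites)
    F = config.drift_vector()
    freqs = np.empty((config.n_sites, config.n_breeds))
    for k, f in enumerate(F):
        if f == 1.0:
            # fixation limit: each breed frequency collapses to 0 or 1
            freqs[:, k] = (rng.random(config.n_sites) < p).astype(float)
        else:
            scale = (1.0 - f) / f
            freqs[:, k] = rng.beta(p * scale, (1.0 - p) * scale)
    sites = make_site_table(config.positions(), chrom=config.chrom)
    return AlleleFreqPanel(
        freqs,
        sites["id"].tolist(),
        config.breed_names(),
        oriented_to="alt",
        ancestral=p,
        sites=sites,
    )


def sample_purebred_cohort(
    panel: AlleleFreqPanel,
    counts: dict[str, int],
    rng: np.random.Generator,
    missing_rate: float = 0.0,
) -> tuple[GenotypeMatrix, BreedAssignment]:
    """Draw Binomial(2, p_mk) purebred genotypes for each requested breed."""
    unknown = set(counts) - set(panel.breeds)
    if unknown:
        raise KeyError(f"unknown breed {sorted(unknown)[0]!r}")
    sample_ids: list[str] = []
    labels: dict[str, str] = {}
    blocks: list[np.ndarray] = []
    for breed in panel.breeds:
        n = counts.get(breed, 0)
        if n == 0:
            continue
        k = panel.breeds.index(breed)
        blocks.append(rng.binomial(2, panel.freqs[:, k], size=(n, panel.n_sites)).astype(float))
        for i in range(n):
            sid = f"{breed}_s{i + 1}"
            sample_ids.append(sid)
            labels[sid] = breed
    dosages = np.vstack(blocks) if blocks else np.empty((0, panel.n_sites))
    if missing_rate > 0:
        dosages[rng.random(dosages.shape) < missing_rate] = np.nan
    sites = panel.sites if panel.sites is not None else make_site_table(
        np.arange(1, panel.n_sites + 1), ids=panel.site_ids
    )
    return GenotypeMatrix(dosages, sample_ids, sites.copy()), BreedAssignment(labels)


def _tile_haplotype(
    genetic_pos: np.ndarray,
    q: np.ndarray,
    mean_block_morgans: float,
    rng: np.random.Generator,
) -> list[tuple[int, int, int]]:
    """Break the site range into exponential-length blocks with i.i.d. origins.

    Returns ``(start, end, origin)`` site-index segments; merging of
    adjacent same-origin blocks is deliberately not done so block counts
    reflect recombination events.
    """
    n = len(genetic_pos)
    length = genetic_pos[-1] - genetic_pos[0]
    # breakpoints from a Poisson process with rate 1/mean_block_morgans
    t = genetic_pos[0]
    breaks = []
    while True:
        t += rng.exponential(mean_block_morgans)
        if t >= genetic_pos[0] + length:
            break
        breaks.append(t)
    cut_idx = np.searchsorted(genetic_pos, breaks, side="left").tolist()
    bounds = [0] + [i for i in cut_idx if 0 < i < n] + [n]
    segments = []
    prev = 0
    for b in bounds[1:]:
        if b > prev:
            origin = int(rng.choice(len(q), p=q))
            segments.append((prev, b, origin))
            prev = b
    return segments


def sample_admixed_individual(
    panel: AlleleFreqPanel,
    q_true: np.ndarray,
    config: SimulationConfig,
    rng: np.random.Generator,
) -> tuple[np.ndarray, HaplotypeBlockMap]:
    """Simulate one admixed diploid with haplotype-block ancestry truth."""
    q = validate_simplex(np.asarray(q_true, dtype=float))
    if len(q) != panel.n_breeds:
        raise ValueError("q_true length does not match the breed panel")
    gpos = config.genetic_positions()
    if len(gpos) != panel.n_sites:
        raise ValueError("config site count does not match the frequency panel")
    q_norm = q / q.sum()
    haplotypes = []
    dosage = np.zeros(panel.n_sites)
    for _ in range(2):
        segs = _tile_haplotype(gpos, q_norm, config.block_length_morgans, rng)
        hap_alleles = np.empty(panel.n_sites)
        hap_map = []
        for start, end, origin in segs:
            f = panel.freqs[start:end, origin]
            hap_alleles[start:end] = (rng.random(end - start) < f).astype(float)
            hap_map.append((config.chrom, start, end, panel.breeds[origin]))
        haplotypes.append(hap_map)
        dosage += hap_alleles
    block_map = HaplotypeBlockMap(haplotypes, panel.n_sites, list(panel.breeds))
    if config.missing_base_rate > 0:
        dosage[rng.random(panel.n_sites) < config.missing_base_rate] = np.nan
    return dosage, block_map


def random_two_breed_scenario(
    breeds: list[str], rng: np.random.Generator
) -> pd.Series:
    """Pick two distinct breeds and a uniform random split between them."""
    if len(breeds) < 2:
        raise ValueError("need at least two breeds")
    i, j = rng.choice(len(breeds), size=2, replace=False)
    u = rng.uniform()
    q = pd.Series(0.0, index=list(breeds))
    q.iloc[int(i)] = u
    q.iloc[int(j)] = 1.0 - u
    return q


def simulate_admixed_cohort(
    panel: AlleleFreqPanel,
    n_queries: int,
    config: SimulationConfig,
    rng: np.random.Generator,
) -> tuple[GenotypeMatrix, pd.DataFrame, list[HaplotypeBlockMap]]:
    """Two-breed admixed queries with a truth table of proportions.

    Each query mixes two randomly chosen breeds in uniform random
    proportions; the truth table has one simplex row per query.
    """
    rows = np.empty((n_queries, panel.n_sites))
    truth = pd.DataFrame(
        0.0, index=[f"mix_{i + 1}" for i in range(n_queries)], columns=list(panel.breeds)
    )
    maps: list[HaplotypeBlockMap] = []
    for i in range(n_queries):
        q = random_two_breed_scenario(list(panel.breeds), rng)
        rows[i], bm = sample_admixed_individual(panel, q.to_numpy(), config, rng)
        truth.iloc[i] = q.to_numpy()
        maps.append(bm)
    sites = panel.sites if panel.sites is not None else make_site_table(
        np.arange(1, panel.n_sites + 1), ids=panel.site_ids
    )
    G = GenotypeMatrix(rows, list(truth.index), sites.copy())
    return G, truth, maps


def apply_depth_missingness(
    G: GenotypeMatrix,
    read_fraction: float,
    rng: np.random.Generator,
    full_depth: float = 2.5,
    rate: float = 1.0,
) -> GenotypeMatrix:
    """Emulate read downsampling as Poisson zero-coverage missingness.

    Each genotype is independently lost with probability
    ``exp(-rate * read_fraction * full_depth)``; existing missingness is
    preserved. ``full_depth`` defaults to 2.5x, a typical low-coverage
    query sample.
    """
    if not 0.0 <= read_fraction <= 1.0:
        raise ValueError("read_fraction must be in [0, 1]")
    p_miss = float(np.exp(-rate * read_fraction * full_depth))
    dosages = G.dosages.copy()
    dosages[rng.random(dosages.shape) < p_miss] = np.nan
    return GenotypeMatrix(dosages, list(G.samples), G.sites.copy())


def simulate_reference(
    config: SimulationConfig, rng: np.random.Generator | None = None
) -> tuple[AlleleFreqPanel, GenotypeMatrix, BreedAssignment]:
    """Frequency panel plus a purebred reference cohort in one call."""
    rng = config.rng() if rng is None else rng
    panel = draw_breed_freq_panel(config, rng)
    counts = dict(zip(config.breed_names(), config.per_breed_counts()))
    G, labels = sample_purebred_cohort(
        panel, counts, rng, missing_rate=config.missing_base_rate
    )
    return panel, G, labels
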