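"""Reference-construction filters: MAF, call rate, and windowed LD pruning.

The pruning step mirrors PLINK-style ``--indep-pairwise`` greedy pruning,
with one twist: the pair-eligibility window is constrained by BOTH a
variant-count width and a physical (kb) width simultaneously, which is
conservative and reduces to either convention when the other bound is
made loose.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .genotypes import GenotypeMatrix


@dataclass
class FilterStage:
    name: str
    params: dict
    sites_before: int
    sites_after: int


@dataclass
class FilterReport:
    """Ordered record of site counts through each filter stage."""

    stages: list[FilterStage] = field(default_factory=list)

    def add(self, name: str, params: dict, before: int, after: int) -> None:
        if after > before:
            raise ValueError("filter stages cannot add sites")
        if self.stages and before != self.stages[-1].sites_after:
            raise ValueError("stage input count does not chain from previous stage")
        self.stages.append(FilterStage(name, dict(params), before, after))

    def to_dict(self) -> dict:
        return {
            "stages": [
                {
                    "name": s.name,
                    "params": s.params,
                    "sites_before": s.sites_before,
                    "sites_after": s.sites_after,
                }
                for s in self.stages
            ]
        }


def site_maf(G: GenotypeMatrix) -> tuple[np.ndarray, np.ndarray]:
    """Per-site minor-allele frequency among called genotypes.

    Returns ``(maf, defined)``: sites with zero called genotypes are
    flagged undefined (``maf`` nan) rather than raising.
    """
    called = G.called
    n = called.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        alt = np.nan_to_num(G.dosages).sum(axis=0) / (2.0 * n)
    defined = n > 0
    maf = np.where(defined, np.minimum(alt, 1.0 - alt), np.nan)
    return maf, defined


def filter_sites(
    G: GenotypeMatrix,
    maf_min: float = 0.01,
    min_call_rate: float = 0.20,
    report: FilterReport | None = None,
) -> tuple[GenotypeMatrix, FilterReport]:
    """Keep sites with MAF >= ``maf_min`` and call rate >= ``min_call_rate``.

    Defaults follow the reference recipe (MAF 0.01, genotyping rate 20%,
    the latter read literally as a minimum call rate; pass
    ``min_call_rate=0.8`` for the max-20%-missing reading).
    """
    if not (0.0 <= maf_min <= 1.0 and 0.0 <= min_call_rate <= 1.0):
        raise ValueError("thresholds must be in [0, 1]")
    report = report or FilterReport()
    maf, defined = site_maf(G)
    call_rate = G.site_call_rate()
    keep = defined & (maf >= maf_min) & (call_rate >= min_call_rate)
    out = G.take_sites(np.flatnonzero(keep))
    report.add(
        "maf_call_rate",
        {"maf_min": maf_min, "min_call_rate": min_call_rate},
        G.n_sites,
        out.n_sites,
    )
    return out, report


def genotype_r2(g_i: np.ndarray, g_j: np.ndarray) -> float:
    """Squared Pearson correlation of two dosage vectors.

    Computed over samples called at both sites; returns 0 by convention
    when either site is constant over the shared samples or fewer than
    two shared samples exist.
    """
    g_i = np.asarray(g_i, dtype=float)
    g_j = np.asarray(g_j, dtype=float)
    shared = ~np.isnan(g_i) & ~np.isnan(g_j)
    if shared.sum() < 2:
        return 0.0
    x = g_i[shared]
    y = g_j[shared]
    vx = x.var()
    vy = y.var()
    if vx == 0.0 or vy == 0.0:
        return 0.0
    cov = ((x - x.mean()) * (y - y.mean())).mean()
    return float(cov * cov / (vx * vy))


def ld_prune(
    G: GenotypeMatrix,
    window_kb: float = 250.0,
    window_ct: int = 50,
    r2_max: float = 0.8,
    step_ct: int = 1,
    report: FilterReport | None = None,
) -> list[int]:
    """Greedy sliding-window LD pruning; returns kept site indices.

    Within each window of ``window_ct`` consecutive sites, a pair is
    eligible only if additionally within ``window_kb`` kilobases. While any
    eligible surviving pair exceeds ``r2_max`` (scanned in genomic order),
    the lower-MAF member is removed (tie: the later position). The window
    then advances by ``step_ct`` sites; removed sites are never
    reconsidered.
    """
    if window_ct < 2 or step_ct < 1:
        raise ValueError("window_ct must be >= 2 and step_ct >= 1")
    sites = G.sites
    chroms = sites["chrom"].to_numpy()
    pos = sites["pos"].to_numpy()
    for c in dict.fromkeys(chroms):
        p = pos[chroms == c]
        if np.any(np.diff(p) <= 0):
            raise ValueError("sites must be sorted by (chrom, pos)")

    maf, _ = site_maf(G)
    maf = np.nan_to_num(maf, nan=-1.0)
    alive = np.ones(G.n_sites, dtype=bool)
    max_bp = window_kb * 1000.0

    r2_cache: dict[tuple[int, int], float] = {}
    for c in dict.fromkeys(chroms):
        idx = np.flatnonzero(chroms == c)
        n = len(idx)
        start = 0
        while start < n:
            window = idx[start : start + window_ct]
            _prune_window(G, window, pos, maf, alive, max_bp, r2_max, r2_cache)
            if start + window_ct >= n:
                break
            start += step_ct

    kept = np.flatnonzero(alive).tolist()
    if report is not None:
        report.add(
            "ld_prune",
            {
                "window_kb": window_kb,
                "window_ct": window_ct,
                "r2_max": r2_max,
                "step_ct": step_ct,
            },
            G.n_sites,
            len(kept),
        )
    return kept


def _prune_window(
    G: GenotypeMatrix,
    window: np.ndarray,
    pos: np.ndarray,
    maf: np.ndarray,
    alive: np.ndarray,
    max_bp: float,
    r2_max: float,
    r2_cache: dict[tuple[int, int], float] | None = None,
) -> None:
    """Remove high-r2 pairs inside one window until none remain."""
    if r2_cache is None:
        r2_cache = {}
    while True:
        members = [i for i in window if alive[i]]
        victim = -1
        for a_i in range(len(members)):
            i = members[a_i]
            for b_i in range(a_i + 1, len(members)):
                j = members[b_i]
                if pos[j] - pos[i] > max_bp:
                    break
                r2 = r2_cache.get((i, j))
                if r2 is None:
                    r2 = genotype_r2(G.dosages[:, i], G.dosages[:, j])
                    r2_cache[(i, j)] = r2
                if r2 > r2_max:
                    if maf[i] < maf[j]:
                        victim = i
                    elif maf[j] < maf[i]:
                        victim = j
                    else:
                        victim = j  # tie: drop the later position
                    break
            if victim >= 0:
                break
        if victim < 0:
            return
        alive[victim] = False
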