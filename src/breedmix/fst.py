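"""Weir-Cockerham FST, breed-informative panel selection, stratified frequencies.

The differentiation estimator is the Weir & Cockerham (1984) analysis of
variance for r populations of unequal size: per-site components a (among
populations), b (among individuals within populations) and c (within
individuals), with theta-hat = a / (a + b + c). This is what PLINK's
``--fst`` reports and is the estimator used both globally (all breeds as
clusters) and in one-vs-rest mode (one breed against all others pooled) to
rank ancestry-informative markers.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genotypes import GenotypeMatrix

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# Breed labels / cluster files
# ---------------------------------------------------------------------------


@dataclass
class BreedAssignment:
    """Sample -> breed labelling, serializable as a 3-column cluster file.

    The cluster-file dialect is whitespace-delimited ``family_id sample_id
    breed``; a header row or ``#`` comments are tolerated on read.
    """

    labels: dict[str, str]
    families: dict[str, str] | None = None

    def __post_init__(self) -> None:
        self.labels = dict(self.labels)
        if not self.labels:
            raise ValueError("empty breed assignment")

    @property
    def samples(self) -> list[str]:
        return list(self.labels)

    def breeds(self) -> list[str]:
        """Breed labels in first-appearance order."""
        seen: dict[str, None] = {}
        for b in self.labels.values():
            seen.setdefault(b)
        return list(seen)

    def samples_of(self, breed: str) -> list[str]:
        return [s for s, b in self.labels.items() if b == breed]

    def one_vs_rest(self, breed: str) -> "BreedAssignment":
        """Derived two-cluster view: ``breed`` vs ``NOT_<breed>``.

        The original labels are untouched; this mirrors the modified
        cluster files used to rank markers for a single breed.
        """
        if breed not in self.labels.values():
            raise KeyError(f"breed {breed!r} has no samples")
        rest = f"NOT_{breed}"
        return BreedAssignment(
            {s: (breed if b == breed else rest) for s, b in self.labels.items()},
            families=self.families,
        )

    def label_vector(self, samples: list[str]) -> np.ndarray:
        missing = [s for s in samples if s not in self.labels]
        if missing:
            raise KeyError(f"{len(missing)} samples lack a breed label (e.g. {missing[0]!r})")
        return np.asarray([self.labels[s] for s in samples])

    # -- cluster-file io ------------------------------------------------

    def write_cluster_file(self, path) -> None:
        fams = self.families or {}
        with open(path, "w") as fh:
            for s, b in self.labels.items():
                fh.write(f"{fams.get(s, s)}\t{s}\t{b}\n")

    @classmethod
    def read_cluster_file(cls, path) -> "BreedAssignment":
        labels: dict[str, str] = {}
        families: dict[str, str] = {}
        first_row = True
        with open(path) as fh:
            for lineno, line in enumerate(fh):
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                parts = line.split()
                if len(parts) != 3:
                    raise ValueError(f"cluster file line {lineno + 1}: expected 3 columns")
                fid, iid, breed = parts
                if first_row:
                    first_row = False
                    if (fid.lower(), iid.lower()) in {
                        ("fid", "iid"),
                        ("family", "sample"),
                        ("family_id", "sample_id"),
                    }:
                        continue  # header row
                labels[iid] = breed
                families[iid] = fid
        return cls(labels, families=families)


# ---------------------------------------------------------------------------
# Per-site FST tables
# ---------------------------------------------------------------------------


@dataclass
class SiteFstTable:
    """Per-site Weir-Cockerham components and theta-hat for one cluster scheme.

    ``table`` columns: ``id, chrom, pos, a, b, c, fst, defined``. Sites where
    the estimator is undefined (fewer than two populations with data, a
    single individual on average, or a non-positive component sum) carry
    ``defined == False`` and ``fst == nan``.
    """

    table: pd.DataFrame = field(repr=False)
    scheme: str = "global"

    def __post_init__(self) -> None:
        required = {"id", "chrom", "pos", "a", "b", "c", "fst", "defined"}
        if not required <= set(self.table.columns):
            raise ValueError("FST table missing required columns")
        self.table = self.table.reset_index(drop=True)

    @property
    def fst(self) -> np.ndarray:
        return self.table["fst"].to_numpy()


def _pop_site_stats(G: GenotypeMatrix, labels: np.ndarray):
    """Per (population, site): called-count n, alt frequency p, het fraction h."""
    pops = list(dict.fromkeys(labels))
    called = G.called
    dos = np.nan_to_num(G.dosages)
    n = np.empty((len(pops), G.n_sites))
    p = np.empty_like(n)
    h = np.empty_like(n)
    for i, pop in enumerate(pops):
        rows = labels == pop
        c = called[rows]
        n[i] = c.sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            p[i] = (dos[rows] * c).sum(axis=0) / (2.0 * n[i])
            h[i] = ((G.dosages[rows] == 1.0) & c).sum(axis=0) / n[i]
    return pops, n, p, h


def wc_fst(G: GenotypeMatrix, labels: BreedAssignment, scheme: str | None = None) -> SiteFstTable:
    """Weir-Cockerham (1984) per-site FST across the labelled populations.

    Missing genotypes are excluded from their population's counts; a
    population with zero calls at a site drops out of that site's r.
    Negative estimates are reported, not clamped.
    """
    lab = labels.label_vector(G.samples)
    if len(set(lab)) < 2:
        raise ValueError("FST requires at least two populations")
    _, n, p, h = _pop_site_stats(G, lab)

    present = n > 0
    r = present.sum(axis=0).astype(float)
    n_sum = n.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        nbar = n_sum / r
        nc = (n_sum - (n**2).sum(axis=0) / n_sum) / (r - 1.0)
        pbar = np.where(n_sum > 0, (n * np.nan_to_num(p)).sum(axis=0) / n_sum, np.nan)
        s2 = ((n * (np.nan_to_num(p) - pbar) ** 2) * present).sum(axis=0) / ((r - 1.0) * nbar)
        hbar = (n * np.nan_to_num(h)).sum(axis=0) / n_sum

        inner = pbar * (1.0 - pbar) - (r - 1.0) / r * s2
        a = nbar / nc * (s2 - (inner - hbar / 4.0) / (nbar - 1.0))
        b = nbar / (nbar - 1.0) * (inner - (2.0 * nbar - 1.0) / (4.0 * nbar) * hbar)
        c = hbar / 2.0
        denom = a + b + c
        theta = a / denom

    defined = (r >= 2) & (nbar > 1.0) & np.isfinite(nc) & (nc > 0) & np.isfinite(denom) & (denom > 0)
    theta = np.where(defined, theta, np.nan)
    for comp in (a, b, c):
        comp[~defined] = np.nan

    table = pd.DataFrame(
        {
            "id": G.sites["id"],
            "chrom": G.sites["chrom"],
            "pos": G.sites["pos"],
            "a": a,
            "b": b,
            "c": c,
            "fst": theta,
            "defined": defined,
        }
    )
    return SiteFstTable(table, scheme=scheme or "global")


def one_vs_rest_tables(G: GenotypeMatrix, labels: BreedAssignment) -> dict[str, SiteFstTable]:
    """One table per breed: that breed vs all other breeds pooled."""
    breeds = labels.breeds()
    if len(breeds) < 2:
        raise ValueError("one-vs-rest needs at least two breeds")
    return {
        breed: wc_fst(G, labels.one_vs_rest(breed), scheme=f"{breed}_vs_rest")
        for breed in breeds
    }


# ---------------------------------------------------------------------------
# Panel selection
# ---------------------------------------------------------------------------


@dataclass
class PanelSelection:
    """Deduplicated marker panel with per-site provenance.

    ``site_ids`` is in genomic order; ``provenance`` maps each id to the
    rules that selected it (``top_k:<breed>`` and/or ``global``).
    """

    site_ids: list[str]
    provenance: dict[str, list[str]] = field(repr=False)

    def __post_init__(self) -> None:
        if len(set(self.site_ids)) != len(self.site_ids):
            raise ValueError("duplicate site ids in panel")
        orphans = [s for s in self.site_ids if not self.provenance.get(s)]
        if orphans:
            raise ValueError(f"{len(orphans)} panel sites lack provenance")

    def __len__(self) -> int:
        return len(self.site_ids)

    def write_site_list(self, path) -> None:
        with open(path, "w") as fh:
            for s in self.site_ids:
                fh.write(s + "\n")


def select_panel(
    per_breed_tables: dict[str, SiteFstTable],
    global_table: SiteFstTable | None,
    top_k: int = 10_000,
    global_threshold: float = 0.350,
) -> PanelSelection:
    """Union of each breed's top-K one-vs-rest sites with global high-FST sites.

    Ties at the top-K boundary break by genomic order (chrom, pos
    ascending); undefined FST values are never selected. Defaults follow
    the reference-panel recipe: top 10,000 per breed plus all sites with
    global FST above 0.350.
    """
    if top_k < 0:
        raise ValueError("top_k must be non-negative")
    if global_table is not None and not -1.0 <= global_threshold <= 1.0:
        raise ValueError("global_threshold outside [-1, 1]")

    provenance: dict[str, list[str]] = {}
    site_order: dict[str, int] | None = None

    for breed, tbl in per_breed_tables.items():
        df = tbl.table
        if site_order is None:
            ordered = df.sort_values(["chrom", "pos"], kind="stable")
            site_order = {s: i for i, s in enumerate(ordered["id"])}
        elif set(df["id"]) != set(site_order):
            raise ValueError("per-breed tables do not share a site universe")
        cand = df[df["defined"]].copy()
        cand["rank_order"] = cand["id"].map(site_order)
        cand = cand.sort_values(["fst", "rank_order"], ascending=[False, True], kind="stable")
        for sid in cand["id"].head(top_k):
            provenance.setdefault(sid, []).append(f"top_k:{breed}")

    if global_table is not None:
        df = global_table.table
        if site_order is None:
            ordered = df.sort_values(["chrom", "pos"], kind="stable")
            site_order = {s: i for i, s in enumerate(ordered["id"])}
        hits = df[df["defined"] & (df["fst"] > global_threshold)]
        for sid in hits["id"]:
            provenance.setdefault(sid, []).append("global")

    assert site_order is not None
    ids = sorted(provenance, key=site_order.__getitem__)
    return PanelSelection(ids, provenance)


# ---------------------------------------------------------------------------
# Stratified allele frequencies
# ---------------------------------------------------------------------------


@dataclass
class AlleleFreqPanel:
    """Sites x breeds allele-frequency matrix (the supervised reference P).

    All frequencies at a site refer to the same allele across breeds —
    ``oriented_to`` records which (``"alt"`` by default). One consistent
    orientation per site is what the linear model F-hat = P Q requires.
    """

    freqs: np.ndarray
    site_ids: list[str]
    breeds: list[str]
    oriented_to: str = "alt"
    ancestral: np.ndarray | None = None
    sites: pd.DataFrame | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.freqs = np.asarray(self.freqs, dtype=float)
        if self.freqs.shape != (len(self.site_ids), len(self.breeds)):
            raise ValueError("frequency matrix shape does not match ids/breeds")
        if np.any((self.freqs < 0) | (self.freqs > 1)):
            raise ValueError("allele frequencies outside [0, 1]")

    @property
    def n_sites(self) -> int:
        return self.freqs.shape[0]

    @property
    def n_breeds(self) -> int:
        return self.freqs.shape[1]

    def subset_site_ids(self, ids: list[str]) -> "AlleleFreqPanel":
        lookup = {s: i for i, s in enumerate(self.site_ids)}
        idx = [lookup[s] for s in ids]
        return AlleleFreqPanel(
            self.freqs[idx],
            [self.site_ids[i] for i in idx],
            list(self.breeds),
            oriented_to=self.oriented_to,
            ancestral=None if self.ancestral is None else self.ancestral[idx],
            sites=None if self.sites is None else self.sites.iloc[idx].reset_index(drop=True),
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.freqs, index=self.site_ids, columns=self.breeds)

    def write_tsv(self, path) -> None:
        df = self.to_frame()
        df.insert(0, "allele", self.oriented_to)
        df.to_csv(path, sep="\t", index_label="site_id", float_format="%.6f")

    @classmethod
    def read_tsv(cls, path) -> "AlleleFreqPanel":
        df = pd.read_csv(path, sep="\t", index_col="site_id")
        allele = df.pop("allele")
        oriented = str(allele.iloc[0]) if len(allele) else "alt"
        return cls(
            df.to_numpy(dtype=float),
            [str(s) for s in df.index],
            [str(c) for c in df.columns],
            oriented_to=oriented,
        )


def breed_allele_freqs(
    G: GenotypeMatrix,
    labels: BreedAssignment,
    panel: PanelSelection | None = None,
    on_empty: str = "impute",
) -> AlleleFreqPanel:
    """Alt-allele frequency per (panel site, breed) among called genotypes.

    A breed with zero calls at a site gets the pooled-cohort frequency
    imputed (logged) when ``on_empty="impute"``; ``on_empty="nan"`` leaves
    it missing instead.
    """
    if on_empty not in {"impute", "nan"}:
        raise ValueError("on_empty must be 'impute' or 'nan'")
    sub = G if panel is None else G.subset_site_ids(panel.site_ids)
    lab = labels.label_vector(sub.samples)
    breeds = labels.breeds()
    empty = [b for b in breeds if not np.any(lab == b)]
    if empty:
        raise ValueError(f"breed {empty[0]!r} has no samples in the cohort")

    called = sub.called
    dos = np.nan_to_num(sub.dosages)
    pooled_n = called.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        pooled = (dos * called).sum(axis=0) / (2.0 * pooled_n)

    freqs = np.empty((sub.n_sites, len(breeds)))
    n_imputed = 0
    for j, breed in enumerate(breeds):
        rows = lab == breed
        n = called[rows].sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            f = (dos[rows] * called[rows]).sum(axis=0) / (2.0 * n)
        hole = n == 0
        if hole.any():
            n_imputed += int(hole.sum())
            f = np.where(hole, pooled if on_empty == "impute" else np.nan, f)
        freqs[:, j] = f
    if n_imputed:
        logger.warning(
            "%d (site, breed) cells had zero calls; %s",
            n_imputed,
            "imputed pooled frequency" if on_empty == "impute" else "left as nan",
        )
    if on_empty == "impute" and np.isnan(freqs).any():
        # pooled frequency itself undefined (no calls at all): fall back to 0.5
        freqs = np.where(np.isnan(freqs), 0.5, freqs)

    return AlleleFreqPanel(
        freqs,
        sub.site_ids(),
        breeds,
        oriented_to="alt",
        sites=sub.sites.copy(),
    )
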