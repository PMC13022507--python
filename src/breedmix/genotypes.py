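"""Diploid genotype container shared by every analysis stage.

Genotypes are stored as alternate-allele dosages (0, 1, 2) in a dense
float matrix with ``numpy.nan`` marking missing calls. Site metadata
(chromosome, 1-based position, id, ref/alt alleles) travels alongside the
matrix; site identity throughout the package is ``(chrom, pos, ref, alt)``,
with the string id used only in panel lists.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

SITE_COLUMNS = ("chrom", "pos", "id", "ref", "alt")


@dataclass
class GenotypeMatrix:
    """Samples x sites dosage matrix with missingness.

    Parameters
    ----------
    dosages
        ``(n_samples, n_sites)`` float array with entries in {0, 1, 2}
        or ``nan`` for missing.
    samples
        Sample identifiers, one per row.
    sites
        Per-site metadata with columns ``chrom, pos, id, ref, alt``;
        positions are 1-based and strictly increasing within a chromosome.
    """

    dosages: np.ndarray
    samples: list[str]
    sites: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages, dtype=float)
        if self.dosages.ndim != 2:
            raise ValueError("dosages must be 2-D (samples x sites)")
        self.samples = list(self.samples)
        if len(self.samples) != self.dosages.shape[0]:
            raise ValueError("sample ids do not match matrix rows")
        if len(set(self.samples)) != len(self.samples):
            raise ValueError("duplicate sample ids")
        missing_cols = set(SITE_COLUMNS) - set(self.sites.columns)
        if missing_cols:
            raise ValueError(f"site metadata lacks columns {sorted(missing_cols)}")
        if len(self.sites) != self.dosages.shape[1]:
            raise ValueError("site metadata does not match matrix columns")
        self.sites = self.sites.reset_index(drop=True)
        vals = self.dosages[~np.isnan(self.dosages)]
        if vals.size and not np.isin(vals, (0.0, 1.0, 2.0)).all():
            raise ValueError("dosages must be 0, 1, 2 or nan")
        for _, grp in self.sites.groupby("chrom", sort=False):
            pos = grp["pos"].to_numpy()
            if np.any(np.diff(pos) <= 0):
                raise ValueError("positions must be strictly increasing per chromosome")

    # -- basic views ---------------------------------------------------

    @property
    def n_samples(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_sites(self) -> int:
        return self.dosages.shape[1]

    @property
    def called(self) -> np.ndarray:
        """Boolean mask of non-missing genotypes."""
        return ~np.isnan(self.dosages)

    def site_call_rate(self) -> np.ndarray:
        """Fraction of samples called at each site."""
        return self.called.mean(axis=0)

    def site_ids(self) -> list[str]:
        return self.sites["id"].tolist()

    # -- subsetting ----------------------------------------------------

    def take_sites(self, index: np.ndarray | list[int]) -> "GenotypeMatrix":
        index = np.asarray(index, dtype=int)
        return GenotypeMatrix(
            self.dosages[:, index],
            self.samples,
            self.sites.iloc[index].reset_index(drop=True),
        )

    def take_samples(self, index: np.ndarray | list[int]) -> "GenotypeMatrix":
        index = np.asarray(index, dtype=int)
        return GenotypeMatrix(
            self.dosages[index, :],
            [self.samples[i] for i in index],
            self.sites.copy(),
        )

    def subset_samples(self, ids: list[str]) -> "GenotypeMatrix":
        lookup = {s: i for i, s in enumerate(self.samples)}
        try:
            index = [lookup[s] for s in ids]
        except KeyError as exc:  # pragma: no cover - defensive
            raise KeyError(f"unknown sample id {exc.args[0]!r}") from exc
        return self.take_samples(index)

    def subset_site_ids(self, ids: list[str]) -> "GenotypeMatrix":
        lookup = {s: i for i, s in enumerate(self.sites["id"])}
        missing = [s for s in ids if s not in lookup]
        if missing:
            raise KeyError(f"{len(missing)} requested site ids absent (e.g. {missing[0]!r})")
        index = sorted(lookup[s] for s in ids)
        return self.take_sites(index)


def make_site_table(
    pos: np.ndarray,
    chrom: str = "1",
    ids: list[str] | None = None,
    ref: str = "A",
    alt: str = "G",
) -> pd.DataFrame:
    """Build a minimal site-metadata table for synthetic cohorts."""
    pos = np.asarray(pos, dtype=int)
    if ids is None:
        ids = [f"{chrom}:{p}:{ref}:{alt}" for p in pos]
    return pd.DataFrame(
        {
            "chrom": chrom,
            "pos": pos,
            "id": ids,
            "ref": ref,
            "alt": alt,
        }
    )
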