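"""Cohort-structure diagnostics: GRM, Hamming distances, NJ trees, PCA,
and the sample-to-breed-centroid score used to compare marker panels.

Two relationship products are provided with explicit metric tags, since
"genetic relationship / IBS matrix" is used loosely in practice: the
covariance-standardized relationship matrix (PLINK ``--make-rel`` style)
and the allele-count Hamming distance (``--distance square`` style).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from skbio import DistanceMatrix as SkbioDistanceMatrix
from skbio.tree import TreeNode, nj

from .fst import BreedAssignment
from .genotypes import GenotypeMatrix


@dataclass
class DistanceMatrix:
    """Square sample x sample matrix with a metric tag."""

    values: pd.DataFrame
    metric: str

    def __post_init__(self) -> None:
        v = self.values.to_numpy()
        if v.shape[0] != v.shape[1]:
            raise ValueError("matrix must be square")
        if not np.all(np.isfinite(v)):
            raise ValueError("matrix entries must be finite")
        if not np.allclose(v, v.T, atol=1e-9):
            raise ValueError("matrix must be symmetric")

    @property
    def samples(self) -> list[str]:
        return list(self.values.index)

    def write_tsv(self, path) -> None:
        self.values.to_csv(path, sep="\t", index_label="sample")


def standardized_grm(G: GenotypeMatrix) -> DistanceMatrix:
    """Covariance-standardized genetic relationship matrix.

    R_ij = (1/M') sum_m (g_im - 2 f_m)(g_jm - 2 f_m) / (2 f_m (1 - f_m)),
    with f_m the cohort alt frequency; monomorphic sites and pairwise
    missing genotypes are excluded, M' counting the shared informative
    sites per pair.
    """
    if G.n_samples < 2:
        raise ValueError("need at least two samples")
    called = G.called
    n = called.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        f = np.nan_to_num(G.dosages).sum(axis=0) / (2.0 * n)
    poly = (n > 0) & (f > 0.0) & (f < 1.0)
    if not poly.any():
        raise ValueError("no polymorphic sites")
    f = f[poly]
    Z = (G.dosages[:, poly] - 2.0 * f) / np.sqrt(2.0 * f * (1.0 - f))
    W = called[:, poly].astype(float)
    Z0 = np.nan_to_num(Z)
    num = Z0 @ Z0.T
    counts = W @ W.T
    with np.errstate(invalid="ignore", divide="ignore"):
        R = np.where(counts > 0, num / counts, 0.0)
    df = pd.DataFrame(R, index=G.samples, columns=G.samples)
    return DistanceMatrix(df, metric="standardized-relationship")


def hamming_distance_matrix(G: GenotypeMatrix) -> DistanceMatrix:
    """Allele-count Hamming distance: D_ij = sum_m |g_im - g_jm|.

    Summed over sites called in both samples (pairwise-complete).
    """
    if G.n_samples < 2:
        raise ValueError("need at least two samples")
    called = G.called
    ind = [((G.dosages == k) & called).astype(float) for k in (0.0, 1.0, 2.0)]
    D = np.zeros((G.n_samples, G.n_samples))
    for a in range(3):
        for b in range(3):
            if a != b:
                D += abs(a - b) * (ind[a] @ ind[b].T)
    df = pd.DataFrame(D, index=G.samples, columns=G.samples)
    return DistanceMatrix(df, metric="allele-count-hamming")


def neighbor_joining(D: DistanceMatrix) -> TreeNode:
    """Saitou-Nei neighbor joining on a distance matrix.

    Returns an unrooted tree (scikit-bio ``TreeNode``; serialize with
    ``str(tree)`` or ``tree.write``). Negative branch lengths, which NJ
    can produce on non-additive input, are reported unclamped.
    """
    samples = D.samples
    if len(samples) < 3:
        raise ValueError("neighbor joining needs at least three taxa")
    vals = D.values.to_numpy()
    if np.any(vals < 0):
        raise ValueError("distances must be non-negative")
    vals = (vals + vals.T) / 2.0  # exact symmetry for float-rounded input
    np.fill_diagonal(vals, 0.0)
    dm = SkbioDistanceMatrix(vals, ids=samples)
    tree = nj(dm)
    return tree


def tree_path_lengths(tree: TreeNode, ids: list[str]) -> np.ndarray:
    """Leaf-to-leaf patristic distance matrix in the order of ``ids``."""
    dm = tree.tip_tip_distances(endpoints=list(ids))
    frame = pd.DataFrame(dm.data, index=dm.ids, columns=dm.ids)
    return frame.loc[ids, ids].to_numpy()


def pca_embedding(G: GenotypeMatrix, n_components: int = 2) -> pd.DataFrame:
    """PCA of the site-standardized genotype matrix.

    Sites are mean-centered and scaled by sqrt(2 f (1 - f)); missing
    genotypes are imputed to the site mean (zero after centering).
    Components are ordered by explained variance; column names PC1, PC2...
    """
    if G.n_samples < 2:
        raise ValueError("need at least two samples")
    max_comp = min(G.n_samples - 1, G.n_sites)
    if n_components > max_comp:
        raise ValueError(f"n_components must be <= {max_comp}")
    called = G.called
    n = called.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        f = np.nan_to_num(G.dosages).sum(axis=0) / (2.0 * n)
    poly = (n > 0) & (f > 0.0) & (f < 1.0)
    if not poly.any():
        raise ValueError("no polymorphic sites")
    f = f[poly]
    Z = (G.dosages[:, poly] - 2.0 * f) / np.sqrt(2.0 * f * (1.0 - f))
    Z = np.nan_to_num(Z)  # mean imputation: centered missing -> 0
    Z = Z - Z.mean(axis=0)  # re-center in case of missingness
    U, s, _ = np.linalg.svd(Z, full_matrices=False)
    coords = U[:, :n_components] * s[:n_components]
    return pd.DataFrame(
        coords,
        index=pd.Index(G.samples, name="sample"),
        columns=[f"PC{i + 1}" for i in range(n_components)],
    )


@dataclass
class CentroidScore:
    """Distances from each sample to its own-breed centroid.

    The global mean is the sample-weighted mean of per-breed means, i.e.
    the plain mean over samples.
    """

    per_sample: pd.Series
    per_breed: pd.Series = field(repr=False)
    global_mean: float = 0.0


def centroid_distance_score(
    coords: pd.DataFrame, labels: BreedAssignment
) -> CentroidScore:
    """Euclidean distance of every sample to its breed's mean coordinate.

    A lower global mean means the embedding packs same-breed samples more
    tightly — the criterion used to compare candidate marker panels.
    Singleton breeds score 0 (a sample is its own centroid).
    """
    lab = labels.label_vector(list(coords.index))
    dists = pd.Series(0.0, index=coords.index)
    per_breed = {}
    for breed in labels.breeds():
        rows = coords.index[lab == breed]
        if len(rows) == 0:
            raise ValueError(f"breed {breed!r} has no samples in the embedding")
        pts = coords.loc[rows].to_numpy()
        centroid = pts.mean(axis=0)
        d = np.linalg.norm(pts - centroid, axis=1)
        dists.loc[rows] = d
        per_breed[breed] = float(d.mean())
    return CentroidScore(
        per_sample=dists,
        per_breed=pd.Series(per_breed),
        global_mean=float(dists.mean()),
    )
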