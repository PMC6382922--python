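"""Rarefaction, alpha/beta diversity, principal coordinates, and Mantel tests.

Metric conventions
------------------
* ``observed_otus`` — number of features with count >= 1.
* ``faith_pd`` — total branch length spanned by the observed features.
* ``jaccard`` — presence/absence dissimilarity ``1 - |A∩B| / |A∪B|``.
* ``bray_curtis`` — ``Σ|x_i - y_i| / Σ(x_i + y_i)`` on counts.
* ``unweighted_unifrac`` — branch length unique to either sample over branch
  length covered by either.
* ``weighted_unifrac`` — unnormalised ``Σ_b l_b |p_b(x) - p_b(y)|`` over
  branches (abundance-weighted branch flow); a flag divides by the total
  flow for the normalised variant.

Distance computations delegate to scikit-bio / scipy; this module fixes the
conventions and the sample bookkeeping around them.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.spatial.distance as ssd
import skbio.diversity
from skbio import DistanceMatrix, TreeNode
from skbio.stats.distance import mantel as _skbio_mantel
from skbio.stats.ordination import pcoa as _skbio_pcoa
from sklearn.base import BaseEstimator

from .core_io import FeatureTable

__all__ = [
    "ALPHA_METRICS",
    "BETA_METRICS",
    "OrdinationResult",
    "PrincipalCoordinates",
    "rarefy",
    "alpha_diversity",
    "beta_diversity",
    "pcoa",
    "mantel",
]

ALPHA_METRICS = ("observed_otus", "faith_pd")
BETA_METRICS = ("jaccard", "bray_curtis", "unweighted_unifrac", "weighted_unifrac")
_PHYLO_METRICS = ("faith_pd", "unweighted_unifrac", "weighted_unifrac")


def _check_tree_covers(tree: TreeNode, feature_ids) -> None:
    tips = {t.name for t in tree.tips()}
    missing = [f for f in feature_ids if f not in tips]
    if missing:
        raise ValueError(f"feature(s) missing from tree: {missing[:5]}")


def rarefy(table: FeatureTable, depth: int, seed: int) -> FeatureTable:
    """Subsample each sample to exactly ``depth`` reads without replacement.

    Samples whose total count is below ``depth`` are excluded from the
    result (the standard even-depth rule).  One draw per sample, all driven
    by ``seed``; a multivariate hypergeometric draw per sample is exactly
    subsampling without replacement.
    """
    if depth < 1:
        raise ValueError("depth must be >= 1")
    rng = np.random.default_rng(seed)
    totals = table.depths()
    keep = [s for s in table.sample_ids if totals[s] >= depth]
    if not keep:
        raise ValueError(f"no sample reaches rarefaction depth {depth}")
    out = np.empty((len(keep), table.n_features), np.int64)
    data = table.data
    for i, s in enumerate(keep):
        row = data.loc[s].to_numpy()
        if row.sum() == depth:
            out[i] = row
        else:
            out[i] = rng.multivariate_hypergeometric(row, depth)
    return FeatureTable(pd.DataFrame(out, index=keep, columns=table.feature_ids))


def alpha_diversity(
    table: FeatureTable, metric: str, tree: TreeNode | None = None
) -> pd.Series:
    """Per-sample richness: ``observed_otus`` or ``faith_pd``."""
    if metric not in ALPHA_METRICS:
        raise ValueError(f"metric must be one of {ALPHA_METRICS}")
    if metric == "faith_pd":
        if tree is None:
            raise ValueError("faith_pd requires a tree")
        _check_tree_covers(tree, table.feature_ids)
        vals = skbio.diversity.alpha_diversity(
            "faith_pd",
            table.counts,
            ids=table.sample_ids,
            taxa=table.feature_ids,
            tree=tree,
        )
    else:
        vals = pd.Series(
            (table.counts > 0).sum(axis=1).astype(float), index=table.sample_ids
        )
    vals.name = metric
    return vals


def beta_diversity(
    table: FeatureTable,
    metric: str,
    tree: TreeNode | None = None,
    normalized_weighted_unifrac: bool = False,
) -> DistanceMatrix:
    """All-pairs sample dissimilarity under one of the four study metrics."""
    if metric not in BETA_METRICS:
        raise ValueError(f"metric must be one of {BETA_METRICS}")
    ids = table.sample_ids
    counts = table.counts
    if metric == "jaccard":
        condensed = ssd.pdist(counts > 0, metric="jaccard")
        return DistanceMatrix(ssd.squareform(condensed), ids=ids)
    if metric == "bray_curtis":
        condensed = ssd.pdist(counts.astype(float), metric="braycurtis")
        return DistanceMatrix(ssd.squareform(condensed), ids=ids)
    if tree is None:
        raise ValueError(f"{metric} requires a tree")
    _check_tree_covers(tree, table.feature_ids)
    kwargs = {}
    if metric == "weighted_unifrac":
        kwargs["normalized"] = normalized_weighted_unifrac
    return skbio.diversity.beta_diversity(
        metric, counts, ids=ids, taxa=table.feature_ids, tree=tree, **kwargs
    )


@dataclass(frozen=True)
class OrdinationResult:
    """Principal-coordinate embedding of a distance matrix.

    ``coordinates`` columns are PC1, PC2, ... ordered by non-increasing
    eigenvalue; ``proportion_explained`` uses the sum of positive
    eigenvalues as denominator, and negative eigenvalues are retained in
    ``eigenvalues`` for diagnostics.
    """

    coordinates: pd.DataFrame
    eigenvalues: np.ndarray
    proportion_explained: np.ndarray

    @property
    def sample_ids(self) -> list[str]:
        return list(self.coordinates.index)

    def pc1(self) -> pd.Series:
        return self.coordinates["PC1"]


class PrincipalCoordinates(BaseEstimator):
    """Classical multidimensional scaling (PCoA) of a distance matrix.

    Eigendecomposition of the double-centred squared-distance matrix
    ``-1/2 J D^2 J``; coordinates are eigenvectors scaled by the square root
    of their (positive) eigenvalues.

    Attributes
    ----------
    coordinates_ : pandas.DataFrame
        Sample coordinates on PC axes.
    eigenvalues_ : ndarray
        All eigenvalues, sorted non-increasing (negatives retained).
    proportion_explained_ : ndarray
        Share of the positive-eigenvalue total, per axis.
    """

    def fit(self, d: DistanceMatrix) -> "PrincipalCoordinates":
        if not isinstance(d, DistanceMatrix):
            d = DistanceMatrix(d)  # validates symmetry / zero diagonal
        import warnings

        with warnings.catch_warnings():
            warnings.filterwarnings("ignore", message=".*all dimensions.*")
            # degenerate all-zero matrices divide 0/0 inside skbio; the
            # proportions are recomputed below either way
            warnings.filterwarnings("ignore", message=".*invalid value.*")
            res = _skbio_pcoa(d, method="eigh", warn_neg_eigval=False)
        eig = res.eigvals.to_numpy()
        order = np.argsort(-eig)
        eig = eig[order]
        coords = res.samples.to_numpy()[:, order]
        pos = eig[eig > 0].sum()
        prop = np.where(eig > 0, eig, 0.0) / pos if pos > 0 else np.zeros_like(eig)
        cols = [f"PC{i + 1}" for i in range(coords.shape[1])]
        self.coordinates_ = pd.DataFrame(coords, index=list(d.ids), columns=cols)
        self.eigenvalues_ = eig
        self.proportion_explained_ = prop
        return self

    def fit_transform(self, d: DistanceMatrix) -> np.ndarray:
        return self.fit(d).coordinates_.to_numpy()

    def result(self) -> OrdinationResult:
        return OrdinationResult(
            self.coordinates_, self.eigenvalues_, self.proportion_explained_
        )


def pcoa(d: DistanceMatrix) -> OrdinationResult:
    """Functional wrapper over :class:`PrincipalCoordinates`."""
    return PrincipalCoordinates().fit(d).result()


def mantel(
    d1: DistanceMatrix,
    d2: DistanceMatrix,
    method: str = "spearman",
    n_perm: int = 999,
    seed: int | None = None,
) -> tuple[float, float]:
    """Mantel test between two distance matrices on the same samples.

    Rank (or product-moment) correlation of the lower triangles; two-sided
    permutation p-value with the ``(b + 1) / (n_perm + 1)`` pseudo-count
    convention, permuting sample labels jointly in one matrix.
    """
    if set(d1.ids) != set(d2.ids):
        raise ValueError("distance matrices must cover the same samples")
    if len(d1.ids) < 3:
        raise ValueError("mantel test needs at least 3 samples")
    rho, p, _ = _skbio_mantel(
        d1, d2, method=method, permutations=n_perm, alternative="two-sided",
        seed=seed,
    )
    return float(rho), float(p)


def distance_matrix_to_tsv(d: DistanceMatrix, path) -> None:
    df = d.to_data_frame()
    df.index.name = "#sample_id"
    df.to_csv(path, sep="\t", lineterminator="\n")


def ordination_to_tsv(res: OrdinationResult, path) -> None:
    with open(path, "w") as fh:
        fh.write("#eigenvalues\t" + "\t".join(f"{v:.10g}" for v in res.eigenvalues) + "\n")
        fh.write(
            "#proportion_explained\t"
            + "\t".join(f"{v:.10g}" for v in res.proportion_explained)
            + "\n"
        )
        res.coordinates.round(10).to_csv(fh, sep="\t", lineterminator="\n")
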