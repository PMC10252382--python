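"""Microbiome-metabolome congruence: ordination and the Mantel test.

Community composition is CLR-transformed for PCA or turned into Bray-Curtis
dissimilarities for PCoA; metabolite profiles (log2, scaled) are ordinated by
PCA and compared to the community geometry with a one-sided permutation
Mantel test.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.decomposition import PCA

from .metabolites import MetaboliteTable, preprocess

__all__ = [
    "MantelResult",
    "CLRTransformer",
    "clr_transform",
    "bray_curtis",
    "pcoa",
    "pca_metabolites",
    "mantel",
    "metabolite_distance",
]


def _check_distance_matrix(d: pd.DataFrame, name: str) -> pd.DataFrame:
    values = d.values.astype(float)
    if values.shape[0] != values.shape[1]:
        raise ValueError(f"{name}: distance matrix must be square")
    if not np.allclose(values, values.T, atol=1e-12):
        raise ValueError(f"{name}: distance matrix must be symmetric")
    if np.any(np.diag(values) != 0):
        raise ValueError(f"{name}: diagonal must be exactly 0")
    if np.any(values < 0):
        raise ValueError(f"{name}: distances must be non-negative")
    return d


def clr_transform(composition: pd.DataFrame) -> pd.DataFrame:
    """Centered log-ratio transform of a compositional table.

    Zeros are replaced by half the smallest nonzero value in the matrix;
    each row is then log-transformed (natural log) and centered to mean 0.

    Raises
    ------
    ValueError
        If any row is all zero (naming the sample) or any value is negative.
    """
    x = composition.values.astype(float)
    if np.any(x < 0):
        raise ValueError("compositions must be non-negative")
    zero_rows = composition.index[(x.sum(axis=1) == 0)]
    if len(zero_rows):
        raise ValueError(f"all-zero sample(s): {list(zero_rows)}")
    nonzero = x[x > 0]
    if np.any(x == 0):
        x = np.where(x == 0, nonzero.min() / 2.0, x)
    logs = np.log(x)
    clr = logs - logs.mean(axis=1, keepdims=True)
    return pd.DataFrame(clr, index=composition.index, columns=composition.columns)


class CLRTransformer(BaseEstimator, TransformerMixin):
    """sklearn-composable CLR transform (stateless; pseudocount per call)."""

    def fit(self, X, y=None):
        return self

    def transform(self, X) -> pd.DataFrame:
        return clr_transform(pd.DataFrame(X))


def bray_curtis(abundances: pd.DataFrame) -> pd.DataFrame:
    """Bray-Curtis dissimilarity matrix between sample rows.

    ``d(x, y) = 1 - 2 * sum(min(x_i, y_i)) / (sum x + sum y)``; bounded in
    [0, 1] and invariant to joint rescaling of both samples.
    """
    x = abundances.values.astype(float)
    if np.any(x < 0):
        raise ValueError("abundances must be non-negative")
    zero_rows = abundances.index[x.sum(axis=1) == 0]
    if len(zero_rows):
        raise ValueError(f"all-zero sample(s): {list(zero_rows)}")
    d = squareform(pdist(x, metric="braycurtis"))
    return pd.DataFrame(d, index=abundances.index, columns=abundances.index)


@dataclass
class PCoAResult:
    samples: pd.DataFrame  # coordinates, one column per retained axis
    eigenvalues: np.ndarray  # positive eigenvalues, descending
    proportion_explained: np.ndarray


def pcoa(d: pd.DataFrame) -> PCoAResult:
    """Classical (metric) multidimensional scaling of a distance matrix.

    Double-centers ``-d**2 / 2``, keeps the axes with positive eigenvalues,
    and reports variance explained over the positive spectrum only.
    """
    d = _check_distance_matrix(d, "pcoa input")
    D2 = d.values.astype(float) ** 2
    n = D2.shape[0]
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ D2 @ J
    eigval, eigvec = np.linalg.eigh(B)
    order = np.argsort(eigval)[::-1]
    eigval, eigvec = eigval[order], eigvec[:, order]
    pos = eigval > max(1e-10 * abs(eigval[0]), 1e-12) if eigval[0] > 0 else eigval > 0
    eigval, eigvec = eigval[pos], eigvec[:, pos]
    coords = eigvec * np.sqrt(eigval)
    frame = pd.DataFrame(
        coords,
        index=d.index,
        columns=[f"PCo{i + 1}" for i in range(coords.shape[1])],
    )
    return PCoAResult(frame, eigval, eigval / eigval.sum())


@dataclass
class MetabolitePCAResult:
    scores: pd.DataFrame
    loadings: pd.DataFrame
    proportion_explained: np.ndarray
    top_metabolites: list[str]


def pca_metabolites(
    table: MetaboliteTable, n_components: int | None = None, n_top: int = 20
) -> MetabolitePCAResult:
    """PCA of samples on the preprocessed, unit-variance-scaled metabolites.

    Constant metabolite columns are dropped with a warning.  Reports scores,
    loadings, and the ``n_top`` metabolites with the largest loading
    magnitude across the first two axes.
    """
    table = preprocess(table)
    x = table.intensities
    constant = x.columns[x.std(axis=0) == 0]
    if len(constant):
        warnings.warn(
            f"dropping {len(constant)} constant metabolite(s): {list(constant[:5])}",
            stacklevel=2,
        )
        x = x.drop(columns=constant)
    z = (x - x.mean(axis=0)) / x.std(axis=0, ddof=0)
    k = n_components or min(z.shape[0] - 1, z.shape[1], 10)
    model = PCA(n_components=k, svd_solver="full")
    scores = model.fit_transform(z.values)
    axes = [f"PC{i + 1}" for i in range(model.n_components_)]
    loadings = pd.DataFrame(model.components_.T, index=z.columns, columns=axes)
    mag = np.sqrt((loadings.iloc[:, : min(2, loadings.shape[1])] ** 2).sum(axis=1))
    top = list(mag.sort_values(ascending=False).index[:n_top])
    return MetabolitePCAResult(
        pd.DataFrame(scores, index=z.index, columns=axes),
        loadings,
        model.explained_variance_ratio_,
        top,
    )


def metabolite_distance(table: MetaboliteTable) -> pd.DataFrame:
    """Euclidean distances between samples on the preprocessed, scaled table."""
    table = preprocess(table)
    x = table.intensities
    keep = x.columns[x.std(axis=0) > 0]
    z = (x[keep] - x[keep].mean(axis=0)) / x[keep].std(axis=0, ddof=0)
    d = squareform(pdist(z.values, metric="euclidean"))
    return pd.DataFrame(d, index=x.index, columns=x.index)


@dataclass
class MantelResult:
    r: float
    p_value: float
    n_permutations: int
    seed: int | None


def mantel(
    d1: pd.DataFrame,
    d2: pd.DataFrame,
    n_permutations: int = 9999,
    seed: int | None = None,
) -> MantelResult:
    """One-sided (greater) permutation Mantel test between distance matrices.

    r is the Pearson correlation of upper-triangle entries; the null is
    built by simultaneously permuting the rows and columns of ``d2``.  The
    add-one estimate ``p = (1 + #{r_perm >= r_obs}) / (1 + n_permutations)``
    keeps p off zero, so the smallest attainable p at 9999 permutations is
    1/10000.  The identity permutation is not among the draws.

    Raises
    ------
    ValueError
        If the two matrices do not share the same sample labels (the
        difference is listed).
    """
    d1 = _check_distance_matrix(d1, "d1")
    d2 = _check_distance_matrix(d2, "d2")
    if set(d1.index) != set(d2.index):
        only1 = sorted(set(d1.index) - set(d2.index))
        only2 = sorted(set(d2.index) - set(d1.index))
        raise ValueError(
            f"label mismatch: only in d1: {only1}; only in d2: {only2}"
        )
    d2 = d2.loc[d1.index, d1.index]
    n = d1.shape[0]
    if n < 4:
        raise ValueError("Mantel test needs >= 4 samples")
    iu = np.triu_indices(n, k=1)
    v1 = d1.values[iu]
    m2 = d2.values

    def corr(v2: np.ndarray) -> float:
        return float(np.corrcoef(v1, v2)[0, 1])

    r_obs = corr(m2[iu])
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_permutations):
        perm = rng.permutation(n)
        count += corr(m2[np.ix_(perm, perm)][iu]) >= r_obs
    p = (1 + count) / (1 + n_permutations)
    return MantelResult(r=r_obs, p_value=p, n_permutations=n_permutations, seed=seed)
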