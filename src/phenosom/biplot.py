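"""PCA biplot of phenotypic similarity and the component dendrogram.

The encoded feature matrix (standardized numerics plus one-hot indicator
columns, all rescaled to unit variance) is decomposed by eigenanalysis of
its correlation matrix.  Variable loadings are scaled so each equals the
correlation between its feature and the principal component; Cos2 (squared
loading, the squared coordinate) measures how well a feature is represented
by each PC.  In the PC1 x PC2 biplot, arrow lengths are bounded by 1 and the
cosine of the full-space angle between two variables' loading vectors equals
their sample correlation.

Complementing the biplot, :func:`component_similarity` clusters the features
themselves by average-linkage AHC on the Spearman correlation distance
(1 - rho), the rank-based analogue shown atop co-expression heat maps.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import linkage
from scipy.spatial.distance import squareform
from scipy.stats import spearmanr

from .errors import DegenerateError, InputError
from .features import EncodedMatrix


@dataclass
class BiplotResult:
    eigenvalues: np.ndarray            # descending, >= 0
    variance_explained: np.ndarray     # percent per PC, sums to 100
    cumulative: np.ndarray             # cumulative percent
    scores: np.ndarray                 # (n_samples, n_PCs)
    loadings: np.ndarray               # (n_features, n_PCs), = correlations
    cos2: np.ndarray                   # squared loadings
    feature_names: list[str]

    @property
    def n_pcs(self) -> int:
        return len(self.eigenvalues)

    def variance_table(self) -> pd.DataFrame:
        return pd.DataFrame({
            "PC": [f"PC{i + 1}" for i in range(self.n_pcs)],
            "eigenvalue": self.eigenvalues,
            "variance_percent": self.variance_explained,
            "cumulative_percent": self.cumulative,
        })

    def loadings_table(self) -> pd.DataFrame:
        pcs = [f"PC{i + 1}" for i in range(self.n_pcs)]
        load = pd.DataFrame(self.loadings, index=self.feature_names,
                            columns=[f"loading_{p}" for p in pcs])
        c2 = pd.DataFrame(self.cos2, index=self.feature_names,
                          columns=[f"cos2_{p}" for p in pcs])
        out = pd.concat([load, c2], axis=1)
        out.index.name = "feature"
        return out.reset_index()


def _standardized(values: np.ndarray, feature_names) -> np.ndarray:
    X = np.asarray(values, dtype=float)
    sd = X.std(axis=0, ddof=1)
    bad = np.flatnonzero(~(sd > 0))
    if bad.size:
        raise DegenerateError(
            f"constant feature(s) cannot enter the correlation PCA: "
            f"{[feature_names[j] for j in bad]}")
    return (X - X.mean(axis=0)) / sd


def pca_fit(encoded: EncodedMatrix | np.ndarray,
            feature_names: list[str] | None = None) -> BiplotResult:
    """Correlation-matrix PCA of the encoded features.

    All columns (indicator columns included) are scaled to unit variance, so
    the decomposed matrix is the correlation matrix and the eigenvalue sum
    equals the feature count.  Eigenvector signs are fixed so each PC's
    largest-magnitude loading is positive.
    """
    if isinstance(encoded, EncodedMatrix):
        values = encoded.values
        feature_names = list(encoded.feature_names)
    else:
        values = np.asarray(encoded, dtype=float)
        feature_names = (list(feature_names) if feature_names is not None
                         else [f"f{j}" for j in range(values.shape[1])])
    if values.ndim != 2 or values.shape[0] < 2 or values.shape[1] < 2:
        raise InputError("PCA needs >= 2 rows and >= 2 columns")

    Xs = _standardized(values, feature_names)
    n = Xs.shape[0]
    R = (Xs.T @ Xs) / (n - 1)
    eigvals, eigvecs = np.linalg.eigh(R)
    order = np.argsort(eigvals)[::-1]
    eigvals = np.clip(eigvals[order], 0.0, None)
    eigvecs = eigvecs[:, order]

    # deterministic sign: largest-|.| entry of each eigenvector positive
    for j in range(eigvecs.shape[1]):
        jmax = int(np.abs(eigvecs[:, j]).argmax())
        if eigvecs[jmax, j] < 0:
            eigvecs[:, j] = -eigvecs[:, j]

    scores = Xs @ eigvecs
    loadings = eigvecs * np.sqrt(eigvals)[None, :]
    total = eigvals.sum()
    if total <= 0:
        raise DegenerateError("rank-0 input: total variance is zero")
    var_pct = 100.0 * eigvals / total
    return BiplotResult(
        eigenvalues=eigvals, variance_explained=var_pct,
        cumulative=np.cumsum(var_pct), scores=scores, loadings=loadings,
        cos2=loadings ** 2, feature_names=feature_names)


def cos2_ranking(result: BiplotResult, top_k: int = 5
                 ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-variable ranking of PCs and per-PC ranking of variables by Cos2
    over the leading ``top_k`` PCs."""
    if top_k > result.n_pcs:
        raise InputError(f"top_k={top_k} exceeds PC count {result.n_pcs}")
    pcs = [f"PC{i + 1}" for i in range(top_k)]
    c2 = pd.DataFrame(result.cos2[:, :top_k], index=result.feature_names,
                      columns=pcs)
    by_variable = c2.apply(
        lambda row: pd.Series(row.sort_values(ascending=False).index,
                              index=[f"rank{i + 1}" for i in range(top_k)]),
        axis=1)
    by_pc = pd.DataFrame({
        pc: c2[pc].sort_values(ascending=False).index for pc in pcs})
    return by_variable.reset_index(names="feature"), by_pc


def biplot_coords(result: BiplotResult
                  ) -> tuple[np.ndarray, np.ndarray]:
    """(sample points, variable arrows) on the PC1 x PC2 plane."""
    if result.n_pcs < 2:
        raise InputError("biplot needs at least 2 PCs")
    return result.scores[:, :2], result.loadings[:, :2]


def component_similarity(encoded: EncodedMatrix | np.ndarray,
                         feature_names: list[str] | None = None
                         ) -> tuple[np.ndarray, list[str]]:
    """Average-linkage AHC of features on Spearman correlation distance.

    Returns the scipy merge history and the feature order.  Distance is
    1 - rho, so a feature is at distance 0 from any strictly monotone
    transform of itself and at distance 2 from its rank reversal.
    """
    if isinstance(encoded, EncodedMatrix):
        values = encoded.values
        feature_names = list(encoded.feature_names)
    else:
        values = np.asarray(encoded, dtype=float)
        feature_names = (list(feature_names) if feature_names is not None
                         else [f"f{j}" for j in range(values.shape[1])])
    if values.shape[1] < 2:
        raise InputError("need at least 2 features")
    sd = values.std(axis=0, ddof=1)
    bad = np.flatnonzero(~(sd > 0))
    if bad.size:
        raise DegenerateError(
            f"Spearman correlation undefined for constant feature(s): "
            f"{[feature_names[j] for j in bad]}")
    rho = spearmanr(values).statistic
    if np.ndim(rho) == 0:  # scipy returns a scalar for exactly 2 columns
        rho = np.array([[1.0, float(rho)], [float(rho), 1.0]])
    dist = 1.0 - rho
    np.fill_diagonal(dist, 0.0)
    dist = np.clip((dist + dist.T) / 2.0, 0.0, None)
    Z = linkage(squareform(dist, checks=False), method="average")
    return Z, feature_names
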