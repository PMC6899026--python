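"""PCA embedding with explained-variance-threshold component selection.

The embedding is fit per cell type on the pooled normalized data of all
that cell type's conditions.  The number of retained components is the
smallest k whose cumulative explained-variance ratio reaches the threshold
(default 0.99).  Downstream spatial correlations are computed on these
component scores by default; a raw-feature mode is available upstream.

PCA component signs are arbitrary; to make repeated fits bit-identical we
fix each component so its largest-magnitude loading is positive.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA

from .io_tables import FeatureTable, SchemaError


class EmbeddingError(ValueError):
    pass


@dataclasses.dataclass
class EmbeddingModel:
    feature_names: list[str]
    mean: np.ndarray                     # fit-population feature means
    components: np.ndarray               # full basis, (m x p), rows orthonormal
    explained_variance: np.ndarray       # per-component eigenvalues
    explained_variance_ratio: np.ndarray
    n_components: int                    # selected by the cumulative rule
    variance_threshold: float
    fit_population: str = ""

    @property
    def loadings(self) -> np.ndarray:
        """Selected components only, (n_components x p)."""
        return self.components[: self.n_components]

    @property
    def score_names(self) -> list[str]:
        return [f"PC{i + 1:03d}" for i in range(self.n_components)]


def select_n_components(
    explained_variance_ratio: np.ndarray, variance_threshold: float
) -> int:
    """Smallest k with cumulative explained-variance ratio >= threshold.

    A 1e-12 slack absorbs floating-point shortfall when the data span a
    subspace exactly (cumulative ratio 1.0 up to rounding).
    """
    cum = np.cumsum(explained_variance_ratio)
    k = int(np.searchsorted(cum, variance_threshold - 1e-12) + 1)
    return min(k, len(cum))


def fit_embedding(
    table: FeatureTable,
    variance_threshold: float = 0.99,
    fit_population: str = "",
) -> EmbeddingModel:
    """Fit the PCA basis on a normalized table and select components."""
    if table.n_cells < 2:
        raise EmbeddingError("need at least 2 cells to fit an embedding")
    if not 0 < variance_threshold <= 1:
        raise EmbeddingError("variance_threshold must be in (0, 1]")
    X = table.features
    pca = PCA(svd_solver="full")
    pca.fit(X)
    comps = pca.components_.copy()
    # sign convention: largest-magnitude loading positive
    for row in comps:
        if row[np.argmax(np.abs(row))] < 0:
            row *= -1.0
    evr = pca.explained_variance_ratio_
    return EmbeddingModel(
        feature_names=list(table.feature_names),
        mean=pca.mean_,
        components=comps,
        explained_variance=pca.explained_variance_,
        explained_variance_ratio=evr,
        n_components=select_n_components(evr, variance_threshold),
        variance_threshold=variance_threshold,
        fit_population=fit_population,
    )


def transform(
    table: FeatureTable, model: EmbeddingModel, n_components: int | None = None
) -> FeatureTable:
    """Project a table onto the selected components.

    Scores are ``(X - fit mean) @ loadings.T``.  Returns a score table with
    metadata and coordinates carried through and columns PC001..PCk; it
    satisfies the same contract as a feature table, so every downstream
    step (null, neighbors, scoring) applies unchanged.
    """
    if list(table.feature_names) != model.feature_names:
        raise SchemaError("table features do not match the embedding's feature list")
    k = model.n_components if n_components is None else n_components
    scores = (table.features - model.mean) @ model.components[:k].T
    out = table.data.drop(columns=table.feature_names).copy()
    names = [f"PC{i + 1:03d}" for i in range(k)]
    out = pd.concat(
        [out, pd.DataFrame(scores, columns=names, index=out.index)], axis=1
    )
    return FeatureTable(out, names)
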