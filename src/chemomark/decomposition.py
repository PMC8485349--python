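"""Principal component analysis by singular value decomposition.

Used both for exploring the autoscaled abundance matrix and for
interpreting the weight vectors of a trained self-organizing map
(each SOM neuron is a point in variable space; PCA of the neuron
weights reveals which variables drive the map's organisation).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["PCAModel", "pca_fit", "pca_on_som_weights"]


@dataclass
class PCAModel:
    """SVD-based PCA decomposition.

    ``loadings`` (variables x components) has orthonormal columns;
    ``scores`` = centered data @ loadings; ``explained_variance_pct``
    is each component's share of the total variance, in percent.
    The sign of each component is fixed so its largest-magnitude
    loading is positive, making the decomposition deterministic.
    """

    loadings: np.ndarray
    scores: np.ndarray
    explained_variance_pct: np.ndarray
    mean_: np.ndarray

    @property
    def n_components(self) -> int:
        return self.loadings.shape[1]

    def transform(self, matrix: np.ndarray) -> np.ndarray:
        return (np.asarray(matrix, dtype=float) - self.mean_) @ self.loadings


def pca_fit(matrix: np.ndarray, n_components: int | None = None, center: bool = True) -> PCAModel:
    """Fit PCA on a matrix (expected autoscaled, or at least centered).

    Components are ordered by decreasing explained variance.  Raises if
    ``n_components`` exceeds ``min(n_samples - 1, n_variables)`` or the
    matrix has no variance at all.
    """
    X = np.asarray(matrix, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2:
        raise ValueError("pca_fit requires a 2-D matrix with at least 2 rows")
    n, p = X.shape
    max_rank = min(n - 1, p)
    if n_components is None:
        n_components = max_rank
    if not 1 <= n_components <= max_rank:
        raise ValueError(f"n_components must be in [1, {max_rank}], got {n_components}")
    mean = X.mean(axis=0) if center else np.zeros(p)
    Xc = X - mean
    total_var = (Xc**2).sum()
    if total_var == 0:
        raise ValueError("matrix has zero variance; PCA undefined")
    U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    V = Vt[:n_components].T
    # deterministic sign: largest |loading| of each component positive
    flip = np.sign(V[np.abs(V).argmax(axis=0), np.arange(n_components)])
    flip[flip == 0] = 1.0
    V = V * flip
    scores = Xc @ V
    explained = 100.0 * (s[:n_components] ** 2) / total_var
    return PCAModel(loadings=V, scores=scores, explained_variance_pct=explained, mean_=mean)


def pca_on_som_weights(som_model, n_components: int = 2, labels=None):
    """PCA of a trained SOM's neuron weight matrix, with class annotation.

    The neurons x variables weight matrix is mean-centered (not
    re-autoscaled: the weights already live in autoscaled data space)
    and decomposed.  Each neuron is annotated from the samples assigned
    to it: the class name if all its samples share one label, "mixed"
    otherwise, and "empty" for neurons holding no samples (the "black
    circles" of a top-map score plot).

    Returns ``(PCAModel, annotation)`` where ``annotation`` is a pandas
    Series over neuron indices.
    """
    if som_model.weights is None:
        raise ValueError("SOM is not trained")
    model = pca_fit(som_model.weights, n_components=n_components, center=True)
    n_neurons = som_model.weights.shape[0]
    if labels is None:
        annotation = pd.Series(["unlabeled"] * n_neurons, name="neuron_class")
    else:
        labels = np.asarray(labels)
        if len(labels) != len(som_model.assignments):
            raise ValueError("labels length does not match assigned samples")
        ann = []
        for k in range(n_neurons):
            here = labels[som_model.assignments == k]
            if here.size == 0:
                ann.append("empty")
            elif len(set(here.tolist())) == 1:
                ann.append(str(here[0]))
            else:
                ann.append("mixed")
        annotation = pd.Series(ann, name="neuron_class")
    return model, annotation
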