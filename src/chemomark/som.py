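"""Batch Kohonen self-organizing map on a hexagonal toroidal grid.

The SOM places each sample on a low-dimensional grid of neurons such
that similar samples land on the same or adjacent neurons.  Here the
grid is hexagonal (six equidistant neighbours per neuron) and toroidal
(left/right and top/bottom edges wrap), so the map has no privileged
border and the neuron lattice is fully homogeneous.  Both grid
dimensions must be even: an odd dimension cannot be closed into a
consistent hexagonal torus.

Training is the batch algorithm with a learning-rate blend.  Each
epoch:

1. every sample is assigned to its winning neuron — the one whose
   weight vector is nearest in Euclidean distance (ties broken by the
   lowest neuron index);
2. each neuron's batch target is the neighbourhood-kernel-weighted mean
   of the samples, with Gaussian kernel ``h = exp(-d^2 / (2 sigma^2))``
   in hexagonal toroidal grid distance ``d`` from the winner;
3. weights move toward the target by the epoch's learning rate:
   ``w_new = (1 - alpha) w_old + alpha * target``.

The learning rate decreases linearly between its endpoints (default
0.5 -> 0.01) and the kernel width sigma decreases linearly from
``neighborhood_start`` to 0, so the final epochs correct the winner
only.  Neurons receiving no kernel mass keep their weights for that
epoch.  All randomness (weight initialization) is seeded.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass

import numpy as np
import pandas as pd

__all__ = ["SOMGrid", "SOMConfig", "SOMModel", "hex_toroidal_distance", "som_fit", "top_map"]


class SOMGrid:
    """Hexagonal toroidal neuron lattice with ``rows * cols`` neurons.

    Neurons are indexed row-major (``k = r * cols + c``).  Rows use
    odd-row offset coordinates: odd rows are shifted half a cell right,
    which gives each neuron six neighbours at grid distance 1.
    """

    def __init__(self, rows: int, cols: int):
        if rows < 2 or cols < 2:
            raise ValueError("grid dimensions must be >= 2")
        if rows % 2 or cols % 2:
            raise ValueError("grid dimensions must be even to close the hexagonal torus")
        self.rows, self.cols = rows, cols

    @property
    def n_neurons(self) -> int:
        return self.rows * self.cols

    def _cube(self) -> np.ndarray:
        """Cube coordinates (x, y, z) of every neuron, odd-row offset."""
        r, c = np.divmod(np.arange(self.n_neurons), self.cols)
        x = c - (r - (r & 1)) // 2
        z = r
        y = -x - z
        return np.stack([x, y, z], axis=1).astype(np.int64)

    def distance_matrix(self) -> np.ndarray:
        """All-pairs hexagonal grid distance under minimal-image wrap-around."""
        cube = self._cube()
        delta = cube[:, None, :] - cube[None, :, :]
        R, C = self.rows, self.cols
        row_wrap = np.array([-(R // 2), -(R // 2), R], dtype=np.int64)
        col_wrap = np.array([C, -C, 0], dtype=np.int64)
        best = None
        for a in (-1, 0, 1):
            for b in (-1, 0, 1):
                img = delta + a * row_wrap + b * col_wrap
                d = np.abs(img).sum(axis=2) // 2  # hex distance from cube coords
                best = d if best is None else np.minimum(best, d)
        return best.astype(float)


def hex_toroidal_distance(grid: SOMGrid, neuron_i: int, neuron_j: int) -> float:
    """Grid distance between two neurons on the hexagonal torus."""
    n = grid.n_neurons
    if not (0 <= neuron_i < n and 0 <= neuron_j < n):
        raise ValueError(f"neuron index out of grid (0..{n - 1})")
    return float(grid.distance_matrix()[neuron_i, neuron_j])


@dataclass
class SOMConfig:
    rows: int = 8
    cols: int = 8
    epochs: int = 200
    lr_start: float = 0.5
    lr_end: float = 0.01
    neighborhood_start: float | None = None  # default: half the larger grid dimension
    seed: int = 0

    def __post_init__(self) -> None:
        SOMGrid(self.rows, self.cols)  # validates shape
        if not (self.lr_start > self.lr_end > 0):
            raise ValueError("need lr_start > lr_end > 0")
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if self.neighborhood_start is None:
            self.neighborhood_start = max(self.rows, self.cols) / 2.0
        if self.neighborhood_start < 0:
            raise ValueError("neighborhood_start must be >= 0")


#: Grid/epoch presets: the larger map for the three-timepoint comparison,
#: the smaller one for pairwise contrasts.
GENERAL_SOM = SOMConfig(rows=10, cols=10, epochs=300)
PAIRWISE_SOM = SOMConfig(rows=8, cols=8, epochs=200)


@dataclass
class SOMModel:
    """A trained map: neuron weights, sample assignments and error trace."""

    config: SOMConfig
    grid: SOMGrid
    weights: np.ndarray  # neurons x variables, autoscaled-data units
    assignments: np.ndarray  # winning neuron per sample
    qe_trace: np.ndarray  # per-epoch quantization error (mean sample->winner distance)

    def winners(self, matrix: np.ndarray) -> np.ndarray:
        """Nearest neuron (Euclidean over weights) per row; ties -> lowest index."""
        d2 = _sq_distances(np.asarray(matrix, dtype=float), self.weights)
        return d2.argmin(axis=1)

    def quantization_error(self, matrix: np.ndarray) -> float:
        d2 = _sq_distances(np.asarray(matrix, dtype=float), self.weights)
        return float(np.sqrt(d2.min(axis=1)).mean())

    def to_json(self) -> str:
        return json.dumps(
            {
                "config": asdict(self.config),
                "weights": self.weights.tolist(),
                "assignments": self.assignments.tolist(),
                "qe_trace": self.qe_trace.tolist(),
            }
        )

    @classmethod
    def from_json(cls, text: str) -> "SOMModel":
        d = json.loads(text)
        cfg = SOMConfig(**d["config"])
        return cls(
            config=cfg,
            grid=SOMGrid(cfg.rows, cfg.cols),
            weights=np.asarray(d["weights"], dtype=float),
            assignments=np.asarray(d["assignments"], dtype=int),
            qe_trace=np.asarray(d["qe_trace"], dtype=float),
        )


def _sq_distances(X: np.ndarray, W: np.ndarray) -> np.ndarray:
    d2 = (X**2).sum(axis=1)[:, None] - 2.0 * X @ W.T + (W**2).sum(axis=1)[None, :]
    return np.maximum(d2, 0.0)


def som_fit(
    matrix: np.ndarray, config: SOMConfig, init_weights: np.ndarray | None = None
) -> SOMModel:
    """Train a batch SOM on an (autoscaled) samples x variables matrix.

    ``init_weights`` overrides the seeded random initialization (used
    e.g. to start from chosen codebook vectors); by default weights are
    drawn uniformly within each variable's data range.
    """
    X = np.asarray(matrix, dtype=float)
    if X.ndim != 2 or X.shape[0] == 0:
        raise ValueError("matrix must be 2-D and nonempty")
    if not np.all(np.isfinite(X)):
        raise ValueError("matrix contains non-finite values")
    grid = SOMGrid(config.rows, config.cols)
    K = grid.n_neurons
    rng = np.random.default_rng(config.seed)
    if init_weights is not None:
        W = np.array(init_weights, dtype=float, copy=True)
        if W.shape != (K, X.shape[1]):
            raise ValueError(f"init_weights must have shape {(K, X.shape[1])}")
    else:
        lo, hi = X.min(axis=0), X.max(axis=0)
        W = rng.uniform(lo, hi, size=(K, X.shape[1]))

    D2 = grid.distance_matrix() ** 2
    T = config.epochs
    alphas = np.linspace(config.lr_start, config.lr_end, T)
    sigmas = (
        np.linspace(config.neighborhood_start, 0.0, T) if T > 1 else np.array([0.0])
    )

    qe_trace = np.empty(T)
    for t in range(T):
        d2 = _sq_distances(X, W)
        winners = d2.argmin(axis=1)
        qe_trace[t] = np.sqrt(d2[np.arange(len(X)), winners]).mean()
        sigma = sigmas[t]
        if sigma > 0:
            H = np.exp(-D2 / (2.0 * sigma * sigma))  # kernel over winner -> neuron
        else:
            H = np.eye(K)
        A = H[winners]  # samples x neurons kernel weights
        denom = A.sum(axis=0)
        active = denom > 0
        target = np.empty_like(W)
        target[active] = (A.T[active] @ X) / denom[active, None]
        target[~active] = W[~active]  # no kernel mass: keep previous weights
        W = (1.0 - alphas[t]) * W + alphas[t] * target

    final_assign = _sq_distances(X, W).argmin(axis=1)
    return SOMModel(
        config=config, grid=grid, weights=W, assignments=final_assign, qe_trace=qe_trace
    )


def top_map(som_model: SOMModel, labels) -> pd.DataFrame:
    """Per-neuron occupancy summary of a trained map.

    One row per neuron with its grid position, the sample count per
    class label, the total occupancy and an ``empty`` flag.
    """
    labels = np.asarray(labels)
    if len(labels) != len(som_model.assignments):
        raise ValueError(
            f"{len(labels)} labels for {len(som_model.assignments)} assigned samples"
        )
    grid = som_model.grid
    classes = sorted(set(labels.tolist()), key=str)
    rows = []
    for k in range(grid.n_neurons):
        here = labels[som_model.assignments == k]
        row = {"neuron": k, "row": k // grid.cols, "col": k % grid.cols}
        for cl in classes:
            row[f"n_{cl}"] = int((here == cl).sum())
        row["total"] = int(here.size)
        row["empty"] = here.size == 0
        rows.append(row)
    return pd.DataFrame(rows).set_index("neuron")
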