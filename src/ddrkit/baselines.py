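"""Trial-averaged and single-trial PCA reducers (taPCA / stPCA).

Both are the standard PCA variants a decoding analysis would reach for, and
both differ from dDR in what their components mean:

* **taPCA** averages trials within each condition first, then takes the top
  principal components of the ``S x N`` condition-mean matrix (centered by
  the grand mean of the condition means).  Its components capture
  stimulus-evoked variance only; for two conditions the single existing
  component is exactly the normalized ``delta mu`` — the dDR signal axis.
* **stPCA** takes the top components of all pooled single trials, centered
  by the grand mean over trials (not per condition — per-condition
  centering would turn it into the dDR noise estimator).  Its components
  mix trial-to-trial and across-condition variance.

No variance-explained thresholding is done: the caller always states ``d``
explicitly.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import numpy as np
from sklearn.decomposition import PCA

from .exceptions import (
    DegenerateSignalError,
    InsufficientDataError,
    RankError,
    ShapeError,
)
from .population_data import ResponseSet

__all__ = ["LinearReducer", "fit_tapca", "fit_stpca"]


def _fix_sign(v: np.ndarray) -> np.ndarray:
    i = int(np.argmax(np.abs(v)))
    return -v if v[i] < 0 else v


@dataclass(frozen=True)
class LinearReducer:
    """``d x N`` orthonormal projection rows plus the centering vector used."""

    axes: np.ndarray
    method: str
    centering_vector: np.ndarray

    def __post_init__(self) -> None:
        axes = np.atleast_2d(np.asarray(self.axes, dtype=float))
        if axes.shape[0] > axes.shape[1]:
            raise RankError("more axes than dimensions")
        if not np.allclose(axes @ axes.T, np.eye(axes.shape[0]), atol=1e-9):
            raise ShapeError("reducer rows are not orthonormal")
        object.__setattr__(self, "axes", axes)

    @property
    def d(self) -> int:
        return self.axes.shape[0]

    def transform(self, rs: ResponseSet) -> ResponseSet:
        if rs.n_neurons != self.axes.shape[1]:
            raise ShapeError("dimension mismatch")
        return ResponseSet(
            counts=rs.counts @ self.axes.T,
            condition_labels=rs.condition_labels,
            neuron_ids=tuple(f"{self.method}_{i + 1}" for i in range(self.d)),
        )


def fit_tapca(
    rs: ResponseSet, conditions: Iterable[str] | None = None, d: int = 1
) -> LinearReducer:
    """PCA on the condition-mean matrix (one row per condition).

    Only ``S - 1`` nontrivial components exist for ``S`` conditions, so
    ``d`` beyond that (or beyond the rank of the centered mean matrix) is a
    rank error; identical condition means are a degenerate signal.
    """
    labels = tuple(conditions) if conditions is not None else rs.conditions
    if len(labels) < 2:
        raise InsufficientDataError("taPCA needs >= 2 conditions")
    if d < 1:
        raise ValueError("d must be >= 1")
    if d > min(len(labels) - 1, rs.n_neurons):
        raise RankError(
            f"d = {d} exceeds the {len(labels) - 1} nontrivial components "
            f"available for S = {len(labels)} conditions"
        )
    means = np.vstack([rs.trials(lab).mean(axis=0) for lab in labels])
    center = means.mean(axis=0)
    centered = means - center
    u, s, vt = np.linalg.svd(centered, full_matrices=False)
    scale = float(np.linalg.norm(means)) or 1.0
    if s[0] <= 1e-12 * scale:
        raise DegenerateSignalError("all condition means are identical")
    if s[d - 1] <= 1e-8 * s[0]:
        raise RankError(
            f"condition means have rank < {d} (collinear means)"
        )
    axes = np.vstack([_fix_sign(vt[i]) for i in range(d)])
    return LinearReducer(axes=axes, method="tapca", centering_vector=center)


def fit_stpca(
    rs: ResponseSet, conditions: Iterable[str] | None = None, d: int = 2
) -> LinearReducer:
    """PCA on pooled single trials, centered by the grand mean over trials."""
    if d < 1:
        raise ValueError("d must be >= 1")
    sub = rs if conditions is None else rs.select_conditions(conditions)
    if sub.n_trials < d + 1:
        raise InsufficientDataError(
            f"{sub.n_trials} trials cannot support d = {d} components"
        )
    if d > sub.n_neurons:
        raise RankError(f"d = {d} exceeds N = {sub.n_neurons}")
    pca = PCA(n_components=d, svd_solver="full")
    pca.fit(sub.counts)
    axes = np.vstack([_fix_sign(c) for c in pca.components_])
    return LinearReducer(axes=axes, method="stpca", centering_vector=pca.mean_)
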