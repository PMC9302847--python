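"""Decoding-based dimensionality reduction (dDR).

dDR projects an N-neuron population response into a small ``(1 + m)``
dimensional subspace chosen for *decoding* rather than for variance
explained:

* the **signal axis** is the unit vector along ``delta mu = mu_a - mu_b``,
  the difference of the two condition-mean responses;
* the first **noise axis** is the component of ``e_1`` — the leading
  eigenvector of the pooled (per-condition mean-centered) noise covariance —
  orthogonal to the signal axis, renormalized (Gram–Schmidt);
* further noise axes (``m > 1``) come from deflation: the centered data are
  projected off the span of all previously chosen axes and the leading
  principal component of the residual is taken, re-orthogonalized against
  every prior axis.

Together the signal axis and ``e_1`` span the plane in state space where a
two-condition linear decoding analysis keeps both the stimulus separation
and the dominant mode of shared trial-to-trial covariability, which is the
part of the covariance that can actually be estimated from few trials.

The rationale for the Gram–Schmidt step: the defining requirement for the
second dDR dimension is "the axis orthogonal to delta mu in the plane
spanned by delta mu and e_1", which is exactly the normalized Gram–Schmidt
remainder ``e_1 - (e_1 . s) s`` for the unit signal axis ``s``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .exceptions import (
    DegenerateNoiseError,
    DegenerateSignalError,
    InsufficientDataError,
    RankError,
    ShapeError,
)
from .population_data import (
    ConditionPair,
    ResponseSet,
    condition_statistics,
)

__all__ = [
    "DDRBasis",
    "fit_ddr",
    "project",
    "leading_noise_eigenvector",
]

_ORTHO_TOL = 1e-10


def _fix_sign(v: np.ndarray) -> np.ndarray:
    """Sign convention: the entry of largest magnitude is positive."""
    i = int(np.argmax(np.abs(v)))
    return -v if v[i] < 0 else v


@dataclass(frozen=True)
class DDRBasis:
    """Orthonormal dDR axes: row 0 the signal axis, rows 1..m the noise axes.

    ``delta_mu_norm`` records the magnitude of ``delta mu`` before
    normalization, so projected condition means remain interpretable in
    units of the original responses.
    """

    axes: np.ndarray  # (1 + m, N)
    delta_mu_norm: float
    neuron_ids: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        axes = np.asarray(self.axes, dtype=float)
        if axes.ndim != 2:
            raise ShapeError("axes must be a 2-D array of row vectors")
        if axes.shape[0] > axes.shape[1]:
            raise RankError(
                f"{axes.shape[0]} axes exceed population size {axes.shape[1]}"
            )
        gram = axes @ axes.T
        if not np.allclose(gram, np.eye(axes.shape[0]), atol=1e-9):
            raise ShapeError("axes rows are not orthonormal")
        object.__setattr__(self, "axes", axes)

    @property
    def m(self) -> int:
        """Number of noise dimensions."""
        return self.axes.shape[0] - 1

    @property
    def n_neurons(self) -> int:
        return self.axes.shape[1]

    @property
    def signal_axis(self) -> np.ndarray:
        return self.axes[0]

    @property
    def noise_axes(self) -> np.ndarray:
        return self.axes[1:]

    @property
    def component_names(self) -> tuple[str, ...]:
        return ("signal",) + tuple(f"noise_{i}" for i in range(1, self.m + 1))

    def to_csv(self, path) -> None:
        cols = list(self.neuron_ids or (f"n{i}" for i in range(self.n_neurons)))
        df = pd.DataFrame(self.axes, columns=cols)
        df.insert(0, "component", list(self.component_names))
        df.insert(1, "delta_mu_norm", [self.delta_mu_norm] * len(df))
        df.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "DDRBasis":
        df = pd.read_csv(path)
        neuron_cols = [c for c in df.columns if c not in ("component", "delta_mu_norm")]
        return cls(
            axes=df[neuron_cols].to_numpy(dtype=float),
            delta_mu_norm=float(df["delta_mu_norm"].iloc[0]),
            neuron_ids=tuple(neuron_cols),
        )


def _pooled_noise_covariance(
    rs: ResponseSet, labels: Sequence[str]
) -> tuple[np.ndarray, np.ndarray]:
    """Unweighted average of per-condition sample covariances, plus the
    stacked per-condition mean-centered trials (for deflation)."""
    covs = []
    centered = []
    for lab in labels:
        x = rs.trials(lab)
        if x.shape[0] < 2:
            raise InsufficientDataError(
                f"condition {lab!r} has {x.shape[0]} trials; need >= 2"
            )
        centered.append(x - x.mean(axis=0))
        covs.append(np.atleast_2d(np.cov(x, rowvar=False, ddof=1)))
    sigma = np.mean(covs, axis=0)
    sigma = 0.5 * (sigma + sigma.T)
    return sigma, np.vstack(centered)


def leading_noise_eigenvector(
    rs: ResponseSet,
    pair: ConditionPair | None = None,
    conditions: Iterable[str] | None = None,
) -> tuple[np.ndarray, float]:
    """Leading eigenvector and eigenvalue of the pooled noise covariance.

    Trials are mean-centered within each included condition before the
    covariance is estimated, so condition-mean (signal) differences do not
    leak into the noise estimate.  By default the noise is pooled over the
    two conditions of ``pair``; pass ``conditions`` to pool over any subset
    (or, with a single condition, to use that condition alone).

    The returned vector has unit norm and a fixed sign (largest-magnitude
    entry positive).  For a near-isotropic spectrum the direction is
    ill-determined — that is a property of the data, not an error.
    """
    if pair is not None and conditions is not None:
        raise ValueError("pass either pair or conditions, not both")
    if pair is not None:
        labels: Sequence[str] = (pair.label_a, pair.label_b)
    elif conditions is not None:
        labels = tuple(conditions)
    else:
        labels = rs.conditions
    if not labels:
        raise InsufficientDataError("no conditions selected")
    sigma, _ = _pooled_noise_covariance(rs, labels)
    evals, evecs = np.linalg.eigh(sigma)
    vec = _fix_sign(evecs[:, -1])
    return vec, float(evals[-1])


def fit_ddr(
    rs: ResponseSet,
    pair: ConditionPair,
    n_noise_dims: int = 1,
    noise_conditions: Iterable[str] | None = None,
) -> DDRBasis:
    """Fit a dDR basis with one signal axis and ``n_noise_dims`` noise axes.

    Parameters
    ----------
    rs, pair
        The labeled responses and the two conditions to decode.
    n_noise_dims
        Number of noise dimensions ``m >= 1``; ``1 + m`` must not exceed the
        number of neurons, and the pair must contribute at least ``m + 2``
        trials in total.
    noise_conditions
        Optional set of conditions over which the noise covariance is pooled
        (per-condition centered).  Default: the two conditions being decoded.
        Pooling across all conditions supports a "global noise axis"
        workflow.

    Raises
    ------
    DegenerateSignalError
        If ``|delta mu|`` is numerically zero (scale-aware test).
    DegenerateNoiseError
        If ``e_1`` is parallel to ``delta mu``; reduce ``m`` or accept a
        one-dimensional (signal only) analysis.
    """
    m = int(n_noise_dims)
    if m < 1:
        raise ValueError("n_noise_dims must be >= 1")
    pair.validate(rs, min_trials=2)
    if 1 + m > rs.n_neurons:
        raise RankError(
            f"1 + m = {1 + m} dimensions exceed N = {rs.n_neurons} neurons"
        )
    stats = condition_statistics(rs, pair)
    if stats.k_a + stats.k_b < m + 2:
        raise InsufficientDataError(
            f"{stats.k_a + stats.k_b} trials cannot support m = {m} noise dims"
        )

    delta_mu = stats.delta_mu
    dmu_norm = float(np.linalg.norm(delta_mu))
    scale = float(np.mean(np.sqrt(np.clip(np.diag(stats.sigma_pooled), 0, None))))
    tol = 1e-12 * max(scale, np.finfo(float).tiny)
    if dmu_norm <= tol:
        raise DegenerateSignalError(
            "conditions are indistinguishable in mean (|delta mu| ~ 0)"
        )
    signal = delta_mu / dmu_norm

    if noise_conditions is None:
        noise_labels: Sequence[str] = (pair.label_a, pair.label_b)
    else:
        noise_labels = tuple(noise_conditions)
    sigma_noise, centered = _pooled_noise_covariance(rs, noise_labels)
    evals, evecs = np.linalg.eigh(sigma_noise)
    e1 = evecs[:, -1]

    residual = e1 - (e1 @ signal) * signal
    res_norm = float(np.linalg.norm(residual))
    if res_norm <= 1e-8:
        raise DegenerateNoiseError(
            "leading noise eigenvector is parallel to delta mu; "
            "reduce n_noise_dims or use the signal axis alone"
        )
    axes = [signal, _fix_sign(residual / res_norm)]

    # Deflation for additional noise dimensions: remove the span of all
    # chosen axes from the centered data, then take the top principal
    # component of the residual.
    for _ in range(m - 1):
        basis = np.asarray(axes)
        resid_data = centered - (centered @ basis.T) @ basis
        _, svals, vt = np.linalg.svd(resid_data, full_matrices=False)
        if svals[0] <= 1e-12 * max(1.0, float(np.linalg.norm(centered))):
            raise InsufficientDataError(
                "residual data have no variance left for another noise axis"
            )
        v = vt[0]
        v = v - basis.T @ (basis @ v)
        nv = float(np.linalg.norm(v))
        if nv <= 1e-10:
            raise DegenerateNoiseError(
                "next noise axis is degenerate after re-orthogonalization"
            )
        axes.append(_fix_sign(v / nv))

    # One modified Gram-Schmidt sweep to pin orthonormality at ~1e-15.
    ortho: list[np.ndarray] = []
    for v in axes:
        for u in ortho:
            v = v - (u @ v) * u
        v = v / np.linalg.norm(v)
        ortho.append(v)

    return DDRBasis(
        axes=np.asarray(ortho),
        delta_mu_norm=dmu_norm,
        neuron_ids=rs.neuron_ids,
    )


def project(basis: DDRBasis, rs: ResponseSet) -> ResponseSet:
    """Project raw (uncentered) responses onto the dDR axes.

    Returns a ResponseSet with ``1 + m`` columns named ``signal``,
    ``noise_1`` ... — the coordinates of each trial in the reduced space.
    Labels and trial order are preserved.
    """
    if rs.n_neurons != basis.n_neurons:
        raise ShapeError(
            f"ResponseSet has {rs.n_neurons} neurons; basis expects "
            f"{basis.n_neurons}"
        )
    return ResponseSet(
        counts=rs.counts @ basis.axes.T,
        condition_labels=rs.condition_labels,
        neuron_ids=basis.component_names,
    )
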