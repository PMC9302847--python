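"""Optimal linear decoding and the d'2 discriminability statistic.

For two conditions with mean responses ``mu_a``, ``mu_b`` and pooled noise
covariance ``Sigma``, the optimal linear decoding axis and the squared
discriminability (the discrete analog of Fisher information) are

    w_opt = Sigma^{-1} (mu_a - mu_b)
    d'2   = (mu_a - mu_b)^T w_opt

``w_opt`` is deliberately unnormalized — the d'2 identity requires the raw
``Sigma^{-1} delta mu`` form.  When ``Sigma`` is singular (unavoidable for
full-rank decoding when trials < neurons) the Moore–Penrose pseudo-inverse
is used, which lets the full-rank estimator run at any sample size and fail
honestly by overfitting rather than by crashing.  An optional diagonal
loading (ridge) parameter exists but defaults to zero so that the full-rank
baseline keeps its natural small-sample behaviour.

Cross-validation splits trials per condition into estimation and validation
halves: the reducer (dDR / taPCA / stPCA / none) and ``w_opt`` are fit on
the estimation half only; the validation d'2 projects held-out trials onto
the frozen axis and compares held-out means and variances.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np
from scipy.linalg import pinvh

from .exceptions import (
    DegenerateVarianceError,
    InsufficientDataError,
    ShapeError,
)
from .population_data import ConditionPair, ResponseSet, condition_statistics

__all__ = [
    "DecodingResult",
    "dprime_squared",
    "optimal_decoder",
    "projected_dprime_squared",
    "cross_validated_dprime",
]

_PINV_RTOL = 1e-10


def _check_sigma(sigma: np.ndarray, delta_mu: np.ndarray) -> np.ndarray:
    sigma = np.atleast_2d(np.asarray(sigma, dtype=float))
    delta_mu = np.asarray(delta_mu, dtype=float)
    if sigma.shape[0] != sigma.shape[1]:
        raise ShapeError(f"sigma must be square, got {sigma.shape}")
    if sigma.shape[0] != delta_mu.shape[0]:
        raise ShapeError(
            f"sigma is {sigma.shape[0]}-dim but delta_mu is {delta_mu.shape[0]}-dim"
        )
    scale = max(float(np.max(np.abs(sigma))), np.finfo(float).tiny)
    if not np.allclose(sigma, sigma.T, atol=1e-8 * scale):
        raise ShapeError("sigma is not symmetric")
    return 0.5 * (sigma + sigma.T)


def optimal_decoder(
    delta_mu: np.ndarray, sigma: np.ndarray, ridge: float = 0.0
) -> np.ndarray:
    """w_opt = Sigma^{-1} delta_mu (pseudo-inverse; unnormalized)."""
    delta_mu = np.asarray(delta_mu, dtype=float)
    sigma = _check_sigma(sigma, delta_mu)
    if ridge:
        sigma = sigma + ridge * np.eye(sigma.shape[0])
    return pinvh(sigma, rtol=_PINV_RTOL) @ delta_mu


def dprime_squared(
    mu_a: np.ndarray,
    mu_b: np.ndarray,
    sigma: np.ndarray,
    ridge: float = 0.0,
) -> float:
    """Squared discriminability ``delta_mu^T Sigma^{-1} delta_mu``.

    Nonnegative for any symmetric positive-semidefinite ``sigma``
    (pseudo-inverse branch included); tiny negative round-off is clamped
    to zero.
    """
    mu_a = np.asarray(mu_a, dtype=float)
    mu_b = np.asarray(mu_b, dtype=float)
    if mu_a.shape != mu_b.shape:
        raise ShapeError("mu_a and mu_b have different shapes")
    delta = mu_a - mu_b
    w = optimal_decoder(delta, sigma, ridge=ridge)
    return max(float(delta @ w), 0.0)


def projected_dprime_squared(
    w: np.ndarray, a_trials: np.ndarray, b_trials: np.ndarray
) -> float:
    """d'2 of responses projected onto a fixed axis ``w``.

    Projects every trial onto ``w`` and returns
    ``(mean_a - mean_b)^2 / pooled variance`` with unbiased per-condition
    variances averaged (unweighted).  This is the validation-set statistic:
    ``w`` is typically a decoding axis frozen on estimation data.
    """
    w = np.asarray(w, dtype=float)
    if not np.any(w):
        raise DegenerateVarianceError("decoding axis w is zero")
    a = np.atleast_2d(np.asarray(a_trials, dtype=float))
    b = np.atleast_2d(np.asarray(b_trials, dtype=float))
    if a.shape[1] != w.shape[0] or b.shape[1] != w.shape[0]:
        raise ShapeError("trial matrices do not match the axis dimension")
    if a.shape[0] < 2 or b.shape[0] < 2:
        raise InsufficientDataError("need >= 2 trials per condition")
    pa = a @ w
    pb = b @ w
    pooled = 0.5 * (pa.var(ddof=1) + pb.var(ddof=1))
    if pooled <= 0:
        raise DegenerateVarianceError("zero pooled variance along w")
    return float((pa.mean() - pb.mean()) ** 2 / pooled)


@dataclass(frozen=True)
class DecodingResult:
    """Train/validation d'2 and the decoding axis in the evaluation space."""

    dprime_sq_train: float
    dprime_sq_test: float
    w_opt: np.ndarray
    reducer_name: str
    split_info: dict[str, Any] = field(repr=False, default_factory=dict)

    @property
    def d(self) -> int:
        """Evaluation-space dimension."""
        return int(np.asarray(self.w_opt).shape[0])


def _reducer_axes(
    train: ResponseSet,
    pair: ConditionPair,
    reducer: str,
    n_noise_dims: int,
    n_components: int | None,
):
    from .baselines import fit_stpca, fit_tapca  # local import avoids a cycle
    from .ddr import fit_ddr

    if reducer == "fullrank":
        return None, "fullrank"
    if reducer == "ddr":
        basis = fit_ddr(train, pair, n_noise_dims=n_noise_dims)
        return basis.axes, "ddr"
    if reducer == "tapca":
        red = fit_tapca(train, conditions=(pair.label_a, pair.label_b),
                        d=n_components or 1)
        return red.axes, "tapca"
    if reducer == "stpca":
        red = fit_stpca(train, conditions=(pair.label_a, pair.label_b),
                        d=n_components or (1 + n_noise_dims))
        return red.axes, "stpca"
    raise ValueError(f"unknown reducer {reducer!r}")


def cross_validated_dprime(
    rs: ResponseSet,
    pair: ConditionPair,
    reducer: str = "ddr",
    n_noise_dims: int = 1,
    n_components: int | None = None,
    split: float = 0.5,
    seed: int | np.random.Generator | None = None,
) -> DecodingResult:
    """Estimation/validation d'2 with the reducer and decoder fit on the
    estimation half only.

    ``split`` is the estimation fraction; the split is stratified per
    condition and seeded.  The validation statistic uses the frozen basis
    and frozen ``w_opt`` (standard cross-validation; the alternative of
    refitting on validation data would not measure overfitting).
    """
    if not 0 < split < 1:
        raise ValueError("split must be in (0, 1)")
    rng = np.random.default_rng(seed)
    pair.validate(rs, min_trials=4)

    train_idx: list[np.ndarray] = []
    test_idx: list[np.ndarray] = []
    for lab in (pair.label_a, pair.label_b):
        idx = rs.trial_indices(lab)
        k = idx.size
        n_train = int(round(k * split))
        if n_train < 2 or k - n_train < 2:
            raise InsufficientDataError(
                f"condition {lab!r}: split {split} leaves fewer than 2 trials "
                "in one half"
            )
        perm = rng.permutation(k)
        train_idx.append(idx[perm[:n_train]])
        test_idx.append(idx[perm[n_train:]])

    train = rs.subset(np.concatenate(train_idx))
    axes, name = _reducer_axes(train, pair, reducer, n_noise_dims, n_components)

    def reduce(x: np.ndarray) -> np.ndarray:
        return x if axes is None else x @ axes.T

    stats = condition_statistics(train, pair)
    if axes is None:
        mu_a, mu_b, sigma = stats.mu_a, stats.mu_b, stats.sigma_pooled
    else:
        mu_a = axes @ stats.mu_a
        mu_b = axes @ stats.mu_b
        sigma = axes @ stats.sigma_pooled @ axes.T
        sigma = 0.5 * (sigma + sigma.T)
    train_dp = dprime_squared(mu_a, mu_b, sigma)
    w_opt = optimal_decoder(mu_a - mu_b, sigma)

    a_test = reduce(rs.counts[test_idx[0]])
    b_test = reduce(rs.counts[test_idx[1]])
    test_dp = projected_dprime_squared(w_opt, a_test, b_test)

    return DecodingResult(
        dprime_sq_train=train_dp,
        dprime_sq_test=test_dp,
        w_opt=w_opt,
        reducer_name=name,
        split_info={
            "train_indices": [t.tolist() for t in train_idx],
            "test_indices": [t.tolist() for t in test_idx],
            "split": split,
        },
    )
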