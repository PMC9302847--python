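"""Permutation and bootstrap procedures for trial-limited decoding.

Two resampling tools:

* a permutation null for a single pairwise covariance — shuffle one
  neuron's responses to destroy the pairing, recompute the sample
  covariance, and ask where the observed value falls in the null.  At small
  trial counts even a strong true covariance sits inside the null, which is
  the basic reliability problem this package exists to mitigate;
* a bootstrap over estimation sets of growing size, evaluated against a
  fixed held-out validation set, comparing a baseline reducer (taPCA or
  stPCA) to dDR.  The comparison statistic is the baseline's validation
  d'2 divided by the across-bootstrap mean dDR validation d'2 at the same
  sample size ("relative d'2").

The bootstrap standard error is the standard deviation across bootstrap
samples; when the estimation sets resample only ``n_est`` of the
``n_pool`` available trials, an m-out-of-n style correction
``sqrt(n_est / n_pool)`` rescales it.  This is the standard rescaling, and
an approximation to more elaborate corrections; the uncorrected value is
also reported.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .baselines import fit_stpca, fit_tapca
from .ddr import fit_ddr
from .decoding import optimal_decoder, projected_dprime_squared
from .exceptions import (
    ConfigError,
    DegenerateVarianceError,
    InsufficientDataError,
)
from .population_data import ConditionPair, ResponseSet, condition_statistics

__all__ = [
    "PermutationNullResult",
    "BootstrapRelativeResult",
    "permutation_covariance_null",
    "bootstrap_relative_dprime",
    "corrected_bootstrap_se",
]


@dataclass(frozen=True)
class PermutationNullResult:
    observed: float
    null: np.ndarray
    quantile: float  # fraction of |null| >= |observed|
    n_perm: int


def permutation_covariance_null(
    x: np.ndarray,
    y: np.ndarray,
    n_perm: int = 500,
    seed: int | np.random.Generator | None = None,
) -> PermutationNullResult:
    """Null distribution of the pairwise covariance under shuffling of ``x``.

    ``x`` and ``y`` are the two neurons' responses across the same trials.
    Returns the observed sample covariance, the ``n_perm`` shuffled
    covariances, and the two-sided tail fraction ``P(|null| >= |observed|)``.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ConfigError("x and y must be 1-D arrays of equal length")
    if x.size < 3:
        raise InsufficientDataError("need >= 3 paired observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise DegenerateVarianceError("constant input has no covariance null")
    rng = np.random.default_rng(seed)
    xc = x - x.mean()
    yc = y - y.mean()
    k = x.size
    observed = float(xc @ yc / (k - 1))
    null = np.empty(n_perm)
    for p in range(n_perm):
        null[p] = xc[rng.permutation(k)] @ yc / (k - 1)
    quantile = float(np.mean(np.abs(null) >= abs(observed)))
    return PermutationNullResult(
        observed=observed, null=null, quantile=quantile, n_perm=n_perm
    )


def corrected_bootstrap_se(
    boot_values: np.ndarray, n_resampled: int, n_pool: int
) -> float:
    """Bootstrap SE with the m-out-of-n rescaling ``sqrt(m / n)``.

    The bootstrap SE of a statistic is the standard deviation of its
    bootstrap distribution; when each bootstrap sample draws only
    ``n_resampled`` of ``n_pool`` available observations the SD
    overstates the uncertainty at the full sample size and is rescaled by
    ``sqrt(n_resampled / n_pool)``.  No correction when the full pool is
    resampled.
    """
    vals = np.asarray(boot_values, dtype=float)
    if vals.size < 2:
        raise InsufficientDataError("need >= 2 bootstrap values")
    if not 0 < n_resampled <= n_pool:
        raise ConfigError("need 0 < n_resampled <= n_pool")
    sd = float(vals.std(ddof=1))
    if n_resampled < n_pool:
        sd *= float(np.sqrt(n_resampled / n_pool))
    return sd


@dataclass(frozen=True)
class BootstrapRelativeResult:
    """Relative decoding performance of a baseline reducer vs. dDR."""

    k_grid: tuple[int, ...]
    relative_dprime_mean: np.ndarray
    relative_dprime_se: np.ndarray  # corrected (m-out-of-n) SE
    relative_dprime_sd: np.ndarray  # uncorrected bootstrap SD
    n_boot: int
    comparison: str

    def __post_init__(self) -> None:
        if any(np.asarray(self.relative_dprime_se) < 0):
            raise ConfigError("SEs must be nonnegative")
        if list(self.k_grid) != sorted(self.k_grid):
            raise ConfigError("k_grid must be sorted")


def _fit_and_score(
    est_a: np.ndarray,
    est_b: np.ndarray,
    val_a: np.ndarray,
    val_b: np.ndarray,
    reducer: str,
    n_noise_dims: int,
    n_components: int,
    neuron_ids: tuple[str, ...],
) -> float:
    """Fit reducer + decoder on an estimation sample, score on validation."""
    est = ResponseSet(
        counts=np.vstack([est_a, est_b]),
        condition_labels=("a",) * est_a.shape[0] + ("b",) * est_b.shape[0],
        neuron_ids=neuron_ids,
    )
    pair = ConditionPair("a", "b")
    if reducer == "ddr":
        axes = fit_ddr(est, pair, n_noise_dims=n_noise_dims).axes
    elif reducer == "tapca":
        axes = fit_tapca(est, d=1).axes
    elif reducer == "stpca":
        axes = fit_stpca(est, d=n_components).axes
    else:
        raise ConfigError(f"unknown reducer {reducer!r}")
    stats = condition_statistics(est, pair)
    mu_a = axes @ stats.mu_a
    mu_b = axes @ stats.mu_b
    sigma = axes @ stats.sigma_pooled @ axes.T
    w = optimal_decoder(mu_a - mu_b, np.atleast_2d(sigma))
    return projected_dprime_squared(w, val_a @ axes.T, val_b @ axes.T)


def bootstrap_relative_dprime(
    rs: ResponseSet,
    pair: ConditionPair,
    comparison_reducer: str,
    k_grid: Sequence[int] = (20, 30, 40, 50),
    n_validation: int = 15,
    n_boot: int = 200,
    n_noise_dims: int = 1,
    seed: int | np.random.Generator | None = None,
) -> BootstrapRelativeResult:
    """Bootstrap the relative d'2 of a baseline reducer against dDR.

    ``n_validation`` trials per condition are held out once; for each grid
    value ``k`` and each of ``n_boot`` bootstraps, ``k - n_validation``
    estimation trials per condition are drawn with replacement from the
    remaining pool, dDR and the comparison reducer (with their decoders)
    are fit on that sample, and both are scored on the fixed validation
    trials.  The comparison's validation d'2 is normalized by the
    across-bootstrap mean dDR validation d'2 at the same ``k``.

    The comparison reducer is ``tapca`` (1 component — all that exists for
    two conditions), ``stpca`` (``1 + n_noise_dims`` components, matching
    the dDR dimensionality), or ``ddr`` itself (self-normalization check).
    Validation trials never enter any estimation sample.
    """
    rng = np.random.default_rng(seed)
    k_grid = tuple(int(k) for k in k_grid)
    if list(k_grid) != sorted(k_grid):
        raise ConfigError("k_grid must be sorted ascending")
    pair.validate(rs, min_trials=n_validation + 2)
    if min(k_grid) <= n_validation:
        raise ConfigError(
            f"every k must exceed n_validation = {n_validation} "
            "(estimation size is k - n_validation)"
        )
    a_all = rs.trials(pair.label_a)
    b_all = rs.trials(pair.label_b)

    val_sel_a = rng.choice(a_all.shape[0], size=n_validation, replace=False)
    val_sel_b = rng.choice(b_all.shape[0], size=n_validation, replace=False)
    val_a, val_b = a_all[val_sel_a], b_all[val_sel_b]
    pool_a = np.delete(a_all, val_sel_a, axis=0)
    pool_b = np.delete(b_all, val_sel_b, axis=0)
    n_pool = min(pool_a.shape[0], pool_b.shape[0])
    d_comp = 1 + n_noise_dims

    means, ses, sds = [], [], []
    for k in k_grid:
        n_est = k - n_validation
        if n_est < 2:
            raise ConfigError(f"k = {k} leaves < 2 estimation trials")
        ddr_vals = np.empty(n_boot)
        comp_vals = np.empty(n_boot)
        for b in range(n_boot):
            ia = rng.integers(0, pool_a.shape[0], size=n_est)
            ib = rng.integers(0, pool_b.shape[0], size=n_est)
            est_a, est_b = pool_a[ia], pool_b[ib]
            ddr_vals[b] = _fit_and_score(
                est_a, est_b, val_a, val_b, "ddr",
                n_noise_dims, d_comp, rs.neuron_ids,
            )
            if comparison_reducer == "ddr":
                comp_vals[b] = ddr_vals[b]
            else:
                comp_vals[b] = _fit_and_score(
                    est_a, est_b, val_a, val_b, comparison_reducer,
                    n_noise_dims, d_comp, rs.neuron_ids,
                )
        rel = comp_vals / ddr_vals.mean()
        means.append(rel.mean())
        ses.append(corrected_bootstrap_se(rel, n_est, n_pool))
        sds.append(float(rel.std(ddof=1)))

    return BootstrapRelativeResult(
        k_grid=k_grid,
        relative_dprime_mean=np.asarray(means),
        relative_dprime_se=np.asarray(ses),
        relative_dprime_sd=np.asarray(sds),
        n_boot=n_boot,
        comparison=comparison_reducer,
    )
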