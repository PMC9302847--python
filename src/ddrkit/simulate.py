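"""Gaussian population simulator with controlled covariance eigenspectra.

Single-trial population responses are modeled as draws from a multivariate
Gaussian per condition,

    X_c ~ N(mu_c, Sigma + eps_indep * I),

where ``Sigma`` is a *shared* (correlated) covariance built from a
parametric eigenspectrum and ``eps_indep`` is a small independent variance
added to every neuron so the effective covariance is full rank.  Responses
are real-valued (no truncation or rounding to integer counts) — the model
is about second-order structure, not spike-count discreteness.

Four eigenspectrum families are supported:

* ``rank_one`` — all shared variance on a single random direction;
* ``rank_m`` — ``m`` directions, eigenvalues proportional to ``1/i`` by
  default (or caller-specified);
* ``power_law`` — eigenvalues proportional to ``1/n`` over all ``N``
  dimensions, the empirically motivated scree for cortical populations;
* ``independent`` — a flat spectrum (scaled identity), the no-shared-
  structure control.

Eigenvectors are Haar-random orthonormal unless the family fixes them
(``independent``).  The signal direction between the two condition means
can be given exact cosines with the leading shared eigenvectors, which is
how the experiments construct aligned-noise and orthogonal-noise regimes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd

from .exceptions import ConfigError
from .population_data import ResponseSet

__all__ = [
    "CovarianceSpec",
    "CovarianceTruth",
    "PopulationModel",
    "make_covariance",
    "make_population_model",
    "sample_population",
    "analytic_dprime_squared",
    "eigenvector_recovery_curve",
    "covariance_estimator_variance",
]

FAMILIES = ("rank_one", "rank_m", "independent", "power_law")


@dataclass(frozen=True)
class CovarianceSpec:
    """Parametric description of a shared-covariance eigenspectrum.

    ``total_shared_variance`` is the trace of the shared covariance; for
    ``rank_m`` the per-direction eigenvalues default to ``1/i`` weights
    normalized to that total, or can be given explicitly via
    ``eigenvalues``.
    """

    family: str
    n_neurons: int
    total_shared_variance: float = 1.0
    m: int = 1
    eigenvalues: tuple[float, ...] | None = None
    eigenvector_seed: int | None = None

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise ConfigError(
                f"unknown covariance family {self.family!r}; choose from {FAMILIES}"
            )
        if self.n_neurons < 1:
            raise ConfigError("n_neurons must be positive")
        if self.total_shared_variance < 0:
            raise ConfigError("total_shared_variance must be nonnegative")
        if not 1 <= self.m <= self.n_neurons:
            raise ConfigError("need 1 <= m <= n_neurons")
        if self.eigenvalues is not None:
            if self.family != "rank_m":
                raise ConfigError("explicit eigenvalues only apply to rank_m")
            if len(self.eigenvalues) != self.m or any(
                v < 0 for v in self.eigenvalues
            ):
                raise ConfigError("eigenvalues must be m nonnegative values")


class CovarianceTruth(NamedTuple):
    """Ground-truth covariance and its eigenpairs (descending order)."""

    sigma: np.ndarray
    eigenvalues: np.ndarray  # length N, descending
    eigenvectors: np.ndarray  # (N, N), columns match eigenvalues


def _haar_orthonormal(n: int, rng: np.random.Generator) -> np.ndarray:
    q, r = np.linalg.qr(rng.standard_normal((n, n)))
    return q * np.sign(np.diag(r))


def make_covariance(spec: CovarianceSpec) -> CovarianceTruth:
    """Build the shared covariance matrix for ``spec``.

    Returns the matrix plus the ground-truth eigenpairs so oracle tests and
    recovery experiments can compare estimates against truth.
    """
    n = spec.n_neurons
    total = spec.total_shared_variance
    rng = np.random.default_rng(spec.eigenvector_seed)
    lam = np.zeros(n)
    if spec.family == "rank_one":
        lam[0] = total
        vecs = _haar_orthonormal(n, rng)
    elif spec.family == "rank_m":
        if spec.eigenvalues is not None:
            lam[: spec.m] = spec.eigenvalues
        else:
            w = 1.0 / np.arange(1, spec.m + 1)
            lam[: spec.m] = total * w / w.sum()
        vecs = _haar_orthonormal(n, rng)
    elif spec.family == "power_law":
        w = 1.0 / np.arange(1, n + 1)
        lam = total * w / w.sum()
        vecs = _haar_orthonormal(n, rng)
    else:  # independent
        lam = np.full(n, total / n)
        vecs = np.eye(n)
    sigma = (vecs * lam) @ vecs.T
    sigma = 0.5 * (sigma + sigma.T)
    return CovarianceTruth(sigma=sigma, eigenvalues=lam, eigenvectors=vecs)


@dataclass(frozen=True)
class PopulationModel:
    """Ground-truth two-condition Gaussian population model."""

    mu_a: np.ndarray
    mu_b: np.ndarray
    sigma: np.ndarray
    eps_indep: float
    truth: CovarianceTruth | None = field(repr=False, default=None)

    def __post_init__(self) -> None:
        mu_a = np.asarray(self.mu_a, dtype=float)
        mu_b = np.asarray(self.mu_b, dtype=float)
        sigma = np.asarray(self.sigma, dtype=float)
        if mu_a.shape != mu_b.shape or sigma.shape != (mu_a.size, mu_a.size):
            raise ConfigError("mean/covariance dimensions disagree")
        if self.eps_indep < 0:
            raise ConfigError("eps_indep must be nonnegative")
        evals = np.linalg.eigvalsh(0.5 * (sigma + sigma.T))
        if evals[0] < -1e-8 * max(evals[-1], 1.0):
            raise ConfigError("sigma is not positive semidefinite")
        object.__setattr__(self, "mu_a", mu_a)
        object.__setattr__(self, "mu_b", mu_b)
        object.__setattr__(self, "sigma", 0.5 * (sigma + sigma.T))

    @property
    def n_neurons(self) -> int:
        return self.mu_a.shape[0]

    @property
    def delta_mu(self) -> np.ndarray:
        return self.mu_a - self.mu_b

    @property
    def effective_sigma(self) -> np.ndarray:
        return self.sigma + self.eps_indep * np.eye(self.n_neurons)


def default_eps_indep(spec: CovarianceSpec) -> float:
    """Default independent noise: 10% of the mean shared variance per neuron."""
    return 0.1 * spec.total_shared_variance / spec.n_neurons


def _signal_direction(
    truth: CovarianceTruth,
    alignments: Sequence[float],
    rng: np.random.Generator,
) -> np.ndarray:
    """Unit vector with exact cosines ``alignments`` to the leading true
    eigenvectors, remainder random in their orthocomplement."""
    c = np.asarray(alignments, dtype=float)
    if (c**2).sum() > 1 + 1e-12:
        raise ConfigError("sum of squared alignments exceeds 1")
    n = truth.sigma.shape[0]
    lead = truth.eigenvectors[:, : c.size]
    u = lead @ c
    rest = float(np.sqrt(max(1.0 - (c**2).sum(), 0.0)))
    if rest > 0:
        if c.size >= n:
            raise ConfigError("alignments fix every dimension; no remainder left")
        v = rng.standard_normal(n)
        v -= lead @ (lead.T @ v)
        u = u + rest * v / np.linalg.norm(v)
    return u / np.linalg.norm(u)


def make_population_model(
    spec: CovarianceSpec,
    delta_mu_magnitude: float,
    alignments: Sequence[float] = (),
    eps_indep: float | None = None,
    seed: int | np.random.Generator | None = None,
) -> PopulationModel:
    """Build a two-condition model: ``mu_a = 0``, ``mu_b = delta * u``.

    ``alignments`` are exact cosines between the signal direction ``u`` and
    the leading shared eigenvectors (e.g. ``(0.8,)`` for strong overlap
    with ``e_1``, ``(0.0, 0.0)`` for exact orthogonality to ``e_1`` and
    ``e_2``); the remaining component of ``u`` is drawn uniformly from the
    orthocomplement of the constrained eigenvectors.
    """
    rng = np.random.default_rng(seed)
    truth = make_covariance(spec)
    n = spec.n_neurons
    u = _signal_direction(truth, alignments, rng)
    eps = default_eps_indep(spec) if eps_indep is None else float(eps_indep)
    return PopulationModel(
        mu_a=np.zeros(n),
        mu_b=delta_mu_magnitude * u,
        sigma=truth.sigma,
        eps_indep=eps,
        truth=truth,
    )


def sample_population(
    model: PopulationModel,
    k: int,
    seed: int | np.random.Generator | None = None,
    labels: tuple[str, str] = ("a", "b"),
) -> ResponseSet:
    """Draw ``k`` trials per condition from the model.

    Deterministic for a fixed integer seed.  The returned ResponseSet has
    ``2k`` rows (condition ``a`` first) and generic neuron ids ``n1..nN``.
    """
    if k < 2:
        raise ConfigError("k must be >= 2")
    rng = np.random.default_rng(seed)
    n = model.n_neurons
    chol = np.linalg.cholesky(
        model.effective_sigma + 1e-12 * np.eye(n)
    )
    a = model.mu_a + rng.standard_normal((k, n)) @ chol.T
    b = model.mu_b + rng.standard_normal((k, n)) @ chol.T
    return ResponseSet(
        counts=np.vstack([a, b]),
        condition_labels=(labels[0],) * k + (labels[1],) * k,
        neuron_ids=tuple(f"n{i + 1}" for i in range(n)),
    )


def analytic_dprime_squared(model: PopulationModel) -> float:
    """Ground-truth d'2 of the model: ``dmu^T (Sigma_eff)^{-1} dmu``."""
    dmu = model.delta_mu
    return float(dmu @ np.linalg.solve(model.effective_sigma, dmu))


def eigenvector_recovery_curve(
    spec: CovarianceSpec,
    eps_indep: float | None = None,
    k_grid: Sequence[int] = (5, 10, 25, 50, 100, 250),
    n_reps: int = 100,
    seed: int | np.random.Generator | None = None,
) -> pd.DataFrame:
    """How well PCA recovers the true leading eigenvector vs. sample size.

    For each ``k`` and replicate: draw ``k`` samples from
    ``N(0, Sigma + eps I)``, mean-center them, estimate the leading
    eigenvector of the sample covariance, and record the absolute cosine
    similarity with the true ``e_1``.  Returns a table with columns
    ``k``, ``mean_abs_cosine``, ``sem``.

    For the ``independent`` family the true leading eigenvector is taken as
    the first coordinate axis; the direction is arbitrary by symmetry, which
    is exactly why recovery fails there — that is the point of the control.
    """
    if n_reps < 2:
        raise ConfigError("n_reps must be >= 2")
    rng = np.random.default_rng(seed)
    truth = make_covariance(spec)
    eps = default_eps_indep(spec) if eps_indep is None else float(eps_indep)
    n = spec.n_neurons
    chol = np.linalg.cholesky(truth.sigma + (eps + 1e-12) * np.eye(n))
    e1 = truth.eigenvectors[:, 0]
    rows = []
    for k in k_grid:
        if k < 2:
            raise ConfigError("every k must be >= 2")
        cosines = np.empty(n_reps)
        for r in range(n_reps):
            x = rng.standard_normal((k, n)) @ chol.T
            xc = x - x.mean(axis=0)
            cov = np.cov(xc, rowvar=False, ddof=1)
            _, vecs = np.linalg.eigh(cov)
            cosines[r] = abs(vecs[:, -1] @ e1)
        rows.append(
            {
                "k": int(k),
                "mean_abs_cosine": cosines.mean(),
                "sem": cosines.std(ddof=1) / np.sqrt(n_reps),
            }
        )
    return pd.DataFrame(rows)


def covariance_estimator_variance(
    model: PopulationModel,
    pair_indices: tuple[int, int] = (0, 1),
    k_grid: Sequence[int] = (10, 50, 200),
    n_reps: int = 2000,
    seed: int | np.random.Generator | None = None,
) -> pd.DataFrame:
    """Empirical variance of a single sample-covariance entry vs. sample size.

    For Gaussian data the sample covariance entry ``S_ij`` (unbiased,
    ``k - 1`` denominator) has variance
    ``(sigma_ii sigma_jj + sigma_ij^2) / (k - 1)`` — the closed form the
    empirical column is compared against.  Columns: ``k``,
    ``var_empirical``, ``var_analytic``, ``se_empirical`` (Monte-Carlo
    standard error of the empirical variance, from the fourth central
    moment).
    """
    if n_reps < 2:
        raise ConfigError("n_reps must be >= 2")
    i, j = pair_indices
    rng = np.random.default_rng(seed)
    sig = model.effective_sigma
    n = model.n_neurons
    chol = np.linalg.cholesky(sig + 1e-12 * np.eye(n))
    analytic_num = sig[i, i] * sig[j, j] + sig[i, j] ** 2
    rows = []
    for k in k_grid:
        est = np.empty(n_reps)
        for r in range(n_reps):
            x = model.mu_a + rng.standard_normal((k, n)) @ chol.T
            xc = x - x.mean(axis=0)
            est[r] = xc[:, i] @ xc[:, j] / (k - 1)
        var_emp = est.var(ddof=1)
        m4 = np.mean((est - est.mean()) ** 4)
        se = np.sqrt(max(m4 - var_emp**2, 0.0) / n_reps)
        rows.append(
            {
                "k": int(k),
                "var_empirical": var_emp,
                "var_analytic": analytic_num / (k - 1),
                "se_empirical": se,
            }
        )
    return pd.DataFrame(rows)
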