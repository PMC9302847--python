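import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ddrkit import (
    ConditionPair,
    DegenerateVarianceError,
    InsufficientDataError,
    ShapeError,
    cross_validated_dprime,
    dprime_squared,
    make_population_model,
    optimal_decoder,
    projected_dprime_squared,
    sample_population,
)
from ddrkit.simulate import CovarianceSpec, analytic_dprime_squared

from conftest import make_response_set

SIGMA_04 = np.array([[1.0, 0.4], [0.4, 1.0]])


class TestDPrimeSquared:
    @pytest.mark.parametrize(
        "mu_a, mu_b, sigma, expected",
        [
            ([2.0], [0.0], [[1.0]], 4.0),
            ([1.0, 1.0], [0.0, 0.0], np.eye(2), 2.0),
            ([1.0, 1.0], [0.0, 0.0], SIGMA_04, 1.2 / 0.84),
            ([1.0, -1.0], [0.0, 0.0], SIGMA_04, 2.8 / 0.84),
        ],
    )
    def test_closed_forms(self, mu_a, mu_b, sigma, expected):
        got = dprime_squared(np.asarray(mu_a), np.asarray(mu_b), np.asarray(sigma))
        assert got == pytest.approx(expected, abs=1e-12)

    def test_orthogonal_noise_beats_aligned_noise(self):
        # Shared covariance helps when it is orthogonal to the signal.
        aligned = dprime_squared(np.array([1.0, 1.0]), np.zeros(2), SIGMA_04)
        orthogonal = dprime_squared(np.array([1.0, -1.0]), np.zeros(2), SIGMA_04)
        assert orthogonal > aligned

    def test_singular_sigma_uses_pseudoinverse(self):
        sigma = np.outer([1.0, 1.0], [1.0, 1.0])  # rank one
        val = dprime_squared(np.array([1.0, 0.0]), np.zeros(2), sigma)
        assert np.isfinite(val) and val >= 0

    def test_asymmetric_sigma_rejected(self):
        with pytest.raises(ShapeError):
            dprime_squared(
                np.array([1.0, 0.0]), np.zeros(2), np.array([[1.0, 0.5], [0.0, 1.0]])
            )

    def test_dimension_mismatch_rejected(self):
        with pytest.raises(ShapeError):
            dprime_squared(np.array([1.0, 0.0]), np.zeros(2), np.eye(3))

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(n=st.integers(2, 4), seed=st.integers(0, 10_000))
    def test_invariant_under_invertible_linear_maps(self, n, seed):
        rng = np.random.default_rng(seed)
        mu_a = rng.standard_normal(n)
        mu_b = rng.standard_normal(n)
        x = rng.standard_normal((3 * n, n))
        sigma = x.T @ x / (3 * n) + 0.1 * np.eye(n)
        base = dprime_squared(mu_a, mu_b, sigma)
        t = rng.standard_normal((n, n)) + 0.5 * np.eye(n)
        while abs(np.linalg.det(t)) < 1e-3:
            t = rng.standard_normal((n, n)) + 0.5 * np.eye(n)
        mapped = dprime_squared(t @ mu_a, t @ mu_b, t @ sigma @ t.T)
        assert mapped == pytest.approx(base, rel=1e-8, abs=1e-8)

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(n=st.integers(1, 4), rank=st.integers(0, 4), seed=st.integers(0, 10_000))
    def test_nonnegative_for_psd_sigma(self, n, rank, seed):
        rng = np.random.default_rng(seed)
        rank = min(rank, n)
        x = rng.standard_normal((max(rank, 1), n))
        sigma = x.T @ x if rank else np.zeros((n, n))
        assert dprime_squared(rng.standard_normal(n), rng.standard_normal(n), sigma) >= 0


class TestOptimalDecoder:
    def test_identity_covariance_returns_delta_mu(self):
        dmu = np.array([2.0, -1.0])
        assert np.allclose(optimal_decoder(dmu, np.eye(2)), dmu)

    def test_hand_inverted_2x2(self):
        w = optimal_decoder(np.array([1.0, 1.0]), SIGMA_04)
        assert np.allclose(w, [0.6 / 0.84, 0.6 / 0.84], atol=1e-12)

    def test_decoder_rotates_away_from_shared_noise(self):
        w = optimal_decoder(np.array([1.0, 0.0]), SIGMA_04)
        assert np.allclose(w, [1.0 / 0.84, -0.4 / 0.84], atol=1e-12)
        # discounts the correlated neuron even though delta mu ignores it
        assert w[1] < 0


class TestProjectedDPrime:
    def test_hand_arithmetic(self):
        val = projected_dprime_squared(
            np.array([1.0]), np.array([[-1.0], [1.0]]), np.array([[3.0], [5.0]])
        )
        assert val == pytest.approx(8.0)

    def test_identical_sets_give_zero(self):
        a = np.array([[1.0], [2.0], [3.0]])
        assert projected_dprime_squared(np.array([1.0]), a, a.copy()) == 0.0

    def test_large_sample_matches_analytic(self, rng):
        k = 100_000
        a = rng.standard_normal((k, 1)) * 1.0
        b = 2.0 + rng.standard_normal((k, 1))
        val = projected_dprime_squared(np.array([1.0]), a, b)
        se = np.sqrt(8.0 * (4.0 + 2.0) / k)  # rough delta-method scale
        assert abs(val - 4.0) < 3 * max(se, 0.05)

    def test_zero_variance_raises(self):
        a = np.array([[1.0], [1.0]])
        b = np.array([[2.0], [2.0]])
        with pytest.raises(DegenerateVarianceError):
            projected_dprime_squared(np.array([1.0]), a, b)


class TestInformationOrdering:
    """Reducing to the true dDR plane can never create information, and
    loses none exactly when the covariance outside the plane is isotropic
    and delta mu lies inside it (rank-one shared noise)."""

    @staticmethod
    def _plane_dprime(model):
        dmu = model.delta_mu
        s = dmu / np.linalg.norm(dmu)
        e1 = model.truth.eigenvectors[:, 0]
        n1 = e1 - (e1 @ s) * s
        n1 /= np.linalg.norm(n1)
        plane = np.vstack([s, n1])
        sig = plane @ model.effective_sigma @ plane.T
        return dprime_squared(plane @ model.mu_a, plane @ model.mu_b, sig)

    @pytest.mark.parametrize("family", ["rank_one", "rank_m", "power_law"])
    def test_plane_never_exceeds_full_rank(self, family):
        spec = CovarianceSpec(family=family, n_neurons=12,
                              total_shared_variance=5.0, m=3,
                              eigenvector_seed=17)
        model = make_population_model(spec, 2.0, alignments=(0.5, 0.3),
                                      eps_indep=0.1, seed=18)
        assert self._plane_dprime(model) <= analytic_dprime_squared(model) + 1e-10

    def test_equality_for_rank_one_shared_noise(self):
        spec = CovarianceSpec(family="rank_one", n_neurons=12,
                              total_shared_variance=5.0, eigenvector_seed=19)
        model = make_population_model(spec, 2.0, alignments=(0.4,),
                                      eps_indep=0.1, seed=20)
        assert self._plane_dprime(model) == pytest.approx(
            analytic_dprime_squared(model), rel=1e-10
        )


@pytest.fixture(scope="module")
def gap_model():
    spec = CovarianceSpec(family="rank_one", n_neurons=2,
                          total_shared_variance=0.8, eigenvector_seed=5)
    # 2-neuron model with pairwise covariance; modest mean separation
    model = make_population_model(spec, 2.0, alignments=(0.5,),
                                  eps_indep=0.6, seed=5)
    return model


class TestCrossValidatedDPrime:
    def test_permuted_labels_match_null_separation(self, gap_model):
        # Independent oracle: data with genuinely identical means define the
        # null distribution of the validation statistic; permuting labels of
        # separated data must land in the same place on average.
        rng = np.random.default_rng(99)
        pair = ConditionPair("a", "b")
        n_rep, k = 200, 12
        null_vals, perm_vals = [], []
        null_model = make_population_model(
            CovarianceSpec(family="rank_one", n_neurons=2,
                           total_shared_variance=0.8, eigenvector_seed=5),
            0.0, alignments=(0.5,), eps_indep=0.6, seed=5,
        )
        for r in range(n_rep):
            rs0 = sample_population(null_model, k, seed=rng)
            null_vals.append(
                cross_validated_dprime(rs0, pair, reducer="fullrank", seed=rng)
                .dprime_sq_test
            )
            rs = sample_population(gap_model, k, seed=rng)
            perm = rng.permutation(rs.n_trials)
            shuffled = type(rs)(
                counts=rs.counts,
                condition_labels=tuple(rs.condition_labels[i] for i in perm),
                neuron_ids=rs.neuron_ids,
            )
            perm_vals.append(
                cross_validated_dprime(shuffled, pair, reducer="fullrank", seed=rng)
                .dprime_sq_test
            )
        null_vals = np.asarray(null_vals)
        perm_vals = np.asarray(perm_vals)
        se = np.sqrt(null_vals.var(ddof=1) / n_rep + perm_vals.var(ddof=1) / n_rep)
        assert abs(perm_vals.mean() - null_vals.mean()) < 3 * se

    def test_train_exceeds_test_on_average(self, gap_model):
        rng = np.random.default_rng(7)
        pair = ConditionPair("a", "b")
        diffs = []
        for r in range(200):
            rs = sample_population(gap_model, 10, seed=rng)
            res = cross_validated_dprime(rs, pair, reducer="fullrank", seed=rng)
            diffs.append(res.dprime_sq_train - res.dprime_sq_test)
        assert np.mean(diffs) > 0

    def test_fullrank_converges_to_analytic(self, gap_model):
        rng = np.random.default_rng(11)
        pair = ConditionPair("a", "b")
        truth = analytic_dprime_squared(gap_model)
        vals = [
            cross_validated_dprime(
                sample_population(gap_model, 20_000, seed=rng),
                pair, reducer="fullrank", seed=rng,
            ).dprime_sq_test
            for _ in range(5)
        ]
        assert np.mean(vals) == pytest.approx(truth, rel=0.05)

    def test_split_too_small_raises(self, gap_model):
        rs = sample_population(gap_model, 3, seed=0)
        with pytest.raises(InsufficientDataError):
            cross_validated_dprime(rs, ConditionPair("a", "b"), split=0.5, seed=0)

    def test_seeded_split_is_reproducible(self, gap_model):
        rs = sample_population(gap_model, 20, seed=1)
        pair = ConditionPair("a", "b")
        r1 = cross_validated_dprime(rs, pair, reducer="ddr", seed=42)
        r2 = cross_validated_dprime(rs, pair, reducer="ddr", seed=42)
        assert r1.dprime_sq_train == r2.dprime_sq_train
        assert r1.dprime_sq_test == r2.dprime_sq_test
        assert r1.split_info == r2.split_info

    @pytest.mark.parametrize("reducer,kwargs,d", [
        ("ddr", {"n_noise_dims": 1}, 2),
        ("ddr", {"n_noise_dims": 2}, 3),
        ("tapca", {}, 1),
        ("stpca", {"n_components": 2}, 2),
        ("fullrank", {}, 5),
    ])
    def test_reducers_report_their_dimension(self, reducer, kwargs, d):
        spec = CovarianceSpec(family="power_law", n_neurons=5,
                              total_shared_variance=2.0, eigenvector_seed=0)
        model = make_population_model(spec, 2.0, seed=0)
        rs = sample_population(model, 20, seed=0)
        res = cross_validated_dprime(
            rs, ConditionPair("a", "b"), reducer=reducer, seed=0, **kwargs
        )
        assert res.d == d
        assert res.dprime_sq_train >= 0
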