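"""Davidian density construction, EM fitting, and order selection."""

import numpy as np
import pytest
from scipy import optimize
from scipy.stats import norm

from ordlmi.davidian import (
    DavidianDensity,
    _normal_moments,
    density_summary,
    fit_graded_davidian,
    hannan_quinn,
    select_order,
)


class TestDensity:
    def test_order_zero_is_standard_normal(self):
        d = DavidianDensity(order=0)
        assert d.pdf(0.0) == pytest.approx(norm.pdf(0.0), abs=1e-12)
        z = np.linspace(-4, 4, 9)
        np.testing.assert_allclose(d.pdf(z), norm.pdf(z), atol=1e-12)

    @pytest.mark.parametrize("k", [1, 2, 3, 5, 7])
    def test_normalization_for_random_angles(self, k):
        rng = np.random.default_rng(k)
        d = DavidianDensity(order=k, phi_angles=rng.uniform(-1.5, 1.5, k))
        z, h = d.grid()
        assert np.trapezoid(h, z) == pytest.approx(1.0, abs=1e-6)

    def test_quadrature_moments_match_analytic_oracle(self):
        """Moments of P(z)^2 phi(z) computed analytically from normal
        moments: E[Z^m h] = sum_jl c_j c_l E[Z^{j+l+m}]."""
        rng = np.random.default_rng(3)
        k = 4
        d = DavidianDensity(order=k, phi_angles=rng.uniform(-1.0, 1.0, k))
        c = d.poly_coeffs
        nm = _normal_moments(2 * k + 3)

        def raw_moment(m):
            total = 0.0
            for j in range(k + 1):
                for l in range(k + 1):
                    total += c[j] * c[l] * nm[j + l + m]
            return total

        mu = raw_moment(1)
        var = raw_moment(2) - mu**2
        mu3 = raw_moment(3) - 3 * mu * raw_moment(2) + 2 * mu**3
        skew = mu3 / var**1.5
        qm, qv, qg = d.moments()
        assert qm == pytest.approx(mu, abs=1e-4)
        assert qv == pytest.approx(var, abs=1e-4)
        assert qg == pytest.approx(skew, abs=1e-3)

    def test_can_approximate_bimodal_target(self):
        """A moderate-order curve fitted to a two-component mixture shows
        two local maxima."""
        z = np.linspace(-4, 4, 401)
        target = 0.5 * norm.pdf(z, -1.5, 0.6) + 0.5 * norm.pdf(z, 1.5, 0.6)

        def loss(angles):
            d = DavidianDensity(order=6, phi_angles=angles)
            return np.sum((d.pdf(z) - target) ** 2)

        res = optimize.minimize(loss, 0.1 * np.ones(6), method="Nelder-Mead",
                                options={"maxiter": 4000, "fatol": 1e-12})
        h = DavidianDensity(order=6, phi_angles=res.x).pdf(z)
        interior = (h[1:-1] > h[:-2]) & (h[1:-1] > h[2:])
        peaks = z[1:-1][interior & (h[1:-1] > 0.05)]
        assert (peaks < 0).any() and (peaks > 0).any()

    def test_standardized_grid_self_check(self):
        rng = np.random.default_rng(5)
        d = DavidianDensity(order=3, phi_angles=rng.uniform(-1, 1, 3))
        m, v, g, (z_std, h_std) = density_summary(d)
        mass = np.trapezoid(h_std, z_std)
        mean = np.trapezoid(h_std * z_std, z_std) / mass
        var = np.trapezoid(h_std * (z_std - mean) ** 2, z_std) / mass
        assert abs(mean) < 1e-8
        assert abs(var - 1.0) < 1e-6

    def test_order_zero_summary(self):
        m, v, g, _ = density_summary(DavidianDensity(order=0))
        assert (m, v, g) == pytest.approx((0.0, 1.0, 0.0), abs=1e-6)

    def test_nonfinite_angles_rejected(self):
        with pytest.raises(ValueError, match="finite"):
            DavidianDensity(order=1, phi_angles=[np.nan])


class TestHannanQuinn:
    def test_closed_form(self):
        hq = hannan_quinn(-1000.0, 10, 1000)
        assert hq == pytest.approx(2000 + 20 * np.log(np.log(1000)), abs=1e-9)
        assert hq == pytest.approx(2038.65, abs=0.01)

    def test_penalty_monotonicity(self):
        assert hannan_quinn(-500.0, 5, 100) < hannan_quinn(-500.0, 8, 100)

    def test_zero_params(self):
        assert hannan_quinn(-500.0, 0, 100) == 1000.0

    def test_tiny_n_rejected(self):
        with pytest.raises(ValueError, match="log"):
            hannan_quinn(-1.0, 1, 2)


def _small_sample(seed=0, n=800, fam="normal", fp=None):
    from ordlmi.synthetic import (
        SyntheticConfig, generate_latent_trajectories, render_ordinal_items,
    )

    cfg = SyntheticConfig(
        n_subjects=n, n_items=4, n_sessions=1,
        latent_means=np.zeros(1), latent_variances=np.ones(1),
        latent_family=fam, family_params=fp or {}, seed=seed,
    )
    lat = generate_latent_trajectories(cfg)
    return render_ordinal_items(lat, cfg).responses[:, :, 0]


class TestEmFit:
    def test_loglik_monotone_every_iteration(self):
        X = _small_sample()
        _, _, _, info = fit_graded_davidian(X, order=3, max_iter=60)
        path = info["loglik_path"]
        assert np.all(np.diff(path) >= -1e-8)

    def test_pattern_probabilities_sum_to_one(self):
        """Brute-force enumeration of all C^I response patterns under the
        fitted model integrates to 1."""
        from itertools import product

        from ordlmi.davidian import _category_probs

        X = _small_sample(seed=1, n=600)
        items, dens, _, _ = fit_graded_davidian(X, order=3, max_iter=80)
        z = np.linspace(-6, 6, 101)
        w = dens.pdf(z)
        w = w / w.sum()
        P = [
            _category_probs(items.discrimination[i], items.boundaries[i], z)
            for i in range(4)
        ]
        total = 0.0
        for pattern in product(range(4), repeat=4):
            lik = np.ones_like(z)
            for i, c in enumerate(pattern):
                lik = lik * P[i][c]
            total += np.sum(lik * w)
        assert total == pytest.approx(1.0, abs=1e-8)

    def test_order_zero_matches_normal_latent_ml(self):
        """With k = 0 the EM solution sits at a stationary point of the
        plain normal-latent marginal likelihood (checked by numerical
        gradient)."""
        from ordlmi.davidian import _category_probs

        X = _small_sample(seed=2, n=600)
        items, dens, ll, _ = fit_graded_davidian(X, order=0, max_iter=400)
        z = np.linspace(-6, 6, 101)
        w = norm.pdf(z)
        w = w / w.sum()
        patterns, counts = np.unique(X, axis=0, return_counts=True)

        def negll(x):
            a = x[:4]
            b = x[4:].reshape(4, 3)
            ll_pq = np.zeros((len(patterns), z.size))
            for i in range(4):
                P = _category_probs(a[i], np.sort(b[i]), z)
                ll_pq += np.log(P[patterns[:, i], :])
            from scipy.special import logsumexp
            return -np.sum(counts * logsumexp(ll_pq + np.log(w), axis=1))

        x_hat = np.concatenate(
            [items.discrimination, items.boundaries.ravel()]
        )
        f0 = negll(x_hat)
        assert f0 == pytest.approx(-ll, abs=1e-6)
        grad = optimize.approx_fprime(x_hat, negll, 1e-6)
        assert np.max(np.abs(grad)) < 0.5  # flat at the optimum, n=600 scale

    def test_too_few_items_rejected(self):
        with pytest.raises(ValueError, match="3 items"):
            fit_graded_davidian(np.zeros((100, 2), dtype=int) , order=3)


class TestSelectOrder:
    def test_singleton_candidate(self):
        X = _small_sample(seed=3, n=500)
        best, results, table = select_order(X, orders=[3], max_iter=60)
        assert best == 3 and set(results) == {3}

    def test_empty_candidates_rejected(self):
        with pytest.raises(ValueError, match="nonempty"):
            select_order(np.zeros((100, 4), dtype=int), orders=[])


def test_davidian_family_generator_standardized():
    """The synthetic 'davidian' latent family delivers the configured
    session mean and variance."""
    from ordlmi.synthetic import SyntheticConfig, generate_latent_trajectories

    cfg = SyntheticConfig(
        n_subjects=50_000, n_items=3, n_sessions=1,
        latent_means=np.array([-0.5]), latent_variances=np.array([2.0]),
        latent_family="davidian",
        family_params={"phi_angles": [0.4, 0.2, -0.3]}, seed=9,
    )
    x = generate_latent_trajectories(cfg)[:, 0]
    assert x.mean() == pytest.approx(-0.5, abs=0.03)
    assert x.var() == pytest.approx(2.0, abs=0.06)
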