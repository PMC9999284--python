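"""Model ledger bookkeeping, implied moments, and DWLS fitting."""

from types import SimpleNamespace

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from ordlmi.datatypes import LongitudinalOrdinalData
from ordlmi.sem import (
    LEVELS,
    LmiModel,
    build_model,
    constant_sd_reparameterization,
    delta_df,
    fit_dwls,
    fix_variance_constraint,
    model_implied_moments,
)


class TestDfLedger:
    def test_seven_item_thirteen_session_design(self):
        specs = {lvl: build_model(lvl, 7, 13, 4) for lvl in LEVELS}
        assert delta_df(specs["configural"], specs["loadings"]) == 72
        assert delta_df(specs["loadings"], specs["threshold"]) == 156
        assert delta_df(specs["threshold"], specs["unique_factor"]) == 84

    def test_twenty_item_four_session_design(self):
        specs = {lvl: build_model(lvl, 20, 4, 4) for lvl in LEVELS}
        assert delta_df(specs["configural"], specs["loadings"]) == 57
        assert delta_df(specs["threshold"], specs["unique_factor"]) == 60

    def test_reduced_category_item_changes_threshold_count(self):
        """A category empty at one session drops one sample threshold and
        one session-specific free threshold, shrinking the
        loadings -> threshold df step by exactly one (117 -> 116 on the
        20-item, 4-session design)."""
        loadings_f = build_model("loadings", 20, 4, 4)
        threshold_f = build_model("threshold", 20, 4, 4)
        assert delta_df(loadings_f, threshold_f) == 117

        cats = np.full((20, 4), 4)
        cats[0, 3] = 3  # one item misses its top category at one session
        loadings_r = build_model("loadings", 20, 4, 4,
                                 n_categories_per_item=cats)
        threshold_r = build_model("threshold", 20, 4, 4,
                                  n_categories_per_item=cats)
        assert delta_df(loadings_r, threshold_r) == 116

    def test_single_session_collapses_all_levels(self):
        dfs = {build_model(lvl, 7, 1, 4).df for lvl in LEVELS}
        assert len(dfs) == 1

    def test_identical_specs_give_zero(self):
        a = build_model("loadings", 7, 13, 4)
        b = build_model("loadings", 7, 13, 4)
        assert delta_df(a, b) == 0

    def test_non_nested_order_warns(self):
        a = build_model("threshold", 7, 4, 4)
        b = build_model("configural", 7, 4, 4)
        with pytest.warns(UserWarning, match="not nested"):
            delta_df(a, b)

    def test_unsupported_level_rejected(self):
        with pytest.raises(ValueError, match="unknown level"):
            build_model("scalar", 7, 4, 4)

    @given(
        I=st.integers(min_value=3, max_value=10),
        T=st.integers(min_value=1, max_value=8),
        C=st.integers(min_value=2, max_value=5),
    )
    @settings(max_examples=60, deadline=None, derandomize=True)
    def test_ledger_count_matches_independent_closed_forms(self, I, T, C):
        """Free-parameter counts re-derived algebraically, independent of
        the ledger enumeration."""
        V = I * T
        moments = V * (C - 1) + V * (V - 1) // 2
        cross = T * (T - 1) // 2
        expected = {
            "configural": I * T * C + cross,
            "loadings": I + I * T * (C - 1) + (T - 1) + cross,
            "threshold": I * C + 2 * (T - 1) + I * (T - 1) + cross,
            "unique_factor": I * C + 2 * (T - 1) + cross,
        }
        for lvl in LEVELS:
            spec = build_model(lvl, I, T, C)
            free = expected[lvl] if T > 1 else expected["configural"]
            assert spec.n_free_parameters() == free
            assert spec.df == moments - free


class TestFixedVariance:
    def test_thirteen_sessions_add_twelve_constraints(self):
        spec = build_model("unique_factor", 7, 13, 4)
        assert fix_variance_constraint(spec).df - spec.df == 12

    def test_two_sessions_add_one(self):
        spec = build_model("unique_factor", 7, 2, 4)
        assert fix_variance_constraint(spec).df - spec.df == 1

    def test_single_session_unchanged(self):
        spec = build_model("unique_factor", 7, 1, 4)
        assert fix_variance_constraint(spec).df == spec.df

    def test_requires_unique_factor_level(self):
        with pytest.raises(ValueError, match="unique_factor"):
            fix_variance_constraint(build_model("loadings", 7, 4, 4))


def _unit_values(I, T, Cm1=3, lam=1.0, phi_ts=0.0):
    tau = np.repeat(
        np.tile(np.array([-1.0, 0.0, 1.0])[:Cm1], (I, 1))[:, :, None], T, axis=2
    )
    Phi = np.full((T, T), phi_ts)
    np.fill_diagonal(Phi, 1.0)
    return {
        "lam": np.full((I, T), lam),
        "tau": tau,
        "psi": np.ones((I, T)),
        "alpha": np.zeros(T),
        "Phi": Phi,
    }


class TestImpliedMoments:
    def test_unit_case(self):
        spec = build_model("configural", 3, 2, 4)
        corr, thr = model_implied_moments(spec, _unit_values(3, 2))
        I = 3
        within = corr[:I, :I]
        cross = corr[:I, I:]
        offdiag = within[np.triu_indices(I, k=1)]
        np.testing.assert_allclose(offdiag, 0.5, atol=1e-12)
        np.testing.assert_allclose(cross, 0.0, atol=1e-12)

    def test_null_loading_item(self):
        spec = build_model("configural", 3, 2, 4)
        values = _unit_values(3, 2, phi_ts=0.5)
        values["lam"][0, :] = 0.0
        corr, thr = model_implied_moments(spec, values)
        for t in (0, 1):
            v = t * 3
            row = np.delete(corr[v], v)
            np.testing.assert_allclose(row, 0.0, atol=1e-12)
            np.testing.assert_allclose(thr[v], [-1.0, 0.0, 1.0], atol=1e-12)

    def test_scale_invariance(self):
        """Jointly rescaling (lambda, sqrt(psi), tau) leaves implied
        moments unchanged."""
        spec = build_model("configural", 4, 2, 4)
        rng = np.random.default_rng(0)
        values = _unit_values(4, 2, phi_ts=0.4)
        values["lam"] += rng.uniform(0, 0.5, values["lam"].shape)
        values["alpha"] = np.array([0.0, -0.7])
        s = 2.0
        scaled = {
            "lam": values["lam"] * s,
            "tau": values["tau"] * s,
            "psi": values["psi"] * s**2,
            "alpha": values["alpha"].copy(),
            "Phi": values["Phi"].copy(),
        }
        c1, t1 = model_implied_moments(spec, values)
        c2, t2 = model_implied_moments(spec, scaled)
        np.testing.assert_allclose(c1, c2, atol=1e-12)
        np.testing.assert_allclose(t1, t2, atol=1e-12)

    def test_non_pd_phi_rejected(self):
        spec = build_model("configural", 3, 2, 4)
        values = _unit_values(3, 2, phi_ts=1.5)
        with pytest.raises(ValueError, match="positive definite"):
            model_implied_moments(spec, values)


class TestConstantSd:
    def test_unit_variances_are_identity(self):
        values = _unit_values(3, 2, phi_ts=0.5)
        out = constant_sd_reparameterization(values)
        np.testing.assert_allclose(out["lam"], values["lam"], atol=1e-14)
        np.testing.assert_allclose(out["alpha"], values["alpha"], atol=1e-14)

    def test_closed_form_rescaling(self):
        values = _unit_values(3, 2, phi_ts=0.5)
        values["alpha"] = np.array([0.0, -1.4])
        values["Phi"] = np.array([[1.0, 0.5 * np.sqrt(3)],
                                  [0.5 * np.sqrt(3), 3.0]])
        out = constant_sd_reparameterization(values)
        assert out["alpha"][1] == pytest.approx(-1.4 / np.sqrt(3.0))
        np.testing.assert_allclose(np.diag(out["Phi"]), 1.0)

    def test_preserves_implied_moments_to_1e10(self, recovery_sample):
        model = LmiModel(level="unique_factor").fit(recovery_sample)
        values = model.result_.estimates
        repar = constant_sd_reparameterization(values)
        c1, t1 = model_implied_moments(model.spec_, values)
        c2, t2 = model_implied_moments(model.spec_, repar)
        assert np.max(np.abs(c1 - c2)) < 1e-10
        assert np.max(np.abs(t1 - t2)) < 1e-10


def _synthetic_sample(spec, values, n=10_000):
    """Exact-population sample object whose moments equal the implied
    moments of ``values``."""
    corr, thr = model_implied_moments(spec, values)
    V = corr.shape[0]
    I = spec.n_items
    T = spec.n_sessions
    labels = [f"item_{i + 1}@session_{t + 1}" for t in range(T)
              for i in range(I)]
    return SimpleNamespace(
        correlation_=corr,
        thresholds_=[thr[v] for v in range(V)],
        pair_n_=np.full((V, V), n),
        avar_rho_=np.full((V, V), 1.0 / n),
        labels_=labels,
        n_categories_=spec.n_categories,
    )


class TestDwlsFit:
    def test_zero_discrepancy_fixed_point(self):
        """Sample moments exactly equal to a ledger-complete parameter
        set's implied moments: the fit reproduces them with T ~ 0."""
        spec = build_model("unique_factor", 5, 3, 4)
        values = _unit_values(5, 3, lam=0.9, phi_ts=0.5)
        values["alpha"] = np.array([0.0, -0.4, -0.8])
        values["Phi"] = np.array(
            [[1.0, 0.5, 0.4], [0.5, 1.3, 0.6], [0.4, 0.6, 1.6]]
        )
        sample = _synthetic_sample(spec, values)
        res = fit_dwls(sample, spec)
        assert res.T_stat < 1e-3
        np.testing.assert_allclose(
            res.estimates["alpha"], values["alpha"], atol=0.01
        )
        np.testing.assert_allclose(
            np.diag(res.estimates["Phi"]), np.diag(values["Phi"]), atol=0.02
        )

    def test_single_replicate_recovery(self, recovery_config,
                                       recovery_sample):
        model = LmiModel(level="unique_factor").fit(recovery_sample)
        assert model.result_.converged
        np.testing.assert_allclose(
            model.latent_means_, recovery_config.latent_means, atol=0.12
        )
        np.testing.assert_allclose(
            np.diag(model.latent_cov_),
            recovery_config.latent_variances, rtol=0.15,
        )
        np.testing.assert_allclose(
            model.loadings_[:, 0], recovery_config.loadings, atol=0.1
        )

    def test_nesting_monotone_discrepancy(self, recovery_sample):
        """T is non-decreasing along the constraint sequence on the same
        sample moments and weights."""
        stats = [
            LmiModel(level=lvl).fit(recovery_sample).T_stat_
            for lvl in LEVELS
        ]
        for a, b in zip(stats, stats[1:]):
            assert b >= a - 1e-6, stats

    def test_reparameterization_preserves_T(self, recovery_sample):
        model = LmiModel(level="unique_factor").fit(recovery_sample)
        fixed = LmiModel(level="unique_factor",
                         fix_latent_variances=True).fit(recovery_sample)
        # the constraint costs fit; the reparameterization does not
        assert fixed.T_stat_ > model.T_stat_
        assert fixed.df_ == model.df_ + recovery_sample_T(recovery_sample) - 1

    def test_misspecified_two_factor_discrepancy_grows_with_n(self):
        """A one-factor fit to two-factor data has T/df growing in n."""
        ratios = []
        for n in (600, 4800):
            rng = np.random.default_rng(42)
            fa = rng.standard_normal(n)
            fb = rng.standard_normal(n)
            lam = 1.2
            liab = np.empty((n, 6))
            for i in range(6):
                f = fa if i < 3 else fb
                liab[:, i] = lam * f + rng.standard_normal(n)
            cuts = np.array([-0.5, 0.5, 1.5])
            resp = (liab[:, :, None] > cuts[None, None, :]).sum(axis=2)
            data = LongitudinalOrdinalData(resp[:, :, None], 4)
            model = LmiModel(level="configural").fit(data)
            ratios.append(model.T_stat_ / model.df_)
        assert ratios[1] > 2 * ratios[0]


def recovery_sample_T(sample):
    return len({lab.split("@")[1] for lab in sample.labels_})
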