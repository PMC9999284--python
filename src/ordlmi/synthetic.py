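"""Synthetic longitudinal ordinal cohorts.

Generates register-style therapy cohorts with the structure the downstream
analyses assume — a unidimensional latent trait per session with configurable
mean/variance/shape trajectory and cross-session correlation, ordinal items
produced through a liability-threshold link, and monotone dropout — plus
controlled violations of that structure (session-varying loadings or
thresholds, non-normal latent families).
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
from scipy import stats, optimize
from scipy.special import expit, ndtri

from .datatypes import MISSING, LongitudinalOrdinalData


class ConfigError(ValueError):
    """Invalid synthetic-cohort configuration."""


# Printed retention schedule for the 13-session anxiety therapy: 91% at
# session 2, 83% at session 3, declining to 44% at session 12, 10% at the
# follow-up session 13.  Sessions 4-11 are linearly interpolated between the
# printed anchors.
GAD7_RETENTION = (
    1.00, 0.91, 0.83, 0.787, 0.743, 0.70, 0.657, 0.613,
    0.57, 0.527, 0.483, 0.44, 0.10,
)
# Depression therapy assessments at sessions 1, 3, 7 and 8 (follow-up):
# 72% continued to session 3, 46% to session 7, 11% completed follow-up.
BDI_RETENTION = (1.00, 0.72, 0.46, 0.11)


@dataclass
class SyntheticConfig:
    """Generating parameters for one synthetic cohort.

    Latent structure: per-session trait theta_t with mean ``latent_means[t]``
    and variance ``latent_variances[t]``; cross-session correlation is either
    a full T x T matrix or an AR(1) lag-one correlation (default 0.8).
    Measurement: liability y*_ist = loadings[i] * theta_st + eps, with
    eps ~ N(0, unique_variances[i, t]); the response is the count of
    thresholds below y*.  Dropout: monotone, from a per-session retention
    schedule or a subject-level logistic model on standardized covariates.
    """

    n_subjects: int = 1000
    n_items: int = 7
    n_sessions: int = 13
    n_categories: int = 4
    latent_means: np.ndarray | None = None       # alpha_t, default declining
    latent_variances: np.ndarray | None = None   # phi_tt, default all 1
    latent_corr: np.ndarray | float = 0.8        # matrix or AR(1) rho
    latent_family: str = "normal"                # normal | lognormal_shifted | davidian
    family_params: dict = field(default_factory=dict)
    loadings: np.ndarray | None = None           # (I,) or (I, T)
    thresholds: np.ndarray | None = None         # (I, C-1) or (I, C-1, T)
    unique_variances: np.ndarray | float = 1.0   # scalar, (I,) or (I, T)
    retention: tuple | None = None               # per-session proportions
    dropout_logistic: dict | None = None         # {"odds_ratios": {...}, "rate": p}
    seed: int = 0

    def __post_init__(self):
        if self.n_subjects < 1 or self.n_items < 1 or self.n_sessions < 1:
            raise ConfigError("counts must be positive")
        if self.n_categories < 2:
            raise ConfigError("need at least 2 response categories")
        T, I, C = self.n_sessions, self.n_items, self.n_categories
        if self.latent_means is None:
            # gentle symptom decline over therapy, session-1 scale units
            self.latent_means = -1.2 * np.arange(T) / max(T - 1, 1)
        self.latent_means = np.asarray(self.latent_means, dtype=float)
        if self.latent_variances is None:
            self.latent_variances = np.ones(T)
        self.latent_variances = np.asarray(self.latent_variances, dtype=float)
        if self.latent_means.shape != (T,) or self.latent_variances.shape != (T,):
            raise ConfigError("latent trajectory length must equal n_sessions")
        if np.any(self.latent_variances < 0):
            raise ConfigError("latent variances must be nonnegative")
        if self.loadings is None:
            # standardized loading ~0.79 with psi = 1, typical of short
            # symptom inventories
            self.loadings = np.full(I, 1.3)
        self.loadings = np.asarray(self.loadings, dtype=float)
        if self.loadings.shape not in ((I,), (I, T)):
            raise ConfigError("loadings must have shape (I,) or (I, T)")
        if self.thresholds is None:
            self.thresholds = default_thresholds(I, C, self.loadings)
        self.thresholds = np.asarray(self.thresholds, dtype=float)
        if self.thresholds.shape not in ((I, C - 1), (I, C - 1, T)):
            raise ConfigError(
                "thresholds must have shape (I, C-1) or (I, C-1, T)"
            )
        if np.any(np.diff(self.thresholds, axis=1) <= 0):
            raise ConfigError("thresholds must be strictly increasing in c")
        uv = np.asarray(self.unique_variances, dtype=float)
        if uv.ndim == 0:
            uv = np.full((I, T), float(uv))
        elif uv.ndim == 1:
            if uv.shape != (I,):
                raise ConfigError("unique_variances vector must have length I")
            uv = np.repeat(uv[:, None], T, axis=1)
        elif uv.shape != (I, T):
            raise ConfigError("unique_variances must be scalar, (I,) or (I, T)")
        self.unique_variances = uv
        if np.any(self.unique_variances <= 0):
            raise ConfigError("unique variances must be positive")
        if self.retention is not None:
            r = np.asarray(self.retention, dtype=float)
            if r.shape != (T,):
                raise ConfigError("retention schedule length must equal n_sessions")
            if np.any(r <= 0) or np.any(r > 1):
                raise ConfigError("retention proportions must lie in (0, 1]")
            if np.any(np.diff(r) > 1e-12):
                raise ConfigError("retention schedule must be non-increasing")

    def corr_matrix(self) -> np.ndarray:
        """Cross-session latent correlation as a full T x T matrix."""
        T = self.n_sessions
        if np.ndim(self.latent_corr) == 2:
            R = np.asarray(self.latent_corr, dtype=float)
            if R.shape != (T, T):
                raise ConfigError("latent_corr matrix must be T x T")
            if not np.allclose(R, R.T):
                raise ConfigError("latent_corr must be symmetric")
            if np.min(np.linalg.eigvalsh(R)) <= 0:
                raise ConfigError("latent_corr must be positive definite")
            return R
        rho = float(self.latent_corr)
        lag = np.abs(np.subtract.outer(np.arange(T), np.arange(T)))
        return rho ** lag

    def loadings_at(self, t: int) -> np.ndarray:
        return self.loadings if self.loadings.ndim == 1 else self.loadings[:, t]

    def thresholds_at(self, t: int) -> np.ndarray:
        return (
            self.thresholds
            if self.thresholds.ndim == 2
            else self.thresholds[:, :, t]
        )

    def to_dict(self) -> dict:
        return asdict(self)


def default_thresholds(n_items: int, n_categories: int, loadings) -> np.ndarray:
    """Thresholds placing ~45% of baseline liability mass at category 0,
    with the remaining mass thinning toward the top category (symptom-report
    sparsity).  Computed on the marginal liability scale at session 1
    (theta ~ N(0,1), psi = 1)."""
    lam = np.asarray(loadings, dtype=float)
    if lam.ndim == 2:
        lam = lam[:, 0]
    cum = np.linspace(0.45, 0.92, n_categories - 1)
    sd = np.sqrt(lam**2 + 1.0)
    return sd[:, None] * ndtri(cum)[None, :]


def gad7_config(**overrides) -> SyntheticConfig:
    """7 four-category items over 13 sessions with the printed retention."""
    kw = dict(n_items=7, n_sessions=13, retention=GAD7_RETENTION)
    kw.update(overrides)
    return SyntheticConfig(**kw)


def bdi_config(**overrides) -> SyntheticConfig:
    """20 four-category items over 4 assessment sessions."""
    kw = dict(n_items=20, n_sessions=4, retention=BDI_RETENTION)
    kw.update(overrides)
    return SyntheticConfig(**kw)


# ---------------------------------------------------------------------------
# latent trajectories


def _lognormal_sigma(target_skew: float) -> float:
    """Shape sigma of a log-normal with the requested skewness.

    Skewness of LN(mu, sigma^2) is (w + 2) sqrt(w - 1) with w = exp(sigma^2);
    solved by bisection (skewness is increasing in sigma)."""
    if target_skew <= 0:
        raise ConfigError("lognormal_shifted needs positive target skewness")

    def f(sig):
        w = np.exp(sig**2)
        return (w + 2.0) * np.sqrt(w - 1.0) - target_skew

    return optimize.brentq(f, 1e-6, 3.0)


def generate_latent_trajectories(
    config: SyntheticConfig, rng: np.random.Generator | None = None
) -> np.ndarray:
    """Draw the (n_subjects, n_sessions) latent-trait matrix.

    Rows are i.i.d. subjects.  Session margins match the configured means and
    variances for every family; ``lognormal_shifted`` attains a target
    skewness by moment-matching a shifted, scaled log-normal, and
    ``davidian`` draws margins from a squared-polynomial x normal density
    through a normal copula.
    """
    rng = np.random.default_rng(config.seed) if rng is None else rng
    T = config.n_sessions
    R = config.corr_matrix()
    L = np.linalg.cholesky(R)
    Z = rng.standard_normal((config.n_subjects, T)) @ L.T
    sd = np.sqrt(config.latent_variances)

    if config.latent_family == "normal":
        return config.latent_means[None, :] + sd[None, :] * Z

    if config.latent_family == "lognormal_shifted":
        skew = float(config.family_params.get("skewness", 1.5))
        sigma = _lognormal_sigma(skew)
        w = np.exp(sigma**2)
        raw = np.exp(sigma * Z)  # LN(0, sigma^2) margins, normal copula
        raw_mean, raw_sd = np.sqrt(w), np.sqrt(w * (w - 1.0))
        std = (raw - raw_mean) / raw_sd  # mean 0, var 1, skewness = target
        return config.latent_means[None, :] + sd[None, :] * std

    if config.latent_family == "davidian":
        from .davidian import DavidianDensity

        angles = np.asarray(
            config.family_params.get("phi_angles", [0.3]), dtype=float
        )
        dens = DavidianDensity(order=len(angles), phi_angles=angles)
        std = dens.ppf(stats.norm.cdf(Z))
        m, v, _ = dens.moments()
        std = (std - m) / np.sqrt(v)
        return config.latent_means[None, :] + sd[None, :] * std

    raise ConfigError(f"unknown latent family: {config.latent_family!r}")


# ---------------------------------------------------------------------------
# liability-threshold measurement


def render_ordinal_items(
    latents: np.ndarray,
    config: SyntheticConfig,
    rng: np.random.Generator | None = None,
) -> LongitudinalOrdinalData:
    """Map latent trajectories to ordinal responses.

    Liability y*_ist = lambda_i(t) theta_st + eps, eps ~ N(0, psi_it); the
    recorded category is the number of thresholds tau_i.(t) below y*.
    """
    rng = (
        np.random.default_rng(config.seed + 1) if rng is None else rng
    )
    n, T = latents.shape
    I = config.n_items
    resp = np.empty((n, I, T), dtype=int)
    for t in range(T):
        lam = config.loadings_at(t)
        tau = config.thresholds_at(t)
        psi = config.unique_variances[:, t]
        eps = rng.standard_normal((n, I)) * np.sqrt(psi)[None, :]
        liab = latents[:, t][:, None] * lam[None, :] + eps
        resp[:, :, t] = (liab[:, :, None] > tau[None, :, :]).sum(axis=2)
    return LongitudinalOrdinalData(
        responses=resp, n_categories=config.n_categories
    )


# ---------------------------------------------------------------------------
# dropout


def apply_dropout(
    data: LongitudinalOrdinalData,
    config: SyntheticConfig,
    rng: np.random.Generator | None = None,
) -> LongitudinalOrdinalData:
    """Impose monotone missingness.

    Schedule mode: subjects continue from session t-1 to t independently with
    probability retention[t]/retention[t-1], so the expected observed
    fraction at session t equals retention[t].  Logistic mode: a subject's
    probability of dropping out before the final session follows a logistic
    model on standardized covariates with the configured odds ratios; the
    dropout session of non-completers is drawn from the schedule-implied
    distribution (uniform when no schedule is given).
    """
    rng = np.random.default_rng(config.seed + 2) if rng is None else rng
    n, I, T = data.responses.shape
    resp = data.responses.copy()
    covariates = data.covariates

    if config.dropout_logistic is not None:
        if covariates is None:
            covariates = _draw_covariates(n, rng)
        odds = config.dropout_logistic.get("odds_ratios", {})
        rate = float(config.dropout_logistic.get("rate", 0.5))
        eta = np.full(n, np.log(rate / (1.0 - rate)))
        for name, or_per_sd in odds.items():
            z = np.asarray(covariates[name], dtype=float)
            z = (z - z.mean()) / z.std()
            eta = eta + np.log(float(or_per_sd)) * z
        dropped = rng.random(n) < expit(eta)
        last = np.full(n, T - 1)
        probs = _dropout_session_probs(config, T)
        last[dropped] = rng.choice(np.arange(T - 1), size=int(dropped.sum()), p=probs)
        for t in range(1, T):
            resp[last < t, :, t] = MISSING
        return LongitudinalOrdinalData(
            resp, data.n_categories, data.item_labels, data.session_labels,
            covariates,
        )

    if config.retention is None:
        return data
    r = np.asarray(config.retention, dtype=float)
    alive = np.ones(n, dtype=bool)
    for t in range(1, T):
        cont = r[t] / r[t - 1]
        alive = alive & (rng.random(n) < cont)
        resp[~alive, :, t] = MISSING
    return LongitudinalOrdinalData(
        resp, data.n_categories, data.item_labels, data.session_labels,
        covariates,
    )


def _dropout_session_probs(config: SyntheticConfig, T: int) -> np.ndarray:
    """P(last observed session = t | dropped out), t = 0..T-2."""
    if config.retention is not None:
        r = np.asarray(config.retention, dtype=float)
        p = r[:-1] - r[1:]
    else:
        p = np.ones(T - 1)
    return p / p.sum()


def _draw_covariates(n: int, rng: np.random.Generator):
    import pandas as pd

    return pd.DataFrame(
        {
            "age": rng.normal(34.0, 12.0, n),
            "female": (rng.random(n) < 0.75).astype(float),
        }
    )


# ---------------------------------------------------------------------------
# one-call cohort generation


def generate_cohort(config: SyntheticConfig) -> LongitudinalOrdinalData:
    """Latents -> ordinal items -> dropout, with seed-derived substreams so
    each stage's draws are independent of the others."""
    ss = np.random.SeedSequence(config.seed).spawn(3)
    latents = generate_latent_trajectories(config, np.random.default_rng(ss[0]))
    data = render_ordinal_items(latents, config, np.random.default_rng(ss[1]))
    if config.dropout_logistic is not None and data.covariates is None:
        data.covariates = _draw_covariates(
            config.n_subjects, np.random.default_rng(ss[2].spawn(1)[0])
        )
    return apply_dropout(data, config, np.random.default_rng(ss[2]))
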