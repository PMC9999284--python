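"""Longitudinal ordinal factor models: ledger, implied moments, DWLS fit.

The invariance sequence fits one latent trait per session to ordinal items
through a liability-threshold link, under increasingly strict cross-session
constraints:

configural    same one-factor structure each session; loadings and
              thresholds free per session; identification fixes all latent
              means to 0, latent variances to 1 and unique variances to 1.
loadings      loadings equated across sessions; latent variances free after
              session 1.
threshold     thresholds equated across sessions; latent means and unique
              variances free after session 1.
unique_factor unique variances re-fixed to 1 everywhere (full invariance).

Degrees of freedom are bookkept from an explicit parameter ledger: sample
moments are the I*T*(C-1) standardized thresholds plus the C(I*T, 2)
polychoric correlations; every ledger entry is free, fixed, or tied to an
equality group.  Estimation is diagonally weighted least squares on the
two-step sample moments, with inverse asymptotic variances as weights, so
the discrepancy statistic is T = sum_k (s_k - sigma_k)^2 / avar_k.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize
from scipy.special import ndtr
from sklearn.base import BaseEstimator

from .datatypes import LongitudinalOrdinalData
from .polychoric import PolychoricCorrelation
from . import fitstats

LEVELS = ("configural", "loadings", "threshold", "unique_factor")


# ---------------------------------------------------------------------------
# model specification ledger


@dataclass
class LmiModelSpec:
    """Parameter ledger for one invariance level.

    The ledger maps every scalar model parameter to a status:
    ``("free",)``, ``("fixed", value)`` or ``("equal", group_id)``.  Keys are
    ``("lambda", i, t)``, ``("tau", i, c, t)``, ``("psi", i, t)``,
    ``("alpha", t)`` and ``("phi", t, s)`` with t <= s.
    """

    level: str
    n_items: int
    n_sessions: int
    n_categories: int = 4
    n_categories_per_item: np.ndarray | None = None
    extra_constraints: list = field(default_factory=list)

    def __post_init__(self):
        if self.level not in LEVELS:
            raise ValueError(
                f"unknown level {self.level!r}; expected one of {LEVELS}"
            )
        if self.n_items < 3 or self.n_sessions < 1 or self.n_categories < 2:
            raise ValueError("need I >= 3, T >= 1, C >= 2")
        if self.n_categories_per_item is None:
            self.n_categories_per_item = np.full(
                self.n_items, self.n_categories
            )
        self.n_categories_per_item = np.asarray(
            self.n_categories_per_item, dtype=int
        )
        # (I,) = per-item reduction at every session; (I, T) additionally
        # allows a category empty at specific sessions (df bookkeeping only)
        if self.n_categories_per_item.shape not in (
            (self.n_items,), (self.n_items, self.n_sessions),
        ):
            raise ValueError(
                "n_categories_per_item must have shape (I,) or (I, T)"
            )

    def categories_at(self, i: int, t: int) -> int:
        if self.n_categories_per_item.ndim == 1:
            return int(self.n_categories_per_item[i])
        return int(self.n_categories_per_item[i, t])

    def uniform_categories(self) -> np.ndarray:
        """Per-item category counts, requiring them constant over sessions
        (the estimable case)."""
        if self.n_categories_per_item.ndim == 1:
            return self.n_categories_per_item
        if np.all(
            self.n_categories_per_item
            == self.n_categories_per_item[:, [0]]
        ):
            return self.n_categories_per_item[:, 0]
        raise NotImplementedError(
            "session-varying category counts are supported for df "
            "bookkeeping only"
        )

    # -- constraint flags (T = 1 collapses everything to configural) -------

    @property
    def _longitudinal(self) -> bool:
        return self.n_sessions > 1

    @property
    def loadings_equal(self) -> bool:
        return self._longitudinal and self.level in (
            "loadings", "threshold", "unique_factor",
        )

    @property
    def thresholds_equal(self) -> bool:
        return self._longitudinal and self.level in (
            "threshold", "unique_factor",
        )

    @property
    def psi_free_later(self) -> bool:
        return self._longitudinal and self.level == "threshold"

    @property
    def alpha_free_later(self) -> bool:
        return self._longitudinal and self.level in (
            "threshold", "unique_factor",
        )

    @property
    def phi_free_later(self) -> bool:
        if "fix_latent_variances" in self.extra_constraints:
            return False
        return self._longitudinal and self.level in (
            "loadings", "threshold", "unique_factor",
        )

    # -- ledger enumeration -------------------------------------------------

    def ledger(self) -> dict:
        I, T = self.n_items, self.n_sessions
        entries = {}
        for i in range(I):
            for t in range(T):
                if self.loadings_equal:
                    entries[("lambda", i, t)] = ("equal", f"lambda_{i}")
                else:
                    entries[("lambda", i, t)] = ("free",)
                for c in range(self.categories_at(i, t) - 1):
                    if self.thresholds_equal:
                        entries[("tau", i, c, t)] = ("equal", f"tau_{i}_{c}")
                    else:
                        entries[("tau", i, c, t)] = ("free",)
                if self.psi_free_later and t > 0:
                    entries[("psi", i, t)] = ("free",)
                else:
                    entries[("psi", i, t)] = ("fixed", 1.0)
        for t in range(T):
            if self.alpha_free_later and t > 0:
                entries[("alpha", t)] = ("free",)
            else:
                entries[("alpha", t)] = ("fixed", 0.0)
            if self.phi_free_later and t > 0:
                entries[("phi", t, t)] = ("free",)
            else:
                entries[("phi", t, t)] = ("fixed", 1.0)
            for s in range(t + 1, T):
                entries[("phi", t, s)] = ("free",)
        return entries

    def n_free_parameters(self) -> int:
        groups = set()
        n_free = 0
        for status in self.ledger().values():
            if status[0] == "free":
                n_free += 1
            elif status[0] == "equal":
                groups.add(status[1])
        return n_free + len(groups)

    def n_moments(self) -> int:
        V = self.n_items * self.n_sessions
        thr = sum(
            self.categories_at(i, t) - 1
            for i in range(self.n_items)
            for t in range(self.n_sessions)
        )
        return thr + V * (V - 1) // 2

    @property
    def df(self) -> int:
        return self.n_moments() - self.n_free_parameters()


def build_model(
    level: str,
    n_items: int,
    n_sessions: int,
    n_categories: int = 4,
    n_categories_per_item=None,
) -> LmiModelSpec:
    """Construct the ledger for one invariance level."""
    return LmiModelSpec(
        level=level,
        n_items=n_items,
        n_sessions=n_sessions,
        n_categories=n_categories,
        n_categories_per_item=n_categories_per_item,
    )


def delta_df(spec_a: LmiModelSpec, spec_b: LmiModelSpec) -> int:
    """df(spec_b) - df(spec_a); warns when the specs are not nested in the
    canonical order."""
    same_design = (
        spec_a.n_items == spec_b.n_items
        and spec_a.n_sessions == spec_b.n_sessions
        and np.array_equal(
            spec_a.n_categories_per_item, spec_b.n_categories_per_item
        )
    )
    if not same_design:
        raise ValueError("specs must share the item/session/category design")
    order = {lvl: k for k, lvl in enumerate(LEVELS)}
    if order[spec_b.level] < order[spec_a.level]:
        warnings.warn("specs are not nested in the canonical order")
    return spec_b.df - spec_a.df


def fix_variance_constraint(spec: LmiModelSpec) -> LmiModelSpec:
    """Add phi_tt = 1 for t > 1 on top of the full-invariance model;
    df grows by T - 1."""
    if spec.level != "unique_factor":
        raise ValueError("fixed-variance constraint applies to the "
                         "unique_factor model")
    return LmiModelSpec(
        level=spec.level,
        n_items=spec.n_items,
        n_sessions=spec.n_sessions,
        n_categories=spec.n_categories,
        n_categories_per_item=spec.n_categories_per_item.copy(),
        extra_constraints=spec.extra_constraints + ["fix_latent_variances"],
    )


# ---------------------------------------------------------------------------
# implied moments


def model_implied_moments(spec: LmiModelSpec, values: dict):
    """Implied polychoric correlations and standardized thresholds.

    ``values``: lam (I, T), tau (I, C-1, T), psi (I, T), alpha (T,),
    Phi (T, T).  Liability variance v_it = lam_it^2 phi_tt + psi_it;
    corr[(i,t),(j,s)] = lam_it phi_ts lam_js / sqrt(v_it v_js);
    standardized threshold = (tau_ict - lam_it alpha_t) / sqrt(v_it).
    Variable order is session-major (items fastest), matching the wide
    data layout.
    """
    lam = np.asarray(values["lam"], dtype=float)
    tau = np.asarray(values["tau"], dtype=float)
    psi = np.asarray(values["psi"], dtype=float)
    alpha = np.asarray(values["alpha"], dtype=float)
    Phi = np.asarray(values["Phi"], dtype=float)
    I, T = lam.shape
    if np.any(np.linalg.eigvalsh(Phi) <= 0):
        raise ValueError("latent covariance matrix must be positive definite")
    if np.any(psi <= 0):
        raise ValueError("unique variances must be positive")

    lam_v = lam.T.reshape(-1)                      # v = t*I + i
    psi_v = psi.T.reshape(-1)
    phi_tt_v = np.repeat(np.diag(Phi), I)
    v_var = lam_v**2 * phi_tt_v + psi_v
    sd_v = np.sqrt(v_var)

    Phi_big = np.kron(Phi, np.ones((I, I)))
    M = np.outer(lam_v, lam_v) * Phi_big
    implied_corr = M / np.outer(sd_v, sd_v)
    np.fill_diagonal(implied_corr, 1.0)

    alpha_v = np.repeat(alpha, I)
    # tau is (I, C-1, T) -> (V, C-1) session-major
    tau_v = tau.transpose(2, 0, 1).reshape(I * T, -1)
    implied_thr = (tau_v - (lam_v * alpha_v)[:, None]) / sd_v[:, None]
    return implied_corr, implied_thr


def constant_sd_reparameterization(values: dict) -> dict:
    """Rescale to unit latent variance at every session without changing
    implied moments: lam' = lam sqrt(phi_tt), alpha' = alpha / sqrt(phi_tt),
    Phi' = correlation form of Phi."""
    Phi = np.asarray(values["Phi"], dtype=float)
    d = np.sqrt(np.diag(Phi))
    if np.any(d <= 0):
        raise ValueError("latent variances must be positive")
    out = {
        "lam": np.asarray(values["lam"]) * d[None, :],
        "tau": np.asarray(values["tau"]).copy(),
        "psi": np.asarray(values["psi"]).copy(),
        "alpha": np.asarray(values["alpha"]) / d,
        "Phi": Phi / np.outer(d, d),
    }
    return out


# ---------------------------------------------------------------------------
# parameter packing for optimization


class _Packer:
    """Maps the ledger's free parameters to an unconstrained vector.

    Thresholds use (first, log-increment) blocks so monotonicity holds by
    construction; unique and latent variances are log-transformed and
    cross-session correlations atanh-transformed.
    """

    def __init__(self, spec: LmiModelSpec):
        self.spec = spec
        I, T = spec.n_items, spec.n_sessions
        self.slots = []  # (kind, index info, length)
        lam_reps = 1 if spec.loadings_equal else T
        for i in range(I):
            for rep in range(lam_reps):
                self.slots.append(("lam", (i, rep), 1))
        tau_reps = 1 if spec.thresholds_equal else T
        cats = spec.uniform_categories()
        for i in range(I):
            Ci = cats[i]
            for rep in range(tau_reps):
                self.slots.append(("tau", (i, rep), Ci - 1))
        if spec.psi_free_later:
            for i in range(I):
                for t in range(1, T):
                    self.slots.append(("psi", (i, t), 1))
        if spec.alpha_free_later:
            for t in range(1, T):
                self.slots.append(("alpha", (t,), 1))
        if spec.phi_free_later:
            for t in range(1, T):
                self.slots.append(("phi_tt", (t,), 1))
        for t in range(T):
            for s in range(t + 1, T):
                self.slots.append(("phi_ts", (t, s), 1))
        self.n_params = sum(length for _, _, length in self.slots)

    def pack(self, values: dict) -> np.ndarray:
        spec = self.spec
        x = np.empty(self.n_params)
        pos = 0
        Phi = values["Phi"]
        d = np.sqrt(np.diag(Phi))
        for kind, idx, length in self.slots:
            if kind == "lam":
                i, rep = idx
                x[pos] = values["lam"][i, rep]
            elif kind == "tau":
                i, rep = idx
                tau = values["tau"][i, :length, rep]
                x[pos] = tau[0]
                x[pos + 1 : pos + length] = np.log(
                    np.maximum(np.diff(tau), 1e-8)
                )
            elif kind == "psi":
                i, t = idx
                x[pos] = np.log(values["psi"][i, t])
            elif kind == "alpha":
                x[pos] = values["alpha"][idx[0]]
            elif kind == "phi_tt":
                x[pos] = np.log(Phi[idx[0], idx[0]])
            elif kind == "phi_ts":
                t, s = idx
                r = Phi[t, s] / (d[t] * d[s])
                x[pos] = np.arctanh(np.clip(r, -0.999, 0.999))
            pos += length
        return x

    def unpack(self, x: np.ndarray) -> dict:
        spec = self.spec
        I, T = spec.n_items, spec.n_sessions
        Cm1 = spec.n_categories - 1
        lam = np.empty((I, T))
        tau = np.full((I, Cm1, T), np.inf)
        psi = np.ones((I, T))
        alpha = np.zeros(T)
        phi_d = np.ones(T)
        r = np.zeros((T, T))
        pos = 0
        for kind, idx, length in self.slots:
            if kind == "lam":
                i, rep = idx
                if spec.loadings_equal:
                    lam[i, :] = x[pos]
                else:
                    lam[i, rep] = x[pos]
            elif kind == "tau":
                i, rep = idx
                block = np.empty(length)
                block[0] = x[pos]
                if length > 1:
                    block[1:] = block[0] + np.cumsum(
                        np.exp(x[pos + 1 : pos + length])
                    )
                if spec.thresholds_equal:
                    tau[i, :length, :] = block[:, None]
                else:
                    tau[i, :length, rep] = block
            elif kind == "psi":
                i, t = idx
                psi[i, t] = np.exp(np.clip(x[pos], -12.0, 12.0))
            elif kind == "alpha":
                alpha[idx[0]] = x[pos]
            elif kind == "phi_tt":
                phi_d[idx[0]] = np.exp(np.clip(x[pos], -12.0, 12.0))
            elif kind == "phi_ts":
                t, s = idx
                r[t, s] = r[s, t] = np.tanh(x[pos])
            pos += length
        d = np.sqrt(phi_d)
        Phi = r * np.outer(d, d)
        np.fill_diagonal(Phi, phi_d)
        return {"lam": lam, "tau": tau, "psi": psi, "alpha": alpha, "Phi": Phi}


# ---------------------------------------------------------------------------
# DWLS fitting


@dataclass
class FitResult:
    """Converged (or flagged) DWLS solution for one model spec."""

    spec: LmiModelSpec
    estimates: dict
    T_stat: float
    df: int
    N: int
    implied_corr: np.ndarray
    implied_thresholds: np.ndarray
    converged: bool
    n_iterations: int
    srmr_: float = np.nan
    cfi_: float = np.nan
    heywood_: bool = False

    @property
    def label(self) -> str:
        name = self.spec.level
        if "fix_latent_variances" in self.spec.extra_constraints:
            name += "+fixed_variance"
        return name


def _sample_moment_vectors(sample: PolychoricCorrelation, spec: LmiModelSpec):
    """Stack sample thresholds and correlations with their inverse-variance
    weights.  Requires the full item x session variable set (no excluded
    variables)."""
    V = spec.n_items * spec.n_sessions
    if len(sample.labels_) != V:
        raise ValueError(
            "sample has excluded variables; refit the design or reduce it"
        )
    thr_list, w_thr = [], []
    ns = np.diag(sample.pair_n_)
    cats = spec.uniform_categories()
    for v in range(V):
        tau = sample.thresholds_[v]
        Ci = cats[v % spec.n_items]
        tau = tau[: Ci - 1]
        p = ndtr(tau)
        dens = np.exp(-0.5 * tau**2) / np.sqrt(2 * np.pi)
        var = p * (1 - p) / (ns[v] * np.maximum(dens, 1e-300) ** 2)
        thr_list.append(tau)
        w_thr.append(1.0 / np.maximum(var, 1e-12))
    iu = np.triu_indices(V, k=1)
    s_corr = sample.correlation_[iu]
    avar = sample.avar_rho_[iu]
    w_corr = 1.0 / np.maximum(np.where(np.isfinite(avar), avar, np.inf), 1e-12)
    w_corr = np.where(np.isfinite(w_corr), w_corr, 0.0)
    s_thr = np.concatenate(thr_list)
    w_thr = np.concatenate(w_thr)
    finite_thr = np.isfinite(s_thr)
    if not finite_thr.all():
        warnings.warn("non-finite sample thresholds dropped from the fit")
        w_thr = np.where(finite_thr, w_thr, 0.0)
        s_thr = np.where(finite_thr, s_thr, 0.0)
    return s_thr, w_thr, s_corr, w_corr, iu


def _implied_vectors(spec, values, iu):
    corr, thr = model_implied_moments(spec, values)
    cats = spec.uniform_categories()
    thr_list = [
        thr[v, : cats[v % spec.n_items] - 1]
        for v in range(corr.shape[0])
    ]
    return np.concatenate(thr_list), corr[iu]


def initial_values(sample: PolychoricCorrelation, spec: LmiModelSpec) -> dict:
    """Deterministic start: thresholds from margins, loadings from the first
    principal axis of the session-1 polychorics, unit variances, moderate
    cross-session correlation."""
    I, T = spec.n_items, spec.n_sessions
    Cm1 = spec.n_categories - 1
    R1 = sample.correlation_[:I, :I]
    vals, vecs = np.linalg.eigh(R1)
    pa = np.abs(vecs[:, -1]) * np.sqrt(max(vals[-1], 0.1))
    l_std = np.clip(pa, 0.2, 0.9)            # standardized loading
    lam0 = l_std / np.sqrt(1.0 - l_std**2)   # psi = 1 scale
    lam = np.repeat(lam0[:, None], T, axis=1)
    tau = np.full((I, Cm1, T), np.inf)
    cats = spec.uniform_categories()
    for t in range(T):
        for i in range(I):
            v = t * I + i
            Ci = cats[i]
            samp = sample.thresholds_[v][: Ci - 1]
            samp = np.nan_to_num(samp, posinf=3.0, neginf=-3.0)
            samp = np.maximum.accumulate(samp + 1e-6 * np.arange(Ci - 1))
            # sample thresholds are standardized; rescale to liability scale
            tau[i, : Ci - 1, t] = samp * np.sqrt(lam0[i] ** 2 + 1.0)
    if spec.thresholds_equal:
        tau = np.repeat(tau.mean(axis=2, keepdims=True), T, axis=2)
    Phi = 0.6 * np.ones((T, T))
    np.fill_diagonal(Phi, 1.0)
    return {
        "lam": lam,
        "tau": tau,
        "psi": np.ones((I, T)),
        "alpha": np.zeros(T),
        "Phi": Phi,
    }


def fit_dwls(
    sample: PolychoricCorrelation,
    spec: LmiModelSpec,
    start: dict | None = None,
    max_iter: int = 2000,
) -> FitResult:
    """Diagonally weighted least squares fit of one ledger.

    Minimizes sum_k w_k (s_k - sigma_k)^2 over the free parameters, with
    w_k the inverse asymptotic variances of the two-step sample moments
    (thresholds by the delta method on cumulative proportions, correlations
    from the pairwise observed information).  Because the weights absorb
    the per-pair sample sizes, the minimized discrepancy is itself the test
    statistic, referred to chi-square on the ledger df.
    """
    s_thr, w_thr, s_corr, w_corr, iu = _sample_moment_vectors(sample, spec)
    packer = _Packer(spec)
    values0 = start or initial_values(sample, spec)
    x0 = packer.pack(values0)

    def objective(x):
        vals = packer.unpack(x)
        try:
            m_thr, m_corr = _implied_vectors(spec, vals, iu)
        except (ValueError, np.linalg.LinAlgError):
            return 1e12
        return float(
            np.sum(w_thr * (s_thr - m_thr) ** 2)
            + np.sum(w_corr * (s_corr - m_corr) ** 2)
        )

    res = optimize.minimize(
        objective,
        x0,
        method="L-BFGS-B",
        options={"maxiter": max_iter, "ftol": 1e-12, "gtol": 1e-6},
    )
    values = packer.unpack(res.x)
    implied_corr, implied_thr = model_implied_moments(spec, values)
    T_stat = max(float(res.fun), 0.0)
    heywood = bool(np.any(values["psi"] < 1e-4))
    if heywood:
        warnings.warn("unique variance driven to its bound (Heywood pattern)")

    N = int(np.diag(sample.pair_n_)[: spec.n_items].max())
    m_thr_vec, m_corr_vec = _implied_vectors(spec, values, iu)
    srmr = float(np.sqrt(np.mean((s_corr - m_corr_vec) ** 2)))
    # independence baseline: zero correlations, free thresholds
    T_base = float(np.sum(w_corr * s_corr**2))
    df_base = s_corr.size
    cfi = fitstats.cfi(T_stat, spec.df, T_base, df_base)
    return FitResult(
        spec=spec,
        estimates=values,
        T_stat=T_stat,
        df=spec.df,
        N=N,
        implied_corr=implied_corr,
        implied_thresholds=implied_thr,
        converged=bool(res.success),
        n_iterations=int(res.nit),
        srmr_=srmr,
        cfi_=cfi,
        heywood_=heywood,
    )


# ---------------------------------------------------------------------------
# estimator facade


class LmiModel(BaseEstimator):
    """Longitudinal measurement-invariance factor model (sklearn-style).

    Parameters
    ----------
    level : {"configural", "loadings", "threshold", "unique_factor"}
    fix_latent_variances : bool, default False
        Add the phi_tt = 1 (all t) constraint on top of unique_factor.
    smooth : bool, default True
        PD-smooth the sample polychoric matrix before fitting.
    max_iter : int, default 2000

    Attributes (after fit)
    ----------
    spec_ : LmiModelSpec; result_ : FitResult;
    loadings_, thresholds_, unique_variances_ : measurement estimates;
    latent_means_, latent_cov_ : structural estimates;
    T_stat_, df_, N_ : discrepancy statistic bookkeeping.
    """

    def __init__(
        self,
        level: str = "unique_factor",
        fix_latent_variances: bool = False,
        smooth: bool = True,
        max_iter: int = 2000,
    ):
        self.level = level
        self.fix_latent_variances = fix_latent_variances
        self.smooth = smooth
        self.max_iter = max_iter

    def fit(self, data, y=None, sample: PolychoricCorrelation | None = None):
        """Fit to a LongitudinalOrdinalData (or reuse a precomputed
        PolychoricCorrelation passed via ``sample``)."""
        if sample is None:
            if isinstance(data, PolychoricCorrelation):
                sample = data
                data = None
            else:
                sample = PolychoricCorrelation(smooth=self.smooth).fit(data)
        n_items = (
            data.n_items if data is not None
            else int(len(sample.labels_) / _n_sessions_of(sample))
        )
        n_sessions = (
            data.n_sessions if data is not None else _n_sessions_of(sample)
        )
        n_categories = sample.n_categories_
        spec = build_model(self.level, n_items, n_sessions, n_categories)
        if self.fix_latent_variances:
            spec = fix_variance_constraint(spec)
        self.sample_ = sample
        self.spec_ = spec
        self.result_ = fit_dwls(sample, spec, max_iter=self.max_iter)
        est = self.result_.estimates
        self.loadings_ = est["lam"]
        self.thresholds_ = est["tau"]
        self.unique_variances_ = est["psi"]
        self.latent_means_ = est["alpha"]
        self.latent_cov_ = est["Phi"]
        self.T_stat_ = self.result_.T_stat
        self.df_ = self.result_.df
        self.N_ = self.result_.N
        return self

    def constant_sd_estimates(self) -> dict:
        """Fit-equivalent reparameterization with unit latent variance at
        every session (loadings absorb the variance trajectory)."""
        return constant_sd_reparameterization(self.result_.estimates)


def _n_sessions_of(sample: PolychoricCorrelation) -> int:
    return len({lab.split("@")[1] for lab in sample.labels_})


def simulate_from_fit(
    estimates: dict,
    session: int,
    n_sim: int,
    n_categories: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """Draw (n_sim, I) ordinal responses at one session from fitted
    parameters under the normal-latent liability-threshold link."""
    lam = estimates["lam"][:, session]
    tau = estimates["tau"][:, :, session]
    psi = estimates["psi"][:, session]
    alpha = estimates["alpha"][session]
    phi = estimates["Phi"][session, session]
    theta = alpha + np.sqrt(phi) * rng.standard_normal(n_sim)
    eps = rng.standard_normal((n_sim, lam.size)) * np.sqrt(psi)[None, :]
    liab = theta[:, None] * lam[None, :] + eps
    return (liab[:, :, None] > tau[None, :, :]).sum(axis=2)
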