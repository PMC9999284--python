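"""Thresholds, polychoric correlations, and latent-normality diagnostics.

An ordinal variable is modeled as a normal liability cut at ordered
thresholds.  For a pair of ordinal variables the polychoric correlation is
the latent bivariate-normal correlation maximizing the multinomial
likelihood of the two-way contingency table, with thresholds estimated from
the margins first (two-step ML).  The same likelihood yields a G-squared
test of the latent bivariate-normality assumption itself: with all margins
occupied an r x c table has rc - 1 free cells, the model spends
(r-1) + (c-1) + 1 parameters, leaving df = rc - r - c.

Bivariate normal rectangle probabilities use Owen's T function, which is
exact and fast enough for simulation studies with hundreds of replicates.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import optimize, stats
from scipy.special import ndtr, ndtri, owens_t
from sklearn.base import BaseEstimator

from .datatypes import LongitudinalOrdinalData

RHO_MAX = 0.999
_ATANH_MAX = np.arctanh(RHO_MAX)


class DegenerateTableError(ValueError):
    """Contingency table with fewer than 2 occupied rows or columns."""


def bvn_cdf(h, k, rho):
    """P(X <= h, Y <= k) for standard bivariate normal with correlation rho.

    Owen (1956): Phi2(h,k;rho) = (Phi(h)+Phi(k))/2 - T(h,a_h) - T(k,a_k)
    - beta, beta = 1/2 iff h*k < 0 (or one is 0 and h+k < 0).  Infinite
    arguments reduce to the univariate CDF; exact zeros are nudged to keep
    a_h, a_k finite (error < 1e-12).
    """
    h = np.asarray(h, dtype=float)
    k = np.asarray(k, dtype=float)
    h, k = np.broadcast_arrays(h, k)
    rho = float(np.clip(rho, -1.0 + 1e-12, 1.0 - 1e-12))

    hh = np.where(h == 0.0, 1e-13, h)
    kk = np.where(k == 0.0, 1e-13, k)
    hh = np.clip(hh, -38.0, 38.0)
    kk = np.clip(kk, -38.0, 38.0)
    denom = np.sqrt(1.0 - rho * rho)
    a_h = (kk - rho * hh) / (hh * denom)
    a_k = (hh - rho * kk) / (kk * denom)
    beta = np.where(hh * kk < 0.0, 0.5, 0.0)
    out = (
        0.5 * (ndtr(hh) + ndtr(kk))
        - owens_t(hh, a_h)
        - owens_t(kk, a_k)
        - beta
    )
    # infinities short-circuit to marginals
    out = np.where(h == np.inf, ndtr(k), out)
    out = np.where(k == np.inf, np.where(h == np.inf, 1.0, ndtr(h)), out)
    out = np.where((h == -np.inf) | (k == -np.inf), 0.0, out)
    return np.clip(out, 0.0, 1.0)


def cell_probabilities(tau_a, tau_b, rho):
    """Bivariate-normal rectangle probabilities for the (r x c) grid cut at
    thresholds tau_a (length r-1) and tau_b (length c-1)."""
    ga = np.concatenate(([-np.inf], tau_a, [np.inf]))
    gb = np.concatenate(([-np.inf], tau_b, [np.inf]))
    F = bvn_cdf(ga[:, None], gb[None, :], rho)
    return np.clip(np.diff(np.diff(F, axis=0), axis=1), 0.0, 1.0)


# ---------------------------------------------------------------------------
# thresholds


def estimate_thresholds(category_counts) -> np.ndarray:
    """Normal-liability thresholds from marginal category counts.

    tau_c = Phi^{-1}(cumulative proportion through c), c = 0..C-2.  Empty
    leading/trailing categories produce -inf/+inf sentinels; interior empty
    categories produce duplicated boundaries (callers collapse them before
    bivariate fitting).
    """
    counts = np.asarray(category_counts, dtype=float)
    n = counts.sum()
    if n <= 0:
        raise ValueError("all category counts are zero")
    if np.any(counts < 0):
        raise ValueError("negative category counts")
    cum = np.cumsum(counts)[:-1] / n
    with np.errstate(divide="ignore"):
        return ndtri(cum)


def collapse_empty_categories(counts) -> tuple[np.ndarray, np.ndarray]:
    """Drop empty categories, merging each with its lower neighbor.

    Returns (collapsed counts, index map old->new).  Leading empty
    categories merge upward into the first occupied one.
    """
    counts = np.asarray(counts)
    occupied = counts > 0
    if not occupied.any():
        raise ValueError("all category counts are zero")
    new_index = np.maximum.accumulate(
        np.where(occupied, np.cumsum(occupied) - 1, -1)
    )
    new_index = np.maximum(new_index, 0)  # leading empties join first occupied
    collapsed = np.bincount(new_index, weights=counts).astype(counts.dtype)
    return collapsed, new_index


# ---------------------------------------------------------------------------
# pairwise polychoric ML


@dataclass
class PolychoricResult:
    """Two-step ML fit of the latent bivariate-normal model to one table."""

    rho: float
    thresholds_a: np.ndarray
    thresholds_b: np.ndarray
    loglik: float
    chi2: float
    df: int
    p: float
    n: int
    avar_rho: float = np.nan
    sparse_warning: bool = False


def _validate_table(table) -> np.ndarray:
    table = np.asarray(table, dtype=float)
    if table.ndim != 2:
        raise ValueError("contingency table must be 2-dimensional")
    if np.any(table < 0) or table.sum() < 1:
        raise ValueError("table needs nonnegative counts with total >= 1")
    rows = (table.sum(axis=1) > 0).sum()
    cols = (table.sum(axis=0) > 0).sum()
    if rows < 2 or cols < 2:
        raise DegenerateTableError(
            "need at least 2 occupied rows and columns"
        )
    return table


def _collapse_table(table) -> np.ndarray:
    """Remove empty rows/columns (merging with lower neighbors keeps the
    count layout identical to simply dropping zero margins)."""
    table = table[table.sum(axis=1) > 0][:, table.sum(axis=0) > 0]
    return table


def _neg_loglik(z, table, tau_a, tau_b):
    P = cell_probabilities(tau_a, tau_b, np.tanh(z))
    return -np.sum(table * np.log(np.maximum(P, 1e-300)))


def estimate_polychoric(table) -> PolychoricResult:
    """Polychoric correlation by two-step maximum likelihood.

    Thresholds come from the margins; rho then maximizes the multinomial
    likelihood with bivariate-normal cell probabilities, searched on the
    atanh scale and clamped to |rho| <= 0.999.  Also computes the G-squared
    statistic of latent bivariate normality with df = rc - r - c.
    """
    table = _collapse_table(_validate_table(table))
    n = table.sum()
    tau_a = estimate_thresholds(table.sum(axis=1))
    tau_b = estimate_thresholds(table.sum(axis=0))

    res = optimize.minimize_scalar(
        _neg_loglik,
        bounds=(-_ATANH_MAX, _ATANH_MAX),
        args=(table, tau_a, tau_b),
        method="bounded",
        options={"xatol": 1e-8},
    )
    z_hat = res.x
    # bounded Brent can stall short of the boundary on monotone objectives
    for z_edge in (-_ATANH_MAX, _ATANH_MAX):
        if _neg_loglik(z_edge, table, tau_a, tau_b) < res.fun:
            z_hat = z_edge
    rho = float(np.clip(np.tanh(z_hat), -RHO_MAX, RHO_MAX))
    loglik = -_neg_loglik(np.arctanh(rho), table, tau_a, tau_b)

    expected = n * cell_probabilities(tau_a, tau_b, rho)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(table > 0, table / np.maximum(expected, 1e-300), 1.0)
        g2_terms = np.where(table > 0, table * np.log(ratio), 0.0)
    sparse = bool(np.any((expected <= 0) & (table > 0)))
    chi2 = np.inf if sparse else float(2.0 * g2_terms.sum())
    if sparse:
        warnings.warn("zero expected cell with nonzero observed count")
    r, c = table.shape
    df = r * c - r - c
    p = float(stats.chi2.sf(chi2, df)) if df > 0 else np.nan

    # observed information for rho by central difference on the profile
    eps = 1e-4
    if abs(rho) < RHO_MAX - 2 * eps:
        f0 = -loglik
        fp = _neg_loglik(np.arctanh(rho + eps), table, tau_a, tau_b)
        fm = _neg_loglik(np.arctanh(rho - eps), table, tau_a, tau_b)
        # chain rule: info wrt rho, not atanh(rho)
        info = (fp + fm - 2 * f0) / eps**2
        avar = 1.0 / info if info > 0 else np.nan
    else:
        avar = np.nan

    return PolychoricResult(
        rho=rho,
        thresholds_a=tau_a,
        thresholds_b=tau_b,
        loglik=float(loglik),
        chi2=chi2,
        df=int(df),
        p=p,
        n=int(n),
        avar_rho=float(avar),
        sparse_warning=sparse,
    )


def bivariate_normality_test(table) -> tuple[float, int, float]:
    """G-squared test of latent bivariate normality for one table.

    Returns (chi2, df, p); df = rc - r - c over occupied categories."""
    res = estimate_polychoric(table)
    return res.chi2, res.df, res.p


def contingency_table(x, y, n_categories: int) -> np.ndarray:
    """Cross-tabulate two coded vectors (missing entries already removed)."""
    return np.bincount(
        x * n_categories + y, minlength=n_categories * n_categories
    ).reshape(n_categories, n_categories)


# ---------------------------------------------------------------------------
# matrix over item x session variables


def smooth_correlation(R: np.ndarray, min_eig: float = 1e-4) -> np.ndarray:
    """Eigenvalue-clip a symmetric matrix to PD and rescale to unit diagonal.

    Pairwise-complete estimation does not guarantee positive definiteness;
    the SEM stage requires it.
    """
    vals, vecs = np.linalg.eigh((R + R.T) / 2.0)
    if vals.min() >= min_eig:
        return R
    vals = np.maximum(vals, min_eig)
    S = vecs @ np.diag(vals) @ vecs.T
    d = np.sqrt(np.diag(S))
    return S / np.outer(d, d)


class PolychoricCorrelation(BaseEstimator):
    """Pairwise polychoric correlation matrix over item x session variables.

    Pairwise-complete subjects are used for every pair; per-pair sample
    sizes are recorded.  Variables with a single occupied category are
    excluded with a warning.

    Parameters
    ----------
    smooth : bool, default True
        Eigenvalue-clip the matrix to positive definiteness.
    min_eig : float, default 1e-4
        Clipping floor for the smallest eigenvalue.

    Attributes
    ----------
    correlation_ : (V, V) symmetric unit-diagonal matrix.
    raw_correlation_ : same, before PD smoothing.
    thresholds_ : list of per-variable threshold vectors (length C-1,
        +-inf sentinels for empty edge categories).
    pair_n_ : (V, V) pairwise-complete sample sizes.
    avar_rho_ : (V, V) asymptotic variances of the pairwise correlations.
    labels_ : variable labels "item@session".
    kept_ : indices of retained variables in the wide layout.
    """

    def __init__(self, smooth: bool = True, min_eig: float = 1e-4):
        self.smooth = smooth
        self.min_eig = min_eig

    def fit(self, data: LongitudinalOrdinalData, y=None):
        wide = data.wide()
        labels = data.wide_labels()
        C = data.n_categories
        V = wide.shape[1]

        kept = []
        for v in range(V):
            obs = wide[:, v][wide[:, v] >= 0]
            if obs.size and np.unique(obs).size >= 2:
                kept.append(v)
            else:
                warnings.warn(
                    f"variable {labels[v]} has < 2 occupied categories; excluded"
                )
        k = len(kept)
        if k < 2:
            raise ValueError("need >= 2 variables with >= 2 occupied categories")

        R = np.eye(k)
        N = np.zeros((k, k), dtype=int)
        A = np.full((k, k), np.nan)
        thresholds = []
        for a_pos, v in enumerate(kept):
            col = wide[:, v]
            counts = np.bincount(col[col >= 0], minlength=C)
            thresholds.append(estimate_thresholds(counts))
            N[a_pos, a_pos] = int(counts.sum())
        for a_pos in range(k):
            xa = wide[:, kept[a_pos]]
            for b_pos in range(a_pos + 1, k):
                xb = wide[:, kept[b_pos]]
                both = (xa >= 0) & (xb >= 0)
                if both.sum() < 2:
                    continue
                tab = contingency_table(xa[both], xb[both], C)
                try:
                    res = estimate_polychoric(tab)
                except DegenerateTableError:
                    continue
                R[a_pos, b_pos] = R[b_pos, a_pos] = res.rho
                N[a_pos, b_pos] = N[b_pos, a_pos] = res.n
                A[a_pos, b_pos] = A[b_pos, a_pos] = res.avar_rho

        self.raw_correlation_ = R
        self.correlation_ = (
            smooth_correlation(R, self.min_eig) if self.smooth else R
        )
        self.thresholds_ = thresholds
        self.pair_n_ = N
        self.avar_rho_ = A
        self.labels_ = [labels[v] for v in kept]
        self.kept_ = np.asarray(kept)
        self.n_categories_ = C
        return self


def polychoric_matrix(data: LongitudinalOrdinalData, smooth: bool = True):
    """Functional wrapper: returns (correlation matrix, thresholds, pair n)."""
    est = PolychoricCorrelation(smooth=smooth).fit(data)
    return est.correlation_, est.thresholds_, est.pair_n_


def pairwise_normality_tests(
    data: LongitudinalOrdinalData, session: int
) -> "pd.DataFrame":
    """All item-pair G-squared normality tests at one session (0-based).

    Returns a tidy frame: item_a, item_b, session, chi2, df, p.
    """
    import pandas as pd

    rows = []
    resp = data.responses[:, :, session]
    C = data.n_categories
    for i in range(data.n_items):
        for j in range(i + 1, data.n_items):
            both = (resp[:, i] >= 0) & (resp[:, j] >= 0)
            if both.sum() < 10:
                continue
            tab = contingency_table(resp[both, i], resp[both, j], C)
            try:
                chi2, df, p = bivariate_normality_test(tab)
            except DegenerateTableError:
                continue
            rows.append(
                {
                    "item_a": data.item_labels[i],
                    "item_b": data.item_labels[j],
                    "session": data.session_labels[session],
                    "chi2": chi2,
                    "df": df,
                    "p": p,
                }
            )
    return pd.DataFrame(rows)
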