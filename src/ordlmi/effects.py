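"""Latent versus sum-score treatment-effect comparison.

The conventional outcome is the per-session mean of the item sum score,
standardized to the session-1 distribution.  The invariance model instead
reads the treatment effect from the fitted latent means, which are already
in session-1 standard-deviation units under the identification scheme
(alpha_1 = 0, phi_11 = 1).  When the fitted latent variance grows over
sessions, the two estimates diverge; the fit-equivalent constant-SD
reparameterization (alpha_t / sqrt(phi_tt)) moves the latent estimate back
toward the sum score without changing fit.  Tail risk ratios translate the
same variance growth into the probability of very severe latent values.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import ndtr

from .datatypes import LongitudinalOrdinalData


def sum_scores(data: LongitudinalOrdinalData) -> np.ndarray:
    """(n_subjects, n_sessions) item totals; NaN where any item is missing."""
    resp = data.responses.astype(float)
    resp[resp < 0] = np.nan
    return resp.sum(axis=1)  # NaN propagates


def sample_skewness(values) -> float:
    """Adjusted Fisher-Pearson skewness, g1 * sqrt(n(n-1)) / (n-2)."""
    x = np.asarray(values, dtype=float)
    x = x[np.isfinite(x)]
    n = x.size
    if n < 3:
        raise ValueError("need at least 3 values")
    s = x.std(ddof=0)
    if s == 0:
        raise ValueError("zero standard deviation")
    g1 = np.mean((x - x.mean()) ** 3) / s**3
    return float(g1 * np.sqrt(n * (n - 1.0)) / (n - 2.0))


@dataclass
class TrajectorySummary:
    """Per-session latent and sum-score effect summaries (session-1
    standardized)."""

    table: pd.DataFrame  # session, estimator, effect, ci_low, ci_high
    latent_effects: np.ndarray
    sum_effects: np.ndarray
    sum_skewness: np.ndarray
    latent_variances: np.ndarray


def standardized_trajectories(
    data: LongitudinalOrdinalData,
    fit,
    bootstrap: int = 0,
    seed: int = 0,
) -> TrajectorySummary:
    """Latent and sum-score treatment trajectories on a common scale.

    The latent effect at session t is the fitted alpha_t (phi_11 = 1 under
    the identification scheme).  The sum-score effect is
    (mean_t - mean_1) / SD_1 over observed cases.  Sum-score CIs use the
    normal approximation; latent CIs use a subject-level nonparametric
    bootstrap refitting the model (``bootstrap`` resamples; 0 skips it).
    """
    totals = sum_scores(data)
    T = data.n_sessions
    alpha = np.asarray(fit.estimates["alpha"], dtype=float)
    phi = np.diag(np.asarray(fit.estimates["Phi"], dtype=float))

    base = totals[:, 0]
    base = base[np.isfinite(base)]
    mean1, sd1 = base.mean(), base.std(ddof=1)
    rows = []
    sum_eff = np.full(T, np.nan)
    sum_skew = np.full(T, np.nan)
    for t in range(T):
        col = totals[:, t]
        col = col[np.isfinite(col)]
        if col.size < 3:
            warnings.warn(f"session {t + 1} empty; skipped")
            continue
        eff = (col.mean() - mean1) / sd1
        half = 1.96 * col.std(ddof=1) / (np.sqrt(col.size) * sd1)
        sum_eff[t] = eff
        sum_skew[t] = sample_skewness(col)
        rows.append(
            {
                "session": t + 1,
                "estimator": "sum_score",
                "effect": eff,
                "ci_low": eff - half,
                "ci_high": eff + half,
            }
        )
        rows.append(
            {
                "session": t + 1,
                "estimator": "latent_lmi",
                "effect": alpha[t],
                "ci_low": np.nan,
                "ci_high": np.nan,
            }
        )
        rows.append(
            {
                "session": t + 1,
                "estimator": "latent_constant_sd",
                "effect": alpha[t] / np.sqrt(phi[t]),
                "ci_low": np.nan,
                "ci_high": np.nan,
            }
        )
    table = pd.DataFrame(rows)

    if bootstrap > 0:
        from .polychoric import PolychoricCorrelation
        from .sem import fit_dwls

        rng = np.random.default_rng(seed)
        boots = np.full((bootstrap, T), np.nan)
        n = data.n_subjects
        for b in range(bootstrap):
            idx = rng.integers(0, n, n)
            resampled = LongitudinalOrdinalData(
                data.responses[idx], data.n_categories,
                data.item_labels, data.session_labels,
            )
            try:
                samp = PolychoricCorrelation().fit(resampled)
                res = fit_dwls(samp, fit.spec)
                boots[b] = res.estimates["alpha"]
            except (ValueError, np.linalg.LinAlgError):
                continue
        lo = np.nanpercentile(boots, 2.5, axis=0)
        hi = np.nanpercentile(boots, 97.5, axis=0)
        mask = table["estimator"] == "latent_lmi"
        for t in range(T):
            sel = mask & (table["session"] == t + 1)
            table.loc[sel, "ci_low"] = lo[t]
            table.loc[sel, "ci_high"] = hi[t]

    return TrajectorySummary(
        table=table,
        latent_effects=alpha,
        sum_effects=sum_eff,
        sum_skewness=sum_skew,
        latent_variances=phi,
    )


def effect_ratio(latent_effect: float, sum_effect: float) -> float:
    """How much larger the latent estimate is than the sum-score estimate."""
    if sum_effect == 0:
        raise ValueError("sum-score effect is zero")
    return float(latent_effect / sum_effect)


def tail_risk_ratio(mean_first, var_first, mean_last, var_last, x):
    """P(latent > x) at the last session over the same at the first.

    TRR(x) = Phi_bar((x - mean_last)/sd_last) /
             Phi_bar((x - mean_first)/sd_first); values below 1 mean the
    treated distribution puts less mass above x, values above 1 more.
    Vectorized over x.
    """
    if var_first <= 0 or var_last <= 0:
        raise ValueError("variances must be positive")
    x = np.asarray(x, dtype=float)
    num = ndtr(-(x - mean_last) / np.sqrt(var_last))
    den = ndtr(-(x - mean_first) / np.sqrt(var_first))
    with np.errstate(divide="ignore", invalid="ignore"):
        return num / den


def trr_crossing_point(mean_first, var_first, mean_last, var_last) -> float:
    """Upper crossing of TRR(x) = 1 when the last-session variance exceeds
    the first's: the larger root of
    (x - mean_last)^2 / var_last = (x - mean_first)^2 / var_first."""
    if var_last == var_first:
        raise ValueError("equal variances: no quadratic crossing")
    a = 1.0 / var_last - 1.0 / var_first
    b = -2.0 * (mean_last / var_last - mean_first / var_first)
    c = mean_last**2 / var_last - mean_first**2 / var_first
    disc = b**2 - 4 * a * c
    if disc < 0:
        raise ValueError("no real crossing")
    roots = np.sort(np.roots([a, b, c]))
    return float(roots[-1])


def trr_grid(
    mean_first, var_first, mean_last, var_last, lo=-4.0, hi=6.0, n=201
) -> pd.DataFrame:
    x = np.linspace(lo, hi, n)
    return pd.DataFrame(
        {"x": x, "trr": tail_risk_ratio(mean_first, var_first,
                                        mean_last, var_last, x)}
    )
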