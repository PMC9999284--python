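"""Chi-square difference and equivalence tests, and global fit indices.

The classic difference test takes exact fit as the null, so with large
samples tiny misfits become significant.  The equivalence test reverses the
logic: its null is that fit is unacceptably poor (population RMSEA at least
eps0), so a small p-value supports acceptable fit.  Under that null the test
statistic is noncentral chi-square with noncentrality (N - 1) * df * eps0^2,
and the p-value is the lower tail probability of the observed statistic.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats


def chi_square_difference(T_a: float, df_a: int, T_b: float, df_b: int):
    """Nested-model difference test; model b is the more constrained one.

    Returns (delta_T, delta_df, p) with p the upper tail of a central
    chi-square.  Robust (adjusted) statistics can order slightly the wrong
    way; a negative difference is floored at 0 with a warning.
    """
    if df_b <= df_a:
        raise ValueError("model b must be more constrained (df_b > df_a)")
    delta_T = T_b - T_a
    if delta_T < 0:
        warnings.warn("negative chi-square difference floored at 0")
        delta_T = 0.0
    delta_df = df_b - df_a
    return float(delta_T), int(delta_df), float(stats.chi2.sf(delta_T, delta_df))


def equivalence_test(T: float, df: int, N: int, eps0: float = 0.08) -> float:
    """Equivalence (acceptable-fit) test p-value.

    p = P[ chi2(df, ncp) <= T ] with ncp = (N - 1) * df * eps0^2.
    p < .05 rejects "population RMSEA >= eps0", i.e. supports acceptable
    fit; T far above the noncentral mass gives p near 1 (fit genuinely
    poor).
    """
    if eps0 <= 0:
        raise ValueError("eps0 must be positive")
    if T < 0 or df < 1 or N < 2:
        raise ValueError("need T >= 0, df >= 1, N >= 2")
    ncp = (N - 1) * df * eps0**2
    return float(stats.ncx2.cdf(T, df, ncp))


def rmsea(T: float, df: int, N: int) -> float:
    """Root mean square error of approximation,
    sqrt(max(0, (T - df) / (df * (N - 1))))."""
    if df < 1 or N < 2:
        raise ValueError("need df >= 1, N >= 2")
    return float(np.sqrt(max(0.0, (T - df) / (df * (N - 1)))))


def cfi(T: float, df: int, T_baseline: float, df_baseline: int) -> float:
    """Comparative fit index against the independence baseline,
    1 - max(T - df, 0) / max(T_b - df_b, T - df, 0), clamped to [0, 1]."""
    num = max(T - df, 0.0)
    denom = max(T_baseline - df_baseline, T - df, 0.0)
    if denom == 0.0:
        return 1.0
    if T_baseline - df_baseline < T - df:
        warnings.warn("baseline fits no worse than target model")
    return float(np.clip(1.0 - num / denom, 0.0, 1.0))


def srmr(
    sample_corr,
    sample_thresholds=None,
    implied_corr=None,
    implied_thresholds=None,
) -> float:
    """Standardized root mean square residual over the unique off-diagonal
    correlation entries.  Threshold residuals are accepted for interface
    symmetry but excluded from the summary (the conventional definition for
    categorical-moment models)."""
    if implied_corr is None:  # positional call (sample, implied)
        implied_corr = sample_thresholds
        sample_thresholds = None
    S = np.asarray(sample_corr, dtype=float)
    M = np.asarray(implied_corr, dtype=float)
    if S.shape != M.shape or S.ndim != 2 or S.shape[0] != S.shape[1]:
        raise ValueError("correlation matrices must share a square shape")
    iu = np.triu_indices_from(S, k=1)
    resid = S[iu] - M[iu]
    return float(np.sqrt(np.mean(resid**2)))


def comparison_table(fits, N: int, eps0: float = 0.08) -> pd.DataFrame:
    """Fit-sequence summary: one row per model with SRMR, RMSEA, CFI,
    difference test against the previous row (delta chi2, delta df, P_MI)
    and the equivalence test (P_ME).

    ``fits`` is an ordered list of objects exposing ``T_stat``, ``df``,
    ``srmr_``, ``cfi_`` and a ``label``.
    """
    rows = []
    prev = None
    for fit in fits:
        if hasattr(fit, "label"):
            label = fit.label
        else:
            label = getattr(getattr(fit, "spec", None), "level", "model")
        row = {
            "model": label,
            "SRMR": getattr(fit, "srmr_", np.nan),
            "RMSEA": rmsea(fit.T_stat, fit.df, N),
            "CFI": getattr(fit, "cfi_", np.nan),
            "delta_chi2": np.nan,
            "delta_df": np.nan,
            "P_MI": np.nan,
            "P_ME": equivalence_test(fit.T_stat, fit.df, N, eps0),
        }
        if prev is not None and fit.df > prev.df:
            dT, ddf, p = chi_square_difference(
                prev.T_stat, prev.df, fit.T_stat, fit.df
            )
            row.update({"delta_chi2": dT, "delta_df": ddf, "P_MI": p})
        rows.append(row)
        prev = fit
    return pd.DataFrame(rows)
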