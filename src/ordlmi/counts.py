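"""Zero-inflation diagnostics on endorsed-symptom counts.

A subject's endorsed-symptom count at a session is the number of items with
a nonzero response.  If counts follow a Poisson law, the observed number of
all-zero subjects should match n * exp(-lambda); the 1-df score test below
(van den Broek form) measures excess zeros against that prediction.  The
same test applied to counts simulated from a fitted invariance model shows
how much zero-inflation the normal-latent model itself predicts.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats

from .datatypes import LongitudinalOrdinalData


def endorsed_counts(data: LongitudinalOrdinalData, session: int) -> np.ndarray:
    """Per-subject count of items with response > 0 at one session
    (0-based); subjects with any missing item at the session are excluded."""
    resp = data.responses[:, :, session]
    complete = (resp >= 0).all(axis=1)
    if not complete.any():
        raise ValueError(f"no complete responses at session index {session}")
    return (resp[complete] > 0).sum(axis=1)


def zero_inflation_score_test(counts) -> tuple[float, int, float]:
    """Score test of zero-inflation against a Poisson fit.

    With lambda-hat the sample mean, p0 = exp(-lambda-hat) and n0 the
    number of zeros:

        S = (n0/p0 - n)^2 / (n (1/p0 - 1) - n lambda-hat)

    referred to chi-square(1).  Counts are treated as unbounded even though
    they cannot exceed the item count; a warning flags regimes where that
    truncation could bite.
    """
    counts = np.asarray(counts)
    n = counts.size
    if n < 30:
        raise ValueError("need at least 30 counts")
    lam = counts.mean()
    if lam <= 0:
        raise ValueError("all counts are zero; the test is undefined")
    if lam > counts.max() / 2 and counts.max() > 0:
        warnings.warn(
            "mean count exceeds half the maximum; Poisson truncation may "
            "distort the test"
        )
    p0 = np.exp(-lam)
    n0 = int((counts == 0).sum())
    denom = n * (1.0 / p0 - 1.0) - n * lam
    if denom <= 0:
        warnings.warn("degenerate score-test denominator")
        return np.nan, 1, np.nan
    S = (n0 / p0 - n) ** 2 / denom
    S = max(float(S), 0.0)
    return S, 1, float(stats.chi2.sf(S, 1))


def model_implied_count_test(
    fit, session: int, n_sim: int = 20000, seed: int = 0
) -> tuple[float, int, float]:
    """Zero-inflation test on counts simulated from a fitted invariance
    model at one session (normal latent, liability-threshold link)."""
    from .sem import simulate_from_fit

    if not fit.converged:
        raise ValueError("fit did not converge")
    rng = np.random.default_rng(seed)
    resp = simulate_from_fit(
        fit.estimates, session, n_sim, fit.spec.n_categories, rng
    )
    counts = (resp > 0).sum(axis=1)
    if (counts == 0).sum() == 0:
        warnings.warn("no zero counts in simulated data; test degenerate")
        return np.nan, 1, np.nan
    return zero_inflation_score_test(counts)


def count_test_table(
    data: LongitudinalOrdinalData,
    fit=None,
    sessions=None,
    n_sim: int = 20000,
    seed: int = 0,
) -> pd.DataFrame:
    """Tidy per-session summary of observed (and optionally model-implied)
    zero-inflation tests."""
    sessions = range(data.n_sessions) if sessions is None else sessions
    rows = []
    for t in sessions:
        try:
            counts = endorsed_counts(data, t)
            S, df, p = zero_inflation_score_test(counts)
        except ValueError:
            continue
        rows.append(
            {
                "session": data.session_labels[t],
                "n": counts.size,
                "n_zero": int((counts == 0).sum()),
                "lambda_hat": counts.mean(),
                "S": S,
                "p": p,
                "source": "observed",
            }
        )
        if fit is not None:
            S_m, _, p_m = model_implied_count_test(fit, t, n_sim, seed + t)
            rows.append(
                {
                    "session": data.session_labels[t],
                    "n": n_sim,
                    "n_zero": np.nan,
                    "lambda_hat": np.nan,
                    "S": S_m,
                    "p": p_m,
                    "source": "model_implied",
                }
            )
    return pd.DataFrame(rows)
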