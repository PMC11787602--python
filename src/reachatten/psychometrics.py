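"""Psychometric fitting for the two-interval force-discrimination task.

Responses are modelled with the two-parameter logistic

    p(x) = exp(b0 + b1 x) / (1 + exp(b0 + b1 x)),

where x is the comparison intensity (N) and p the probability of judging
the comparison stronger than the test force. The point of subjective
equality PSE = -b0/b1 is the comparison intensity felt equal to the test
(p = 0.5) and measures the perceived test intensity; the just-noticeable
difference JND = log(3)/b1 is the distance between the p = 0.5 and p = 0.75
thresholds and measures discrimination ability. Goodness of fit is
McFadden's pseudo-R².

Measured comparison forces are rebinned to the nearest of the seven
canonical intensities before fitting; the fit itself is maximum-likelihood
(Newton / iteratively reweighted least squares) with a weak ridge fallback
under complete separation, which is flagged rather than silently reported.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import expit

from .config import REACHING_TYPES

__all__ = [
    "PsychFit",
    "FitError",
    "rebin_comparison",
    "response_table",
    "fit_psychometric",
    "derive_pse_jnd",
    "mcfadden_r2",
    "fit_cohort",
    "FIT_COLUMNS",
]

LOG3 = float(np.log(3.0))

FIT_COLUMNS = [
    "participant",
    "trial_type",
    "beta0",
    "beta1",
    "pse",
    "jnd",
    "mcfadden_r2",
    "n_trials",
    "converged",
]


class FitError(ValueError):
    """Raised for degenerate response tables or undefined derived quantities."""


@dataclass(frozen=True)
class PsychFit:
    """Logistic coefficients and derived psychometric quantities."""

    beta0: float
    beta1: float
    pse: float
    jnd: float
    mcfadden_r2: float
    converged: bool
    n_trials: int


def rebin_comparison(values, canonical) -> np.ndarray:
    """Snap measured comparison forces to the nearest canonical intensity.

    Ties at a midpoint break upward. Works element-wise on arrays.
    """
    canon = np.asarray(canonical, dtype=float)
    if canon.size == 0:
        raise FitError("canonical intensity set must be non-empty")
    if canon.size == 1:
        out = np.full(np.shape(values), canon[0])
        return out if np.ndim(values) else float(canon[0])
    mids = (canon[:-1] + canon[1:]) / 2.0
    idx = np.searchsorted(mids, np.asarray(values, dtype=float), side="right")
    out = canon[idx]
    return out if np.ndim(values) else float(out)


def response_table(trials: pd.DataFrame, canonical) -> pd.DataFrame:
    """Aggregate trials into (intensity, n_trials, n_comparison_stronger)."""
    x = rebin_comparison(trials["comparison_measured_n"].to_numpy(), canonical)
    stronger = (trials["response"] == "comparison_stronger").to_numpy()
    df = pd.DataFrame({"intensity": x, "stronger": stronger})
    tab = (
        df.groupby("intensity")
        .agg(n_trials=("stronger", "size"), n_comparison_stronger=("stronger", "sum"))
        .reset_index()
    )
    return tab


def _log_likelihood(beta0, beta1, x, n, k):
    eta = beta0 + beta1 * x
    # log(p) and log(1-p) in a numerically stable form
    log_p = -np.logaddexp(0.0, -eta)
    log_q = -np.logaddexp(0.0, eta)
    return float(np.sum(k * log_p + (n - k) * log_q))


def fit_psychometric(
    table: pd.DataFrame,
    tol: float = 1e-8,
    max_iter: int = 100,
    ridge_fallback: float = 1e-6,
) -> PsychFit:
    """Maximum-likelihood Bernoulli-logistic fit of a response table.

    Newton iterations on the binomial log-likelihood (equivalently IRLS)
    with convergence tolerance ``tol``; under complete separation (or any
    non-convergence) the fit is repeated with a weak quadratic coefficient
    penalty and flagged ``converged=False`` so downstream consumers can
    treat it as unreliable rather than receive a silent number.
    """
    x = table["intensity"].to_numpy(dtype=float)
    n = table["n_trials"].to_numpy(dtype=float)
    k = table["n_comparison_stronger"].to_numpy(dtype=float)
    if np.any(k < 0) or np.any(k > n):
        raise FitError("counts must satisfy 0 <= k <= n")
    used = n > 0
    x, n, k = x[used], n[used], k[used]
    if np.unique(x).size < 2:
        raise FitError("need >= 2 distinct intensities with trials")
    if k.sum() == 0 or k.sum() == n.sum():
        raise FitError("all responses identical; psychometric fit undefined")

    def newton(lam: float):
        beta = np.array([0.0, 0.0])
        X = np.column_stack([np.ones_like(x), x])
        for _ in range(max_iter):
            eta = X @ beta
            p = expit(eta)
            w = n * p * (1.0 - p)
            grad = X.T @ (k - n * p) - lam * beta
            hess = X.T @ (w[:, None] * X) + lam * np.eye(2)
            try:
                step = np.linalg.solve(hess, grad)
            except np.linalg.LinAlgError:
                return beta, False
            beta = beta + step
            if np.max(np.abs(step)) < tol:
                return beta, bool(np.all(np.isfinite(beta)))
        return beta, False

    beta, ok = newton(0.0)
    converged = ok and bool(np.all(np.abs(beta) < 1e3))
    if not converged:
        beta, _ = newton(ridge_fallback)
    beta0, beta1 = float(beta[0]), float(beta[1])
    pse, jnd = derive_pse_jnd(beta0, beta1)
    tab = pd.DataFrame({"intensity": x, "n_trials": n, "n_comparison_stronger": k})
    r2 = mcfadden_r2(beta0, beta1, tab)
    return PsychFit(
        beta0=beta0,
        beta1=beta1,
        pse=pse,
        jnd=jnd,
        mcfadden_r2=r2,
        converged=converged,
        n_trials=int(n.sum()),
    )


def derive_pse_jnd(beta0: float, beta1: float) -> tuple[float, float]:
    """PSE = -b0/b1 (p = 0.5 point); JND = log(3)/b1 (0.75-minus-0.5 distance)."""
    if beta1 == 0:
        raise FitError("beta1 = 0: PSE and JND are undefined")
    return -beta0 / beta1, LOG3 / beta1


def mcfadden_r2(beta0: float, beta1: float, table: pd.DataFrame) -> float:
    """McFadden pseudo-R²: 1 - LL(model) / LL(intercept-only)."""
    x = table["intensity"].to_numpy(dtype=float)
    n = table["n_trials"].to_numpy(dtype=float)
    k = table["n_comparison_stronger"].to_numpy(dtype=float)
    pbar = k.sum() / n.sum()
    if pbar <= 0.0 or pbar >= 1.0:
        raise FitError("intercept-only likelihood degenerate (all-identical responses)")
    ll0 = float(np.sum(k * np.log(pbar) + (n - k) * np.log1p(-pbar)))
    ll = _log_likelihood(beta0, beta1, x, n, k)
    if ll0 == 0.0:
        raise FitError("intercept-only log-likelihood is zero")
    return max(0.0, 1.0 - ll / ll0)


def fit_cohort(
    retained_trials: pd.DataFrame, canonical
) -> pd.DataFrame:
    """Fit every participant x trial type (five reaching phases + baseline).

    Returns the fits table; fits that failed outright (degenerate tables)
    appear with NaN coefficients and ``converged=False``.
    """
    labels = list(REACHING_TYPES) + ["baseline"]
    df = retained_trials[retained_trials["label"].isin(labels)]
    counts = pd.DataFrame(
        {
            "participant": df["participant"].to_numpy(),
            "trial_type": df["label"].to_numpy(),
            "intensity": rebin_comparison(
                df["comparison_measured_n"].to_numpy(), canonical
            ),
            "stronger": (df["response"] == "comparison_stronger").to_numpy(),
        }
    )
    tab = (
        counts.groupby(["participant", "trial_type", "intensity"], observed=True)
        .agg(n_trials=("stronger", "size"), n_comparison_stronger=("stronger", "sum"))
        .reset_index()
    )
    rows = []
    for (pid, label), sub in tab.groupby(["participant", "trial_type"], observed=True):
        rec = {
            "participant": pid,
            "trial_type": label,
            "n_trials": int(sub["n_trials"].sum()),
        }
        try:
            fit = fit_psychometric(sub)
            rec.update(
                beta0=fit.beta0, beta1=fit.beta1, pse=fit.pse, jnd=fit.jnd,
                mcfadden_r2=fit.mcfadden_r2, converged=fit.converged,
            )
        except FitError:
            rec.update(
                beta0=np.nan, beta1=np.nan, pse=np.nan, jnd=np.nan,
                mcfadden_r2=np.nan, converged=False,
            )
        rows.append(rec)
    return pd.DataFrame(rows, columns=FIT_COLUMNS)
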