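"""Vectorized univariate proportional-hazards machinery for binary covariates.

Every survival test in this package reduces to a proportional-hazards fit on
a single binary indicator (above/below an expression cutoff, LR/HR label,
risk-score split).  Cutoff scans evaluate hundreds of such fits per gene and
the Monte-Carlo suites evaluate millions, so routing each one through a
general-purpose Cox implementation is the dominant cost.  This module solves
the one-parameter Efron partial likelihood directly, with Newton iteration
vectorized across an arbitrary number of candidate splits that share the same
survival data.

The score test at ``beta = 0`` equals the classic log-rank statistic (exactly
so in the absence of tied event times) and doubles as the fallback p-value
when the partial likelihood is monotone (complete separation of events
between the two groups).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import chi2

#: Absolute bound on the log hazard-ratio; hitting it flags monotone likelihood.
BETA_CAP = 20.0


@dataclass
class BinaryCoxFits:
    """Per-split results of simultaneous binary-covariate Cox fits.

    All arrays have one entry per column of the indicator matrix passed to
    :func:`fit_binary_cox_many`.
    """

    beta: np.ndarray
    se: np.ndarray
    hazard_ratio: np.ndarray
    wald_chi2: np.ndarray
    wald_p: np.ndarray
    score_chi2: np.ndarray
    score_p: np.ndarray
    converged: np.ndarray
    separated: np.ndarray
    valid: np.ndarray
    n_events: int

    def __len__(self) -> int:  # pragma: no cover - trivial
        return self.beta.size


def _empty_fits(n_splits: int, n_events: int) -> BinaryCoxFits:
    nan = np.full(n_splits, np.nan)
    false = np.zeros(n_splits, dtype=bool)
    return BinaryCoxFits(
        beta=nan.copy(), se=nan.copy(), hazard_ratio=nan.copy(),
        wald_chi2=nan.copy(), wald_p=nan.copy(),
        score_chi2=nan.copy(), score_p=nan.copy(),
        converged=false.copy(), separated=false.copy(), valid=false.copy(),
        n_events=n_events,
    )


def fit_binary_cox_many(
    times: np.ndarray,
    events: np.ndarray,
    indicators: np.ndarray,
    *,
    max_iter: int = 80,
    tol: float = 1e-11,
) -> BinaryCoxFits:
    """Fit a univariate Cox model per column of a binary indicator matrix.

    Parameters
    ----------
    times, events:
        Observed survival times and event indicators (1 = event), length n.
    indicators:
        Boolean/0-1 array of shape (n,) or (n, G); each column is one split
        (1 = "exposed" group whose log hazard ratio ``beta`` is estimated).

    Notes
    -----
    Tied event times are handled with the Efron approximation, matching the
    default of mainstream Cox implementations.  Columns where the likelihood
    is monotone (events fully separated) are flagged ``separated`` with
    ``beta`` capped at +-``BETA_CAP``; their Wald p is meaningless and the
    caller should use ``score_p`` instead.
    """
    times = np.asarray(times, dtype=np.float64)
    events = np.asarray(events, dtype=np.float64)
    X = np.asarray(indicators, dtype=np.float64)
    if X.ndim == 1:
        X = X[:, None]
    n, G = X.shape
    if times.shape != (n,) or events.shape != (n,):
        raise ValueError("times/events must align with indicator rows")

    order = np.argsort(times, kind="stable")
    t = times[order]
    e = events[order]
    Xs = X[order]

    _, start = np.unique(t, return_index=True)
    n_risk = (n - start).astype(np.float64)                      # (J,)
    suffix = np.cumsum(Xs[::-1], axis=0)[::-1]                   # (n, G)
    n1 = suffix[start]                                           # (J, G)
    d_cnt = np.add.reduceat(e, start)                            # (J,)
    d1 = np.add.reduceat(Xs * e[:, None], start, axis=0)         # (J, G)

    keep = d_cnt > 0
    n_events = int(d_cnt.sum())
    if not keep.any():
        return _empty_fits(G, 0)
    n_risk, n1, d_cnt, d1 = n_risk[keep], n1[keep], d_cnt[keep], d1[keep]

    # Efron expansion: one row per (event-time group j, within-tie index l).
    reps = d_cnt.astype(np.intp)
    jidx = np.repeat(np.arange(reps.size), reps)
    l = np.concatenate([np.arange(r) for r in reps])
    frac = l / d_cnt[jidx]                                       # (R,)

    N1 = n1[jidx]                                                # (R, G)
    D1 = d1[jidx]
    Ntot = n_risk[jidx][:, None]
    Dtot = d_cnt[jidx][:, None]
    C = N1 - frac[:, None] * D1                                  # exposed risk mass
    A0 = (Ntot - N1) - frac[:, None] * (Dtot - D1)               # unexposed risk mass
    S1 = d1.sum(axis=0)                                          # (G,) events in exposed

    out = _empty_fits(G, n_events)

    # Score test at beta = 0 (log-rank).
    with np.errstate(divide="ignore", invalid="ignore"):
        w0 = C / (A0 + C)
    U0 = S1 - w0.sum(axis=0)
    I0 = (w0 - w0 * w0).sum(axis=0)
    valid = I0 > 1e-12
    out.valid = valid
    out.score_chi2 = np.where(valid, U0 * U0 / np.where(valid, I0, 1.0), np.nan)
    out.score_p = np.where(valid, chi2.sf(out.score_chi2, 1), np.nan)

    beta = np.zeros(G)
    converged = np.zeros(G, dtype=bool)
    separated = np.zeros(G, dtype=bool)

    for _ in range(max_iter):
        active = valid & ~converged & ~separated
        if not active.any():
            break
        eb = np.exp(beta[active])
        denom = A0[:, active] + eb * C[:, active]
        w = eb * C[:, active] / denom
        U = S1[active] - w.sum(axis=0)
        info = (w - w * w).sum(axis=0)
        flat = info <= 1e-12
        step = np.where(flat, np.sign(U), U / np.where(flat, 1.0, info))
        step = np.clip(step, -1.0, 1.0)
        new_beta = beta[active] + step
        beta[active] = new_beta
        idx = np.flatnonzero(active)
        sep_now = np.abs(new_beta) >= BETA_CAP
        conv_now = (np.abs(step) < tol) & ~flat & ~sep_now
        separated[idx[sep_now]] = True
        converged[idx[conv_now]] = True
    beta = np.clip(beta, -BETA_CAP, BETA_CAP)

    eb = np.exp(beta)
    with np.errstate(divide="ignore", invalid="ignore"):
        w = eb * C / (A0 + eb * C)
    info = (w - w * w).sum(axis=0)
    ok = valid & converged
    se = np.where(ok & (info > 0), 1.0 / np.sqrt(np.where(info > 0, info, 1.0)), np.nan)
    wald_chi2 = np.where(ok, beta * beta * info, np.nan)

    out.beta = np.where(valid, beta, np.nan)
    out.se = se
    out.hazard_ratio = np.where(valid, np.exp(beta), np.nan)
    out.wald_chi2 = wald_chi2
    out.wald_p = np.where(ok, chi2.sf(wald_chi2, 1), np.nan)
    out.converged = ok
    out.separated = separated & valid
    return out


def fit_binary_cox(times, events, indicator, **kw) -> BinaryCoxFits:
    """Single-split convenience wrapper around :func:`fit_binary_cox_many`."""
    return fit_binary_cox_many(times, events, np.asarray(indicator), **kw)
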