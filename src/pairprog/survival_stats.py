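"""Survival and categorical statistics shared across the pipeline.

Thin, contract-stable wrappers: Kaplan-Meier estimation and multivariate
proportional-hazards fits are delegated to lifelines; the ubiquitous
two-group test runs on the package's own fast binary-covariate solver (Efron
ties) with a log-rank fallback under complete separation.  Fisher's exact
test (2x2) comes from scipy; the r x c generalization enumerates exactly
when feasible and falls back to seeded Monte-Carlo sampling of margin-fixed
tables otherwise.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from scipy.special import gammaln
from scipy.stats import mannwhitneyu, norm, random_table
from scipy.stats import fisher_exact as _scipy_fisher

from ._cox import BETA_CAP, fit_binary_cox


@dataclass
class KMCurve:
    times: np.ndarray       # starts at 0
    survival: np.ndarray    # product-limit estimate, starts at 1
    at_risk: np.ndarray
    label: str = ""


@dataclass
class TwoGroupResult:
    wald_p: float
    hazard_ratio: float
    ci: tuple[float, float]
    logrank_p: float
    n_groups: tuple[int, int]   # (n_reference, n_exposed)
    separated: bool


@dataclass
class CoxFit:
    terms: pd.DataFrame         # coef, hazard_ratio, ci_low, ci_high, wald_p
    n_used: int
    converged: bool


def km_estimate(times, events, label: str = "") -> KMCurve:
    """Product-limit survival estimate for one group."""
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=float)
    if times.size < 1:
        raise ValueError("empty survival data")
    if (times < 0).any():
        raise ValueError("negative survival times")
    kmf = KaplanMeierFitter()
    kmf.fit(times, events, label=label or "KM")
    sf = kmf.survival_function_
    at_risk = kmf.event_table["at_risk"].reindex(sf.index).ffill()
    return KMCurve(times=sf.index.to_numpy(float),
                   survival=sf.iloc[:, 0].to_numpy(float),
                   at_risk=at_risk.to_numpy(float),
                   label=label)


def km_median(curve: KMCurve) -> float:
    """Smallest time with survival <= 0.5 (NaN if never reached)."""
    below = curve.survival <= 0.5
    return float(curve.times[below][0]) if below.any() else float("nan")


def two_group_test(times, events, hr_group, conf_level: float = 0.95) -> TwoGroupResult:
    """Univariate proportional-hazards Wald test on a binary group indicator.

    ``hr_group`` marks the exposed group; the hazard ratio is exposed vs
    reference.  Under monotone likelihood (separation) the Wald p is replaced
    by the score (log-rank) p, the HR is capped, and the CI is undefined.
    """
    hr_group = np.asarray(hr_group, dtype=bool)
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=float)
    n1 = int(hr_group.sum())
    n0 = int((~hr_group).sum())
    if n0 == 0 or n1 == 0:
        raise ValueError("both groups must be non-empty")
    fit = fit_binary_cox(times, events, hr_group)
    if not fit.valid[0]:
        raise ValueError("uninformative survival data (no usable events)")
    beta = float(fit.beta[0])
    logrank_p = float(fit.score_p[0])
    if fit.converged[0]:
        z = norm.ppf(1 - (1 - conf_level) / 2)
        se = float(fit.se[0])
        return TwoGroupResult(
            wald_p=float(fit.wald_p[0]), hazard_ratio=float(np.exp(beta)),
            ci=(float(np.exp(beta - z * se)), float(np.exp(beta + z * se))),
            logrank_p=logrank_p, n_groups=(n0, n1), separated=False)
    hr = float(np.exp(np.clip(beta, -BETA_CAP, BETA_CAP)))
    return TwoGroupResult(wald_p=logrank_p, hazard_ratio=hr,
                          ci=(float("nan"), float("nan")),
                          logrank_p=logrank_p, n_groups=(n0, n1), separated=True)


def _collinear_columns(X: np.ndarray, names: list[str]) -> list[str]:
    Xc = X - X.mean(axis=0, keepdims=True)
    rank = np.linalg.matrix_rank(Xc)
    if rank == Xc.shape[1]:
        return []
    bad = []
    for j in range(Xc.shape[1]):
        others = np.delete(Xc, j, axis=1)
        if np.linalg.matrix_rank(others) == rank:
            bad.append(names[j])
    return bad or names


def cox_multivariate(table: pd.DataFrame, terms: list[str],
                     duration_col: str = "os_years", event_col: str = "event",
                     conf_level: float = 0.95) -> CoxFit:
    """Joint proportional-hazards fit with listwise deletion.

    ``table`` holds survival columns plus numeric covariates; rows missing
    any requested term are dropped (complete-case), ``n_used`` reports the
    remaining count.  Constant or collinear covariates raise, naming them.
    """
    if not terms:
        raise ValueError("at least one covariate term required")
    cols = [duration_col, event_col, *terms]
    missing = [c for c in cols if c not in table.columns]
    if missing:
        raise KeyError(f"missing columns: {missing}")
    data = table[cols].apply(pd.to_numeric, errors="coerce").dropna()
    n_used = len(data)
    if n_used < 10:
        raise ValueError(f"only {n_used} complete-case rows (need >= 10)")
    X = data[terms].to_numpy(float)
    constant = [t for t, s in zip(terms, X.std(axis=0)) if s == 0]
    if constant:
        raise ValueError(f"constant covariates: {constant}")
    collinear = _collinear_columns(X, terms)
    if collinear:
        raise ValueError(f"collinear covariates: {collinear}")
    cph = CoxPHFitter(alpha=1 - conf_level)
    cph.fit(data, duration_col=duration_col, event_col=event_col,
            fit_options={"precision": 1e-10})
    summ = cph.summary
    lo = [c for c in summ.columns if c.startswith("exp(coef) lower")][0]
    hi = [c for c in summ.columns if c.startswith("exp(coef) upper")][0]
    out = pd.DataFrame({
        "coef": summ["coef"],
        "hazard_ratio": summ["exp(coef)"],
        "ci_low": summ[lo],
        "ci_high": summ[hi],
        "wald_p": summ["p"],
    })
    out.index.name = "term"
    return CoxFit(terms=out, n_used=n_used, converged=True)


def _validate_table(table: np.ndarray) -> np.ndarray:
    t = np.asarray(table)
    if t.ndim != 2:
        raise ValueError("contingency table must be 2-dimensional")
    if np.any(t < 0) or not np.all(t == np.floor(t)):
        raise ValueError("counts must be non-negative integers")
    t = t.astype(np.int64)
    if np.any(t.sum(axis=1) == 0) or np.any(t.sum(axis=0) == 0):
        raise ValueError("empty row/column margin")
    return t


def fisher_exact_2x2(table) -> float:
    """Two-sided Fisher exact p: total probability of tables (same margins)
    no more probable than the observed one."""
    t = _validate_table(table)
    if t.shape != (2, 2):
        raise ValueError("fisher_exact_2x2 requires a 2x2 table")
    return float(_scipy_fisher(t, alternative="two-sided")[1])


def _log_table_prob(t: np.ndarray) -> float:
    return (gammaln(t.sum(axis=1) + 1).sum() + gammaln(t.sum(axis=0) + 1).sum()
            - gammaln(t.sum() + 1) - gammaln(t + 1).sum())


def freeman_halton(table, max_enumeration: int = 200_000,
                   n_mc: int = 100_000, seed: int = 0) -> float:
    """Exact r x c generalization of Fisher's test (enumeration), with a
    seeded Monte-Carlo fallback when the table space is too large."""
    t = _validate_table(table)
    if t.shape == (2, 2):
        return fisher_exact_2x2(t)
    obs_lp = _log_table_prob(t)
    rows, cols = t.sum(axis=1), t.sum(axis=0)
    tables = _enumerate_tables(rows, cols, cap=max_enumeration)
    if tables is not None:
        total = 0.0
        for cand in tables:
            lp = _log_table_prob(cand)
            if lp <= obs_lp + 1e-9:
                total += np.exp(lp)
        return float(min(1.0, total))
    rng = np.random.default_rng(seed)
    draws = random_table(rows, cols).rvs(size=n_mc, random_state=rng)
    lps = np.array([_log_table_prob(d) for d in draws])
    count = int(np.sum(lps <= obs_lp + 1e-9))
    return (1 + count) / (1 + n_mc)


def _enumerate_tables(rows, cols, cap):
    """All non-negative integer tables with the given margins, or None if
    more than ``cap`` would be generated."""
    out = []
    r, c = len(rows), len(cols)

    def rec(i, remaining_cols, current):
        if len(out) > cap:
            raise OverflowError
        if i == r - 1:
            last = np.asarray(remaining_cols)
            if np.all(last >= 0):
                out.append(np.vstack(current + [last]))
            return
        def fill(j, left, row):
            if j == c - 1:
                if 0 <= left <= remaining_cols[j]:
                    rec(i + 1,
                        [rc - rv for rc, rv in zip(remaining_cols, row + [left])],
                        current + [np.asarray(row + [left])])
                return
            for v in range(min(left, remaining_cols[j]) + 1):
                fill(j + 1, left - v, row + [v])
        fill(0, rows[i], [])

    try:
        rec(0, list(cols), [])
    except OverflowError:
        return None
    return out


def mann_whitney(x, y) -> float:
    """Two-sided Mann-Whitney U p-value, normal approximation with tie
    correction (and continuity correction)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    return float(mannwhitneyu(x, y, alternative="two-sided",
                              method="asymptotic")[1])
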