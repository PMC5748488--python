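"""Independent brute-force oracles used by the test suite.

Deliberately naive implementations (python loops, generic root finding,
exhaustive enumeration) that share no code with the package's fast paths.
"""

import math

import numpy as np
from scipy.optimize import brentq
from scipy.stats import chi2, norm


def efron_loglik_parts(times, events, x, beta):
    """(U, I) of the one-parameter Efron partial likelihood, naive loops."""
    order = np.argsort(times, kind="stable")
    t = np.asarray(times, float)[order]
    e = np.asarray(events, float)[order]
    xs = np.asarray(x, float)[order]
    n = len(t)
    U = 0.0
    info = 0.0
    for ut in np.unique(t):
        death_idx = [i for i in range(n) if t[i] == ut and e[i] > 0]
        if not death_idx:
            continue
        risk_idx = [i for i in range(n) if t[i] >= ut]
        d = len(death_idx)
        n1 = sum(xs[i] for i in risk_idx)
        n0 = len(risk_idx) - n1
        d1 = sum(xs[i] for i in death_idx)
        d0 = d - d1
        U += d1
        for el in range(d):
            frac = el / d
            c = n1 - frac * d1
            a0 = n0 - frac * d0
            w = math.exp(beta) * c / (a0 + math.exp(beta) * c)
            U -= w
            info += w - w * w
    return U, info


def naive_wald_binary_cox(times, events, x):
    """(beta, wald_p) by root-finding the score equation; None if the
    likelihood is monotone (separation) or uninformative."""
    _, i0 = efron_loglik_parts(times, events, x, 0.0)
    if i0 <= 1e-12:
        return None
    lo, hi = -18.0, 18.0
    u_lo, _ = efron_loglik_parts(times, events, x, lo)
    u_hi, _ = efron_loglik_parts(times, events, x, hi)
    if not (u_lo > 0 > u_hi):
        return None  # monotone likelihood
    beta = brentq(lambda b: efron_loglik_parts(times, events, x, b)[0],
                  lo, hi, xtol=1e-13)
    _, info = efron_loglik_parts(times, events, x, beta)
    return beta, float(chi2.sf(beta * beta * info, 1))


def naive_score_p(times, events, x):
    u0, i0 = efron_loglik_parts(times, events, x, 0.0)
    if i0 <= 1e-12:
        return None
    return float(chi2.sf(u0 * u0 / i0, 1))


def naive_grid(values, min_side):
    u = sorted(set(values))
    out = []
    for a, b in zip(u[:-1], u[1:]):
        mid = (a + b) / 2
        below = sum(v <= mid for v in values)
        if below >= min_side and len(values) - below >= min_side:
            out.append(mid)
    return out


def brute_force_scan(values, times, events, cfg):
    """(cutoff, p) by exhaustive per-cutoff fits with the package's selection
    semantics (min p; ties -> closest to median, then smaller cutoff;
    score-test fallback under separation)."""
    values = np.asarray(values, float)
    grid = naive_grid(list(values), cfg.min_side(len(values)))
    results = []
    for c in grid:
        x = (values > c).astype(float)
        fit = naive_wald_binary_cox(times, events, x)
        if fit is None:
            p = naive_score_p(times, events, x)
            if p is None:
                continue
        else:
            p = fit[1]
        results.append((c, p))
    if not results:
        return None
    pmin = min(p for _, p in results)
    med = float(np.median(values))
    tied = [(abs(c - med), c, p) for c, p in results
            if p <= pmin + 1e-9 * max(pmin, 1e-300)]
    tied.sort()
    return tied[0][1], tied[0][2]


def enumerate_fisher_2x2(table):
    """Two-sided Fisher p by exhaustive enumeration over the free cell."""
    (a, b), (c, d) = table
    r1, r2 = a + b, c + d
    c1 = a + c
    n = r1 + r2

    def log_prob(aa):
        return (math.lgamma(r1 + 1) + math.lgamma(r2 + 1)
                + math.lgamma(c1 + 1) + math.lgamma(n - c1 + 1)
                - math.lgamma(n + 1) - math.lgamma(aa + 1)
                - math.lgamma(r1 - aa + 1) - math.lgamma(c1 - aa + 1)
                - math.lgamma(r2 - c1 + aa + 1))

    lp_obs = log_prob(a)
    total = 0.0
    for aa in range(max(0, c1 - r2), min(r1, c1) + 1):
        lp = log_prob(aa)
        if lp <= lp_obs + 1e-9:
            total += math.exp(lp)
    return min(1.0, total)


def invert_cc_score_interval(k, n, conf_level=0.95):
    """Wilson continuity-corrected bounds by numeric inversion of the score
    test (independent of the closed form)."""
    z = norm.ppf(1 - (1 - conf_level) / 2)
    phat = k / n

    def upper_eq(p):
        return (p - phat - 1 / (2 * n)) - z * math.sqrt(p * (1 - p) / n)

    def lower_eq(p):
        return (phat - p - 1 / (2 * n)) - z * math.sqrt(p * (1 - p) / n)

    low = 0.0 if k == 0 else brentq(lower_eq, 1e-12, phat, xtol=1e-13)
    high = 1.0 if k == n else brentq(upper_eq, phat, 1 - 1e-12, xtol=1e-13)
    return low, high


def enumerate_hypergeom_tail(n_a, n_b, universe, overlap):
    """P(X >= overlap) by summing the exact pmf."""
    total = 0.0
    for m in range(overlap, min(n_a, n_b) + 1):
        total += (math.comb(n_a, m) * math.comb(universe - n_a, n_b - m)
                  / math.comb(universe, n_b))
    return min(1.0, total)
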