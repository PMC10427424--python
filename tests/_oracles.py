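"""Independent brute-force oracles used to validate the package's implementations.

Each oracle deliberately takes a different computational route from the code it
checks: exact rational arithmetic for the Fisher test, nested-loop running sums
for ssGSEA, an event-by-event product for Kaplan-Meier, and closed-form /
proximal-gradient solutions for the elastic net.
"""

from __future__ import annotations

from fractions import Fraction
from math import comb

import numpy as np


def fisher_oracle(count_pre: int, total_pre: int, count_post: int, total_post: int) -> float:
    """Two-sided Fisher p by exact hypergeometric enumeration with Fractions.

    Sums the probability of every table (same margins) whose probability does not
    exceed the observed one up to the documented 1e-7 relative tie slack.
    """
    a, b, n1, n2 = count_pre, count_post, total_pre, total_post
    n = a + b
    kmin = max(0, n - n2)
    kmax = min(n, n1)
    denom = comb(n1 + n2, n)
    pmf = {k: Fraction(comb(n1, k) * comb(n2, n - k), denom) for k in range(kmin, kmax + 1)}
    cutoff = pmf[a] * Fraction(10**7 + 1, 10**7)
    return float(sum(p for p in pmf.values() if p <= cutoff))


def ssgsea_oracle(values: np.ndarray, in_set: np.ndarray, exponent: float) -> float:
    """Running-sum enrichment score for one sample, computed with explicit loops."""
    n = len(values)
    ranks = np.empty(n)
    order_by_value = sorted(range(n), key=lambda i: values[i])
    i = 0
    while i < n:  # average ranks for ties (ascending: rank 1 = smallest)
        j = i
        while j + 1 < n and values[order_by_value[j + 1]] == values[order_by_value[i]]:
            j += 1
        avg = (i + j) / 2 + 1
        for k in range(i, j + 1):
            ranks[order_by_value[k]] = avg
        i = j + 1
    walk = sorted(range(n), key=lambda i: (-ranks[i], i))  # descending, stable
    w_total = sum(ranks[i] ** exponent for i in walk if in_set[i])
    n_out = sum(1 for i in walk if not in_set[i])
    es = 0.0
    cum_in = cum_out = 0.0
    for i in walk:
        if in_set[i]:
            cum_in += ranks[i] ** exponent / w_total
        else:
            cum_out += 1.0 / n_out
        es += cum_in - cum_out
    return es


def km_oracle(times, events) -> tuple[np.ndarray, np.ndarray]:
    """Product-limit survival curve computed subject by subject."""
    t = np.asarray(times, dtype=float)
    e = np.asarray(events, dtype=bool)
    event_times = sorted(set(t[e]))
    surv = []
    s = 1.0
    for u in event_times:
        at_risk = int((t >= u).sum())
        deaths = int(((t == u) & e).sum())
        s *= 1.0 - deaths / at_risk
        surv.append(s)
    return np.asarray(event_times), np.asarray(surv)


def soft_threshold_coef(x: np.ndarray, y: np.ndarray, lam: float, alpha: float) -> float:
    """Closed-form single-predictor elastic-net coefficient (standardised x).

    For the objective (1/2n)||y - b0 - x b||^2 + lam(alpha|b| + (1-alpha)/2 b^2)
    with x standardised (mean 0, variance 1 with 1/n), the solution is
    soft(b_ols, lam*alpha) / (1 + lam*(1-alpha)).
    """
    n = len(y)
    yc = y - y.mean()
    b_ols = float(x @ yc) / n
    thr = lam * alpha
    if abs(b_ols) <= thr:
        return 0.0
    return (b_ols - np.sign(b_ols) * thr) / (1.0 + lam * (1.0 - alpha))


def elastic_net_fista(
    x: np.ndarray, y: np.ndarray, lam: float, alpha: float,
    n_iter: int = 200_000, tol: float = 1e-12,
) -> tuple[np.ndarray, float]:
    """Proximal-gradient (FISTA) solver for the same elastic-net objective."""
    n, p = x.shape
    xc = x - x.mean(axis=0)
    yc = y - y.mean()
    lip = np.linalg.eigvalsh(xc.T @ xc / n).max() + lam * (1 - alpha)
    beta = np.zeros(p)
    z = beta.copy()
    t_mom = 1.0
    for _ in range(n_iter):
        grad = xc.T @ (xc @ z - yc) / n + lam * (1 - alpha) * z
        w = z - grad / lip
        thr = lam * alpha / lip
        new = np.sign(w) * np.maximum(np.abs(w) - thr, 0.0)
        t_new = (1 + np.sqrt(1 + 4 * t_mom**2)) / 2
        z = new + (t_mom - 1) / t_new * (new - beta)
        if np.max(np.abs(new - beta)) < tol:
            beta = new
            break
        beta, t_mom = new, t_new
    intercept = float(y.mean() - x.mean(axis=0) @ beta)
    return beta, intercept
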