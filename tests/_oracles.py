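"""Independent reference implementations used only to check the package.

Everything here is deliberately naive — exhaustive enumeration, brute-force
recursion, direct numerical integration — and shares no code with the
implementation under test.
"""

from __future__ import annotations

import itertools
import math

import numpy as np
from scipy import integrate
from scipy.stats import norm


def exhaustive_assignment(nominals, onsets, tolerance):
    """Best one-to-one strike->event assignment by exhaustive recursion.

    Maximizes the number of strikes matched within ``tolerance`` and, among
    those, minimizes total |deviation|.  Returns (n_matched, total_cost,
    matched_flags) for the strikes in input order.
    """
    n = len(nominals)
    feasible = [
        [j for j, t in enumerate(onsets) if abs(t - nominals[i]) <= tolerance + 1e-9]
        for i in range(n)
    ]
    best = {"matches": -1, "cost": math.inf, "flags": None}

    def recurse(i, used, matches, cost, flags):
        if i == n:
            if matches > best["matches"] or (
                matches == best["matches"] and cost < best["cost"] - 1e-12
            ):
                best.update(matches=matches, cost=cost, flags=tuple(flags))
            return
        # upper bound prune: even matching everything left cannot beat best
        if matches + (n - i) < best["matches"]:
            return
        for j in feasible[i]:
            if j not in used:
                flags.append(True)
                recurse(i + 1, used | {j}, matches + 1,
                        cost + abs(onsets[j] - nominals[i]), flags)
                flags.pop()
        flags.append(False)
        recurse(i + 1, used, matches, cost, flags)
        flags.pop()

    recurse(0, frozenset(), 0, 0.0, [])
    return best["matches"], best["cost"], list(best["flags"])


def mann_whitney_enumeration(x, y):
    """Exact two-sided Mann-Whitney p by enumerating all group labelings.

    Tie-free samples only.  Under the null every assignment of the pooled
    ranks to the x-group is equally likely; U1 = (rank sum of x) - nx(nx+1)/2.
    Returns (U1, p).
    """
    x, y = list(x), list(y)
    nx, ny = len(x), len(y)
    pooled = sorted(x + y)
    assert len(set(pooled)) == len(pooled), "enumeration oracle needs tie-free data"
    offset = nx * (nx + 1) // 2
    u_obs = sum(sorted(pooled).index(v) + 1 for v in x) - offset
    us = [sum(c) - offset for c in itertools.combinations(range(1, nx + ny + 1), nx)]
    n = len(us)
    p_le = sum(u <= u_obs for u in us) / n
    p_ge = sum(u >= u_obs for u in us) / n
    return u_obs, min(1.0, 2.0 * min(p_le, p_ge))


def kendall_tau_b_pairwise(x, y):
    """Kendall tau-b straight from the concordant/discordant pair counts."""
    n = len(x)
    conc = disc = tx = ty = 0
    for i, j in itertools.combinations(range(n), 2):
        dx = np.sign(x[j] - x[i])
        dy = np.sign(y[j] - y[i])
        if dx == 0 and dy == 0:
            continue
        if dx == 0:
            tx += 1
        elif dy == 0:
            ty += 1
        elif dx == dy:
            conc += 1
        else:
            disc += 1
    denom = math.sqrt((conc + disc + tx) * (conc + disc + ty))
    return (conc - disc) / denom


def expected_gaussian_range(mus, sigma):
    """E[max_j X_j - min_j X_j] for independent X_j ~ N(mu_j, sigma^2) by quadrature."""
    mus = np.asarray(mus, float)
    lo = mus.min() - 12 * sigma - 1
    hi = mus.max() + 12 * sigma + 1

    def cdf_max(t):
        return np.prod(norm.cdf((t - mus) / sigma))

    def cdf_min(t):
        return 1.0 - np.prod(1.0 - norm.cdf((t - mus) / sigma))

    def expectation(cdf):
        upper, _ = integrate.quad(lambda t: 1.0 - cdf(t), 0.0, hi, limit=200)
        lower, _ = integrate.quad(cdf, lo, 0.0, limit=200)
        return upper - lower

    return expectation(cdf_max) - expectation(cdf_min)


def ols_f_tests(y, X):
    """Overall and per-column F statistics from first principles (normal equations).

    Returns (F_model, p_model, F_col1, p_col1) where column 1 is tested by
    comparing residual sums of squares of the full model and the model with
    that column removed.
    """
    from scipy.stats import f as f_dist

    y = np.asarray(y, float)
    X = np.asarray(X, float)
    n, k = X.shape

    def rss(m):
        beta, *_ = np.linalg.lstsq(m, y, rcond=None)
        r = y - m @ beta
        return float(r @ r)

    rss_full = rss(X)
    rss_null = float(((y - y.mean()) ** 2).sum())
    df_model, df_resid = k - 1, n - k
    f_model = ((rss_null - rss_full) / df_model) / (rss_full / df_resid)
    p_model = float(f_dist.sf(f_model, df_model, df_resid))
    rss_drop = rss(np.delete(X, 1, axis=1))
    f_col = (rss_drop - rss_full) / (rss_full / df_resid)
    p_col = float(f_dist.sf(f_col, 1, df_resid))
    return f_model, p_model, f_col, p_col
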