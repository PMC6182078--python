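"""Independent brute-force / closed-form oracles used by the tests.

These deliberately avoid the package's own update formulas: the event
scale is minimised by exhaustive per-coordinate grid search, sequential
F statistics come from explicit nested-model residual sums of squares,
the plateau breakpoint from a dense grid, and the permutation null from
the exact hypergeometric law.
"""

from __future__ import annotations

import numpy as np
from scipy import stats


# -- event scale ------------------------------------------------------------


def profile_sse(x: np.ndarray, s_idx: np.ndarray, e_idx: np.ndarray, y: np.ndarray,
                n_species: int) -> float:
    """SSE of log10 days with per-species OLS profiled out at fixed scores."""
    total = 0.0
    xe = x[e_idx]
    for j in range(n_species):
        m = s_idx == j
        xj, yj = xe[m], y[m]
        X = np.column_stack([np.ones(m.sum()), xj])
        beta, *_ = np.linalg.lstsq(X, yj, rcond=None)
        r = yj - X @ beta
        total += float(r @ r)
    return total


def grid_search_scale(s_idx: np.ndarray, e_idx: np.ndarray, y: np.ndarray,
                      n_species: int, n_events: int, step: float = 0.001,
                      x0: np.ndarray | None = None, max_sweeps: int = 50) -> tuple[np.ndarray, float]:
    """Cyclic exhaustive grid descent over event scores.

    Each event score is scanned over the full [0, 1] grid at ``step`` with
    the others fixed (regressions refit per candidate); sweeps repeat until
    no coordinate moves.  Brute force per coordinate, independent of any
    closed-form update.
    """
    grid = np.arange(0.0, 1.0 + step / 2, step)
    x = np.full(n_events, 0.5) if x0 is None else x0.copy()
    best = profile_sse(x, s_idx, e_idx, y, n_species)
    for _ in range(max_sweeps):
        moved = False
        for i in range(n_events):
            vals = np.empty(len(grid))
            xi_old = x[i]
            for g, v in enumerate(grid):
                x[i] = v
                vals[g] = profile_sse(x, s_idx, e_idx, y, n_species)
            g_best = int(np.argmin(vals))
            x[i] = grid[g_best]
            if vals[g_best] < best - 1e-15:
                best = vals[g_best]
                if abs(x[i] - xi_old) > step / 2:
                    moved = True
            else:
                x[i] = xi_old
        if not moved:
            break
    return x, best


# -- sequential F -----------------------------------------------------------


def sequential_f(y: np.ndarray, x: np.ndarray, g: np.ndarray):
    """Type-I F statistics for y ~ x + g + x:g from nested RSS."""
    n = len(y)
    ones = np.ones(n)
    designs = [
        np.column_stack([ones]),
        np.column_stack([ones, x]),
        np.column_stack([ones, x, g]),
        np.column_stack([ones, x, g, x * g]),
    ]
    rss = []
    for X in designs:
        beta, *_ = np.linalg.lstsq(X, y, rcond=None)
        r = y - X @ beta
        rss.append(float(r @ r))
    df_resid = n - 4
    mse = rss[-1] / df_resid
    out = {}
    for name, k in (("x", 1), ("g", 2), ("xg", 3)):
        f = (rss[k - 1] - rss[k]) / mse
        out[name] = (f, float(stats.f.sf(f, 1, df_resid)))
    f_model = ((rss[0] - rss[-1]) / 3) / mse
    return out, f_model, df_resid


# -- plateau ----------------------------------------------------------------


def plateau_grid_rss(x: np.ndarray, y: np.ndarray, step_frac: float = 0.01):
    """Minimum RSS of y = a + b*min(x, c) over a dense c grid."""
    lo, hi = x.min(), x.max()
    best = np.inf
    best_c = lo
    for c in np.arange(lo, hi + 1e-12, step_frac * (hi - lo)):
        z = np.minimum(x, c)
        if np.ptp(z) == 0:
            X = np.ones((len(x), 1))
        else:
            X = np.column_stack([np.ones(len(x)), z])
        beta, *_ = np.linalg.lstsq(X, y, rcond=None)
        r = y - X @ beta
        rss = float(r @ r)
        if rss < best:
            best, best_c = rss, c
    return best, best_c


# -- permutation null -------------------------------------------------------


def hypergeom_null(n: int, n_marker: int, n_anchor: int):
    """Exact null of the co-detection ratio under label shuffling.

    Returns (support ratios, pmf): the intersection count is
    Hypergeometric(M=n, K=n_marker, N=n_anchor).
    """
    rv = stats.hypergeom(M=n, n=n_marker, N=n_anchor)
    kmin = max(0, n_anchor + n_marker - n)
    kmax = min(n_anchor, n_marker)
    ks = np.arange(kmin, kmax + 1)
    return ks / n_anchor, rv.pmf(ks)


def ks_distance_discrete(samples: np.ndarray, support: np.ndarray, pmf: np.ndarray) -> float:
    """KS distance between an empirical sample and a discrete law."""
    cdf = np.cumsum(pmf)
    ecdf = np.searchsorted(np.sort(samples), support + 1e-12) / len(samples)
    return float(np.max(np.abs(ecdf - cdf)))
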