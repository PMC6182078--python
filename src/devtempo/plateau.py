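"""Linear-plateau fits to gene-expression time courses.

A developmental transition in a bulk expression trajectory is modelled
as a rising line that goes flat at a breakpoint:

    y = a + b * x          for x <= c
    y = a + b * c          for x >  c

Equivalently y = a + b * min(x, c).  The breakpoint c is read as the
age (PC days) at which expression plateaus.  For fixed c the model is
linear, so c is profiled: the residual sum of squares is minimised over
a dense grid of interior breakpoints and polished by bounded scalar
optimisation, with closed-form OLS for (a, b) at every candidate.

Fits whose optimal breakpoint sits on the boundary of the observed age
range are declared non-converged — a line with no interior kink is not
evidence of a plateau.  Retained genes must additionally have all
coefficient p-values below a significance cutoff; breakpoint ages of
genes surviving in two species are averaged (per species, over the
shared ortholog set) into a single derived developmental event.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import optimize, stats

from .epochs import DerivedEvent

__all__ = [
    "ExpressionTimecourse",
    "PlateauFit",
    "OrthologMap",
    "fit_linear_plateau",
    "detect_plateaus",
    "cross_species_plateau_event",
]


@dataclass(frozen=True)
class ExpressionTimecourse:
    """One gene's normalized expression against sample age (PC days)."""

    gene: str
    species: str
    age_pc: np.ndarray
    expression: np.ndarray

    def __post_init__(self) -> None:
        age = np.asarray(self.age_pc, dtype=float)
        expr = np.asarray(self.expression, dtype=float)
        if age.shape != expr.shape or age.ndim != 1:
            raise ValueError("age_pc and expression must be 1-D arrays of equal length")
        if np.any(age <= 0):
            raise ValueError("ages must be positive PC days")
        order = np.argsort(age, kind="stable")
        object.__setattr__(self, "age_pc", age[order])
        object.__setattr__(self, "expression", expr[order])

    def __len__(self) -> int:
        return len(self.age_pc)

    def restricted(self, window: tuple[float, float]) -> "ExpressionTimecourse":
        lo, hi = window
        mask = (self.age_pc >= lo) & (self.age_pc <= hi)
        return ExpressionTimecourse(self.gene, self.species, self.age_pc[mask], self.expression[mask])


@dataclass(frozen=True)
class PlateauFit:
    gene: str
    species: str
    a: float
    b: float
    c: float
    p_a: float
    p_b: float
    p_c: float
    rss: float
    converged: bool
    n: int


@dataclass(frozen=True)
class OrthologMap:
    """One-to-one gene pairing between two species' analysis sets."""

    pairs: tuple[tuple[str, str], ...]

    def __post_init__(self) -> None:
        g1 = [a for a, _ in self.pairs]
        g2 = [b for _, b in self.pairs]
        if len(set(g1)) != len(g1) or len(set(g2)) != len(g2):
            raise ValueError("ortholog map must be one-to-one")

    def __len__(self) -> int:
        return len(self.pairs)


def _rss_at(c: float, x: np.ndarray, y: np.ndarray) -> tuple[float, float, float]:
    """OLS of y on min(x, c); returns (rss, a, b)."""
    z = np.minimum(x, c)
    zm, ym = z.mean(), y.mean()
    dz = z - zm
    denom = float(dz @ dz)
    if denom == 0.0:
        # all samples past the candidate breakpoint: intercept-only model
        r = y - ym
        return float(r @ r), float(ym), 0.0
    b = float(dz @ (y - ym)) / denom
    a = ym - b * zm
    r = y - (a + b * z)
    return float(r @ r), a, b


def fit_linear_plateau(
    tc: ExpressionTimecourse, n_grid: int = 200, boundary_tol: float = 1e-6
) -> PlateauFit:
    """Profile the breakpoint of the linear-plateau model.

    The candidate c runs over a dense grid spanning the ages that keep at
    least two distinct ages on each side of the breakpoint; the best grid
    cell is refined with bounded Brent minimisation.  (a, b)
    come from closed-form OLS at the chosen c.  Coefficient p-values are
    asymptotic t-tests with n - 3 residual degrees of freedom, using the
    nonlinear-least-squares covariance sigma^2 (J'J)^-1 where the
    Jacobian column for c is b * 1[x > c] — so a near-zero slope leaves
    the breakpoint uninformative and its p-value near 1.
    """
    x, y = tc.age_pc, tc.expression
    n = len(x)
    if n < 5:
        raise ValueError(f"need >= 5 samples, got {n}")
    if np.ptp(y) == 0:
        raise ValueError("no signal: expression has zero variance")
    ages = np.unique(x)
    if len(ages) < 4:
        raise ValueError("need >= 4 distinct ages to bracket a breakpoint")
    # candidate breakpoints must keep >= 2 distinct ages on each side
    lo, hi = float(ages[1]), float(ages[-2])

    grid = np.linspace(lo, hi, n_grid)
    rss_grid = np.array([_rss_at(c, x, y)[0] for c in grid])
    i = int(np.argmin(rss_grid))
    bl = grid[max(i - 1, 0)]
    bu = grid[min(i + 1, n_grid - 1)]
    if bu > bl:
        res = optimize.minimize_scalar(
            lambda c: _rss_at(c, x, y)[0], bounds=(bl, bu), method="bounded",
            options={"xatol": 1e-10 * (hi - lo)},
        )
        c_hat = float(res.x)
        if res.fun > rss_grid[i]:
            c_hat = float(grid[i])
    else:
        c_hat = float(grid[i])
    rss, a, b = _rss_at(c_hat, x, y)

    span = hi - lo
    converged = (c_hat - lo) > boundary_tol * span and (hi - c_hat) > boundary_tol * span

    df = n - 3
    sigma2 = rss / df if df > 0 else 0.0

    # asymptotic covariance from the model Jacobian at the optimum:
    # d/da = 1, d/db = min(x, c), d/dc = b * 1[x > c]
    J = np.column_stack([np.ones(n), np.minimum(x, c_hat), b * (x > c_hat)])
    if sigma2 == 0.0:
        # noiseless data: every estimated coefficient is exact
        p_a = p_b = p_c = 0.0
    else:
        jtj = J.T @ J
        if np.linalg.matrix_rank(jtj) < 3:
            # breakpoint column degenerate (b ~ 0 or no points past c):
            # c carries no information
            se = np.sqrt(sigma2 * np.diag(np.linalg.pinv(jtj)))
            p_c = 1.0
        else:
            se = np.sqrt(sigma2 * np.diag(np.linalg.inv(jtj)))
            p_c = 2 * stats.t.sf(abs(c_hat) / se[2], df) if se[2] > 0 else 1.0
        p_a = 2 * stats.t.sf(abs(a) / se[0], df) if se[0] > 0 else 0.0
        p_b = 2 * stats.t.sf(abs(b) / se[1], df) if se[1] > 0 else 0.0

    return PlateauFit(
        gene=tc.gene,
        species=tc.species,
        a=float(a),
        b=float(b),
        c=float(c_hat),
        p_a=float(p_a),
        p_b=float(p_b),
        p_c=float(p_c),
        rss=float(rss),
        converged=bool(converged),
        n=n,
    )


def detect_plateaus(
    dataset: Iterable[ExpressionTimecourse],
    window: tuple[float, float],
    alpha: float = 0.05,
    require_breakpoint_p: bool = True,
) -> dict[str, PlateauFit]:
    """Fit every time course inside an age window; keep significant plateaus.

    Retains only converged fits with all coefficient p-values below
    ``alpha`` (``require_breakpoint_p=False`` relaxes the test to the
    intercept and slope only).
    """
    lo, hi = window
    if hi <= lo:
        raise ValueError(f"empty window [{lo}, {hi}]")
    kept: dict[str, PlateauFit] = {}
    for tc in dataset:
        sub = tc.restricted(window)
        if len(sub) < 5:
            continue
        try:
            fit = fit_linear_plateau(sub)
        except ValueError:
            continue
        if not fit.converged:
            continue
        ps = [fit.p_a, fit.p_b] + ([fit.p_c] if require_breakpoint_p else [])
        if all(p < alpha for p in ps):
            kept[tc.gene] = fit
    return kept


def cross_species_plateau_event(
    fits_s1: Mapping[str, PlateauFit],
    fits_s2: Mapping[str, PlateauFit],
    orthologs: OrthologMap,
    event_name: str = "rna_expression_plateau",
) -> tuple[DerivedEvent, DerivedEvent]:
    """Average shared-ortholog breakpoint ages into one event per species.

    Genes whose plateau survives filtering in both species (paired through
    the ortholog map) contribute their breakpoint age; the per-species
    arithmetic means become two records of a single developmental event.
    """
    shared = [(g1, g2) for g1, g2 in orthologs.pairs if g1 in fits_s1 and g2 in fits_s2]
    if not shared:
        raise ValueError("no shared plateau genes between the two species")
    c1 = float(np.mean([fits_s1[g1].c for g1, _ in shared]))
    c2 = float(np.mean([fits_s2[g2].c for _, g2 in shared]))
    sp1 = next(iter(fits_s1.values())).species
    sp2 = next(iter(fits_s2.values())).species
    ev1 = DerivedEvent(species=sp1, event=event_name, day_pc=c1, limbic=True,
                       neurogenetic=False, source=f"mean plateau of {len(shared)} genes")
    ev2 = DerivedEvent(species=sp2, event=event_name, day_pc=c2, limbic=True,
                       neurogenetic=False, source=f"mean plateau of {len(shared)} genes")
    return ev1, ev2
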