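"""Does limbic neurogenesis end early, given the event scale?

For one species, log10 event timing is regressed on the event scale, a
limbic indicator, and their interaction:

    log10(day) ~ scale + limbic + scale:limbic

Terms are tested with sequential (Type-I) F statistics in that order, so
the interaction F asks whether limbic neurogenetic events traverse the
scale with a different slope — i.e. whether limbic neurogenesis
terminates earlier (shallower slope) than the rest of the timetable
predicts.  The overall model F and R^2 are reported alongside.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf
from statsmodels.stats.anova import anova_lm

from .events import EventTimingTable
from .event_model import EventScale

__all__ = ["LimbicModelResult", "fit_limbic_anova"]


@dataclass(frozen=True)
class LimbicModelResult:
    species: str
    f_model: float
    r2_model: float
    f_scale: float
    p_scale: float
    f_limbic: float
    p_limbic: float
    f_interaction: float
    p_interaction: float
    n: int
    df_resid: int

    def to_dict(self) -> dict:
        return {k: getattr(self, k) for k in self.__dataclass_fields__}


def fit_limbic_anova(
    table: EventTimingTable,
    scale: EventScale,
    species: str,
    ss_type: int = 1,
) -> LimbicModelResult:
    """Fit the limbic interaction model for one species.

    ``ss_type=1`` (default) gives sequential sums of squares in the order
    scale, limbic, scale:limbic; ``ss_type=2`` gives partial (Type-II)
    tests.  Requires at least 3 limbic and 3 non-limbic scored events.
    """
    sub = table.subset_species(species)
    sub = sub[sub["event"].isin(scale.scores)]
    n_limbic = int(sub["limbic"].sum())
    n_other = int((~sub["limbic"]).sum())
    if n_limbic == 0 or n_other == 0:
        raise ValueError("limbic factor not estimable: only one class present")
    if n_limbic < 3 or n_other < 3:
        raise ValueError(
            f"need >= 3 events per limbic class, got {n_limbic} limbic / {n_other} other"
        )
    if len(sub) <= 4:
        raise ValueError("need more than 4 events to fit 4 coefficients")

    df = pd.DataFrame(
        {
            "y": np.log10(sub["day_pc"].to_numpy()),
            "x": [scale[e] for e in sub["event"]],
            "limbic": sub["limbic"].to_numpy().astype(int),
        }
    )
    fit = smf.ols("y ~ x + limbic + x:limbic", data=df).fit()
    table_anova = anova_lm(fit, typ=ss_type)
    return LimbicModelResult(
        species=species,
        f_model=float(fit.fvalue),
        r2_model=float(fit.rsquared),
        f_scale=float(table_anova.loc["x", "F"]),
        p_scale=float(table_anova.loc["x", "PR(>F)"]),
        f_limbic=float(table_anova.loc["limbic", "F"]),
        p_limbic=float(table_anova.loc["limbic", "PR(>F)"]),
        f_interaction=float(table_anova.loc["x:limbic", "F"]),
        p_interaction=float(table_anova.loc["x:limbic", "PR(>F)"]),
        n=len(df),
        df_resid=int(fit.df_resid),
    )
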