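"""Alpha diversity and the univariate test battery.

Richness (observed OTUs) and Shannon diversity (natural log) per
sample; Shapiro-Wilk and Levene prechecks; one-way ANOVA with Tukey HSD
pairwise comparisons rendered as a compact letter display (groups
sharing a letter are not significantly different); optional two-way
ANOVA with interaction (compartment x month) for diversity responses.

Prechecks are reported alongside the ANOVA rather than gating it: a
failed normality or homogeneity check flags the result but the
parametric test still runs.
"""

from __future__ import annotations

import dataclasses
import itertools

import numpy as np
import pandas as pd
import scipy.stats as st
import statsmodels.api as sm
import statsmodels.formula.api as smf

from .io import DesignError, OtuCountTable
from .preprocess import relative_abundance


def alpha_diversity(table: OtuCountTable) -> pd.DataFrame:
    """Per-sample richness (count > 0) and Shannon index in nats."""
    comp = relative_abundance(table)
    richness = (table.counts > 0).sum(axis=1)
    shannon = comp.apply(lambda row: st.entropy(row[row > 0]), axis=1)
    return pd.DataFrame({"richness": richness, "shannon": shannon})


def shapiro_wilk(values) -> tuple[float, float]:
    """Shapiro-Wilk W and p (3 <= n <= 5000, non-constant input)."""
    x = np.asarray(values, dtype=float)
    if x.size < 3 or x.size > 5000:
        raise DesignError(f"Shapiro-Wilk requires 3 <= n <= 5000, got {x.size}")
    if np.ptp(x) == 0:
        raise DesignError("Shapiro-Wilk undefined for constant input")
    res = st.shapiro(x)
    return float(res.statistic), float(res.pvalue)


def levene_test(groups, center: str = "mean") -> tuple[float, float]:
    """Levene's homogeneity-of-variance test (Brown-Forsythe with
    ``center='median'``)."""
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2:
        raise DesignError("Levene's test needs at least two groups")
    if any(g.size < 2 for g in groups):
        raise DesignError("each group needs n >= 2")
    devs = [np.abs(g - (np.mean(g) if center == "mean" else np.median(g)))
            for g in groups]
    if np.ptp(np.concatenate(devs)) == 0:
        # every absolute deviation identical (e.g. all groups constant): 0/0
        raise DesignError("no spread in absolute deviations; F undefined")
    with np.errstate(divide="ignore"):  # zero within-group spread -> F = inf
        res = st.levene(*groups, center=center)
    return float(res.statistic), float(res.pvalue)


@dataclasses.dataclass(frozen=True)
class AnovaTukeyResult:
    levels: list[str]
    F: float
    p: float
    tukey_p: pd.DataFrame  # symmetric level-by-level p matrix
    group_letters: dict[str, str]
    group_means: dict[str, float]
    shapiro: dict[str, tuple[float, float] | None]
    levene: tuple[float, float]

    def summary(self) -> pd.DataFrame:
        """Table-style 'mean +/- SD letter' rows per level."""
        rows = [
            {"level": lev, "mean": self.group_means[lev], "letters": self.group_letters[lev]}
            for lev in self.levels
        ]
        return pd.DataFrame(rows)


def anova_tukey(values, groups, conf: float = 0.95) -> AnovaTukeyResult:
    """One-way ANOVA + Tukey HSD + compact letter display.

    ``groups`` are level labels parallel to ``values``.  Pairs with
    Tukey p below 1 - ``conf`` are considered different when assigning
    letters.
    """
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    levels = sorted(pd.unique(groups).tolist())
    if len(levels) < 2:
        raise DesignError("ANOVA needs at least two levels")
    arrays = [values[groups == lev] for lev in levels]
    if any(a.size < 2 for a in arrays):
        raise DesignError("each level needs n >= 2")
    pooled_resid = np.concatenate([a - a.mean() for a in arrays])
    if np.allclose(pooled_resid, 0):
        raise DesignError("zero residual variance; F undefined")
    F, p = st.f_oneway(*arrays)
    # prechecks: per-group normality (skipped for n < 3), variance homogeneity
    shapiro: dict[str, tuple[float, float] | None] = {}
    for lev, a in zip(levels, arrays):
        try:
            shapiro[lev] = shapiro_wilk(a)
        except DesignError:
            shapiro[lev] = None
    levene = levene_test(arrays)
    hsd = st.tukey_hsd(*arrays)
    pmat = pd.DataFrame(hsd.pvalue, index=levels, columns=levels)
    differ = {
        frozenset((a, b))
        for a, b in itertools.combinations(levels, 2)
        if pmat.loc[a, b] < (1 - conf)
    }
    means = {lev: float(a.mean()) for lev, a in zip(levels, arrays)}
    letters = compact_letter_display(levels, differ, means)
    return AnovaTukeyResult(
        levels=levels, F=float(F), p=float(p), tukey_p=pmat,
        group_letters=letters, group_means=means, shapiro=shapiro, levene=levene,
    )


def compact_letter_display(
    levels: list[str],
    differ: set[frozenset],
    means: dict[str, float] | None = None,
) -> dict[str, str]:
    """Insert-and-absorb letter assignment.

    Start with one letter shared by all levels; for each significantly
    different pair split every letter group containing both; absorb
    groups contained in others.  Letters are ordered by descending
    group mean so 'a' marks the highest-mean group.
    """
    groups: list[set] = [set(levels)]
    for pair in sorted(differ, key=sorted):
        a, b = sorted(pair)
        for g in [g for g in groups if a in g and b in g]:
            groups.remove(g)
            for candidate in (g - {a}, g - {b}):
                if candidate and not any(candidate <= other for other in groups):
                    groups.append(candidate)
        groups = [g for g in groups if not any(g < other for other in groups)]
    if means:
        groups.sort(key=lambda g: -max(means[lev] for lev in g))
    else:
        groups.sort(key=lambda g: sorted(g))
    alphabet = "abcdefghijklmnopqrstuvwxyz"
    out = {lev: "" for lev in levels}
    for letter, g in zip(alphabet, groups):
        for lev in g:
            out[lev] += letter
    return {lev: "".join(sorted(s)) for lev, s in out.items()}


def anova_two_way(
    data: pd.DataFrame, response: str, factor_a: str, factor_b: str
) -> pd.DataFrame:
    """Two-way ANOVA with interaction (sequential sums of squares)."""
    for col in (response, factor_a, factor_b):
        if col not in data.columns:
            raise DesignError(f"column {col!r} missing from data")
    df = data[[response, factor_a, factor_b]].copy()
    df.columns = ["y", "a", "b"]
    df["a"] = df["a"].astype(str)
    df["b"] = df["b"].astype(str)
    model = smf.ols("y ~ C(a) * C(b)", data=df).fit()
    table = sm.stats.anova_lm(model, typ=1)
    table.index = [
        idx.replace("C(a)", factor_a).replace("C(b)", factor_b) for idx in table.index
    ]
    return table
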