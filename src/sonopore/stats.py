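"""Statistical decision tree for the 3-treatment x 3-temperature design.

The experiment crosses three treatments (US+UCA, US, UCA) with three bath
temperatures (37, 39.5, 42 degC), n = 3 biological replicates per cell.
Each response (transfected fraction, cell loss, apoptotic fraction) is
routed through one decision tree at alpha = 0.05:

1. Assumptions: Shapiro-Wilk normality on the residuals from cell means,
   and Bartlett's homogeneity of variance across the nine cells.
2. If both pass: balanced two-way fixed-effects ANOVA with interaction,
   then Tukey HSD on significant main effects.
3. Otherwise: Kruskal-Wallis per factor (pooled over the other factor),
   then pairwise Wilcoxon rank-sum tests with Holm adjustment on
   significant factors. Interactions cannot be assessed on this branch and
   are reported as not assessed.

Exposed both as functions and as a model/results pair:
``FactorialExperiment.from_dataframe(df).fit()`` returns a
:class:`StatReport` carrying every branch decision, with ``summary()``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.formula.api import ols
from statsmodels.stats.anova import anova_lm
from statsmodels.stats.multicomp import pairwise_tukeyhsd
from statsmodels.stats.multitest import multipletests

from .exceptions import DegenerateDataError, UnsupportedDesignError

__all__ = [
    "TREATMENTS",
    "TEMPERATURES",
    "AssumptionReport",
    "StatReport",
    "FactorialExperiment",
    "check_assumptions",
    "two_way_anova",
    "nonparametric_tests",
    "run_decision_tree",
]

TREATMENTS = ("US+UCA", "US", "UCA")
TEMPERATURES = (37.0, 39.5, 42.0)


def _validate(df: pd.DataFrame, response: str, factors: Sequence[str]) -> pd.DataFrame:
    for col in (*factors, response):
        if col not in df.columns:
            raise ValueError(f"missing column {col!r}")
    out = df.copy()
    if not np.all(np.isfinite(out[response].astype(float))):
        raise ValueError("response values must be finite")
    return out


def _cells(df: pd.DataFrame, response: str, factors: Sequence[str]):
    return [g[response].to_numpy(dtype=float) for _, g in df.groupby(list(factors))]


@dataclass
class AssumptionReport:
    shapiro_p: float
    bartlett_p: float
    branch: str  # "parametric" | "nonparametric"
    alpha: float


def check_assumptions(
    df: pd.DataFrame,
    response: str = "response",
    factors: Sequence[str] = ("treatment", "temperature"),
    alpha: float = 0.05,
) -> AssumptionReport:
    """Shapiro-Wilk on cell-mean residuals and Bartlett across cells.

    The parametric branch is chosen iff both p-values exceed alpha. With
    n = 3 per cell, per-cell normality testing is impossible, so normality
    is assessed on the pooled residuals from the cell means.
    """
    df = _validate(df, response, factors)
    cells = _cells(df, response, factors)
    if len(cells) < 2:
        raise ValueError("need at least two factor-level cells")
    if any(len(c) < 2 for c in cells):
        raise ValueError("each cell needs at least two observations")
    residuals = np.concatenate([c - c.mean() for c in cells])
    if np.allclose(residuals, 0.0):
        raise DegenerateDataError(
            "responses are constant within every cell; assumption tests undefined"
        )
    shapiro_p = float(sps.shapiro(residuals).pvalue)
    bartlett_p = float(sps.bartlett(*cells).pvalue)
    branch = "parametric" if (shapiro_p > alpha and bartlett_p > alpha) else "nonparametric"
    return AssumptionReport(shapiro_p, bartlett_p, branch, alpha)


def _check_balanced(df: pd.DataFrame, response: str, factors: Sequence[str]) -> None:
    sizes = df.groupby(list(factors))[response].size()
    if sizes.min() < 2:
        raise UnsupportedDesignError("need n >= 2 replicates per cell")
    if sizes.nunique() != 1:
        raise UnsupportedDesignError(
            "unbalanced designs are not supported (the study design is balanced)"
        )


def two_way_anova(
    df: pd.DataFrame,
    response: str = "response",
    factors: Sequence[str] = ("treatment", "temperature"),
    alpha: float = 0.05,
) -> dict:
    """Balanced fixed-effects two-way ANOVA with interaction + Tukey HSD.

    Returns a dict with the ANOVA table, per-effect p-values and, for each
    significant main effect, a Tukey HSD table over that factor's levels
    (pooled over the other factor). A zero residual mean square (noiseless
    cells) yields p = 0 for effects with positive sum of squares.
    """
    df = _validate(df, response, factors)
    _check_balanced(df, response, factors)
    fa, fb = factors
    work = df.rename(columns={response: "_y", fa: "_a", fb: "_b"})
    work["_a"] = work["_a"].astype(str)
    work["_b"] = work["_b"].astype(str)
    model = ols("_y ~ C(_a) * C(_b)", data=work).fit()
    with np.errstate(divide="ignore", invalid="ignore"):
        table = anova_lm(model, typ=2)
    ss = table["sum_sq"]
    total_ss = float(ss.sum())
    resid_ss = float(ss.loc["Residual"])
    if total_ss > 0 and resid_ss <= 1e-12 * total_ss:
        # zero-noise limit: F is infinite for any effect with signal
        for term in table.index[:-1]:
            if ss.loc[term] > 0:
                table.loc[term, "F"] = np.inf
                table.loc[term, "PR(>F)"] = 0.0
    key = {fa: "C(_a)", fb: "C(_b)", "interaction": "C(_a):C(_b)"}
    pvals = {
        fa: float(table.loc[key[fa], "PR(>F)"]),
        fb: float(table.loc[key[fb], "PR(>F)"]),
        "interaction": float(table.loc[key["interaction"], "PR(>F)"]),
    }
    posthoc: dict[str, pd.DataFrame] = {}
    for factor, col in ((fa, "_a"), (fb, "_b")):
        if pvals[factor] < alpha:
            tk = pairwise_tukeyhsd(work["_y"], work[col], alpha=alpha)
            posthoc[factor] = pd.DataFrame(
                tk.summary().data[1:], columns=tk.summary().data[0]
            )
    table = table.rename(index={v: k for k, v in key.items()})
    return {"anova_table": table, "p_values": pvals, "tukey": posthoc}


def nonparametric_tests(
    df: pd.DataFrame,
    response: str = "response",
    factors: Sequence[str] = ("treatment", "temperature"),
    alpha: float = 0.05,
) -> dict:
    """Kruskal-Wallis per factor plus pairwise Wilcoxon rank-sum tests.

    Each factor is tested marginally on data pooled over the other factor
    (rank tests cannot assess interactions). For significant factors, all
    level pairs are compared with the two-sided Wilcoxon rank-sum test and
    Holm-adjusted.
    """
    df = _validate(df, response, factors)
    y = df[response].to_numpy(dtype=float)
    if np.unique(y).size == 1:
        raise DegenerateDataError("all responses tied; rank tests undefined")
    pvals: dict[str, float] = {}
    pairwise: dict[str, pd.DataFrame] = {}
    for factor in factors:
        levels = list(pd.unique(df[factor]))
        groups = [y[(df[factor] == lv).to_numpy()] for lv in levels]
        try:
            pvals[factor] = float(sps.kruskal(*groups).pvalue)
        except ValueError as err:  # all values identical
            raise DegenerateDataError(f"degenerate ranks for factor {factor!r}") from err
        if pvals[factor] < alpha:
            rows = []
            for i in range(len(levels)):
                for j in range(i + 1, len(levels)):
                    p = float(sps.ranksums(groups[i], groups[j]).pvalue)
                    rows.append((levels[i], levels[j], p))
            raw = [r[2] for r in rows]
            adj = multipletests(raw, method="holm")[1]
            pairwise[factor] = pd.DataFrame(
                [(a, b, p, q) for (a, b, p), q in zip(rows, adj)],
                columns=["level_1", "level_2", "p_raw", "p_holm"],
            )
    return {"p_values": pvals, "pairwise": pairwise}


@dataclass
class StatReport:
    """Routed test results for one response variable.

    Carries the assumption checks, the branch taken, per-effect p-values
    and post-hoc tables. ``summary()`` renders a human-readable report.
    """

    response: str
    factors: tuple
    alpha: float
    shapiro_p: float
    bartlett_p: float
    branch: str
    p_values: dict
    posthoc: dict
    anova_table: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        for name, p in (("shapiro", self.shapiro_p), ("bartlett", self.bartlett_p)):
            if not (0.0 <= p <= 1.0):
                raise ValueError(f"{name} p-value outside [0, 1]")
        for k, p in self.p_values.items():
            if p is not None and not (0.0 <= p <= 1.0):
                raise ValueError(f"p-value for {k!r} outside [0, 1]")

    def significant(self, effect: str) -> bool:
        p = self.p_values.get(effect)
        return p is not None and p < self.alpha

    def to_dict(self) -> dict:
        return {
            "response": self.response,
            "factors": list(self.factors),
            "alpha": self.alpha,
            "shapiro_p": self.shapiro_p,
            "bartlett_p": self.bartlett_p,
            "branch": self.branch,
            "p_values": self.p_values,
            "posthoc": {
                k: v.to_dict(orient="records") for k, v in self.posthoc.items()
            },
        }

    def summary(self) -> str:
        lines = [
            f"Response: {self.response}",
            f"Factors: {' x '.join(map(str, self.factors))} (alpha = {self.alpha})",
            f"Shapiro-Wilk (residuals) p = {self.shapiro_p:.4g}",
            f"Bartlett (9 cells)       p = {self.bartlett_p:.4g}",
            f"Branch: {self.branch}",
        ]
        for effect, p in self.p_values.items():
            shown = "not assessed" if p is None else f"p = {p:.4g}"
            mark = ""
            if p is not None:
                mark = "  *" if p < self.alpha else ""
            lines.append(f"  effect {effect}: {shown}{mark}")
        for factor, tab in self.posthoc.items():
            lines.append(f"Post hoc ({factor}):")
            lines.append(tab.to_string(index=False))
        return "\n".join(lines)


def run_decision_tree(
    df: pd.DataFrame,
    response: str = "response",
    factors: Sequence[str] = ("treatment", "temperature"),
    alpha: float = 0.05,
) -> StatReport:
    """Assumption checks, branch routing, omnibus tests and post hocs."""
    assumptions = check_assumptions(df, response, factors, alpha)
    fa, fb = factors
    if assumptions.branch == "parametric":
        res = two_way_anova(df, response, factors, alpha)
        p_values = res["p_values"]
        posthoc = res["tukey"]
        table = res["anova_table"]
    else:
        res = nonparametric_tests(df, response, factors, alpha)
        p_values = {**res["p_values"], "interaction": None}
        posthoc = res["pairwise"]
        table = None
    return StatReport(
        response=response,
        factors=tuple(factors),
        alpha=alpha,
        shapiro_p=assumptions.shapiro_p,
        bartlett_p=assumptions.bartlett_p,
        branch=assumptions.branch,
        p_values=p_values,
        posthoc=posthoc,
        anova_table=table,
    )


class FactorialExperiment:
    """Two-factor factorial experiment with replicate-level responses.

    Model object wrapping a tidy replicate table; ``fit()`` routes the data
    through the decision tree and returns a :class:`StatReport`.

    Parameters
    ----------
    data : DataFrame
        Tidy table with one row per replicate.
    response : str
        Name of the response column.
    factors : (str, str)
        Names of the two factor columns (default treatment, temperature).
    """

    def __init__(
        self,
        data: pd.DataFrame,
        response: str = "response",
        factors: Sequence[str] = ("treatment", "temperature"),
    ) -> None:
        self.data = _validate(data, response, factors)
        self.response = response
        self.factors = tuple(factors)

    @classmethod
    def from_dataframe(cls, data: pd.DataFrame, **kwargs) -> "FactorialExperiment":
        return cls(data, **kwargs)

    @classmethod
    def from_csv(cls, path, **kwargs) -> "FactorialExperiment":
        return cls(pd.read_csv(path), **kwargs)

    def fit(self, alpha: float = 0.05) -> StatReport:
        return run_decision_tree(self.data, self.response, self.factors, alpha)
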