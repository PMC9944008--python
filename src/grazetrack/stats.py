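"""Stoichiometric quantities and the grazing-experiment statistical layer.

Covers molar C:P ratios, percent reductions, per-individual grazing rates,
two-group comparisons (Student, Welch, Wilcoxon-Mann-Whitney), balanced
2 x 2 factorial ANOVA with Tukey HSD, and the usual Shapiro-Wilk / Levene
assumption checks. A summary-statistic entry point for the t-tests supports
comparisons when only printed means/SDs/n are available.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
import statsmodels.api as sm
from statsmodels.formula.api import ols
from statsmodels.stats.multicomp import pairwise_tukeyhsd

ATOMIC_MASS_C = 12.011
ATOMIC_MASS_P = 30.974


def molar_cp(c_mass_ug: float, p_mass_ug: float) -> float:
    """Molar C:P ratio from carbon and phosphorus masses (same mass unit)."""
    if p_mass_ug <= 0:
        raise ValueError("P mass must be positive (C:P undefined at P = 0)")
    if c_mass_ug < 0:
        raise ValueError("C mass must be >= 0")
    return (c_mass_ug / ATOMIC_MASS_C) / (p_mass_ug / ATOMIC_MASS_P)


def percent_reduction(control_mean: float, treated_mean: float) -> float:
    """Percent reduction of the treated mean relative to the control mean."""
    if control_mean <= 0:
        raise ValueError("control mean must be positive")
    return 100.0 * (control_mean - treated_mean) / control_mean


def grazing_rate(
    control_mean_dm_mg_cm2: float,
    grazed_dm_mg_cm2: float,
    substrate_cm2: float,
    n_grazers: int,
    duration_h: float,
) -> float:
    """Per-individual grazing rate in ug dry mass h^-1 ind^-1.

    Computed from the dry-mass difference between ungrazed and grazed
    substrate, scaled to the full substrate area and shared over grazers and
    exposure time. A negative difference (grazed exceeding control) is
    returned as 0 with a warning.
    """
    if duration_h <= 0:
        raise ValueError("duration must be positive")
    if n_grazers < 1:
        raise ValueError("need at least one grazer")
    if substrate_cm2 <= 0:
        raise ValueError("substrate area must be positive")
    diff = control_mean_dm_mg_cm2 - grazed_dm_mg_cm2
    if diff < 0:
        warnings.warn("grazed dry mass exceeds control; rate clipped to 0", stacklevel=2)
        return 0.0
    return diff * 1000.0 * substrate_cm2 / (n_grazers * duration_h)


@dataclass(frozen=True)
class GroupSummary:
    """Summary statistics of one sample group (for printed-table reanalysis)."""

    mean: float
    sd: float
    n: int

    def __post_init__(self) -> None:
        if self.sd < 0:
            raise ValueError("sd must be >= 0")
        if self.n < 2:
            raise ValueError("n must be >= 2")

    @classmethod
    def from_data(cls, x: Sequence[float]) -> "GroupSummary":
        x = np.asarray(x, dtype=float)
        return cls(mean=float(x.mean()), sd=float(x.std(ddof=1)), n=len(x))


@dataclass(frozen=True)
class TestResult:
    name: str
    statistic: float
    df: float | None
    p_value: float
    groups: tuple[GroupSummary, ...] = ()
    note: str = ""
    extra: dict = field(default_factory=dict)


def _summary(x) -> GroupSummary:
    return x if isinstance(x, GroupSummary) else GroupSummary.from_data(x)


def compare_two_groups(a, b, method: str = "student") -> TestResult:
    """Two-group comparison.

    ``a`` and ``b`` are raw samples (sequences) or :class:`GroupSummary`
    objects (``student``/``welch`` only). Methods: ``student`` (pooled
    variance, df = n1 + n2 - 2), ``welch`` (Satterthwaite df), ``wilcoxon``
    (Mann-Whitney rank sum, statistic = U of the first group; exact p when
    min(n) <= 8 and there are no ties, normal approximation without
    continuity correction otherwise; both branches are reported in
    ``extra`` when available).
    """
    if method not in ("student", "welch", "wilcoxon"):
        raise ValueError(f"unknown method {method!r}")
    summary_mode = isinstance(a, GroupSummary) or isinstance(b, GroupSummary)
    if method == "wilcoxon":
        if summary_mode:
            raise ValueError("wilcoxon requires raw data")
        return _wilcoxon(np.asarray(a, float), np.asarray(b, float))
    ga, gb = _summary(a), _summary(b)
    if ga.sd == 0 and gb.sd == 0 and ga.mean == gb.mean:
        return TestResult(
            name=f"{method}_t",
            statistic=float("nan"),
            df=None,
            p_value=float("nan"),
            groups=(ga, gb),
            note="t undefined: zero variance in both groups with equal means",
        )
    equal_var = method == "student"
    res = sps.ttest_ind_from_stats(
        ga.mean, ga.sd, ga.n, gb.mean, gb.sd, gb.n, equal_var=equal_var
    )
    if equal_var:
        df = float(ga.n + gb.n - 2)
    else:
        va, vb = ga.sd**2 / ga.n, gb.sd**2 / gb.n
        df = (va + vb) ** 2 / (va**2 / (ga.n - 1) + vb**2 / (gb.n - 1))
    return TestResult(
        name=f"{method}_t",
        statistic=float(res.statistic),
        df=df,
        p_value=float(res.pvalue),
        groups=(ga, gb),
    )


def _wilcoxon(a: np.ndarray, b: np.ndarray) -> TestResult:
    ties = len(np.unique(np.concatenate([a, b]))) < len(a) + len(b)
    small = min(len(a), len(b)) <= 8
    extra: dict = {}
    if not ties:
        extra["p_exact"] = float(
            sps.mannwhitneyu(a, b, alternative="two-sided", method="exact").pvalue
        )
    approx = sps.mannwhitneyu(
        a, b, alternative="two-sided", method="asymptotic", use_continuity=False
    )
    extra["p_normal_approx"] = float(approx.pvalue)
    use_exact = small and not ties
    p = extra["p_exact"] if use_exact else extra["p_normal_approx"]
    note = "" if not ties else "ties present: exact enumeration unavailable, normal approximation used"
    return TestResult(
        name="wilcoxon_mann_whitney",
        statistic=float(approx.statistic),
        df=None,
        p_value=p,
        groups=(GroupSummary.from_data(a), GroupSummary.from_data(b)),
        note=note,
        extra=extra,
    )


@dataclass(frozen=True)
class FactorEffect:
    F: float
    df_num: float
    df_den: float
    p_value: float
    ss: float


@dataclass(frozen=True)
class AnovaTable:
    """Balanced two-way ANOVA table (type I and II coincide)."""

    factors: dict[str, FactorEffect]
    residual_df: float
    residual_ss: float

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"effect": k, "F": e.F, "df_num": e.df_num, "df_den": e.df_den, "p": e.p_value, "ss": e.ss}
            for k, e in self.factors.items()
        ]
        rows.append(
            {
                "effect": "residual",
                "F": float("nan"),
                "df_num": self.residual_df,
                "df_den": float("nan"),
                "p": float("nan"),
                "ss": self.residual_ss,
            }
        )
        return pd.DataFrame(rows)


def factorial_anova(
    data: pd.DataFrame,
    response: str,
    factor_a: str,
    factor_b: str,
) -> tuple[AnovaTable, pd.DataFrame]:
    """Balanced 2 x 2 two-way ANOVA with interaction, plus Tukey HSD on the
    four cell means.

    Rejects unbalanced or non-2-level designs and cells with fewer than two
    replicates. Returns the ANOVA table and a Tukey pairwise DataFrame
    (group1, group2, meandiff, p_adj, lower, upper, reject).
    """
    df = data[[response, factor_a, factor_b]].copy()
    df.columns = ["y", "A", "B"]
    if df["A"].nunique() != 2 or df["B"].nunique() != 2:
        raise ValueError("both factors must have exactly two levels")
    counts = df.groupby(["A", "B"], sort=True).size()
    if len(counts) != 4:
        raise ValueError("all four factor-level cells must be present")
    if counts.nunique() != 1:
        raise ValueError("design must be balanced (equal cell sizes)")
    if counts.iloc[0] < 2:
        raise ValueError("need at least two replicates per cell")

    model = ols("y ~ C(A) * C(B)", data=df).fit()
    table = sm.stats.anova_lm(model, typ=2)
    names = {"C(A)": factor_a, "C(B)": factor_b, "C(A):C(B)": f"{factor_a}:{factor_b}"}
    resid_df = float(table.loc["Residual", "df"])
    resid_ss = float(table.loc["Residual", "sum_sq"])
    factors = {}
    for key, label in names.items():
        factors[label] = FactorEffect(
            F=float(table.loc[key, "F"]),
            df_num=float(table.loc[key, "df"]),
            df_den=resid_df,
            p_value=float(table.loc[key, "PR(>F)"]),
            ss=float(table.loc[key, "sum_sq"]),
        )
    anova = AnovaTable(factors=factors, residual_df=resid_df, residual_ss=resid_ss)

    cells = df["A"].astype(str) + ":" + df["B"].astype(str)
    tukey = pairwise_tukeyhsd(df["y"].values, cells.values)
    tk = pd.DataFrame(
        tukey.summary().data[1:],
        columns=["group1", "group2", "meandiff", "p_adj", "lower", "upper", "reject"],
    )
    for c in ("meandiff", "p_adj", "lower", "upper"):
        tk[c] = tk[c].astype(float)
    return anova, tk


def assumption_checks(groups: Mapping[str, Sequence[float]]) -> dict:
    """Shapiro-Wilk per group plus Levene (center = mean) across groups.

    Groups with n < 3 or zero variance are skipped with a notice. Returns
    ``{"shapiro": {name: {"W": ..., "p": ...} | {"note": ...}},
    "levene": {"F": ..., "p": ...}}``.
    """
    shapiro = {}
    for name, x in groups.items():
        x = np.asarray(x, dtype=float)
        if len(x) < 3:
            shapiro[name] = {"note": "n < 3: Shapiro-Wilk not applicable"}
        elif np.ptp(x) == 0:
            shapiro[name] = {"note": "constant sample: Shapiro-Wilk undefined"}
        else:
            w, p = sps.shapiro(x)
            shapiro[name] = {"W": float(w), "p": float(p)}
    arrays = [np.asarray(x, dtype=float) for x in groups.values()]
    out: dict = {"shapiro": shapiro}
    if len(arrays) >= 2:
        F, p = sps.levene(*arrays, center="mean")
        out["levene"] = {"F": float(F), "p": float(p)}
    return out
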