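"""Distribution summaries and country-fixed-effects group comparisons.

Box-plot style summaries report the median, quartiles and the notch
half-width ``1.58 * IQR / sqrt(N)`` (an approximate 95% interval for the
median). Cross-group comparisons regress the outcome on demographic-group
indicators plus an indicator for every country; the country fixed effects
absorb all cross-country differences in price levels and food-list length,
so group contrasts reflect requirement differences only. Adjusted group
means are reported at the grand mean of the country effects, with
classical (homoskedastic) 95% confidence intervals.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .errors import ValidationError

NOTCH_FACTOR = 1.58


@dataclass(frozen=True)
class SummaryStats:
    median: float
    q25: float
    q75: float
    iqr: float
    notch_halfwidth: float
    n: int


def median_iqr_notch(values) -> SummaryStats:
    """Median, quartiles (linear interpolation) and notch half-width."""
    arr = np.asarray(list(values), dtype=float)
    if arr.size == 0:
        raise ValueError("median_iqr_notch requires a non-empty input")
    q25, med, q75 = np.quantile(arr, [0.25, 0.5, 0.75])
    iqr = q75 - q25
    return SummaryStats(
        median=float(med), q25=float(q25), q75=float(q75), iqr=float(iqr),
        notch_halfwidth=float(NOTCH_FACTOR * iqr / np.sqrt(arr.size)),
        n=int(arr.size),
    )


@dataclass(frozen=True)
class GroupEffectEstimate:
    group_id: str
    adjusted_mean: float
    ci_lower: float
    ci_upper: float
    n_countries: int
    reliable: bool  # False when the group appears in < 2 countries


def _design(panel: pd.DataFrame, factor: str, ref: str,
            countries: list[str]) -> tuple[np.ndarray, list[str], list[str]]:
    """Intercept + treatment-coded factor dummies + country dummies."""
    levels = sorted(panel[factor].unique())
    if ref not in levels:
        raise ValidationError(f"reference level {ref!r} not present")
    lv = [l for l in levels if l != ref]
    X = [np.ones(len(panel))]
    for l in lv:
        X.append((panel[factor] == l).to_numpy(float))
    for c in countries[1:]:
        X.append((panel["country_id"] == c).to_numpy(float))
    return np.column_stack(X), levels, lv


def fe_group_means(panel: pd.DataFrame, outcome: str = "value",
                   reference_group: str | None = None,
                   ) -> list[GroupEffectEstimate]:
    """Country-fixed-effects adjusted mean per demographic group.

    ``panel`` needs columns ``country_id``, ``group_id`` and the outcome.
    The adjusted mean for group g is the model prediction for g averaged
    over the country effects, so adding any per-country constant to the
    outcome shifts all means equally and leaves contrasts unchanged.
    Groups observed in fewer than 2 countries are flagged unreliable.
    """
    panel = panel.dropna(subset=[outcome])
    countries = sorted(panel["country_id"].unique())
    groups = sorted(panel["group_id"].unique())
    if len(countries) < 2 or len(groups) < 2:
        raise ValidationError("panel needs >= 2 countries and >= 2 groups")
    ref = reference_group or groups[0]
    X, levels, lv = _design(panel, "group_id", ref, countries)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValidationError("collinear design matrix")
    fit = sm.OLS(panel[outcome].to_numpy(float), X).fit()
    n_c = len(countries)
    # weights for averaging over country effects (first country is baseline)
    country_w = np.full(n_c - 1, 1.0 / n_c)
    out = []
    counts = panel.groupby("group_id")["country_id"].nunique()
    for g in levels:
        L = np.zeros(X.shape[1])
        L[0] = 1.0
        if g != ref:
            L[1 + lv.index(g)] = 1.0
        L[1 + len(lv):] = country_w
        tt = fit.t_test(L)
        lo, hi = np.atleast_2d(tt.conf_int())[0]
        out.append(GroupEffectEstimate(
            group_id=g,
            adjusted_mean=float(np.atleast_1d(tt.effect)[0]),
            ci_lower=float(lo), ci_upper=float(hi),
            n_countries=int(counts[g]),
            reliable=bool(counts[g] >= 2),
        ))
    return out


@dataclass(frozen=True)
class ContrastEstimate:
    estimate: float
    ci_lower: float
    ci_upper: float
    label: str


def adjusted_income_contrast(panel: pd.DataFrame,
                             income_groups: dict[str, str],
                             outcome: str = "value",
                             low_class: str = "low",
                             high_class: str = "high",
                             ) -> ContrastEstimate:
    """Low- minus high-income adjusted mean of an outcome.

    Regresses the outcome (e.g. grams/day of one food category) on income-
    class indicators with demographic-group fixed effects; returns the
    adjusted low-vs-high difference with its 95% CI.
    """
    panel = panel.dropna(subset=[outcome]).copy()
    panel["income_class"] = panel["country_id"].map(income_groups)
    classes = sorted(panel["income_class"].dropna().unique())
    if len(classes) < 2:
        raise ValidationError("need >= 2 income classes for a contrast")
    for cls in (low_class, high_class):
        if cls not in classes:
            raise ValidationError(f"income class {cls!r} not present")
    groups = sorted(panel["group_id"].unique())
    cls_lv = [c for c in classes if c != high_class]
    X = [np.ones(len(panel))]
    for c in cls_lv:
        X.append((panel["income_class"] == c).to_numpy(float))
    for g in groups[1:]:
        X.append((panel["group_id"] == g).to_numpy(float))
    X = np.column_stack(X)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValidationError("collinear design matrix")
    fit = sm.OLS(panel[outcome].to_numpy(float), X).fit()
    L = np.zeros(X.shape[1])
    L[1 + cls_lv.index(low_class)] = 1.0
    tt = fit.t_test(L)
    lo, hi = np.atleast_2d(tt.conf_int())[0]
    return ContrastEstimate(
        estimate=float(np.atleast_1d(tt.effect)[0]),
        ci_lower=float(lo), ci_upper=float(hi),
        label=f"{low_class} - {high_class}",
    )
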