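"""Attrition accounting and multinomial logistic attrition modelling.

Given an individual-level multi-wave cohort, this module tabulates the five
attrition states per survey, filters to complete cases, and fits a
five-outcome multinomial logistic regression of final (Survey-5) status on
baseline categorical risk factors, with ``respondent`` as the reference
outcome.  Odds ratios are exponentiated coefficients with Wald 95%
confidence intervals; a factor category is flagged significant for an
outcome when its CI excludes 1.  A two-stage screen mirrors common
model-building practice: factors associated with attrition on their own are
entered jointly, and factors with no significant category are dropped,
iterating to a fixed point.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .cohort_simulator import ATTRITION_OUTCOMES, STATUSES, CohortTable, RiskFactorSpec

__all__ = [
    "AttritionSummary",
    "ORTable",
    "SeparationError",
    "attrition_table",
    "complete_case_filter",
    "select_reference_category",
    "fit_attrition_model",
    "univariate_screen",
]

_Z975 = stats.norm.ppf(0.975)


class SeparationError(ValueError):
    """An empty factor-by-outcome cell makes the multinomial fit unidentifiable."""


@dataclass(frozen=True)
class AttritionSummary:
    """Per-survey attrition accounting.

    ``counts`` and ``proportions`` are survey-indexed frames with one column
    per status; denominators are the initial cohort size, so each row of
    ``proportions`` sums to 1 exactly.
    """

    counts: pd.DataFrame
    proportions: pd.DataFrame
    n_initial: int

    def __post_init__(self) -> None:
        if not np.allclose(self.proportions.sum(axis=1), 1.0, atol=1e-12):
            raise ValueError("status proportions must sum to 1 per survey")
        for st in ("dead", "frail", "withdrawn"):
            if (np.diff(self.proportions[st].to_numpy()) < -1e-12).any():
                raise ValueError(f"cumulative share of absorbing state {st!r} decreased")

    def to_percent_frame(self, decimals: int = 1) -> pd.DataFrame:
        return (self.proportions * 100).round(decimals)


def attrition_table(cohort: CohortTable) -> AttritionSummary:
    """Tabulate the five status shares at each survey (2..5)."""
    cols = cohort.status_columns
    if len(cols) != len(CohortTable.STATUS_COLUMNS):
        raise ValueError("cohort must carry statuses for surveys 2..5")
    cohort.validate()
    n = len(cohort)
    counts = {}
    for col in cols:
        survey = int(col[-1])
        vc = cohort.data[col].value_counts()
        counts[survey] = [int(vc.get(s, 0)) for s in STATUSES]
    counts_df = pd.DataFrame.from_dict(counts, orient="index", columns=list(STATUSES))
    counts_df.index.name = "survey"
    return AttritionSummary(counts_df, counts_df / n, n)


def complete_case_filter(
    cohort: CohortTable, factors: list[str]
) -> tuple[CohortTable, dict]:
    """Drop records missing any of the listed factors.

    Returns the filtered cohort and a report with per-factor missingness and
    the retained fraction of the initial sample.
    """
    unknown = [f for f in factors if f not in cohort.data.columns]
    if unknown:
        raise ValueError(f"unknown factors: {unknown}")
    n0 = len(cohort)
    missing = cohort.data[factors].isna()
    keep = ~missing.any(axis=1)
    n_keep = int(keep.sum())
    report = {
        "n_initial": n0,
        "n_complete": n_keep,
        "retained_fraction": n_keep / n0,
        "missingness": {f: float(missing[f].mean()) for f in factors},
    }
    if n_keep == 0:
        raise ValueError("complete-case filter removed every record")
    out = CohortTable(cohort.data.loc[keep].reset_index(drop=True), cohort.factors)
    return out, report


def select_reference_category(
    spec: RiskFactorSpec, counts: pd.Series | None = None
) -> str:
    """Reference category per the model-building rule.

    Nominal factors use the modal category (observed ``counts`` if given,
    otherwise the configured baseline distribution), breaking ties toward the
    first declared category with a warning.  Ordinal factors use the declared
    reference — the end category associated with the best survival.
    """
    if spec.scale == "ordinal":
        return spec.reference
    if counts is not None:
        freq = {c: float(counts.get(c, 0)) for c in spec.categories}
    else:
        freq = spec.prob_map
    best = max(freq.values())
    modal = [c for c in spec.categories if freq[c] == best]
    if len(modal) > 1:
        warnings.warn(
            f"{spec.name}: modal-frequency tie between {modal}; "
            f"using first declared category {modal[0]!r}",
            UserWarning,
            stacklevel=2,
        )
    return modal[0]


@dataclass(frozen=True)
class ORTable:
    """Odds ratios versus the respondent outcome, in long form.

    One row per (factor, category, outcome) with columns ``odds_ratio``,
    ``ci_low``, ``ci_high`` and ``significant``; reference categories carry
    OR exactly 1 and NaN CIs.  ``counts`` holds per-category N and % of the
    complete-case sample.
    """

    frame: pd.DataFrame
    counts: pd.DataFrame
    references: dict[str, str]
    n: int
    converged: bool
    llf: float

    def __post_init__(self) -> None:
        ref = self.frame["is_reference"]
        if not (self.frame.loc[ref, "odds_ratio"] == 1.0).all():
            raise ValueError("reference-category odds ratios must be exactly 1")
        est = self.frame.loc[~ref]
        if not (
            (est["ci_low"] <= est["odds_ratio"] + 1e-12)
            & (est["odds_ratio"] <= est["ci_high"] + 1e-12)
        ).all():
            raise ValueError("confidence interval does not bracket its odds ratio")
        flag = (est["ci_low"] > 1.0) | (est["ci_high"] < 1.0)
        if not (est["significant"] == flag).all():
            raise ValueError("significance flag inconsistent with CI-excludes-1 rule")

    def lookup(self, factor: str, category: str, outcome: str) -> pd.Series:
        f = self.frame
        row = f[(f["factor"] == factor) & (f["category"] == category) & (f["outcome"] == outcome)]
        if row.empty:
            raise KeyError((factor, category, outcome))
        return row.iloc[0]

    def significant_factors(self) -> list[str]:
        sig = self.frame[self.frame["significant"].eq(True)]
        return sorted(sig["factor"].unique())

    def to_wide(self, decimals: int = 2) -> pd.DataFrame:
        """Display layout: one row per category, OR (CI) columns per outcome."""
        rows = []
        for (factor, category), grp in self.frame.groupby(
            ["factor", "category"], sort=False
        ):
            cnt = self.counts[
                (self.counts["factor"] == factor) & (self.counts["category"] == category)
            ].iloc[0]
            row = {
                "factor": factor,
                "category": category,
                "N": int(cnt["n"]),
                "pct": round(100 * cnt["share"], 1),
            }
            for rec in grp.itertuples():
                row[f"or_{rec.outcome}"] = round(rec.odds_ratio, decimals)
                if rec.is_reference:
                    row[f"ci_{rec.outcome}"] = ""
                else:
                    row[f"ci_{rec.outcome}"] = (
                        f"({rec.ci_low:.{decimals}f},{rec.ci_high:.{decimals}f})"
                    )
            rows.append(row)
        return pd.DataFrame(rows)


def _design_matrix(
    data: pd.DataFrame, specs: list[RiskFactorSpec], references: dict[str, str]
) -> tuple[np.ndarray, list[tuple[str, str]]]:
    cols: list[np.ndarray] = [np.ones(len(data))]
    names: list[tuple[str, str]] = [("_const", "_const")]
    for spec in specs:
        for cat in spec.categories:
            if cat == references[spec.name]:
                continue
            cols.append((data[spec.name] == cat).to_numpy(dtype=float))
            names.append((spec.name, cat))
    return np.column_stack(cols), names


def _check_cells(data: pd.DataFrame, specs: list[RiskFactorSpec], status_col: str) -> None:
    for spec in specs:
        tab = pd.crosstab(data[spec.name], data[status_col])
        for cat in spec.categories:
            for outcome in STATUSES:
                if outcome in tab.columns and cat in tab.index:
                    if tab.loc[cat, outcome] == 0:
                        raise SeparationError(
                            f"empty cell: factor {spec.name!r}, category {cat!r}, "
                            f"outcome {outcome!r} has no observations"
                        )
                elif cat not in tab.index:
                    raise SeparationError(
                        f"factor {spec.name!r}: category {cat!r} unobserved in the data"
                    )


def fit_attrition_model(
    cohort: CohortTable,
    specs: list[RiskFactorSpec],
    status_col: str = "status_s5",
    references: dict[str, str] | None = None,
) -> ORTable:
    """Fit the five-outcome multinomial logit of final status on baseline factors.

    Complete cases only; respondent is the reference outcome and each
    factor's reference category follows :func:`select_reference_category`
    unless overridden.  Raises :class:`SeparationError` for empty
    factor-by-outcome cells and reports optimizer diagnostics on
    non-convergence.
    """
    from statsmodels.discrete.discrete_model import MNLogit

    data = cohort.data
    if status_col not in data.columns:
        raise ValueError(f"cohort has no {status_col!r} column")
    names = [s.name for s in specs]
    if data[names].isna().any().any():
        raise ValueError("missing factor values: apply complete_case_filter first")
    observed = set(data[status_col].unique())
    if len(observed) < 2 or "respondent" not in observed:
        raise ValueError("need respondents plus at least one attrition outcome to fit")
    _check_cells(data, specs, status_col)

    refs = {
        s.name: select_reference_category(s, counts=data[s.name].value_counts())
        for s in specs
    }
    if references:
        refs.update(references)
    exog, coef_names = _design_matrix(data, specs, refs)
    # Outcomes absent from the data contribute no equations; respondent stays
    # the reference (code 0).
    outcomes = [s for s in ATTRITION_OUTCOMES if s in observed]
    endog = pd.Categorical(data[status_col], categories=["respondent", *outcomes]).codes

    res = MNLogit(endog, exog).fit(method="newton", maxiter=100, tol=1e-10, disp=0)
    if not res.mle_retvals.get("converged", False):
        raise RuntimeError(
            "multinomial logit did not converge: "
            f"iterations={res.mle_retvals.get('iterations')}, "
            f"|score|={np.abs(res.score(res.params)).max():.3g}"
        )
    params = np.asarray(res.params)  # (k_exog, n_outcomes), columns = outcomes order
    bse = np.asarray(res.bse)

    rows = []
    for spec in specs:
        ref = refs[spec.name]
        ordered = [ref] + [c for c in spec.categories if c != ref]
        for cat in ordered:
            for j, outcome in enumerate(outcomes):
                if cat == ref:
                    rows.append(
                        dict(
                            factor=spec.name, category=cat, outcome=outcome,
                            odds_ratio=1.0, ci_low=np.nan, ci_high=np.nan,
                            significant=np.nan, is_reference=True,
                        )
                    )
                else:
                    k = coef_names.index((spec.name, cat))
                    beta, se = params[k, j], bse[k, j]
                    lo, hi = np.exp(beta - _Z975 * se), np.exp(beta + _Z975 * se)
                    rows.append(
                        dict(
                            factor=spec.name, category=cat, outcome=outcome,
                            odds_ratio=float(np.exp(beta)),
                            ci_low=float(lo), ci_high=float(hi),
                            significant=bool(lo > 1.0 or hi < 1.0),
                            is_reference=False,
                        )
                    )
    counts = pd.DataFrame(
        [
            dict(
                factor=s.name,
                category=c,
                n=int((data[s.name] == c).sum()),
                share=float((data[s.name] == c).mean()),
            )
            for s in specs
            for c in s.categories
        ]
    )
    return ORTable(
        frame=pd.DataFrame(rows),
        counts=counts,
        references=refs,
        n=len(data),
        converged=True,
        llf=float(res.llf),
    )


def univariate_screen(
    cohort: CohortTable,
    specs: list[RiskFactorSpec],
    status_col: str = "status_s5",
    max_rounds: int = 10,
) -> tuple[list[str], dict]:
    """Two-stage factor retention.

    Stage 1 fits each factor alone and keeps it if any category's CI excludes
    1 for any outcome.  Stage 2 fits the keepers jointly and drops factors
    with no significant category, refitting until stable (at most
    ``max_rounds`` rounds).  Returns the retained factor names and a report
    of every stage-wise decision.
    """
    by_name = {s.name: s for s in specs}
    report: dict = {"univariate": {}, "rounds": []}
    keep: list[str] = []
    for spec in specs:
        table = fit_attrition_model(cohort, [spec], status_col=status_col)
        sig = spec.name in table.significant_factors()
        report["univariate"][spec.name] = sig
        if sig:
            keep.append(spec.name)

    for _ in range(max_rounds):
        if not keep:
            break
        table = fit_attrition_model(cohort, [by_name[f] for f in keep], status_col=status_col)
        still = table.significant_factors()
        dropped = [f for f in keep if f not in still]
        report["rounds"].append({"entered": list(keep), "dropped": dropped})
        if not dropped:
            break
        keep = [f for f in keep if f in still]
    report["retained"] = list(keep)
    return keep, report
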