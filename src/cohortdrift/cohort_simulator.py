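"""Synthetic multi-wave cohort generator.

Emulates a longitudinal survey of older women (12,432 recruited at Survey 1,
followed to Survey 5) in which each participant ends up in one of five
attrition states per wave: still a respondent, dead, withdrawn due to
frailty, withdrawn for other reasons, or lost to follow up.  Baseline
categorical risk factors (country of birth, education, BMI group, physical
activity, alcohol, smoking, self-reported health) are drawn from configured
marginal distributions; final attrition status is drawn from a multinomial
logistic model whose log-odds-ratio coefficients are supplied as a fixture,
with intercepts calibrated so the expected status marginals hit configured
targets.  A separate wave-by-wave simulator draws per-survey transitions
from interval rates so cumulative attrition tracks a configured table.

Everything is deterministic under (configuration, seed).
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

STATUSES = ("respondent", "dead", "frail", "withdrawn", "lost")
#: Non-respondent statuses, i.e. the model outcomes with free coefficients.
ATTRITION_OUTCOMES = STATUSES[1:]

__all__ = [
    "STATUSES",
    "ATTRITION_OUTCOMES",
    "RiskFactorSpec",
    "AttritionModelSpec",
    "CohortTable",
    "CalibrationError",
    "generate_baseline",
    "enumerate_joint",
    "calibrate_intercepts",
    "assign_final_status",
    "interval_rates_from_marginals",
    "expand_to_surveys",
    "assign_transition_surveys",
    "impose_missingness",
    "assign_weights",
]


@dataclass(frozen=True)
class RiskFactorSpec:
    """One categorical baseline risk factor.

    ``baseline_probs`` are the marginal category probabilities (must sum to
    1); ``reference`` is the category against which odds ratios are
    parameterized — for ordinal factors it is the end category with the best
    survival, declared rather than inferred.
    """

    name: str
    categories: tuple[str, ...]
    baseline_probs: tuple[float, ...]
    reference: str
    scale: str = "nominal"

    def __post_init__(self) -> None:
        if len(self.categories) != len(self.baseline_probs):
            raise ValueError(f"{self.name}: categories and probabilities differ in length")
        if len(set(self.categories)) != len(self.categories):
            raise ValueError(f"{self.name}: duplicate category labels")
        probs = np.asarray(self.baseline_probs, dtype=float)
        if (probs < 0).any():
            raise ValueError(f"{self.name}: negative category probability")
        if abs(probs.sum() - 1.0) > 1e-9:
            raise ValueError(f"{self.name}: probabilities sum to {probs.sum()!r}, not 1")
        if self.reference not in self.categories:
            raise ValueError(f"{self.name}: reference {self.reference!r} not a category")
        if self.scale not in ("nominal", "ordinal"):
            raise ValueError(f"{self.name}: scale must be 'nominal' or 'ordinal'")
        object.__setattr__(self, "categories", tuple(self.categories))
        object.__setattr__(self, "baseline_probs", tuple(float(p) for p in probs))

    @property
    def prob_map(self) -> dict[str, float]:
        return dict(zip(self.categories, self.baseline_probs))


@dataclass(frozen=True)
class AttritionModelSpec:
    """Multinomial logistic model of final attrition status.

    ``respondent`` is the reference outcome (all-zero implicit coefficients);
    each non-respondent outcome has an intercept and per-(factor, category)
    log odds ratios versus the factor's reference category.
    """

    intercepts: dict[str, float]
    coefficients: dict[tuple[str, str, str], float]  # (outcome, factor, category)

    def __post_init__(self) -> None:
        missing = set(ATTRITION_OUTCOMES) - set(self.intercepts)
        if missing:
            raise ValueError(f"missing intercepts for outcomes: {sorted(missing)}")
        bad = [o for o, _, _ in self.coefficients if o not in ATTRITION_OUTCOMES]
        if bad:
            raise ValueError(f"coefficients for unknown outcomes: {sorted(set(bad))}")

    @classmethod
    def null(cls) -> "AttritionModelSpec":
        return cls(intercepts={o: 0.0 for o in ATTRITION_OUTCOMES}, coefficients={})

    @classmethod
    def from_or_table(cls, table: pd.DataFrame) -> "AttritionModelSpec":
        """Build from a long table with columns factor, category, outcome,
        odds_ratio (the shipped coefficient fixture's layout)."""
        coefs = {
            (row.outcome, row.factor, row.category): float(np.log(row.odds_ratio))
            for row in table.itertuples()
        }
        return cls(intercepts={o: 0.0 for o in ATTRITION_OUTCOMES}, coefficients=coefs)

    def with_intercepts(self, intercepts: Mapping[str, float]) -> "AttritionModelSpec":
        return replace(self, intercepts=dict(intercepts))

    def validate_against(self, specs: Sequence[RiskFactorSpec]) -> None:
        """Reject coefficients referencing unknown factors/categories or a
        factor's reference category (which must stay at log-OR 0)."""
        known = {s.name: set(s.categories) for s in specs}
        refs = {s.name: s.reference for s in specs}
        for outcome, factor, category in self.coefficients:
            if factor not in known:
                raise ValueError(f"coefficient references unknown factor {factor!r}")
            if category not in known[factor]:
                raise ValueError(
                    f"coefficient references unknown category {category!r} of {factor!r}"
                )
            if category == refs[factor]:
                raise ValueError(
                    f"coefficient on reference category {category!r} of {factor!r} "
                    f"(outcome {outcome!r}) is not identifiable"
                )

    def linear_predictors(self, data: pd.DataFrame) -> pd.DataFrame:
        """Per-row linear predictor for each non-respondent outcome."""
        factors = sorted({f for _, f, _ in self.coefficients})
        eta = pd.DataFrame(
            {o: np.full(len(data), self.intercepts[o]) for o in ATTRITION_OUTCOMES},
            index=data.index,
        )
        for outcome in ATTRITION_OUTCOMES:
            for fac in factors:
                lookup = {
                    cat: val
                    for (o, f, cat), val in self.coefficients.items()
                    if o == outcome and f == fac
                }
                if lookup:
                    eta[outcome] += data[fac].map(lookup).fillna(0.0).to_numpy()
        return eta

    def outcome_probabilities(self, data: pd.DataFrame) -> pd.DataFrame:
        """Row-wise five-outcome probabilities (respondent as baseline 0)."""
        eta = self.linear_predictors(data)
        expeta = np.exp(eta.to_numpy())
        denom = 1.0 + expeta.sum(axis=1)
        probs = np.column_stack([1.0 / denom, expeta / denom[:, None]])
        return pd.DataFrame(probs, columns=list(STATUSES), index=data.index)


class CohortTable:
    """Individual-level cohort records backed by a :class:`pandas.DataFrame`.

    Columns: ``id``, one column per risk factor (missing values are NaN),
    optionally ``area_stratum`` and ``weight``, and ``status_s2``..
    ``status_s5`` once attrition has been simulated.  Dead, frail and
    withdrawn are absorbing; lost may not revert to respondent.
    """

    STATUS_COLUMNS = tuple(f"status_s{k}" for k in range(2, 6))

    def __init__(self, data: pd.DataFrame, factors: Sequence[str]):
        if "id" not in data.columns:
            raise ValueError("cohort table requires an 'id' column")
        missing = [f for f in factors if f not in data.columns]
        if missing:
            raise ValueError(f"factor columns missing from table: {missing}")
        self.data = data.reset_index(drop=True)
        self.factors = list(factors)

    def __len__(self) -> int:
        return len(self.data)

    def copy(self) -> "CohortTable":
        return CohortTable(self.data.copy(), list(self.factors))

    @property
    def status_columns(self) -> list[str]:
        return [c for c in self.STATUS_COLUMNS if c in self.data.columns]

    def validate(self) -> None:
        """Check status vocabulary and absorbing-state rules."""
        cols = self.status_columns
        for col in cols:
            bad = set(self.data[col].dropna()) - set(STATUSES)
            if bad:
                raise ValueError(f"unknown status labels in {col}: {sorted(bad)}")
        absorbing = ("dead", "frail", "withdrawn")
        for earlier, later in zip(cols, cols[1:]):
            e, l = self.data[earlier], self.data[later]
            for st in absorbing:
                if ((e == st) & (l != st)).any():
                    raise ValueError(f"{st!r} is absorbing but reverts between {earlier} and {later}")
            if ((e == "lost") & (l == "respondent")).any():
                raise ValueError(f"'lost' reverts to respondent between {earlier} and {later}")


def _spawn_rng(seed: int, *path: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=path))


def generate_baseline(n: int, specs: Sequence[RiskFactorSpec], seed: int) -> CohortTable:
    """Draw ``n`` participants with independent baseline risk factors."""
    if n < 1:
        raise ValueError("n must be >= 1")
    data = {"id": np.arange(1, n + 1)}
    for i, spec in enumerate(specs):
        rng = _spawn_rng(seed, 0, i)
        codes = rng.choice(len(spec.categories), size=n, p=spec.baseline_probs)
        data[spec.name] = pd.Categorical.from_codes(
            codes, categories=list(spec.categories)
        ).astype(object)
    return CohortTable(pd.DataFrame(data), [s.name for s in specs])


def enumerate_joint(specs: Sequence[RiskFactorSpec]) -> tuple[pd.DataFrame, np.ndarray]:
    """Exact joint distribution of independent factors: every category
    combination plus its probability.  Used for infinite-n expectations."""
    cells = list(itertools.product(*(s.categories for s in specs)))
    probs = np.array(
        [np.prod([s.prob_map[c] for s, c in zip(specs, cell)]) for cell in cells]
    )
    df = pd.DataFrame(cells, columns=[s.name for s in specs])
    df.insert(0, "id", np.arange(1, len(df) + 1))
    return df, probs


class CalibrationError(RuntimeError):
    """Intercept calibration failed; carries the best achieved marginals."""

    def __init__(self, message: str, achieved: Mapping[str, float]):
        super().__init__(message)
        self.achieved = dict(achieved)


def calibrate_intercepts(
    model: AttritionModelSpec,
    baseline: CohortTable | pd.DataFrame,
    target_marginals: Mapping[str, float],
    weights: np.ndarray | None = None,
    tol: float = 1e-6,
    max_iter: int = 500,
) -> AttritionModelSpec:
    """Adjust intercepts so expected status marginals match targets.

    Holds coefficients fixed and iterates multiplicative (log-space) updates
    ``intercept_k += log(target_k / achieved_k)`` — an iterative-proportional
    style search over the empirical (or supplied weighted) covariate
    distribution.  Targets must sum to 1 over the five statuses and every
    non-respondent target must be interior (0, 1).
    """
    targets = {s: float(target_marginals[s]) for s in STATUSES}
    total = sum(targets.values())
    if abs(total - 1.0) > 1e-6:
        raise ValueError(f"target marginals sum to {total}, not 1")
    if any(not (0.0 < targets[s] < 1.0) for s in STATUSES):
        raise ValueError(f"degenerate target marginals {targets}: every status share "
                         "must be strictly between 0 and 1 for intercepts to exist")
    data = baseline.data if isinstance(baseline, CohortTable) else baseline
    if weights is None:
        w = np.full(len(data), 1.0 / len(data))
    else:
        w = np.asarray(weights, dtype=float)
        w = w / w.sum()

    current = model
    achieved: dict[str, float] = {}
    for _ in range(max_iter):
        probs = current.outcome_probabilities(data)
        achieved = {s: float(probs[s].to_numpy() @ w) for s in STATUSES}
        err = max(abs(achieved[s] - targets[s]) for s in STATUSES)
        if err < tol:
            return current
        new_intercepts = {
            o: current.intercepts[o] + np.log(targets[o] / achieved[o])
            for o in ATTRITION_OUTCOMES
        }
        current = current.with_intercepts(new_intercepts)
    raise CalibrationError(
        f"intercept calibration did not reach tolerance {tol} in {max_iter} iterations",
        achieved,
    )


def assign_final_status(
    cohort: CohortTable, model: AttritionModelSpec, seed: int
) -> CohortTable:
    """Draw each participant's Survey-5 status from the multinomial model.

    Requires complete risk-factor data for every factor the model uses.
    """
    used = sorted({f for _, f, _ in model.coefficients})
    if used:
        incomplete = cohort.data[used].isna().any(axis=1)
        if incomplete.any():
            raise ValueError(
                f"{int(incomplete.sum())} records have missing values on model factors {used}; "
                "draw statuses before imposing missingness or filter to complete cases"
            )
    probs = model.outcome_probabilities(cohort.data).to_numpy()
    rng = _spawn_rng(seed, 1)
    u = rng.random(len(probs))
    codes = (probs.cumsum(axis=1) < u[:, None]).sum(axis=1)
    out = cohort.copy()
    out.data["status_s5"] = np.asarray(STATUSES, dtype=object)[codes]
    return out


def interval_rates_from_marginals(marginals: pd.DataFrame) -> pd.DataFrame:
    """Per-survey transition rates from cumulative attrition marginals.

    ``marginals`` has one row per survey 2..5 with columns for the five
    status shares (proportions of the initial cohort).  Because all four
    attrition states are treated as absorbing, cumulative shares are
    monotonized with a running maximum and the respondent share re-derived
    as the complement, which absorbs rounding inconsistencies in tabulated
    inputs.  Returns, indexed by survey, the probability that a participant
    still responding at the previous survey transitions to each state
    (columns dead/frail/withdrawn/lost, plus respondent = stay).
    """
    m = marginals.set_index("survey") if "survey" in marginals.columns else marginals
    m = m.sort_index()
    cum = m[list(ATTRITION_OUTCOMES)].cummax()
    respondent = 1.0 - cum.sum(axis=1)
    if (respondent <= 0).any():
        raise ValueError("cumulative attrition shares leave no respondents")
    rates = {}
    prev_resp = 1.0
    prev_cum = pd.Series(0.0, index=list(ATTRITION_OUTCOMES))
    for survey, row in cum.iterrows():
        inc = (row - prev_cum).clip(lower=0.0)
        probs = inc / prev_resp
        if probs.sum() > 1.0 + 1e-9:
            raise ValueError(f"survey {survey}: transition probabilities exceed 1")
        rates[survey] = {**probs.to_dict(), "respondent": 1.0 - probs.sum()}
        prev_resp = float(respondent.loc[survey])
        prev_cum = row
    out = pd.DataFrame.from_dict(rates, orient="index")[list(STATUSES)]
    out.index.name = "survey"
    return out


def expand_to_surveys(
    cohort: CohortTable, interval_rates: pd.DataFrame, seed: int
) -> CohortTable:
    """Simulate wave-by-wave statuses from per-survey transition rates.

    ``interval_rates`` rows (one per survey 2..5, columns = the five states)
    give transition probabilities conditional on responding at the previous
    survey, and must each sum to 1.  Attrition states are absorbing.
    """
    rates = interval_rates[list(STATUSES)]
    if not np.allclose(rates.sum(axis=1), 1.0, atol=1e-9):
        raise ValueError("interval transition rows must sum to 1")
    if (rates.to_numpy() < 0).any():
        raise ValueError("negative transition probability")
    out = cohort.copy()
    n = len(out)
    status = np.full(n, "respondent", dtype=object)
    for k, (survey, row) in enumerate(rates.iterrows()):
        rng = _spawn_rng(seed, 2, k)
        active = status == "respondent"
        draws = rng.choice(len(STATUSES), size=int(active.sum()), p=row.to_numpy())
        status = status.copy()
        status[active] = np.asarray(STATUSES, dtype=object)[draws]
        out.data[f"status_s{survey}"] = status
    return out


def assign_transition_surveys(
    cohort: CohortTable, marginals: pd.DataFrame, seed: int
) -> CohortTable:
    """Back-fill Survey 2..4 statuses given an existing Survey-5 status.

    For each participant whose final status is an attrition state, the survey
    at which they left is drawn from that state's cumulative-increment
    distribution in ``marginals`` (same layout as
    :func:`interval_rates_from_marginals` input); earlier surveys are
    respondent, later surveys carry the absorbing state.  Combined with a
    model-drawn final status this yields one cohort with both the configured
    odds-ratio structure and wave-resolved attrition.
    """
    if "status_s5" not in cohort.data.columns:
        raise ValueError("cohort has no status_s5; draw final statuses first")
    m = marginals.set_index("survey") if "survey" in marginals.columns else marginals
    cum = m.sort_index()[list(ATTRITION_OUTCOMES)].cummax()
    inc = cum.diff().fillna(cum.iloc[[0]]).clip(lower=0.0)
    surveys = cum.index.to_numpy()
    out = cohort.copy()
    final = out.data["status_s5"].to_numpy()
    when = np.full(len(out), surveys[-1] + 1, dtype=int)  # respondents: never
    for j, state in enumerate(ATTRITION_OUTCOMES):
        mask = final == state
        if not mask.any():
            continue
        p = inc[state].to_numpy()
        p = p / p.sum()
        rng = _spawn_rng(seed, 3, j)
        when[mask] = surveys[rng.choice(len(surveys), size=int(mask.sum()), p=p)]
    for survey in surveys:
        col = np.where(when <= survey, final, "respondent")
        out.data[f"status_s{survey}"] = col
    return out


def impose_missingness(
    cohort: CohortTable, rates: Mapping[str, float], seed: int
) -> CohortTable:
    """Blank factor values completely at random at per-factor rates."""
    for name, rate in rates.items():
        if name not in cohort.factors:
            raise ValueError(f"unknown factor {name!r}")
        if not (0.0 <= rate < 1.0):
            raise ValueError(f"missingness rate for {name!r} must be in [0, 1), got {rate}")
    out = cohort.copy()
    for i, (name, rate) in enumerate(sorted(rates.items())):
        if rate == 0.0:
            continue
        rng = _spawn_rng(seed, 4, i)
        mask = rng.random(len(out)) < rate
        col = out.data[name].astype(object)
        col[mask] = np.nan
        out.data[name] = col
    return out


def assign_weights(
    cohort: CohortTable,
    sampling_fractions: Mapping[str, float],
    population_shares: Mapping[str, float],
    seed: int,
) -> CohortTable:
    """Assign area strata and inverse-sampling-fraction weights.

    Strata (e.g. city/rural/remote) are drawn with probability proportional
    to ``population_share * sampling_fraction`` (the sample composition under
    intentional over-sampling); each record's weight is the inverse of its
    stratum's sampling fraction, normalized to mean 1.
    """
    strata = list(sampling_fractions)
    if set(strata) != set(population_shares):
        raise ValueError("sampling_fractions and population_shares name different strata")
    fracs = np.array([sampling_fractions[s] for s in strata], dtype=float)
    shares = np.array([population_shares[s] for s in strata], dtype=float)
    if (fracs <= 0).any():
        raise ValueError("sampling fractions must be positive")
    if (shares <= 0).any():
        raise ValueError("population shares must be positive")
    sample_probs = shares * fracs
    sample_probs = sample_probs / sample_probs.sum()
    rng = _spawn_rng(seed, 5)
    codes = rng.choice(len(strata), size=len(cohort), p=sample_probs)
    out = cohort.copy()
    out.data["area_stratum"] = np.asarray(strata, dtype=object)[codes]
    raw = 1.0 / fracs[codes]
    out.data["weight"] = raw / raw.mean()
    return out
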