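"""Weighted cohort prevalence versus external population series.

Dichotomized risk factors (e.g. non-English-speaking country of birth,
current-or-ex smoking) are compared between the surviving cohort — using
sampling weights that correct for intentional over-sampling of rural and
remote strata — and external population estimates (censuses, national health
surveys) at matched calendar time points.  Bias is stored signed as
population minus cohort prevalence: positive means the cohort
under-represents the factor.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "PopulationSeries",
    "BiasSeries",
    "DICHOTOMIZATION_RULES",
    "weighted_prevalence",
    "dichotomize",
    "bias_series",
]

#: Named dichotomization rules: category -> 1 (has the factor) or 0.
DICHOTOMIZATION_RULES: dict[str, dict[str, int]] = {
    # born in a non-English-speaking country vs other
    "non_english_cob": {"Australia": 0, "Other English speaking": 0, "Other": 1},
    # has ever smoked (current or ex) vs never
    "current_or_ex": {"Never smoker": 0, "Ex-smoker": 1, "Smoker": 1},
}


@dataclass(frozen=True)
class PopulationSeries:
    """External prevalence estimates at ordered calendar time points."""

    label: str
    times: tuple[str, ...]
    prevalence: tuple[float, ...]
    source: str = "synthetic"

    def __post_init__(self) -> None:
        if len(self.times) != len(self.prevalence):
            raise ValueError("times and prevalence differ in length")
        if len(set(self.times)) != len(self.times):
            raise ValueError("duplicate time points")
        if any(not (0.0 <= p <= 1.0) for p in self.prevalence):
            raise ValueError("prevalence values must lie in [0, 1]")
        object.__setattr__(self, "times", tuple(self.times))
        object.__setattr__(self, "prevalence", tuple(float(p) for p in self.prevalence))

    @classmethod
    def from_frame(cls, frame: pd.DataFrame, label: str, source: str) -> "PopulationSeries":
        sel = frame[(frame["label"] == label) & (frame["source"] == source)]
        if sel.empty:
            raise KeyError(f"no series {label!r} with source {source!r}")
        return cls(
            label=label,
            times=tuple(sel["time"]),
            prevalence=tuple(sel["prevalence"]),
            source=source,
        )


@dataclass(frozen=True)
class BiasSeries:
    """Cohort vs population prevalence with signed bias per time point."""

    times: tuple[str, ...]
    cohort: tuple[float, ...]
    population: tuple[float, ...]
    bias: tuple[float, ...]

    def direction(self) -> str:
        """'under-representation' when population exceeds cohort throughout,
        'over-representation' when the reverse holds, else 'mixed'."""
        b = np.asarray(self.bias)
        if (b > 0).all():
            return "under-representation"
        if (b < 0).all():
            return "over-representation"
        return "mixed"

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "time": self.times,
                "cohort_prevalence": self.cohort,
                "population_prevalence": self.population,
                "bias": self.bias,
            }
        )


def weighted_prevalence(values: Sequence[float], weights: Sequence[float]) -> float:
    """Weighted prevalence sum(w*x)/sum(w) over non-missing binary indicators.

    Missing indicators are excluded from numerator and denominator; the
    result is invariant to rescaling all weights by a positive constant.
    """
    x = pd.Series(list(values), dtype="float64")
    w = np.asarray(list(weights), dtype=float)
    if len(x) != len(w):
        raise ValueError("values and weights differ in length")
    if (w <= 0).any():
        raise ValueError("weights must be positive")
    keep = x.notna().to_numpy()
    if not keep.any():
        raise ValueError("all indicator values are missing")
    xk = x.to_numpy()[keep]
    if not np.isin(xk, (0.0, 1.0)).all():
        raise ValueError("values must be binary 0/1 indicators (or missing)")
    wk = w[keep]
    return float((wk * xk).sum() / wk.sum())


def dichotomize(values: pd.Series, rule: str | Mapping[str, int]) -> pd.Series:
    """Map categories to a 0/1 indicator; missing stays missing.

    ``rule`` is a named rule from :data:`DICHOTOMIZATION_RULES` or an
    explicit category -> {0, 1} mapping covering every observed category.
    """
    mapping = DICHOTOMIZATION_RULES[rule] if isinstance(rule, str) else dict(rule)
    if any(v not in (0, 1) for v in mapping.values()):
        raise ValueError("dichotomization rule must map categories to 0 or 1")
    observed = set(pd.Series(values).dropna().unique())
    unmapped = observed - set(mapping)
    if unmapped:
        raise ValueError(f"categories not covered by the rule: {sorted(unmapped)}")
    return pd.Series(values).map(mapping).astype("float64")


def bias_series(
    cohort_prevalence: Mapping[str, float] | Sequence[float],
    population: PopulationSeries,
) -> BiasSeries:
    """Signed bias (population − cohort) at each matched time point.

    ``cohort_prevalence`` is either a time -> prevalence mapping whose keys
    must equal the population series' time points, or a plain sequence
    aligned positionally.
    """
    if isinstance(cohort_prevalence, Mapping):
        missing = set(population.times) - set(cohort_prevalence)
        extra = set(cohort_prevalence) - set(population.times)
        if missing or extra:
            raise ValueError(
                f"misaligned time axes: missing {sorted(missing)}, extra {sorted(extra)}"
            )
        cohort = tuple(float(cohort_prevalence[t]) for t in population.times)
    else:
        if len(cohort_prevalence) != len(population.times):
            raise ValueError("cohort series length does not match population series")
        cohort = tuple(float(v) for v in cohort_prevalence)
    bias = tuple(p - c for p, c in zip(population.prevalence, cohort))
    return BiasSeries(
        times=population.times,
        cohort=cohort,
        population=population.prevalence,
        bias=bias,
    )
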