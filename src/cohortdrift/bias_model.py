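"""Deterministic prevalence-drift model for cohort attrition bias.

A fixed (non-modifiable) binary risk factor has some prevalence in a target
population and in a study cohort sampled from it.  Each time step, death
removes people from *both* groups while non-death attrition (withdrawal, loss
to follow up) removes people from the cohort only.  If the risk factor
multiplies the per-step incidence of either removal process, prevalence among
the survivors shifts, and the cohort can drift away from (or back towards)
the population it is meant to represent.

The update is prevalence-among-survivors.  Writing ``p`` for the current
prevalence, ``I`` for the per-step incidence of removal among the unexposed
and ``RR`` for the relative risk of removal among the exposed, the exposed
retain mass ``p(1 - RR*I)`` and the unexposed retain ``(1-p)(1-I)``; the next
prevalence is the exposed share of the retained mass.  The cohort update
applies two independent removal processes (death, non-death attrition) in the
same way.

Bias is stored signed as ``p_pop - p_cohort``: positive when the cohort
under-represents the factor.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, Mapping

import numpy as np
import pandas as pd

__all__ = [
    "ScenarioParams",
    "PrevalenceTrajectory",
    "ExtinctionError",
    "update_population_prevalence",
    "update_cohort_prevalence",
    "run_scenario",
    "canonical_scenarios",
]


class ExtinctionError(ValueError):
    """Raised when a removal step leaves no survivors (prevalence undefined)."""


def _check_proportion(name: str, value: float, *, upper_open: bool = False) -> None:
    if not np.isfinite(value):
        raise ValueError(f"{name} must be finite, got {value!r}")
    if upper_open:
        if not (0.0 <= value < 1.0):
            raise ValueError(f"{name} must be in [0, 1), got {value}")
    elif not (0.0 <= value <= 1.0):
        raise ValueError(f"{name} must be in [0, 1], got {value}")


def _check_rate(name_rr: str, rr: float, name_i: str, i: float) -> None:
    if not np.isfinite(rr) or rr <= 0:
        raise ValueError(f"{name_rr} must be a positive real, got {rr}")
    if rr * i > 1.0 + 1e-12:
        raise ValueError(
            f"{name_rr}*{name_i} = {rr * i:.6g} > 1: exposed retention would be negative"
        )


@dataclass(frozen=True)
class ScenarioParams:
    """Parameters of one hypothetical attrition scenario.

    Attributes
    ----------
    p_p0, p_c0 : float
        Initial prevalence of the risk factor in the population and cohort.
    I_pd : float
        Per-step incidence of death among unexposed population members.
    I_cd, I_ca : float
        Per-step incidences of death and of non-death attrition among
        unexposed cohort members.
    RR_pd, RR_cd, RR_ca : float
        Relative risks of the corresponding removal for exposed individuals.
        ``RR * I`` may not exceed 1.
    n_steps : int
        Time horizon; steps are abstract units (e.g. years) over which the
        incidences apply.
    """

    p_p0: float
    p_c0: float
    I_pd: float = 0.10
    I_cd: float = 0.10
    I_ca: float = 0.10
    RR_pd: float = 1.0
    RR_cd: float = 1.0
    RR_ca: float = 1.0
    n_steps: int = 10

    def __post_init__(self) -> None:
        _check_proportion("p_p0", self.p_p0)
        _check_proportion("p_c0", self.p_c0)
        _check_proportion("I_pd", self.I_pd, upper_open=True)
        _check_proportion("I_cd", self.I_cd, upper_open=True)
        _check_proportion("I_ca", self.I_ca, upper_open=True)
        _check_rate("RR_pd", self.RR_pd, "I_pd", self.I_pd)
        _check_rate("RR_cd", self.RR_cd, "I_cd", self.I_cd)
        _check_rate("RR_ca", self.RR_ca, "I_ca", self.I_ca)
        if not (isinstance(self.n_steps, (int, np.integer)) and self.n_steps >= 1):
            raise ValueError(f"n_steps must be a positive integer, got {self.n_steps!r}")

    @classmethod
    def from_mapping(cls, mapping: Mapping[str, float]) -> "ScenarioParams":
        known = {f.name for f in cls.__dataclass_fields__.values()}  # type: ignore[attr-defined]
        unknown = set(mapping) - known
        if unknown:
            raise ValueError(f"unknown scenario keys: {sorted(unknown)}")
        return cls(**dict(mapping))


@dataclass(frozen=True)
class PrevalenceTrajectory:
    """Time-indexed prevalence in population and cohort, with signed bias."""

    times: np.ndarray
    p_pop: np.ndarray
    p_cohort: np.ndarray
    bias: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        times = np.asarray(self.times, dtype=int)
        p_pop = np.asarray(self.p_pop, dtype=float)
        p_cohort = np.asarray(self.p_cohort, dtype=float)
        if not (len(times) == len(p_pop) == len(p_cohort)):
            raise ValueError("times, p_pop and p_cohort must have equal length")
        object.__setattr__(self, "times", times)
        object.__setattr__(self, "p_pop", p_pop)
        object.__setattr__(self, "p_cohort", p_cohort)
        object.__setattr__(self, "bias", p_pop - p_cohort)

    def __len__(self) -> int:
        return len(self.times)

    def __iter__(self) -> Iterator[tuple[int, float, float, float]]:
        return iter(zip(self.times, self.p_pop, self.p_cohort, self.bias))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "step": self.times,
                "p_pop": self.p_pop,
                "p_cohort": self.p_cohort,
                "bias": self.bias,
            }
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    def plot(self, path=None, title: str | None = None):
        """Simple two-line trajectory plot; saves to *path* if given."""
        import matplotlib

        if path is not None:
            matplotlib.use("Agg", force=False)
        import matplotlib.pyplot as plt

        fig, ax = plt.subplots(figsize=(5, 3.5))
        ax.plot(self.times, self.p_pop, marker="o", label="population")
        ax.plot(self.times, self.p_cohort, marker="s", label="cohort")
        ax.set_xlabel("time step")
        ax.set_ylabel("prevalence")
        ax.set_ylim(0, max(0.5, float(max(self.p_pop.max(), self.p_cohort.max())) * 1.1))
        if title:
            ax.set_title(title)
        ax.legend()
        fig.tight_layout()
        if path is not None:
            fig.savefig(path, dpi=150)
            plt.close(fig)
        return fig


def update_population_prevalence(p_prev: float, I_pd: float, RR_pd: float) -> float:
    """One-step prevalence update in the target population (death only).

    Returns the prevalence among survivors:
    ``A / [(1-p)(1-I_pd) + A]`` with ``A = p (1 - RR_pd * I_pd)``.
    """
    _check_proportion("p_prev", p_prev)
    _check_proportion("I_pd", I_pd, upper_open=True)
    _check_rate("RR_pd", RR_pd, "I_pd", I_pd)
    retain_exposed = 1.0 - RR_pd * I_pd
    retain_unexposed = 1.0 - I_pd
    if retain_exposed == retain_unexposed:
        # equal retention cancels from the ratio: the update is the identity,
        # kept exact rather than left to floating-point round-off
        return p_prev
    a = p_prev * retain_exposed
    denom = (1.0 - p_prev) * retain_unexposed + a
    if denom <= 0.0:
        raise ExtinctionError(
            "no survivors after one step: prevalence is undefined "
            f"(p={p_prev}, I_pd={I_pd}, RR_pd={RR_pd})"
        )
    return a / denom


def update_cohort_prevalence(
    p_prev: float, I_cd: float, I_ca: float, RR_cd: float, RR_ca: float
) -> float:
    """One-step prevalence update in the remaining cohort (death and
    non-death attrition acting as independent removal processes).

    Returns ``B / [(1-p)(1-I_cd)(1-I_ca) + B]`` with
    ``B = p (1 - RR_cd*I_cd)(1 - RR_ca*I_ca)``.
    """
    _check_proportion("p_prev", p_prev)
    _check_proportion("I_cd", I_cd, upper_open=True)
    _check_proportion("I_ca", I_ca, upper_open=True)
    _check_rate("RR_cd", RR_cd, "I_cd", I_cd)
    _check_rate("RR_ca", RR_ca, "I_ca", I_ca)
    retain_exposed = (1.0 - RR_cd * I_cd) * (1.0 - RR_ca * I_ca)
    retain_unexposed = (1.0 - I_cd) * (1.0 - I_ca)
    if retain_exposed == retain_unexposed:
        return p_prev
    b = p_prev * retain_exposed
    denom = (1.0 - p_prev) * retain_unexposed + b
    if denom <= 0.0:
        raise ExtinctionError(
            "no cohort members retained after one step: prevalence is undefined "
            f"(p={p_prev}, I_cd={I_cd}, I_ca={I_ca}, RR_cd={RR_cd}, RR_ca={RR_ca})"
        )
    return b / denom


def run_scenario(params: ScenarioParams) -> PrevalenceTrajectory:
    """Iterate both updates over the scenario horizon.

    Step ``t`` is obtained by applying the population and cohort updates to
    step ``t-1``; errors raised by an update are re-raised with the failing
    step index attached.
    """
    p_pop = np.empty(params.n_steps + 1)
    p_coh = np.empty(params.n_steps + 1)
    p_pop[0] = params.p_p0
    p_coh[0] = params.p_c0
    for t in range(1, params.n_steps + 1):
        try:
            p_pop[t] = update_population_prevalence(p_pop[t - 1], params.I_pd, params.RR_pd)
            p_coh[t] = update_cohort_prevalence(
                p_coh[t - 1], params.I_cd, params.I_ca, params.RR_cd, params.RR_ca
            )
        except ValueError as err:
            raise type(err)(f"step {t}: {err}") from err
    return PrevalenceTrajectory(np.arange(params.n_steps + 1), p_pop, p_coh)


#: Scenario grid: four association patterns x {A: no initial bias, B: cohort
#: starts at 0.20 vs population 0.25}.  Pattern 1: no associations; pattern 2:
#: death only (population and cohort, RR=2); pattern 3: non-death attrition
#: only; pattern 4: both.
_PATTERNS = {
    "1": dict(RR_pd=1.0, RR_cd=1.0, RR_ca=1.0),
    "2": dict(RR_pd=2.0, RR_cd=2.0, RR_ca=1.0),
    "3": dict(RR_pd=1.0, RR_cd=1.0, RR_ca=2.0),
    "4": dict(RR_pd=2.0, RR_cd=2.0, RR_ca=2.0),
}


def canonical_scenarios() -> dict[str, ScenarioParams]:
    """The eight standard hypothetical scenarios, keyed ``"1A"`` .. ``"4B"``.

    All incidences are 0.10, the population starts at prevalence 0.25, an
    association (where present) means RR=2, and the B variants start the
    cohort at 0.20 (initial under-representation).
    """
    out: dict[str, ScenarioParams] = {}
    for num, rrs in _PATTERNS.items():
        for variant, p_c0 in (("A", 0.25), ("B", 0.20)):
            out[f"{num}{variant}"] = ScenarioParams(
                p_p0=0.25, p_c0=p_c0, I_pd=0.10, I_cd=0.10, I_ca=0.10, n_steps=10, **rrs
            )
    return out
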