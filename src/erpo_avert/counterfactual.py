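"""Counterfactual redistribution of suicidal acts and the deaths-averted estimate.

Steps 2-3 of the procedure: the total number of suicidal acts A estimated by
CFR inversion is held fixed (act conservation — the intervention is assumed
to change the method mix, not the number of acts), redistributed over methods
according to a counterfactual distribution q, and converted back to expected
deaths with the same CFR table:

    D* = A * sum_m q_m * p_m

The intervention's effect estimate follows:

    deaths averted  = D* - D
    risk difference = (D* - D) / N
    NNT             = N / (D* - D)      (undefined when D* <= D)

where D is the observed death total and N the number of respondents.

Two counterfactual constructions are provided: an arbitrary user-supplied
distribution, and the fixed-firearm-fraction construction in which a chosen
fraction of acts involve firearms and the remainder mirror the factual
nonfirearm act mix.  A sensitivity sweep evaluates the latter over a grid of
firearm fractions.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping

import pandas as pd

from .acts import apply_cfr, estimate_acts
from .method_model import (
    FIREARM,
    ActEstimate,
    CFRTable,
    DeathTally,
    DegenerateDistributionError,
    ExpectedDeaths,
    MethodDistribution,
    ValidationError,
)

__all__ = [
    "Scenario",
    "CounterfactualResult",
    "run_counterfactual",
    "nnt_from_totals",
    "swanson_counterfactual",
    "sweep_firearm_fraction",
]


@dataclass(frozen=True)
class Scenario:
    """A complete counterfactual problem instance.

    ``n_subjects`` is the number of people under the intervention (the
    denominator of the risk difference); it must be at least the observed
    death total.
    """

    n_subjects: int
    deaths: DeathTally
    cfr: CFRTable
    counterfactual: MethodDistribution
    label: str = "scenario"

    def __post_init__(self) -> None:
        if self.n_subjects <= 0:
            raise ValidationError("n_subjects must be positive")
        if self.n_subjects < self.deaths.total:
            raise ValidationError(
                f"n_subjects ({self.n_subjects}) cannot be smaller than the "
                f"observed death total ({self.deaths.total})"
            )


@dataclass(frozen=True)
class RiskSummary:
    """Risk difference and its reciprocal, the number needed to treat."""

    risk_difference: float
    nnt: float | None  # None when the risk difference is <= 0 (no excess deaths)


def nnt_from_totals(
    counterfactual_deaths: float, observed_deaths: float, n_subjects: int
) -> RiskSummary:
    """Causal risk difference and NNT from total death counts.

    An NNT is only defined when the counterfactual exceeds the observed
    count; otherwise ``nnt`` is ``None`` (the signed risk difference is
    always reported).
    """
    if n_subjects <= 0:
        raise ValidationError("n_subjects must be positive")
    rd = (counterfactual_deaths - observed_deaths) / n_subjects
    nnt = 1.0 / rd if rd > 0 else None
    return RiskSummary(risk_difference=rd, nnt=nnt)


@dataclass(frozen=True)
class CounterfactualResult:
    """Full output of a counterfactual run, at full float precision."""

    scenario: Scenario
    acts: ActEstimate
    total_acts: float
    counterfactual_acts: Mapping[str, float]
    counterfactual_expected_deaths: ExpectedDeaths
    counterfactual_total_deaths: float
    observed_total_deaths: int
    deaths_averted: float
    risk_difference: float
    nnt: float | None

    @property
    def nnt_defined(self) -> bool:
        return self.nnt is not None

    def summary(self) -> dict[str, float | None]:
        return {
            "n_subjects": self.scenario.n_subjects,
            "total_acts": self.total_acts,
            "observed_deaths": self.observed_total_deaths,
            "counterfactual_deaths": self.counterfactual_total_deaths,
            "deaths_averted": self.deaths_averted,
            "risk_difference": self.risk_difference,
            "nnt": self.nnt,
        }

    def as_frame(self) -> pd.DataFrame:
        """Per-method derivation table (deaths, CFR, acts, q, cf acts, cf deaths)."""
        tax = self.scenario.deaths.taxonomy
        return pd.DataFrame(
            {
                "method": list(tax),
                "deaths": [self.scenario.deaths[m] for m in tax],
                "cfr": [self.scenario.cfr[m] for m in tax],
                "acts": [self.acts[m] for m in tax],
                "counterfactual_share": [self.scenario.counterfactual[m] for m in tax],
                "counterfactual_acts": [self.counterfactual_acts[m] for m in tax],
                "counterfactual_deaths": [self.counterfactual_expected_deaths[m] for m in tax],
            }
        )


def run_counterfactual(scenario: Scenario, *, round_total_acts: bool = False) -> CounterfactualResult:
    """Run the three-step counterfactual pipeline on a scenario.

    With ``round_total_acts=True`` the act total is rounded to the nearest
    integer before redistribution, reproducing the intermediate rounding
    used in published derivations of this estimator; the default keeps full
    precision throughout.
    """
    acts = estimate_acts(scenario.deaths, scenario.cfr)
    total = acts.total_acts
    redistributed_total = float(round(total)) if round_total_acts else total
    q = scenario.counterfactual
    cf_acts = {m: redistributed_total * q[m] for m in acts.taxonomy}
    cf_deaths = apply_cfr(ActEstimate(cf_acts, taxonomy=acts.taxonomy), scenario.cfr)
    d_star = cf_deaths.total
    d_obs = scenario.deaths.total
    risk = nnt_from_totals(d_star, d_obs, scenario.n_subjects)
    return CounterfactualResult(
        scenario=scenario,
        acts=acts,
        total_acts=total,
        counterfactual_acts=cf_acts,
        counterfactual_expected_deaths=cf_deaths,
        counterfactual_total_deaths=d_star,
        observed_total_deaths=d_obs,
        deaths_averted=d_star - d_obs,
        risk_difference=risk.risk_difference,
        nnt=risk.nnt,
    )


def swanson_counterfactual(
    acts: ActEstimate,
    firearm_fraction: float,
    *,
    substituted_method: str = FIREARM,
) -> MethodDistribution:
    """Fixed-firearm-fraction counterfactual distribution.

    Assigns ``firearm_fraction`` of acts to the substituted method and
    spreads the remainder over the other methods in proportion to their
    factual act estimates (the mix of acts that were actually inferred for
    those methods).
    """
    if not (0.0 <= firearm_fraction <= 1.0):
        raise ValidationError(f"firearm_fraction {firearm_fraction} must lie in [0, 1]")
    tax = acts.taxonomy
    if substituted_method not in tax:
        raise ValidationError(f"substituted method {substituted_method!r} not in taxonomy")
    other_total = sum(acts[m] for m in tax if m != substituted_method)
    if firearm_fraction < 1.0 and other_total <= 0:
        raise DegenerateDistributionError(
            "cannot distribute the non-substituted share: zero acts by other methods"
        )
    q: dict[str, float] = {}
    for m in tax:
        if m == substituted_method:
            q[m] = firearm_fraction
        elif firearm_fraction == 1.0:
            q[m] = 0.0
        else:
            q[m] = (1.0 - firearm_fraction) * acts[m] / other_total
    return MethodDistribution(q, provenance="counterfactual", taxonomy=tax)


def sweep_firearm_fraction(
    scenario: Scenario,
    fractions: Iterable[float],
    *,
    substituted_method: str = FIREARM,
) -> pd.DataFrame:
    """Sensitivity of the estimate to the counterfactual firearm fraction.

    For each fraction f in the grid, builds the fixed-fraction
    counterfactual from the scenario's factual acts and reruns the
    pipeline.  Returns a frame ordered by fraction with columns
    ``fraction, counterfactual_deaths, deaths_averted, risk_difference,
    nnt`` (NNT is NaN where undefined).
    """
    grid = sorted(float(f) for f in fractions)
    if not grid:
        raise ValidationError("fraction grid must be non-empty")
    acts = estimate_acts(scenario.deaths, scenario.cfr)
    rows = []
    for f in grid:
        q = swanson_counterfactual(acts, f, substituted_method=substituted_method)
        res = run_counterfactual(
            Scenario(scenario.n_subjects, scenario.deaths, scenario.cfr, q,
                     label=f"{scenario.label}[f={f:g}]")
        )
        rows.append(
            {
                "fraction": f,
                "counterfactual_deaths": res.counterfactual_total_deaths,
                "deaths_averted": res.deaths_averted,
                "risk_difference": res.risk_difference,
                "nnt": res.nnt if res.nnt is not None else math.nan,
            }
        )
    return pd.DataFrame(rows)
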