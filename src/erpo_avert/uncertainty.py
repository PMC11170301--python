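"""Monte-Carlo propagation of sampling uncertainty through the pipeline.

The headline estimator is a plug-in functional of a small death tally, so
its sampling noise is substantial and worth quantifying even though the
point estimate is deterministic.  A parametric bootstrap resamples the
death tally — multinomially, conditional on the observed death total
(deaths are treated as data, not a rate; a Poisson-total variant is
available) — optionally perturbs the case fatality ratios with conjugate
Beta draws governed by user-supplied effective sample sizes, reruns the
counterfactual pipeline on every replicate, and summarizes percentile
intervals for total acts, counterfactual deaths, deaths averted, risk
difference and NNT.

Percentile (rather than BCa) intervals are used: they are consistent under
the monotone transform NNT = 1/RD, so the NNT interval is exactly the
transformed risk-difference interval.  Replicates with no excess deaths
have an undefined NNT; they are counted and reported, never dropped
silently.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

from .counterfactual import CounterfactualResult, Scenario, run_counterfactual
from .method_model import ValidationError

__all__ = ["UncertaintySpec", "IntervalSummary", "bootstrap_scenario"]


@dataclass(frozen=True)
class UncertaintySpec:
    """Bootstrap configuration.

    ``death_resampling``: ``"multinomial"`` (total fixed at the observed
    count), ``"poisson"`` (independent per-method Poisson counts), or
    ``"none"`` (degenerate — every replicate equals the observed tally).
    ``cfr_ess`` maps methods to effective sample sizes for a
    Beta(p*n, (1-p)*n) perturbation of the CFR; omitted methods (or a None
    mapping, the default) keep their CFR fixed.
    """

    n_replicates: int
    seed: int
    death_resampling: str = "multinomial"
    cfr_ess: Mapping[str, float] | None = None
    levels: tuple[float, float] = (0.025, 0.975)

    def __post_init__(self) -> None:
        if self.n_replicates < 1:
            raise ValidationError("n_replicates must be >= 1")
        if self.death_resampling not in ("multinomial", "poisson", "none"):
            raise ValidationError(
                f"unknown death_resampling {self.death_resampling!r}"
            )
        lo, hi = self.levels
        if not (0.0 < lo < hi < 1.0):
            raise ValidationError("levels must satisfy 0 < lower < upper < 1")
        if self.cfr_ess is not None and any(v <= 0 for v in self.cfr_ess.values()):
            raise ValidationError("cfr_ess values must be positive")


@dataclass(frozen=True)
class IntervalSummary:
    """Point estimates with percentile bounds for each pipeline output."""

    point: CounterfactualResult
    levels: tuple[float, float]
    n_replicates: int
    seed: int
    quantities: Mapping[str, dict]
    undefined_nnt_fraction: float

    def to_dict(self) -> dict:
        return {
            "levels": list(self.levels),
            "n_replicates": self.n_replicates,
            "seed": self.seed,
            "undefined_nnt_fraction": self.undefined_nnt_fraction,
            "quantities": {k: dict(v) for k, v in self.quantities.items()},
        }


def _replicate_tallies(
    scenario: Scenario, spec: UncertaintySpec, rng: np.random.Generator
) -> np.ndarray:
    tax = list(scenario.deaths.taxonomy)
    d = np.array([scenario.deaths[m] for m in tax], dtype=float)
    if spec.death_resampling == "none" or d.sum() == 0:
        return np.tile(d, (spec.n_replicates, 1))
    if spec.death_resampling == "multinomial":
        return rng.multinomial(int(d.sum()), d / d.sum(), size=spec.n_replicates).astype(float)
    return rng.poisson(d, size=(spec.n_replicates, len(tax))).astype(float)


def _replicate_cfrs(
    scenario: Scenario, spec: UncertaintySpec, rng: np.random.Generator
) -> np.ndarray:
    tax = list(scenario.deaths.taxonomy)
    p = np.array([scenario.cfr[m] for m in tax])
    out = np.tile(p, (spec.n_replicates, 1))
    if spec.cfr_ess is None:
        return out
    for j, m in enumerate(tax):
        n_eff = spec.cfr_ess.get(m)
        # boundary CFRs (0 or 1) have no conjugate perturbation; keep fixed
        if n_eff is None or p[j] in (0.0, 1.0):
            continue
        out[:, j] = rng.beta(p[j] * n_eff, (1.0 - p[j]) * n_eff, size=spec.n_replicates)
    return out


def bootstrap_scenario(scenario: Scenario, spec: UncertaintySpec) -> IntervalSummary:
    """Percentile-bootstrap the full counterfactual pipeline.

    Deterministic given (scenario, spec): the spec's seed feeds a
    ``SeedSequence`` split into one stream for death resampling and one
    for CFR perturbation.
    """
    point = run_counterfactual(scenario)
    tax = list(scenario.deaths.taxonomy)
    q = np.array([scenario.counterfactual[m] for m in tax])
    n_subj = scenario.n_subjects

    death_rng, cfr_rng = (
        np.random.default_rng(c) for c in np.random.SeedSequence(spec.seed).spawn(2)
    )
    deaths = _replicate_tallies(scenario, spec, death_rng)
    cfrs = _replicate_cfrs(scenario, spec, cfr_rng)

    with np.errstate(divide="ignore", invalid="ignore"):
        acts = np.where(deaths > 0, deaths / cfrs, 0.0)
    if not np.isfinite(acts).all():
        bad = int(np.argwhere(~np.isfinite(acts).all(axis=1))[0, 0])
        raise ValidationError(
            f"replicate {bad}: death observed for a method with zero CFR"
        )
    total_acts = acts.sum(axis=1)
    cf_deaths = total_acts * (cfrs * q).sum(axis=1)
    observed = deaths.sum(axis=1)
    averted = cf_deaths - observed
    rd = averted / n_subj
    undefined = averted <= 0

    lo, hi = spec.levels

    def interval(x: np.ndarray, point_value: float | None) -> dict:
        return {
            "point": point_value,
            "lower": float(np.quantile(x, lo)),
            "upper": float(np.quantile(x, hi)),
        }

    quantities = {
        "total_acts": interval(total_acts, point.total_acts),
        "counterfactual_deaths": interval(cf_deaths, point.counterfactual_total_deaths),
        "deaths_averted": interval(averted, point.deaths_averted),
        "risk_difference": interval(rd, point.risk_difference),
    }
    # NNT bounds are the monotone transform of the averted-death bounds;
    # a bound at or below zero excess deaths maps to an undefined bound.
    av_lo, av_hi = np.quantile(averted, lo), np.quantile(averted, hi)
    quantities["nnt"] = {
        "point": point.nnt,
        "lower": float(n_subj / av_hi) if av_hi > 0 else None,
        "upper": float(n_subj / av_lo) if av_lo > 0 else None,
    }
    return IntervalSummary(
        point=point,
        levels=spec.levels,
        n_replicates=spec.n_replicates,
        seed=spec.seed,
        quantities=quantities,
        undefined_nnt_fraction=float(undefined.mean()),
    )
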