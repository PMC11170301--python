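"""CFR inversion: from observed method-specific deaths to estimated suicidal acts.

Step 1 of the counterfactual procedure.  The number of suicidal acts
(fatal plus nonfatal) by method m is estimated as

    A_m = D_m / p_m

where D_m is the observed death count and p_m the case fatality ratio for
that method in the chosen stratum.  Methods with no observed deaths are
assigned zero acts (no smoothing or pseudo-counts).  All arithmetic is
carried at full float precision; rounding happens only when rendering
reports.
"""

from __future__ import annotations

from dataclasses import dataclass

from .method_model import (
    ActEstimate,
    CFRTable,
    DeathTally,
    DegenerateDistributionError,
    ExpectedDeaths,
    MethodDistribution,
    ValidationError,
)

__all__ = ["ActsDerivation", "estimate_acts", "factual_act_distribution", "apply_cfr"]


class ZeroLethalityError(ValidationError):
    """A death was observed by a method whose CFR is zero — impossible under the model."""


def estimate_acts(deaths: DeathTally, cfr: CFRTable) -> ActEstimate:
    """Invert a death tally into estimated suicidal acts via CFR division.

    Raises :class:`ZeroLethalityError` if any method has observed deaths but
    a zero CFR (the model cannot produce a death from a never-fatal method).
    """
    if deaths.taxonomy != cfr.taxonomy:
        raise ValidationError("death tally and CFR table use different taxonomies")
    acts: dict[str, float] = {}
    for m in deaths.taxonomy:
        d = deaths[m]
        if d == 0:
            acts[m] = 0.0
        elif cfr[m] == 0.0:
            raise ZeroLethalityError(
                f"observed a death by a method with zero lethality: {m} "
                f"(deaths={d}, cfr=0)"
            )
        else:
            acts[m] = d / cfr[m]
    return ActEstimate(acts, taxonomy=deaths.taxonomy)


def factual_act_distribution(acts: ActEstimate) -> MethodDistribution:
    """Share of estimated acts by method: proportion_m = A_m / sum_k A_k."""
    total = acts.total_acts
    if total <= 0:
        raise DegenerateDistributionError("no estimated acts: cannot form a distribution")
    return MethodDistribution(
        {m: acts[m] / total for m in acts.taxonomy},
        provenance="factual",
        taxonomy=acts.taxonomy,
    )


def apply_cfr(acts: ActEstimate, cfr: CFRTable) -> ExpectedDeaths:
    """Expected deaths implied by an act vector: deaths_m = A_m x p_m.

    This is the exact inverse of :func:`estimate_acts` on its image.
    """
    if acts.taxonomy != cfr.taxonomy:
        raise ValidationError("act estimate and CFR table use different taxonomies")
    return ExpectedDeaths({m: acts[m] * cfr[m] for m in acts.taxonomy}, taxonomy=acts.taxonomy)


@dataclass(frozen=True)
class ActsDerivation:
    """Bundle of step 1: inputs, estimated acts, and the factual act distribution."""

    deaths: DeathTally
    cfr: CFRTable
    acts: ActEstimate
    factual_distribution: MethodDistribution

    @classmethod
    def from_tally(cls, deaths: DeathTally, cfr: CFRTable) -> "ActsDerivation":
        acts = estimate_acts(deaths, cfr)
        return cls(deaths, cfr, acts, factual_act_distribution(acts))
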