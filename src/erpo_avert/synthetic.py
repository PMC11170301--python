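"""Synthetic cohorts and forward simulation of the act/lethality model.

Two generators make every pipeline stage testable without restricted data:

``generate_cohort``
    Individual-level records (ownership, sex, suicide death, method) drawn
    from a :class:`CohortSpec`.  Defaults mimic a large handgun-transfer
    cohort: ownership is rare, suicide death is rare, and the method mix of
    decedents differs sharply by ownership and sex (firearm share 0.88 for
    male owners vs 0.40 / 0.17 for male / female nonowners).

``simulate_acts_and_deaths``
    The latent generative model that CFR inversion assumes: a fixed number
    of suicidal acts is distributed multinomially over methods, and each
    act is fatal independently with the method's case fatality ratio,

        A ~ Multinomial(n_acts, q),    D_m | A_m ~ Binomial(A_m, p_m).

    Both the true acts and the realized death tally are returned, so that
    the estimator D_m / p_m can be scored as parameter recovery.

Randomness: every public entry point takes one integer seed.  Internally a
``numpy.random.SeedSequence`` is spawned into named child streams (one per
sampling stage), so adding a stage never perturbs the draws of earlier
stages and compound simulations stay reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .method_model import (
    DEFAULT_TAXONOMY,
    CFRTable,
    DeathTally,
    MethodDistribution,
    MethodTaxonomy,
    ValidationError,
    normalize_distribution,
)

__all__ = [
    "CohortSpec",
    "ActsSimSpec",
    "generate_cohort",
    "simulate_acts_and_deaths",
    "default_method_mix",
]

# Decedent method-mix weights by (ownership, sex).  Whole-percent published
# shares; cells censored below 1% are entered as 0.5 before normalization.
_METHOD_WEIGHTS: dict[tuple[str, str], tuple[float, ...]] = {
    ("handgun_owner", "male"):   (88, 5, 0.5, 0.5, 6, 0.5, 0.5, 0.5, 0.5, 0.5),
    ("handgun_owner", "female"): (88, 7, 0.5, 0.5, 6, 0.5, 0.5, 0.5, 0.5, 0.5),
    ("nonowner", "male"):        (40, 15, 0.5, 3, 30, 0.5, 3, 5, 2, 2),
    ("nonowner", "female"):      (17, 44, 0.5, 3, 27, 2, 2, 5, 2, 2),
}


def default_method_mix(taxonomy: MethodTaxonomy = DEFAULT_TAXONOMY) -> dict[tuple[str, str], MethodDistribution]:
    """Default decedent method distributions per (ownership, sex) cell."""
    return {
        key: normalize_distribution(dict(zip(taxonomy, w)), taxonomy=taxonomy)
        for key, w in _METHOD_WEIGHTS.items()
    }


def _default_death_probability() -> dict[tuple[str, str], float]:
    # Cumulative 11-year suicide-death risk of order 7e-4, equal across
    # sexes within ownership group (decedent sex mix then follows the
    # cohort sex mix).
    return {
        ("handgun_owner", "male"): 7.0e-4,
        ("handgun_owner", "female"): 7.0e-4,
        ("nonowner", "male"): 6.5e-4,
        ("nonowner", "female"): 6.5e-4,
    }


@dataclass(frozen=True)
class CohortSpec:
    """Parameters of the synthetic cohort generator.

    ``male_share`` and ``death_probability`` are keyed by ownership group
    and (ownership, sex) respectively; ``method_mix`` gives the decedent
    method distribution per (ownership, sex) cell.  Defaults echo a large
    linked handgun-owner cohort: 83.8% / 68.9% male among owner / nonowner
    decedents and the published ownership-by-sex firearm shares.
    """

    n_individuals: int = 100_000
    ownership_prevalence: float = 0.07
    male_share: Mapping[str, float] = field(
        default_factory=lambda: {"handgun_owner": 0.838, "nonowner": 0.689}
    )
    death_probability: Mapping[tuple[str, str], float] = field(
        default_factory=_default_death_probability
    )
    method_mix: Mapping[tuple[str, str], MethodDistribution] | None = None
    age_mean_sd: Mapping[str, tuple[float, float]] = field(
        default_factory=lambda: {"handgun_owner": (50.0, 18.0), "nonowner": (53.0, 18.0)}
    )
    taxonomy: MethodTaxonomy = DEFAULT_TAXONOMY

    def __post_init__(self) -> None:
        if self.n_individuals <= 0:
            raise ValidationError("n_individuals must be positive")
        probs = [self.ownership_prevalence, *self.male_share.values(), *self.death_probability.values()]
        if any(not (0.0 <= p <= 1.0) for p in probs):
            raise ValidationError("all probabilities must lie in [0, 1]")
        for own in ("handgun_owner", "nonowner"):
            if own not in self.male_share:
                raise ValidationError(f"male_share missing ownership group {own!r}")
            for sex in ("male", "female"):
                if (own, sex) not in self.death_probability:
                    raise ValidationError(f"death_probability missing cell {(own, sex)}")

    def resolved_method_mix(self) -> Mapping[tuple[str, str], MethodDistribution]:
        return self.method_mix if self.method_mix is not None else default_method_mix(self.taxonomy)


def generate_cohort(spec: CohortSpec, seed: int) -> pd.DataFrame:
    """Draw a synthetic cohort as a validated record DataFrame.

    Columns: id, ownership, sex, died_by_suicide, method (NA for
    survivors), age.  Deterministic given (spec, seed).
    """
    root = np.random.SeedSequence(seed)
    streams = {
        name: np.random.default_rng(child)
        for name, child in zip(
            ("ownership", "sex", "death", "method", "age"), root.spawn(5)
        )
    }
    n = spec.n_individuals
    tax = list(spec.taxonomy)
    mix = spec.resolved_method_mix()

    owner = streams["ownership"].random(n) < spec.ownership_prevalence
    ownership = np.where(owner, "handgun_owner", "nonowner")
    p_male = np.where(owner, spec.male_share["handgun_owner"], spec.male_share["nonowner"])
    sex = np.where(streams["sex"].random(n) < p_male, "male", "female")

    p_death = np.empty(n)
    for own in ("handgun_owner", "nonowner"):
        for sx in ("male", "female"):
            mask = (ownership == own) & (sex == sx)
            p_death[mask] = spec.death_probability[(own, sx)]
    died = streams["death"].random(n) < p_death

    method = np.full(n, None, dtype=object)
    for own in ("handgun_owner", "nonowner"):
        for sx in ("male", "female"):
            mask = died & (ownership == own) & (sex == sx)
            k = int(mask.sum())
            if k:
                probs = [mix[(own, sx)][m] for m in tax]
                method[mask] = streams["method"].choice(tax, size=k, p=probs)

    age = np.empty(n)
    for own, (mu, sd) in spec.age_mean_sd.items():
        mask = ownership == own
        age[mask] = streams["age"].normal(mu, sd, size=int(mask.sum()))
    age = np.clip(np.round(age), 21, 102).astype(int)

    return pd.DataFrame(
        {
            "id": np.arange(n),
            "ownership": ownership,
            "sex": sex,
            "died_by_suicide": died,
            "method": pd.array(method, dtype="object"),
            "age": age,
        }
    )


@dataclass(frozen=True)
class ActsSimSpec:
    """Forward-model simulation parameters: act count, method mix, lethality."""

    n_acts: int
    act_distribution: MethodDistribution
    cfr: CFRTable

    def __post_init__(self) -> None:
        if self.n_acts < 0:
            raise ValidationError("n_acts must be non-negative")
        if self.act_distribution.taxonomy != self.cfr.taxonomy:
            raise ValidationError("act distribution and CFR table use different taxonomies")


def simulate_acts_and_deaths(
    spec: ActsSimSpec, seed: int, *, size: int | None = None
) -> tuple[np.ndarray, np.ndarray] | tuple[dict[str, int], DeathTally]:
    """Simulate latent acts and realized deaths under the lethality model.

    With ``size=None`` returns ``(acts, tally)`` — a per-method dict of
    true act counts and the realized :class:`DeathTally`.  With an integer
    ``size`` returns ``(acts, deaths)`` as two ``(size, n_methods)``
    arrays in taxonomy order, for vectorized replicate studies.
    """
    root = np.random.SeedSequence(seed)
    act_rng, death_rng = (np.random.default_rng(c) for c in root.spawn(2))
    tax = list(spec.cfr.taxonomy)
    q = np.array([spec.act_distribution[m] for m in tax])
    p = np.array([spec.cfr[m] for m in tax])

    reps = 1 if size is None else size
    acts = act_rng.multinomial(spec.n_acts, q, size=reps)
    deaths = death_rng.binomial(acts, p)
    if size is not None:
        return acts, deaths
    acts_d = dict(zip(tax, (int(a) for a in acts[0])))
    tally = DeathTally(dict(zip(tax, (int(d) for d in deaths[0]))), taxonomy=spec.cfr.taxonomy)
    return acts_d, tally
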