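"""Packaged default data: the Connecticut ERPO worked example.

Ships the three inputs needed to reproduce the headline number-needed-to-
treat estimate with no external files: the method-specific death tally for
the 762 Connecticut ERPO respondents (1999-2013), the male case fatality
ratio table, and the male handgun-owner act distribution used as the
counterfactual method mix.
"""

from __future__ import annotations

from importlib import resources

from .counterfactual import Scenario
from .method_model import (
    CFRTable,
    DeathTally,
    MethodDistribution,
    load_cfr_table,
    load_death_tally,
    load_distribution,
)

__all__ = [
    "CONNECTICUT_N_RESPONDENTS",
    "male_cfr_table",
    "connecticut_death_tally",
    "owner_male_act_distribution",
    "connecticut_scenario",
]

#: Number of ERPO respondents in the Connecticut study period.
CONNECTICUT_N_RESPONDENTS = 762


def _data_path(name: str):
    return resources.files("erpo_avert.data").joinpath(name)


def male_cfr_table() -> CFRTable:
    """Male case fatality ratios (emergency-department based) per method."""
    with resources.as_file(_data_path("cfr_male.csv")) as p:
        return load_cfr_table(p, stratum="male")


def connecticut_death_tally() -> DeathTally:
    """Observed suicide deaths by method among Connecticut ERPO respondents."""
    with resources.as_file(_data_path("deaths_connecticut.csv")) as p:
        return load_death_tally(p)


def owner_male_act_distribution() -> MethodDistribution:
    """Counterfactual act distribution: male handgun owners' estimated act mix."""
    with resources.as_file(_data_path("act_distribution_owner_male.csv")) as p:
        return load_distribution(p, provenance="counterfactual")


def connecticut_scenario() -> Scenario:
    """The packaged headline scenario, ready for ``run_counterfactual``."""
    return Scenario(
        n_subjects=CONNECTICUT_N_RESPONDENTS,
        deaths=connecticut_death_tally(),
        cfr=male_cfr_table(),
        counterfactual=owner_male_act_distribution(),
        label="connecticut",
    )
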