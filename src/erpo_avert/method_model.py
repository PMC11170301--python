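"""Core domain types: method taxonomy, case fatality ratios, tallies, distributions.

The model underlying this package is generic over self-harm methods: a
taxonomy fixes the ordered set of method categories, and every other object
(CFR table, death tally, act estimate, method distribution) is validated
against the active taxonomy.  The default taxonomy is the ten ICD-10
(X60-X84 derived) deliberate self-harm categories used in firearm-injury
epidemiology.

All tabular IO is plain comma-delimited UTF-8 text with a header row.
Distribution files may carry a leading comment line ``# units=percent`` (or
``fraction``) declaring the scale of the proportion column.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

logger = logging.getLogger("erpo_avert")

__all__ = [
    "DEFAULT_METHODS",
    "DEFAULT_TAXONOMY",
    "FIREARM",
    "MethodTaxonomy",
    "CFRTable",
    "DeathTally",
    "ExpectedDeaths",
    "ActEstimate",
    "MethodDistribution",
    "ValidationError",
    "DegenerateDistributionError",
    "normalize_distribution",
    "load_cfr_table",
    "load_death_tally",
    "load_distribution",
]

#: Canonical identifier for the firearm category (the substituted method in
#: the means-restriction counterfactual, unless overridden).
FIREARM = "firearm"

#: The ten deliberate self-harm categories, in reporting order.
DEFAULT_METHODS: tuple[str, ...] = (
    "firearm",
    "poisoning_drugs",
    "poisoning_other_solid_liquid",
    "poisoning_gases_vapors",
    "hanging",
    "drowning",
    "cutting",
    "jumping_height",
    "jumping_moving_object",
    "other_unspecified",
)

#: Fraction-scale tolerance on the sum of a distribution before a hard
#: error is raised (percent-scale inputs rounded to whole percent can be
#: off by about this much).
SUM_TOLERANCE = 0.015


class ValidationError(ValueError):
    """An input violates a domain-type invariant."""


class DegenerateDistributionError(ValidationError):
    """All weights are zero: no distribution can be formed."""


@dataclass(frozen=True)
class MethodTaxonomy:
    """Ordered, unique set of self-harm method identifiers.

    Order is significant: every report and CSV written by this package lists
    methods in taxonomy order.  A substitution model needs at least two
    methods to be meaningful.
    """

    methods: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.methods) < 2:
            raise ValidationError("taxonomy must contain at least 2 methods")
        if len(set(self.methods)) != len(self.methods):
            raise ValidationError("taxonomy method identifiers must be unique")
        if any(not m or not str(m).strip() for m in self.methods):
            raise ValidationError("taxonomy method identifiers must be non-empty")

    def __contains__(self, method: str) -> bool:
        return method in self.methods

    def __iter__(self):
        return iter(self.methods)

    def __len__(self) -> int:
        return len(self.methods)

    def index(self, method: str) -> int:
        return self.methods.index(method)

    def validate_keys(self, keys: Iterable[str], what: str) -> None:
        """Check that *keys* are exactly the taxonomy methods."""
        keys = list(keys)
        unknown = [k for k in keys if k not in self.methods]
        if unknown:
            raise ValidationError(f"{what}: unknown method identifiers {unknown}")
        missing = [m for m in self.methods if m not in keys]
        if missing:
            raise ValidationError(f"incomplete {what}: missing methods {missing}")
        if len(keys) != len(set(keys)):
            raise ValidationError(f"{what}: duplicate method rows")

    @classmethod
    def from_file(cls, path: str | Path) -> "MethodTaxonomy":
        """Read a taxonomy from a one-column CSV with header ``method``."""
        df = pd.read_csv(path, comment="#")
        if "method" not in df.columns:
            raise ValidationError(f"{path}: taxonomy file needs a 'method' column")
        return cls(tuple(str(m) for m in df["method"]))


DEFAULT_TAXONOMY = MethodTaxonomy(DEFAULT_METHODS)


def _as_ordered(values: Mapping[str, float], taxonomy: MethodTaxonomy, what: str) -> dict[str, float]:
    taxonomy.validate_keys(values.keys(), what)
    return {m: float(values[m]) for m in taxonomy}


@dataclass(frozen=True)
class CFRTable:
    """Method-specific case fatality ratios for one stratum.

    ``cfr[m]`` is the probability that a single suicidal act by method *m*
    is fatal.  The stratum label (e.g. ``male``, ``female``, ``pooled``) is
    carried explicitly and never inferred.
    """

    cfr: Mapping[str, float]
    stratum: str = "pooled"
    taxonomy: MethodTaxonomy = DEFAULT_TAXONOMY

    def __post_init__(self) -> None:
        values = _as_ordered(self.cfr, self.taxonomy, "CFR table")
        for m, p in values.items():
            if not (0.0 <= p <= 1.0):
                raise ValidationError(
                    f"CFR for {m} is {p}: case fatality ratios must lie in [0, 1]"
                )
        object.__setattr__(self, "cfr", values)

    def __getitem__(self, method: str) -> float:
        return self.cfr[method]

    def as_series(self) -> pd.Series:
        return pd.Series(self.cfr, name="cfr")

    def to_csv(self, path: str | Path) -> None:
        pd.DataFrame({"method": list(self.taxonomy), "cfr": [self.cfr[m] for m in self.taxonomy]}).to_csv(
            path, index=False
        )


@dataclass(frozen=True)
class DeathTally:
    """Per-method counts of observed suicide deaths."""

    deaths: Mapping[str, int]
    taxonomy: MethodTaxonomy = DEFAULT_TAXONOMY

    def __post_init__(self) -> None:
        values = _as_ordered(self.deaths, self.taxonomy, "death tally")
        counts: dict[str, int] = {}
        for m, d in values.items():
            if d < 0 or d != int(d):
                raise ValidationError(f"death count for {m} is {d}: must be a non-negative integer")
            counts[m] = int(d)
        object.__setattr__(self, "deaths", counts)

    @property
    def total(self) -> int:
        return sum(self.deaths.values())

    def __getitem__(self, method: str) -> int:
        return self.deaths[method]

    def as_series(self) -> pd.Series:
        return pd.Series(self.deaths, name="deaths")

    def to_csv(self, path: str | Path) -> None:
        pd.DataFrame(
            {"method": list(self.taxonomy), "deaths": [self.deaths[m] for m in self.taxonomy]}
        ).to_csv(path, index=False)


@dataclass(frozen=True)
class ExpectedDeaths:
    """Real-valued expected death counts (acts x CFR); tally-shaped but fractional."""

    deaths: Mapping[str, float]
    taxonomy: MethodTaxonomy = DEFAULT_TAXONOMY

    def __post_init__(self) -> None:
        values = _as_ordered(self.deaths, self.taxonomy, "expected deaths")
        for m, d in values.items():
            if d < 0:
                raise ValidationError(f"expected deaths for {m} is {d}: must be >= 0")
        object.__setattr__(self, "deaths", values)

    @property
    def total(self) -> float:
        return sum(self.deaths.values())

    def __getitem__(self, method: str) -> float:
        return self.deaths[method]

    def as_series(self) -> pd.Series:
        return pd.Series(self.deaths, name="expected_deaths")


@dataclass(frozen=True)
class ActEstimate:
    """Per-method estimated suicidal acts (fatal plus nonfatal), real-valued."""

    acts: Mapping[str, float]
    taxonomy: MethodTaxonomy = DEFAULT_TAXONOMY

    def __post_init__(self) -> None:
        values = _as_ordered(self.acts, self.taxonomy, "act estimate")
        for m, a in values.items():
            if a < 0 or not math.isfinite(a):
                raise ValidationError(f"act count for {m} is {a}: must be finite and >= 0")
        object.__setattr__(self, "acts", values)

    @property
    def total_acts(self) -> float:
        return sum(self.acts.values())

    def __getitem__(self, method: str) -> float:
        return self.acts[method]

    def as_series(self) -> pd.Series:
        return pd.Series(self.acts, name="acts")


@dataclass(frozen=True)
class MethodDistribution:
    """Per-method proportions of suicidal acts, summing to one.

    ``provenance`` records whether the distribution was derived from
    observed deaths (``factual``), constructed as a counterfactual, or
    supplied by the user.
    """

    proportions: Mapping[str, float]
    provenance: str = "user-supplied"
    taxonomy: MethodTaxonomy = DEFAULT_TAXONOMY

    def __post_init__(self) -> None:
        values = _as_ordered(self.proportions, self.taxonomy, "method distribution")
        for m, p in values.items():
            if not (0.0 <= p <= 1.0):
                raise ValidationError(f"proportion for {m} is {p}: must lie in [0, 1]")
        total = sum(values.values())
        if abs(total - 1.0) > 1e-9:
            raise ValidationError(
                f"method distribution sums to {total!r}, not 1; normalize first "
                "(see normalize_distribution)"
            )
        object.__setattr__(self, "proportions", values)

    def __getitem__(self, method: str) -> float:
        return self.proportions[method]

    def as_series(self) -> pd.Series:
        return pd.Series(self.proportions, name="proportion")

    def to_csv(self, path: str | Path, units: str = "fraction") -> None:
        scale = 100.0 if units == "percent" else 1.0
        with open(path, "w", encoding="utf-8") as fh:
            fh.write(f"# units={units}\n")
            pd.DataFrame(
                {
                    "method": list(self.taxonomy),
                    "proportion": [self.proportions[m] * scale for m in self.taxonomy],
                }
            ).to_csv(fh, index=False)


def normalize_distribution(
    raw: Mapping[str, float],
    *,
    units: str = "weights",
    provenance: str = "user-supplied",
    taxonomy: MethodTaxonomy = DEFAULT_TAXONOMY,
) -> MethodDistribution:
    """Build a :class:`MethodDistribution` from non-negative per-method weights.

    Parameters
    ----------
    raw
        Per-method weights covering the full taxonomy; all must be >= 0 and
        at least one > 0.
    units
        ``"weights"`` rescales any non-negative vector to sum to one.
        ``"percent"`` and ``"fraction"`` declare the scale of the input and
        enforce that the declared-scale sum is within the normalization
        tolerance (|sum - 1| <= 0.015 after percent -> fraction conversion);
        a larger discrepancy raises, which catches percent/fraction mix-ups.
    """
    values = _as_ordered(raw, taxonomy, "distribution weights")
    if any(v < 0 for v in values.values()):
        raise ValidationError("distribution weights must be non-negative")
    total = sum(values.values())
    if total <= 0:
        raise DegenerateDistributionError("all distribution weights are zero")

    if units == "percent":
        values = {m: v / 100.0 for m, v in values.items()}
        total /= 100.0
    if units in ("percent", "fraction"):
        if abs(total - 1.0) > SUM_TOLERANCE:
            raise ValidationError(
                f"{units} distribution sums to {total:.6g} (fraction scale); "
                f"outside tolerance {SUM_TOLERANCE} — check the units"
            )
        if total != 1.0:
            logger.info("rescaling distribution with sum %.6g to exactly 1", total)
    elif units != "weights":
        raise ValidationError(f"unknown units {units!r}: expected weights|percent|fraction")

    props = {m: v / total for m, v in values.items()}
    return MethodDistribution(props, provenance=provenance, taxonomy=taxonomy)


def _read_table(path: str | Path, required: tuple[str, str]) -> pd.DataFrame:
    df = pd.read_csv(path, comment="#")
    for col in required:
        if col not in df.columns:
            raise ValidationError(f"{path}: missing required column {col!r}")
    return df


def _declared_units(path: str | Path) -> str | None:
    """Return the units declared in a leading ``# units=...`` comment, if any."""
    with open(path, "r", encoding="utf-8") as fh:
        for line in fh:
            line = line.strip()
            if not line.startswith("#"):
                break
            if "units=" in line:
                return line.split("units=", 1)[1].strip()
    return None


def load_cfr_table(
    path: str | Path,
    stratum: str,
    taxonomy: MethodTaxonomy = DEFAULT_TAXONOMY,
) -> CFRTable:
    """Read a CFR table (columns ``method,cfr``) for the given stratum."""
    df = _read_table(path, ("method", "cfr"))
    return CFRTable(dict(zip(df["method"], df["cfr"])), stratum=stratum, taxonomy=taxonomy)


def load_death_tally(path: str | Path, taxonomy: MethodTaxonomy = DEFAULT_TAXONOMY) -> DeathTally:
    """Read a death tally (columns ``method,deaths``)."""
    df = _read_table(path, ("method", "deaths"))
    return DeathTally(dict(zip(df["method"], df["deaths"])), taxonomy=taxonomy)


def load_distribution(
    path: str | Path,
    *,
    provenance: str = "user-supplied",
    taxonomy: MethodTaxonomy = DEFAULT_TAXONOMY,
) -> MethodDistribution:
    """Read a method distribution (columns ``method,proportion``).

    The scale is taken from a leading ``# units=percent|fraction`` comment
    line, defaulting to ``fraction``; the declared-scale sum must be within
    the normalization tolerance.
    """
    units = _declared_units(path) or "fraction"
    df = _read_table(path, ("method", "proportion"))
    return normalize_distribution(
        dict(zip(df["method"], df["proportion"])),
        units=units,
        provenance=provenance,
        taxonomy=taxonomy,
    )
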