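"""Tabulation of individual-level cohort records into descriptive surfaces.

A cohort is a pandas DataFrame with one row per person and columns

    id, ownership (handgun_owner | nonowner), sex (male | female),
    died_by_suicide (bool), method (taxonomy id, present iff decedent),
    age (optional), plus any extra stratum columns (preserved, ignored).

From such records this module builds:

* a mortality tabulation — per (ownership, sex) cell, the method-specific
  death tally and within-cell percent distribution;
* CFR-derived act distributions per cell, by inverting each cell's tally
  with the sex-matched CFR table;
* generic demographic group-by summaries (age, extra categorical strata).

Records with missing analytic fields are excluded with a logged count
rather than imputed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import pandas as pd

from .acts import estimate_acts, factual_act_distribution
from .method_model import (
    DEFAULT_TAXONOMY,
    ActEstimate,
    CFRTable,
    DeathTally,
    MethodDistribution,
    MethodTaxonomy,
    ValidationError,
)

logger = logging.getLogger("erpo_avert")

__all__ = [
    "REQUIRED_COLUMNS",
    "validate_cohort",
    "MortalityCell",
    "MortalityTabulation",
    "tabulate_mortality",
    "act_distribution_by_cell",
    "summarize_demographics",
]

REQUIRED_COLUMNS = ("id", "ownership", "sex", "died_by_suicide")
OWNERSHIP_LEVELS = ("handgun_owner", "nonowner")
SEX_LEVELS = ("male", "female")


def validate_cohort(records: pd.DataFrame, taxonomy: MethodTaxonomy = DEFAULT_TAXONOMY) -> pd.DataFrame:
    """Validate cohort records and drop rows with missing analytic fields.

    Enforces the record invariant that ``method`` is present exactly when
    ``died_by_suicide`` is true; violations raise with the offending ids.
    Returns the validated frame (a copy) with ``died_by_suicide`` as bool.
    """
    missing_cols = [c for c in REQUIRED_COLUMNS if c not in records.columns]
    if missing_cols:
        raise ValidationError(f"cohort is missing required columns {missing_cols}")
    df = records.copy()
    if "method" not in df.columns:
        df["method"] = pd.NA

    analytic = df[["ownership", "sex", "died_by_suicide"]].notna().all(axis=1)
    n_dropped = int((~analytic).sum())
    if n_dropped:
        logger.warning("excluding %d cohort records with missing analytic fields", n_dropped)
        df = df[analytic]
    df = df.copy()
    df["died_by_suicide"] = df["died_by_suicide"].astype(bool)

    bad_own = ~df["ownership"].isin(OWNERSHIP_LEVELS)
    if bad_own.any():
        raise ValidationError(
            f"unknown ownership values {sorted(df.loc[bad_own, 'ownership'].unique())}"
        )
    bad_sex = ~df["sex"].isin(SEX_LEVELS)
    if bad_sex.any():
        raise ValidationError(f"unknown sex values {sorted(df.loc[bad_sex, 'sex'].unique())}")

    has_method = df["method"].notna()
    inconsistent = df[has_method != df["died_by_suicide"]]
    if len(inconsistent):
        ids = inconsistent["id"].tolist()[:20]
        raise ValidationError(
            "method must be recorded exactly for suicide decedents; "
            f"{len(inconsistent)} inconsistent records (ids {ids}...)"
        )
    unknown = df.loc[has_method, "method"][~df.loc[has_method, "method"].isin(list(taxonomy))]
    if len(unknown):
        raise ValidationError(f"unknown method identifiers {sorted(unknown.unique())}")
    return df


@dataclass(frozen=True)
class MortalityCell:
    """One stratification cell: death tally, decedent count, percent distribution."""

    key: tuple[str, ...]
    tally: DeathTally
    n_decedents: int
    percent: Mapping[str, float] | None  # None when the cell has no decedents


@dataclass(frozen=True)
class MortalityTabulation:
    """Method-specific mortality distribution by stratification cell."""

    by: tuple[str, ...]
    cells: Mapping[tuple[str, ...], MortalityCell]
    taxonomy: MethodTaxonomy

    @property
    def total_decedents(self) -> int:
        return sum(c.n_decedents for c in self.cells.values())

    def as_frame(self, percent_decimals: int | None = None) -> pd.DataFrame:
        """Wide table: one row per method, one percent column per cell.

        ``percent_decimals`` rounds for display (half-up at 0 decimals
        matches whole-percent published tables); values are stored at full
        precision.
        """
        data: dict[str, list] = {"method": list(self.taxonomy)}
        for key, cell in self.cells.items():
            name = "/".join(key) or "all"
            col = []
            for m in self.taxonomy:
                if cell.percent is None:
                    col.append(float("nan"))
                else:
                    v = cell.percent[m]
                    if percent_decimals is not None:
                        # half-up, not banker's rounding, to match published style
                        q = 10**percent_decimals
                        v = int(v * q + 0.5) / q if v >= 0 else v
                    col.append(v)
            data[name] = col
        return pd.DataFrame(data)


def tabulate_mortality(
    records: pd.DataFrame,
    by: Sequence[str] = ("ownership", "sex"),
    taxonomy: MethodTaxonomy = DEFAULT_TAXONOMY,
) -> MortalityTabulation:
    """Tally decedent methods within each stratification cell.

    ``by`` is any subset of {ownership, sex} (empty for a pooled tally).
    Cells are formed from the full level cross so empty cells are reported
    with count 0 and an undefined (None) distribution.  The result is
    independent of input record order.
    """
    bad = [b for b in by if b not in ("ownership", "sex")]
    if bad:
        raise ValidationError(f"stratification supports ownership/sex only, got {bad}")
    df = validate_cohort(records, taxonomy)
    dec = df[df["died_by_suicide"]]

    levels = {"ownership": OWNERSHIP_LEVELS, "sex": SEX_LEVELS}
    keys: list[tuple[str, ...]] = [()]
    for b in by:
        keys = [k + (lvl,) for k in keys for lvl in levels[b]]

    cells: dict[tuple[str, ...], MortalityCell] = {}
    for key in keys:
        sub = dec
        for col, lvl in zip(by, key):
            sub = sub[sub[col] == lvl]
        counts = sub["method"].value_counts()
        tally = DeathTally({m: int(counts.get(m, 0)) for m in taxonomy}, taxonomy=taxonomy)
        n = tally.total
        percent = {m: 100.0 * tally[m] / n for m in taxonomy} if n > 0 else None
        cells[key] = MortalityCell(key=key, tally=tally, n_decedents=n, percent=percent)
    return MortalityTabulation(by=tuple(by), cells=cells, taxonomy=taxonomy)


def act_distribution_by_cell(
    tab: MortalityTabulation,
    cfr_by_sex: Mapping[str, CFRTable],
) -> dict[tuple[str, ...], tuple[ActEstimate, MethodDistribution]]:
    """CFR-derived act estimates and act distributions per tabulation cell.

    ``cfr_by_sex`` maps sex labels to CFR tables; cells not stratified by
    sex use the ``"pooled"`` entry.  Empty cells are omitted from the
    result (no acts can be inferred from zero deaths).
    """
    if "sex" in tab.by:
        sex_pos = tab.by.index("sex")
    else:
        sex_pos = None
    out: dict[tuple[str, ...], tuple[ActEstimate, MethodDistribution]] = {}
    for key, cell in tab.cells.items():
        if cell.n_decedents == 0:
            continue
        stratum = key[sex_pos] if sex_pos is not None else "pooled"
        if stratum not in cfr_by_sex:
            raise ValidationError(f"no CFR table supplied for stratum {stratum!r}")
        acts = estimate_acts(cell.tally, cfr_by_sex[stratum])
        out[key] = (acts, factual_act_distribution(acts))
    return out


def summarize_demographics(
    records: pd.DataFrame,
    by: Sequence[str] = ("ownership",),
    extra_categoricals: Sequence[str] = (),
) -> pd.DataFrame:
    """Generic group-by summary: counts, sex split, age moments, extras.

    Returns one row per group with n, percent male, and (when an ``age``
    column exists) mean/SD/median age; each column of
    ``extra_categoricals`` adds per-level counts.
    """
    df = validate_cohort(records)
    rows = []
    for key, g in df.groupby(list(by), sort=False):
        key = key if isinstance(key, tuple) else (key,)
        row: dict[str, object] = dict(zip(by, key))
        row["n"] = len(g)
        row["percent_male"] = 100.0 * (g["sex"] == "male").mean()
        if "age" in g.columns and g["age"].notna().any():
            row["age_mean"] = g["age"].mean()
            row["age_sd"] = g["age"].std()
            row["age_median"] = g["age"].median()
        for col in extra_categoricals:
            for lvl, cnt in g[col].value_counts().items():
                row[f"{col}={lvl}"] = int(cnt)
        rows.append(row)
    return pd.DataFrame(rows)
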