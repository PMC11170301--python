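"""Rendering of counterfactual results: derivation table, summaries, JSON."""

from __future__ import annotations

import json
import math

import pandas as pd

from .counterfactual import CounterfactualResult

__all__ = ["render_derivation_table", "render_summary", "result_to_json"]


def _fmt_nnt(nnt: float | None, deaths_averted: float) -> str:
    # No excess deaths: an NNT of "inf" (nothing to avert); negative NNTs
    # (protective counterfactual) are never printed.
    if nnt is None:
        return "inf" if deaths_averted == 0 else "undefined (protective)"
    return f"{nnt:.1f}"


def render_derivation_table(result: CounterfactualResult, decimals: int = 1) -> str:
    """Step-by-step derivation table, one row per method plus a total row.

    Columns: observed deaths, CFR, estimated acts, counterfactual share
    (percent, integer), counterfactual acts, counterfactual expected
    deaths.  Numeric rendering is rounded for display only.
    """
    df = result.as_frame()
    df["counterfactual_share"] = (df["counterfactual_share"] * 100).map(lambda v: f"{v:.0f}")
    for col in ("acts", "counterfactual_acts", "counterfactual_deaths"):
        df[col] = df[col].map(lambda v: f"{v:.{decimals}f}")
    df["cfr"] = df["cfr"].map(lambda v: f"{v:g}")
    total = {
        "method": "all_methods_combined",
        "deaths": result.observed_total_deaths,
        "cfr": "",
        "acts": f"{result.total_acts:.{decimals}f}",
        "counterfactual_share": "100",
        "counterfactual_acts": f"{sum(result.counterfactual_acts.values()):.{decimals}f}",
        "counterfactual_deaths": f"{result.counterfactual_total_deaths:.{decimals}f}",
    }
    df = pd.concat([df, pd.DataFrame([total])], ignore_index=True)
    return df.to_string(index=False)


def render_summary(result: CounterfactualResult) -> str:
    s = result.summary()
    lines = [
        f"subjects (N):            {s['n_subjects']}",
        f"estimated total acts:    {s['total_acts']:.1f}",
        f"observed deaths:         {s['observed_deaths']}",
        f"counterfactual deaths:   {s['counterfactual_deaths']:.1f}",
        f"deaths averted:          {s['deaths_averted']:.1f}",
        f"risk difference:         {100 * s['risk_difference']:.1f} percentage points",
        f"NNT:                     {_fmt_nnt(result.nnt, result.deaths_averted)}",
    ]
    return "\n".join(lines)


def result_to_json(result: CounterfactualResult, indent: int | None = 2) -> str:
    """Machine-readable result; numerically identical to the in-memory object."""
    payload = {
        "label": result.scenario.label,
        "summary": result.summary(),
        "per_method": result.as_frame().to_dict(orient="records"),
    }
    return json.dumps(payload, indent=indent, allow_nan=True)
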