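"""Attribution of disease burden to child maltreatment via PAFs.

Age- and gender-specific PAFs are applied multiplicatively to burden-of-
disease envelopes (deaths, YLL, YLD), with attributable DALY computed as
attributable YLL + attributable YLD.  Three cause-specific wrinkles:

* anxiety disorders are a single envelope cause but two modelled outcomes:
  the PTSD PAF applies to the PTSD share of anxiety burden and the GAD PAF
  (proxy for other anxiety disorders) to the remainder;
* the suicide-attempt PAF applies to the whole intentional self-harm
  envelope, fatal and non-fatal components alike;
* smoking is a two-step chain: the maltreatment->smoking PAF applies to
  burden *already attributable to tobacco smoking*, never to a total-burden
  envelope (guarded to prevent double counting).

Burden rows for age groups younger than the surveyed population (under 15)
receive PAF 0.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = [
    "attribute_cause",
    "attribute_anxiety",
    "attribute_self_harm",
    "attribute_smoking",
    "summarise",
    "MEASURES",
]

MEASURES = ("deaths", "yll", "yld")

#: burden age bands below the surveyed range: attributable burden not estimated
_UNDER_SURVEY = {"0–4", "5–9", "10–14", "0-4", "5-9", "10-14"}


def _paf_for(paf_table: pd.DataFrame, outcome: str) -> pd.DataFrame:
    sub = paf_table[paf_table["outcome"] == outcome] if "outcome" in paf_table else paf_table
    if sub.empty:
        raise ValueError(f"no PAF rows for outcome {outcome!r}")
    return sub[["gender", "age_group", "paf"]]


def _merge_paf(burden: pd.DataFrame, paf: pd.DataFrame) -> pd.DataFrame:
    merged = burden.merge(paf, on=["gender", "age_group"], how="left")
    young = merged["age_group"].isin(_UNDER_SURVEY)
    merged.loc[young, "paf"] = merged.loc[young, "paf"].fillna(0.0)
    if merged["paf"].isna().any():
        bad = merged.loc[merged["paf"].isna(), ["gender", "age_group"]].drop_duplicates()
        raise ValueError(f"no PAF for burden strata: {bad.to_dict('records')}")
    return merged


def attribute_cause(
    paf_table: pd.DataFrame, burden_table: pd.DataFrame, cause: str, outcome: str | None = None
) -> pd.DataFrame:
    """Attributable deaths/YLL/YLD/DALY for one cause.

    ``outcome`` selects the PAF rows (defaults to the cause name).  Output has
    one row per gender x age group with attributable measures and the PAF used.
    """
    outcome = outcome or cause
    rows = burden_table[burden_table["cause"] == cause]
    if rows.empty:
        raise ValueError(f"cause {cause!r} not in burden table")
    merged = _merge_paf(rows, _paf_for(paf_table, outcome))
    out = merged[["cause", "gender", "age_group", "paf"]].copy()
    for m in MEASURES:
        out[m] = merged["paf"] * merged[m]
    out["daly"] = out["yll"] + out["yld"]
    return out


def attribute_anxiety(
    paf_ptsd: pd.DataFrame,
    paf_gad: pd.DataFrame,
    anxiety_burden: pd.DataFrame,
    ptsd_share: float | dict[str, float] | pd.DataFrame,
) -> pd.DataFrame:
    """Attributable anxiety burden with PTSD/other-anxiety disaggregation.

    ``ptsd_share`` (the PTSD fraction of total anxiety burden, from an
    external mental-health survey) may be a scalar, a per-gender mapping, or a
    table with columns (gender, age_group, share); each share must lie in
    [0, 1].  Attribution is paf_ptsd*s*B + paf_gad*(1-s)*B per measure.
    """
    merged = _merge_paf(anxiety_burden, _paf_for(paf_ptsd, "ptsd").rename(columns={"paf": "paf"}))
    merged = merged.rename(columns={"paf": "paf_ptsd"})
    merged = merged.merge(
        _paf_for(paf_gad, "gad").rename(columns={"paf": "paf_gad"}),
        on=["gender", "age_group"],
        how="left",
    )
    young = merged["age_group"].isin(_UNDER_SURVEY)
    merged.loc[young, "paf_gad"] = merged.loc[young, "paf_gad"].fillna(0.0)

    if isinstance(ptsd_share, pd.DataFrame):
        merged = merged.merge(ptsd_share, on=["gender", "age_group"], how="left")
        share = merged["share"].to_numpy(float)
    elif isinstance(ptsd_share, dict):
        share = merged["gender"].map(ptsd_share).to_numpy(float)
    else:
        share = np.full(len(merged), float(ptsd_share))
    if np.any(np.isnan(share)) or np.any((share < 0) | (share > 1)):
        raise ValueError("ptsd_share must be within [0, 1] for every stratum")

    eff_paf = merged["paf_ptsd"].to_numpy() * share + merged["paf_gad"].to_numpy() * (1 - share)
    out = merged[["cause", "gender", "age_group"]].copy()
    out["paf"] = eff_paf
    for m in MEASURES:
        out[m] = eff_paf * merged[m]
    out["daly"] = out["yll"] + out["yld"]
    return out


def attribute_self_harm(paf_suicide_attempt: pd.DataFrame, self_harm_burden: pd.DataFrame) -> pd.DataFrame:
    """Suicide-attempt PAF applied to the full intentional self-harm envelope
    (deaths and YLL from suicides, YLD from non-fatal injuries)."""
    cause = self_harm_burden["cause"].iloc[0]
    return attribute_cause(paf_suicide_attempt, self_harm_burden, cause, outcome="suicide_attempt")


def attribute_smoking(paf_smoking: pd.DataFrame, smoking_attributable_burden: pd.DataFrame) -> pd.DataFrame:
    """Maltreatment-attributable share of smoking-attributable burden.

    The input must already be burden attributable to tobacco smoking (flagged
    ``burden_type == "attributable"``); applying this PAF to a total-burden
    envelope would double count.
    """
    if "burden_type" not in smoking_attributable_burden.columns or not (
        smoking_attributable_burden["burden_type"] == "attributable"
    ).all():
        raise ValueError(
            "smoking attribution requires a table flagged burden_type='attributable' "
            "(burden already attributable to tobacco smoking), not a total-burden envelope"
        )
    cause = smoking_attributable_burden["cause"].iloc[0]
    return attribute_cause(paf_smoking, smoking_attributable_burden, cause, outcome="smoking")


def summarise(attributables: list[pd.DataFrame], total_burden: pd.DataFrame) -> dict:
    """Cross-cause summary of attributable burden.

    Returns ``by_cause`` (attributable DALY and % of each cause's burden, per
    gender) and ``totals`` (total attributable DALY, % of all DALYs, % of the
    studied-outcomes burden, per gender).  ``total_burden`` must contain the
    cause envelopes used plus an ``all_causes`` row set per gender.
    """
    if not attributables:
        return {
            "by_cause": pd.DataFrame(
                columns=["cause", "gender", "attributable_daly", "pct_of_cause"]
            ),
            "totals": pd.DataFrame(
                columns=[
                    "gender",
                    "attributable_daly",
                    "pct_of_all_dalys",
                    "pct_of_studied_burden",
                ]
            ),
        }
    att = pd.concat(attributables, ignore_index=True)
    by_cause = (
        att.groupby(["cause", "gender"], sort=False)["daly"].sum().rename("attributable_daly")
    ).reset_index()
    cause_tot = (
        total_burden.groupby(["cause", "gender"], sort=False)["daly"].sum().rename("cause_daly")
    ).reset_index()
    by_cause = by_cause.merge(cause_tot, on=["cause", "gender"], how="left")
    by_cause["pct_of_cause"] = 100.0 * by_cause["attributable_daly"] / by_cause["cause_daly"]

    all_tot = (
        total_burden[total_burden["cause"] == "all_causes"].groupby("gender")["daly"].sum()
    )
    studied = by_cause.groupby("gender")["cause_daly"].sum()
    totals = by_cause.groupby("gender")["attributable_daly"].sum().reset_index()
    if not all_tot.empty:
        totals["pct_of_all_dalys"] = totals.apply(
            lambda r: 100.0 * r["attributable_daly"] / all_tot[r["gender"]], axis=1
        )
    else:
        totals["pct_of_all_dalys"] = np.nan
    totals["pct_of_studied_burden"] = totals.apply(
        lambda r: 100.0 * r["attributable_daly"] / studied[r["gender"]], axis=1
    )
    return {"by_cause": by_cause, "totals": totals}
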