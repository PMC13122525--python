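"""Population attributable fractions for a polytomous maltreatment exposure.

The counterfactual (theoretical minimum risk exposure level, TMREL) is zero
exposure to any maltreatment: all population mass on pattern "00000".  For a
categorical exposure with prevalences p_i and relative risks RR_i (reference
category RR = 1) the PAF is

    PAF = sum_i p_i (RR_i - 1) / (1 + sum_i p_i (RR_i - 1))
        = (sum_i p_i RR_i - 1) / (sum_i p_i RR_i),

the proportional reduction in outcome risk if exposure moved to the TMREL.
The same relative risks apply across all age groups, so age variation in the
PAF is driven entirely by age variation in exposure prevalence.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .patterns import ExposureCoding, pattern_codes

__all__ = ["TMREL", "compute_paf", "paf_table", "aggregate_paf", "rr_by_pattern"]

#: the counterfactual exposure distribution: all mass on "00000"
TMREL = {code: (1.0 if code == "00000" else 0.0) for code in pattern_codes()}

_NORM_TOL = 1e-6


def compute_paf(proportions: np.ndarray, rr: np.ndarray, *, tol: float = _NORM_TOL) -> float:
    """PAF from 32 pattern proportions and 32 pattern-level relative risks.

    The first entry corresponds to the unexposed pattern "00000" and must
    carry RR exactly 1; proportions must sum to 1 (within *tol*).
    """
    p = np.asarray(proportions, dtype=float)
    r = np.asarray(rr, dtype=float)
    if p.shape != r.shape:
        raise ValueError(f"shape mismatch: {p.shape} vs {r.shape}")
    if abs(p.sum() - 1.0) > tol:
        raise ValueError(f"proportions sum to {p.sum():.6g}, not 1")
    if np.any(p < -tol):
        raise ValueError("negative proportion")
    if r[0] != 1.0:
        raise ValueError(f"RR for the unexposed pattern must be 1, got {r[0]}")
    if np.any(r < 0):
        raise ValueError("negative relative risk")
    mean_rr = float(p @ r)
    return (mean_rr - 1.0) / mean_rr


def rr_by_pattern(rrset: pd.DataFrame, outcome: str, gender: str, coding: ExposureCoding) -> np.ndarray:
    """Expand a level-indexed RR table to the 32 patterns via the coding."""
    sub = rrset[(rrset["outcome"] == outcome) & (rrset["gender"] == gender)]
    levels = dict(zip(sub["level"].astype(str), sub["rr"].astype(float)))
    lvl_map = coding.level_map()
    missing = sorted({lvl_map[c] for c in pattern_codes()} - levels.keys())
    if missing:
        raise KeyError(
            f"RR table for outcome={outcome!r} gender={gender!r} lacks levels: {missing}"
        )
    return np.array([levels[lvl_map[c]] for c in pattern_codes()])


def paf_table(
    prevalence: pd.DataFrame, rrset: pd.DataFrame, coding: ExposureCoding
) -> pd.DataFrame:
    """One PAF per outcome x gender x age group.

    *prevalence* is long form (gender, age_group, pattern, proportion) with a
    full 32-pattern distribution per stratum; *rrset* is level-indexed
    (outcome, gender, level, rr, ...).
    """
    codes = pattern_codes()
    outcomes = list(dict.fromkeys(rrset["outcome"]))
    rows = []
    for (gender, age_group), chunk in prevalence.groupby(["gender", "age_group"], sort=False):
        got = set(chunk["pattern"])
        if got != set(codes):
            raise ValueError(
                f"stratum {gender}/{age_group}: expected all 32 patterns, "
                f"missing {sorted(set(codes) - got)[:5]}"
            )
        p = chunk.set_index("pattern").loc[codes, "proportion"].to_numpy(dtype=float)
        for outcome in outcomes:
            rr32 = rr_by_pattern(rrset, outcome, gender, coding)
            rows.append(
                {
                    "outcome": outcome,
                    "gender": gender,
                    "age_group": age_group,
                    "paf": compute_paf(p, rr32),
                }
            )
    return pd.DataFrame(rows)


def aggregate_paf(paf: pd.DataFrame, burden_weights: pd.DataFrame) -> pd.DataFrame:
    """Burden-weighted all-ages PAF per outcome x gender.

    *burden_weights* has columns (gender, age_group, weight) — typically the
    cause-specific DALYs by age — and the aggregate is
    sum_a PAF_a * w_a / sum_a w_a over the age groups present in *paf*.
    """
    merged = paf.merge(burden_weights, on=["gender", "age_group"], how="left")
    if merged["weight"].isna().any():
        bad = merged.loc[merged["weight"].isna(), ["gender", "age_group"]].drop_duplicates()
        raise ValueError(f"no burden weight for strata: {bad.to_dict('records')}")
    rows = []
    for (outcome, gender), chunk in merged.groupby(["outcome", "gender"], sort=False):
        total = chunk["weight"].sum()
        if total <= 0:
            raise ValueError(f"zero total burden weight for {outcome}/{gender}")
        rows.append(
            {
                "outcome": outcome,
                "gender": gender,
                "paf": float((chunk["paf"] * chunk["weight"]).sum() / total),
            }
        )
    return pd.DataFrame(rows)
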