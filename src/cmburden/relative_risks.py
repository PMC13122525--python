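"""Adjusted relative risks of each outcome by maltreatment exposure level.

Risks are modelled with log-binomial regression (binomial GLM, log link), so
exponentiated coefficients are relative risks.  Models are fitted separately
for women and men, pooling all ages, with exposure level entered as a
categorical variable against the no-maltreatment reference (RR = 1) and two
adjustment sets:

* ``simply``  — age (standardised ln age and age^2), childhood financial
  stress, geographical remoteness;
* ``fully``   — simply + other adverse childhood experiences + peer/sibling
  bullying victimisation.

The log link constrains fitted probabilities above 1 only implicitly, so the
MLE can sit on the boundary and Fisher scoring can fail; when that happens the
model is refitted as a Poisson regression with robust (HC1 sandwich) standard
errors — the standard rescue that preserves the RR interpretation — and the
estimate is flagged.  The same relative risks are assumed to apply across all
age groups, so the output carries no age dimension.
"""

from __future__ import annotations

import warnings
from pathlib import Path

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .patterns import ExposureCoding, TYPE_NAMES, pattern_codes

__all__ = [
    "ADJUSTMENT_SETS",
    "OUTCOME_LABELS",
    "fit_log_binomial",
    "rr_trend_check",
    "load_rr_table",
    "validate_rr_table",
]

OUTCOME_LABELS = ("mdd", "gad", "ptsd", "aud", "smoking", "suicide_attempt")

ADJUSTMENT_SETS: dict[str, tuple[str, ...]] = {
    "simply": ("financial_stress", "remoteness"),
    "fully": ("financial_stress", "remoteness", "other_aces", "bullying"),
}

_Z975 = float(stats.norm.ppf(0.975))
_CODE_TO_IDX = {c: i for i, c in enumerate(pattern_codes())}


def _exposure_levels(md: pd.DataFrame, coding: ExposureCoding) -> pd.Series:
    codes = md[list(TYPE_NAMES)].astype(int).astype(str).agg("".join, axis=1)
    lvl_map = coding.level_map()
    return codes.map(lvl_map)


def _age_terms(age: np.ndarray) -> np.ndarray:
    cols = []
    for x in (np.log(age / 10.0), (age / 10.0) ** 2):
        cols.append((x - x.mean()) / x.std())
    return np.column_stack(cols)


def fit_log_binomial(
    microdata: pd.DataFrame,
    outcome: str,
    coding: ExposureCoding,
    adjustment: str = "simply",
    genders: tuple[str, ...] = ("women", "men"),
) -> pd.DataFrame:
    """RRs with Wald 95% CIs per exposure level, per gender.

    Returns a long table (outcome, gender, coding, adjustment, level, rr,
    lcl, ucl, converged, fallback) including the reference level at RR 1.
    """
    if outcome not in microdata.columns:
        raise ValueError(f"outcome column {outcome!r} not in microdata")
    if adjustment not in ADJUSTMENT_SETS:
        raise ValueError(f"adjustment must be one of {sorted(ADJUSTMENT_SETS)}")
    covars = [c for c in ADJUSTMENT_SETS[adjustment] if c in microdata.columns]
    levels_all = coding.levels
    rows = []
    for gender in genders:
        sub = microdata[microdata["gender"] == gender]
        if sub.empty:
            raise ValueError(f"no respondents with gender {gender!r}")
        lvl = _exposure_levels(sub, coding)
        y = sub[outcome].to_numpy(float)
        present = [l for l in levels_all if (lvl == l).any()]
        for l in present[1:]:
            cases = y[(lvl == l).to_numpy()]
            if cases.sum() == 0 or cases.sum() == len(cases):
                raise ValueError(
                    f"quasi-separation: level {l!r} ({outcome}, {gender}) has "
                    f"{'no cases' if cases.sum() == 0 else 'no non-cases'}"
                )
        X = pd.DataFrame({"const": np.ones(len(sub))}, index=sub.index)
        for l in present[1:]:
            X[f"level[{l}]"] = (lvl == l).astype(float)
        age_t = _age_terms(sub["age_years"].to_numpy(float))
        X["ln_age"] = age_t[:, 0]
        X["age_sq"] = age_t[:, 1]
        for c in covars:
            X[c] = sub[c].to_numpy(float)

        params, cov, converged, fallback = _fit_rr_glm(y, X, outcome, gender)
        se = np.sqrt(np.diag(cov))
        rows.append(
            {
                "outcome": outcome,
                "gender": gender,
                "coding": coding.mode,
                "adjustment": adjustment,
                "level": present[0],
                "rr": 1.0,
                "lcl": 1.0,
                "ucl": 1.0,
                "converged": converged,
                "fallback": fallback,
            }
        )
        for l in present[1:]:
            k = list(X.columns).index(f"level[{l}]")
            b, s = params[k], se[k]
            rows.append(
                {
                    "outcome": outcome,
                    "gender": gender,
                    "coding": coding.mode,
                    "adjustment": adjustment,
                    "level": l,
                    "rr": float(np.exp(b)),
                    "lcl": float(np.exp(b - _Z975 * s)),
                    "ucl": float(np.exp(b + _Z975 * s)),
                    "converged": converged,
                    "fallback": fallback,
                }
            )
    return pd.DataFrame(rows)


def _fit_rr_glm(y, X, outcome, gender):
    """Log-binomial fit with Poisson/robust fallback; returns
    (params, cov, converged, fallback)."""
    start = np.zeros(X.shape[1])
    start[0] = np.log(max(y.mean(), 1e-6))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            res = sm.GLM(y, X, family=sm.families.Binomial(link=sm.families.links.Log())).fit(
                start_params=start, maxiter=200, tol=1e-9
            )
            mu_ok = np.all(res.fittedvalues < 1.0)
            if res.converged and mu_ok and np.all(np.isfinite(res.bse)):
                return res.params.to_numpy(), res.cov_params().to_numpy(), True, False
        except Exception:
            pass
        try:
            res = sm.GLM(y, X, family=sm.families.Poisson()).fit(
                start_params=start, maxiter=200, tol=1e-9, cov_type="HC1"
            )
        except Exception as exc:
            raise RuntimeError(
                f"log-binomial and Poisson-robust fits both failed for "
                f"outcome={outcome!r}, gender={gender!r}: {exc}"
            ) from exc
    if not res.converged:
        raise RuntimeError(
            f"no converged RR model for outcome={outcome!r}, gender={gender!r}"
        )
    return res.params.to_numpy(), res.cov_params().to_numpy(), True, True


def rr_trend_check(rrset: pd.DataFrame) -> pd.DataFrame:
    """Dose-response check: is RR non-decreasing in the number of types?

    Applies to count-coded RR sets; non-monotone sequences are flagged (with
    the offending levels) but never rejected.
    """
    sub = rrset[rrset.get("coding", "count_of_types") == "count_of_types"]
    rows = []
    for (outcome, gender), chunk in sub.groupby(["outcome", "gender"], sort=False):
        chunk = chunk.assign(_lvl=chunk["level"].astype(int)).sort_values("_lvl")
        rr = chunk["rr"].to_numpy()
        lvls = chunk["_lvl"].to_numpy()
        drops = [int(lvls[i + 1]) for i in range(len(rr) - 1) if rr[i + 1] < rr[i]]
        rows.append(
            {
                "outcome": outcome,
                "gender": gender,
                "monotone": not drops,
                "violations": drops,
            }
        )
    return pd.DataFrame(rows)


def validate_rr_table(df: pd.DataFrame) -> pd.DataFrame:
    """Validate (and normalise) an externally supplied RR table."""
    required = {"outcome", "gender", "coding", "level", "rr", "lcl", "ucl"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"RR table lacks columns: {sorted(missing)}")
    df = df.copy()
    df["outcome"] = df["outcome"].astype(str).str.lower()
    bad = sorted(set(df["outcome"]) - set(OUTCOME_LABELS))
    if bad:
        raise ValueError(f"unknown outcome labels {bad}; allowed: {list(OUTCOME_LABELS)}")
    df["level"] = df["level"].astype(str)
    for col in ("rr", "lcl", "ucl"):
        df[col] = pd.to_numeric(df[col], errors="raise")
    bad_ci = df[(df["lcl"] > df["rr"]) | (df["rr"] > df["ucl"]) | (df["lcl"] <= 0)]
    if not bad_ci.empty:
        first = bad_ci.iloc[0]
        raise ValueError(
            f"invalid CI (need 0 < lcl <= rr <= ucl) at outcome={first['outcome']}, "
            f"gender={first['gender']}, level={first['level']}: "
            f"rr={first['rr']}, lcl={first['lcl']}, ucl={first['ucl']}"
        )
    # auto-insert the unexposed reference where absent
    add = []
    for (outcome, gender, coding), chunk in df.groupby(["outcome", "gender", "coding"]):
        if "0" not in set(chunk["level"]):
            add.append(
                {
                    "outcome": outcome,
                    "gender": gender,
                    "coding": coding,
                    "level": "0",
                    "rr": 1.0,
                    "lcl": 1.0,
                    "ucl": 1.0,
                }
            )
    if add:
        df = pd.concat([pd.DataFrame(add), df], ignore_index=True)
    ref = df[df["level"] == "0"]
    if not np.allclose(ref["rr"], 1.0):
        raise ValueError("reference level '0' must carry RR = 1")
    return df.reset_index(drop=True)


def load_rr_table(path: str | Path) -> pd.DataFrame:
    """Read a relative-risk CSV (schema outcome,gender,coding,level,rr,lcl,ucl)."""
    return validate_rr_table(pd.read_csv(path, dtype={"level": str}))
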