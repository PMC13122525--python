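"""Weighted prevalence of the 32 maltreatment patterns by gender x age group.

Direct cell proportions at gender x 5-year-age-group x 32-pattern
disaggregation are noisy at survey sample sizes, so the production estimator
is a smoothed log-linear model: a Poisson regression on the 32 x strata table
of weighted cell counts with

* a free intercept per stratum (making each stratum's fitted cells a proper
  multinomial distribution),
* a main effect per maltreatment type, interacted with gender and with a
  second-order fractional-polynomial age basis (default powers (0, 2):
  ln(age) and age^2 of the age-group midpoint, standardised),
* all ten two-way type x type interactions (optionally gender-specific).

This is the classical contingency-table smoother: it borrows strength across
ages through the smooth age trend while leaving the dependence structure of
the five types free at two-way order.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import combinations, combinations_with_replacement

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .agegroups import AGE_MIDPOINTS, age_to_group
from .patterns import TYPE_ABBREV, TYPE_NAMES, pattern_codes

__all__ = [
    "PrevalenceModelSpec",
    "PrevalenceFit",
    "direct_prevalence",
    "fit_joint_prevalence",
    "aggregate_prevalence",
    "FP_POWERS",
]

#: the standard fractional-polynomial power set (0 denotes log)
FP_POWERS = (-2.0, -1.0, -0.5, 0.0, 0.5, 1.0, 2.0, 3.0)

_CODES = pattern_codes()
_XPAT = np.array([[int(c) for c in code] for code in _CODES], dtype=float)
_PAIRS = list(combinations(range(5), 2))


@dataclass(frozen=True)
class PrevalenceModelSpec:
    """Configuration of the log-linear prevalence smoother."""

    fp_powers: tuple[float, float] = (0.0, 2.0)
    select_powers: bool = False  # exhaustive deviance search over FP2 pairs
    gender_by_type: bool = True
    gender_by_pair: bool = True
    saturated: bool = False  # free parameter per pattern (no smoothing across patterns)

    def __post_init__(self) -> None:
        for p in self.fp_powers:
            if p not in FP_POWERS:
                raise ValueError(f"FP power {p} not in the standard set {FP_POWERS}")


@dataclass
class PrevalenceFit:
    """Fitted prevalence table plus model diagnostics."""

    table: pd.DataFrame  # gender, age_group, pattern, proportion, modelled_count, effective_n
    params: pd.Series
    bse: pd.Series
    deviance: float
    fp_powers: tuple[float, float]


def _scaled_weights(md: pd.DataFrame) -> pd.Series:
    """Weights rescaled within stratum to sum to the stratum respondent count,
    so the weight scale cannot distort effective sample sizes."""
    grp = md.groupby(["gender", "_age_group"], observed=True)["survey_weight"]
    return md["survey_weight"] * grp.transform("size") / grp.transform("sum")


def _with_groups(microdata: pd.DataFrame) -> pd.DataFrame:
    md = microdata.copy()
    md["_age_group"] = age_to_group(md["age_years"].to_numpy())
    return md


def _cell_counts(microdata: pd.DataFrame) -> pd.DataFrame:
    """Weighted 32-cell counts per stratum (zero cells included)."""
    md = _with_groups(microdata)
    md["_w"] = _scaled_weights(md)
    md["pattern"] = (
        md[list(TYPE_NAMES)].astype(int).astype(str).agg("".join, axis=1)
    )
    counts = (
        md.groupby(["gender", "_age_group", "pattern"], observed=True)["_w"]
        .sum()
        .rename("count")
    )
    kish = md.groupby(["gender", "_age_group"], observed=True)["survey_weight"].agg(
        lambda w: w.sum() ** 2 / (w**2).sum()
    )
    strata = counts.index.droplevel("pattern").unique()
    full = pd.MultiIndex.from_tuples(
        [(g, a, c) for g, a in strata for c in _CODES],
        names=["gender", "_age_group", "pattern"],
    )
    out = counts.reindex(full, fill_value=0.0).reset_index()
    out = out.rename(columns={"_age_group": "age_group"})
    out["effective_n"] = out.set_index(["gender", "age_group"]).index.map(
        lambda k: kish.loc[k]
    ).astype(float)
    return out


def direct_prevalence(microdata: pd.DataFrame) -> pd.DataFrame:
    """Raw weighted cell proportions per gender x age-group stratum.

    Strata absent from the data are simply absent from the output; zero cells
    within observed strata are retained with proportion 0.
    """
    cells = _cell_counts(microdata)
    totals = cells.groupby(["gender", "age_group"], observed=True)["count"].transform("sum")
    cells["proportion"] = cells["count"] / totals
    return cells[["gender", "age_group", "pattern", "proportion", "count", "effective_n"]]


def _fp_basis(age_mid: np.ndarray, powers: tuple[float, float]) -> np.ndarray:
    """Standardised FP2 basis of the age covariate."""
    a = np.asarray(age_mid, float) / 10.0  # conventional rescaling
    cols = []
    for p in powers:
        x = np.log(a) if p == 0 else a**p
        cols.append((x - x.mean()) / x.std())
    return np.column_stack(cols)


def _design(cells: pd.DataFrame, spec: PrevalenceModelSpec) -> pd.DataFrame:
    """Model matrix for the Poisson log-linear smoother (one row per cell)."""
    strata = cells[["gender", "age_group"]].agg("/".join, axis=1)
    X = pd.get_dummies(strata, prefix="stratum", dtype=float)
    pat_idx = pd.Index(_CODES).get_indexer(cells["pattern"])
    xt = _XPAT[pat_idx]  # (rows, 5)

    if spec.saturated:
        for k, code in enumerate(_CODES[1:], start=1):
            X[f"pat[{code}]"] = (pat_idx == k).astype(float)
        return X

    female = (cells["gender"] == "women").to_numpy(float)
    age_mid = cells["age_group"].map(AGE_MIDPOINTS).to_numpy(float)
    fp = _fp_basis(age_mid, spec.fp_powers)

    for i, ab in enumerate(TYPE_ABBREV):
        X[ab] = xt[:, i]
        if spec.gender_by_type:
            X[f"{ab}:female"] = xt[:, i] * female
        X[f"{ab}:fp1"] = xt[:, i] * fp[:, 0]
        X[f"{ab}:fp2"] = xt[:, i] * fp[:, 1]
    for i, j in _PAIRS:
        name = f"{TYPE_ABBREV[i]}:{TYPE_ABBREV[j]}"
        X[name] = xt[:, i] * xt[:, j]
        if spec.gender_by_pair:
            X[f"{name}:female"] = xt[:, i] * xt[:, j] * female
    return X


def _fit_once(cells: pd.DataFrame, spec: PrevalenceModelSpec) -> tuple:
    X = _design(cells, spec)
    y = cells["count"].to_numpy()
    model = sm.GLM(y, X, family=sm.families.Poisson())
    with warnings.catch_warnings():
        # weighted counts are legitimately non-integer
        warnings.simplefilter("ignore")
        try:
            res = model.fit(maxiter=200, tol=1e-10)
        except Exception as exc:  # pragma: no cover - diagnostic path
            raise RuntimeError(
                f"log-linear prevalence model failed to converge ({exc}); "
                "consider pruning type x type interactions"
            ) from exc
    if not res.converged:
        raise RuntimeError(
            "log-linear prevalence model did not converge; "
            "consider pruning type x type interactions"
        )
    return res, X


def fit_joint_prevalence(
    microdata: pd.DataFrame, spec: PrevalenceModelSpec | None = None
) -> PrevalenceFit:
    """Smoothed pattern prevalence per stratum from survey microdata.

    Returns fitted cell probabilities (each stratum a proper distribution over
    the 32 patterns), modelled counts, and the fitted coefficients with
    standard errors.  When ``spec.select_powers`` is set, all 36 FP2 power
    pairs are fitted and the deviance-minimising pair is kept.
    """
    spec = spec or PrevalenceModelSpec()
    cells = _cell_counts(microdata)
    n_groups = cells.groupby("gender")["age_group"].nunique()
    if (n_groups < 2).any() and not spec.saturated:
        raise ValueError("need at least 2 age groups per gender to smooth by age")

    if spec.select_powers:
        best = None
        for p1, p2 in combinations_with_replacement(FP_POWERS, 2):
            trial = PrevalenceModelSpec(
                fp_powers=(p1, p2),
                gender_by_type=spec.gender_by_type,
                gender_by_pair=spec.gender_by_pair,
            )
            try:
                res, X = _fit_once(cells, trial)
            except RuntimeError:
                continue
            if best is None or res.deviance < best[0].deviance:
                best, powers = (res, X), (p1, p2)
        if best is None:
            raise RuntimeError("no FP power pair converged")
        res, X = best
    else:
        powers = spec.fp_powers
        res, X = _fit_once(cells, spec)

    out = cells.copy()
    out["modelled_count"] = res.fittedvalues
    totals = out.groupby(["gender", "age_group"], observed=True)["modelled_count"].transform("sum")
    out["proportion"] = out["modelled_count"] / totals
    table = out[
        ["gender", "age_group", "pattern", "proportion", "modelled_count", "effective_n"]
    ]
    sums = table.groupby(["gender", "age_group"], observed=True)["proportion"].sum()
    assert np.allclose(sums, 1.0, atol=1e-9), "fitted stratum distributions must sum to 1"
    return PrevalenceFit(
        table=table,
        params=res.params,
        bse=res.bse,
        deviance=float(res.deviance),
        fp_powers=powers,
    )


def aggregate_prevalence(table: pd.DataFrame, by: str) -> pd.DataFrame:
    """Summary proportions per stratum.

    ``by`` is one of:

    * ``any_maltreatment`` — 1 - P("00000");
    * ``multi_type`` — total mass on patterns with two or more types;
    * ``per_type`` — marginal prevalence of each of the five types.
    """
    gcols = ["gender", "age_group"]
    rows = []
    for key, chunk in table.groupby(gcols, observed=True, sort=False):
        p = chunk.set_index("pattern")["proportion"].reindex(_CODES).fillna(0.0).to_numpy()
        rec = dict(zip(gcols, key))
        if by == "any_maltreatment":
            rec["proportion"] = 1.0 - p[0]
        elif by == "multi_type":
            rec["proportion"] = float(p[_XPAT.sum(axis=1) >= 2].sum())
        elif by == "per_type":
            for i, name in enumerate(TYPE_NAMES):
                rec[name] = float(p[_XPAT[:, i] == 1].sum())
        else:
            raise ValueError(f"unknown aggregate {by!r}")
        rows.append(rec)
    return pd.DataFrame(rows)
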