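"""Monte Carlo propagation of sampling uncertainty into PAFs and burden.

Two sources of sampling uncertainty are propagated, mirroring how the inputs
were estimated:

* exposure prevalence — each stratum's 32-pattern distribution is drawn from
  a Dirichlet with concentration alpha_i = p_i * n_eff (the conjugate of the
  multinomial), so draws are proper distributions by construction;
* relative risks — each RR is drawn lognormally around its point estimate,
  with sigma = (ln UCL - ln LCL) / (2 * z_0.975) recovered from the reported
  95% CI (the standard relative-risk random function).

Per iteration the full PAF -> attribution chain is recomputed; one RR draw per
outcome x gender x level is shared across all age groups (the point RRs are
age-constant, so independent per-age draws would understate between-age
correlation).  Uncertainty intervals are the 2.5th/97.5th percentiles (linear
interpolation between closest ranks) of 2,000 iteration values by default.
Burden envelopes are treated as fixed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .patterns import ExposureCoding, pattern_codes

__all__ = [
    "UncertaintySpec",
    "UncertaintyResult",
    "sample_prevalence",
    "sample_rr",
    "run_monte_carlo",
    "DEFAULT_CAUSE_MAP",
]

_Z975 = float(stats.norm.ppf(0.975))
_CODES = pattern_codes()

#: outcome -> burden cause for the straightforward one-step attributions;
#: anxiety (ptsd+gad) is handled separately via the PTSD share
DEFAULT_CAUSE_MAP = {
    "mdd": "mdd",
    "aud": "aud",
    "suicide_attempt": "self_harm",
    "smoking": "smoking_attributable",
}


@dataclass(frozen=True)
class UncertaintySpec:
    iterations: int = 2000
    seed: int = 0
    ci_level: float = 0.95
    keep_draws: bool = False

    def __post_init__(self) -> None:
        if self.iterations < 2:
            raise ValueError("need at least 2 iterations")
        if not 0 < self.ci_level < 1:
            raise ValueError("ci_level must be in (0,1)")

    @property
    def quantiles(self) -> tuple[float, float]:
        a = (1.0 - self.ci_level) / 2.0
        return (a, 1.0 - a)


def _rng(seed) -> np.random.Generator:
    return seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)


def sample_prevalence(proportions, effective_n: float, seed) -> np.ndarray:
    """One Dirichlet draw of a pattern distribution.

    Concentration is proportion x effective sample size; empty cells get a
    0.5 pseudo-count (the Dirichlet needs positive concentration).  An
    infinite effective_n returns the input exactly (degenerate case).
    """
    p = np.asarray(proportions, dtype=float)
    if abs(p.sum() - 1.0) > 1e-6:
        raise ValueError("proportions must sum to 1")
    if not effective_n > 0:
        raise ValueError("effective_n must be positive")
    if np.isinf(effective_n):
        return p.copy()
    alpha = np.where(p > 0, p * effective_n, 0.5)
    return _rng(seed).dirichlet(alpha)


def sample_rr(rr: float, lcl: float, ucl: float, seed, size=None):
    """Lognormal RR draw(s): exp(N(ln rr, sigma)), sigma from the 95% CI.

    A degenerate CI (lcl == ucl == rr) returns the point value.
    """
    if not 0 < lcl <= rr <= ucl:
        raise ValueError(f"need 0 < lcl <= rr <= ucl, got {lcl}, {rr}, {ucl}")
    sigma = (np.log(ucl) - np.log(lcl)) / (2.0 * _Z975)
    if sigma == 0.0:
        return rr if size is None else np.full(size, rr)
    return np.exp(_rng(seed).normal(np.log(rr), sigma, size=size))


@dataclass
class UncertaintyResult:
    """Point estimates with percentile uncertainty intervals."""

    paf: pd.DataFrame  # outcome, gender, age_group, paf, ui_lower, ui_upper
    attributable_daly: pd.DataFrame  # cause, gender, daly, ui_lower, ui_upper
    share_all_dalys: pd.DataFrame  # gender, pct, ui_lower, ui_upper
    n_failed: int = 0
    draws: dict = field(default_factory=dict)


def _prep(prevalence: pd.DataFrame, rrset: pd.DataFrame, coding: ExposureCoding):
    """Dense arrays for the iteration loop."""
    strata = prevalence[["gender", "age_group"]].drop_duplicates().reset_index(drop=True)
    S = len(strata)
    P = np.empty((S, 32))
    n_eff = np.empty(S)
    for s, (g, a) in enumerate(zip(strata["gender"], strata["age_group"])):
        chunk = prevalence[(prevalence["gender"] == g) & (prevalence["age_group"] == a)]
        P[s] = chunk.set_index("pattern").loc[_CODES, "proportion"].to_numpy()
        n_eff[s] = chunk["effective_n"].iloc[0] if "effective_n" in chunk else np.inf
    lvl_map = coding.level_map()
    rr_params = {}  # (outcome, gender) -> (mu[L], sigma[L], idx32[32])
    for (outcome, gender), chunk in rrset.groupby(["outcome", "gender"], sort=False):
        levels = list(chunk["level"].astype(str))
        mu = np.log(chunk["rr"].to_numpy(float))
        with np.errstate(divide="ignore"):
            sigma = (np.log(chunk["ucl"].to_numpy(float)) - np.log(chunk["lcl"].to_numpy(float))) / (
                2.0 * _Z975
            )
        pos = {l: k for k, l in enumerate(levels)}
        missing = sorted({lvl_map[c] for c in _CODES} - pos.keys())
        if missing:
            raise KeyError(f"RR table {outcome}/{gender} lacks levels {missing}")
        idx32 = np.array([pos[lvl_map[c]] for c in _CODES])
        rr_params[(outcome, gender)] = (mu, sigma, idx32)
    return strata, P, n_eff, rr_params


def _burden_vector(burden: pd.DataFrame, cause: str, strata: pd.DataFrame) -> np.ndarray:
    """DALY per stratum for *cause*, 0 where the cause has no row (e.g. the
    under-survey-age bands are simply not PAF strata)."""
    sub = burden[burden["cause"] == cause].set_index(["gender", "age_group"])["daly"]
    return np.array(
        [sub.get((g, a), 0.0) for g, a in zip(strata["gender"], strata["age_group"])]
    )


def run_monte_carlo(
    prevalence: pd.DataFrame,
    rrset: pd.DataFrame,
    coding: ExposureCoding,
    burden: pd.DataFrame,
    ptsd_share: float | dict[str, float],
    spec: UncertaintySpec,
    cause_map: dict[str, str] | None = None,
) -> UncertaintyResult:
    """Full-chain Monte Carlo: draw prevalence and RRs, recompute PAFs and
    attributable burden, summarise with percentile uncertainty intervals.

    Iterations producing non-finite output are dropped with a warning; more
    than 1% failures is a hard error.  Fully reproducible given ``spec.seed``.
    """
    cause_map = DEFAULT_CAUSE_MAP if cause_map is None else cause_map
    rng = np.random.default_rng(spec.seed)
    strata, P, n_eff, rr_params = _prep(prevalence, rrset, coding)
    S, it = len(strata), spec.iterations
    genders = list(dict.fromkeys(strata["gender"]))
    outcomes = list(dict.fromkeys(rrset["outcome"]))

    # prevalence draws (Dirichlet via normalised Gammas, batched)
    alpha = np.where(P > 0, P * np.where(np.isinf(n_eff), 1.0, n_eff)[:, None], 0.5)
    G = rng.gamma(alpha, size=(it, S, 32))
    Pd = G / G.sum(axis=2, keepdims=True)
    degen = np.isinf(n_eff)
    if degen.any():
        Pd[:, degen, :] = P[degen][None, :, :]
    assert np.allclose(Pd.sum(axis=2), 1.0, atol=1e-12)

    # RR draws: one per outcome x gender x level per iteration
    rr32_draws = {}
    rr32_point = {}
    for key, (mu, sigma, idx32) in rr_params.items():
        z = rng.standard_normal((it, len(mu)))
        rr32_draws[key] = np.exp(mu + sigma * z)[:, idx32]
        rr32_point[key] = np.exp(mu)[idx32]

    def chain(Pmat, rr32_of):
        """PAFs, per-cause attributable DALY and %-of-all-DALYs for one set of
        inputs; Pmat is (..., S, 32) and rr32_of maps (outcome,gender)->(...,32)."""
        paf = {}
        for outcome in outcomes:
            arr = np.zeros(Pmat.shape[:-2] + (S,))
            for g in genders:
                mask = (strata["gender"] == g).to_numpy()
                rr32 = rr32_of[(outcome, g)]
                mean_rr = np.einsum("...sk,...k->...s", Pmat[..., mask, :], rr32)
                arr[..., mask] = (mean_rr - 1.0) / mean_rr
            paf[outcome] = arr
        share = {g: (strata["gender"] == g).to_numpy() for g in genders}
        att = {}
        for outcome, cause in cause_map.items():
            if outcome not in outcomes:
                continue
            b = _burden_vector(burden, cause, strata)
            att[cause] = {g: (paf[outcome][..., share[g]] * b[share[g]]).sum(-1) for g in genders}
        if "ptsd" in outcomes and "gad" in outcomes:
            b = _burden_vector(burden, "anxiety_total", strata)
            att["anxiety_total"] = {}
            for g in genders:
                s = ptsd_share[g] if isinstance(ptsd_share, dict) else float(ptsd_share)
                if not 0 <= s <= 1:
                    raise ValueError("ptsd_share must be in [0,1]")
                eff = s * paf["ptsd"][..., share[g]] + (1 - s) * paf["gad"][..., share[g]]
                att["anxiety_total"][g] = (eff * b[share[g]]).sum(-1)
        all_daly = burden[burden["cause"] == "all_causes"].groupby("gender")["daly"].sum()
        pct = {}
        for g in genders:
            total_att = sum(a[g] for a in att.values())
            pct[g] = 100.0 * total_att / all_daly[g] if g in all_daly.index else np.nan
        return paf, att, pct

    paf_d, att_d, pct_d = chain(Pd, rr32_draws)
    paf_pt, att_pt, pct_pt = chain(P, rr32_point)

    # drop non-finite iterations
    ok = np.ones(it, bool)
    for arr in paf_d.values():
        ok &= np.isfinite(arr).all(axis=1)
    for g in genders:
        if np.ndim(pct_d[g]):
            ok &= np.isfinite(pct_d[g])
    n_failed = int((~ok).sum())
    if n_failed > 0.01 * it:
        raise RuntimeError(f"{n_failed}/{it} Monte Carlo iterations non-finite")
    if n_failed:
        import warnings

        warnings.warn(f"excluded {n_failed} non-finite Monte Carlo iterations", stacklevel=2)

    qlo, qhi = spec.quantiles

    def ui(draws):  # draws over axis 0
        lo = np.quantile(draws[ok], qlo, axis=0, method="linear")
        hi = np.quantile(draws[ok], qhi, axis=0, method="linear")
        return lo, hi

    paf_rows = []
    for outcome in outcomes:
        lo, hi = ui(paf_d[outcome])
        for s in range(S):
            paf_rows.append(
                {
                    "outcome": outcome,
                    "gender": strata["gender"][s],
                    "age_group": strata["age_group"][s],
                    "paf": float(paf_pt[outcome][s]),
                    "ui_lower": float(lo[s]),
                    "ui_upper": float(hi[s]),
                }
            )
    att_rows = []
    for cause, per_g in att_d.items():
        for g in genders:
            lo, hi = ui(per_g[g])
            att_rows.append(
                {
                    "cause": cause,
                    "gender": g,
                    "daly": float(att_pt[cause][g]),
                    "ui_lower": float(lo),
                    "ui_upper": float(hi),
                }
            )
    share_rows = []
    for g in genders:
        lo, hi = ui(pct_d[g])
        share_rows.append(
            {"gender": g, "pct": float(pct_pt[g]), "ui_lower": float(lo), "ui_upper": float(hi)}
        )

    draws = {}
    if spec.keep_draws:
        draws = {"paf": paf_d, "attributable_daly": att_d, "share_all_dalys": pct_d, "ok": ok}
    return UncertaintyResult(
        paf=pd.DataFrame(paf_rows),
        attributable_daly=pd.DataFrame(att_rows),
        share_all_dalys=pd.DataFrame(share_rows),
        n_failed=n_failed,
        draws=draws,
    )
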