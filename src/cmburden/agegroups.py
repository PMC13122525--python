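"""Canonical 5-year age-group labels and helpers.

Labels use an en dash ("15–19", "20–24", ..., "80+"); an ASCII
hyphen alias is accepted on input because the two glyphs are routinely
confused when tables travel through spreadsheets.  The youngest band is
labelled "15–19" to align with burden-of-disease age groups even though
survey respondents in it are 16–19 years old.
"""

from __future__ import annotations

import numpy as np

EN_DASH = "–"

#: canonical labels, youngest first
AGE_GROUPS: tuple[str, ...] = tuple(
    [f"15{EN_DASH}19"] + [f"{lo}{EN_DASH}{lo + 4}" for lo in range(20, 80, 5)] + ["80+"]
)

#: midpoints used as the age covariate (82.5 for the open-ended 80+ band)
AGE_MIDPOINTS: dict[str, float] = {
    **{g: (int(g.split(EN_DASH)[0]) + int(g.split(EN_DASH)[1])) / 2 for g in AGE_GROUPS[:-1]},
    "80+": 82.5,
}


def canonical_age_group(label: str) -> str:
    """Normalise an age-group label, accepting the ASCII-hyphen alias."""
    norm = label.strip().replace("-", EN_DASH)
    if norm not in AGE_GROUPS:
        raise ValueError(
            f"unknown age group {label!r}; expected one of {', '.join(AGE_GROUPS)} "
            "(ASCII hyphen accepted)"
        )
    return norm


def age_to_group(age_years) -> np.ndarray:
    """Vectorised mapping from age in years (>=15) to canonical group label."""
    age = np.asarray(age_years)
    if np.any(age < 15):
        raise ValueError("ages below 15 have no maltreatment age group")
    lo = np.clip((age // 5) * 5, 15, 80).astype(int)
    out = np.where(
        lo >= 80, "80+", np.char.add(np.char.add(lo.astype(str), EN_DASH), (lo + 4).astype(str))
    )
    out = np.where(lo == 15, f"15{EN_DASH}19", out)
    return out.astype(object)


def group_ages(group: str, age_min: int = 16, age_max: int = 85) -> np.ndarray:
    """Integer ages that fall in *group*, clipped to the survey age range."""
    g = canonical_age_group(group)
    if g == "80+":
        lo, hi = 80, age_max
    else:
        lo, hi = (int(x) for x in g.split(EN_DASH))
    lo, hi = max(lo, age_min), min(hi, age_max)
    return np.arange(lo, hi + 1)
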