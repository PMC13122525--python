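"""CSV readers/writers with schema validation.

All tables travel as plain CSV.  Output files written by the pipeline carry
``# key: value`` comment headers (seed, config hash, package version) so any
table can be traced back to the exact run that produced it; readers skip
comment lines transparently.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .agegroups import canonical_age_group
from .patterns import pattern_codes
from .relative_risks import validate_rr_table

__all__ = ["read_table", "write_table", "config_hash", "SCHEMAS"]

GENDER_LABELS = ("women", "men")
_CODES = set(pattern_codes())


def _check_gender(df: pd.DataFrame) -> None:
    bad = sorted(set(df["gender"].astype(str)) - set(GENDER_LABELS))
    if bad:
        raise ValueError(
            f"unknown gender labels {bad}: the analysis is restricted to "
            f"{GENDER_LABELS} (respondents of other genders were too few to model)"
        )


def _check_age_groups(df: pd.DataFrame, allow_under15: bool = False) -> pd.DataFrame:
    under15 = {"0-4", "5-9", "10-14", "0–4", "5–9", "10–14"}
    out = []
    for i, label in enumerate(df["age_group"].astype(str)):
        if allow_under15 and label.strip() in under15:
            out.append(label.strip().replace("-", "–"))
            continue
        try:
            out.append(canonical_age_group(label))
        except ValueError as exc:
            raise ValueError(f"row {i}: {exc}") from None
    df = df.copy()
    df["age_group"] = out
    return df


def _require(df: pd.DataFrame, cols: tuple[str, ...], numeric: tuple[str, ...]) -> pd.DataFrame:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise ValueError(f"missing columns: {missing}")
    df = df.copy()
    for c in numeric:
        try:
            df[c] = pd.to_numeric(df[c], errors="raise")
        except (ValueError, TypeError):
            bad = df[pd.to_numeric(df[c], errors="coerce").isna()].index[0]
            raise ValueError(f"non-numeric value in column {c!r} at row {bad}") from None
    return df


def _validate_prevalence(df: pd.DataFrame) -> pd.DataFrame:
    df = _require(df, ("gender", "age_group", "pattern", "proportion"), ("proportion",))
    _check_gender(df)
    df = _check_age_groups(df)
    df["pattern"] = df["pattern"].astype(str).str.zfill(5)
    bad = sorted(set(df["pattern"]) - _CODES)
    if bad:
        raise ValueError(f"invalid pattern codes: {bad[:5]}")
    for (g, a), chunk in df.groupby(["gender", "age_group"]):
        if set(chunk["pattern"]) != _CODES:
            raise ValueError(f"stratum {g}/{a}: needs all 32 patterns exactly once")
        s = chunk["proportion"].sum()
        if abs(s - 1.0) > 1e-6:
            raise ValueError(f"stratum {g}/{a}: proportions sum to {s:.6g}, not 1")
    if "effective_n" in df.columns:
        df["effective_n"] = pd.to_numeric(df["effective_n"], errors="raise")
        if (df["effective_n"] <= 0).any():
            raise ValueError("effective_n must be positive")
    return df


def _validate_burden(df: pd.DataFrame) -> pd.DataFrame:
    df = _require(
        df, ("cause", "gender", "age_group", "deaths", "yll", "yld", "daly"),
        ("deaths", "yll", "yld", "daly"),
    )
    _check_gender(df)
    df = _check_age_groups(df, allow_under15=True)
    if (df[["deaths", "yll", "yld", "daly"]] < 0).any().any():
        raise ValueError("burden measures must be non-negative")
    resid = np.abs(df["daly"] - (df["yll"] + df["yld"]))
    scale = np.maximum(df["daly"].abs(), 1.0)
    if (resid / scale > 1e-6).any():
        i = int((resid / scale).idxmax())
        raise ValueError(f"row {i}: DALY != YLL + YLD")
    return df


def _validate_paf(df: pd.DataFrame) -> pd.DataFrame:
    df = _require(df, ("outcome", "gender", "age_group", "paf"), ("paf",))
    _check_gender(df)
    df = _check_age_groups(df)
    if (df["paf"] >= 1).any():
        raise ValueError("PAF must be < 1")
    return df


_VALIDATORS = {
    "prevalence": _validate_prevalence,
    "rr": validate_rr_table,
    "burden": _validate_burden,
    "paf": _validate_paf,
}

SCHEMAS = tuple(_VALIDATORS)


def read_table(path: str | Path, schema: str) -> pd.DataFrame:
    """Read and validate a CSV against a named schema
    (one of ``prevalence``, ``rr``, ``burden``, ``paf``)."""
    if schema not in _VALIDATORS:
        raise ValueError(f"unknown schema {schema!r}; known: {SCHEMAS}")
    dtype = {"pattern": str, "level": str} if schema in ("prevalence", "rr") else None
    df = pd.read_csv(path, comment="#", dtype=dtype)
    try:
        return _VALIDATORS[schema](df)
    except ValueError as exc:
        raise ValueError(f"{path}: {exc}") from None


def write_table(df: pd.DataFrame, path: str | Path, metadata: dict | None = None) -> None:
    """Write a CSV with optional ``# key: value`` provenance header lines."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        for k, v in (metadata or {}).items():
            fh.write(f"# {k}: {v}\n")
        df.to_csv(fh, index=False)


def config_hash(config: dict) -> str:
    """Stable short hash of a configuration mapping."""
    blob = json.dumps(config, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:16]
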