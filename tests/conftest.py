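import dataclasses

import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from cmburden.patterns import TYPE_NAMES, pattern_codes
from cmburden.synthetic import ConfounderSpec, OutcomeSpec, SimulationConfig, simulate_microdata

settings.register_profile(
    "suite", derandomize=True, max_examples=50, suppress_health_check=[HealthCheck.too_slow]
)
settings.load_profile("suite")


def no_exposure_confounders(base: SimulationConfig = None) -> tuple[ConfounderSpec, ...]:
    """Confounders that affect outcomes but not exposure: the exposure joint
    model is then exactly the two-way log-linear family."""
    base = base or SimulationConfig()
    return tuple(dataclasses.replace(c, log_or_exposure=0.0) for c in base.confounders)


@pytest.fixture(scope="session")
def default_config() -> SimulationConfig:
    return SimulationConfig()


@pytest.fixture(scope="session")
def md20k(default_config) -> pd.DataFrame:
    """Mid-sized default-condition microdata shared across tests."""
    return simulate_microdata(dataclasses.replace(default_config, n_respondents=20000), seed=42)


@pytest.fixture(scope="session")
def flat_config() -> SimulationConfig:
    """Independence config: no pairwise terms, no age trend, no exposure
    effect of confounders — all five types independent Bernoullis."""
    return SimulationConfig(
        n_respondents=50000,
        pairwise_log_odds=(0.0,) * 10,
        age_log_coef=0.0,
        age_sq_coef=0.0,
        confounders=no_exposure_confounders(),
    )


def tiny_microdata(patterns: list[str], gender="women", age=40, weight=1.0) -> pd.DataFrame:
    """Hand-built microdata with given exposure pattern codes."""
    rows = []
    for code in patterns:
        row = {"gender": gender, "age_years": age, "survey_weight": weight}
        row.update({name: int(c) for name, c in zip(TYPE_NAMES, code)})
        rows.append(row)
    return pd.DataFrame(rows)


def uniform_prevalence_row(mass: dict[str, float]) -> np.ndarray:
    """32-vector of pattern proportions from a sparse {code: mass} dict."""
    p = np.zeros(32)
    codes = pattern_codes()
    for code, m in mass.items():
        p[codes.index(code)] = m
    return p
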