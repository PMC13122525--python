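import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from cmburden.paf import aggregate_paf, compute_paf, paf_table, rr_by_pattern
from cmburden.patterns import COUNT_CODING, SIX_PATTERN_CODING, pattern_codes

from conftest import uniform_prevalence_row

CODES = pattern_codes()
NTYPES = np.array([c.count("1") for c in CODES])


def counterfactual_paf(p: np.ndarray, rr: np.ndarray, pop: int = 1_000_000) -> float:
    """Independent oracle: enumerate a finite population, compare its mean
    risk with the all-unexposed counterfactual."""
    counts = np.round(p * pop)
    baseline = 0.001  # cancels in the ratio
    risk_current = float((counts * baseline * rr).sum() / counts.sum())
    risk_tmrel = baseline
    return (risk_current - risk_tmrel) / risk_current


class TestComputePaf:
    def test_null_rr_gives_zero(self):
        p = np.full(32, 1 / 32)
        assert compute_paf(p, np.ones(32)) == 0.0

    def test_half_exposed_rr3_gives_half(self):
        p = uniform_prevalence_row({"00000": 0.5, "10000": 0.5})
        rr = np.ones(32)
        rr[CODES.index("10000")] = 3.0
        assert compute_paf(p, rr) == pytest.approx(0.5)

    def test_two_category_hand_example(self):
        p = uniform_prevalence_row({"00000": 0.8, "10000": 0.1, "11000": 0.1})
        rr = np.ones(32)
        rr[CODES.index("10000")] = 2.0
        rr[CODES.index("11000")] = 4.0
        # sum p(RR-1) = 0.4 -> 0.4/1.4
        assert compute_paf(p, rr) == pytest.approx(0.4 / 1.4)
        assert compute_paf(p, rr) == pytest.approx(counterfactual_paf(p, rr), abs=1e-3)

    def test_unnormalised_rejected(self):
        with pytest.raises(ValueError, match="sum"):
            compute_paf(np.full(32, 0.05), np.ones(32))

    def test_reference_rr_must_be_one(self):
        p = np.full(32, 1 / 32)
        rr = np.ones(32)
        rr[0] = 1.5
        with pytest.raises(ValueError, match="unexposed"):
            compute_paf(p, rr)

    def test_matches_enumerated_population_oracle(self):
        rng = np.random.default_rng(2024)
        for _ in range(200):
            p = rng.dirichlet(np.full(32, 0.5))
            rr = np.exp(rng.normal(0.5, 0.6, size=32))
            rr[0] = 1.0
            assert compute_paf(p, rr) == pytest.approx(
                counterfactual_paf(p, rr), abs=1e-3
            )

    @given(
        st.integers(1, 31),
        st.floats(1.0, 20.0),
        st.floats(0.1, 5.0),
    )
    def test_monotone_in_any_single_rr(self, idx, rr_val, bump):
        rng = np.random.default_rng(7)
        p = rng.dirichlet(np.ones(32))
        rr = np.ones(32) * 2.0
        rr[0] = 1.0
        rr[idx] = rr_val
        low = compute_paf(p, rr)
        rr[idx] = rr_val + bump
        assert compute_paf(p, rr) >= low

    @given(st.floats(0.01, 0.3), st.floats(1.5, 10.0))
    def test_mass_transfer_to_exposed_raises_paf(self, shift, rr_val):
        p = uniform_prevalence_row({"00000": 0.7, "10000": 0.3})
        rr = np.ones(32)
        rr[CODES.index("10000")] = rr_val
        before = compute_paf(p, rr)
        p2 = p.copy()
        p2[0] -= shift
        p2[CODES.index("10000")] += shift
        assert compute_paf(p2, rr) > before

    def test_paf_below_one_even_for_extreme_rr(self):
        p = uniform_prevalence_row({"00000": 0.01, "11111": 0.99})
        rr = np.ones(32)
        rr[CODES.index("11111")] = 1e6
        assert compute_paf(p, rr) < 1.0


class TestPafTable:
    def _prevalence(self, strata: dict) -> pd.DataFrame:
        rows = []
        for (gender, age_group), mass in strata.items():
            p = uniform_prevalence_row(mass)
            for code, prop in zip(CODES, p):
                rows.append(
                    {
                        "gender": gender,
                        "age_group": age_group,
                        "pattern": code,
                        "proportion": prop,
                    }
                )
        return pd.DataFrame(rows)

    def _rrset(self, rrs, outcome="mdd", genders=("women", "men")):
        return pd.DataFrame(
            [
                {
                    "outcome": outcome,
                    "gender": g,
                    "level": str(lvl),
                    "rr": rr,
                    "lcl": rr,
                    "ucl": rr,
                }
                for g in genders
                for lvl, rr in enumerate(rrs)
            ]
        )

    def test_unexposed_stratum_gets_zero_paf(self):
        prev = self._prevalence({("women", "40–44"): {"00000": 1.0}})
        out = paf_table(prev, self._rrset([1, 2, 3, 4, 6, 10]), COUNT_CODING)
        assert out.paf.iloc[0] == 0.0

    def test_more_multitype_mass_gives_higher_paf(self):
        prev = self._prevalence(
            {
                ("women", "20–24"): {"00000": 0.6, "10000": 0.3, "11100": 0.1},
                ("women", "40–44"): {"00000": 0.6, "10000": 0.1, "11100": 0.3},
            }
        )
        out = paf_table(prev, self._rrset([1, 2, 3, 4, 6, 10]), COUNT_CODING).set_index(
            "age_group"
        )
        assert out.loc["40–44", "paf"] > out.loc["20–24", "paf"]

    def test_missing_rr_level_named(self):
        prev = self._prevalence({("women", "40–44"): {"00000": 0.5, "11111": 0.5}})
        rr = self._rrset([1, 2, 3])  # levels 3..5 absent
        with pytest.raises(KeyError, match="5"):
            paf_table(prev, rr, COUNT_CODING)

    def test_collapsing_patterns_to_levels_is_exact(self):
        """Applying level RRs via the coding equals expanding them to all 32
        patterns first."""
        rng = np.random.default_rng(5)
        p = rng.dirichlet(np.ones(32))
        prev = self._prevalence({("women", "40–44"): dict(zip(CODES, p))})
        for coding in (COUNT_CODING, SIX_PATTERN_CODING):
            rrs = {lvl: 1.0 + 2 * i for i, lvl in enumerate(coding.levels)}
            rrs["0"] = 1.0
            rrset = pd.DataFrame(
                [
                    {"outcome": "mdd", "gender": "women", "level": lvl, "rr": rr}
                    for lvl, rr in rrs.items()
                ]
            )
            via_table = paf_table(prev, rrset, coding).paf.iloc[0]
            rr32 = rr_by_pattern(rrset, "mdd", "women", coding)
            direct = compute_paf(p, rr32)
            assert via_table == pytest.approx(direct, abs=1e-12)


class TestAggregatePaf:
    def _paf(self, vals: dict, outcome="mdd", gender="women"):
        return pd.DataFrame(
            [
                {"outcome": outcome, "gender": gender, "age_group": a, "paf": v}
                for a, v in vals.items()
            ]
        )

    def _weights(self, vals: dict, gender="women"):
        return pd.DataFrame(
            [{"gender": gender, "age_group": a, "weight": w} for a, w in vals.items()]
        )

    def test_constant_paf_invariant_to_weights(self):
        paf = self._paf({"20–24": 0.3, "40–44": 0.3})
        out = aggregate_paf(paf, self._weights({"20–24": 1.0, "40–44": 17.0}))
        assert out.paf.iloc[0] == pytest.approx(0.3)

    def test_hand_weighted_example(self):
        paf = self._paf({"20–24": 0.2, "40–44": 0.8})
        out = aggregate_paf(paf, self._weights({"20–24": 1.0, "40–44": 3.0}))
        assert out.paf.iloc[0] == pytest.approx(0.65)

    def test_concentrated_weight_selects_that_age(self):
        paf = self._paf({"20–24": 0.2, "40–44": 0.8})
        out = aggregate_paf(paf, self._weights({"20–24": 0.0, "40–44": 5.0}))
        assert out.paf.iloc[0] == pytest.approx(0.8)

    def test_zero_total_burden_rejected(self):
        paf = self._paf({"20–24": 0.2})
        with pytest.raises(ValueError, match="zero total"):
            aggregate_paf(paf, self._weights({"20–24": 0.0}))

    def test_missing_weight_stratum_rejected(self):
        paf = self._paf({"20–24": 0.2, "40–44": 0.8})
        with pytest.raises(ValueError, match="no burden weight"):
            aggregate_paf(paf, self._weights({"20–24": 1.0}))
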