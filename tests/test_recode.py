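"""Eligibility restriction, outcome derivation rules, and covariate coding."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

import mnhcov as m
from mnhcov.recode import ATTENDANT_VOCAB, RAW_COLUMNS, SKILLED_PROVIDERS, apply_column_mapping


class TestDeriveSba:
    @pytest.mark.parametrize(
        "code,expected",
        [
            ("doctor", 1),
            ("nurse", 1),
            ("aux_midwife", 1),
            ("trad_attendant", 0),
            ("relative", 0),
            ("none", 0),
            ("other", 0),
        ],
    )
    def test_skilled_attendant_definition(self, code, expected):
        assert m.derive_sba(code) == expected

    def test_missing_excluded(self):
        assert m.derive_sba("missing") is None
        assert m.derive_sba(None) is None

    def test_unknown_code_rejected(self):
        with pytest.raises(ValueError):
            m.derive_sba("shaman")

    @given(st.sampled_from(sorted(ATTENDANT_VOCAB)))
    def test_total_on_vocabulary(self, code):
        assert m.derive_sba(code) in (0, 1, None)


class TestDeriveAnc4:
    @pytest.mark.parametrize("visits,expected", [(4, 1), (3, 0), (0, 0), (12, 1)])
    def test_four_plus_visits_threshold(self, visits, expected):
        assert m.derive_anc4(visits) == expected

    def test_missing_and_negative(self):
        assert m.derive_anc4(np.nan) is None
        with pytest.raises(ValueError):
            m.derive_anc4(-1)


class TestDerivePnc48:
    @pytest.mark.parametrize(
        "hours,provider,facility,expected",
        [
            (24.0, "nurse", False, 1),  # professional check within the window
            (72.0, "doctor", True, 0),  # recorded timing overrides facility rule
            (48.0, "doctor", False, 1),  # boundary is inclusive
            (24.0, "relative", True, 0),  # non-professional provider
            (None, None, True, 1),  # facility assumption: both fields missing
            (None, None, False, 0),
            (None, None, None, None),  # nothing to go on
        ],
    )
    def test_definition_table(self, hours, provider, facility, expected):
        assert m.derive_pnc48(hours, provider, facility) == expected

    @given(
        hours=st.one_of(st.none(), st.floats(min_value=0, max_value=120)),
        provider=st.one_of(st.none(), st.sampled_from(sorted(ATTENDANT_VOCAB))),
        facility=st.one_of(st.none(), st.booleans()),
    )
    def test_facility_assumption_requires_both_fields_missing(self, hours, provider, facility):
        result = m.derive_pnc48(hours, provider, facility)
        assert result in (0, 1, None)
        if result == 1:
            professional_within = (
                hours is not None
                and hours <= 48
                and provider in SKILLED_PROVIDERS
            )
            both_missing = hours is None and (provider is None or provider == "missing")
            assert professional_within or (both_missing and facility is True)


def _raw_frame(rows):
    base = {c: [None] * len(rows) for c in RAW_COLUMNS}
    df = pd.DataFrame(base)
    for i, r in enumerate(rows):
        for k, v in r.items():
            df.loc[i, k] = v
    return df


class TestFilterEligible:
    def test_rule_and_order(self):
        rows = [
            {"woman_id": f"w{i}", "years_since_birth": y, "is_most_recent_birth": r}
            for i, (y, r) in enumerate(
                [(3.0, True), (6.0, True), (2.0, False), (5.0, True), (4.9, True),
                 (0.5, False), (1.0, True), (7.0, False), (4.0, True), (5.1, True)]
            )
        ]
        df = _raw_frame(rows)
        kept = m.filter_eligible(df)
        assert list(kept["woman_id"]) == ["w0", "w3", "w4", "w6", "w8"][:5]
        # boundary: exactly 5 years is eligible, 5.1 and 6 are not
        assert "w9" not in set(kept["woman_id"])

    def test_idempotent(self):
        df = _raw_frame(
            [{"woman_id": "a", "years_since_birth": 2.0, "is_most_recent_birth": True},
             {"woman_id": "b", "years_since_birth": 9.0, "is_most_recent_birth": True}]
        )
        once = m.filter_eligible(df)
        twice = m.filter_eligible(once)
        pd.testing.assert_frame_equal(once, twice)


class TestRecodeSurvey:
    def test_appends_nullable_outcome_columns(self):
        df = _raw_frame(
            [
                {"attendant_code": "nurse", "anc_visits": 5, "pnc_hours": 24.0,
                 "pnc_provider": "nurse", "facility_delivery": True},
                {"attendant_code": "missing", "anc_visits": None, "pnc_hours": None,
                 "pnc_provider": None, "facility_delivery": None},
            ]
        )
        out = m.recode_survey(df)
        assert out.loc[0, ["sba", "anc4", "pnc48"]].tolist() == [1, 1, 1]
        assert out.loc[1, ["sba", "anc4", "pnc48"]].isna().all()
        assert str(out["sba"].dtype) == "Int8"


class TestColumnMapping:
    def test_renames_and_validates(self):
        df = _raw_frame([{"woman_id": "w0"}]).rename(columns={"anc_visits": "m14"})
        mapped = apply_column_mapping(df, {"m14": "anc_visits"})
        assert "anc_visits" in mapped.columns
        with pytest.raises(KeyError, match="anc_visits"):
            apply_column_mapping(df, {})


class TestBuildDesign:
    @pytest.fixture
    def records(self):
        rng = np.random.default_rng(0)
        n = 200
        return pd.DataFrame(
            {
                "urban": rng.uniform(size=n) < 0.4,
                "education": rng.choice(["none", "primary", "secondary+"], size=n),
                "wealth_quintile": rng.integers(1, 6, size=n),
                "maternal_age": rng.uniform(15, 49, size=n),
                "parity": 1 + rng.poisson(2, size=n),
            }
        )

    def test_ordinal_coding_six_columns(self, records):
        X, names = m.build_design(records, "ordinal")
        assert names == ["intercept", "urban", "education", "wealth", "age_std", "parity_std"]
        assert X.shape == (len(records), 6)
        assert np.allclose(X[:, 0], 1.0)
        assert set(np.unique(X[:, 3])) <= {0.0, 1.0, 2.0, 3.0, 4.0}
        # standardized columns
        assert abs(X[:, 4].mean()) < 1e-12 and abs(X[:, 4].std() - 1) < 1e-12

    def test_categorical_coding_reference_levels(self, records):
        X, names = m.build_design(records, "categorical")
        assert "wealth_q2" in names and "edu_primary" in names
        assert "wealth_q1" not in names and "edu_none" not in names
        assert np.linalg.matrix_rank(X) == X.shape[1]

    def test_unknown_coding_rejected(self, records):
        with pytest.raises(ValueError, match="coding"):
            m.build_design(records, "helmert")
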