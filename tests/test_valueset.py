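"""EQ-5D-3L state parsing and tariff scoring."""

import csv
import json

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from sf36map import (
    DIMENSIONS,
    EQ5DState,
    LookupValueSet,
    ValueSetTable,
    all_states,
    korea_tariff,
    load_valueset,
    parse_state,
    score_state,
)


class TestParseState:
    @pytest.mark.parametrize("text", ["11111", "33333", "21123", "13231"])
    def test_round_trip(self, text):
        assert str(parse_state(text)) == text

    def test_identity_extremes(self):
        assert parse_state("11111").levels == (1, 1, 1, 1, 1)
        assert parse_state("33333").levels == (3, 3, 3, 3, 3)

    def test_invalid_level_names_position(self):
        with pytest.raises(ValueError, match="position 3"):
            parse_state("11411")

    @pytest.mark.parametrize("text", ["1111", "111111", "", "1111a", "01111"])
    def test_malformed_rejected(self, text):
        with pytest.raises(ValueError):
            parse_state(text)

    def test_state_validates_levels(self):
        with pytest.raises(ValueError, match="self_care"):
            EQ5DState(1, 4, 1, 1, 1)

    def test_all_243_round_trip(self):
        seen = {str(s) for s in all_states()}
        assert len(seen) == 243
        for text in seen:
            assert str(parse_state(text)) == text


class TestKoreanTariff:
    def test_full_health_scores_one(self, korea):
        assert score_state("11111", korea) == 1.0

    def test_worst_state_scores_published_floor(self, korea):
        assert score_state("33333", korea) == pytest.approx(-0.171, abs=1e-12)

    def test_single_decrement_formula(self, korea):
        # one step on mobility: 1 - constant - mobility level-2 decrement
        expected = 1.0 - korea.constant - korea.decrements["MO"][0]
        assert score_state("21111", korea) == pytest.approx(expected, abs=1e-12)

    def test_brute_force_enumeration_oracle(self, korea):
        """Literal summation over decrements must match score_state on all 243 states."""
        for state in all_states():
            levels = dict(zip(DIMENSIONS, state.levels))
            if all(v == 1 for v in levels.values()):
                expected = 1.0
            else:
                expected = 1.0 - korea.constant
                for dim, lev in levels.items():
                    if lev == 2:
                        expected -= korea.decrements[dim][0]
                    if lev == 3:
                        expected -= korea.decrements[dim][1]
                if any(v == 3 for v in levels.values()):
                    expected -= korea.n3
            assert score_state(state, korea) == pytest.approx(expected, abs=1e-12)

    def test_extremes_over_all_states(self, korea):
        utils = {str(s): score_state(s, korea) for s in all_states()}
        assert min(utils.values()) == pytest.approx(-0.171, abs=1e-9)
        assert min(utils, key=utils.get) == "33333"
        assert max(utils.values()) == 1.0
        assert max(utils, key=utils.get) == "11111"

    def test_monotonic_in_every_dimension(self, korea):
        """Worsening any single dimension by one level never raises utility."""
        for state in all_states():
            u = score_state(state, korea)
            for j in range(5):
                if state.levels[j] < 3:
                    worse = list(state.levels)
                    worse[j] += 1
                    assert score_state(EQ5DState(*worse), korea) <= u + 1e-12


@st.composite
def tariffs(draw):
    dec = {
        dim: (draw(st.floats(0, 0.3)), draw(st.floats(0, 0.3)) + draw(st.floats(0, 0.3)))
        for dim in DIMENSIONS
    }
    # level-3 decrement at least the level-2 one keeps the tariff monotone
    dec = {d: (l2, max(l2, l3)) for d, (l2, l3) in dec.items()}
    return ValueSetTable(
        name="synthetic",
        constant=draw(st.floats(0, 0.2)),
        decrements=dec,
        n3=draw(st.floats(0, 0.2)),
    )


class TestTariffProperties:
    @given(tariffs())
    def test_full_health_always_one(self, tariff):
        assert tariff.utility(EQ5DState(1, 1, 1, 1, 1)) == 1.0

    @given(tariffs(), st.integers(0, 242), st.integers(0, 4))
    def test_worsening_never_increases(self, tariff, state_idx, dim_idx):
        state = list(all_states())[state_idx]
        if state.levels[dim_idx] == 3:
            return
        worse = list(state.levels)
        worse[dim_idx] += 1
        assert tariff.utility(EQ5DState(*worse)) <= tariff.utility(state) + 1e-12

    def test_negative_decrement_rejected(self):
        dec = {d: (0.1, 0.2) for d in DIMENSIONS}
        dec["PD"] = (-0.01, 0.2)
        with pytest.raises(ValueError, match="PD"):
            ValueSetTable(name="bad", constant=0.1, decrements=dec, n3=0.0)


class TestLoadValueset:
    def test_default_is_korea(self):
        t = load_valueset()
        assert t.name == "korea"
        assert t.utility(EQ5DState(3, 3, 3, 3, 3)) == pytest.approx(-0.171)

    def test_json_round_trip(self, tmp_path, korea):
        path = tmp_path / "tariff.json"
        path.write_text(
            json.dumps(
                {
                    "name": "korea",
                    "constant": korea.constant,
                    "decrements": {d: list(korea.decrements[d]) for d in DIMENSIONS},
                    "n3": korea.n3,
                }
            )
        )
        loaded = load_valueset(path)
        for s in all_states():
            assert loaded.utility(s) == korea.utility(s)

    def test_missing_n3_field_rejected(self, tmp_path):
        path = tmp_path / "bad.json"
        path.write_text(json.dumps({"name": "x", "constant": 0.1, "decrements": {}}))
        with pytest.raises(ValueError, match="n3"):
            load_valueset(path)

    def test_zero_decrement_tariff_accepted_unless_named_korea(self, tmp_path):
        blob = {
            "name": "flat",
            "constant": 0.0,
            "decrements": {d: [0.0, 0.0] for d in DIMENSIONS},
            "n3": 0.0,
        }
        path = tmp_path / "flat.json"
        path.write_text(json.dumps(blob))
        flat = load_valueset(path)
        assert flat.utility(EQ5DState(3, 3, 3, 3, 3)) == 1.0
        blob["name"] = "korea"
        path.write_text(json.dumps(blob))
        with pytest.raises(ValueError, match="anchor"):
            load_valueset(path)

    def test_csv_lookup_round_trip(self, tmp_path, korea):
        path = tmp_path / "lookup.csv"
        with open(path, "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(["state", "utility"])
            for s in all_states():
                w.writerow([str(s), korea.utility(s)])
        loaded = load_valueset(path)
        assert isinstance(loaded, LookupValueSet)
        for s in all_states():
            assert loaded.utility(s) == pytest.approx(korea.utility(s), abs=1e-12)

    def test_incomplete_lookup_rejected(self, tmp_path):
        path = tmp_path / "short.csv"
        path.write_text("state,utility\n11111,1.0\n")
        with pytest.raises(ValueError, match="243"):
            load_valueset(path)
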