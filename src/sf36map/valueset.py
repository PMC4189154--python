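"""EQ-5D-3L health states and value-set (tariff) scoring.

An EQ-5D-3L health state records a level in {1, 2, 3} for each of five
dimensions — mobility (MO), self-care (SC), usual activities (UA),
pain/discomfort (PD) and anxiety/depression (AD) — written compactly as a
5-digit string such as ``"21123"``. A value set (tariff) converts a state
into a utility on a scale anchored at 1 (full health, state 11111) and 0
(death); states valued worse than death score below 0.

Two tariff representations are supported:

* :class:`ValueSetTable` — the additive "N3" form used by most national TTO
  valuation models: a constant decrement for any departure from full health,
  per-dimension level-2/level-3 decrements, and an extra decrement if any
  dimension is at level 3.
* :class:`LookupValueSet` — a generic fallback holding an explicit utility
  for each of the 243 states, for tariffs that are not additive.

The packaged default is the Korean TTO value set, whose extreme states score
1.0 (11111) and -0.171 (33333).
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass
from importlib import resources
from itertools import product
from pathlib import Path
from typing import Iterator, Mapping, Sequence, Union

import numpy as np

__all__ = [
    "DIMENSIONS",
    "EQ5DState",
    "ValueSetTable",
    "LookupValueSet",
    "parse_state",
    "score_state",
    "load_valueset",
    "korea_tariff",
    "all_states",
]

#: Dimension codes in canonical order.
DIMENSIONS: tuple[str, ...] = ("MO", "SC", "UA", "PD", "AD")

_DIMENSION_NAMES = {
    "MO": "mobility",
    "SC": "self_care",
    "UA": "usual_activities",
    "PD": "pain_discomfort",
    "AD": "anxiety_depression",
}

# Anchors the packaged Korean tariff must reproduce.
_KOREA_BEST = 1.0
_KOREA_WORST = -0.171


@dataclass(frozen=True)
class EQ5DState:
    """One EQ-5D-3L health state: five dimension levels, each in {1, 2, 3}."""

    mobility: int
    self_care: int
    usual_activities: int
    pain_discomfort: int
    anxiety_depression: int

    def __post_init__(self) -> None:
        fields = (
            "mobility", "self_care", "usual_activities", "pain_discomfort", "anxiety_depression",
        )
        for pos, (code, name) in enumerate(zip(DIMENSIONS, fields), start=1):
            level = getattr(self, name)
            ok = (
                not isinstance(level, bool)
                and isinstance(level, (int, np.integer))
                and int(level) in (1, 2, 3)
            )
            if not ok:
                raise ValueError(
                    f"{_DIMENSION_NAMES[code]} (position {pos}) must be an "
                    f"integer level in {{1, 2, 3}}, got {level!r}"
                )
            object.__setattr__(self, name, int(level))

    @property
    def levels(self) -> tuple[int, int, int, int, int]:
        """Levels in canonical (MO, SC, UA, PD, AD) order."""
        return (
            self.mobility,
            self.self_care,
            self.usual_activities,
            self.pain_discomfort,
            self.anxiety_depression,
        )

    @property
    def is_full_health(self) -> bool:
        return self.levels == (1, 1, 1, 1, 1)

    @property
    def has_level3(self) -> bool:
        return 3 in self.levels

    def __str__(self) -> str:
        return "".join(str(v) for v in self.levels)

    @classmethod
    def from_string(cls, text: str) -> "EQ5DState":
        return parse_state(text)


def parse_state(text: str) -> EQ5DState:
    """Parse a 5-digit string such as ``"21123"`` into an :class:`EQ5DState`.

    Raises :class:`ValueError` naming the offending position for a string of
    the wrong length or with a character outside 1–3.
    """
    if not isinstance(text, str):
        raise TypeError(f"state must be a string, got {type(text).__name__}")
    if len(text) != 5:
        raise ValueError(f"state string must have exactly 5 characters, got {len(text)}: {text!r}")
    levels = []
    for pos, ch in enumerate(text, start=1):
        if ch not in "123":
            raise ValueError(
                f"invalid level {ch!r} at position {pos} "
                f"({_DIMENSION_NAMES[DIMENSIONS[pos - 1]]}): must be 1, 2 or 3"
            )
        levels.append(int(ch))
    return EQ5DState(*levels)


def all_states() -> Iterator[EQ5DState]:
    """Iterate over all 3^5 = 243 EQ-5D-3L states in lexicographic order."""
    for levels in product((1, 2, 3), repeat=5):
        yield EQ5DState(*levels)


@dataclass(frozen=True)
class ValueSetTable:
    """Additive (N3-style) EQ-5D-3L tariff.

    utility(s) = 1 - constant·[s ≠ 11111]
                   - Σ_d decrement_d(level_d)   (level-2 or level-3 decrement)
                   - n3·[any dimension at level 3]

    ``decrements`` maps each dimension code to ``(level2, level3)`` decrements.
    All decrements must be non-negative, so full health scores exactly 1 and
    worsening a dimension never increases utility.
    """

    name: str
    constant: float
    decrements: Mapping[str, tuple[float, float]]
    n3: float = 0.0

    def __post_init__(self) -> None:
        missing = [d for d in DIMENSIONS if d not in self.decrements]
        if missing:
            raise ValueError(f"tariff {self.name!r} missing decrements for {missing}")
        if self.constant < 0:
            raise ValueError(f"tariff {self.name!r}: constant must be >= 0, got {self.constant}")
        if self.n3 < 0:
            raise ValueError(f"tariff {self.name!r}: n3 must be >= 0, got {self.n3}")
        for dim in DIMENSIONS:
            pair = self.decrements[dim]
            if len(pair) != 2:
                raise ValueError(f"tariff {self.name!r}: {dim} needs [level2, level3] decrements")
            l2, l3 = pair
            if l2 < 0 or l3 < 0:
                raise ValueError(f"tariff {self.name!r}: negative decrement for {dim}")

    def utility(self, state: EQ5DState) -> float:
        """Score one state; no clipping is applied anywhere."""
        if state.is_full_health:
            return 1.0
        u = 1.0 - self.constant
        for dim, level in zip(DIMENSIONS, state.levels):
            if level == 2:
                u -= self.decrements[dim][0]
            elif level == 3:
                u -= self.decrements[dim][1]
        if state.has_level3:
            u -= self.n3
        return u


@dataclass(frozen=True)
class LookupValueSet:
    """Explicit 243-state lookup tariff (fallback for non-additive value sets)."""

    name: str
    table: Mapping[str, float]

    def __post_init__(self) -> None:
        if len(self.table) != 243:
            raise ValueError(
                f"lookup tariff {self.name!r} must cover all 243 states, got {len(self.table)}"
            )
        for state in all_states():
            if str(state) not in self.table:
                raise ValueError(f"lookup tariff {self.name!r} missing state {state}")
        if self.table["11111"] != 1.0:
            raise ValueError(f"lookup tariff {self.name!r}: state 11111 must score exactly 1.0")

    def utility(self, state: EQ5DState) -> float:
        return float(self.table[str(state)])


ValueSet = Union[ValueSetTable, LookupValueSet]

StateLike = Union[EQ5DState, str, Sequence[int]]


def _as_state(state: StateLike) -> EQ5DState:
    if isinstance(state, EQ5DState):
        return state
    if isinstance(state, str):
        return parse_state(state)
    return EQ5DState(*[int(v) for v in state])


def score_state(state: StateLike, tariff: ValueSet | None = None) -> float:
    """Utility of a state under a tariff (Korean tariff when none given)."""
    if tariff is None:
        tariff = korea_tariff()
    return tariff.utility(_as_state(state))


def _check_korea_anchors(tariff: ValueSet) -> None:
    best = tariff.utility(EQ5DState(1, 1, 1, 1, 1))
    worst = tariff.utility(EQ5DState(3, 3, 3, 3, 3))
    if abs(best - _KOREA_BEST) > 1e-9 or abs(worst - _KOREA_WORST) > 1e-9:
        raise ValueError(
            "tariff declared name 'korea' fails its published anchors: "
            f"expected utility(11111)={_KOREA_BEST} and utility(33333)={_KOREA_WORST}, "
            f"got {best:.6g} and {worst:.6g}"
        )


def _from_json_dict(data: dict) -> ValueSetTable:
    for field in ("name", "constant", "decrements", "n3"):
        if field not in data:
            raise ValueError(f"tariff file missing required field {field!r}")
    decs = {dim: tuple(float(x) for x in pair) for dim, pair in data["decrements"].items()}
    return ValueSetTable(
        name=str(data["name"]),
        constant=float(data["constant"]),
        decrements=decs,
        n3=float(data["n3"]),
    )


def load_valueset(path: str | Path | None = None) -> ValueSet:
    """Load a tariff from a JSON (additive schema) or CSV (243-row lookup) file.

    With no ``path`` the packaged Korean tariff is returned. Any tariff whose
    declared name is ``"korea"`` is checked against the published anchors
    (11111 → 1.0, 33333 → −0.171) and rejected if it fails them.
    """
    if path is None:
        return korea_tariff()
    path = Path(path)
    if path.suffix.lower() == ".csv":
        table: dict[str, float] = {}
        with open(path, newline="") as fh:
            for row in csv.reader(fh):
                if not row or row[0].lower() in ("state", ""):
                    continue
                if len(row) < 2:
                    raise ValueError(f"lookup tariff row needs 'state,utility': {row}")
                table[str(parse_state(row[0].strip()))] = float(row[1])
        tariff: ValueSet = LookupValueSet(name=path.stem, table=table)
    else:
        with open(path) as fh:
            tariff = _from_json_dict(json.load(fh))
    if tariff.name.lower() == "korea":
        _check_korea_anchors(tariff)
    return tariff


def korea_tariff() -> ValueSetTable:
    """The packaged Korean EQ-5D-3L TTO value set (N3 model)."""
    with resources.files("sf36map.data").joinpath("korea_eq5d3l.json").open() as fh:
        tariff = _from_json_dict(json.load(fh))
    _check_korea_anchors(tariff)
    return tariff
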