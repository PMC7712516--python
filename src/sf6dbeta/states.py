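"""SF-6D descriptive system: health states, adjacency, and the dummy design.

The SF-6D classifies health along six dimensions — physical functioning (PF),
role limitations (RL), social functioning (SF), pain (PAIN), mental health
(MH) and vitality (VIT) — with 6, 4, 5, 6, 5 and 5 severity levels
respectively, defining 6*4*5*6*5*5 = 18,000 distinct health states.  A state
is written as a six-digit code, one digit per dimension in the order above:
``111111`` is full health, ``645655`` ("the pits") is the worst state.

Regression models built on this system use one indicator per (dimension,
level>1) pair — 25 dummies in all — so that full health is the reference
category and each coefficient is the utility decrement of one severity level.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

#: Dimension names and level counts, in code-digit order.
DIMENSIONS: tuple[tuple[str, int], ...] = (
    ("PF", 6),
    ("RL", 4),
    ("SF", 5),
    ("PAIN", 6),
    ("MH", 5),
    ("VIT", 5),
)

DIMENSION_NAMES: tuple[str, ...] = tuple(name for name, _ in DIMENSIONS)
N_LEVELS: tuple[int, ...] = tuple(k for _, k in DIMENSIONS)
N_DIMENSIONS: int = len(DIMENSIONS)
N_STATES: int = int(np.prod(N_LEVELS))  # 18,000

#: Design-matrix column names, one per level above 1, dimension-major.
DESIGN_COLUMNS: tuple[str, ...] = tuple(
    f"{name}{level}" for name, k in DIMENSIONS for level in range(2, k + 1)
)
N_DESIGN: int = len(DESIGN_COLUMNS)  # 25

# Offset of each dimension's first dummy within DESIGN_COLUMNS.
_DIM_OFFSETS: tuple[int, ...] = tuple(
    int(np.cumsum([0] + [k - 1 for _, k in DIMENSIONS])[d]) for d in range(N_DIMENSIONS)
)


@dataclass(frozen=True, order=True)
class HealthState:
    """One SF-6D health state, an ordered 6-tuple of severity levels."""

    levels: tuple[int, int, int, int, int, int]

    def __post_init__(self) -> None:
        if len(self.levels) != N_DIMENSIONS:
            raise ValueError(f"expected {N_DIMENSIONS} levels, got {len(self.levels)}")
        for level, (name, k) in zip(self.levels, DIMENSIONS):
            if not isinstance(level, (int, np.integer)) or not 1 <= level <= k:
                raise ValueError(f"{name} level must be in 1..{k}, got {level!r}")

    @property
    def code(self) -> str:
        """Six-digit string representation, e.g. ``'645655'``."""
        return "".join(str(level) for level in self.levels)

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.code


FULL_HEALTH = HealthState((1, 1, 1, 1, 1, 1))
PITS = HealthState((6, 4, 5, 6, 5, 5))


@dataclass(frozen=True)
class AdjacentPair:
    """Two states differing in exactly one dimension by exactly one level."""

    state_a: HealthState
    state_b: HealthState

    def __post_init__(self) -> None:
        diffs = [
            d
            for d in range(N_DIMENSIONS)
            if self.state_a.levels[d] != self.state_b.levels[d]
        ]
        if len(diffs) != 1 or abs(
            self.state_a.levels[diffs[0]] - self.state_b.levels[diffs[0]]
        ) != 1:
            raise ValueError("states must differ in exactly one dimension by one level")

    @property
    def differing_dimension(self) -> int:
        for d in range(N_DIMENSIONS):
            if self.state_a.levels[d] != self.state_b.levels[d]:
                return d
        raise AssertionError("unreachable")  # pragma: no cover

    @property
    def worse(self) -> HealthState:
        """The member with the higher (more severe) level in the differing dimension."""
        d = self.differing_dimension
        return self.state_a if self.state_a.levels[d] > self.state_b.levels[d] else self.state_b

    @property
    def better(self) -> HealthState:
        d = self.differing_dimension
        return self.state_a if self.state_a.levels[d] < self.state_b.levels[d] else self.state_b


def parse_state_code(code: str) -> HealthState:
    """Parse a six-digit state code such as ``'645655'`` or ``'645,655'``.

    Comma and space group separators are stripped; anything else that is not
    exactly six digits, or a digit outside its dimension's level range, is
    rejected.
    """
    if not isinstance(code, str):
        raise TypeError(f"state code must be a string, got {type(code).__name__}")
    cleaned = code.replace(",", "").replace(" ", "")
    if len(cleaned) != N_DIMENSIONS or not cleaned.isdigit():
        raise ValueError(f"state code must be 6 digits, got {code!r}")
    return HealthState(tuple(int(ch) for ch in cleaned))


def enumerate_states() -> list[HealthState]:
    """All 18,000 states in lexicographic order of their level tuples."""
    return [
        HealthState(levels)
        for levels in itertools.product(*(range(1, k + 1) for k in N_LEVELS))
    ]


def design_vector(state: HealthState) -> np.ndarray:
    """25-entry 0/1 indicator vector, one per (dimension, level>1) pair.

    Entry for (d, l) is 1 iff the state sits at level l > 1 of dimension d;
    full health maps to the zero vector.
    """
    x = np.zeros(N_DESIGN, dtype=np.int8)
    for d, level in enumerate(state.levels):
        if level > 1:
            x[_DIM_OFFSETS[d] + level - 2] = 1
    return x


def design_matrix(states: Iterable[HealthState]) -> np.ndarray:
    """Stack of design vectors, one row per state."""
    return np.array([design_vector(s) for s in states], dtype=np.int8)


def neighbors(state: HealthState) -> list[HealthState]:
    """States one severity step away in exactly one dimension.

    Every state has between 6 (all dimensions at a boundary level) and 12
    (all dimensions interior) neighbors.  Order is deterministic: dimension
    by dimension, the level below before the level above.
    """
    out: list[HealthState] = []
    for d, level in enumerate(state.levels):
        for new_level in (level - 1, level + 1):
            if 1 <= new_level <= N_LEVELS[d]:
                levels = list(state.levels)
                levels[d] = new_level
                out.append(HealthState(tuple(levels)))
    return out


def sample_adjacent_pairs(
    n_states: int, rng_seed: int | np.random.Generator
) -> list[AdjacentPair]:
    """Sample ``n_states`` adjacent state pairs for the monotonicity audit.

    First members are drawn without replacement from the full 18,000-state
    space; the second member of each pair is drawn uniformly from the first's
    neighbors.  The same unordered pair can recur via different first members.
    """
    if n_states > N_STATES:
        raise ValueError(f"cannot sample {n_states} states without replacement from {N_STATES}")
    rng = (
        rng_seed
        if isinstance(rng_seed, np.random.Generator)
        else np.random.default_rng(rng_seed)
    )
    space = enumerate_states()
    first_idx = rng.choice(N_STATES, size=n_states, replace=False)
    pairs = []
    for i in first_idx:
        a = space[int(i)]
        nbrs = neighbors(a)
        b = nbrs[int(rng.integers(len(nbrs)))]
        pairs.append(AdjacentPair(a, b))
    return pairs
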