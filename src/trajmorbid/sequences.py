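"""Cumulative-diagnosis state sequences on a fixed age grid.

An individual's psychiatric history is represented as a sequence of
*states*, one per time interval from birth, where the state at interval
``t`` is the cumulative set of diagnosis categories received strictly
before the start of that interval.  With ``C`` categories the state
space is the power set of the category set (``2**C`` states: the empty
"no diagnosis" state, the singletons, and all multi-category
combinations), encoded as bitmasks with bit ``i`` standing for category
``i``.

Sequences are built on an age grid (interval boundaries are birthdays),
so individuals born in different years remain comparable; follow-up
differences appear only as differing observed lengths.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from datetime import date

import numpy as np

__all__ = [
    "DEFAULT_CATEGORIES",
    "DAYS_PER_YEAR",
    "StateAlphabet",
    "StateSequence",
    "build_alphabet",
    "build_sequence",
    "build_sequences",
    "write_sequences",
    "read_sequences",
]

#: Default 8-category alphabet of comorbid ICD-10 chapter groupings.
DEFAULT_CATEGORIES = ("F1", "F3", "F4", "F50", "F60", "F70", "F84", "F9")

DAYS_PER_YEAR = 365.25

EMPTY_LABEL = "NONE"


@dataclass(frozen=True)
class StateAlphabet:
    """Composite-state alphabet over a set of diagnosis categories.

    States are all subsets of ``categories`` encoded as integer bitmasks
    (bit ``i`` set iff category ``i`` is in the set); state ``0`` is the
    empty "no diagnosis" state.
    """

    categories: tuple[str, ...]

    def __post_init__(self) -> None:
        if not (1 <= len(self.categories) <= 16):
            raise ValueError("alphabet supports between 1 and 16 categories")
        if len(set(self.categories)) != len(self.categories):
            raise ValueError("duplicate category labels in alphabet")

    @property
    def n_categories(self) -> int:
        return len(self.categories)

    @property
    def n_states(self) -> int:
        return 1 << len(self.categories)

    @property
    def n_combinations(self) -> int:
        """Number of states containing two or more categories."""
        c = len(self.categories)
        return (1 << c) - c - 1

    def encode(self, labels) -> int:
        """Bitmask of a set of category labels."""
        mask = 0
        for lab in labels:
            try:
                mask |= 1 << self.categories.index(lab)
            except ValueError:
                raise KeyError(f"category {lab!r} not in alphabet") from None
        return mask

    def decode(self, state: int) -> frozenset[str]:
        if not 0 <= state < self.n_states:
            raise KeyError(f"state {state} outside alphabet of size {self.n_states}")
        return frozenset(
            c for i, c in enumerate(self.categories) if state >> i & 1
        )

    def label(self, state: int) -> str:
        """Human-readable label, e.g. ``"F1+F3"``; empty set is ``"NONE"``."""
        cats = [c for i, c in enumerate(self.categories) if state >> i & 1]
        return "+".join(cats) if cats else EMPTY_LABEL

    def parse_label(self, label: str) -> int:
        if label == EMPTY_LABEL:
            return 0
        return self.encode(label.split("+"))


def build_alphabet(categories=DEFAULT_CATEGORIES) -> StateAlphabet:
    """Build the composite-state alphabet for the given categories."""
    return StateAlphabet(tuple(categories))


@dataclass
class StateSequence:
    """One person's observed state sequence on a fixed grid.

    ``states`` holds the observed part only (length ``L_obs``); intervals
    beyond follow-up are represented downstream by imputed probability
    distributions, not by states.
    """

    person_id: str
    states: np.ndarray  # int bitmasks, length L_obs
    increment: float = 1.0  # years per interval
    target_length: int = 36
    birth_year: int | None = None

    @property
    def length_observed(self) -> int:
        return len(self.states)

    def __post_init__(self) -> None:
        self.states = np.asarray(self.states, dtype=np.int64)
        if self.length_observed > self.target_length:
            raise ValueError("observed length exceeds target length")
        d = np.diff(self.states)
        if np.any(self.states[:-1] & ~self.states[1:]):
            raise ValueError("state sequence is not monotone (a diagnosis was lost)")
        del d


def _whole_increments(days: float, increment: float) -> int:
    return int(math.floor(days / (increment * DAYS_PER_YEAR) + 1e-9))


def build_sequence(person, alphabet: StateAlphabet, increment: float = 1.0,
                   target_length: int = 36) -> StateSequence:
    """Build the cumulative-state sequence for one person.

    The state at interval ``t`` (intervals indexed from birth) is the set
    of categories whose first-diagnosis date falls strictly before the
    start of interval ``t``; a diagnosis on an interval boundary counts
    from the next interval.  The observed length is the number of whole
    increments between birth and censoring, capped at ``target_length``.
    """
    birth, censor = person.birth_date, person.censor_date
    n_obs = min(_whole_increments((censor - birth).days, increment), target_length)
    inc_days = increment * DAYS_PER_YEAR
    states = np.zeros(max(n_obs, 0), dtype=np.int64)
    for cat, first in person.events.items():
        if not (birth <= first <= censor):
            raise ValueError(
                f"person {person.person_id}: event {cat} on {first} outside "
                f"[{birth}, {censor}]"
            )
        bit = 1 << alphabet.categories.index(cat)
        # smallest t with t * inc_days > offset (strictly before interval start)
        t_first = int(math.floor((first - birth).days / inc_days + 1e-9)) + 1
        if t_first < n_obs:
            states[t_first:] |= bit
    return StateSequence(person.person_id, states, increment, target_length,
                         birth_year=birth.year)


def build_sequences(persons, alphabet: StateAlphabet, increment: float = 1.0,
                    target_length: int = 36) -> list[StateSequence]:
    return [build_sequence(p, alphabet, increment, target_length) for p in persons]


def write_sequences(sequences, alphabet: StateAlphabet, path) -> None:
    """Export sequences as CSV: ``person_id,L_obs,s_0,s_1,...``."""
    with open(path, "w") as fh:
        fh.write("person_id,L_obs,states\n")
        for s in sequences:
            labels = ",".join(alphabet.label(int(x)) for x in s.states)
            fh.write(f"{s.person_id},{s.length_observed},{labels}\n")


def read_sequences(path, alphabet: StateAlphabet, increment: float = 1.0,
                   target_length: int = 36) -> list[StateSequence]:
    out = []
    with open(path) as fh:
        header = fh.readline()
        if not header.startswith("person_id"):
            raise ValueError("sequence file missing header")
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split(",")
            if len(parts) < 2:
                raise ValueError(f"line {lineno}: malformed sequence row")
            pid, n = parts[0], int(parts[1])
            labels = parts[2:]
            if len(labels) != n:
                raise ValueError(f"line {lineno}: expected {n} states, got {len(labels)}")
            states = np.array([alphabet.parse_label(lab) for lab in labels],
                              dtype=np.int64)
            out.append(StateSequence(pid, states, increment, target_length))
    return out
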