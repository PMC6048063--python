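"""Discrete state space for mycorrhizal partner repertoires.

A plant lineage's character state is its *repertoire*: the set of fungal
partner groups it associates with, possibly empty (non-mycorrhizal).
Repertoires are encoded as bitmasks over a fixed, ordered catalog of fungal
groups; direct transitions are restricted to single gains or losses
(Hamming distance 1), and only repertoires admitted into the state space
may ever be visited — the transition graph never passes through
unobserved intermediates.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Iterable, Sequence

__all__ = [
    "DEFAULT_CATALOG",
    "GroupCatalog",
    "RepertoireState",
    "StateSpace",
    "build_state_space",
    "hamming_distance",
]

#: The four fungal partner groups of land-plant mycorrhiza-like
#: associations, in canonical catalog order.
DEFAULT_CATALOG = ("Ascomycota", "Basidiomycota", "Glomeromycotina", "Mucoromycotina")

#: Label used for the empty (non-mycorrhizal) repertoire.
EMPTY_LABEL = "NM"


@dataclass(frozen=True)
class GroupCatalog:
    """Fixed, ordered catalog of fungal partner groups.

    The catalog order fixes the bit layout of repertoire masks and hence
    the canonical state ordering; it must be held constant within one
    analysis and is recorded in serialized outputs.
    """

    names: tuple[str, ...] = DEFAULT_CATALOG
    _abbrevs: tuple[str, ...] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        if len(set(self.names)) != len(self.names):
            raise ValueError("catalog contains duplicate group names")
        if not self.names:
            raise ValueError("catalog is empty")
        # Single-letter abbreviations when unambiguous, full names otherwise.
        initials = [n[0].upper() for n in self.names]
        abbrevs = tuple(
            initials[i] if initials.count(initials[i]) == 1 else self.names[i]
            for i in range(len(self.names))
        )
        object.__setattr__(self, "_abbrevs", abbrevs)

    def __len__(self) -> int:
        return len(self.names)

    def index(self, name: str) -> int:
        """Position of ``name`` in the catalog; accepts abbreviations."""
        if name in self.names:
            return self.names.index(name)
        if name in self._abbrevs:
            return self._abbrevs.index(name)
        raise KeyError(f"fungal group {name!r} is not in the catalog {self.names}")

    def abbrev(self, index: int) -> str:
        return self._abbrevs[index]


@dataclass(frozen=True)
class RepertoireState:
    """A repertoire of fungal partner groups, encoded as a bitmask.

    Bit ``i`` set means the group at catalog position ``i`` is part of the
    repertoire.  ``mask == 0`` is the non-mycorrhizal state.  Two states
    are equal iff their masks (and catalogs) are equal; the label is a
    pure function of mask and catalog order.
    """

    mask: int
    catalog: GroupCatalog = field(default_factory=GroupCatalog, compare=True)

    def __post_init__(self) -> None:
        if self.mask < 0 or self.mask >= (1 << len(self.catalog)):
            raise ValueError(f"mask {self.mask} out of range for catalog of size {len(self.catalog)}")

    @classmethod
    def from_groups(cls, groups: Iterable[str], catalog: GroupCatalog | None = None) -> "RepertoireState":
        catalog = catalog or GroupCatalog()
        mask = 0
        for g in groups:
            mask |= 1 << catalog.index(g)
        return cls(mask, catalog)

    @classmethod
    def from_label(cls, label: str, catalog: GroupCatalog | None = None) -> "RepertoireState":
        """Parse a canonical label such as ``"G+M"`` or ``"NM"``/``"none"``."""
        catalog = catalog or GroupCatalog()
        label = label.strip()
        if label in (EMPTY_LABEL, "none", ""):
            return cls(0, catalog)
        return cls.from_groups(label.split("+"), catalog)

    @property
    def groups(self) -> tuple[str, ...]:
        return tuple(n for i, n in enumerate(self.catalog.names) if self.mask >> i & 1)

    @property
    def label(self) -> str:
        if self.mask == 0:
            return EMPTY_LABEL
        return "+".join(
            self.catalog.abbrev(i) for i in range(len(self.catalog)) if self.mask >> i & 1
        )

    @property
    def is_empty(self) -> bool:
        return self.mask == 0

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.label


def hamming_distance(a: RepertoireState, b: RepertoireState) -> int:
    """Number of fungal groups present in exactly one of the two repertoires.

    A distance of 1 is a single gain or loss; the transition model forbids
    any direct move with distance > 1 (no simultaneous gains/losses).
    """
    if a.catalog != b.catalog:
        raise ValueError("states belong to different catalogs")
    return (a.mask ^ b.mask).bit_count()


class StateSpace:
    """Admissible repertoire states plus the allowed-transition graph.

    States are held in canonical order (ascending mask value).  ``moves``
    is the set of ordered index pairs ``(i, j)`` that are allowed direct
    transitions; every move is a single gain or loss between two admitted
    states.  The graph need not be connected.
    """

    def __init__(self, states: Sequence[RepertoireState], moves: Iterable[tuple[int, int]] | None = None):
        if not states:
            raise ValueError("no observations: cannot build a state space from zero states")
        catalog = states[0].catalog
        if any(s.catalog != catalog for s in states):
            raise ValueError("states mix catalogs")
        ordered = sorted(set(states), key=lambda s: s.mask)
        self.catalog = catalog
        self.states: tuple[RepertoireState, ...] = tuple(ordered)
        self._index = {s.mask: i for i, s in enumerate(self.states)}
        if moves is None:
            moves = (
                (i, j)
                for i in range(len(self.states))
                for j in range(len(self.states))
                if i != j and hamming_distance(self.states[i], self.states[j]) == 1
            )
        self.moves: frozenset[tuple[int, int]] = frozenset(moves)
        for i, j in self.moves:
            if i == j:
                raise ValueError("self-moves are not allowed")
            if hamming_distance(self.states[i], self.states[j]) != 1:
                raise ValueError(
                    f"move {self.states[i].label}->{self.states[j].label} is not a single gain/loss"
                )

    @property
    def n_states(self) -> int:
        return len(self.states)

    @property
    def labels(self) -> tuple[str, ...]:
        return tuple(s.label for s in self.states)

    def index(self, state: RepertoireState) -> int:
        try:
            return self._index[state.mask]
        except KeyError:
            raise KeyError(f"state {state.label!r} is not in the state space") from None

    def index_of_label(self, label: str) -> int:
        return self.index(RepertoireState.from_label(label, self.catalog))

    def __contains__(self, state: RepertoireState) -> bool:
        return state.mask in self._index

    @property
    def empty_index(self) -> int | None:
        return self._index.get(0)

    def single_gains_from_empty(self) -> list[tuple[int, int]]:
        """Moves from the empty state into a single-group repertoire."""
        e = self.empty_index
        if e is None:
            return []
        return sorted((i, j) for (i, j) in self.moves if i == e)

    def move_labels(self) -> list[tuple[str, str]]:
        return sorted((self.states[i].label, self.states[j].label) for i, j in self.moves)

    def to_json(self) -> str:
        return json.dumps(
            {
                "catalog": list(self.catalog.names),
                "states": list(self.labels),
                "moves": [[self.states[i].label, self.states[j].label] for i, j in sorted(self.moves)],
            },
            indent=2,
        )

    @classmethod
    def from_json(cls, text: str) -> "StateSpace":
        obj = json.loads(text)
        catalog = GroupCatalog(tuple(obj["catalog"]))
        states = [RepertoireState.from_label(lbl, catalog) for lbl in obj["states"]]
        space = cls(states, moves=())
        moves = frozenset(
            (space.index_of_label(a), space.index_of_label(b)) for a, b in obj["moves"]
        )
        return cls(states, moves=moves)

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"StateSpace({'/'.join(self.labels)}, {len(self.moves)} moves)"

    def __eq__(self, other: object) -> bool:
        return (
            isinstance(other, StateSpace)
            and self.catalog == other.catalog
            and self.states == other.states
            and self.moves == other.moves
        )

    def __hash__(self) -> int:
        return hash((self.catalog, self.states, self.moves))


def build_state_space(
    tip_repertoires: Iterable[RepertoireState],
    include_empty: bool = True,
    catalog: GroupCatalog | None = None,
) -> StateSpace:
    """Build the constrained state space from observed tip repertoires.

    The admitted states are the unique observed repertoires, plus the empty
    (non-mycorrhizal) state when ``include_empty`` — the empty state is
    needed whenever the root is to be constrained to no association.
    Moves are all ordered pairs of admitted states at Hamming distance 1;
    unobserved intermediates are never inserted, so the graph may be
    disconnected.
    """
    reps = list(tip_repertoires)
    if not reps:
        raise ValueError("no observations: at least one tip repertoire is required")
    catalog = catalog or reps[0].catalog
    for r in reps:
        if r.catalog != catalog:
            raise ValueError("tip repertoires mix catalogs")
    states = {r.mask: r for r in reps}
    if include_empty:
        states.setdefault(0, RepertoireState(0, catalog))
    return StateSpace(sorted(states.values(), key=lambda s: s.mask))
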