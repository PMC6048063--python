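"""States-through-time summaries.

At each grid age (default every 50 Myr from the present back toward the
root) the branches alive at that instant are collected and the fraction
in each repertoire state computed.  A branch above node ``k`` spans the
half-open age interval ``[age[k], age[parent[k]])``: each node's instant
belongs exactly to its child branches, so lineage counts partition
cleanly and equal the lineages-through-time curve.

Branch states may come from the most-probable-state assignment of an
ancestral reconstruction (one state per branch) or from mapped
histories, which resolve state changes within branches.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .ancestral import BranchStates
from .mapping import MappedHistory
from .phylo_io import Chronogram
from .statespace import StateSpace

__all__ = ["TimeBinSummary", "states_through_time", "lineage_count"]


def _alive(tree: Chronogram, t: float) -> np.ndarray:
    """Indices of nodes whose branch interval [child_age, parent_age)
    contains age ``t``."""
    has_parent = tree.parent >= 0
    parent_age = np.where(has_parent, tree.age[tree.parent], np.nan)
    return np.flatnonzero(has_parent & (tree.age <= t) & (t < parent_age))


def lineage_count(tree: Chronogram, t: float) -> int:
    """Number of branches alive at age ``t`` (the LTT curve)."""
    if t < 0 or t > tree.root_age:
        raise ValueError(f"age {t} outside [0, {tree.root_age}]")
    return len(_alive(tree, t))


@dataclass
class TimeBinSummary:
    """Per-age-grid state proportions among the branches then alive."""

    times: np.ndarray            # ages in Myr, ascending from 0
    proportions: pd.DataFrame    # index times, columns state labels
    branch_counts: np.ndarray
    space: StateSpace

    def to_dataframe(self) -> pd.DataFrame:
        rows = []
        for i, t in enumerate(self.times):
            for lbl in self.proportions.columns:
                rows.append({"time_Myr": t, "state": lbl,
                             "proportion": self.proportions.iloc[i][lbl],
                             "n_branches": self.branch_counts[i]})
        return pd.DataFrame(rows)

    def to_tsv(self, path) -> None:
        self.to_dataframe().to_csv(path, sep="\t", index=False)


def states_through_time(
    tree: Chronogram,
    states: "BranchStates | Sequence[MappedHistory]",
    spacing: float = 50.0,
    times: Sequence[float] | None = None,
) -> TimeBinSummary:
    """Proportion of branches in each state at regularly spaced ages.

    With a single-state-per-branch assignment the branch holds that state
    over its whole interval; with mapped histories the state at the exact
    grid age is read off each history and proportions are averaged across
    histories.  Grid ages at or above the root age are skipped with a
    warning (no branch exists there under the half-open convention).
    """
    if times is None:
        if spacing <= 0:
            raise ValueError("spacing must be > 0")
        times = np.arange(0.0, tree.root_age, spacing)
    times = np.asarray(list(times), dtype=float)
    keep = times < tree.root_age
    if not keep.all():
        warnings.warn(f"{int((~keep).sum())} grid age(s) at or above the root age "
                      f"({tree.root_age:.6g} Myr) skipped")
    times = times[keep]

    if isinstance(states, BranchStates):
        space = states.space
        histories: Sequence[MappedHistory] | None = None
    else:
        histories = list(states)
        if not histories:
            raise ValueError("no mapped histories supplied")
        space = histories[0].space

    S = space.n_states
    props = np.zeros((len(times), S))
    counts = np.zeros(len(times), dtype=int)
    for i, t in enumerate(times):
        alive = _alive(tree, float(t))
        counts[i] = len(alive)
        if len(alive) == 0:
            continue
        if histories is None:
            occ = np.zeros(S)
            for k in alive:
                occ[states.assignment[k]] += 1
            props[i] = occ / len(alive)
        else:
            acc = np.zeros(S)
            for h in histories:
                occ = np.zeros(S)
                for k in alive:
                    occ[h.state_at(int(k), float(t), tree)] += 1
                acc += occ / len(alive)
            props[i] = acc / len(histories)
    df = pd.DataFrame(props, index=pd.Index(times, name="time_Myr"),
                      columns=list(space.labels))
    return TimeBinSummary(times, df, counts, space)
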