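"""Stochastic character mapping: full state histories along branches.

A mapped history is one draw from the joint posterior of states along
every branch conditional on the tip repertoires and a rate model: node
states are sampled from the joint conditional (pruning partials combined
preorder), then each branch is filled in by endpoint-conditioned CTMC
simulation via uniformization — exact for the small state spaces used
here, and automatically honoring structural zeros.  Transition counts
averaged over histories are the quantity behind transition-frequency
summaries of repertoire evolution.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import math

import numpy as np
import pandas as pd

from .ctmc import RateModel, RootPrior, TransitionKernel, build_Q, prune_partials
from .inference import PosteriorTrace
from .phylo_io import Chronogram, TipData
from .statespace import StateSpace

__all__ = [
    "MappedHistory",
    "TransitionSummary",
    "sample_history",
    "sample_histories",
    "transition_summary",
    "node_state_frequencies",
    "sample_endpoint_conditioned_path",
]

Move = tuple[int, int]


@dataclass
class MappedHistory:
    """One realization of states along every branch.

    ``branch_segments[k]`` lists ``(state, duration)`` pieces for the
    branch above node ``k``, ordered from the parent end to the child
    end; durations sum to the branch length.  ``events`` records each
    transition as ``(age, from_state, to_state, child_node)``.
    """

    space: StateSpace
    node_states: np.ndarray  # (n_nodes,) state index at each node
    branch_segments: dict[int, list[tuple[int, float]]]
    events: list[tuple[float, int, int, int]] = field(default_factory=list)

    @property
    def n_transitions(self) -> int:
        return len(self.events)

    def transition_count_matrix(self) -> np.ndarray:
        S = self.space.n_states
        C = np.zeros((S, S))
        for _, a, b, _node in self.events:
            C[a, b] += 1
        return C

    def dwell_times(self) -> np.ndarray:
        """Total time spent in each state across the whole tree."""
        S = self.space.n_states
        d = np.zeros(S)
        for segs in self.branch_segments.values():
            for s, dur in segs:
                d[s] += dur
        return d

    def state_at(self, node: int, age: float, tree: Chronogram) -> int:
        """State on the branch above ``node`` at the given age (Myr)."""
        parent_age = tree.age[tree.parent[node]]
        t = parent_age - age  # elapsed time from the parent end
        acc = 0.0
        segs = self.branch_segments[node]
        for s, dur in segs:
            acc += dur
            if t < acc:
                return s
        return segs[-1][0]


def sample_endpoint_conditioned_path(
    Q: np.ndarray, a: int, b: int, t: float, rng: np.random.Generator,
    P_t: np.ndarray | None = None,
) -> list[tuple[int, float]]:
    """Sample a CTMC path on [0, t] conditional on X(0)=a, X(t)=b.

    Uniformization: with Omega >= max_i |Q_ii| and R = I + Q/Omega, the
    number of (possibly virtual) jumps is drawn from
    ``P(n) ∝ Pois(n; Omega t) R^n[a,b]``, jump states from the bridge
    kernel, jump times as uniform order statistics; self-jumps are then
    discarded.  Returns ``(state, duration)`` segments.
    """
    if t < 0:
        raise ValueError("branch length must be >= 0")
    n_states = Q.shape[0]
    omega = 1.05 * float(np.max(-np.diag(Q)))
    if omega <= 0 or t == 0:
        if a != b:
            raise ValueError("endpoints differ but no transitions are possible")
        return [(a, t)]
    R = np.eye(n_states) + Q / omega
    if P_t is None:
        P_t = TransitionKernel(Q).at(t)
    p_ab = float(P_t[a, b])
    if p_ab <= 0:
        raise ValueError("endpoint pair unreachable under Q")
    # sample number of uniformized jumps; Poisson weights updated iteratively
    powers = [np.eye(n_states)]
    u = rng.random() * p_ab
    lam = omega * t
    log_lam = math.log(lam)
    n = 0
    cum = 0.0
    while True:
        # log-space Poisson pmf is robust for large Omega*t
        pois = math.exp(-lam + n * log_lam - math.lgamma(n + 1))
        cum += pois * float(powers[-1][a, b])
        if u <= cum or n > 100_000:
            break
        powers.append(powers[-1] @ R)
        n += 1
    # bridge: states at the n jump epochs
    states = [a]
    for k in range(1, n + 1):
        prev = states[-1]
        w = R[prev, :] * powers[n - k][:, b]
        w_sum = w.sum()
        states.append(int(rng.choice(n_states, p=w / w_sum)))
    times = np.sort(rng.random(n)) * t
    segments: list[tuple[int, float]] = []
    cur, t0 = a, 0.0
    for s, tk in zip(states[1:], times):
        if s != cur:
            segments.append((cur, tk - t0))
            cur, t0 = s, tk
    segments.append((cur, t - t0))
    return segments


def sample_history(tree: Chronogram, data: TipData, model: RateModel,
                   root: RootPrior | None = None,
                   rng: np.random.Generator | int | None = None) -> MappedHistory:
    """Draw one complete mapped history conditional on the tip data."""
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    root = root or RootPrior()
    space = model.space
    Q = build_Q(model)
    kernel = TransitionKernel(Q)
    tip_partials = data.partial_matrix(tree)
    inside, _, P = prune_partials(tree, tip_partials, kernel)
    pi = root.vector(space, Q)

    node_states = np.full(tree.n_nodes, -1, dtype=int)
    w = pi * inside[tree.root_index]
    tot = w.sum()
    if tot <= 0:
        raise ValueError("data have zero likelihood under this model")
    node_states[tree.root_index] = rng.choice(space.n_states, p=w / tot)
    for p_node in tree.preorder():
        i = node_states[p_node]
        for c in tree.children[p_node]:
            w = P[c][i, :] * inside[c]
            node_states[c] = rng.choice(space.n_states, p=w / w.sum())

    segments: dict[int, list[tuple[int, float]]] = {}
    events: list[tuple[float, int, int, int]] = []
    for c in range(tree.n_nodes):
        p_node = tree.parent[c]
        if p_node < 0:
            continue
        segs = sample_endpoint_conditioned_path(
            Q, int(node_states[p_node]), int(node_states[c]),
            float(tree.branch_length[c]), rng, P_t=P[c])
        segments[c] = segs
        elapsed = 0.0
        for (s_prev, dur), (s_next, _) in zip(segs[:-1], segs[1:]):
            elapsed += dur
            events.append((float(tree.age[p_node]) - elapsed, s_prev, s_next, c))
    return MappedHistory(space, node_states, segments, events)


def sample_histories(tree: Chronogram, data: TipData,
                     models: "RateModel | PosteriorTrace | Sequence[Mapping[Move, float]]",
                     root: RootPrior | None = None,
                     n_histories: int = 100, seed: int | None = 0,
                     histories_per_sample: int = 10) -> list[MappedHistory]:
    """Histories over the rate posterior: for a trace, rate draws are
    thinned and ``histories_per_sample`` maps are drawn per rate draw,
    separating rate uncertainty from mapping noise."""
    rng = np.random.default_rng(seed)
    space = data.space
    if isinstance(models, RateModel):
        return [sample_history(tree, data, models, root, rng) for _ in range(n_histories)]
    if isinstance(models, PosteriorTrace):
        n_draws = max(1, n_histories // histories_per_sample)
        draws = models.thin(n_draws)
    else:
        draws = list(models)
    out: list[MappedHistory] = []
    while len(out) < n_histories:
        for rates in draws:
            full = {mv: float(rates.get(mv, 0.0)) for mv in space.moves}
            model = RateModel(space, full)
            out.append(sample_history(tree, data, model, root, rng))
            if len(out) >= n_histories:
                break
    return out


@dataclass
class TransitionSummary:
    """Mean transition counts per ordered state pair across histories."""

    counts: pd.DataFrame       # mean count per history, states x states
    proportions: pd.DataFrame  # counts / total, NaN when no transitions
    outflow: pd.Series         # per-state share of all transitions leaving it
    n_histories: int
    is_empty: bool

    def to_tsv(self, path) -> None:
        self.counts.to_csv(path, sep="\t", index_label="from")

    def to_chord_csv(self, path) -> None:
        rows = [
            {"source": a, "target": b, "weight": self.counts.loc[a, b]}
            for a in self.counts.index for b in self.counts.columns
            if self.counts.loc[a, b] > 0
        ]
        pd.DataFrame(rows, columns=["source", "target", "weight"]).to_csv(path, index=False)


def transition_summary(histories: Sequence[MappedHistory]) -> TransitionSummary:
    """Posterior-mean transition counts and their normalized proportions."""
    if not histories:
        raise ValueError("at least one mapped history is required")
    space = histories[0].space
    C = np.zeros((space.n_states, space.n_states))
    for h in histories:
        C += h.transition_count_matrix()
    C /= len(histories)
    labels = list(space.labels)
    counts = pd.DataFrame(C, index=labels, columns=labels)
    total = C.sum()
    empty = total == 0
    props = counts / total if not empty else counts * np.nan
    outflow = counts.sum(axis=1) / total if not empty else counts.sum(axis=1) * np.nan
    return TransitionSummary(counts, props, outflow, len(histories), bool(empty))


def node_state_frequencies(histories: Sequence[MappedHistory]) -> np.ndarray:
    """(n_nodes, n_states) frequency of sampled node states — converges to
    the marginal reconstruction as the number of histories grows."""
    if not histories:
        raise ValueError("at least one mapped history is required")
    space = histories[0].space
    n_nodes = len(histories[0].node_states)
    F = np.zeros((n_nodes, space.n_states))
    for h in histories:
        F[np.arange(n_nodes), h.node_states] += 1
    return F / len(histories)


def to_simmap(history: MappedHistory, tree: Chronogram) -> str:
    """Annotated Newick in a simmap-style dialect: each branch carries
    ``{state,duration:...}`` segments listed from the parent end."""
    labels = history.space.labels

    def annot(k: int) -> str:
        inner = ":".join(f"{labels[s]},{d:.10g}" for s, d in history.branch_segments[k])
        return "{" + inner + "}"

    def render(k: int) -> str:
        if not tree.children[k]:
            return f"{(tree.label[k] or '').replace(' ', '_')}:{annot(k)}"
        inner = ",".join(render(c) for c in tree.children[k])
        if k == tree.root_index:
            return f"({inner})"
        return f"({inner}):{annot(k)}"

    return render(tree.root_index) + ";"
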