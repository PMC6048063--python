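"""Continuous-time Markov model of repertoire evolution.

The instantaneous rate matrix Q has one nonnegative rate per allowed
directed move (a single gain or loss of one fungal group, in events per
Myr); all other off-diagonal entries are structural zeros and the
diagonal makes rows sum to zero.  Moves may share a rate through a
rate-class partition (the reversible-jump state), and individual moves
may be pinned to zero as structural constraints for hypothesis tests.

The likelihood of tip repertoires on a chronogram is computed by
Felsenstein's pruning algorithm with per-node rescaling, so trees with
hundreds of tips do not underflow.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping

import numpy as np
import scipy.linalg

from .phylo_io import Chronogram, TipData
from .statespace import RepertoireState, StateSpace

__all__ = [
    "RateModel",
    "RootPrior",
    "build_Q",
    "transition_probabilities",
    "TransitionKernel",
    "log_likelihood",
    "prune_partials",
    "TreeLikelihood",
]

Move = tuple[int, int]


@dataclass
class RateModel:
    """A structured Q matrix: one rate per allowed move.

    ``rates`` maps each allowed directed move (pair of state indices) to a
    nonnegative rate in events/Myr.  ``rate_classes`` optionally maps each
    free move to an integer class id; moves in one class share a rate
    value (they are kept consistent by the samplers, not enforced here).
    ``structural_zeros`` are moves whose rate is fixed at exactly 0 and
    which belong to no free class.
    """

    space: StateSpace
    rates: dict[Move, float]
    rate_classes: dict[Move, int] | None = None
    structural_zeros: frozenset[Move] = frozenset()

    def __post_init__(self) -> None:
        self.structural_zeros = frozenset(self.structural_zeros)
        missing = self.space.moves - set(self.rates)
        if missing:
            raise ValueError(f"rates missing for moves {sorted(missing)}")
        extra = set(self.rates) - self.space.moves
        if extra:
            raise ValueError(f"rates given for disallowed moves {sorted(extra)}")
        bad = self.structural_zeros - self.space.moves
        if bad:
            raise ValueError(f"structural zeros on disallowed moves {sorted(bad)}")
        for mv, r in self.rates.items():
            if not np.isfinite(r) or r < 0:
                raise ValueError(f"rate for move {mv} must be finite and >= 0, got {r}")
        for mv in self.structural_zeros:
            if self.rates[mv] != 0.0:
                raise ValueError(f"structural-zero move {mv} has nonzero rate {self.rates[mv]}")
        if self.rate_classes is not None:
            overlap = set(self.rate_classes) & self.structural_zeros
            if overlap:
                raise ValueError(f"structural-zero moves cannot be in free classes: {sorted(overlap)}")

    @property
    def free_moves(self) -> tuple[Move, ...]:
        return tuple(sorted(self.space.moves - self.structural_zeros))

    @classmethod
    def uniform(cls, space: StateSpace, rate: float = 0.01,
                structural_zeros: Iterable[Move] = ()) -> "RateModel":
        """All allowed moves at one shared rate (default 1 event / 100 Myr)."""
        zeros = frozenset(structural_zeros)
        rates = {mv: (0.0 if mv in zeros else rate) for mv in space.moves}
        return cls(space, rates, structural_zeros=zeros)

    def with_rates(self, rates: Mapping[Move, float]) -> "RateModel":
        new = dict(self.rates)
        new.update(rates)
        return replace(self, rates=new)

    def with_structural_zero(self, move: Move) -> "RateModel":
        if move not in self.space.moves:
            raise ValueError(f"{move} is not an allowed move")
        rates = dict(self.rates)
        rates[move] = 0.0
        classes = None if self.rate_classes is None else {
            mv: c for mv, c in self.rate_classes.items() if mv != move
        }
        return RateModel(self.space, rates, rate_classes=classes,
                         structural_zeros=self.structural_zeros | {move})

    def to_json(self) -> str:
        lbl = self.space.labels
        return json.dumps(
            {
                "space": json.loads(self.space.to_json()),
                "rates": [[lbl[i], lbl[j], r] for (i, j), r in sorted(self.rates.items())],
                "rate_classes": None if self.rate_classes is None else [
                    [lbl[i], lbl[j], c] for (i, j), c in sorted(self.rate_classes.items())
                ],
                "structural_zeros": [[lbl[i], lbl[j]] for i, j in sorted(self.structural_zeros)],
            },
            indent=2,
        )

    @classmethod
    def from_json(cls, text: str) -> "RateModel":
        obj = json.loads(text)
        space = StateSpace.from_json(json.dumps(obj["space"]))
        ix = space.index_of_label
        rates = {(ix(a), ix(b)): float(r) for a, b, r in obj["rates"]}
        classes = None if obj["rate_classes"] is None else {
            (ix(a), ix(b)): int(c) for a, b, c in obj["rate_classes"]
        }
        zeros = frozenset((ix(a), ix(b)) for a, b in obj["structural_zeros"])
        return cls(space, rates, rate_classes=classes, structural_zeros=zeros)


@dataclass(frozen=True)
class RootPrior:
    """Prior over the root state: uniform, stationary, or a fixed state.

    The fixed-state form implements the root constraint of the first-gain
    hypothesis tests (mass 1 on the non-mycorrhizal state); ``stationary``
    uses the stationary distribution of Q when one exists.
    """

    kind: str = "uniform"
    fixed_state: RepertoireState | None = None

    def __post_init__(self) -> None:
        if self.kind not in ("uniform", "stationary", "fixed"):
            raise ValueError(f"unknown root prior kind {self.kind!r}")
        if (self.kind == "fixed") != (self.fixed_state is not None):
            raise ValueError("fixed-state prior requires (exactly) a fixed_state")

    @classmethod
    def fixed(cls, state: RepertoireState) -> "RootPrior":
        return cls("fixed", state)

    def vector(self, space: StateSpace, Q: np.ndarray | None = None) -> np.ndarray:
        n = space.n_states
        if self.kind == "uniform":
            return np.full(n, 1.0 / n)
        if self.kind == "fixed":
            pi = np.zeros(n)
            pi[space.index(self.fixed_state)] = 1.0
            return pi
        if Q is None:
            raise ValueError("stationary root prior needs the Q matrix")
        # left null vector of Q, normalized; least-squares for robustness
        a = np.vstack([Q.T, np.ones(n)])
        b = np.zeros(n + 1)
        b[-1] = 1.0
        pi, *_ = np.linalg.lstsq(a, b, rcond=None)
        pi = np.clip(pi, 0.0, None)
        s = pi.sum()
        if s <= 0:
            raise ValueError("Q has no normalizable stationary distribution")
        return pi / s


def build_Q(model: RateModel) -> np.ndarray:
    """Assemble the dense Q matrix: rates on moves, zeros elsewhere,
    diagonal set so every row sums to 0."""
    n = model.space.n_states
    Q = np.zeros((n, n))
    for (i, j), r in model.rates.items():
        Q[i, j] = r
    np.fill_diagonal(Q, 0.0)
    np.fill_diagonal(Q, -Q.sum(axis=1))
    return Q


def transition_probabilities(Q: np.ndarray, t: float) -> np.ndarray:
    """P(t) = exp(Qt); row-stochastic for any valid Q and t >= 0."""
    if t < 0:
        raise ValueError(f"time must be >= 0, got {t}")
    P = scipy.linalg.expm(Q * t)
    np.clip(P, 0.0, 1.0, out=P)
    return P


class TransitionKernel:
    """Evaluates P(t) = exp(Qt) for many t against one Q.

    Uses an eigendecomposition fast path when Q is safely diagonalizable
    (the usual case for these small, sparse repertoire matrices) and falls
    back to scaling-and-squaring ``expm`` per branch length otherwise.
    Exactness at dimension <= ~12 matters more than speed here.
    """

    def __init__(self, Q: np.ndarray):
        self.Q = np.asarray(Q, dtype=float)
        self.n = Q.shape[0]
        self._eig = None
        try:
            w, V = np.linalg.eig(self.Q)
            Vinv = np.linalg.inv(V)
            cond = np.linalg.cond(V)
            # verify reconstruction; reject ill-conditioned eigenbases
            if cond < 1e8 and np.allclose((V * w) @ Vinv, self.Q, atol=1e-10):
                self._eig = (w, V, Vinv)
        except np.linalg.LinAlgError:
            pass

    def at(self, t: float) -> np.ndarray:
        return self.at_many(np.array([t]))[0]

    def at_many(self, ts: np.ndarray) -> np.ndarray:
        """Stack of P(t) for each t, shape (len(ts), n, n)."""
        ts = np.asarray(ts, dtype=float)
        if np.any(ts < 0):
            raise ValueError("times must be >= 0")
        if self._eig is not None:
            w, V, Vinv = self._eig
            ew = np.exp(np.multiply.outer(ts, w))  # (m, n)
            P = np.einsum("ij,tj,jk->tik", V, ew, Vinv)
            P = np.real_if_close(P, tol=1e6).real
        else:
            P = np.stack([scipy.linalg.expm(self.Q * t) for t in ts])
        np.clip(P, 0.0, 1.0, out=P)
        return P


def prune_partials(tree: Chronogram, tip_partials: np.ndarray,
                   kernel: TransitionKernel) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Postorder pass of the pruning algorithm with per-node rescaling.

    Returns ``(partials, log_scale, P)`` where ``partials[k]`` is the
    rescaled conditional likelihood of the data below node ``k`` given the
    state at ``k``, ``log_scale[k]`` the accumulated log rescaling factor
    for the subtree at ``k``, and ``P[k]`` the transition matrix along the
    branch above ``k``.
    """
    n_nodes, n_states = tip_partials.shape
    P = kernel.at_many(tree.branch_length)
    partials = np.array(tip_partials, dtype=float, copy=True)
    log_scale = np.zeros(n_nodes)
    for k in tree.postorder():
        kids = tree.children[k]
        if not kids:
            continue
        vec = partials[k]  # ones unless an internal node carries data
        ls = 0.0
        for c in kids:
            vec = vec * (P[c] @ partials[c])
            ls += log_scale[c]
        m = vec.max()
        if m > 0:
            vec = vec / m
            ls += np.log(m)
        partials[k] = vec
        log_scale[k] = ls
    return partials, log_scale, P


def log_likelihood(tree: Chronogram, data: TipData, model: RateModel,
                   root: RootPrior | None = None) -> float:
    """Log-likelihood of tip repertoires under the CTMC by pruning.

    Returns ``-inf`` when the data are impossible under the model's
    structural constraints (e.g. the root is fixed to a state from which
    an observed tip state is unreachable).
    """
    if data.space is not model.space and data.space != model.space:
        raise ValueError("tip data and rate model use different state spaces")
    root = root or RootPrior()
    Q = build_Q(model)
    kernel = TransitionKernel(Q)
    tip_partials = data.partial_matrix(tree)
    return _log_likelihood_given(tree, tip_partials, kernel,
                                 root.vector(model.space, Q))


def _log_likelihood_given(tree: Chronogram, tip_partials: np.ndarray,
                          kernel: TransitionKernel, pi: np.ndarray) -> float:
    partials, log_scale, _ = prune_partials(tree, tip_partials, kernel)
    r = tree.root_index
    lik = float(pi @ partials[r])
    if lik <= 0:
        return -np.inf
    return np.log(lik) + log_scale[r]


class TreeLikelihood:
    """Repeated pruning likelihood evaluations against one tree and dataset.

    Nodes are scheduled by height (distance to the farthest descendant
    leaf) so each level's partials are computed in one vectorized sweep —
    the per-evaluation cost that matters inside MCMC.  When every tip is
    uncertain the likelihood is identically 1 and evaluation short-circuits.
    """

    def __init__(self, tree: Chronogram, data: TipData, root: RootPrior | None = None):
        self.tree = tree
        self.space = data.space
        self.root = root or RootPrior()
        data.validate_against(tree)
        self.tip_partials = data.partial_matrix(tree)
        self.constant = bool((self.tip_partials == 1.0).all())
        n = tree.n_nodes
        height = np.zeros(n, dtype=int)
        for k in tree.postorder():
            if tree.children[k]:
                height[k] = 1 + max(height[c] for c in tree.children[k])
        self._levels = []
        for h in range(1, height.max() + 1):
            nodes_h = np.flatnonzero(height == h)
            nodes_h = nodes_h[~tree.is_tip[nodes_h]]
            kids = [tree.children[k] for k in nodes_h]
            concat = np.concatenate(kids)
            offsets = np.cumsum([0] + [len(c) for c in kids[:-1]])
            self._levels.append((nodes_h, concat, offsets))
        self._pi_static = None
        if self.root.kind != "stationary":
            self._pi_static = self.root.vector(self.space)

    def log_likelihood_Q(self, Q: np.ndarray) -> float:
        if self.constant:
            return 0.0
        tree = self.tree
        kernel = TransitionKernel(Q)
        P = kernel.at_many(tree.branch_length)
        partials = self.tip_partials.copy()
        log_scale = np.zeros(tree.n_nodes)
        M = np.empty_like(partials)
        tips = tree.tip_indices
        M[tips] = np.einsum("nij,nj->ni", P[tips], partials[tips])
        for nodes_h, concat, offsets in self._levels:
            prod = np.multiply.reduceat(M[concat], offsets, axis=0)
            prod *= partials[nodes_h]
            mx = prod.max(axis=1)
            safe = np.where(mx > 0, mx, 1.0)
            partials[nodes_h] = prod / safe[:, None]
            log_scale[nodes_h] = (np.add.reduceat(log_scale[concat], offsets)
                                  + np.where(mx > 0, np.log(safe), -np.inf))
            M[nodes_h] = np.einsum("nij,nj->ni", P[nodes_h], partials[nodes_h])
        r = tree.root_index
        pi = self._pi_static if self._pi_static is not None else self.root.vector(self.space, Q)
        lik = float(pi @ partials[r])
        if lik <= 0 or not np.isfinite(log_scale[r]):
            return -np.inf
        return np.log(lik) + log_scale[r]

    def log_likelihood(self, model: RateModel) -> float:
        if model.space != self.space:
            raise ValueError("rate model uses a different state space")
        return self.log_likelihood_Q(build_Q(model))
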