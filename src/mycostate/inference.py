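"""Bayesian sampling of transition rates, with reversible-jump moves.

The sampler targets the posterior over (a) a partition of the free moves
into rate classes, where one distinguished — possibly empty — *zero bin*
holds moves whose rate is pinned at 0, and (b) one rate per nonzero
class, with i.i.d. exponential priors.  The partition prior is uniform
over all such configurations, which by the Bell-number identity is the
same as a uniform set partition of the moves plus one auxiliary element
marking the zero bin.

Move set:

- multiplicative log-scale update of one class rate (plain MH),
- reallocation of a single move to another class / the zero bin / a
  fresh singleton class,
- merge of two classes and its reverse split,
- sending a whole class to the zero bin and reviving a subset from it.

Newly born class rates are drawn from the prior, so all proposal
densities cancel against the prior and the acceptance ratios reduce to
likelihood ratios times counting factors (Jacobian 1 throughout).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .ctmc import RateModel, RootPrior, TreeLikelihood
from .phylo_io import Chronogram, TipData
from .statespace import StateSpace

__all__ = [
    "McmcConfig",
    "PosteriorTrace",
    "TraceSummary",
    "run_mcmc",
    "summarize_trace",
    "sample_prior_configuration",
]

Move = tuple[int, int]

# fixed selection probabilities; merge/split and send/revive are chosen
# with equal probability so the type factors cancel in the MH ratio
_P_RATE = 0.55
_P_REALLOC = 0.15
_P_STRUCT = 0.075  # each of merge, split, send, revive


@dataclass
class McmcConfig:
    """Sampler settings.

    ``rate_prior_mean`` is the mean of the exponential prior on each class
    rate, in events/Myr (default one event per 100 Myr).  Production runs
    mirror triplicate chains of 10^6 generations; tests use far shorter
    chains.  One generation is one proposed update.
    """

    n_generations: int = 1_000_000
    n_chains: int = 3
    sample_every: int = 100
    burnin_fraction: float = 0.25
    seed: int = 0
    rate_prior_mean: float = 0.01
    rj_enabled: bool = True
    proposal_scale: float = 2.5

    def __post_init__(self) -> None:
        if self.n_generations < self.sample_every:
            raise ValueError("n_generations must be >= sample_every")
        if not 0 <= self.burnin_fraction < 1:
            raise ValueError("burnin_fraction must be in [0, 1)")
        if self.rate_prior_mean <= 0:
            raise ValueError("rate_prior_mean must be > 0")


@dataclass
class ChainSamples:
    generation: np.ndarray
    log_likelihood: np.ndarray
    log_prior: np.ndarray
    rates: np.ndarray    # (n_samples, n_free_moves) realized per-move rates
    classes: np.ndarray  # (n_samples, n_free_moves) class ids, 0 = zero bin


@dataclass
class PosteriorTrace:
    """Posterior samples from one or more chains over the free moves."""

    space: StateSpace
    free_moves: tuple[Move, ...]
    chains: list[ChainSamples]
    acceptance: dict[str, tuple[int, int]]  # move type -> (accepted, proposed)
    config: McmcConfig

    @property
    def move_labels(self) -> list[str]:
        lbl = self.space.labels
        return [f"{lbl[i]}->{lbl[j]}" for i, j in self.free_moves]

    @property
    def n_samples(self) -> int:
        return sum(len(c.generation) for c in self.chains)

    def rates_matrix(self) -> np.ndarray:
        """All retained samples pooled across chains, (n_samples, n_moves)."""
        return np.concatenate([c.rates for c in self.chains], axis=0)

    def classes_matrix(self) -> np.ndarray:
        return np.concatenate([c.classes for c in self.chains], axis=0)

    def to_dataframe(self) -> pd.DataFrame:
        frames = []
        for ci, c in enumerate(self.chains):
            df = pd.DataFrame(c.rates, columns=[f"rate:{l}" for l in self.move_labels])
            for k, lbl in enumerate(self.move_labels):
                df[f"class:{lbl}"] = c.classes[:, k]
            df.insert(0, "chain", ci)
            df.insert(1, "generation", c.generation)
            df.insert(2, "logL", c.log_likelihood)
            df.insert(3, "logPrior", c.log_prior)
            frames.append(df)
        return pd.concat(frames, ignore_index=True)

    def to_tsv(self, path) -> None:
        self.to_dataframe().to_csv(path, sep="\t", index=False)

    def acceptance_rates(self) -> dict[str, float]:
        return {k: (a / p if p else float("nan")) for k, (a, p) in self.acceptance.items()}

    def thin(self, n: int, rng: np.random.Generator | None = None) -> list[dict[Move, float]]:
        """Up to ``n`` per-move rate dictionaries, evenly spaced through the
        pooled samples (used to integrate downstream analyses over the
        rate posterior)."""
        rates = self.rates_matrix()
        idx = np.unique(np.linspace(0, len(rates) - 1, num=min(n, len(rates)), dtype=int))
        if rng is not None:
            idx = rng.choice(len(rates), size=min(n, len(rates)), replace=False)
        return [dict(zip(self.free_moves, rates[i])) for i in idx]


@dataclass
class TraceSummary:
    per_move: pd.DataFrame
    co_membership: pd.DataFrame


def _log_expon(r: np.ndarray | float, mean: float) -> float:
    return float(np.sum(-np.asarray(r) / mean - math.log(mean)))


class _ChainState:
    """Mutable RJ chain state: assignment vector + class rates."""

    def __init__(self, assignment: np.ndarray, class_rates: dict[int, float]):
        self.assignment = assignment  # len m, 0 = zero bin, >0 class id
        self.class_rates = class_rates
        self.next_id = max(class_rates, default=0) + 1

    def copy(self) -> "_ChainState":
        st = _ChainState(self.assignment.copy(), dict(self.class_rates))
        st.next_id = self.next_id
        return st

    def move_rates(self) -> np.ndarray:
        return np.array([self.class_rates.get(c, 0.0) for c in self.assignment])

    def class_ids(self) -> list[int]:
        return sorted(self.class_rates)

    def members(self, cid: int) -> np.ndarray:
        return np.flatnonzero(self.assignment == cid)

    def log_prior_rates(self, mean: float) -> float:
        return _log_expon(np.array(list(self.class_rates.values())), mean)

    def canonical_classes(self) -> np.ndarray:
        """Relabel class ids by first appearance (0 stays the zero bin)."""
        out = np.zeros_like(self.assignment)
        seen: dict[int, int] = {}
        for k, c in enumerate(self.assignment):
            if c == 0:
                continue
            if c not in seen:
                seen[c] = len(seen) + 1
            out[k] = seen[c]
        return out


def _build_Q_from_state(space: StateSpace, free_moves: Sequence[Move],
                        rates: np.ndarray) -> np.ndarray:
    n = space.n_states
    Q = np.zeros((n, n))
    for (i, j), r in zip(free_moves, rates):
        Q[i, j] = r
    np.fill_diagonal(Q, -Q.sum(axis=1))
    return Q


def _realloc_options(state: _ChainState, e: int) -> list[object]:
    """Target blocks for reallocating move ``e``: existing class ids, 0 for
    the zero bin, or "new" for a fresh singleton class (excluded when the
    result would be the current configuration)."""
    cur = state.assignment[e]
    others = [c for c in state.class_ids() if c != cur]
    if cur == 0:
        return others + ["new"]
    if len(state.members(cur)) > 1:
        return [0] + others + ["new"]
    return [0] + others  # singleton: "new" would reproduce the same partition


def _run_chain(
    loglik: Callable[[np.ndarray], float],
    space: StateSpace,
    free_moves: tuple[Move, ...],
    state: _ChainState,
    rng: np.random.Generator,
    n_generations: int,
    sample_every: int,
    burnin: int,
    prior_mean: float,
    proposal_scale: float,
    rj: bool,
    beta: float = 1.0,
    acceptance: dict[str, list[int]] | None = None,
) -> tuple[ChainSamples, _ChainState]:
    """Run one MH/RJ chain targeting prior x likelihood^beta; mutates ``state``."""
    m = len(free_moves)
    cur_rates = state.move_rates()
    cur_ll = loglik(cur_rates)
    if not np.isfinite(cur_ll) and beta > 0:
        raise ValueError("initial state has zero likelihood; check constraints")
    acc = acceptance if acceptance is not None else {}
    for key in ("rate", "realloc", "merge", "split", "send", "revive"):
        acc.setdefault(key, [0, 0])

    kept_gen, kept_ll, kept_lp, kept_rates, kept_classes = [], [], [], [], []

    def try_accept(kind: str, prop: _ChainState, log_factor: float) -> None:
        nonlocal state, cur_rates, cur_ll
        acc[kind][1] += 1
        new_rates = prop.move_rates()
        new_ll = loglik(new_rates)
        if beta > 0 and not np.isfinite(new_ll):
            return
        ll_term = beta * (new_ll - cur_ll) if beta > 0 else 0.0
        logr = ll_term + log_factor
        if logr >= 0 or rng.random() < math.exp(logr):
            acc[kind][0] += 1
            state = prop
            cur_rates = new_rates
            cur_ll = new_ll

    for gen in range(1, n_generations + 1):
        u = rng.random()
        K = len(state.class_rates)
        zero_bin = state.members(0)
        if (not rj) or u < _P_RATE:
            # multiplicative rate update of one class
            if K > 0:
                cid = state.class_ids()[rng.integers(K)]
                r = state.class_rates[cid]
                r_new = r * math.exp(proposal_scale * (rng.random() - 0.5))
                prop = state.copy()
                prop.class_rates[cid] = r_new
                # exponential prior ratio + Hastings factor of the
                # multiplicative proposal
                log_factor = -(r_new - r) / prior_mean + math.log(r_new / r)
                try_accept("rate", prop, log_factor)
        elif u < _P_RATE + _P_REALLOC:
            e = int(rng.integers(m))
            options = _realloc_options(state, e)
            if options:
                target = options[rng.integers(len(options))]
                prop = state.copy()
                cur_block = prop.assignment[e]
                if target == "new":
                    cid = prop.next_id
                    prop.next_id += 1
                    prop.class_rates[cid] = rng.exponential(prior_mean)
                    prop.assignment[e] = cid
                else:
                    prop.assignment[e] = target
                if cur_block != 0 and len(prop.members(cur_block)) == 0:
                    del prop.class_rates[cur_block]
                n_rev = len(_realloc_options(prop, e))
                try_accept("realloc", prop, math.log(len(options) / n_rev))
        elif u < _P_RATE + _P_REALLOC + _P_STRUCT:
            if K >= 2:  # merge two classes (reverse: split)
                ids = state.class_ids()
                a, b = rng.choice(len(ids), size=2, replace=False)
                ca, cb = ids[a], ids[b]
                prop = state.copy()
                prop.assignment[prop.assignment == cb] = ca
                del prop.class_rates[cb]
                size = len(prop.members(ca))
                m_split = sum(1 for c in prop.class_ids() if len(prop.members(c)) >= 2)
                log_factor = math.log(K * (K - 1)) - math.log(m_split * (2.0 ** size - 2))
                try_accept("merge", prop, log_factor)
        elif u < _P_RATE + _P_REALLOC + 2 * _P_STRUCT:
            splittable = [c for c in state.class_ids() if len(state.members(c)) >= 2]
            if splittable:  # split one class (reverse: merge)
                cid = splittable[rng.integers(len(splittable))]
                members = state.members(cid)
                size = len(members)
                while True:  # nonempty proper subset via uniform bits
                    bits = rng.random(size) < 0.5
                    if 0 < bits.sum() < size:
                        break
                prop = state.copy()
                new_id = prop.next_id
                prop.next_id += 1
                prop.class_rates[new_id] = rng.exponential(prior_mean)
                prop.assignment[members[bits]] = new_id
                Kp = K + 1
                log_factor = (math.log(len(splittable) * (2.0 ** size - 2))
                              - math.log(Kp * (Kp - 1)))
                try_accept("split", prop, log_factor)
        elif u < _P_RATE + _P_REALLOC + 3 * _P_STRUCT:
            if K >= 1:  # send a whole class to the zero bin (reverse: revive)
                ids = state.class_ids()
                cid = ids[rng.integers(K)]
                prop = state.copy()
                prop.assignment[prop.assignment == cid] = 0
                del prop.class_rates[cid]
                z_new = len(prop.members(0))
                log_factor = math.log(K) - math.log(2.0 ** z_new - 1)
                try_accept("send", prop, log_factor)
        else:
            z = len(zero_bin)
            if z >= 1:  # revive a subset of the zero bin as a new class
                while True:
                    bits = rng.random(z) < 0.5
                    if bits.sum() > 0:
                        break
                prop = state.copy()
                new_id = prop.next_id
                prop.next_id += 1
                prop.class_rates[new_id] = rng.exponential(prior_mean)
                prop.assignment[zero_bin[bits]] = new_id
                log_factor = math.log(2.0 ** z - 1) - math.log(K + 1)
                try_accept("revive", prop, log_factor)

        if gen > burnin and (gen - burnin) % sample_every == 0:
            kept_gen.append(gen)
            kept_ll.append(cur_ll)
            kept_lp.append(state.log_prior_rates(prior_mean))
            kept_rates.append(state.move_rates())
            kept_classes.append(state.canonical_classes())

    samples = ChainSamples(
        generation=np.array(kept_gen, dtype=int),
        log_likelihood=np.array(kept_ll),
        log_prior=np.array(kept_lp),
        rates=np.array(kept_rates) if kept_rates else np.zeros((0, m)),
        classes=np.array(kept_classes, dtype=int) if kept_classes else np.zeros((0, m), dtype=int),
    )
    return samples, state


def _initial_state(model0: RateModel, free_moves: tuple[Move, ...],
                   rng: np.random.Generator, prior_mean: float) -> _ChainState:
    if model0.rate_classes is not None:
        ids = sorted(set(model0.rate_classes.values()))
        remap = {c: k + 1 for k, c in enumerate(ids)}
        assignment = np.array([remap[model0.rate_classes[mv]] for mv in free_moves])
    else:
        assignment = np.arange(1, len(free_moves) + 1)
    class_rates = {int(c): float(rng.exponential(prior_mean))
                   for c in np.unique(assignment) if c != 0}
    return _ChainState(assignment, class_rates)


def run_mcmc(tree: Chronogram, data: TipData, model0: RateModel,
             root: RootPrior | None = None, cfg: McmcConfig | None = None) -> PosteriorTrace:
    """Sample the rate posterior by MH, with reversible jump when enabled.

    Chains are run sequentially with independent streams derived from
    ``cfg.seed``; burn-in is discarded before thinning, so each chain
    retains ``floor((n_generations - burnin) / sample_every)`` samples.
    """
    cfg = cfg or McmcConfig()
    root = root or RootPrior()
    free_moves = model0.free_moves
    if not free_moves:
        raise ValueError("nothing to sample: the model has zero free parameters")
    tl = TreeLikelihood(tree, data, root)

    def loglik(rates: np.ndarray) -> float:
        return tl.log_likelihood_Q(_build_Q_from_state(model0.space, free_moves, rates))

    burnin = int(round(cfg.burnin_fraction * cfg.n_generations))
    acceptance: dict[str, list[int]] = {}
    chains = []
    for ci in range(cfg.n_chains):
        rng = np.random.default_rng([cfg.seed, ci])
        state = _initial_state(model0, free_moves, rng, cfg.rate_prior_mean)
        samples, _ = _run_chain(
            loglik, model0.space, free_moves, state, rng,
            n_generations=cfg.n_generations, sample_every=cfg.sample_every,
            burnin=burnin, prior_mean=cfg.rate_prior_mean,
            proposal_scale=cfg.proposal_scale, rj=cfg.rj_enabled,
            acceptance=acceptance,
        )
        chains.append(samples)
    return PosteriorTrace(
        space=model0.space, free_moves=free_moves, chains=chains,
        acceptance={k: (v[0], v[1]) for k, v in acceptance.items()}, config=cfg,
    )


def _ess_1d(x: np.ndarray) -> float:
    if np.ptp(x) == 0:
        return float(len(x))
    import arviz
    return float(arviz.ess(np.asarray(x)[None, :]))


def _rhat(chains: list[np.ndarray]) -> float:
    if len(chains) < 2 or any(np.ptp(c) == 0 for c in chains):
        return float("nan")
    import arviz
    n = min(len(c) for c in chains)
    return float(arviz.rhat(np.stack([c[:n] for c in chains])))


def summarize_trace(trace: PosteriorTrace) -> TraceSummary:
    """Posterior summary per move: mean/sd rate, probability of the zero
    bin, ESS and (multi-chain) R-hat; plus the class co-membership matrix."""
    if trace.n_samples == 0:
        raise ValueError("empty trace")
    rates = trace.rates_matrix()
    classes = trace.classes_matrix()
    labels = trace.move_labels
    rows = []
    for k, lbl in enumerate(labels):
        per_chain = [c.rates[:, k] for c in trace.chains if len(c.rates)]
        rows.append({
            "move": lbl,
            "mean_rate": rates[:, k].mean(),
            "sd_rate": rates[:, k].std(ddof=1) if len(rates) > 1 else 0.0,
            "p_zero": float(np.mean(classes[:, k] == 0)),
            "ess": _ess_1d(rates[:, k]),
            "rhat": _rhat(per_chain),
        })
    per_move = pd.DataFrame(rows).set_index("move")
    m = len(labels)
    co = np.zeros((m, m))
    for a in range(m):
        for b in range(m):
            co[a, b] = np.mean((classes[:, a] == classes[:, b]) & (classes[:, a] != 0))
        co[a, a] = np.mean(classes[:, a] != 0)
    co_df = pd.DataFrame(co, index=labels, columns=labels)
    return TraceSummary(per_move=per_move, co_membership=co_df)


def _bell_numbers(n: int) -> list[float]:
    # Bell triangle in floats; n <= ~60 here so precision is ample for sampling
    bell = [1.0]
    row = [1.0]
    for _ in range(n):
        new = [row[-1]]
        for v in row:
            new.append(new[-1] + v)
        bell.append(new[0])
        row = new
    return bell


def _uniform_set_partition(items: list[int], rng: np.random.Generator) -> list[list[int]]:
    """Uniformly random set partition via the Bell-number recursion."""
    bell = _bell_numbers(len(items))
    blocks: list[list[int]] = []
    rest = list(items)
    while rest:
        n = len(rest)
        first, pool = rest[0], rest[1:]
        # size k of the block containing `first`: P(k) ∝ C(n-1, k-1) * B(n-k)
        weights = np.array([math.comb(n - 1, k - 1) * bell[n - k] for k in range(1, n + 1)])
        k = 1 + int(rng.choice(n, p=weights / weights.sum()))
        chosen = list(rng.choice(len(pool), size=k - 1, replace=False)) if k > 1 else []
        block = [first] + [pool[i] for i in chosen]
        blocks.append(block)
        rest = [x for i, x in enumerate(pool) if i not in set(chosen)]
    return blocks


def sample_prior_configuration(n_moves: int, prior_mean: float,
                               rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """Direct draw from the sampler's prior: a uniform configuration
    (partition of moves + distinguished zero bin) with exponential class
    rates.  Returns ``(class_assignment, per-move rates)``; used as the
    independent oracle in prior-recovery checks.

    Uniformity over configurations is exactly uniformity over set
    partitions of ``n_moves + 1`` elements, with the block containing the
    auxiliary element acting as the zero bin.
    """
    blocks = _uniform_set_partition(list(range(n_moves + 1)), rng)
    assignment = np.zeros(n_moves, dtype=int)
    rates = np.zeros(n_moves)
    cid = 1
    for block in blocks:
        if n_moves in block:  # auxiliary element -> zero bin
            continue
        r = rng.exponential(prior_mean)
        for e in block:
            assignment[e] = cid
            rates[e] = r
        cid += 1
    return assignment, rates
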