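# Methods

## Model

A plant lineage's character state is its repertoire of fungal partner
groups, encoded as a bitmask over an ordered catalog (default:
Ascomycota, Basidiomycota, Glomeromycotina, Mucoromycotina; the empty
mask is the non-mycorrhizal state NM).  The admissible state set is the
set of repertoires observed at the tips, plus NM (always admitted,
because the hypothesis tests constrain the root to it).  States are
ordered by ascending mask value so the Q-matrix layout is deterministic
across runs.

Evolution is a continuous-time Markov chain on a rooted, ultrametric
chronogram with branch lengths in Myr.  Allowed moves are ordered state
pairs at Hamming distance 1 — a single gain or loss of one group — and
only between admitted states: the chain never passes through an
unobserved intermediate repertoire.  Each allowed move (i→j) carries a
nonnegative rate q_ij in events/Myr; all other off-diagonal entries of Q
are structural zeros and the diagonal makes rows sum to zero.  The move
graph need not be connected (a repertoire with no admitted single-move
neighbor is simply isolated).

The likelihood of tip repertoires is computed by Felsenstein pruning.
Uncertain tips (`?`) contribute all-ones partials.  Partial likelihoods
are rescaled per node by their maximum, with accumulated log factors, so
trees with hundreds of tips do not underflow.  P(t) = exp(Qt) is
evaluated by eigendecomposition when the eigenbasis is well conditioned
(condition number < 1e8 and exact reconstruction to 1e-10), falling back
to scipy's scaling-and-squaring `expm` otherwise; at the ≤ ~12 state
dimensions used here both are effectively exact.

Root priors: uniform over states (default), the stationary distribution
of Q, or a point mass on one state.  The fixed-state form implements the
root constraint of the hypothesis tests.  The uniform default follows
common multistate-tool behavior; analyses that care should set it
explicitly.

## Priors and MCMC

Free rates carry i.i.d. exponential priors with configurable mean
(default 0.01 events/Myr, i.e. one event per 100 Myr — the scale at
which a ~475-Myr land-plant phylogeny sees a handful of events per
lineage).  The reversible-jump state is a partition of the free moves
into rate classes sharing one rate value, plus a distinguished (possibly
empty) *zero bin* of moves pinned to rate 0.  The partition prior is
uniform over all such configurations; by the Bell-number identity this
equals a uniform set partition of the moves plus one auxiliary element
whose block is the zero bin, which is also how the direct prior sampler
draws configurations.

Moves, with fixed selection probabilities (0.55 rate update, 0.15
reallocation, 0.075 each for merge/split/send/revive so paired move
types cancel in the Hastings ratio):

- *rate update*: multiplicative log-scale proposal on one class rate
  with step 2.5 (acceptance typically lands in the 0.2–0.7 band on
  informative data; no adaptation, preserving detailed balance);
- *reallocation*: one move is reassigned to another class, the zero bin,
  or a fresh singleton class, with the forward/reverse option counts in
  the acceptance ratio;
- *merge/split*: two classes merge (one rate dies) or one class splits
  (a fresh rate is born from the prior), with explicit counting factors;
- *send/revive*: a whole class enters the zero bin, or a uniformly
  chosen nonempty subset of the zero bin is revived as a new class.

Born rates are always drawn from the prior, so proposal densities cancel
against the prior and every acceptance ratio reduces to a likelihood
ratio times a counting factor (Jacobian 1).  Validity is checked by the
standard prior-recovery test: with all tips uncertain the likelihood is
constant and the sampler must reproduce the prior, which it does to KS
distance < 0.05 against the direct prior sampler (tests/test_acceptance).

Chains run independently with streams derived from the seed; burn-in
(default 25%) is discarded before thinning.  Production-scale settings
mirror triplicate chains of 10^6 generations; the tests and the
acceptance script use 10^4–10^5 generations on trees of 8–200 tips,
which the calibration checks show is enough at those sizes.

## Marginal likelihoods and the first-gain test

ln Z is estimated by stepping-stone sampling along the power schedule
beta_k = (k/K)^(1/0.3) (quantiles of Beta(0.3, 1), concentrating stones
near the prior).  Chains are warm-started stone to stone with reversible
jump disabled, keeping the model dimension fixed — stepping stone across
varying dimension is not well defined without extra machinery.  Each
stone contributes ln E[L^Δβ]; the standard error sums per-stone
delta-method variances with an ESS correction for autocorrelation.
Models with zero free parameters return lnZ = logL exactly with SE 0.
Defaults mirror production scale (100 stones × 200,000 iterations);
tests use 8–24 stones of 400–3,000 iterations.

The first-gain test fixes the root to NM in all models.  The base model
is otherwise unconstrained; each alternative places a structural zero on
the single move NM→{g} for one group g.  Only the root-adjacent gain is
zeroed — later gains of g from richer repertoires stay allowed — because
the test targets the *first* gain from the non-mycorrhizal root, and
losses back to NM demonstrably occur later in such histories.  The root
constraint is implemented through the root prior, not by zeroing moves
into NM, for the same reason.  Bayes factors are reported as
2·(lnZ_base − lnZ_alt), the scale on which >10 reads as strong and 6–10
as substantial support; the same seed and schedule are reused across
models so BF(base, base) is exactly 0.  If an alternative's constraints
leave no path to the observed repertoires its marginal likelihood is
exactly zero and the BF is reported as +inf rather than an error.

## Reconstruction, mapping, through time

Ancestral states are *marginal* per-node posteriors from the standard
two-pass (inside/outside) algorithm, averaged over thinned draws from
the rate posterior (default up to 100, evenly spaced) — integrating over
rate uncertainty rather than plugging in posterior means.  Branch states
are the arg-max of the child node's distribution; exact ties break to
the lower canonical state index and are flagged.

Stochastic character mapping draws node states from the joint
conditional (root from prior × root partials, children given parents),
then fills each branch with an endpoint-conditioned path by
uniformization: jump counts from P(n) ∝ Pois(n; Ωt)·Rⁿ[a,b] with
Ω = 1.05·max|Q_ii| and R = I + Q/Ω, bridge-sampled jump states, uniform
order-statistic jump times, virtual jumps discarded.  This is exact and,
at these dimensions, cheaper and simpler than interval bisection.
Poisson weights are computed in log space so long branches with fast
rates cannot underflow.  When mapping over a posterior trace, a fixed
number of histories (default 10) is drawn per rate draw, separating rate
uncertainty from mapping noise.  Transition summaries report mean counts
per ordered pair across histories and their normalized proportions; with
no transitions at all the proportions are flagged empty rather than
divided by zero.

The states-through-time summary samples a grid of ages (default every
50 Myr from the present) and, at each age, the fraction of live branches
in each state.  A branch above node k spans the half-open interval
[age(k), age(parent k)): each node's instant belongs exactly to its
child branches, so counts partition cleanly, equal the
lineages-through-time curve, and t = 0 yields the tip count.  With
single-state branch assignments the branch holds that state over its
whole interval; mapped histories resolve within-branch changes and are
averaged across histories.

## Synthetic data

Trees are pure-birth (Yule) with a uniform birth rate: the root splits
into two lineages, each speciation waits Exp(k·λ), and after the n-th
tip appears one further Exp(n·λ) interval is appended so terminal
branches are not truncated at a speciation instant.  Default λ = 0.03
/lineage/Myr puts a 50-tip root age near 120 Myr, matching the
one-event-per-100-Myr rate scale.  Characters evolve by exact Gillespie
simulation down each branch, returning both tip data and the full true
history for recovery tests.

`make_paper_like_fixture` emulates the *shape* of a real 732-species
land-plant dataset: 732 tips, root age exactly 475 Myr, repertoires over
NM, M, G, G+M, B, A+B, G+B, A+B+G generated by an entry path
NM→M→G+M→G with slower B/A side paths, and exactly 45 non-mycorrhizal
tips enforced by recoding.  Its generating rates are a documented
invention; the fixture is an integration-test object, never an oracle
for biological claims.  What the generator does not emulate: extinction
and fossil tips, diversification-rate variation, clade-specific rate
heterogeneity, and sampling bias — so passing tests demonstrate
correctness of the inference machinery under the model, not robustness
to real-data violations of it.

## Numerical and design notes

- Ultrametricity is checked at 1e-6 relative tolerance and is a warning
  by default (published chronograms carry rounding); strict mode raises.
- Polytomies are accepted and handled natively by pruning, the two-pass
  algorithm and mapping; no random resolution.
- Likelihood of data impossible under structural constraints is exactly
  −inf, which the samplers treat as a rejected state and
  `stepping_stone_lnZ` reports as a constraint-conflict error at start.
- Rates are events/Myr throughout because branch lengths are Myr.
- The spec-level identities used in tests (two-state closed form
  P00(t) = ½(1+e^(−2qt)), Chapman–Kolmogorov, Bell-number prior
  identities, Bernoulli transition counts on single branches) are
  computed independently of the code paths they check.

## Known limitations

- No covarion/hidden-rate or branch-heterogeneous models; no
  path-sampling alternatives to stepping stone; no model averaging over
  rooting scenarios (run once per candidate rooting).
- The reversible-jump scheme is this package's own explicit definition
  of merge/split/zero moves with a uniform partition prior; other
  multistate tools implement related but not bit-compatible samplers.
- Through-time summaries do not correct for unsampled or extinct
  lineages.
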