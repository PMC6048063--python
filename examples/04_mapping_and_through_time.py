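"""Stochastic character mapping and the states-through-time summary.

Draws full state histories conditional on the tips, summarizes which
transitions dominate repertoire evolution (the chord-diagram quantity),
and bins branch states through time: early dominance of the entry
states giving way to derived repertoires toward the present.
"""

from mycostate import (
    RateModel,
    RepertoireState,
    SimulationSpec,
    branch_states,
    build_state_space,
    marginal_asr,
    sample_histories,
    simulate_characters,
    simulate_tree,
    states_through_time,
    transition_summary,
)
from mycostate.synthetic_data import default_true_model

space = build_state_space(
    [RepertoireState.from_label(l) for l in ("NM", "M", "G", "G+M")]
)
tree = simulate_tree(SimulationSpec(n_tips=80, root_age_rescale=400.0, seed=10))
truth = default_true_model(space)
data, _ = simulate_characters(tree, truth, RepertoireState.from_label("NM"), seed=11)

hists = sample_histories(tree, data, truth, n_histories=500, seed=12)
ts = transition_summary(hists)
print("mean transition counts per history (rows = from, columns = to):")
print(ts.counts.round(2).to_string())
print("\nshare of all transitions leaving each state:")
print(ts.outflow.round(3).to_string())

asr = marginal_asr(tree, data, truth)
stt = states_through_time(tree, branch_states(asr), spacing=50.0)
print("\nproportion of lineages per state at 50-Myr intervals "
      "(0 = present):")
print(stt.proportions.round(3).to_string())
print("\nlineages alive per age:",
      {float(t): int(n) for t, n in zip(stt.times, stt.branch_counts)})
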