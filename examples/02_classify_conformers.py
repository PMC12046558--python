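"""Classify carboxylate-arm conformer states along a flexible trajectory.

Simulates a two-state Markov ensemble that hops between the bowl-shaped
αααα conformer and the doubly flipped ααββ conformer (stationary
populations 0.75/0.25), classifies every frame, and prints the recovered
conformer populations and flexibility metrics.
"""

import paddleface as pf

spec = pf.GeneratorSpec(
    markov_states=(
        pf.MarkovState(("α", "α", "α", "α")),
        pf.MarkovState(("α", "α", "β", "β")),
    ),
    markov_transition=((0.9, 0.1), (0.3, 0.7)),  # stationary (0.75, 0.25)
    n_frames=5000,
    seed=2,
)
traj, topo = pf.simulate_trajectory(spec)

pop = pf.population_table(traj, topo)
flex = pf.flexibility_metrics(pop)

print(f"frames classified: {pop.n_frames}  "
      f"excluded: {pop.exclusion_fraction:.1%}")
for label, frac in sorted(pop.fractions.items(), key=lambda kv: -kv[1]):
    print(f"  {label:8s} {frac:7.4f}")
print(f"states visited: {flex['n_states_visited']}  "
      f"entropy: {flex['shannon_entropy_bits']:.3f} bits  "
      f"max fraction: {flex['max_fraction']:.3f}")
# The two dominant fractions should sit within a couple of percent of the
# chain's stationary distribution (0.75 / 0.25); the entropy quantifies how
# flexible the catalyst is across conformers.
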