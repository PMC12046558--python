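"""Generate a synthetic paddlewheel–carbene ensemble and write it to disk.

Builds a 500-frame ensemble of an idealized Rh2(carboxylate)4–carbene
complex whose Re face is sterically blocked (closest blocking-ring centroid
planted at 3.5 Å from the carbene donor ring, the open Si face at 6.0 Å),
with 0.15 Å Gaussian coordinate noise, then writes the multi-frame XYZ and
the topology-map JSON that annotates every atom role.
"""

from pathlib import Path

import paddleface as pf

out = Path("scratch/example_ensemble")
out.mkdir(parents=True, exist_ok=True)

spec = pf.GeneratorSpec.re_blocked(n_frames=500, seed=1)
traj, topo = pf.simulate_trajectory(spec)

pf.write_trajectory_xyz(traj, out / "traj.xyz")
pf.write_topology_map(topo, out / "topology.json",
                      metadata={"generator_spec": spec.to_dict()})

print(f"wrote {len(traj)} frames of {traj.n_atoms} atoms to {out}/traj.xyz")
print(f"planted arm states: {spec.arm_states}  "
      f"d_block(Re)={spec.d_block_re} Å  d_block(Si)={spec.d_block_si} Å")
# The trajectory stands in for MD output: each frame is the same complex
# with planted conformer states plus thermal-like coordinate noise.
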