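# paddleface

Conformer classification and prochiral facial-selectivity prediction for
dirhodium paddlewheel carbene complexes from conformational ensembles.

## The problem

Chiral dirhodium tetracarboxylate catalysts (Rh₂L₄ "paddlewheels") control
the enantioselectivity of carbene-transfer reactions through the steric
environment around the Rh-bound carbene. That environment is *dynamic*: the
four carboxylate arms flip their blocking groups between the carbene face
(**α**) and the opposite face (**β**), or partially rotate by ~90° about
the C_carboxylate–C_α bond (**α′**, **β′**). Which prochiral face of the
trigonal carbene carbon — *Re* or *Si* — is left open decides which
enantiomer of the product forms, and strongly hydrogen-bond-donating
solvents can reshape the whole conformational landscape.

`paddleface` takes a multi-frame structure of such a complex (from MD or
any other source) plus a *topology map* annotating atom roles, and:

1. classifies each carboxylate arm per frame into α/β/α′/β′ using the
   imide-group side of the paddlewheel midplane and the rotation dihedral
   θ (primed when Δθ ∈ [60°, 120°]), canonicalizing the 4-arm label under
   cyclic rotation (e.g. `αααβ`, `αβαβ`, `αααα′`);
2. computes per-frame steric descriptors, chiefly **d(Re)** and **d(Si)**:
   the distance from the carbene donor-ring centroid to the closest ligand
   blocking-ring centroid on each prochiral face (plus per-arm θ, arm–carbene
   distances and optional percent buried volume %V_bur);
3. turns the descriptor series into a facial-selectivity prediction:
   `p_re_blocked` = fraction of frames with d(Re) < d(Si); the alkene is
   predicted to approach the *less* hindered face (Si when p > 0.8, Re when
   p < 0.2, no call in between), with kernel-density estimates of the two
   distance distributions as rigidity/multimodality diagnostics;
4. optionally checks the prediction against a signed experimental
   enantiomeric excess (positive ee ⇔ Si-face addition).

A first-class synthetic generator builds idealized Rh₂(carboxylate)₄–carbene
ensembles with planted arm states, planted blocking distances, Markov
switching between conformational states and Gaussian coordinate noise — the
ground-truth fixtures used throughout the tests.

## Worked example

`examples/04_selectivity_prediction.py` builds three 2000-frame ensembles
(σ = 0.15 Å noise) and runs the full predictor:

```
Re-blocked   predicted_face=Si   p_re_blocked=1.000 modes d(Re)/d(Si)=3.48/6.00 Å multimodal=False/False  vs ee=+90% → agrees=True
mirrored     predicted_face=Re   p_re_blocked=0.000 modes d(Re)/d(Si)=6.00/3.48 Å multimodal=False/False  vs ee=-90% → agrees=True
flexible     predicted_face=none p_re_blocked=0.492 modes d(Re)/d(Si)=6.00/3.50 Å multimodal=True/True
```

Reading: the first ensemble has its Re face blocked (d(Re) peaks at 3.5 Å,
well under d(Si) at 6.0 Å in every frame), so alkene approach is predicted
on the open Si face — consistent with a positive experimental ee. Its
mirror image inverts the call exactly. The third ensemble hops 50/50
between Re-blocked and Si-blocked geometries: no face is called and both
KDEs are flagged multimodal, the signature of a conformationally flexible
catalyst that has lost facial selectivity.

The same pipeline is available from the shell:

```bash
paddleface simulate --spec spec.json --out sim/
paddleface analyze --traj sim/traj.xyz --topo sim/topology.json \
    --out results/ --ee 90
```

writing per-frame labels (CSV), descriptors (CSV), conformer populations
(JSON) and the selectivity report (JSON), each embedding the exact
parameter set used.

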