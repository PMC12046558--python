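# Methods

This note records the models, conventions and numerical choices behind
`paddleface`, and what the synthetic benchmarks do and do not demonstrate.

## Structural model and conventions

**Frames and topology.** A trajectory is an ordered list of frames with a
fixed atom count and element order; coordinates are Cartesian angstroms.
All chemistry-specific knowledge enters through the topology map, which
binds 1-based atom indices (file order, the way structure viewers count)
to roles: the carbene-bearing and distal Rh, the carbene carbon, its ester
carbonyl carbon, the donor-group benzene ring, and per arm the carboxylate
carbon, the C_α, a four-atom dihedral quadruple, the blocking ring and the
imide group. Indices are converted to 0-based once at parse time.

**Carbene plane and Re/Si faces.** The carbene plane is the least-squares
plane through the carbene carbon and its three substituent anchors (Rh,
ester carbonyl C, donor-ring ipso C) rather than an exact three-point
plane, so that slight pyramidalization in MD snapshots does not make the
face split erratic. The Re side is the side from which the priority
sequence Rh > ester C > aryl C appears clockwise. Those priorities are
hard-coded for this chemotype — Rh dominates on atomic number and the
ester carbon outranks the aryl carbon by its (O,O,O) duplicated-atom set —
which avoids shipping a general CIP engine; it is a documented limitation
that the module is not a general stereodescriptor tool. Points within
0.5 Å of the plane are reported as *ambiguous* rather than forced to a
face, and excluded from face-resolved statistics; the near-plane behavior
is not defined by the underlying method, so an explicit exclusion band
with a reported exclusion fraction was preferred over silently assigning
borderline geometry.

**Arm states.** The α/β side of an arm is the side of the paddlewheel
midplane (through the Rh–Rh midpoint, normal along the Rh–Rh axis oriented
toward the carbene-bearing Rh) on which the arm's imide-group centroid
projects. The primed flag uses the rotation dihedral θ measured on the
declared quadruple about the C_carboxylate–C_α bond: an arm is primed when
|θ − θ_ref| wrapped to [0°, 180°] falls in **[60°, 120°]**, a symmetric
window around the ~90° partial-rotation waypoint; a ~180° rotation instead
flips the side classification. The window edges are a package decision
(the source material gives only the ~90° and 180° waypoints) and are
exposed as a parameter. θ_ref per arm defaults to the first frame of the
trajectory being analyzed unless the topology map supplies it — supplying
it explicitly is recommended whenever replicas must share one reference.

**Canonical labels.** The four per-arm symbols are canonicalized to the
lexicographically smallest cyclic rotation under α < α′ < β < β′.
Rotations only — never reflections — because the complex is chiral and a
reversed arm order is a different stereochemical object.

**d(Re)/d(Si).** Each arm's blocking-ring centroid (unweighted mean over
the declared heavy ring atoms) is face-assigned against the carbene plane;
d(face) is the minimum centroid–centroid distance from the donor-ring
centroid over the non-ambiguous arms on that face, and missing (NaN) when
a face has none. Missing frames are excluded from the KDE inputs and
counted in the report rather than imputed, since imputation would bias the
facial-bias probability toward whatever value was imputed.

**%V_bur.** The standard protocol: a 3.5 Å probe sphere, Bondi van der
Waals radii scaled by 1.17, hydrogens excluded by default, the two Rh
atoms always excluded, evaluated on a cell-centered cubic grid (default
mesh 0.1 Å, error against the analytic single-sphere case well under
0.1 %). Whole-sphere by default with an optional per-hemisphere
restriction (Re/Si); whether a hemisphere split is the more informative
variant is left to the user, and the whole-sphere number is the
community-comparable one.

## Selectivity statistic

The primary statistic is paired and per-frame: `p_re_blocked` is the
fraction of frames with d(Re) < d(Si), ties counting one half. Pairing
respects the frame-level correlation between the two distances; comparing
KDE modes instead would discard it, so modes are reported only as
diagnostics. The favored approach face is the *less* hindered one: Si when
p exceeds the decision threshold (default 0.8), Re when p falls below one
minus the threshold, otherwise no call. The threshold encodes "blocked in
the large majority of frames" and is deliberately conservative; it is a
package decision exposed as a flag, since the underlying method states
only a qualitative correspondence. No ee *magnitude* is predicted — the
method's claim is a sign/quality correlation, not a regression.

KDEs use a Gaussian kernel with the Silverman bandwidth
h = 0.9·min(sd, IQR/1.34)·n^(−1/5), evaluated on ≥512 grid points spanning
[min − 3h, max + 3h]; degenerate (zero-variance) samples get a 0.01 Å
bandwidth floor and a warning. Local maxima count as peaks only above 20 %
of the main peak height, which matches a qualitative "multiple peaks"
reading while suppressing numerical ripples; two or more such peaks set
the per-face multimodality flag. The experiment check uses the convention
that positive ee means Si-face addition; it returns indeterminate when no
face was called or ee is exactly zero.

## Synthetic generator

The generator emulates what the analysis consumes — a conformational
ensemble with known ground truth — not the physics that produces it. A
template complex places the two Rh on the z axis (Rh–Rh 2.40 Å), an apical
carbene (Rh–C 2.00 Å) with its ester proxy (carbonyl C + two O) and
benzene donor ring in one plane, and four carboxylate arms at 90° spacing
(bridging O at Rh–O 2.04 Å). Each arm's imide proxy (N flanked by two
carbonyl C) rotates rigidly about the C_carboxylate–C_α bond by the
planted angle — 0° (α), 180° (β), 90° (primed) — which defines both θ and,
together with the blocking ring, the side. The six-membered blocking ring
is placed separately so that its centroid sits at the *exact* planted
distance from the donor-ring centroid on the planted side; per face, the
arm nearest the donor ring carries the planted distance and the other sits
2.5 Å farther. Isotropic Gaussian noise (default σ = 0.15 Å per atom) is
added after state placement, so planted labels are exact at σ = 0. Markov
switching rebuilds the template per state (states may differ in arm states
and/or blocking distances) with the initial state drawn from the chain's
stationary distribution. A single NumPy generator seeded once per call
makes every ensemble bit-reproducible.

Default conditions: a facially neutral all-α bowl with both faces at
7.0 Å; the planted-bias presets place the blocked face's closest ring at
3.5 Å and the open face at 6.0 Å with σ = 0.15 Å over 2000 frames —
a rigid blocked complex, its mirror image, and a 50/50 two-state mixture
of the two are the three canonical scenarios.

Two generator internals are deliberately unphysical and worth naming.
First, lever arms along the rotation dihedral (the bridging-O z offset,
the stretched C_carboxylate–C_α distance and imide N bond) are longer than
real bonds so that θ remains well conditioned under the i.i.d. per-atom
noise model: real thermal motion is strongly correlated by bonding, and
i.i.d. noise on a tightly spaced quadruple would otherwise produce torsion
noise far in excess of anything an MD trajectory shows. Second, the
blocking ring is positioned by its planted centroid distance rather than
by bonded geometry (the β-side rings in particular are pulled well below
the midplane), with a feasibility check that rejects specs whose planted
distance would force a ring onto the wrong side — e.g. a β arm closer than
about 5 Å to the donor-ring centroid is geometrically unrealizable in this
template and raises rather than silently mislabeling.

What passing on these ensembles shows: the classifiers and descriptors
recover *known* ground truth through the full pipeline, with exact
agreement at σ = 0 and ≥99 % label recovery at σ = 0.15 Å. What it does
not show: performance on real MD output, where noise is anisotropic and
correlated, arms move cooperatively, rings deform, and solvent effects set
the populations. The package is the measurement instrument; the synthetic
ensembles only calibrate it.

## Numerical choices and degenerate inputs

* Torsions use the standard atan2 formulation, range (−180°, 180°], cis = 0.
  The torsion is invariant under atom-order reversal and changes sign under
  mirror reflection; near-collinear quadruples raise rather than return
  noise.
* Degenerate carbene planes (collinear anchors, zero circulation of the
  substituent directions) raise `GeometryError`; trajectory-level drivers
  log such frames with reasons and continue.
* Population fractions are computed over classifiable frames and sum to 1;
  excluded frames are reported as a fraction, never silently dropped.
* The facial-bias statistic requires ≥10 paired frames; fewer is an error,
  not a weak answer.
* Problem sizes used by the test suite and the reproduction script —
  2000-frame ensembles for the selectivity scenarios, 600 frames per spec
  for noisy label recovery, 20,000 frames for the Markov occupancy check —
  were chosen so that the binomial/sampling error of each measured rate is
  several times smaller than the tolerance it is tested against.

## Known limitations

* The Re/Si construction hard-codes the priority order for this chemotype;
  exotic carbene substituents that invert CIP priorities would need a
  different anchor choice in the topology map.
* The primed window, ambiguity band and decision threshold are documented
  defaults, not fitted quantities; sensitivity to them should be checked
  on real data.
* %V_bur settings follow the community standard; no claim is made that they
  match any particular published variant of the hemisphere split.
* The generator's idealizations (above) make it a calibration target, not
  a structural model of any real catalyst.
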