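"""Idealized paddlewheel–carbene ensemble generator.

Builds trajectories of a model Rh₂(carboxylate)₄–carbene complex with
*planted* ground truth: per-arm rotational states (α/β/α′/β′), exact
blocking-ring centroid distances to the carbene donor ring on the Re and Si
faces, isotropic Gaussian coordinate noise, and optional Markov switching
between conformational states. These ensembles stand in for MD output in
tests and demonstrations; they carry no physical energies.

Construction: the two Rh atoms sit on the z axis, the apical carbene carbon
above the carbene-bearing Rh with its ester proxy (carbonyl C + two O) and
benzene donor ring in the xz plane, and four carboxylate arms at 90°
azimuthal spacing. Each arm's imide proxy (N flanked by two carbonyl C)
rotates about the C_carboxylate–C_α bond by the planted angle (0° for α,
180° for β, 90° for primed states), which defines both the θ dihedral and —
together with the blocking ring — the α/β side. The six-membered blocking
ring is placed separately so that its centroid lies at the exact planted
distance from the donor-ring centroid on the planted side; a feasibility
check verifies that classifying the noise-free template recovers the
planted label and distances, and raises otherwise.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from . import conformers, descriptors, geometry
from .errors import InfeasibleSpecError
from .io import Arm, Frame, TopologyMap, Trajectory

__all__ = [
    "GeneratorSpec",
    "MarkovState",
    "build_template",
    "simulate_trajectory",
    "stationary_distribution",
    "mirror_frame",
    "mirror_trajectory",
    "normalize_state",
]

#: Planted rotation angle ψ (degrees) about the C_carboxylate–C_α bond.
PSI_DEG = {"α": 0.0, "α′": 90.0, "β": 180.0, "β′": 90.0}

#: z anchor (Å) and lateral scale of the blocking-ring placement direction
#: per side. The β anchor is deeper (and pushed outward) because the
#: donor-ring centroid sits high above the paddlewheel midplane, so β rings
#: must be pulled well below it to keep a robust side signal under noise.
_Z_ANCHOR = {"alpha": 4.0, "beta": -8.0}
_XY_SCALE = {"alpha": 1.0, "beta": 1.3}

_ALIASES = {
    "a": "α", "alpha": "α", "α": "α",
    "a'": "α′", "ap": "α′", "alpha'": "α′", "α'": "α′", "α′": "α′",
    "b": "β", "beta": "β", "β": "β",
    "b'": "β′", "bp": "β′", "beta'": "β′", "β'": "β′", "β′": "β′",
}


def normalize_state(symbol: str) -> str:
    """Map ASCII aliases (a, b, a', b', alpha, ...) to canonical symbols."""
    try:
        return _ALIASES[symbol.strip().lower() if symbol.isascii() else symbol]
    except KeyError:
        raise ValueError(f"unknown arm state {symbol!r}") from None


@dataclass(frozen=True)
class MarkovState:
    """One conformational state of a Markov-switching ensemble."""

    arm_states: tuple[str, str, str, str]
    d_block_re: float | None = None  # None → inherit the spec-level value
    d_block_si: float | None = None


@dataclass(frozen=True)
class GeneratorSpec:
    """Parameters of a synthetic ensemble.

    Defaults describe a facially neutral bowl (all-α, both faces at 7.0 Å)
    with MD-like coordinate noise of 0.15 Å; use :meth:`re_blocked` /
    :meth:`si_blocked` for the planted-bias study conditions (closest ring
    at 3.5 Å on the blocked face, 6.0 Å on the open face).
    """

    arm_states: tuple[str, str, str, str] = ("α", "α", "α", "α")
    d_block_re: float = 7.0
    d_block_si: float = 7.0
    noise_sigma: float = 0.15
    n_frames: int = 2000
    seed: int = 0
    markov_transition: tuple[tuple[float, ...], ...] | None = None
    markov_states: tuple[MarkovState, ...] | None = None
    rh_rh_dist: float = 2.40
    rh_o_dist: float = 2.04
    rh_c_carbene_dist: float = 2.00
    far_offset: float = 2.5

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "arm_states", tuple(normalize_state(s) for s in self.arm_states)
        )
        if len(self.arm_states) != 4:
            raise InfeasibleSpecError("exactly 4 arm states required")
        if self.noise_sigma < 0:
            raise InfeasibleSpecError("noise_sigma must be ≥ 0")
        if self.n_frames < 1:
            raise InfeasibleSpecError("n_frames must be ≥ 1")
        for name in ("d_block_re", "d_block_si", "rh_rh_dist", "rh_o_dist",
                     "rh_c_carbene_dist"):
            if getattr(self, name) <= 0:
                raise InfeasibleSpecError(f"{name} must be positive")
        if (self.markov_transition is None) != (self.markov_states is None):
            raise InfeasibleSpecError(
                "markov_transition and markov_states must be given together"
            )
        if self.markov_states is not None:
            states = tuple(
                MarkovState(
                    arm_states=tuple(normalize_state(x) for x in s.arm_states),
                    d_block_re=s.d_block_re,
                    d_block_si=s.d_block_si,
                )
                for s in self.markov_states
            )
            object.__setattr__(self, "markov_states", states)
            P = np.asarray(self.markov_transition, float)
            k = len(states)
            if k < 2:
                raise InfeasibleSpecError("Markov switching needs ≥2 states")
            if P.shape != (k, k):
                raise InfeasibleSpecError(
                    f"transition matrix shape {P.shape} != ({k}, {k})"
                )
            if np.any(P < 0) or np.any(np.abs(P.sum(axis=1) - 1) > 1e-9):
                raise InfeasibleSpecError("transition matrix rows must sum to 1")
            object.__setattr__(
                self, "markov_transition", tuple(tuple(row) for row in P)
            )

    @classmethod
    def re_blocked(cls, **kwargs) -> "GeneratorSpec":
        """Rigid ensemble with the Re face blocked (closest ring 3.5 Å)."""
        kwargs.setdefault("d_block_re", 3.5)
        kwargs.setdefault("d_block_si", 6.0)
        return cls(**kwargs)

    @classmethod
    def si_blocked(cls, **kwargs) -> "GeneratorSpec":
        """Mirror scenario: Si face blocked."""
        kwargs.setdefault("d_block_re", 6.0)
        kwargs.setdefault("d_block_si", 3.5)
        return cls(**kwargs)

    @classmethod
    def from_dict(cls, doc: dict) -> "GeneratorSpec":
        doc = dict(doc)
        doc.pop("_metadata", None)
        if doc.get("markov_states") is not None:
            doc["markov_states"] = tuple(
                MarkovState(
                    arm_states=tuple(s["arm_states"]),
                    d_block_re=s.get("d_block_re"),
                    d_block_si=s.get("d_block_si"),
                )
                for s in doc["markov_states"]
            )
        if doc.get("markov_transition") is not None:
            doc["markov_transition"] = tuple(
                tuple(row) for row in doc["markov_transition"]
            )
        if "arm_states" in doc:
            doc["arm_states"] = tuple(doc["arm_states"])
        return cls(**doc)

    def to_dict(self) -> dict:
        doc = {
            "arm_states": list(self.arm_states),
            "d_block_re": self.d_block_re,
            "d_block_si": self.d_block_si,
            "noise_sigma": self.noise_sigma,
            "n_frames": self.n_frames,
            "seed": self.seed,
            "rh_rh_dist": self.rh_rh_dist,
            "rh_o_dist": self.rh_o_dist,
            "rh_c_carbene_dist": self.rh_c_carbene_dist,
            "far_offset": self.far_offset,
        }
        if self.markov_states is not None:
            doc["markov_states"] = [
                {
                    "arm_states": list(s.arm_states),
                    "d_block_re": s.d_block_re,
                    "d_block_si": s.d_block_si,
                }
                for s in self.markov_states
            ]
            doc["markov_transition"] = [list(r) for r in self.markov_transition]
        return doc


# internal bond-length idealizations (Å); deliberately generous lever arms
# (stretched C_carboxylate–C_α axis and imide N bond) keep the θ dihedral
# well conditioned under per-atom coordinate noise
_C_ESTER = 1.48
_C_IPSO = 1.45
_RING_R = 1.40
_BLOCK_RING_R = 1.35
_R_CARB = 2.00
_R_ALPHA = 4.50
_O_Z = 2.4
_N_BOND = 2.1
_CO_BOND = 1.45
_CO_ALONG = 1.15


def _rot_y(v: np.ndarray, deg: float) -> np.ndarray:
    a = math.radians(deg)
    c, s = math.cos(a), math.sin(a)
    return np.array([c * v[0] + s * v[2], v[1], -s * v[0] + c * v[2]])


def _side_of(symbol: str) -> str:
    return "alpha" if symbol in ("α", "α′") else "beta"


def build_template(
    spec: GeneratorSpec,
    arm_states: Sequence[str] | None = None,
    d_block_re: float | None = None,
    d_block_si: float | None = None,
) -> tuple[Frame, TopologyMap]:
    """Noise-free template frame plus its topology map.

    Raises :class:`InfeasibleSpecError` when the planted states/distances
    cannot be realized (classification or distance round-trip fails on the
    template, or a blocking distance is below the ring radius).
    """
    states = tuple(
        normalize_state(s) for s in (arm_states if arm_states is not None
                                     else spec.arm_states)
    )
    d_re = float(d_block_re if d_block_re is not None else spec.d_block_re)
    d_si = float(d_block_si if d_block_si is not None else spec.d_block_si)
    for d in (d_re, d_si):
        if d <= _BLOCK_RING_R + 0.2:
            raise InfeasibleSpecError(
                f"blocking distance {d} Å is inside the blocking-ring radius"
            )

    half = spec.rh_rh_dist / 2
    elements: list[str] = []
    coords: list[np.ndarray] = []

    def add(el: str, pos) -> int:
        elements.append(el)
        coords.append(np.asarray(pos, float))
        return len(coords) - 1

    i_rh_top = add("Rh", (0, 0, half))
    i_rh_bot = add("Rh", (0, 0, -half))
    z_c = half + spec.rh_c_carbene_dist
    c_pos = np.array([0.0, 0.0, z_c])
    i_carbene = add("C", c_pos)

    d_e = np.array([math.sqrt(3) / 2, 0.0, 0.5])   # ester direction
    d_a = np.array([-math.sqrt(3) / 2, 0.0, 0.5])  # donor-ring direction
    i_ester = add("C", c_pos + _C_ESTER * d_e)
    add("O", c_pos + _C_ESTER * d_e + 1.23 * _rot_y(d_e, 120))
    add("O", c_pos + _C_ESTER * d_e + 1.23 * _rot_y(d_e, -120))

    ring_center = c_pos + (_C_IPSO + _RING_R) * d_a
    u = -d_a
    w = np.array([-0.5, 0.0, -math.sqrt(3) / 2])  # ⊥ d_a in the xz plane
    aryl_idx = []
    for k in range(6):
        ang = math.radians(60 * k)
        aryl_idx.append(
            add("C", ring_center + _RING_R * (math.cos(ang) * u + math.sin(ang) * w))
        )
    donor_centroid = ring_center  # exact centroid of the hexagon

    n_re, _ = geometry._orient_re_normal(
        c_pos, coords[i_rh_top], coords[i_ester], coords[aryl_idx[0]]
    )
    # all plane anchors lie in the xz plane, so n_re = ±ŷ exactly
    re_sign = 1.0 if n_re[1] > 0 else -1.0

    r_o = math.sqrt(spec.rh_o_dist**2 - (_O_Z - half) ** 2)

    # first pass: natural arm geometry and ring-placement anchors
    arm_geo = []
    for a, sym in enumerate(states):
        phi = math.radians(45.0 + 90.0 * a)
        rhat = np.array([math.cos(phi), math.sin(phi), 0.0])
        e2 = np.array([math.sin(phi), -math.cos(phi), 0.0])
        psi = math.radians(PSI_DEG[sym])
        v = math.cos(psi) * np.array([0.0, 0.0, 1.0]) + math.sin(psi) * e2
        c_alpha = _R_ALPHA * rhat
        side = _side_of(sym)
        s = _XY_SCALE[side]
        t_anchor = np.array([s * c_alpha[0], s * c_alpha[1], _Z_ANCHOR[side]])
        face = "Re" if (rhat[1] * re_sign) > 0 else "Si"
        arm_geo.append(
            dict(phi=phi, rhat=rhat, e2=e2, v=v, c_alpha=c_alpha,
                 side=side, face=face, t_anchor=t_anchor, sym=sym)
        )

    # per face, the arm whose anchor is nearest the donor-ring centroid gets
    # the planted distance; the other arm sits far_offset farther out
    for face, d_face in (("Re", d_re), ("Si", d_si)):
        members = [g for g in arm_geo if g["face"] == face]
        members.sort(key=lambda g: np.linalg.norm(g["t_anchor"] - donor_centroid))
        members[0]["d_ring"] = d_face
        for g in members[1:]:
            g["d_ring"] = d_face + spec.far_offset

    arms: list[Arm] = []
    theta_ref: list[float] = []
    for g in arm_geo:
        rhat, e2, v, c_alpha = g["rhat"], g["e2"], g["v"], g["c_alpha"]
        i_o1 = add("O", r_o * rhat + np.array([0, 0, _O_Z]))
        add("O", r_o * rhat + np.array([0, 0, -_O_Z]))
        i_cc = add("C", _R_CARB * rhat)
        i_ca = add("C", c_alpha)
        i_n = add("N", c_alpha + _N_BOND * v)
        i_co1 = add("C", c_alpha + _CO_BOND * v + _CO_ALONG * rhat)
        i_co2 = add("C", c_alpha + _CO_BOND * v - _CO_ALONG * rhat)

        direction = g["t_anchor"] - donor_centroid
        direction /= np.linalg.norm(direction)
        ring_c = donor_centroid + g["d_ring"] * direction
        b1 = np.cross(direction, [0.0, 0.0, 1.0])
        if np.linalg.norm(b1) < 1e-8:
            b1 = np.array([1.0, 0.0, 0.0])
        b1 /= np.linalg.norm(b1)
        b2 = np.cross(direction, b1)
        ring_idx = []
        for k in range(6):
            ang = math.radians(60 * k)
            ring_idx.append(
                add("C", ring_c + _BLOCK_RING_R
                    * (math.cos(ang) * b1 + math.sin(ang) * b2))
            )
        # reference dihedral: same quad with the imide N at ψ = 0
        n_ref = c_alpha + _N_BOND * np.array([0.0, 0.0, 1.0])
        theta_ref.append(
            geometry.dihedral_coords(coords[i_o1], coords[i_cc], coords[i_ca], n_ref)
        )
        arms.append(
            Arm(
                carboxylate_c=i_cc,
                alpha_c=i_ca,
                dihedral_quad=(i_o1, i_cc, i_ca, i_n),
                blocking_ring=tuple(ring_idx),
                imide_group=(i_n, i_co1, i_co2) + tuple(ring_idx),
            )
        )

    frame = Frame(tuple(elements), np.array(coords), frame_index=0)
    topo = TopologyMap(
        rh_carbene=i_rh_top,
        rh_distal=i_rh_bot,
        carbene_c=i_carbene,
        ester_c=i_ester,
        aryl_ring=tuple(aryl_idx),
        arms=tuple(arms),
        theta_ref_deg=tuple(theta_ref),
    )
    topo.validate_against(frame.n_atoms)
    _check_feasible(frame, topo, states, d_re, d_si)
    return frame, topo


def _check_feasible(
    frame: Frame,
    topo: TopologyMap,
    states: tuple[str, ...],
    d_re: float,
    d_si: float,
) -> None:
    planted = conformers.canonical_symbols(states)
    got = conformers.complex_label(frame, topo).label
    if got != planted:
        raise InfeasibleSpecError(
            f"infeasible spec: template classifies as {got!r}, planted {planted!r} "
            "(a planted blocking distance likely puts a ring on the wrong side)"
        )
    fd = descriptors.ligand_carbene_distances(frame, topo)
    for face, want, have in (("Re", d_re, fd.d_re), ("Si", d_si, fd.d_si)):
        if not math.isfinite(have) or abs(have - want) > 1e-9:
            raise InfeasibleSpecError(
                f"infeasible spec: d({face}) on template is {have}, planted {want}"
            )
    if any(fa.face == "ambiguous" for fa in fd.arm_faces):
        raise InfeasibleSpecError(
            "infeasible spec: a blocking ring lies in the carbene-plane "
            "ambiguity band"
        )


def stationary_distribution(transition) -> np.ndarray:
    """Stationary distribution of a row-stochastic matrix (left eigenvector)."""
    P = np.asarray(transition, float)
    w, v = np.linalg.eig(P.T)
    i = int(np.argmin(np.abs(w - 1.0)))
    pi = np.real(v[:, i])
    pi = np.abs(pi)
    return pi / pi.sum()


def simulate_trajectory(spec: GeneratorSpec) -> tuple[Trajectory, TopologyMap]:
    """Generate a reproducible noisy ensemble from a generator spec.

    With Markov switching, the per-frame conformational state is sampled
    from the chain (initial state drawn from the stationary distribution)
    and the matching template used; isotropic Gaussian noise of
    ``noise_sigma`` Å is then added per atom. The planted state index and
    canonical label are recorded in each frame's comment string
    (``"frame I state S label L"``).
    """
    rng = np.random.default_rng(spec.seed)
    if spec.markov_states is not None:
        templates = []
        labels = []
        for st in spec.markov_states:
            fr, topo = build_template(
                spec,
                arm_states=st.arm_states,
                d_block_re=st.d_block_re,
                d_block_si=st.d_block_si,
            )
            templates.append(fr)
            labels.append(conformers.canonical_symbols(st.arm_states))
        P = np.asarray(spec.markov_transition, float)
        pi = stationary_distribution(P)
        k = len(templates)
        state_seq = np.empty(spec.n_frames, dtype=int)
        state_seq[0] = rng.choice(k, p=pi)
        for t in range(1, spec.n_frames):
            state_seq[t] = rng.choice(k, p=P[state_seq[t - 1]])
    else:
        fr, topo = build_template(spec)
        templates = [fr]
        labels = [conformers.canonical_symbols(spec.arm_states)]
        state_seq = np.zeros(spec.n_frames, dtype=int)

    n_atoms = templates[0].n_atoms
    elements = templates[0].elements
    if spec.noise_sigma > 0:
        noise = rng.normal(0.0, spec.noise_sigma, size=(spec.n_frames, n_atoms, 3))
    else:
        noise = np.zeros((spec.n_frames, n_atoms, 3))
    frames = []
    for t in range(spec.n_frames):
        s = int(state_seq[t])
        frames.append(
            Frame(
                elements,
                templates[s].coords + noise[t],
                frame_index=t,
                comment=f"frame {t} state {s} label {labels[s]}",
            )
        )
    return Trajectory(tuple(frames), source=f"synthetic seed={spec.seed}"), topo


def mirror_frame(frame: Frame) -> Frame:
    """Mirror image through the yz plane (x → −x): swaps Re and Si."""
    coords = frame.coords.copy()
    coords[:, 0] *= -1
    return Frame(frame.elements, coords, frame.frame_index,
                 comment=frame.comment + " (mirrored)")


def mirror_trajectory(traj: Trajectory) -> Trajectory:
    """Mirror image of every frame; enantiomeric ensemble."""
    return Trajectory(
        tuple(mirror_frame(fr) for fr in traj),
        source=traj.source + " (mirrored)",
    )
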