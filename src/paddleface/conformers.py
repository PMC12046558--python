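"""Per-arm conformer-state classification and trajectory population statistics.

Each carboxylate arm of the paddlewheel is classified into one of four
rotational states:

* **α** — the arm's imide blocking group points toward the carbene face of
  the complex (the "bowl" orientation),
* **β** — flipped ~180° toward the opposite face,
* **α′ / β′** — partially rotated by ~90° about the C_carboxylate–C_α bond
  (the primed window is Δθ ∈ [60°, 120°] around the reference dihedral).

The α/β side is decided by which side of the paddlewheel midplane (normal =
Rh–Rh axis, oriented toward the carbene-bearing Rh, through the Rh–Rh
midpoint) the imide-group centroid projects onto. The four per-arm symbols
are then canonicalized under cyclic rotation of the arm order — rotations
only, never reflections, because the complex is chiral — with the ordering
α < α′ < β < β′.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .errors import AnalysisError, GeometryError
from .geometry import centroid, dihedral
from .io import Frame, TopologyMap, Trajectory

__all__ = [
    "ArmState",
    "ConformerLabel",
    "PopulationTable",
    "PRIMED_WINDOW",
    "STATE_SYMBOLS",
    "arm_state",
    "complex_label",
    "canonical_label",
    "canonical_symbols",
    "population_table",
    "flexibility_metrics",
    "resolve_theta_ref",
]

#: Δθ window (degrees) in which an arm counts as partially rotated (primed).
PRIMED_WINDOW = (60.0, 120.0)

#: Canonical ordering of the four arm states.
STATE_SYMBOLS = ("α", "α′", "β", "β′")

_RANK = {s: r for r, s in enumerate(STATE_SYMBOLS)}


@dataclass(frozen=True)
class ArmState:
    """Classified rotational state of one carboxylate arm."""

    side: str  # "alpha" | "beta"
    primed: bool
    theta_deg: float
    delta_theta_deg: float

    @property
    def symbol(self) -> str:
        base = "α" if self.side == "alpha" else "β"
        return base + ("′" if self.primed else "")

    @property
    def rank(self) -> int:
        return _RANK[self.symbol]


@dataclass(frozen=True)
class ConformerLabel:
    """Canonical 4-arm label plus the raw per-arm states in arm order."""

    label: str
    raw_states: tuple[ArmState, ArmState, ArmState, ArmState]


def wrap_delta_deg(theta: float, ref: float) -> float:
    """|θ − ref| wrapped to [0, 180] degrees."""
    return abs((theta - ref + 180.0) % 360.0 - 180.0)


def arm_state(
    frame: Frame,
    topo: TopologyMap,
    arm_index: int,
    primed_window: tuple[float, float] = PRIMED_WINDOW,
) -> ArmState:
    """Classify one arm of one frame.

    When the topology map carries no ``theta_ref_deg``, the frame itself is
    taken as the reference (Δθ = 0); trajectory-level drivers resolve the
    reference from the first frame via :func:`resolve_theta_ref` first.
    """
    arm = topo.arms[arm_index]
    c = frame.coords
    axis = c[topo.rh_carbene] - c[topo.rh_distal]
    norm = np.linalg.norm(axis)
    if norm < 1e-8:
        raise GeometryError("zero-length Rh–Rh vector")
    axis /= norm
    midpoint = 0.5 * (c[topo.rh_carbene] + c[topo.rh_distal])
    imide_centroid = centroid(frame, arm.imide_group)
    side = "alpha" if float(np.dot(imide_centroid - midpoint, axis)) > 0 else "beta"

    theta = dihedral(frame, *arm.dihedral_quad)
    if topo.theta_ref_deg is not None:
        ref = topo.theta_ref_deg[arm_index]
    else:
        ref = theta
    delta = wrap_delta_deg(theta, ref)
    primed = primed_window[0] <= delta <= primed_window[1]
    return ArmState(side=side, primed=primed, theta_deg=theta, delta_theta_deg=delta)


def canonical_symbols(symbols: Sequence[str]) -> str:
    """Canonicalize 4 arm-state symbols under cyclic rotation of arm order."""
    try:
        ranks = [_RANK[s] for s in symbols]
    except KeyError as exc:
        raise ValueError(f"unknown arm-state symbol {exc.args[0]!r}") from None
    if len(ranks) != 4:
        raise ValueError("exactly 4 arm states expected")
    best = min(tuple(ranks[i:] + ranks[:i]) for i in range(4))
    return "".join(STATE_SYMBOLS[r] for r in best)


def canonical_label(states: Sequence[ArmState]) -> str:
    """Lexicographically smallest label among the 4 cyclic arm rotations."""
    return canonical_symbols([s.symbol for s in states])


def complex_label(
    frame: Frame,
    topo: TopologyMap,
    primed_window: tuple[float, float] = PRIMED_WINDOW,
) -> ConformerLabel:
    """Canonical conformer label of a frame (e.g. ``"αααβ"``, ``"αααα′"``)."""
    states = tuple(
        arm_state(frame, topo, a, primed_window=primed_window) for a in range(4)
    )
    return ConformerLabel(label=canonical_label(states), raw_states=states)


def resolve_theta_ref(traj: Trajectory, topo: TopologyMap) -> TopologyMap:
    """Fill missing per-arm reference dihedrals from the first frame."""
    if topo.theta_ref_deg is not None:
        return topo
    first = traj.frames[0]
    refs = [dihedral(first, *arm.dihedral_quad) for arm in topo.arms]
    return topo.with_theta_ref(refs)


@dataclass(frozen=True)
class PopulationTable:
    """Conformer-label fractions over the classifiable frames of a trajectory."""

    fractions: dict[str, float]
    n_frames: int
    exclusion_fraction: float

    def __post_init__(self) -> None:
        if self.fractions:
            total = sum(self.fractions.values())
            if abs(total - 1.0) > 1e-9:
                raise ValueError(f"fractions sum to {total}, not 1")


def population_table(
    traj: Trajectory,
    topo: TopologyMap,
    primed_window: tuple[float, float] = PRIMED_WINDOW,
) -> PopulationTable:
    """Fraction of frames per canonical conformer label.

    Frames whose geometry is degenerate (undefined torsion, zero Rh–Rh axis)
    are excluded and reported through ``exclusion_fraction``.
    """
    topo = resolve_theta_ref(traj, topo)
    counts: dict[str, int] = {}
    n_excluded = 0
    for fr in traj:
        try:
            lab = complex_label(fr, topo, primed_window=primed_window).label
        except GeometryError:
            n_excluded += 1
            continue
        counts[lab] = counts.get(lab, 0) + 1
    n_ok = sum(counts.values())
    if n_ok == 0:
        raise AnalysisError("zero classifiable frames")
    fractions = {lab: n / n_ok for lab, n in sorted(counts.items())}
    return PopulationTable(
        fractions=fractions,
        n_frames=n_ok,
        exclusion_fraction=n_excluded / len(traj),
    )


def flexibility_metrics(pop: PopulationTable) -> dict[str, float]:
    """Summaries of conformational flexibility of a population table.

    ``shannon_entropy_bits`` is −Σ f·log₂ f over nonzero fractions: 0 for a
    single rigid conformer, 2 bits for four equally populated states.
    """
    fracs = [f for f in pop.fractions.values() if f > 0]
    entropy = -sum(f * math.log2(f) for f in fracs)
    return {
        "n_states_visited": len(fracs),
        "shannon_entropy_bits": entropy,
        "max_fraction": max(fracs) if fracs else 0.0,
    }
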