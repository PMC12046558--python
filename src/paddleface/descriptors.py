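"""Per-frame steric descriptors of the carbene pocket.

The headline descriptor is the pair d(Re)/d(Si): the distance from the
centroid of the carbene donor-group benzene ring to the *closest* ligand
blocking-ring centroid on the Re and Si faces of the carbene, respectively.
A short d on one face means that prochiral face is sterically blocked by a
carboxylate arm, so alkene attack is funnelled to the other face.

Also computed: the four arm rotation dihedrals θ, the blocking-ring
centroid → carbene-carbon distances, and (optionally) the percent buried
volume %Vbur around the carbene-bearing Rh or the carbene carbon following
the community-standard protocol (3.5 Å probe sphere, Bondi radii × 1.17,
hydrogens excluded by default).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import GeometryError
from .geometry import AMBIGUITY_BAND, FaceAssignment, assign_face, centroid, dihedral
from .io import Frame, TopologyMap, Trajectory
from .conformers import resolve_theta_ref

__all__ = [
    "FrameDistances",
    "DescriptorSeries",
    "ligand_carbene_distances",
    "descriptor_series",
    "buried_volume",
    "BONDI_RADII",
]

#: Bondi van der Waals radii (Å) for the elements that occur in these
#: complexes; unknown elements fall back to 2.0 Å.
BONDI_RADII = {
    "H": 1.20, "C": 1.70, "N": 1.55, "O": 1.52, "F": 1.47, "P": 1.80,
    "S": 1.80, "Cl": 1.75, "Br": 1.85, "I": 1.98, "Rh": 2.00,
}
_DEFAULT_VDW = 2.0


@dataclass(frozen=True)
class FrameDistances:
    """d(Re)/d(Si) for one frame plus the per-arm breakdown."""

    d_re: float  # NaN when no non-ambiguous arm lies on the Re face
    d_si: float
    closest_arm_re: int | None
    closest_arm_si: int | None
    arm_distances: tuple[float, float, float, float]
    arm_faces: tuple[FaceAssignment, ...]


def ligand_carbene_distances(
    frame: Frame,
    topo: TopologyMap,
    ambiguity_band: float = AMBIGUITY_BAND,
) -> FrameDistances:
    """Closest blocking-ring centroid distance per prochiral face.

    Every arm's blocking-ring centroid is face-assigned against the carbene
    plane; d(face) is the minimum centroid–centroid distance from the carbene
    donor-ring centroid over the arms on that face. A face with no
    non-ambiguous arm yields NaN. Raises :class:`GeometryError` when the
    carbene plane itself is degenerate.
    """
    donor_centroid = centroid(frame, topo.aryl_ring)
    dists: list[float] = []
    faces: list[FaceAssignment] = []
    for arm in topo.arms:
        ring_centroid = centroid(frame, arm.blocking_ring)
        faces.append(
            assign_face(frame, topo, ring_centroid, ambiguity_band=ambiguity_band)
        )
        dists.append(float(np.linalg.norm(ring_centroid - donor_centroid)))

    best = {"Re": (math.nan, None), "Si": (math.nan, None)}
    for a, (fa, d) in enumerate(zip(faces, dists)):
        if fa.face in best:
            cur = best[fa.face][0]
            if math.isnan(cur) or d < cur:
                best[fa.face] = (d, a)
    return FrameDistances(
        d_re=best["Re"][0],
        d_si=best["Si"][0],
        closest_arm_re=best["Re"][1],
        closest_arm_si=best["Si"][1],
        arm_distances=tuple(dists),
        arm_faces=tuple(faces),
    )


@dataclass
class DescriptorSeries:
    """Per-frame descriptor table plus skipped-frame bookkeeping.

    ``table`` columns: frame, d_re, d_si, closest_arm_re, closest_arm_si,
    theta_1..theta_4, d_arm_1..d_arm_4 (blocking-ring centroid to carbene
    carbon, Å) and optionally pct_vbur. Missing values are NaN.
    """

    table: pd.DataFrame
    skipped: list[tuple[int, str]] = field(default_factory=list)
    params: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.table)


def descriptor_series(
    traj: Trajectory,
    topo: TopologyMap,
    ambiguity_band: float = AMBIGUITY_BAND,
    include_vbur: bool = False,
    vbur_kwargs: dict | None = None,
) -> DescriptorSeries:
    """Compute the descriptor table over a trajectory, one row per frame.

    Frames with degenerate geometry are logged in ``skipped`` (with reasons)
    and appear in the table as all-NaN rows, preserving frame order.
    """
    topo = resolve_theta_ref(traj, topo)
    rows = []
    skipped: list[tuple[int, str]] = []
    vbur_kwargs = vbur_kwargs or {}
    for fr in traj:
        row: dict = {"frame": fr.frame_index}
        try:
            fd = ligand_carbene_distances(fr, topo, ambiguity_band=ambiguity_band)
            row.update(
                d_re=fd.d_re,
                d_si=fd.d_si,
                closest_arm_re=fd.closest_arm_re,
                closest_arm_si=fd.closest_arm_si,
            )
            for a, arm in enumerate(topo.arms, start=1):
                row[f"theta_{a}"] = dihedral(fr, *arm.dihedral_quad)
                ring_centroid = centroid(fr, arm.blocking_ring)
                row[f"d_arm_{a}"] = float(
                    np.linalg.norm(ring_centroid - fr.coords[topo.carbene_c])
                )
            if include_vbur:
                row["pct_vbur"] = buried_volume(fr, topo, **vbur_kwargs)
        except GeometryError as exc:
            skipped.append((fr.frame_index, str(exc)))
            row.setdefault("d_re", math.nan)
            row.setdefault("d_si", math.nan)
        rows.append(row)
    table = pd.DataFrame(rows)
    return DescriptorSeries(
        table=table,
        skipped=skipped,
        params={"ambiguity_band": ambiguity_band, "include_vbur": include_vbur},
    )


def buried_volume(
    frame: Frame,
    topo: TopologyMap | None = None,
    sphere_radius: float = 3.5,
    center: str | np.ndarray = "carbene_rh",
    mesh: float = 0.1,
    radii_scale: float = 1.17,
    include_hydrogens: bool = False,
    hemisphere: str | None = None,
    exclude: Sequence[int] | None = None,
) -> float:
    """Percent buried volume of the probe sphere, %Vbur.

    Fraction (×100) of grid points inside the probe sphere that fall within
    any non-excluded atom's scaled van der Waals sphere. Excluded atoms
    default to the two Rh atoms of the topology map; ``center`` is
    ``"carbene_rh"``, ``"carbene_c"`` or an explicit 3-vector.
    ``hemisphere="Re"``/``"Si"`` restricts the probe to one prochiral
    half-sphere (requires a topology map).
    """
    if sphere_radius <= 0:
        raise ValueError("sphere_radius must be positive")
    if mesh > sphere_radius / 5:
        raise ValueError("mesh must be at most sphere_radius / 5")

    if isinstance(center, str):
        if topo is None:
            raise ValueError("named center requires a topology map")
        if center == "carbene_rh":
            c0 = frame.coords[topo.rh_carbene]
        elif center == "carbene_c":
            c0 = frame.coords[topo.carbene_c]
        else:
            raise ValueError(f"unknown center {center!r}")
    else:
        c0 = np.asarray(center, float)

    if exclude is None:
        exclude = (topo.rh_carbene, topo.rh_distal) if topo is not None else ()
    excluded = set(exclude)

    # cell-centred grid over the bounding cube
    n_cells = int(math.ceil(2 * sphere_radius / mesh))
    axis = (np.arange(n_cells) + 0.5) * mesh - sphere_radius
    gx, gy, gz = np.meshgrid(axis, axis, axis, indexing="ij")
    pts = np.column_stack([gx.ravel(), gy.ravel(), gz.ravel()])
    inside = np.einsum("ij,ij->i", pts, pts) <= sphere_radius**2
    pts = pts[inside] + c0

    if hemisphere is not None:
        from .geometry import carbene_plane

        if topo is None:
            raise ValueError("hemisphere selection requires a topology map")
        n_re, plane_point = carbene_plane(frame, topo)
        side = (pts - plane_point) @ n_re
        pts = pts[side >= 0] if hemisphere == "Re" else pts[side < 0]

    n_probe = len(pts)
    if n_probe == 0:
        return 0.0
    covered = np.zeros(n_probe, dtype=bool)
    for a, (el, pos) in enumerate(zip(frame.elements, frame.coords)):
        if a in excluded:
            continue
        if not include_hydrogens and el in ("H", "D"):
            continue
        r = BONDI_RADII.get(el, _DEFAULT_VDW) * radii_scale
        if np.linalg.norm(pos - c0) > sphere_radius + r:
            continue
        d2 = np.einsum("ij,ij->i", pts - pos, pts - pos)
        covered |= d2 <= r * r
    return 100.0 * covered.sum() / n_probe
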