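"""Vector geometry for paddlewheel–carbene complexes.

The central construct is the prochiral face split of the trigonal carbene
carbon. The carbene plane is fit through the carbene carbon and its three
substituent anchors (the carbene-bearing Rh, the ester carbonyl carbon and
the donor-ring ipso carbon) by least squares, which tolerates the slight
pyramidalization seen in MD snapshots. The Re side is the side from which
the fixed priority sequence Rh > ester carbon > aryl carbon appears
clockwise — the standard face nomenclature, hard-coded for this chemotype
(Rh wins on atomic number; the ester carbon outranks the aryl carbon via
its (O,O,O) duplicated-atom set) instead of running a full CIP engine.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .errors import GeometryError
from .io import Frame, TopologyMap

__all__ = [
    "FaceAssignment",
    "AMBIGUITY_BAND",
    "centroid",
    "dihedral",
    "dihedral_coords",
    "carbene_plane",
    "assign_face",
]

#: Default half-width (Å) of the near-plane band in which a query point is
#: reported as "ambiguous" rather than Re or Si.
AMBIGUITY_BAND = 0.5

_COLLINEAR_TOL = 1e-10


@dataclass(frozen=True)
class FaceAssignment:
    """Face label of a point relative to the carbene plane.

    ``signed_offset`` is the distance (Å) from the plane, positive toward
    the Re side; ``face`` is ``"ambiguous"`` exactly when ``|signed_offset|``
    is below the ambiguity band.
    """

    face: str  # "Re" | "Si" | "ambiguous"
    signed_offset: float


def centroid(frame: Frame, atom_ids: Sequence[int]) -> np.ndarray:
    """Unweighted arithmetic mean of the selected atom coordinates (Å)."""
    ids = list(atom_ids)
    if not ids:
        raise GeometryError("centroid of an empty atom selection")
    return frame.coords[ids].mean(axis=0)


def dihedral_coords(
    p0: np.ndarray, p1: np.ndarray, p2: np.ndarray, p3: np.ndarray
) -> float:
    """Torsion angle p0–p1–p2–p3 in degrees, range (−180, 180].

    IUPAC sign convention: looking from p1 toward p2, a clockwise rotation
    from the p0 half-plane to the p3 half-plane is positive; cis = 0°,
    trans = 180°.
    """
    b1 = np.asarray(p1, float) - np.asarray(p0, float)
    b2 = np.asarray(p2, float) - np.asarray(p1, float)
    b3 = np.asarray(p3, float) - np.asarray(p2, float)
    c1 = np.cross(b1, b2)
    c2 = np.cross(b2, b3)
    n1 = np.linalg.norm(c1)
    n2 = np.linalg.norm(c2)
    nb2 = np.linalg.norm(b2)
    if nb2 < _COLLINEAR_TOL or n1 < _COLLINEAR_TOL * max(1.0, nb2) or n2 < _COLLINEAR_TOL * max(1.0, nb2):
        raise GeometryError("undefined torsion: three consecutive atoms collinear")
    x = float(np.dot(c1, c2))
    y = float(np.dot(np.cross(c1, c2), b2 / nb2))
    ang = math.degrees(math.atan2(y, x))
    if ang <= -180.0:
        ang += 360.0
    return ang


def dihedral(frame: Frame, i: int, j: int, k: int, l: int) -> float:
    """Torsion angle over four atom indices of a frame (degrees)."""
    if len({i, j, k, l}) != 4:
        raise GeometryError("dihedral needs four distinct atom indices")
    c = frame.coords
    return dihedral_coords(c[i], c[j], c[k], c[l])


def _orient_re_normal(
    carbene: np.ndarray,
    rh: np.ndarray,
    ester: np.ndarray,
    aryl: np.ndarray,
) -> tuple[np.ndarray, np.ndarray]:
    """Least-squares carbene plane with the normal oriented toward Re.

    Returns ``(unit_normal_toward_Re, plane_point)``. The orientation rule:
    project the three substituent directions into the plane; the sum of
    consecutive cross products gives the circulation sense of the sequence
    Rh → ester → aryl viewed from the +normal side. Counterclockwise from a
    side means the priorities appear clockwise from the *other* side, which
    is therefore Re.
    """
    pts = np.stack([carbene, rh, ester, aryl])
    point = pts.mean(axis=0)
    centered = pts - point
    _, s, vt = np.linalg.svd(centered)
    if s[1] < 1e-8:
        raise GeometryError("degenerate carbene plane: anchor atoms collinear")
    normal = vt[2]
    dirs = []
    for sub in (rh, ester, aryl):
        v = sub - carbene
        v = v - np.dot(v, normal) * normal  # in-plane component
        n = np.linalg.norm(v)
        if n < 1e-8:
            raise GeometryError("degenerate carbene plane: substituent along normal")
        dirs.append(v / n)
    w = 0.0
    for a in range(3):
        w += float(np.dot(np.cross(dirs[a], dirs[(a + 1) % 3]), normal))
    if abs(w) < 1e-8:
        raise GeometryError("degenerate carbene plane: zero circulation")
    n_re = -normal if w > 0 else normal
    return n_re, point


def carbene_plane(frame: Frame, topo: TopologyMap) -> tuple[np.ndarray, np.ndarray]:
    """Carbene plane as ``(unit normal toward Re, plane point)``.

    The plane is the least-squares fit through the carbene carbon, the
    carbene-bearing Rh, the ester carbonyl carbon and the donor-ring ipso
    carbon (first index of ``aryl_ring``).
    """
    c = frame.coords
    return _orient_re_normal(
        c[topo.carbene_c],
        c[topo.rh_carbene],
        c[topo.ester_c],
        c[topo.aryl_ring[0]],
    )


def assign_face(
    frame: Frame,
    topo: TopologyMap,
    point: np.ndarray,
    ambiguity_band: float = AMBIGUITY_BAND,
) -> FaceAssignment:
    """Assign a query point to the Re or Si face of the carbene.

    Points within ``ambiguity_band`` Å of the plane are labelled
    ``"ambiguous"``; mirror-reflecting all coordinates (and the point) swaps
    Re and Si while preserving ``|signed_offset|``.
    """
    n_re, plane_point = carbene_plane(frame, topo)
    offset = float(np.dot(np.asarray(point, float) - plane_point, n_re))
    if abs(offset) < ambiguity_band:
        face = "ambiguous"
    else:
        face = "Re" if offset > 0 else "Si"
    return FaceAssignment(face=face, signed_offset=offset)
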