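"""Reading and writing multi-frame structures, topology maps and result tables.

Coordinates are Cartesian angstroms throughout. Trajectories are either
multi-frame XYZ (count / comment / atom-line blocks, read and written here)
or multi-model PDB (MODEL/ENDMDL, parsed through biotite). The topology map
is a small JSON document that binds atom indices (1-based, file order — the
way structure viewers count) to the roles of the paddlewheel/carbene model:
the two Rh atoms, the carbene carbon with its ester and donor-ring
substituents, and the four carboxylate arms with their rotation dihedrals
and blocking rings.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import TopologyError, TrajectoryError

__all__ = [
    "Frame",
    "Trajectory",
    "Arm",
    "TopologyMap",
    "read_trajectory",
    "write_trajectory_xyz",
    "read_topology_map",
    "topology_map_from_dict",
    "write_topology_map",
    "write_table",
]


@dataclass(frozen=True)
class Frame:
    """One snapshot: element symbols plus an (n_atoms, 3) coordinate array in Å."""

    elements: tuple[str, ...]
    coords: np.ndarray
    frame_index: int = 0
    comment: str = ""

    def __post_init__(self) -> None:
        coords = np.asarray(self.coords, dtype=float)
        if coords.ndim != 2 or coords.shape[1] != 3:
            raise TrajectoryError(f"coords must be (n, 3), got {coords.shape}")
        if coords.shape[0] != len(self.elements):
            raise TrajectoryError(
                f"{len(self.elements)} elements but {coords.shape[0]} coordinate rows"
            )
        if not np.all(np.isfinite(coords)):
            raise TrajectoryError("non-finite coordinates in frame")
        if any(not el for el in self.elements):
            raise TrajectoryError("empty element symbol")
        object.__setattr__(self, "coords", coords)
        object.__setattr__(self, "elements", tuple(self.elements))

    @property
    def n_atoms(self) -> int:
        return len(self.elements)


@dataclass(frozen=True)
class Trajectory:
    """An ordered list of frames with uniform atom count and element order."""

    frames: tuple[Frame, ...]
    source: str = ""

    def __post_init__(self) -> None:
        frames = tuple(self.frames)
        if not frames:
            raise TrajectoryError("trajectory must contain at least one frame")
        ref = frames[0]
        for fr in frames[1:]:
            if fr.n_atoms != ref.n_atoms:
                raise TrajectoryError(
                    f"frame {fr.frame_index} has {fr.n_atoms} atoms, "
                    f"expected {ref.n_atoms}"
                )
            if fr.elements != ref.elements:
                raise TrajectoryError(
                    f"frame {fr.frame_index} element order differs from frame "
                    f"{ref.frame_index}"
                )
        object.__setattr__(self, "frames", frames)

    def __len__(self) -> int:
        return len(self.frames)

    def __iter__(self):
        return iter(self.frames)

    def __getitem__(self, i: int) -> Frame:
        return self.frames[i]

    @property
    def n_atoms(self) -> int:
        return self.frames[0].n_atoms


@dataclass(frozen=True)
class Arm:
    """Role annotation for one carboxylate arm (indices 0-based internally)."""

    carboxylate_c: int
    alpha_c: int
    dihedral_quad: tuple[int, int, int, int]
    blocking_ring: tuple[int, ...]
    imide_group: tuple[int, ...]


@dataclass(frozen=True)
class TopologyMap:
    """Atom-role annotation of a paddlewheel–carbene complex.

    ``theta_ref_deg`` holds the per-arm reference dihedral for the unrotated
    carboxylate orientation; when ``None`` it is resolved from the first
    frame of the trajectory being analyzed.
    """

    rh_carbene: int
    rh_distal: int
    carbene_c: int
    ester_c: int
    aryl_ring: tuple[int, ...]
    arms: tuple[Arm, Arm, Arm, Arm]
    theta_ref_deg: tuple[float, float, float, float] | None = None

    def __post_init__(self) -> None:
        if len(self.arms) != 4:
            raise TopologyError("exactly 4 arms required")
        if len(self.aryl_ring) < 5:
            raise TopologyError("aryl_ring_idx needs at least 5 atoms")
        for a, arm in enumerate(self.arms):
            if len(arm.blocking_ring) < 5:
                raise TopologyError(f"arm {a}: blocking_ring_idx needs ≥5 atoms")
            if not arm.imide_group:
                raise TopologyError(f"arm {a}: imide_group_idx is empty")
            if len(arm.dihedral_quad) != 4:
                raise TopologyError(f"arm {a}: dihedral_quad must have 4 indices")
            if arm.dihedral_quad[1:3] != (arm.carboxylate_c, arm.alpha_c):
                raise TopologyError(
                    f"arm {a}: dihedral_quad middle pair must be "
                    "(carboxylate_c_idx, alpha_c_idx)"
                )
        if self.theta_ref_deg is not None and len(self.theta_ref_deg) != 4:
            raise TopologyError("theta_ref_deg must list one angle per arm")

    @property
    def all_indices(self) -> tuple[int, ...]:
        idx = [self.rh_carbene, self.rh_distal, self.carbene_c, self.ester_c]
        idx.extend(self.aryl_ring)
        for arm in self.arms:
            idx.extend((arm.carboxylate_c, arm.alpha_c))
            idx.extend(arm.dihedral_quad)
            idx.extend(arm.blocking_ring)
            idx.extend(arm.imide_group)
        return tuple(idx)

    def validate_against(self, n_atoms: int) -> None:
        bad = [i for i in self.all_indices if not (0 <= i < n_atoms)]
        if bad:
            raise TopologyError(
                f"atom indices out of range for {n_atoms}-atom frame: "
                f"{sorted({i + 1 for i in bad})} (1-based)"
            )

    def with_theta_ref(self, theta_ref_deg: Sequence[float]) -> "TopologyMap":
        return replace(self, theta_ref_deg=tuple(float(t) for t in theta_ref_deg))


# ---------------------------------------------------------------------------
# trajectory reading


def _read_xyz(path: Path) -> Trajectory:
    frames: list[Frame] = []
    with open(path) as fh:
        lines = fh.readlines()
    pos = 0
    n_lines = len(lines)
    frame_index = 0
    while pos < n_lines:
        if not lines[pos].strip():  # trailing blank lines
            pos += 1
            continue
        try:
            n_atoms = int(lines[pos].split()[0])
        except (ValueError, IndexError):
            raise TrajectoryError(
                f"{path}:{pos + 1}: expected atom count, got {lines[pos]!r}"
            )
        if frames and n_atoms != frames[0].n_atoms:
            raise TrajectoryError(
                f"{path}: frame {frame_index + 1} has {n_atoms} atoms, "
                f"expected {frames[0].n_atoms}"
            )
        if pos + 1 + n_atoms >= n_lines + 1:
            raise TrajectoryError(
                f"{path}: frame {frame_index + 1} truncated "
                f"(needs {n_atoms} atom lines)"
            )
        comment = lines[pos + 1].rstrip("\n")
        elements: list[str] = []
        coords = np.empty((n_atoms, 3))
        for a in range(n_atoms):
            ln = pos + 2 + a
            parts = lines[ln].split()
            if len(parts) < 4:
                raise TrajectoryError(f"{path}:{ln + 1}: unparseable atom line")
            try:
                coords[a] = [float(parts[1]), float(parts[2]), float(parts[3])]
            except ValueError:
                raise TrajectoryError(
                    f"{path}:{ln + 1}: unparseable coordinates {parts[1:4]}"
                )
            elements.append(parts[0])
        frames.append(
            Frame(tuple(elements), coords, frame_index=frame_index, comment=comment)
        )
        frame_index += 1
        pos += 2 + n_atoms
    if not frames:
        raise TrajectoryError(f"{path}: no frames found")
    try:
        return Trajectory(tuple(frames), source=str(path))
    except TrajectoryError as exc:
        raise TrajectoryError(f"{path}: {exc}") from None


def _read_pdb(path: Path) -> Trajectory:
    from biotite.structure.io.pdb import PDBFile

    try:
        pdb = PDBFile.read(str(path))
        stack = pdb.get_structure(model=None)
    except Exception as exc:  # biotite raises several types for bad models
        raise TrajectoryError(f"{path}: cannot parse PDB ({exc})") from exc
    elements = tuple(el.capitalize() for el in stack.element)
    coords = np.asarray(stack.coord, dtype=float)
    if coords.ndim == 2:  # single model
        coords = coords[None]
    frames = tuple(
        Frame(elements, coords[m], frame_index=m) for m in range(coords.shape[0])
    )
    return Trajectory(frames, source=str(path))


def _sniff_format(path: Path) -> str:
    with open(path) as fh:
        for line in fh:
            token = line.split()[0] if line.split() else ""
            if not token:
                continue
            if token.isdigit():
                return "xyz"
            if token.upper() in {
                "MODEL", "ATOM", "HETATM", "HEADER", "REMARK", "CRYST1", "TITLE",
            }:
                return "pdb"
            break
    raise TrajectoryError(f"{path}: cannot auto-detect format (use format=...)")


def read_trajectory(path: str | Path, format: str = "auto") -> Trajectory:
    """Read a multi-frame XYZ or multi-model PDB file into a :class:`Trajectory`.

    Frames come back in file order with elements and coordinates preserved to
    input precision. ``format="auto"`` detects by extension, then by sniffing
    the first meaningful line.
    """
    path = Path(path)
    if not path.is_file():
        raise TrajectoryError(f"no such file: {path}")
    fmt = format.lower()
    if fmt == "auto":
        suffix = path.suffix.lower()
        if suffix in {".pdb", ".ent"}:
            fmt = "pdb"
        elif suffix == ".xyz":
            fmt = "xyz"
        else:
            fmt = _sniff_format(path)
    if fmt == "xyz":
        return _read_xyz(path)
    if fmt == "pdb":
        return _read_pdb(path)
    raise TrajectoryError(f"unknown trajectory format {format!r}")


def write_trajectory_xyz(traj: Trajectory, path: str | Path) -> None:
    """Write a trajectory as concatenated XYZ blocks (comments preserved)."""
    path = Path(path)
    with open(path, "w") as fh:
        for fr in traj:
            fh.write(f"{fr.n_atoms}\n")
            fh.write((fr.comment or f"frame {fr.frame_index}") + "\n")
            for el, (x, y, z) in zip(fr.elements, fr.coords):
                fh.write(f"{el:<3s} {x:18.10f} {y:18.10f} {z:18.10f}\n")


# ---------------------------------------------------------------------------
# topology map


_ARM_KEYS = (
    "carboxylate_c_idx",
    "alpha_c_idx",
    "dihedral_quad",
    "blocking_ring_idx",
    "imide_group_idx",
)


def topology_map_from_dict(doc: Mapping, n_atoms: int | None = None) -> TopologyMap:
    """Build a validated :class:`TopologyMap` from a 1-based JSON-style mapping."""

    def need(key: str, src: Mapping = doc, where: str = "topology map"):
        if key not in src:
            raise TopologyError(f"{where}: missing field {key!r}")
        return src[key]

    def to0(value) -> int:
        i = int(value)
        if i < 1:
            raise TopologyError(f"atom index {i} is not 1-based positive")
        return i - 1

    arms_doc = need("arms")
    if len(arms_doc) != 4:
        raise TopologyError("exactly 4 arms required")
    arms = []
    for a, arm_doc in enumerate(arms_doc):
        for key in _ARM_KEYS:
            need(key, arm_doc, f"arm {a + 1}")
        arms.append(
            Arm(
                carboxylate_c=to0(arm_doc["carboxylate_c_idx"]),
                alpha_c=to0(arm_doc["alpha_c_idx"]),
                dihedral_quad=tuple(to0(i) for i in arm_doc["dihedral_quad"]),
                blocking_ring=tuple(to0(i) for i in arm_doc["blocking_ring_idx"]),
                imide_group=tuple(to0(i) for i in arm_doc["imide_group_idx"]),
            )
        )
    theta_ref = doc.get("theta_ref_deg")
    topo = TopologyMap(
        rh_carbene=to0(need("rh_carbene_idx")),
        rh_distal=to0(need("rh_distal_idx")),
        carbene_c=to0(need("carbene_c_idx")),
        ester_c=to0(need("ester_c_idx")),
        aryl_ring=tuple(to0(i) for i in need("aryl_ring_idx")),
        arms=tuple(arms),
        theta_ref_deg=None if theta_ref is None else tuple(float(t) for t in theta_ref),
    )
    if n_atoms is not None:
        topo.validate_against(n_atoms)
    return topo


def read_topology_map(path: str | Path, n_atoms: int | None = None) -> TopologyMap:
    """Read a topology-map JSON file (1-based indices, converted internally)."""
    path = Path(path)
    if not path.is_file():
        raise TopologyError(f"no such file: {path}")
    with open(path) as fh:
        try:
            doc = json.load(fh)
        except json.JSONDecodeError as exc:
            raise TopologyError(f"{path}: invalid JSON ({exc})") from exc
    return topology_map_from_dict(doc, n_atoms=n_atoms)


def topology_map_to_dict(topo: TopologyMap) -> dict:
    """Serialize back to the 1-based JSON schema."""
    doc = {
        "rh_carbene_idx": topo.rh_carbene + 1,
        "rh_distal_idx": topo.rh_distal + 1,
        "carbene_c_idx": topo.carbene_c + 1,
        "ester_c_idx": topo.ester_c + 1,
        "aryl_ring_idx": [i + 1 for i in topo.aryl_ring],
        "arms": [
            {
                "carboxylate_c_idx": arm.carboxylate_c + 1,
                "alpha_c_idx": arm.alpha_c + 1,
                "dihedral_quad": [i + 1 for i in arm.dihedral_quad],
                "blocking_ring_idx": [i + 1 for i in arm.blocking_ring],
                "imide_group_idx": [i + 1 for i in arm.imide_group],
            }
            for arm in topo.arms
        ],
    }
    if topo.theta_ref_deg is not None:
        doc["theta_ref_deg"] = list(topo.theta_ref_deg)
    return doc


def write_topology_map(
    topo: TopologyMap, path: str | Path, metadata: Mapping | None = None
) -> None:
    doc = topology_map_to_dict(topo)
    if metadata:
        doc["_metadata"] = dict(metadata)
    with open(path, "w") as fh:
        json.dump(doc, fh, indent=2, ensure_ascii=False)
        fh.write("\n")


# ---------------------------------------------------------------------------
# tabular results


def write_table(
    records,
    path: str | Path,
    format: str | None = None,
    metadata: Mapping | None = None,
) -> None:
    """Write results as CSV or JSON.

    ``records`` may be a DataFrame, a list of homogeneous dicts (→ rows), or a
    plain mapping (→ JSON object, e.g. label → fraction). Floats keep at least
    six significant digits so files round-trip with standard readers. An
    optional ``metadata`` mapping is embedded: as a ``_metadata`` key in JSON,
    as a single leading ``#`` comment line in CSV (read back with
    ``pandas.read_csv(..., comment="#")``).
    """
    path = Path(path)
    fmt = (format or path.suffix.lstrip(".")).lower()
    if fmt == "csv":
        if isinstance(records, Mapping):
            df = pd.DataFrame([records])
        elif isinstance(records, pd.DataFrame):
            df = records
        else:
            df = pd.DataFrame(list(records))
        with open(path, "w") as fh:
            if metadata:
                fh.write("# " + json.dumps(dict(metadata), ensure_ascii=False) + "\n")
            df.to_csv(fh, index=False, float_format="%.8g")
    elif fmt == "json":
        if isinstance(records, pd.DataFrame):
            payload = records.to_dict(orient="records")
        elif isinstance(records, Mapping):
            payload = dict(records)
        else:
            payload = list(records)
        if metadata:
            if isinstance(payload, dict):
                payload["_metadata"] = dict(metadata)
            else:
                payload = {"records": payload, "_metadata": dict(metadata)}
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2, ensure_ascii=False, allow_nan=True)
            fh.write("\n")
    else:
        raise ValueError(f"unknown table format {fmt!r} (use csv or json)")
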