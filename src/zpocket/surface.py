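"""Molecular-surface point clouds, from DMS files or an internal builder.

Each surface point is attributed to the atom (and hence residue) that
generated it, which is what lets patches be cut by residue selection.  The
surface source is pluggable: parse the output of the external DMS program,
or build a solvent-excluded-surface approximation directly from the atoms
so the whole pipeline runs without external software.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.spatial import cKDTree

from .structure_io import MolecularStructure, ResidueId

__all__ = [
    "SurfacePointCloud",
    "VDW_RADII",
    "DEFAULT_PROBE",
    "DEFAULT_DENSITY",
    "DmsParseError",
    "read_dms",
    "write_dms",
    "build_surface",
]

#: van der Waals radii in Angstrom by element; fallback used for the rest
VDW_RADII = {"C": 1.7, "N": 1.55, "O": 1.52, "S": 1.8, "H": 1.2, "P": 1.8}
DEFAULT_VDW = 1.7
DEFAULT_PROBE = 1.4  # water-sized probe sphere, Angstrom
DEFAULT_DENSITY = 3.0  # surface points per square Angstrom


class DmsParseError(ValueError):
    pass


@dataclass
class SurfacePointCloud:
    """Surface sample points attributed to generating atoms of a structure.

    ``atom_index[i]`` indexes into ``structure.atoms`` for point ``i``;
    residue attribution is derived from it and nothing else.
    """

    positions: np.ndarray
    atom_index: np.ndarray
    structure: MolecularStructure
    source: str = "internal"
    normals: np.ndarray | None = None

    def __post_init__(self):
        self.positions = np.asarray(self.positions, dtype=float).reshape(-1, 3)
        self.atom_index = np.asarray(self.atom_index, dtype=int)
        if len(self.positions) == 0:
            raise ValueError("surface cloud must contain at least one point")
        if self.atom_index.shape != (len(self.positions),):
            raise ValueError("atom_index must align with positions")
        n_atoms = len(self.structure.atoms)
        if self.atom_index.min() < 0 or self.atom_index.max() >= n_atoms:
            raise ValueError("atom_index refers outside the source structure")
        if self.normals is not None:
            self.normals = np.asarray(self.normals, dtype=float).reshape(-1, 3)
            norms = np.linalg.norm(self.normals, axis=1)
            if np.any(np.abs(norms - 1.0) > 1e-6):
                raise ValueError("normals must be unit vectors")

    def __len__(self) -> int:
        return len(self.positions)

    @property
    def residue_ids(self) -> list[ResidueId]:
        atoms = self.structure.atoms
        return [atoms[i].residue_id for i in self.atom_index]

    def subset(self, mask: np.ndarray) -> "SurfacePointCloud":
        mask = np.asarray(mask, dtype=bool)
        return SurfacePointCloud(
            self.positions[mask],
            self.atom_index[mask],
            self.structure,
            source=self.source,
            normals=None if self.normals is None else self.normals[mask],
        )


def vdw_radius(element: str) -> float:
    r = VDW_RADII.get(element.capitalize())
    if r is None:
        warnings.warn(f"unknown element {element!r}: using default vdW radius "
                      f"{DEFAULT_VDW} A", stacklevel=2)
        r = DEFAULT_VDW
    return r


def read_dms(path, structure: MolecularStructure, strict: bool = True) -> SurfacePointCloud:
    """Parse a DMS surface file, resolving each point to an atom of ``structure``.

    DMS lines carry residue name, residue number, atom name, x, y, z and a
    type field; type ``A`` marks atom centers (skipped), types beginning
    with ``S`` mark surface points.  In strict mode an unresolvable
    (residue number, atom name) reference raises with its line number; in
    lenient mode the point is dropped with a warning.
    """
    lookup: dict[tuple[int, str], int] = {}
    for i, a in enumerate(structure.atoms):
        lookup.setdefault((a.residue_id[1], a.name), i)

    positions, indices, normals = [], [], []
    has_normals = True
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        parts = line.split()
        if len(parts) < 7:
            continue
        resname, resnum_s, atom_name = parts[0], parts[1], parts[2]
        try:
            resnum = int(resnum_s)
            xyz = [float(v) for v in parts[3:6]]
        except ValueError as exc:
            raise DmsParseError(f"{path}:{lineno}: malformed DMS line") from exc
        ptype = parts[6]
        if not ptype.upper().startswith("S"):
            continue  # atom-center line
        idx = lookup.get((resnum, atom_name))
        if idx is None:
            msg = (f"{path}:{lineno}: surface point references unknown atom "
                   f"{resname} {resnum} {atom_name}")
            if strict:
                raise DmsParseError(msg)
            warnings.warn(msg + " (dropped)", stacklevel=2)
            continue
        positions.append(xyz)
        indices.append(idx)
        if len(parts) >= 11:
            normals.append([float(v) for v in parts[8:11]])
        else:
            has_normals = False
    if not positions:
        raise DmsParseError(f"{path}: no resolvable surface points")
    return SurfacePointCloud(
        np.array(positions), np.array(indices), structure, source="dms_file",
        normals=np.array(normals) if has_normals and normals else None,
    )


def write_dms(cloud: SurfacePointCloud, path) -> None:
    """Write a cloud in the DMS surface-point dialect read by :func:`read_dms`."""
    atoms = cloud.structure.atoms
    lines = []
    for pos, idx in zip(cloud.positions, cloud.atom_index):
        a = atoms[idx]
        lines.append(
            f"{a.residue_name:<4s}{a.residue_id[1]:>5d} {a.name:<4s}"
            f"{pos[0]:9.3f}{pos[1]:9.3f}{pos[2]:9.3f} SR0"
        )
    Path(path).write_text("\n".join(lines) + "\n")


def _fibonacci_sphere(n: int) -> np.ndarray:
    """Nearly uniform unit directions by the Fibonacci spiral lattice."""
    i = np.arange(n) + 0.5
    z = 1.0 - 2.0 * i / n
    phi = np.pi * (1.0 + np.sqrt(5.0)) * i
    s = np.sqrt(np.maximum(0.0, 1.0 - z * z))
    return np.column_stack([s * np.cos(phi), s * np.sin(phi), z])


def _intrinsic_frame(coords: np.ndarray) -> np.ndarray:
    """Right-handed orthonormal frame from the coordinate covariance.

    Sampling directions are expressed in this frame so that rotating the
    structure co-rotates the sampled surface (equivariance).  Eigenvector
    signs are fixed by the third coordinate moment; for (near-)degenerate
    geometries such as a single atom the frame falls back to the identity.
    """
    centered = coords - coords.mean(axis=0)
    if len(coords) < 3:
        return np.eye(3)
    cov = centered.T @ centered / len(coords)
    evals, evecs = np.linalg.eigh(cov)
    if evals[-1] < 1e-9 or np.min(np.diff(evals)) < 1e-6 * max(evals[-1], 1.0):
        return np.eye(3)
    for k in range(3):
        proj = centered @ evecs[:, k]
        skew = np.sum(proj**3)
        if abs(skew) > 1e-9 and skew < 0:
            evecs[:, k] = -evecs[:, k]
    if np.linalg.det(evecs) < 0:
        evecs[:, 2] = -evecs[:, 2]
    return evecs


def build_surface(
    structure: MolecularStructure,
    probe_radius: float = DEFAULT_PROBE,
    point_density: float = DEFAULT_DENSITY,
    seed: int = 0,
) -> SurfacePointCloud:
    """Approximate the solvent-excluded surface by sphere sampling.

    Points are sampled on each atom's solvent-accessible sphere of radius
    ``vdW + probe``, points falling strictly inside any other atom's
    inflated sphere are discarded, and survivors are retracted by the probe
    radius toward their generating atom, landing on the vdW envelope.  The
    per-atom sampling lattice is deterministic given ``seed`` and expressed
    in a structure-intrinsic frame, so rotating the structure rotates the
    cloud.
    """
    if probe_radius <= 0 or point_density <= 0:
        raise ValueError("probe_radius and point_density must be positive")
    coords = structure.coordinates
    radii = np.array([vdw_radius(a.element) for a in structure.atoms])
    inflated = radii + probe_radius
    frame = _intrinsic_frame(coords)
    rng = np.random.default_rng(seed)
    # one shared random twist of the lattice, applied inside the intrinsic frame
    angle = rng.uniform(0, 2 * np.pi)
    ca, sa = np.cos(angle), np.sin(angle)
    twist = np.array([[ca, -sa, 0.0], [sa, ca, 0.0], [0.0, 0.0, 1.0]])

    tree = cKDTree(coords)
    positions, indices = [], []
    for i, (center, r_sas) in enumerate(zip(coords, inflated)):
        n_pts = max(8, int(round(point_density * 4.0 * np.pi * r_sas**2)))
        dirs = _fibonacci_sphere(n_pts) @ twist.T @ frame.T
        pts = center + r_sas * dirs
        neighbors = tree.query_ball_point(center, r_sas + inflated.max())
        keep = np.ones(len(pts), dtype=bool)
        for j in neighbors:
            if j == i:
                continue
            d = np.linalg.norm(pts - coords[j], axis=1)
            keep &= d >= inflated[j] - 1e-9
        if keep.any():
            # retract surviving SAS points onto the vdW sphere of the atom
            positions.append(center + radii[i] * dirs[keep])
            indices.append(np.full(keep.sum(), i))
    if not positions:
        raise ValueError("structure has no accessible surface at this probe radius")
    return SurfacePointCloud(
        np.vstack(positions), np.concatenate(indices), structure, source="internal"
    )
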