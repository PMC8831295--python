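"""Synthetic fixtures: toy protein-ligand complexes, shapes, rotations.

The toy complex emulates the geometry the binding-site benchmark needs: a
pseudo-protein whose alpha carbons sit on a jittered spherical shell, with
a concave pocket carved as the negative imprint of a small ligand blob.
At ``complementarity = 1`` the pocket wall hugs the ligand surface across
a thin solvent gap; lowering the parameter blends the pocket wall back
toward the convex shell, degrading the shape match continuously.  All
randomness flows from a single integer seed, so every fixture regenerates
bit-identically.

These are geometric caricatures: single-atom residues, no backbone
chemistry, no flexibility.  They exercise the pipeline, not protein
physics.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple

import numpy as np
from scipy.stats import special_ortho_group

from .patches import ResidueSet, define_binding_site
from .structure_io import AtomRecord, MolecularStructure
from .surface import SurfacePointCloud, write_dms

__all__ = [
    "ToyComplexSpec",
    "ToyComplex",
    "make_toy_complex",
    "sample_shape",
    "SHAPE_KINDS",
    "random_rotation",
    "rotate_cloud",
    "write_dms_fixture",
]

# background amino-acid composition used to name pseudo-residues
_AA_NAMES = [
    "ALA", "ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "GLY", "HIS", "ILE",
    "LEU", "LYS", "MET", "PHE", "PRO", "SER", "THR", "TRP", "TYR", "VAL",
]
_AA_FREQS = np.array([
    8.3, 5.5, 4.0, 5.5, 1.4, 3.9, 6.8, 7.1, 2.3, 6.0,
    9.7, 5.8, 2.4, 3.9, 4.7, 6.6, 5.3, 1.1, 2.9, 6.9,
])
_AA_FREQS = _AA_FREQS / _AA_FREQS.sum()

_RESIDUE_AREA = 18.0  # shell area per pseudo-residue, A^2
_CA_VDW = 1.7
_CONTACT_GAP = 2.0  # pocket-wall Calpha offset beyond the ligand envelope, A
_IMPRINT_AREA = 13.0  # denser spacing on the pocket wall for a smooth bowl


@dataclass(frozen=True)
class ToyComplexSpec:
    """Generator conditions for one toy complex (deterministic per seed)."""

    n_residues: int = 80
    pocket_depth: float = 3.0
    ligand_radius: float = 3.0
    complementarity: float = 1.0
    noise_sd: float = 0.3
    seed: int = 0

    def __post_init__(self):
        if self.n_residues < 8:
            raise ValueError("need at least 8 shell residues")
        if not 0.0 <= self.complementarity <= 1.0:
            raise ValueError("complementarity must lie in [0, 1]")
        if self.ligand_radius <= 0 or self.pocket_depth < 0 or self.noise_sd < 0:
            raise ValueError("geometry parameters must be non-negative")


class ToyComplex(NamedTuple):
    protein: MolecularStructure
    ligand: MolecularStructure
    binding_site: ResidueSet | None


def _fibonacci_sphere(n: int) -> np.ndarray:
    i = np.arange(n) + 0.5
    z = 1.0 - 2.0 * i / n
    phi = np.pi * (1.0 + np.sqrt(5.0)) * i
    s = np.sqrt(np.maximum(0.0, 1.0 - z * z))
    return np.column_stack([s * np.cos(phi), s * np.sin(phi), z])


def _residue(serial: int, resnum: int, name: str, pos: np.ndarray) -> AtomRecord:
    return AtomRecord(
        serial=serial, name="CA", element="C", residue_name=name,
        residue_id=("A", resnum, ""), coordinates=pos, is_ca=True, is_heavy=True,
    )


def make_toy_complex(spec: ToyComplexSpec) -> ToyComplex:
    """Build a carved-pocket pseudo-protein and its complementary ligand blob.

    Returns the protein, the ligand, and the ground-truth binding site
    (residues with a Calpha strictly within 6 A of a ligand atom); the
    binding site is ``None`` in the degenerate ``complementarity = 0``
    mode, where the ligand is parked far from the protein and no pocket is
    carved.
    """
    rng = np.random.default_rng(spec.seed)
    shell_radius = np.sqrt(spec.n_residues * _RESIDUE_AREA / (4.0 * np.pi))
    if spec.ligand_radius + _CONTACT_GAP >= shell_radius:
        raise ValueError(
            f"ligand (radius {spec.ligand_radius} A) too large for a protein shell "
            f"of radius {shell_radius:.1f} A"
        )
    axis = _random_unit(rng)
    shell = _fibonacci_sphere(spec.n_residues) @ _rotation_onto(rng) * shell_radius
    shell = shell + rng.normal(0.0, spec.noise_sd, shell.shape)

    # ligand blob: one central atom plus a shell sized so the vdW envelope
    # reaches ligand_radius
    lig_shell_r = max(0.2, spec.ligand_radius - _CA_VDW)
    lig_dirs = _fibonacci_sphere(14) @ _rotation_onto(rng)
    if spec.complementarity == 0.0:
        lig_center = axis * (4.0 * shell_radius)
    else:
        lig_center = axis * (shell_radius - spec.pocket_depth)
    lig_xyz = np.vstack([lig_center, lig_center + lig_shell_r * lig_dirs])
    lig_xyz = lig_xyz + rng.normal(0.0, 0.25 * spec.noise_sd, lig_xyz.shape)

    positions = []
    if spec.complementarity > 0.0:
        r_imprint = spec.ligand_radius + _CONTACT_GAP
        clearance = r_imprint + 1.2
        keep = np.linalg.norm(shell - lig_center, axis=1) >= clearance
        positions.extend(shell[keep])
        # pocket wall: points on the imprint sphere that stay inside the body
        n_wall = int(round(4.0 * np.pi * r_imprint**2 / _IMPRINT_AREA))
        wall_dirs = _fibonacci_sphere(n_wall) @ _rotation_onto(rng)
        wall = lig_center + r_imprint * wall_dirs
        wall = wall[np.linalg.norm(wall, axis=1) <= shell_radius]
        if len(wall) == 0:
            raise ValueError("infeasible geometry: pocket wall lies outside the shell")
        # partial complementarity degrades the imprint two ways: the wall is
        # blended back toward the convex shell (the bowl flattens) and wall
        # roughness grows; the same normal draws are scaled for every level,
        # so the degradation is smooth in the parameter for a fixed seed
        flat = wall / np.linalg.norm(wall, axis=1, keepdims=True) * shell_radius
        wall = spec.complementarity * wall + (1.0 - spec.complementarity) * flat
        roughness = spec.noise_sd + 1.2 * (1.0 - spec.complementarity)
        wall = wall + roughness * rng.standard_normal(wall.shape)
        positions.extend(wall)
    else:
        positions.extend(shell)

    names = rng.choice(_AA_NAMES, size=len(positions), p=_AA_FREQS)
    atoms = [
        _residue(i + 1, i + 1, names[i], np.asarray(p))
        for i, p in enumerate(positions)
    ]
    protein = MolecularStructure(atoms, role="protein", label=f"toy-{spec.seed}")

    lig_atoms = [
        AtomRecord(serial=i + 1, name=f"C{i + 1}", element="C", residue_name="LIG",
                   residue_id=("L", 1, ""), coordinates=p, is_ca=False, is_heavy=True)
        for i, p in enumerate(lig_xyz)
    ]
    ligand = MolecularStructure(lig_atoms, role="ligand", label=f"toy-lig-{spec.seed}")

    binding_site = None
    if spec.complementarity > 0.0:
        binding_site = define_binding_site(protein, ligand)
    return ToyComplex(protein, ligand, binding_site)


def _random_unit(rng: np.random.Generator) -> np.ndarray:
    v = rng.normal(size=3)
    return v / np.linalg.norm(v)


def _rotation_onto(rng: np.random.Generator) -> np.ndarray:
    return special_ortho_group.rvs(3, random_state=rng)


SHAPE_KINDS = ("sphere", "ellipsoid", "dumbbell", "torus", "blob")


def sample_shape(kind: str, n_points: int = 20000, seed: int = 0) -> np.ndarray:
    """Sample a dense surface point cloud of a named reference shape.

    Shapes span distinct symmetry classes (sphere, ellipsoid, two-lobe
    dumbbell, torus, random smooth blob) for exercising the rotation
    invariance of the descriptors.
    """
    rng = np.random.default_rng(seed)
    u = rng.normal(size=(n_points, 3))
    u /= np.linalg.norm(u, axis=1, keepdims=True)
    if kind == "sphere":
        return 5.0 * u
    if kind == "ellipsoid":
        return u * np.array([6.0, 4.0, 2.5])
    if kind == "dumbbell":
        half = n_points // 2
        offs = np.array([0.0, 0.0, 3.2])
        return np.vstack([3.0 * u[:half] - offs, 3.0 * u[half:] + offs])
    if kind == "torus":
        t = rng.uniform(0, 2 * np.pi, n_points)
        p = rng.uniform(0, 2 * np.pi, n_points)
        R, r = 4.0, 1.5
        return np.column_stack([
            (R + r * np.cos(p)) * np.cos(t),
            (R + r * np.cos(p)) * np.sin(t),
            r * np.sin(p),
        ])
    if kind == "blob":
        # smooth radial perturbation of a sphere by a few random lobes
        centers = rng.normal(size=(4, 3))
        centers /= np.linalg.norm(centers, axis=1, keepdims=True)
        radius = 4.0 + 1.2 * np.sum(np.exp(3.0 * (u @ centers.T - 1.0)), axis=1)
        return radius[:, None] * u
    raise ValueError(f"unknown shape kind {kind!r}; choose from {SHAPE_KINDS}")


def random_rotation(seed: int) -> np.ndarray:
    """A uniformly distributed proper rotation matrix."""
    return special_ortho_group.rvs(3, random_state=np.random.default_rng(seed))


def rotate_cloud(obj, rotation: np.ndarray | None = None, seed: int | None = None):
    """Rigidly rotate a structure, cloud, or raw point array about its centroid."""
    if rotation is None:
        if seed is None:
            raise ValueError("supply a rotation matrix or a seed")
        rotation = random_rotation(seed)
    rotation = np.asarray(rotation, dtype=float)
    if rotation.shape != (3, 3) or not np.allclose(
        rotation @ rotation.T, np.eye(3), atol=1e-9
    ) or abs(np.linalg.det(rotation) - 1.0) > 1e-9:
        raise ValueError("rotation must be a proper orthonormal 3x3 matrix")

    def _spin(points: np.ndarray) -> np.ndarray:
        centroid = points.mean(axis=0)
        return (points - centroid) @ rotation.T + centroid

    if isinstance(obj, MolecularStructure):
        return obj.with_coordinates(_spin(obj.coordinates))
    if isinstance(obj, SurfacePointCloud):
        return SurfacePointCloud(
            _spin(obj.positions), obj.atom_index, obj.structure, source=obj.source
        )
    return _spin(np.asarray(obj, dtype=float))


def write_dms_fixture(cloud: SurfacePointCloud, path) -> None:
    """Write an attributed cloud as a DMS-dialect fixture file."""
    write_dms(cloud, path)
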