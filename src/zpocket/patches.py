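"""Binding sites, size-matched decoys, and residue-restricted surface patches.

The binding site (BS) of a complex is the set of residues whose alpha
carbon lies strictly within a cutoff (default 6 A) of any ligand atom.
Binding-site decoys (BSD) are residue-centered spherical regions whose
radius is chosen on a 6-20 A grid so that their mean residue count matches
the BS size — negative controls of comparable extent cut from the same
surface.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from .structure_io import MolecularStructure, ResidueId
from .surface import SurfacePointCloud

__all__ = [
    "ResidueSet",
    "Patch",
    "EmptyBindingSiteError",
    "EmptyPatchError",
    "define_binding_site",
    "residue_centered_set",
    "generate_decoys",
    "cut_patch",
]

DEFAULT_BS_CUTOFF = 6.0  # A, Calpha-to-any-ligand-atom
DEFAULT_PATCH_RADIUS = 9.0  # A, Calpha-to-Calpha for residue-centered patches
DECOY_RADIUS_GRID = (6.0, 20.0, 1.0)  # r_min, r_max, r_step in A


class EmptyBindingSiteError(ValueError):
    pass


class EmptyPatchError(ValueError):
    pass


@dataclass(frozen=True)
class ResidueSet:
    residues: frozenset[ResidueId]
    kind: str  # BS | BSD | residue_centered
    center_residue: ResidueId | None = None

    def __post_init__(self):
        object.__setattr__(self, "residues", frozenset(self.residues))
        if not self.residues:
            raise ValueError("residue set must be non-empty")
        if self.kind not in ("BS", "BSD", "residue_centered"):
            raise ValueError(f"unknown residue-set kind {self.kind!r}")
        if self.center_residue is not None and self.center_residue not in self.residues:
            raise ValueError("center residue must belong to the set")

    def __len__(self) -> int:
        return len(self.residues)


@dataclass
class Patch:
    """A residue set together with the surface points it generates."""

    residue_set: ResidueSet
    cloud: SurfacePointCloud
    patch_id: str = ""

    def __post_init__(self):
        if len(self.cloud) == 0:
            raise EmptyPatchError("patch cloud is empty")

    @property
    def positions(self) -> np.ndarray:
        return self.cloud.positions


def _ca_table(protein: MolecularStructure) -> tuple[list[ResidueId], np.ndarray]:
    cas = protein.ca_atoms()
    if not cas:
        raise ValueError("protein structure has no alpha carbons")
    return [a.residue_id for a in cas], np.array([a.coordinates for a in cas])


def define_binding_site(
    protein: MolecularStructure,
    ligand: MolecularStructure,
    cutoff: float = DEFAULT_BS_CUTOFF,
) -> ResidueSet:
    """Residues whose Calpha lies strictly within ``cutoff`` of any ligand atom."""
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    res_ids, ca_xyz = _ca_table(protein)
    lig_xyz = ligand.coordinates
    d = np.min(np.linalg.norm(ca_xyz[:, None, :] - lig_xyz[None, :, :], axis=2), axis=1)
    selected = {rid for rid, dist in zip(res_ids, d) if dist < cutoff}
    if not selected:
        raise EmptyBindingSiteError(
            f"no residue Calpha within {cutoff} A of the ligand"
        )
    return ResidueSet(frozenset(selected), kind="BS")


def residue_centered_set(
    protein: MolecularStructure,
    center: ResidueId,
    radius: float = DEFAULT_PATCH_RADIUS,
    kind: str = "residue_centered",
) -> ResidueSet:
    """Residues whose Calpha-Calpha distance to ``center`` is strictly below ``radius``."""
    if radius <= 0:
        raise ValueError("radius must be positive")
    res_ids, ca_xyz = _ca_table(protein)
    try:
        ci = res_ids.index(center)
    except ValueError:
        raise ValueError(f"center residue {center} has no alpha carbon") from None
    d = np.linalg.norm(ca_xyz - ca_xyz[ci], axis=1)
    selected = {rid for rid, dist in zip(res_ids, d) if dist < radius}
    selected.add(center)
    return ResidueSet(frozenset(selected), kind=kind, center_residue=center)


def generate_decoys(
    protein: MolecularStructure,
    binding_site: ResidueSet,
    cloud: SurfacePointCloud | None = None,
    r_min: float = DECOY_RADIUS_GRID[0],
    r_max: float = DECOY_RADIUS_GRID[1],
    r_step: float = DECOY_RADIUS_GRID[2],
    keep_overlapping: bool = False,
    return_radius: bool = False,
) -> list[ResidueSet]:
    """Size-matched decoy regions centered on every exposed Calpha.

    For each radius R on the grid, a candidate region is grown around every
    eligible residue; the radius R* whose mean region size is closest to
    the binding-site size is selected (ties to the smaller R), and the
    regions at R* are returned with kind ``BSD``.  Eligible centers are
    residues contributing at least one point to ``cloud`` when a surface is
    supplied (buried residues yield empty patches), all Calpha-bearing
    residues otherwise.  Decoys centered inside the true binding site are
    excluded unless ``keep_overlapping``.
    """
    res_ids, ca_xyz = _ca_table(protein)
    if cloud is not None:
        exposed = set(cloud.residue_ids)
        centers = [i for i, rid in enumerate(res_ids) if rid in exposed]
    else:
        centers = list(range(len(res_ids)))
    if not centers:
        raise ValueError("no eligible decoy centers")

    dmat = np.linalg.norm(ca_xyz[:, None, :] - ca_xyz[None, :, :], axis=2)
    radii = np.arange(r_min, r_max + 0.5 * r_step, r_step)
    target = len(binding_site)
    best_r, best_dev = None, None
    for r in radii:
        sizes = [(dmat[i] < r).sum() for i in centers]
        dev = abs(float(np.mean(sizes)) - target)
        if best_dev is None or dev < best_dev - 1e-12:
            best_r, best_dev = r, dev

    decoys = []
    for i in centers:
        rid = res_ids[i]
        if not keep_overlapping and rid in binding_site.residues:
            continue
        members = {res_ids[j] for j in np.nonzero(dmat[i] < best_r)[0]}
        members.add(rid)
        decoys.append(ResidueSet(frozenset(members), kind="BSD", center_residue=rid))
    if not decoys:
        raise ValueError("all candidate decoys overlap the binding site")
    if return_radius:
        return decoys, float(best_r)
    return decoys


def cut_patch(cloud: SurfacePointCloud, residue_set: ResidueSet, patch_id: str = "") -> Patch:
    """Subset of surface points whose generating residue belongs to the set."""
    residues = residue_set.residues
    mask = np.fromiter((rid in residues for rid in cloud.residue_ids),
                       dtype=bool, count=len(cloud))
    if not mask.any():
        raise EmptyPatchError("no surface point is attributed to the residue set")
    return Patch(residue_set, cloud.subset(mask), patch_id=patch_id)
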