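"""Shape-complementarity scoring between ligand and patch descriptors.

Two perfectly fitting surfaces share their shape and hence their Zernike
descriptors, so complementarity is scored as the Manhattan (L1) distance
between descriptor vectors — the lower the distance, the better the fit.
Within one receptor-ligand complex the distances of all patches (the true
binding site plus its decoys) are standardized to Z-scores; a strongly
negative Z-score of the binding site marks a specific interaction.
Associations between a ligand and a receptor's best pocket are called
against an empirical lower quantile of a background (non-association)
distance distribution, never against a fixed constant.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .zernike import ZernikeDescriptor

__all__ = [
    "ComplementarityRow",
    "ComplementarityTable",
    "AssociationCall",
    "manhattan_distance",
    "zscore_table",
    "best_pocket",
    "association_threshold",
    "call_association",
]

DEFAULT_QUANTILE = 0.05
MIN_BACKGROUND = 20


@dataclass(frozen=True)
class ComplementarityRow:
    patch_id: str
    kind: str  # BS | BSD | residue_centered
    distance: float
    zscore: float = math.nan


@dataclass
class ComplementarityTable:
    """Per-patch ligand distances with per-complex Z-scores."""

    ligand_id: str
    rows: list[ComplementarityRow]

    def distances(self) -> np.ndarray:
        return np.array([r.distance for r in self.rows])

    def zscores(self) -> np.ndarray:
        return np.array([r.zscore for r in self.rows])

    def row(self, kind: str) -> list[ComplementarityRow]:
        return [r for r in self.rows if r.kind == kind]

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "ligand_id": self.ligand_id,
                "patch_id": [r.patch_id for r in self.rows],
                "kind": [r.kind for r in self.rows],
                "distance": self.distances(),
                "zscore": self.zscores(),
            }
        )


@dataclass
class AssociationCall:
    ligand_id: str
    receptor_id: str
    best_patch_id: str
    distance: float
    threshold_used: float | None = None
    quality_gate_passed: bool = True
    is_association: bool | None = None
    tie: bool = False


def manhattan_distance(a: ZernikeDescriptor, b: ZernikeDescriptor) -> float:
    """L1 distance between two descriptor vectors of equal order."""
    va = a.values if isinstance(a, ZernikeDescriptor) else np.asarray(a, dtype=float)
    vb = b.values if isinstance(b, ZernikeDescriptor) else np.asarray(b, dtype=float)
    if va.shape != vb.shape:
        raise ValueError(f"descriptor length mismatch: {va.shape} vs {vb.shape}")
    return float(np.sum(np.abs(va - vb)))


def zscore_table(
    distances: list[tuple[str, str, float]], ligand_id: str = ""
) -> ComplementarityTable:
    """Standardize patch-ligand distances over the whole table.

    ``Z_i = (x_i - mean(x)) / sd(x)`` with the population standard
    deviation (divide by N), computed over all rows of the complex —
    binding site and decoys together.
    """
    if len(distances) < 2:
        raise ValueError("need at least two patch distances to standardize")
    x = np.array([d for _, _, d in distances], dtype=float)
    mu = x.mean()
    sigma = x.std()  # population (ddof=0)
    if sigma <= 0:
        raise ValueError("zero variance: all patch distances identical")
    z = (x - mu) / sigma
    rows = [
        ComplementarityRow(pid, kind, float(dist), float(zi))
        for (pid, kind, dist), zi in zip(distances, z)
    ]
    return ComplementarityTable(ligand_id=ligand_id, rows=rows)


def best_pocket(
    ligand: ZernikeDescriptor,
    patches: list,
    ligand_id: str = "",
    receptor_id: str = "",
) -> AssociationCall:
    """Patch with the minimal descriptor distance to the ligand.

    ``patches`` is a list of (patch_id, descriptor) pairs or Patch objects
    carrying a descriptor attribute.  Exact ties are broken by patch-id
    order and flagged on the returned call.
    """
    if not patches:
        raise ValueError("no patches to rank")
    entries = []
    for p in patches:
        if isinstance(p, tuple):
            pid, desc = p
        else:
            pid, desc = p.patch_id, p.descriptor
        entries.append((pid, manhattan_distance(ligand, desc)))
    entries.sort(key=lambda e: (e[1], e[0]))
    best_id, best_d = entries[0]
    tie = len(entries) > 1 and entries[1][1] == best_d
    return AssociationCall(
        ligand_id=ligand_id,
        receptor_id=receptor_id,
        best_patch_id=best_id,
        distance=best_d,
        tie=tie,
    )


def association_threshold(
    background_distances, quantile: float = DEFAULT_QUANTILE
) -> float:
    """Empirical lower-quantile bound of the non-association distance distribution.

    Type-1 empirical quantile: the ceil(q*N)-th smallest order statistic,
    no interpolation.  A dataset-dependent number — always recomputed from
    the supplied background, never fixed.
    """
    x = np.sort(np.asarray(background_distances, dtype=float))
    if len(x) < MIN_BACKGROUND:
        raise ValueError(
            f"need at least {MIN_BACKGROUND} background distances, got {len(x)}"
        )
    if not 0.0 < quantile <= 1.0:
        raise ValueError("quantile must lie in (0, 1]")
    k = max(1, math.ceil(quantile * len(x)))
    return float(x[k - 1])


def call_association(
    candidate: AssociationCall,
    threshold: float,
    quality_scores: dict | None = None,
    quality_quartile_bound: float | None = None,
    patch_residues=None,
) -> AssociationCall:
    """Decide whether the best-pocket candidate is a positive association.

    Positive iff the distance is strictly below the threshold and, when a
    per-residue quality table is supplied (lower score = better modeled
    region), the mean quality over the patch residues does not exceed the
    supplied first-quartile bound.
    """
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    gate_ok = True
    if quality_scores is not None:
        if quality_quartile_bound is None:
            raise ValueError("quality gate requires a quartile bound")
        if patch_residues is None:
            raise ValueError("quality gate requires the patch residue list")
        missing = [r for r in patch_residues if r not in quality_scores]
        if missing:
            raise KeyError(f"quality table missing residues: {missing[:5]}")
        mean_quality = float(np.mean([quality_scores[r] for r in patch_residues]))
        gate_ok = mean_quality <= quality_quartile_bound
    positive = candidate.distance < threshold and gate_ok
    return AssociationCall(
        ligand_id=candidate.ligand_id,
        receptor_id=candidate.receptor_id,
        best_patch_id=candidate.best_patch_id,
        distance=candidate.distance,
        threshold_used=threshold,
        quality_gate_passed=gate_ok,
        is_association=positive,
        tie=candidate.tie,
    )
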