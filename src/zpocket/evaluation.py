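"""Evaluation machinery: ROC/AUC, model-vs-experiment similarity, benchmarks.

Positives are true binding sites (BS), negatives are size-matched decoys
(BSD); the discriminant score is the Zernike descriptor distance to the
cognate ligand, where LOW distance means positive.  The AUC is computed
from the Mann-Whitney rank statistic with tie correction and must agree
with the trapezoidal integral of the stored curve.

The specific/non-specific similarity analysis compares two structures of
the same protein (e.g. experimental vs modeled) patch by patch:

    S_s  = mean over i of dist(E_i, M_i)            (corresponding patches)
    S_ns = mean over i != j of dist(E_i, M_j)       (non-corresponding)
    S_Z  = S_ns - S_s                               (sensitivity)

with S_Z > 0 when corresponding regions are preferentially matched.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from . import complementarity as comp
from . import patches as patches_mod
from . import surface as surface_mod
from . import zernike
from .structure_io import MolecularStructure

__all__ = [
    "RocResult",
    "SimilarityReport",
    "roc_auc",
    "specific_similarity",
    "nonspecific_similarity",
    "sensitivity",
    "residue_frequencies",
    "quartile_stratify",
    "evaluate_complex",
    "run_benchmark",
]

AMINO_ACIDS = (
    "ALA", "ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "GLY", "HIS", "ILE",
    "LEU", "LYS", "MET", "PHE", "PRO", "SER", "THR", "TRP", "TYR", "VAL",
)


@dataclass
class RocResult:
    thresholds: np.ndarray
    tpr: np.ndarray
    fpr: np.ndarray
    auc: float

    def curve_auc(self) -> float:
        """Trapezoidal integral of the stored curve (cross-check for ``auc``)."""
        return float(np.trapezoid(self.tpr, self.fpr))


@dataclass
class SimilarityReport:
    s_specific: float
    s_nonspecific: float
    sensitivity: float
    zscores: np.ndarray | None = None


def roc_auc(labels, scores, positive_is_low: bool = True) -> RocResult:
    """ROC analysis with the Mann-Whitney rank AUC (tie-corrected).

    ``labels`` are binary (1 = true binding site); by default a LOW score
    (small descriptor distance) indicates a positive, implemented by
    negating the scores internally.
    """
    y = np.asarray(labels, dtype=int)
    s = np.asarray(scores, dtype=float)
    if y.shape != s.shape:
        raise ValueError("labels and scores must align")
    n_pos = int(y.sum())
    n_neg = int(len(y) - n_pos)
    if n_pos == 0 or n_neg == 0:
        raise ValueError("ROC needs both classes present")
    if positive_is_low:
        s = -s
    ranks = rankdata(s)  # average ranks handle ties
    auc = (ranks[y == 1].sum() - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg)

    order = np.argsort(-s, kind="mergesort")
    sorted_s, sorted_y = s[order], y[order]
    distinct = np.r_[np.nonzero(np.diff(sorted_s))[0], len(sorted_s) - 1]
    tp = np.cumsum(sorted_y)[distinct]
    fp = (distinct + 1) - tp
    tpr = np.r_[0.0, tp / n_pos]
    fpr = np.r_[0.0, fp / n_neg]
    thresholds = np.r_[np.inf, sorted_s[distinct]]
    return RocResult(thresholds=thresholds, tpr=tpr, fpr=fpr, auc=float(auc))


def _distance_matrix(pairsA, pairsB) -> np.ndarray:
    A = [p.values if isinstance(p, zernike.ZernikeDescriptor) else np.asarray(p)
         for p in pairsA]
    B = [p.values if isinstance(p, zernike.ZernikeDescriptor) else np.asarray(p)
         for p in pairsB]
    return np.array([[float(np.sum(np.abs(a - b))) for b in B] for a in A])


def specific_similarity(pairsA, pairsB) -> float:
    """Mean descriptor distance over corresponding (index-aligned) patch pairs."""
    if len(pairsA) != len(pairsB):
        raise ValueError("patch lists must be index-aligned and equal length")
    if len(pairsA) == 0:
        raise ValueError("empty patch lists")
    d = _distance_matrix(pairsA, pairsB)
    return float(np.mean(np.diag(d)))


def nonspecific_similarity(pairsA, pairsB) -> float:
    """Mean descriptor distance over all ordered non-corresponding pairs (i != j)."""
    if len(pairsA) != len(pairsB):
        raise ValueError("patch lists must be index-aligned and equal length")
    n = len(pairsA)
    if n < 2:
        raise ValueError("need at least two patches for non-specific similarity")
    d = _distance_matrix(pairsA, pairsB)
    off = ~np.eye(n, dtype=bool)
    return float(d[off].mean())


def sensitivity(pairsA, pairsB) -> SimilarityReport:
    """Similarity report with S_Z = S_ns - S_s and per-pair similarity Z-scores."""
    s_s = specific_similarity(pairsA, pairsB)
    s_ns = nonspecific_similarity(pairsA, pairsB)
    d = _distance_matrix(pairsA, pairsB)
    mu, sd = d.mean(), d.std()
    z = None if sd == 0 else (np.diag(d) - mu) / sd
    return SimilarityReport(
        s_specific=s_s, s_nonspecific=s_ns, sensitivity=s_ns - s_s, zscores=z
    )


def residue_frequencies(sites, residue_names: dict | None = None) -> pd.Series:
    """Amino-acid occurrence fractions over a list of residue sets.

    ``sites`` may contain ResidueSet objects (then ``residue_names`` maps
    residue ids to 3-letter codes) or plain iterables of 3-letter codes.
    Unknown codes are pooled under ``other`` with a warning.
    """
    if not sites:
        raise ValueError("no residue sets supplied")
    counts: dict[str, int] = {aa: 0 for aa in AMINO_ACIDS}
    other = 0
    for site in sites:
        if isinstance(site, patches_mod.ResidueSet):
            if residue_names is None:
                raise ValueError("residue_names mapping required for ResidueSet input")
            codes = [residue_names[r] for r in site.residues]
        else:
            codes = list(site)
        for code in codes:
            code = code.upper()
            if code in counts:
                counts[code] += 1
            else:
                other += 1
    if other:
        import warnings

        warnings.warn(f"{other} residues with unknown codes pooled under 'other'",
                      stacklevel=2)
        counts["other"] = other
    total = sum(counts.values())
    if total == 0:
        raise ValueError("no residues counted")
    return pd.Series({k: v / total for k, v in counts.items()}, name="frequency")


def quartile_stratify(zscores) -> np.ndarray:
    """Assign quartile labels 1-4 by empirical quartiles, 1 = most negative.

    Type-1 quantile boundaries; values tied with a boundary fall in the
    lower (better) stratum.
    """
    z = np.asarray(zscores, dtype=float)
    if len(z) < 4:
        raise ValueError("need at least 4 values to stratify into quartiles")
    bounds = [np.quantile(z, q, method="inverted_cdf") for q in (0.25, 0.5, 0.75)]
    labels = np.ones(len(z), dtype=int)
    for b in bounds:
        labels += z > b
    return labels


def size_weight_correlation(sizes, weights) -> tuple[float, float]:
    """Pearson correlation between binding-site sizes and ligand weights.

    Returns (r, p) with the p-value from the usual t-approximation; used to
    check that descriptor-based site detection is not driven by site size.
    """
    from scipy.stats import pearsonr

    r, p = pearsonr(np.asarray(sizes, float), np.asarray(weights, float))
    return float(r), float(p)


def evaluate_complex(
    protein: MolecularStructure,
    ligand: MolecularStructure,
    bs_cutoff: float = patches_mod.DEFAULT_BS_CUTOFF,
    grid_side: int = 32,
    order: int = zernike.DEFAULT_ORDER,
    probe_radius: float = surface_mod.DEFAULT_PROBE,
    point_density: float = surface_mod.DEFAULT_DENSITY,
    seed: int = 0,
) -> comp.ComplementarityTable:
    """Full single-complex pipeline: surfaces, BS + decoys, descriptors, Z-scores.

    Builds internal surfaces for protein and ligand, defines the binding
    site by the Calpha cutoff rule, generates size-matched decoys over the
    exposed residues, computes order-``order`` descriptors at
    ``grid_side``^3 voxel resolution, and returns the standardized
    distance table (one BS row plus one row per decoy).
    """
    protein_cloud = surface_mod.build_surface(
        protein, probe_radius=probe_radius, point_density=point_density, seed=seed
    )
    ligand_cloud = surface_mod.build_surface(
        ligand, probe_radius=probe_radius, point_density=point_density, seed=seed
    )
    lig_desc = zernike.describe_points(ligand_cloud, order=order, grid_side=grid_side)

    bs = define_bs = patches_mod.define_binding_site(protein, ligand, cutoff=bs_cutoff)
    decoys = patches_mod.generate_decoys(protein, bs, cloud=protein_cloud)

    rows: list[tuple[str, str, float]] = []
    bs_patch = patches_mod.cut_patch(protein_cloud, bs, patch_id="BS")
    d_bs = comp.manhattan_distance(
        lig_desc, zernike.describe_points(bs_patch.cloud, order=order, grid_side=grid_side)
    )
    rows.append(("BS", "BS", d_bs))
    for decoy in decoys:
        pid = f"BSD:{decoy.center_residue[1]}"
        try:
            patch = patches_mod.cut_patch(protein_cloud, decoy, patch_id=pid)
        except patches_mod.EmptyPatchError:
            continue
        d = comp.manhattan_distance(
            lig_desc, zernike.describe_points(patch.cloud, order=order, grid_side=grid_side)
        )
        rows.append((pid, "BSD", d))
    return comp.zscore_table(rows, ligand_id=ligand.label or "ligand")


def run_benchmark(
    n_complexes: int = 50,
    seed: int = 0,
    complementarity: float = 1.0,
    noise_sd: float = 0.3,
    grid_side: int = 32,
    order: int = zernike.DEFAULT_ORDER,
) -> pd.DataFrame:
    """Score a batch of seeded carved-pocket toy complexes.

    Returns one row per patch of every complex (columns: complex, patch_id,
    kind, distance, zscore); pooled over complexes this feeds the ROC
    analysis and the BS Z-score statistics.
    """
    from .synthetic import ToyComplexSpec, make_toy_complex

    frames = []
    rng = np.random.default_rng(seed)
    sub_seeds = rng.integers(0, 2**31 - 1, size=n_complexes)
    for i, s in enumerate(sub_seeds):
        spec = ToyComplexSpec(
            complementarity=complementarity, noise_sd=noise_sd, seed=int(s)
        )
        toy = make_toy_complex(spec)
        table = evaluate_complex(
            toy.protein, toy.ligand, grid_side=grid_side, order=order, seed=int(s)
        )
        frame = table.to_frame()
        frame.insert(0, "complex", i)
        frames.append(frame)
    return pd.concat(frames, ignore_index=True)
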