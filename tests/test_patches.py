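import numpy as np
import pytest

from conftest import make_ligand, make_protein
from zpocket import patches as pt


def test_binding_site_distance_rule():
    protein = make_protein([[0, 0, 0], [12, 0, 0]])
    ligand = make_ligand([[5, 0, 0]])
    bs = pt.define_binding_site(protein, ligand, cutoff=6.0)
    assert bs.residues == {("A", 1, "")}  # d=5 in, d=7 out
    assert bs.kind == "BS"


def test_binding_site_boundary_is_strict():
    protein = make_protein([[0, 0, 0]])
    ligand = make_ligand([[6.0, 0, 0]])
    with pytest.raises(pt.EmptyBindingSiteError):
        pt.define_binding_site(protein, ligand, cutoff=6.0)
    bs = pt.define_binding_site(protein, ligand, cutoff=6.0 + 1e-9)
    assert len(bs) == 1


def test_binding_site_no_contacts_errors():
    protein = make_protein([[0, 0, 0]])
    ligand = make_ligand([[5, 0, 0]])
    with pytest.raises(pt.EmptyBindingSiteError):
        pt.define_binding_site(protein, ligand, cutoff=0.1)


def test_binding_site_monotone_in_cutoff(toy_complex):
    sets = [pt.define_binding_site(toy_complex.protein, toy_complex.ligand, c)
            for c in (4.0, 6.0, 8.0, 12.0)]
    for small, big in zip(sets, sets[1:]):
        assert small.residues <= big.residues


def test_residue_centered_threshold_arithmetic():
    protein = make_protein([[0, 0, 0], [5, 0, 0], [8.9, 0, 0], [9.1, 0, 0]])
    rs = pt.residue_centered_set(protein, ("A", 1, ""), radius=9.0)
    assert {r[1] for r in rs.residues} == {1, 2, 3}
    assert rs.center_residue == ("A", 1, "")


def test_residue_centered_covers_all_at_large_radius(toy_complex):
    protein = toy_complex.protein
    rs = pt.residue_centered_set(protein, protein.atoms[0].residue_id, radius=1e4)
    assert rs.residues == set(protein.residue_ids())


def test_residue_centered_matches_brute_force():
    rng = np.random.default_rng(4)
    coords = rng.normal(scale=8.0, size=(50, 3))
    protein = make_protein(coords)
    center_idx = 17
    rs = pt.residue_centered_set(protein, ("A", center_idx + 1, ""), radius=9.0)
    brute = {("A", j + 1, "") for j in range(50)
             if np.linalg.norm(coords[j] - coords[center_idx]) < 9.0}
    brute.add(("A", center_idx + 1, ""))
    assert rs.residues == brute


def test_missing_calpha_center_errors():
    protein = make_protein([[0, 0, 0]])
    with pytest.raises(ValueError, match="alpha carbon"):
        pt.residue_centered_set(protein, ("A", 99, ""), radius=9.0)


def _brute_force_rstar(coords, bs_size, radii):
    best_r, best_dev = None, None
    for r in radii:
        sizes = [np.sum(np.linalg.norm(coords - c, axis=1) < r) for c in coords]
        dev = abs(np.mean(sizes) - bs_size)
        if best_dev is None or dev < best_dev - 1e-12:
            best_r, best_dev = r, dev
    return best_r


@pytest.mark.parametrize("seed", range(3))
def test_decoy_radius_matches_brute_force(seed):
    rng = np.random.default_rng(seed)
    coords = rng.normal(scale=9.0, size=(60, 3))
    protein = make_protein(coords)
    bs = pt.ResidueSet(frozenset({("A", i + 1, "") for i in range(8)}), kind="BS")
    decoys = pt.generate_decoys(protein, bs, keep_overlapping=True)
    r_star = _brute_force_rstar(coords, 8, np.arange(6.0, 20.5, 1.0))
    # recover the radius the implementation used from any decoy's extent rule
    got = decoys[0]
    center = coords[[r[1] - 1 for r in [got.center_residue]][0]]
    inside = {("A", j + 1, "") for j in range(60)
              if np.linalg.norm(coords[j] - center) < r_star}
    inside.add(got.center_residue)
    assert got.residues == inside
    assert len(decoys) == 60  # one per center when overlaps are kept


def test_decoy_boundary_argmin_at_rmax():
    rng = np.random.default_rng(1)
    coords = rng.normal(scale=30.0, size=(40, 3))  # sparse: even R=20 under-fills
    protein = make_protein(coords)
    bs = pt.ResidueSet(frozenset({("A", i + 1, "") for i in range(39)}), kind="BS")
    decoys = pt.generate_decoys(protein, bs, keep_overlapping=True)
    sizes_at_rmax = [np.sum(np.linalg.norm(coords - coords[i], axis=1) < 20.0)
                     for i in range(40)]
    got_sizes = sorted(len(d) for d in decoys)
    assert got_sizes == sorted(sizes_at_rmax)


def test_decoys_exclude_binding_site_centers_by_default(toy_complex, toy_surface):
    bs = toy_complex.binding_site
    decoys = pt.generate_decoys(toy_complex.protein, bs, cloud=toy_surface)
    assert all(d.center_residue not in bs.residues for d in decoys)
    kept = pt.generate_decoys(toy_complex.protein, bs, cloud=toy_surface,
                              keep_overlapping=True)
    assert len(kept) > len(decoys)


def test_decoy_mean_size_near_best_achievable(toy_complex, toy_surface):
    bs = toy_complex.binding_site
    coords = np.array([a.coordinates for a in toy_complex.protein.ca_atoms()])
    decoys = pt.generate_decoys(toy_complex.protein, bs, cloud=toy_surface,
                                keep_overlapping=True)
    mean_size = np.mean([len(d) for d in decoys])
    best_dev = min(
        abs(np.mean([np.sum(np.linalg.norm(coords - c, axis=1) < r) for c in coords])
            - len(bs))
        for r in np.arange(6.0, 20.5, 1.0)
    )
    assert abs(mean_size - len(bs)) <= best_dev + 1.0


def test_cut_patch_filters_by_residue(toy_surface, toy_complex):
    bs = toy_complex.binding_site
    patch = pt.cut_patch(toy_surface, bs)
    assert 0 < len(patch.cloud) < len(toy_surface)
    assert set(patch.cloud.residue_ids) <= bs.residues
    # full residue set reproduces the whole cloud
    full = pt.ResidueSet(frozenset(toy_complex.protein.residue_ids()), kind="BSD",
                         center_residue=None)
    assert len(pt.cut_patch(toy_surface, full).cloud) == len(toy_surface)


def test_cut_patch_union_superset(toy_surface, toy_complex):
    rids = toy_complex.protein.residue_ids()
    a = pt.ResidueSet(frozenset(rids[:10]), kind="BSD")
    b = pt.ResidueSet(frozenset(rids[10:20]), kind="BSD")
    ab = pt.ResidueSet(frozenset(rids[:20]), kind="BSD")
    n_union = len(pt.cut_patch(toy_surface, ab).cloud)
    assert n_union == len(pt.cut_patch(toy_surface, a).cloud) + \
        len(pt.cut_patch(toy_surface, b).cloud)


def test_cut_patch_disjoint_set_errors(toy_surface):
    ghost = pt.ResidueSet(frozenset({("Z", 999, "")}), kind="BSD")
    with pytest.raises(pt.EmptyPatchError):
        pt.cut_patch(toy_surface, ghost)
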