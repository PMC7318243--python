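"""Covalent anchoring and the surrogate pocket score (closed-form checks)."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy.spatial.transform import Rotation

from covhop.chemcore import ChemError, MoleculeRecord, mol_from_smiles
from covhop.pharmacophore import FeatureKind, LigandFeaturePoint, embed_conformers
from covhop.pocket import (
    CovalentPose,
    ExcludedVolume,
    InteractionScore,
    PocketModel,
    PocketSite,
    anchor_pose,
    find_electrophile,
    import_external_scores,
    rank_by_external_dg,
    rank_top_n,
    score_points,
    score_pose,
)

LIGAND = "C=CC(=O)N1CCN(c2ncncc2O)CC1"


def _pose(features, coords, anchored=0):
    return CovalentPose(np.asarray(coords, float), features, anchored)


def _feat(kind, xyz):
    return LigandFeaturePoint(kind, tuple(xyz), (0,))


def test_score_is_zero_with_empty_pocket():
    pocket = PocketModel(anchor=(0, 0, 0))
    pose = _pose([_feat(FeatureKind.DONOR, (1, 2, 3))], [[1, 2, 3]])
    assert score_pose(pose, pocket).total == 0.0


def test_feature_at_site_center_scores_full_weight():
    pocket = PocketModel(
        anchor=(0, 0, 0),
        sites=(PocketSite(FeatureKind.ACCEPTOR, (1.0, 1.0, 1.0), radius=2.0, weight=3.5),),
    )
    pose = _pose([_feat(FeatureKind.ACCEPTOR, (1.0, 1.0, 1.0))], [[1, 1, 1]])
    score = score_pose(pose, pocket)
    assert math.isclose(score.total, 3.5, abs_tol=1e-12)


def test_far_features_score_approximately_zero():
    pocket = PocketModel(
        anchor=(0, 0, 0),
        sites=(PocketSite(FeatureKind.DONOR, (0.0, 0.0, 0.0), radius=2.0, weight=1.0),),
    )
    # 3 sigma = 3 angstroms away for radius 2 (sigma = 1)
    pose = _pose([_feat(FeatureKind.DONOR, (4.0, 0.0, 0.0))], [[4, 0, 0]])
    assert score_pose(pose, pocket).total < 0.001


def test_score_matches_hand_computed_closed_form():
    """Three sites, two features, one clash: spreadsheet arithmetic."""
    sites = (
        PocketSite(FeatureKind.ACCEPTOR, (0.0, 0.0, 0.0), radius=2.0, weight=2.0),
        PocketSite(FeatureKind.DONOR, (4.0, 0.0, 0.0), radius=1.0, weight=1.5),
        PocketSite(FeatureKind.AROMATIC_RING, (0.0, 5.0, 0.0), radius=3.0, weight=1.0),
    )
    pocket = PocketModel(
        anchor=(0, 0, 0), sites=sites,
        excluded_volumes=(ExcludedVolume((10.0, 0.0, 0.0), 1.5),),
    )
    feats = [
        _feat(FeatureKind.ACCEPTOR, (1.0, 0.0, 0.0)),   # d=1, sigma=1
        _feat(FeatureKind.DONOR, (4.0, 1.0, 0.0)),      # d=1, sigma=0.5
    ]
    coords = [[1, 0, 0], [4, 1, 0], [10.5, 0, 0]]       # third atom clashes
    expected = (
        2.0 * math.exp(-1.0 / 2.0)
        + 1.5 * math.exp(-1.0 / (2 * 0.25))
        + 0.0                                            # no aromatic feature
        - 1.0
    )
    score = score_pose(_pose(feats, coords), pocket)
    assert math.isclose(score.total, expected, abs_tol=1e-12)
    assert math.isclose(score.clash_penalty, -1.0, abs_tol=1e-12)
    score.check()


def test_removing_excluded_volume_never_decreases_score():
    rng = np.random.default_rng(3)
    feats = [_feat(FeatureKind.DONOR, xyz) for xyz in rng.normal(size=(3, 3)) * 3]
    coords = rng.normal(size=(8, 3)) * 3
    sites = (PocketSite(FeatureKind.DONOR, (0.5, 0.5, 0.5), 2.0, 1.0),)
    vols = (ExcludedVolume((0, 0, 0), 2.0), ExcludedVolume((1, 1, 1), 1.0))
    with_vol = score_pose(_pose(feats, coords), PocketModel((0, 0, 0), sites=sites, excluded_volumes=vols))
    without = score_pose(_pose(feats, coords), PocketModel((0, 0, 0), sites=sites, excluded_volumes=vols[:1]))
    assert without.total >= with_vol.total


def test_adding_site_never_decreases_score():
    rng = np.random.default_rng(4)
    feats = [_feat(FeatureKind.ACCEPTOR, xyz) for xyz in rng.normal(size=(3, 3)) * 3]
    coords = rng.normal(size=(5, 3)) * 3
    sites = [PocketSite(FeatureKind.ACCEPTOR, (0, 0, 0), 2.0, 1.0)]
    base = score_pose(_pose(feats, coords), PocketModel((0, 0, 0), sites=tuple(sites)))
    sites.append(PocketSite(FeatureKind.ACCEPTOR, (2, 2, 2), 2.0, 0.5))
    more = score_pose(_pose(feats, coords), PocketModel((0, 0, 0), sites=tuple(sites)))
    assert more.total >= base.total


def test_score_invariant_under_joint_rigid_motion():
    rng = np.random.default_rng(9)
    feats = [_feat(FeatureKind.DONOR, xyz) for xyz in rng.normal(size=(2, 3)) * 2]
    coords = rng.normal(size=(4, 3)) * 2
    pocket = PocketModel(
        anchor=(0, 0, 0),
        sites=(PocketSite(FeatureKind.DONOR, (1, 0, 0), 2.0, 2.0),),
        excluded_volumes=(ExcludedVolume((0, 2, 0), 1.5),),
    )
    base = score_pose(_pose(feats, coords), pocket).total
    R = Rotation.from_rotvec([0.3, -1.2, 0.8]).as_matrix()
    shift = np.array([5.0, 6.0, -2.0])

    def move(p):
        return tuple(R @ np.asarray(p, float) + shift)

    moved_pocket = PocketModel(
        anchor=move(pocket.anchor),
        sites=tuple(PocketSite(s.kind, move(s.position), s.radius, s.weight)
                    for s in pocket.sites),
        excluded_volumes=tuple(ExcludedVolume(move(v.position), v.radius)
                               for v in pocket.excluded_volumes),
    )
    moved_feats = [_feat(f.kind, move(f.position)) for f in feats]
    moved_coords = coords @ R.T + shift
    moved = score_pose(_pose(moved_feats, moved_coords), moved_pocket).total
    assert math.isclose(base, moved, abs_tol=1e-9)


# --- anchoring -------------------------------------------------------------


def _toy_pocket():
    return PocketModel(
        anchor=(0.0, 0.0, 0.0),
        sites=(
            PocketSite(FeatureKind.ACCEPTOR, (2.0, 1.0, 3.0), 2.5, 2.0),
            PocketSite(FeatureKind.AROMATIC_RING, (-1.0, 2.0, 5.0), 3.0, 1.0),
        ),
    )


def test_anchor_places_electrophile_at_bond_distance():
    mol = embed_conformers(mol_from_smiles(LIGAND), n=1, seed=2020)
    pocket = _toy_pocket()
    pose = anchor_pose(mol, pocket)
    d = np.linalg.norm(pose.electrophile_xyz() - pocket.anchor_xyz)
    assert abs(d - pocket.ideal_bond_length) < 0.01


def test_anchor_distance_independent_of_start_position():
    mol = embed_conformers(mol_from_smiles(LIGAND), n=1, seed=2020)
    conf = mol.GetConformer()
    xyz = conf.GetPositions() + np.array([10.0, -7.0, 3.0])
    for k in range(mol.GetNumAtoms()):
        conf.SetAtomPosition(k, xyz[k].tolist())
    pocket = _toy_pocket()
    pose = anchor_pose(mol, pocket)
    d = np.linalg.norm(pose.electrophile_xyz() - pocket.anchor_xyz)
    assert abs(d - pocket.ideal_bond_length) < 0.01


def test_orientation_matches_brute_force_over_grid():
    """The chosen orientation attains the best score over its own grid."""
    from covhop.pocket import _frame_from_z, _orientation_grid, score_points
    from covhop.pharmacophore import perceive_features

    mol = embed_conformers(mol_from_smiles(LIGAND), n=1, seed=2020)
    pocket = _toy_pocket()
    pose = anchor_pose(mol, pocket)
    chosen = score_pose(pose, pocket).total

    coords = mol.GetConformer().GetPositions()
    feats = perceive_features(mol)
    heavy = np.array([a.GetIdx() for a in mol.GetAtoms() if a.GetAtomicNum() > 1])
    feat_xyz = np.array([f.xyz for f in feats])
    kinds = [f.kind for f in feats]
    beta = find_electrophile(mol)
    target = pocket.anchor_xyz + pocket.ideal_bond_length * pocket.axis
    frame = _frame_from_z(pocket.axis)
    best = -np.inf
    for rot in _orientation_grid(10.0, 30.0):
        R = frame @ rot.as_matrix() @ frame.T
        nc = (coords - coords[beta]) @ R.T + target
        nf = (feat_xyz - coords[beta]) @ R.T + target
        s = score_points(None, nc[heavy], pocket, feature_xyz=nf, feature_kinds=kinds)
        best = max(best, s.total)
    assert math.isclose(chosen, best, abs_tol=1e-9)


def test_missing_warhead_is_an_error():
    mol = embed_conformers(mol_from_smiles("c1ccccc1O"), n=1, seed=1)
    with pytest.raises(ChemError, match="warhead"):
        anchor_pose(mol, _toy_pocket())


# --- ranking and external scores -------------------------------------------


def _scored(n, seed=0):
    rng = np.random.default_rng(seed)
    out = []
    for i in range(n):
        rec = MoleculeRecord(f"m-{i:03d}", "C" * (i % 3 + 1) + "O")
        out.append((rec, InteractionScore(float(rng.normal()), [], 0.0)))
    return out


def test_rank_top_n_against_sort_oracle():
    scored = _scored(20, seed=1)
    top5 = rank_top_n(scored, cap=5)
    oracle = sorted(scored, key=lambda p: -p[1].total)[:5]
    assert [r.id for r, _ in top5] == [r.id for r, _ in oracle]


def test_rank_cap_larger_than_input_returns_all():
    scored = _scored(7)
    assert len(rank_top_n(scored, cap=100)) == 7


def test_import_external_scores_empty_table_is_noop():
    scored = _scored(5)
    out = import_external_scores(scored, pd.DataFrame({"id": [], "dg": []}))
    assert all(s.external_dg is None for _, s in out)


def test_import_external_scores_annotates_known_ids(capsys):
    scored = _scored(10)
    table = pd.DataFrame({
        "id": ["m-001", "m-003", "m-005", "m-007", "m-999"],
        "dg": [-8.1, -9.2, -7.7, -8.8, -5.0],
    })
    out = import_external_scores(scored, table)
    annotated = [(r.id, s.external_dg) for r, s in out if s.external_dg is not None]
    assert len(annotated) == 4
    assert "m-999" in capsys.readouterr().err


def test_final_selection_four_lowest_dg_from_132():
    """Final funnel stage: 4 best external binding energies out of 132."""
    rng = np.random.default_rng(2020)
    scored = _scored(132, seed=3)
    dgs = rng.normal(loc=-7.0, scale=1.5, size=132).round(3)
    table = pd.DataFrame({"id": [r.id for r, _ in scored], "dg": dgs})
    annotated = import_external_scores(scored, table)
    final = rank_by_external_dg(annotated, cap=4)
    assert len(final) == 4
    oracle = table.sort_values("dg").head(4)["id"].tolist()
    assert [r.id for r, _ in final] == oracle


def test_malformed_dg_raises():
    scored = _scored(2)
    table = pd.DataFrame({"id": ["m-000"], "dg": ["not-a-number"]})
    with pytest.raises(ValueError):
        import_external_scores(scored, table)
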