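"""Relaxed torsion scans, minima detection, and intramolecular H-bonds."""

import numpy as np
import pytest
from rdkit import Chem
from scipy.spatial.transform import Rotation

from covhop.chemcore import ChemError, mol_from_smiles
from covhop.pharmacophore import embed_conformers
from covhop.torsion import (
    NAPHTHYRIDINONE_HEAD_FRAGMENT,
    ISOQUINOLINONE_HEAD_FRAGMENT,
    ORTHO_DECORATED_ANALOGUE,
    TorsionProfile,
    compare_profiles,
    detect_intramolecular_hbond,
    find_minima,
    scan_conformer_at,
    scan_torsion,
)


@pytest.fixture(scope="module")
def frag13_profile():
    return scan_torsion(NAPHTHYRIDINONE_HEAD_FRAGMENT, step=15.0, seed=2020)


@pytest.fixture(scope="module")
def frag2_profile():
    return scan_torsion(ISOQUINOLINONE_HEAD_FRAGMENT, step=15.0, seed=2020)


def test_scan_normalizes_to_zero_minimum(frag13_profile):
    assert frag13_profile.energies.min() == 0.0
    assert len(frag13_profile.angles) == 24


def test_biphenyl_profile_is_symmetric():
    prof = scan_torsion("c1ccccc1-c1ccccc1", step=15.0, seed=2020)
    e = prof.energies
    # E(phi) == E(360 - phi) by molecular symmetry
    for k in range(1, len(e)):
        assert abs(e[k] - e[len(e) - k]) < 0.3, prof.angles[k]


def test_butane_global_minimum_near_anti():
    mol = embed_conformers(mol_from_smiles("CCCC"), n=1, seed=2020)
    heavy = [a.GetIdx() for a in mol.GetAtoms() if a.GetAtomicNum() > 1]
    prof = scan_torsion(mol, dihedral_atoms=heavy, step=15.0, seed=2020)
    gmin = prof.global_minimum_angle()
    assert min(abs(gmin - 180.0), 360 - abs(gmin - 180.0)) <= 15.0


def test_scan_invariant_under_rigid_motion_of_start():
    smiles = "CCCC"
    mol = embed_conformers(mol_from_smiles(smiles), n=1, seed=2020)
    heavy = [a.GetIdx() for a in mol.GetAtoms() if a.GetAtomicNum() > 1]
    base = scan_torsion(Chem.Mol(mol), dihedral_atoms=heavy, step=30.0)
    conf = mol.GetConformer()
    R = Rotation.from_rotvec([1.0, 0.2, -0.5]).as_matrix()
    xyz = conf.GetPositions() @ R.T + np.array([3.0, -8.0, 2.0])
    for k in range(mol.GetNumAtoms()):
        conf.SetAtomPosition(k, xyz[k].tolist())
    moved = scan_torsion(mol, dihedral_atoms=heavy, step=30.0)
    # minimizer line-search numerics are orientation-sensitive near barriers,
    # so agreement is to a fraction of kcal/mol, not machine precision
    assert np.allclose(base.energies, moved.energies, atol=0.2)


def test_halving_step_keeps_global_minimum_stable():
    coarse = scan_torsion("CCCC", dihedral_atoms=(0, 1, 2, 3), step=30.0, seed=2020)
    fine = scan_torsion("CCCC", dihedral_atoms=(0, 1, 2, 3), step=15.0, seed=2020)
    diff = abs(coarse.global_minimum_angle() - fine.global_minimum_angle())
    assert min(diff, 360 - diff) <= 30.0


def test_non_chain_dihedral_atoms_rejected():
    with pytest.raises(ChemError, match="chain"):
        scan_torsion("CCCC", dihedral_atoms=(0, 2, 1, 3))


def test_unsupported_method_rejected():
    with pytest.raises(ValueError, match="method"):
        scan_torsion("CCCC", dihedral_atoms=(0, 1, 2, 3), method="semiempirical")


# --- minima detection on constructed profiles -------------------------------


def _profile(energies, step=15.0):
    e = np.asarray(energies, float)
    return TorsionProfile((0, 1, 2, 3), np.arange(0, 360, step), e - e.min(), "synthetic")


def test_flat_profile_degenerate_minimum_warns():
    prof = _profile(np.zeros(24))
    with pytest.warns(UserWarning, match="flat"):
        minima = find_minima(prof)
    assert len(minima) == 1
    assert minima[0].angle == 0.0
    assert minima[0].is_global


def test_cosine_profile_single_minimum_at_180():
    angles = np.arange(0, 360, 15.0)
    prof = _profile(np.cos(np.radians(angles)))
    minima = find_minima(prof)
    assert len(minima) == 1
    assert minima[0].angle == 180.0
    assert minima[0].is_global


def test_two_well_profile_finds_both_wells():
    angles = np.arange(0, 360, 15.0)
    # Gaussian wells at 60 and 300 degrees, the one at 300 deeper
    e = (3.0
         - 1.5 * np.exp(-(((angles - 60) / 25.0) ** 2))
         - 3.0 * np.exp(-(((angles - 300) / 25.0) ** 2)))
    prof = _profile(e)
    minima = find_minima(prof, tolerance=0.1)
    angles_found = sorted(m.angle for m in minima)
    assert len(minima) == 2
    assert angles_found == [60.0, 300.0]
    deeper = min(minima, key=lambda m: m.energy)
    assert deeper.is_global and deeper.angle == 300.0


def test_wraparound_minimum_at_zero_detected():
    angles = np.arange(0, 360, 15.0)
    prof = _profile(1 - np.cos(np.radians(angles)))  # minimum exactly at 0
    minima = find_minima(prof)
    assert [m.angle for m in minima if m.is_global] == [0.0]


# --- the compound series ----------------------------------------------------


def test_naphthyridinone_fragment_minimum_in_coplanar_window(frag13_profile):
    """The 2,6-naphthyridinone / fluorophenol biaryl prefers near-coplanarity."""
    gmin = frag13_profile.global_minimum_angle()
    assert 150.0 <= gmin <= 210.0


def test_isoquinolinone_fragment_prefers_twist(frag2_profile):
    """Without the ortho ring nitrogen the biaryl twists out of plane."""
    gmin = frag2_profile.global_minimum_angle()
    assert not (150.0 <= gmin <= 210.0)


def test_window_penalty_ordering(frag13_profile, frag2_profile):
    """Coplanarity penalty: H-bonded naphthyridinone <= plain isoquinolinone."""
    table = compare_profiles(
        {"naphthyridinone": frag13_profile, "isoquinolinone": frag2_profile}, window=(150.0, 210.0)
    )
    penalties = dict(zip(table["name"], table["window_penalty_kcal"]))
    assert penalties["naphthyridinone"] <= penalties["isoquinolinone"]
    assert penalties["naphthyridinone"] == 0.0  # global minimum inside the window


def test_ortho_decorated_analogue_disfavors_coplanarity(frag13_profile):
    """Cl/F flanking groups push the coplanar window uphill."""
    analogue = scan_torsion(ORTHO_DECORATED_ANALOGUE, step=15.0, seed=2020)
    table = compare_profiles(
        {"naphthyridinone": frag13_profile, "analogue": analogue}, window=(150.0, 210.0)
    )
    penalties = dict(zip(table["name"], table["window_penalty_kcal"]))
    assert penalties["analogue"] > penalties["naphthyridinone"]


def test_compare_profiles_offset_invariance(frag13_profile):
    shifted = TorsionProfile(
        frag13_profile.dihedral_atoms, frag13_profile.angles.copy(),
        frag13_profile.energies.copy(), "copy",
    )
    table = compare_profiles({"a": frag13_profile, "b": shifted})
    assert table["window_penalty_kcal"].nunique() == 1


def test_compare_profiles_rejects_mismatched_grids(frag13_profile):
    other = _profile(np.zeros(12), step=30.0)
    with pytest.raises(ValueError, match="grid"):
        compare_profiles({"a": frag13_profile, "b": other})


# --- intramolecular hydrogen bonds ------------------------------------------


def test_alkane_has_no_hbonds():
    mol = embed_conformers(mol_from_smiles("CCCCCC"), n=1, seed=1)
    assert detect_intramolecular_hbond(mol) == []


def test_requires_explicit_hydrogens():
    mol = mol_from_smiles("OCCCO")
    from rdkit.Chem import AllChem
    AllChem.Compute2DCoords(mol)
    with pytest.raises(ChemError, match="hydrogens"):
        detect_intramolecular_hbond(mol)


def test_constructed_oh_n_geometry_detected():
    """An OH donor 2.8 A from a pyridine N at a near-linear angle is a contact."""
    mol = Chem.AddHs(mol_from_smiles("[OH2]"))
    # build coordinates by hand: O-H...N with d(O,N)=2.8, angle 165 deg
    from rdkit.Chem import rdmolops
    from rdkit.Geometry import Point3D

    em = Chem.RWMol(mol)
    n = em.AddAtom(Chem.Atom(7))
    target = em.GetMol()
    Chem.SanitizeMol(target, Chem.SANITIZE_FINDRADICALS | Chem.SANITIZE_SETAROMATICITY)
    conf = Chem.Conformer(target.GetNumAtoms())
    conf.SetAtomPosition(0, Point3D(0.0, 0.0, 0.0))       # O
    conf.SetAtomPosition(1, Point3D(0.96, 0.0, 0.0))      # H toward N
    conf.SetAtomPosition(2, Point3D(-0.3, 0.9, 0.0))      # other H
    conf.SetAtomPosition(3, Point3D(2.79, 0.2, 0.0))      # N, d(O,N) ~ 2.8
    target.AddConformer(conf)
    contacts = detect_intramolecular_hbond(target, min_bond_separation=0)
    assert len(contacts) == 1
    assert contacts[0].donor == 0 and contacts[0].acceptor == 3
    assert 2.7 < contacts[0].distance < 2.9
    assert contacts[0].angle > 150


def test_coplanar_naphthyridinone_forms_internal_hbond():
    """At the coplanar geometry the phenol OH hydrogen-bonds the core ring N."""
    mol13 = scan_conformer_at(NAPHTHYRIDINONE_HEAD_FRAGMENT, 180.0, seed=2020)
    contacts = detect_intramolecular_hbond(mol13)
    assert len(contacts) >= 1
    kinds = {(mol13.GetAtomWithIdx(c.donor).GetSymbol(),
              mol13.GetAtomWithIdx(c.acceptor).GetSymbol()) for c in contacts}
    assert ("O", "N") in kinds


def test_isoquinolinone_cannot_form_internal_hbond():
    mol2 = scan_conformer_at(ISOQUINOLINONE_HEAD_FRAGMENT, 180.0, seed=2020)
    contacts = detect_intramolecular_hbond(mol2)
    assert all(
        mol2.GetAtomWithIdx(c.acceptor).GetSymbol() != "N" for c in contacts
    )
    assert contacts == []
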