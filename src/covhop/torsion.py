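"""Relaxed torsion scans of the core-head biaryl bond.

The design rationale behind the naphthyridinone series is conformational: a
near-coplanar core-head orientation (dihedral near 180 degrees) is the active
conformation, and placing a ring nitrogen ortho to the biaryl bond lets the
fluorophenol OH form an intramolecular hydrogen bond that stabilizes
coplanarity, whereas ortho CH / decorating groups twist the biaryl.  This
module quantifies that with relaxed force-field torsion scans: step the
dihedral on a uniform grid over [0, 360), restrain it harmonically, minimize
all other degrees of freedom with MMFF94, and record the unrestrained energy,
normalized so the global minimum is zero.

Every grid point takes its lowest energy over a fixed set of deterministic
starts (seeded conformers, their hydroxyl rotamers, and two sequential
continuation passes), so scans are reproducible for a fixed seed and robust
against local traps in slow degrees of freedom.  Energies are
force-field relative energies in kcal/mol; the deliverable claims concern the
*location* of minima (e.g. the 150-210 degree window), not absolute barriers.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from rdkit import Chem
from rdkit.Chem import AllChem, rdMolTransforms

from covhop.chemcore import ChemError, mol_from_smiles
from covhop.pharmacophore import embed_conformers

# Core-head fragments of the scaffold series, hydrogen-capped at the bridge
# attachment.  Naphthyridinone: 2,6-naphthyridin-1(2H)-one core with the
# 2-fluoro-6-hydroxyphenyl head at C7 (ring N6 ortho to the biaryl bond ->
# intramolecular OH...N hydrogen bond available in the coplanar conformation).
# Isoquinolinone: the isoquinolin-1(2H)-one analogue (CH in place of N6, no
# such H-bond).  The ortho-decorated virtual analogue flanks the head
# attachment of the isoquinolinone core with Cl and F.
NAPHTHYRIDINONE_HEAD_FRAGMENT = "O=c1[nH]ccc2cnc(-c3c(O)cccc3F)cc12"
ISOQUINOLINONE_HEAD_FRAGMENT = "O=c1[nH]ccc2ccc(-c3c(O)cccc3F)cc12"
ORTHO_DECORATED_ANALOGUE = "O=c1[nH]ccc2cc(Cl)c(-c3c(O)cccc3F)c(F)c12"

TORSION_RESTRAINT_KCAL = 1.0e4


@dataclass(frozen=True)
class TorsionMinimum:
    angle: float
    energy: float
    is_global: bool


@dataclass
class TorsionProfile:
    """Relative energy (kcal/mol, min = 0) on a uniform dihedral grid."""

    dihedral_atoms: tuple[int, int, int, int]
    angles: np.ndarray       # degrees, strictly increasing, uniform, [0, 360)
    energies: np.ndarray     # kcal/mol relative to the scan minimum
    method: str = "mmff94"

    def __post_init__(self):
        self.angles = np.asarray(self.angles, float)
        self.energies = np.asarray(self.energies, float)
        steps = np.diff(self.angles)
        if len(self.angles) < 3 or not np.allclose(steps, steps[0]):
            raise ValueError("angles must form a uniform grid")
        if abs(self.energies.min()) > 1e-9:
            raise ValueError("energies must be normalized to min = 0")

    @property
    def step(self) -> float:
        return float(self.angles[1] - self.angles[0])

    def global_minimum_angle(self) -> float:
        return float(self.angles[int(np.argmin(self.energies))])

    def to_csv(self, path: str | Path) -> None:
        pd.DataFrame({"angle_deg": self.angles, "energy_kcal": self.energies}) \
            .to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path,
                 dihedral_atoms=(0, 1, 2, 3), method="csv") -> "TorsionProfile":
        df = pd.read_csv(path)
        e = df["energy_kcal"].to_numpy(float)
        return cls(tuple(dihedral_atoms), df["angle_deg"].to_numpy(float),
                   e - e.min(), method)


def find_biaryl_bond(mol: Chem.Mol) -> tuple[int, int]:
    """The acyclic single bond joining two aromatic rings (core-head bond)."""
    for bond in mol.GetBonds():
        if bond.GetBondType() != Chem.BondType.SINGLE or bond.IsInRing():
            continue
        a, b = bond.GetBeginAtom(), bond.GetEndAtom()
        if a.GetIsAromatic() and b.GetIsAromatic():
            return a.GetIdx(), b.GetIdx()
    raise ChemError("no acyclic aromatic-aromatic single bond found")


def dihedral_reference_atoms(
    mol: Chem.Mol, i: int, j: int
) -> tuple[int, int, int, int]:
    """Four-atom dihedral definition for the bond i-j.

    Convention: on each side the reference neighbor is the ring neighbor of
    the bonded atom with the lowest canonical rank (recorded in outputs; the
    choice fixes the 0/180 frame of reported angles).
    """
    if mol.GetBondBetweenAtoms(i, j) is None:
        raise ChemError(f"atoms {i} and {j} are not bonded")
    ranks = list(Chem.CanonicalRankAtoms(mol, breakTies=True))

    def pick(center: int, exclude: int) -> int:
        nbrs = [n.GetIdx() for n in mol.GetAtomWithIdx(center).GetNeighbors()
                if n.GetIdx() != exclude and n.IsInRing() and n.GetAtomicNum() > 1]
        if not nbrs:
            nbrs = [n.GetIdx() for n in mol.GetAtomWithIdx(center).GetNeighbors()
                    if n.GetIdx() != exclude and n.GetAtomicNum() > 1]
        if not nbrs:
            raise ChemError(f"atom {center} has no heavy neighbor besides {exclude}")
        return min(nbrs, key=lambda x: ranks[x])

    return pick(i, j), i, j, pick(j, i)


def scan_torsion(
    smiles_or_mol: str | Chem.Mol,
    dihedral_atoms: Sequence[int] | None = None,
    step: float = 15.0,
    seed: int = 2020,
    method: str = "forcefield",
    n_starts: int = 4,
) -> TorsionProfile:
    """Relaxed torsion scan on a uniform grid over [0, 360).

    For each grid angle the dihedral is set and harmonically restrained, all
    other degrees of freedom are MMFF-minimized, and the unrestrained MMFF
    energy of the relaxed geometry is recorded.  To approximate the lower
    envelope over the remaining slow degrees of freedom (e.g. hydroxyl
    rotamers), each grid point takes the lowest energy over restarts from
    ``n_starts`` seeded conformers plus forward and backward sequential
    continuation passes.  Grid points whose minimization fails are linearly
    interpolated from their neighbors with a warning.  ``method`` currently
    supports only the force-field backend.
    """
    if method != "forcefield":
        raise ValueError(f"unsupported scan method {method!r}; available: 'forcefield'")
    if isinstance(smiles_or_mol, str):
        mol = mol_from_smiles(smiles_or_mol)
        mol = embed_conformers(mol, n=max(1, n_starts), seed=seed, rms_threshold=0.2)
    else:
        mol = Chem.Mol(smiles_or_mol)
        if mol.GetNumConformers() == 0:
            mol = embed_conformers(mol, n=max(1, n_starts), seed=seed, rms_threshold=0.2)
        elif not any(a.GetAtomicNum() == 1 for a in mol.GetAtoms()):
            mol = Chem.AddHs(mol, addCoords=True)

    if dihedral_atoms is None:
        i, j = find_biaryl_bond(mol)
        dihedral_atoms = dihedral_reference_atoms(mol, i, j)
    a, i, j, d = (int(x) for x in dihedral_atoms)
    _check_dihedral_chain(mol, (a, i, j, d))

    start_confs = [Chem.Conformer(c) for c in mol.GetConformers()]
    start_confs = _expand_hydroxyl_rotamers(mol, start_confs)
    base_conf = start_confs[0]
    angles = np.arange(0.0, 360.0, float(step))
    if AllChem.MMFFGetMoleculeProperties(mol) is None:
        raise ChemError("MMFF parameters unavailable for this molecule")

    def relax_at(conf: Chem.Conformer, angle: float):
        """Restrained minimization at one angle; returns (energy|None, conf)."""
        work = Chem.Mol(mol)
        work.RemoveAllConformers()
        work.AddConformer(Chem.Conformer(conf), assignId=True)
        rdMolTransforms.SetDihedralDeg(work.GetConformer(), a, i, j, d, float(angle))
        wprops = AllChem.MMFFGetMoleculeProperties(work)
        ff = AllChem.MMFFGetMoleculeForceField(work, wprops)
        ff.MMFFAddTorsionConstraint(a, i, j, d, False, float(angle), float(angle),
                                    TORSION_RESTRAINT_KCAL)
        try:
            status = ff.Minimize(maxIts=2000)
            retries = 0
            while status == 1 and retries < 5:  # needs more iterations
                status = ff.Minimize(maxIts=2000)
                retries += 1
        except RuntimeError:
            status = -1
        if status < 0:
            return None, work.GetConformer()
        plain = AllChem.MMFFGetMoleculeForceField(work, wprops)
        return plain.CalcEnergy(), work.GetConformer()

    n = len(angles)
    # three deterministic passes guard against local traps at single grid
    # points: independent restarts from the base conformer, plus forward and
    # backward sequential continuation; each point keeps its lowest energy
    energies: list[float | None] = [None] * n
    for conf in start_confs:
        for k, angle in enumerate(angles):
            e, _ = relax_at(conf, angle)
            if e is not None and (energies[k] is None or e < energies[k]):
                energies[k] = e
    for order in (range(n), range(n - 1, -1, -1)):
        conf = base_conf
        for k in order:
            e, conf = relax_at(conf, angles[k])
            if e is not None and (energies[k] is None or e < energies[k]):
                energies[k] = e
    if any(e is None for e in energies):
        warnings.warn("some grid points failed to minimize; interpolating")
    filled = _interpolate_missing(energies)
    filled -= filled.min()
    return TorsionProfile((a, i, j, d), angles, filled, method="mmff94")


def _expand_hydroxyl_rotamers(
    mol: Chem.Mol, confs: list[Chem.Conformer]
) -> list[Chem.Conformer]:
    """Add 180-degree O-H flips of every start conformer.

    Hydroxyl orientation is a slow degree of freedom that restrained
    minimization rarely crosses; enumerating both rotamers makes the scan's
    lower envelope independent of the embedding seed.
    """
    pattern = Chem.MolFromSmarts("[!#1][OX2][H]")
    matches = mol.GetSubstructMatches(pattern)
    if not matches:
        return confs
    work = Chem.Mol(mol)
    out = list(confs)
    for conf in confs:
        for heavy, oxy, hyd in matches:
            ref = next(
                n.GetIdx() for n in work.GetAtomWithIdx(heavy).GetNeighbors()
                if n.GetIdx() != oxy
            )
            flipped = Chem.Conformer(conf)
            work.RemoveAllConformers()
            cid = work.AddConformer(flipped, assignId=True)
            c = work.GetConformer(cid)
            current = rdMolTransforms.GetDihedralDeg(c, ref, heavy, oxy, hyd)
            rdMolTransforms.SetDihedralDeg(c, ref, heavy, oxy, hyd, current + 180.0)
            out.append(Chem.Conformer(c))
    return out


def _check_dihedral_chain(mol: Chem.Mol, atoms: tuple[int, int, int, int]) -> None:
    for x, y in zip(atoms, atoms[1:]):
        if mol.GetBondBetweenAtoms(x, y) is None:
            raise ChemError(f"dihedral atoms {atoms} are not a bonded chain "
                            f"({x}-{y} missing)")


def _interpolate_missing(energies: list) -> np.ndarray:
    vals = np.array([np.nan if e is None else e for e in energies], float)
    if np.all(np.isnan(vals)):
        raise ChemError("every grid point failed to minimize")
    n = len(vals)
    if np.any(np.isnan(vals)):
        good = ~np.isnan(vals)
        idx = np.arange(n)
        # periodic interpolation: extend by one period on both sides
        xs = np.concatenate([idx[good] - n, idx[good], idx[good] + n])
        ys = np.tile(vals[good], 3)
        vals[~good] = np.interp(idx[~good], xs, ys)
    return vals


def find_minima(profile: TorsionProfile, tolerance: float = 0.0) -> list[TorsionMinimum]:
    """Grid-local minima (periodic wraparound) deeper than ``tolerance``.

    Depth is measured to the lower of the two adjacent maxima along the
    periodic profile.  A completely flat profile yields one degenerate
    minimum at the first grid point, with a warning.  Exactly one returned
    minimum has ``is_global=True`` (ties broken by lowest angle).
    """
    e = profile.energies
    n = len(e)
    if np.allclose(e, e[0]):
        warnings.warn("flat torsion profile; reporting degenerate minimum at "
                      f"{profile.angles[0]:.0f} deg")
        return [TorsionMinimum(float(profile.angles[0]), float(e[0]), True)]
    mins = [k for k in range(n) if e[k] <= e[(k - 1) % n] and e[k] <= e[(k + 1) % n]]
    # suppress plateau duplicates: keep the first index of a run of equals
    mins = [k for k in mins if e[k] < e[(k - 1) % n] or k == 0 or (k - 1) not in mins]

    def adjacent_max(k: int, direction: int) -> float:
        best = e[k]
        idx = k
        for _ in range(n):
            idx = (idx + direction) % n
            best = max(best, e[idx])
            if idx in mins and idx != k:
                break
        return best

    out = []
    for k in mins:
        depth = min(adjacent_max(k, +1), adjacent_max(k, -1)) - e[k]
        if depth > tolerance:
            out.append((k, e[k]))
    if not out:
        k = int(np.argmin(e))
        out = [(k, e[k])]
    global_k = min(out, key=lambda pair: (pair[1], profile.angles[pair[0]]))[0]
    return [
        TorsionMinimum(float(profile.angles[k]), float(ek), k == global_k)
        for k, ek in out
    ]


# --- intramolecular hydrogen bonds -----------------------------------------

HBOND_MAX_DA = 3.5     # donor-acceptor heavy-atom distance, angstroms
HBOND_MIN_ANGLE = 120  # D-H...A angle, degrees
HBOND_MIN_BOND_SEPARATION = 4


@dataclass(frozen=True)
class IntramolecularHBond:
    donor: int
    hydrogen: int
    acceptor: int
    distance: float
    angle: float


def _is_acceptor(atom: Chem.Atom) -> bool:
    if atom.GetFormalCharge() > 0:
        return False
    if atom.GetAtomicNum() == 8:
        return True
    if atom.GetAtomicNum() == 7:
        # pyridine-type N accepts; pyrrole-type (aromatic NH) and amide N do not
        if atom.GetIsAromatic():
            return atom.GetTotalNumHs() == 0 and atom.GetDegree() == 2
        return not any(
            nbr.GetAtomicNum() == 6 and any(
                b.GetBondTypeAsDouble() == 2 for b in nbr.GetBonds()
            )
            for nbr in atom.GetNeighbors()
        )
    return False


def detect_intramolecular_hbond(
    mol_with_conf: Chem.Mol, conf_id: int = 0,
    max_distance: float = HBOND_MAX_DA,
    min_angle: float = HBOND_MIN_ANGLE,
    min_bond_separation: int = HBOND_MIN_BOND_SEPARATION,
) -> list[IntramolecularHBond]:
    """Intramolecular D-H...A contacts in one conformer.

    Criteria: donor-acceptor heavy-atom distance <= 3.5 A, D-H...A angle
    >= 120 deg, donor and acceptor separated by at least 4 bonds (closer
    pairs are covalent geometry, not hydrogen bonds).  Requires explicit
    polar hydrogens.
    """
    if not any(a.GetAtomicNum() == 1 for a in mol_with_conf.GetAtoms()):
        raise ChemError("explicit hydrogens required; call Chem.AddHs with "
                        "coordinates before H-bond detection")
    conf = mol_with_conf.GetConformer(conf_id)
    xyz = conf.GetPositions()
    dmat = Chem.GetDistanceMatrix(mol_with_conf)  # topological (bond counts)

    donors = []  # (heavy, hydrogen)
    for atom in mol_with_conf.GetAtoms():
        if atom.GetAtomicNum() in (7, 8):
            for nbr in atom.GetNeighbors():
                if nbr.GetAtomicNum() == 1:
                    donors.append((atom.GetIdx(), nbr.GetIdx()))
    acceptors = [a.GetIdx() for a in mol_with_conf.GetAtoms() if _is_acceptor(a)]

    contacts = []
    for d_idx, h_idx in donors:
        for a_idx in acceptors:
            if a_idx == d_idx or dmat[d_idx][a_idx] < min_bond_separation:
                continue
            dist = float(np.linalg.norm(xyz[d_idx] - xyz[a_idx]))
            if dist > max_distance:
                continue
            v1 = xyz[d_idx] - xyz[h_idx]
            v2 = xyz[a_idx] - xyz[h_idx]
            cosang = np.dot(v1, v2) / (np.linalg.norm(v1) * np.linalg.norm(v2))
            angle = math.degrees(math.acos(np.clip(cosang, -1.0, 1.0)))
            if angle >= min_angle:
                contacts.append(
                    IntramolecularHBond(d_idx, h_idx, a_idx, dist, angle)
                )
    return contacts


def scan_conformer_at(
    smiles: str, angle: float, step: float = 15.0, seed: int = 2020
) -> Chem.Mol:
    """Relaxed conformer with the core-head dihedral restrained at ``angle``."""
    mol = embed_conformers(mol_from_smiles(smiles), n=1, seed=seed)
    i, j = find_biaryl_bond(mol)
    a, i, j, d = dihedral_reference_atoms(mol, i, j)
    rdMolTransforms.SetDihedralDeg(mol.GetConformer(), a, i, j, d, float(angle))
    props = AllChem.MMFFGetMoleculeProperties(mol)
    ff = AllChem.MMFFGetMoleculeForceField(mol, props)
    ff.MMFFAddTorsionConstraint(a, i, j, d, False, float(angle), float(angle),
                                TORSION_RESTRAINT_KCAL)
    ff.Minimize(maxIts=2000)
    return mol


def compare_profiles(
    profiles: dict[str, TorsionProfile],
    window: tuple[float, float] = (150.0, 210.0),
) -> pd.DataFrame:
    """Energy penalty of the best angle inside a window, per profile.

    The penalty is the lowest energy on grid points inside ``window``
    (inclusive) relative to the profile's global minimum; a profile whose
    global minimum lies inside the window has penalty 0.  Profiles must share
    their grid.  Returns a DataFrame sorted ascending by penalty.
    """
    grids = [tuple(p.angles) for p in profiles.values()]
    if len(set(grids)) > 1:
        raise ValueError("profiles do not share a common angle grid")
    lo, hi = window
    rows = []
    for name, prof in profiles.items():
        inside = (prof.angles >= lo) & (prof.angles <= hi)
        if not inside.any():
            raise ValueError(f"window {window} contains no grid points")
        penalty = float(prof.energies[inside].min())
        rows.append({"name": name, "window_penalty_kcal": penalty,
                     "global_min_angle": prof.global_minimum_angle()})
    return (
        pd.DataFrame(rows)
        .sort_values(["window_penalty_kcal", "name"])
        .reset_index(drop=True)
    )
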