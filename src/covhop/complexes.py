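"""Geometric analysis of covalent ligand-protein complexes (PDB).

Parses a crystal structure, identifies the covalent cysteine-ligand linkage
(SG within covalent-bond distance of a ligand atom, or from LINK records),
measures the core-head biaryl dihedral of the bound ligand, and maps
protein-ligand hydrogen bonds such as the Gly backbone contact and the
Lys-warhead-carbonyl coordination that characterize the rotated binding mode
of the isoquinolinone series.

Crystal structures at typical resolution carry no hydrogens, so hydrogen
bonds use the heavy-atom criterion only: donor/acceptor nitrogen or oxygen
pairs within 3.5 angstroms.  Coordinates are angstroms in the PDB orthogonal
frame; residues keep the numbering of the file.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import gemmi
import numpy as np

COVALENT_SG_CUTOFF = 1.9   # angstroms, SG-ligand carbon
HBOND_HEAVY_CUTOFF = 3.5   # angstroms, donor/acceptor heavy atoms
BOND_CUTOFF = 1.75         # angstroms, generic heavy-atom covalent bond


class ComplexError(ValueError):
    pass


@dataclass(frozen=True)
class AtomRef:
    chain: str
    residue_name: str
    residue_number: int
    atom_name: str
    element: str
    xyz: tuple[float, float, float]

    @property
    def pos(self) -> np.ndarray:
        return np.asarray(self.xyz, dtype=float)

    def __str__(self) -> str:
        return f"{self.chain}/{self.residue_name}{self.residue_number}/{self.atom_name}"


@dataclass(frozen=True)
class CovalentLink:
    cys: AtomRef       # the SG atom
    ligand_atom: AtomRef
    distance: float


@dataclass(frozen=True)
class HBondContact:
    protein_atom: AtomRef
    ligand_atom: AtomRef
    distance: float
    role: str          # e.g. "Gly10-backbone", "Lys16-sidechain"


@dataclass
class CovalentComplex:
    protein_atoms: list[AtomRef]
    ligand_atoms: list[AtomRef]
    het_code: str
    covalent_link: CovalentLink | None = None

    def ligand_atom(self, name: str) -> AtomRef:
        for atom in self.ligand_atoms:
            if atom.atom_name == name:
                return atom
        raise ComplexError(f"no ligand atom named {name!r}")


def _atom_ref(chain: gemmi.Chain, res: gemmi.Residue, atom: gemmi.Atom) -> AtomRef:
    return AtomRef(
        chain=chain.name,
        residue_name=res.name,
        residue_number=res.seqid.num,
        atom_name=atom.name,
        element=atom.element.name,
        xyz=(atom.pos.x, atom.pos.y, atom.pos.z),
    )


def load_complex(pdb_path: str | Path, het_code: str) -> CovalentComplex:
    """Parse a PDB file and locate the ligand and its cysteine linkage.

    The covalent link is detected geometrically: any cysteine SG within
    1.9 angstroms of a ligand heavy atom (symmetric in file order; the
    closest pair wins).  Raises :class:`ComplexError` listing available het
    codes when ``het_code`` is absent.
    """
    structure = gemmi.read_pdb(str(pdb_path))
    structure.setup_entities()
    model = structure[0]
    protein_atoms: list[AtomRef] = []
    ligand_atoms: list[AtomRef] = []
    het_codes_seen: set[str] = set()
    for chain in model:
        for res in chain:
            info = gemmi.find_tabulated_residue(res.name)
            is_amino = info is not None and info.is_amino_acid()
            if res.name == het_code:
                ligand_atoms.extend(_atom_ref(chain, res, a) for a in res)
            elif is_amino:
                protein_atoms.extend(_atom_ref(chain, res, a) for a in res)
            elif res.name not in ("HOH", "WAT"):
                het_codes_seen.add(res.name)
    if not ligand_atoms:
        raise ComplexError(
            f"het code {het_code!r} not found; available: "
            f"{', '.join(sorted(het_codes_seen)) or 'none'}"
        )

    link = None
    best = COVALENT_SG_CUTOFF
    for patom in protein_atoms:
        if not (patom.residue_name == "CYS" and patom.atom_name == "SG"):
            continue
        for latom in ligand_atoms:
            if latom.element == "H":
                continue
            d = float(np.linalg.norm(patom.pos - latom.pos))
            if d <= best:
                best = d
                link = CovalentLink(patom, latom, d)
    return CovalentComplex(protein_atoms, ligand_atoms, het_code, link)


def _ligand_bonds(atoms: list[AtomRef], cutoff: float = BOND_CUTOFF) -> dict[int, list[int]]:
    """Distance-based heavy-atom bond graph of the ligand."""
    adj: dict[int, list[int]] = {i: [] for i in range(len(atoms))}
    for i in range(len(atoms)):
        if atoms[i].element == "H":
            continue
        for j in range(i + 1, len(atoms)):
            if atoms[j].element == "H":
                continue
            if np.linalg.norm(atoms[i].pos - atoms[j].pos) <= cutoff:
                adj[i].append(j)
                adj[j].append(i)
    return adj


def _ring_atoms(adj: dict[int, list[int]]) -> set[int]:
    import networkx as nx

    g = nx.Graph((i, j) for i, nbrs in adj.items() for j in nbrs)
    ring: set[int] = set()
    for cycle in nx.cycle_basis(g):
        ring.update(cycle)
    return ring


def dihedral_angle(p0, p1, p2, p3) -> float:
    """Standard 4-point dihedral, degrees in [0, 360)."""
    b0 = np.asarray(p0, float) - np.asarray(p1, float)
    b1 = np.asarray(p2, float) - np.asarray(p1, float)
    b2 = np.asarray(p3, float) - np.asarray(p2, float)
    b1 /= np.linalg.norm(b1)
    v = b0 - np.dot(b0, b1) * b1
    w = b2 - np.dot(b2, b1) * b1
    x = np.dot(v, w)
    y = np.dot(np.cross(b1, v), w)
    return float(math.degrees(math.atan2(y, x))) % 360.0


def core_head_dihedral(
    complex_: CovalentComplex, core_atom: str, head_atom: str
) -> float:
    """Core-head biaryl dihedral of the bound ligand, degrees in [0, 360).

    ``core_atom`` / ``head_atom`` name the two bonded ring atoms across the
    biaryl bond.  The flanking reference atoms are each side's ring neighbor
    with the lowest atom name (lexicographic; recorded convention, mirroring
    the lowest-canonical-rank rule used for molecules).
    """
    atoms = complex_.ligand_atoms
    name_to_idx = {a.atom_name: i for i, a in enumerate(atoms)}
    try:
        ci, hi = name_to_idx[core_atom], name_to_idx[head_atom]
    except KeyError as exc:
        raise ComplexError(f"ligand atom {exc} not found") from exc
    adj = _ligand_bonds(atoms)
    if hi not in adj[ci]:
        raise ComplexError(f"{core_atom} and {head_atom} are not bonded")
    rings = _ring_atoms(adj)

    def pick(center: int, exclude: int) -> int:
        nbrs = [n for n in adj[center] if n != exclude and n in rings]
        if not nbrs:
            nbrs = [n for n in adj[center] if n != exclude]
        if not nbrs:
            raise ComplexError(f"atom {atoms[center]} has no usable neighbor")
        return min(nbrs, key=lambda n: atoms[n].atom_name)

    a, d = pick(ci, hi), pick(hi, ci)
    return dihedral_angle(atoms[a].pos, atoms[ci].pos, atoms[hi].pos, atoms[d].pos)


_PROTEIN_POLAR = {"N", "O"}  # element symbols that can donate/accept


def map_hbonds(
    complex_: CovalentComplex, cutoff: float = HBOND_HEAVY_CUTOFF
) -> list[HBondContact]:
    """Protein-ligand donor/acceptor pairs within the heavy-atom cutoff.

    Every protein N/O against every ligand N/O (halogens and carbons are not
    hydrogen-bond partners under this criterion).  Contacts are tagged
    ``<Res><num>-backbone`` for protein backbone N/O and
    ``<Res><num>-sidechain`` otherwise.
    """
    contacts = []
    backbone_names = {"N", "O", "OXT"}
    for patom in complex_.protein_atoms:
        if patom.element not in _PROTEIN_POLAR:
            continue
        for latom in complex_.ligand_atoms:
            if latom.element not in _PROTEIN_POLAR:
                continue
            d = float(np.linalg.norm(patom.pos - latom.pos))
            if d <= cutoff:
                part = "backbone" if patom.atom_name in backbone_names else "sidechain"
                role = f"{patom.residue_name.capitalize()}{patom.residue_number}-{part}"
                contacts.append(HBondContact(patom, latom, d, role))
    contacts.sort(key=lambda c: c.distance)
    return contacts
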