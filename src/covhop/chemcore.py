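"""Molecule and fragment data model.

Fragments carry labeled attachment points encoded as dummy atoms with atom-map
numbers (``[*:1]``); two fragments can be joined wherever their dummy labels
match.  A reference ligand annotated with cut bonds is deconstructed into
role-labeled fragments (warhead / bridge / core / head), and the inverse
operation (:func:`reassemble`) restores the parent molecule, which gives a
round-trip identity check used throughout the test suite.

Molecular identity is a canonical key: the canonical SMILES of the
standardized structure (largest fragment, neutralized, stereochemistry kept).
Tautomer-insensitive keys are available behind a flag but are off by default.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Iterator, Sequence

from rdkit import Chem, RDLogger
from rdkit.Chem.MolStandardize import rdMolStandardize

RDLogger.DisableLog("rdApp.*")


class ChemError(ValueError):
    """Base class for chemistry-level input errors."""


class ParseError(ChemError):
    """A SMILES/SDF input failed to parse; the message names the input."""


class FragmentationError(ChemError):
    """Invalid cut-bond annotation (ring bond, missing bond, bad roles)."""


class Role(str, Enum):
    """Role of a fragment in the assembly graph warhead-bridge-core-head."""

    WARHEAD = "warhead"
    BRIDGE = "bridge"
    CORE = "core"
    HEAD = "head"


#: attachment labels expected per role, by assembly edge:
#: warhead-[1]-bridge-[2]-core-[3]-head
ROLE_LABELS: dict[Role, frozenset[str]] = {
    Role.WARHEAD: frozenset({"1"}),
    Role.BRIDGE: frozenset({"1", "2"}),
    Role.CORE: frozenset({"2", "3"}),
    Role.HEAD: frozenset({"3"}),
}


@dataclass(frozen=True)
class MoleculeRecord:
    """An identified molecule: id, canonical SMILES, and provenance tag."""

    id: str
    smiles: str
    source: str = "fixture"  # enumerated | reference | fixture

    def mol(self) -> Chem.Mol:
        return mol_from_smiles(self.smiles)


@dataclass(frozen=True)
class FragmentRecord:
    """A fragment with a role and labeled attachment points.

    ``attachment_points`` maps each label to the index of the dummy atom
    carrying it; every label appears on exactly one atom.
    """

    id: str
    smiles: str
    role: Role
    attachment_points: tuple[tuple[str, int], ...] = ()

    def mol(self) -> Chem.Mol:
        return mol_from_smiles(self.smiles)

    @property
    def labels(self) -> frozenset[str]:
        return frozenset(lbl for lbl, _ in self.attachment_points)


@dataclass(frozen=True)
class CutBondAnnotation:
    """A user-annotated acyclic single bond to sever, with per-side roles."""

    bond: tuple[int, int]
    roles: tuple[Role, Role]

    @classmethod
    def from_dict(cls, d: dict) -> "CutBondAnnotation":
        a, b = d["bond"]
        ra, rb = d["roles"]
        return cls((int(a), int(b)), (Role(ra), Role(rb)))


def mol_from_smiles(smiles: str) -> Chem.Mol:
    """Parse a SMILES string, raising :class:`ParseError` on failure."""
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise ParseError(f"unparsable SMILES: {smiles!r}")
    return mol


_UNCHARGER = rdMolStandardize.Uncharger()
_LARGEST = rdMolStandardize.LargestFragmentChooser()
_TAUTOMER = rdMolStandardize.TautomerEnumerator()


def canonical_key(smiles: str, *, tautomer_insensitive: bool = False) -> str:
    """Dialect-independent identity key for a molecule.

    Canonical SMILES of the standardized molecule: largest covalent fragment,
    neutralized charges, stereochemistry preserved.  Kekulized and aromatic
    inputs of the same molecule map to the same key.  ``tautomer_insensitive``
    additionally canonicalizes the tautomer (off by default: enumeration and
    novelty checks treat tautomers as distinct unless asked otherwise).
    """
    mol = mol_from_smiles(smiles)
    if mol.GetNumAtoms() > 1:
        mol = _LARGEST.choose(mol)
    mol = _UNCHARGER.uncharge(mol)
    if tautomer_insensitive:
        mol = _TAUTOMER.Canonicalize(mol)
    return Chem.MolToSmiles(mol)


def validate_no_dangling_attachments(smiles: str) -> None:
    """Raise if a product SMILES still carries attachment dummies."""
    mol = mol_from_smiles(smiles)
    for atom in mol.GetAtoms():
        if atom.GetAtomicNum() == 0:
            raise ChemError(
                f"dangling attachment label *:{atom.GetAtomMapNum()} in {smiles!r}"
            )


def attachment_points(mol: Chem.Mol) -> tuple[tuple[str, int], ...]:
    """All labeled dummy atoms in ``mol`` as ``(label, atom_index)`` pairs."""
    points = []
    for atom in mol.GetAtoms():
        if atom.GetAtomicNum() == 0 and atom.GetAtomMapNum() > 0:
            points.append((str(atom.GetAtomMapNum()), atom.GetIdx()))
    return tuple(points)


def _check_cut_bonds(mol: Chem.Mol, cuts: Sequence[CutBondAnnotation]) -> list[int]:
    bond_indices = []
    for cut in cuts:
        a, b = cut.bond
        bond = mol.GetBondBetweenAtoms(a, b)
        if bond is None:
            raise FragmentationError(f"no bond between atoms {a} and {b}")
        if bond.GetBondType() != Chem.BondType.SINGLE:
            raise FragmentationError(f"cut bond {a}-{b} is not a single bond")
        if bond.IsInRing():
            raise FragmentationError(f"cut bond {a}-{b} is a ring bond; cuts must be acyclic")
        bond_indices.append(bond.GetIdx())
    if len(set(bond_indices)) != len(bond_indices):
        raise FragmentationError("duplicate cut-bond annotations")
    return bond_indices


def fragment_reference_ligand(
    record: MoleculeRecord, cuts: Sequence[CutBondAnnotation]
) -> list[FragmentRecord]:
    """Deconstruct a ligand into role-labeled fragments at annotated cut bonds.

    Cutting ``k`` acyclic bonds yields ``k + 1`` fragments.  The two ends of
    cut ``i`` receive the shared attachment label ``str(i + 1)``, so
    :func:`reassemble` can restore the parent.  Each cut annotates the role of
    the fragment on either side; conflicting role votes raise
    :class:`FragmentationError`.

    With no cuts the molecule itself is returned as a single core fragment.
    """
    mol = mol_from_smiles(record.smiles)
    if not cuts:
        return [FragmentRecord(id=f"{record.id}:whole", smiles=record.smiles, role=Role.CORE)]
    bond_indices = _check_cut_bonds(mol, cuts)

    for atom in mol.GetAtoms():
        atom.SetIntProp("_orig_idx", atom.GetIdx())
    # dummyLabels sets isotopes; converted to atom-map labels below
    fragmented = Chem.FragmentOnBonds(
        mol, bond_indices, addDummies=True,
        dummyLabels=[(i + 1, i + 1) for i in range(len(bond_indices))],
    )
    for atom in fragmented.GetAtoms():
        if atom.GetAtomicNum() == 0 and atom.GetIsotope() > 0:
            atom.SetAtomMapNum(atom.GetIsotope())
            atom.SetIsotope(0)

    pieces = Chem.GetMolFrags(fragmented, asMols=True, sanitizeFrags=True)
    if len(pieces) != len(cuts) + 1:
        raise FragmentationError(
            f"cutting {len(cuts)} bonds produced {len(pieces)} fragments; "
            "cuts must be acyclic and distinct"
        )

    # vote roles onto fragments via the original atom index of each cut end
    orig_to_piece: dict[int, int] = {}
    for pi, piece in enumerate(pieces):
        for atom in piece.GetAtoms():
            if atom.HasProp("_orig_idx"):
                orig_to_piece[atom.GetIntProp("_orig_idx")] = pi
    votes: dict[int, set[Role]] = {}
    for cut in cuts:
        for orig_idx, role in zip(cut.bond, cut.roles):
            votes.setdefault(orig_to_piece[orig_idx], set()).add(role)
    records = []
    for pi, piece in enumerate(pieces):
        roles = votes.get(pi, set())
        if len(roles) != 1:
            raise FragmentationError(
                f"fragment {pi} received role votes {sorted(r.value for r in roles)}; "
                "cut-bond role annotations are inconsistent with connectivity"
            )
        role = roles.pop()
        smiles = Chem.MolToSmiles(piece)
        piece_canon = mol_from_smiles(smiles)  # indices in canonical output order
        records.append(
            FragmentRecord(
                id=f"{record.id}:{role.value}",
                smiles=smiles,
                role=role,
                attachment_points=attachment_points(piece_canon),
            )
        )
    return records


def join_on_labels(mols: Iterable[Chem.Mol]) -> Chem.Mol:
    """Join molecules at dummy atoms with matching atom-map labels."""
    mols = list(mols)
    combined = mols[0]
    for other in mols[1:]:
        combined = Chem.CombineMols(combined, other)
    joined = Chem.molzip(combined)
    Chem.SanitizeMol(joined)
    return joined


def reassemble(fragments: Sequence[FragmentRecord]) -> str:
    """Rejoin fragments at matching attachment labels; returns the canonical key."""
    joined = join_on_labels(frag.mol() for frag in fragments)
    return canonical_key(Chem.MolToSmiles(joined))


# ---------------------------------------------------------------------------
# io


def read_smiles_file(path: str | Path) -> Iterator[MoleculeRecord]:
    """Read a SMILES file (one per line, optional tab-separated id)."""
    path = Path(path)
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            smiles = parts[0]
            mol_id = parts[1] if len(parts) > 1 else f"{path.stem}-{lineno}"
            yield MoleculeRecord(id=mol_id, smiles=smiles)


def write_smiles_file(path: str | Path, records: Iterable[MoleculeRecord]) -> int:
    n = 0
    with Path(path).open("w") as fh:
        for rec in records:
            fh.write(f"{rec.smiles}\t{rec.id}\n")
            n += 1
    return n


def read_fragment_library(path: str | Path, role: Role) -> list[FragmentRecord]:
    """Read a fragment SMILES file; attachment labels come from [*:n] dummies."""
    fragments = []
    for rec in read_smiles_file(path):
        mol = mol_from_smiles(rec.smiles)
        fragments.append(
            FragmentRecord(
                id=rec.id, smiles=rec.smiles, role=role,
                attachment_points=attachment_points(mol),
            )
        )
    return fragments


def read_cuts_json(path: str | Path) -> list[CutBondAnnotation]:
    data = json.loads(Path(path).read_text())
    return [CutBondAnnotation.from_dict(d) for d in data]
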