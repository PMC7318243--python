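"""Combinatorial assembly of warhead x bridge x core x head libraries.

Assembly follows the linear graph warhead-[1]-bridge-[2]-core-[3]-head:
fragments are joined at dummy atoms sharing an attachment label.  Enumeration
streams products one at a time (constant memory apart from the dedup key set),
iterates deterministically in lexicographic fragment-id order, deduplicates by
canonical key, and counts valence/sanitization rejects instead of raising, so
a large combinatorial space survives individual bad combinations.

Each product tracks its provenance (the four source fragment ids) and the
index of the core atom bonded to the bridge — the position whose SNAr
electrophilicity is assessed downstream.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, Sequence

from rdkit import Chem

from covhop.chemcore import (
    ChemError,
    FragmentRecord,
    MoleculeRecord,
    ROLE_LABELS,
    Role,
    canonical_key,
)

#: Michael-acceptor motif every product must retain (acrylamide-class warhead)
MICHAEL_ACCEPTOR_SMARTS = Chem.MolFromSmarts("C=CC(=O)N")

_ASSEMBLY_ORDER = (Role.WARHEAD, Role.BRIDGE, Role.CORE, Role.HEAD)


@dataclass(frozen=True)
class FragmentLibrary:
    """All fragments of one role, with a homogeneous attachment-label set."""

    role: Role
    fragments: tuple[FragmentRecord, ...]

    def __post_init__(self):
        expected = ROLE_LABELS[self.role]
        for frag in self.fragments:
            if frag.role != self.role:
                raise ChemError(f"fragment {frag.id} has role {frag.role.value}, "
                                f"library is {self.role.value}")
            if frag.labels != expected:
                raise ChemError(
                    f"fragment {frag.id} carries labels {sorted(frag.labels)}, "
                    f"role {self.role.value} requires {sorted(expected)}"
                )

    def __len__(self) -> int:
        return len(self.fragments)

    def sorted_fragments(self) -> list[FragmentRecord]:
        return sorted(self.fragments, key=lambda f: f.id)


@dataclass
class EnumerationManifest:
    """Bookkeeping for one enumeration run; counts reconcile exactly."""

    input_sizes: dict[str, int]
    combinations: int
    unique_products: int = 0
    duplicates: int = 0
    rejected_valence: int = 0

    def check(self) -> None:
        assert self.combinations == (
            self.unique_products + self.duplicates + self.rejected_valence
        ), "manifest counts do not reconcile"


@dataclass(frozen=True)
class AssembledMolecule(MoleculeRecord):
    """An enumerated product with provenance back to its fragments."""

    fragment_ids: tuple[str, ...] = ()
    core_attachment_idx: int = -1  # atom index (in .mol()) of the core-bridge carbon


def _libraries_by_role(libraries: Sequence[FragmentLibrary]) -> dict[Role, FragmentLibrary]:
    by_role = {lib.role: lib for lib in libraries}
    missing = [r.value for r in _ASSEMBLY_ORDER if r not in by_role]
    if missing:
        raise ChemError(f"missing fragment libraries for roles: {', '.join(missing)}")
    return by_role


def count_combinations(libraries: Sequence[FragmentLibrary]) -> int:
    """Size of the full combinatorial space: product of library sizes."""
    by_role = _libraries_by_role(libraries)
    n = 1
    for role in _ASSEMBLY_ORDER:
        n *= len(by_role[role])
    return n


def assemble(fragments: Sequence[FragmentRecord]) -> Chem.Mol:
    """Join one fragment per role into a product molecule.

    The core atom bonded to the bridge (across label "2") is tagged with the
    atom property ``core_attach`` before joining; RDKit properties survive the
    zip, so the product can recover the position for the electrophilicity rule.
    """
    mols = []
    for frag in fragments:
        mol = frag.mol()
        if frag.role is Role.CORE:
            for atom in mol.GetAtoms():
                if atom.GetAtomicNum() == 0 and atom.GetAtomMapNum() == 2:
                    atom.GetNeighbors()[0].SetBoolProp("core_attach", True)
        mols.append(mol)
    combined = mols[0]
    for other in mols[1:]:
        combined = Chem.CombineMols(combined, other)
    product = Chem.molzip(combined)
    Chem.SanitizeMol(product)
    return product


def core_attachment_index(mol: Chem.Mol) -> int:
    for atom in mol.GetAtoms():
        if atom.HasProp("core_attach"):
            return atom.GetIdx()
    return -1


def enumerate_library(
    libraries: Sequence[FragmentLibrary],
    id_prefix: str = "cmpd",
) -> tuple[Iterator[AssembledMolecule], EnumerationManifest]:
    """Stream the full combinatorial library, deduplicated by canonical key.

    Returns ``(generator, manifest)``; the manifest is filled in as the
    generator is consumed and reconciles exactly once it is exhausted
    (combinations = unique + duplicates + rejected).  Iteration order is
    deterministic: lexicographic by fragment id, nested
    warhead > bridge > core > head.
    """
    by_role = _libraries_by_role(libraries)
    manifest = EnumerationManifest(
        input_sizes={r.value: len(by_role[r]) for r in _ASSEMBLY_ORDER},
        combinations=count_combinations(libraries),
    )

    def generate() -> Iterator[AssembledMolecule]:
        seen: set[str] = set()
        counter = 0
        for warhead in by_role[Role.WARHEAD].sorted_fragments():
            for bridge in by_role[Role.BRIDGE].sorted_fragments():
                for core in by_role[Role.CORE].sorted_fragments():
                    for head in by_role[Role.HEAD].sorted_fragments():
                        parts = (warhead, bridge, core, head)
                        try:
                            product = assemble(parts)
                            raw = Chem.MolToSmiles(product)
                            key = canonical_key(raw)
                        except (ChemError, Chem.rdchem.AtomValenceException,
                                Chem.rdchem.KekulizeException):
                            manifest.rejected_valence += 1
                            continue
                        if key in seen:
                            manifest.duplicates += 1
                            continue
                        seen.add(key)
                        counter += 1
                        manifest.unique_products += 1
                        # map the tagged core atom into the canonical SMILES
                        # atom order (= parse order of `key`); valid only when
                        # standardization left the SMILES unchanged
                        attach = core_attachment_index(product)
                        canon_attach = -1
                        if attach >= 0 and key == raw:
                            out_order = list(
                                product.GetPropsAsDict(True, True)["_smilesAtomOutputOrder"]
                            )
                            canon_attach = out_order.index(attach)
                        yield AssembledMolecule(
                            id=f"{id_prefix}-{counter:06d}",
                            smiles=key,
                            source="enumerated",
                            fragment_ids=tuple(p.id for p in parts),
                            core_attachment_idx=canon_attach,
                        )
        manifest.check()

    return generate(), manifest
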