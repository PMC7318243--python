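"""Chemistry filters of the prioritization funnel.

Three pure, order-independent molecule-level filters:

* **novelty** — drop products whose canonical key occurs in a reference
  database (e.g. a ChEMBL export), so only new chemical matter survives;
* **electrophilicity** — the core position bonded to the bridge must be
  SNAr-activated, i.e. the aromatic attachment carbon lies ortho or para
  (within its fused aromatic system) to a pyridine-type ring nitrogen or to a
  ring carbon bearing an exocyclic carbonyl / strong electron-withdrawing
  group.  This encodes, as an explicit configurable rule, a judgement the
  original workflow made by eye; the default is an interpretation, not a
  claim of equivalence;
* **availability** — every building block a product was assembled from must
  occur (by canonical key) in a commercial catalog.

Each filter returns a :class:`FilterReport` whose counts reconcile exactly
with the stream it consumed, plus stable machine-readable reason codes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from rdkit import Chem

from covhop.chemcore import ChemError, FragmentRecord, canonical_key
from covhop.enumeration import AssembledMolecule

# stable reason codes (tested; do not rename)
REASON_KNOWN = "known_in_reference"
REASON_POOR_ELECTROPHILICITY = "poor_electrophilicity"
REASON_NOT_AROMATIC = "attachment_not_aromatic"
REASON_NO_ATTACHMENT = "attachment_untracked"
REASON_BLOCK_UNAVAILABLE = "building_block_unavailable"


@dataclass
class FilterReport:
    """Outcome of one filter stage; ``passed + failed == input_count``."""

    filter_name: str
    input_count: int = 0
    passed: int = 0
    failed: int = 0
    verdicts: dict[str, str] = field(default_factory=dict)  # molecule id -> reason code

    def record(self, mol_id: str, reason: str | None) -> bool:
        self.input_count += 1
        if reason is None:
            self.passed += 1
            return True
        self.failed += 1
        self.verdicts[mol_id] = reason
        return False

    def check(self) -> None:
        assert self.passed + self.failed == self.input_count


@dataclass(frozen=True)
class ElectrophilicityRule:
    """Positional SNAr-activation rule for the core attachment carbon.

    ``ring_distances``: topological distances (within the fused aromatic
    system) at which an activating group counts; 1 = ortho, 3 = para for a
    six-membered ring.  Activators are pyridine-type ring nitrogens and ring
    atoms bearing an exocyclic activating group (``ewg_smarts``, matched with
    the first atom on the ring).
    """

    ring_distances: tuple[int, ...] = (1, 3)
    ewg_smarts: tuple[str, ...] = (
        "[c,C]=[O,S]",        # ring-fused / exocyclic carbonyl, thiocarbonyl
        "[c,C][N+](=O)[O-]",  # nitro
        "[c,C]C#N",           # nitrile
        "[c,C]S(=O)=O",       # sulfonyl
    )


DEFAULT_ELECTROPHILICITY_RULE = ElectrophilicityRule()


def novelty_filter(
    molecules: Iterable[AssembledMolecule],
    reference_keys: frozenset[str] | set[str],
) -> tuple[list[AssembledMolecule], FilterReport]:
    """Pass molecules whose canonical key is absent from the reference set.

    ``reference_keys`` must be built with :func:`covhop.chemcore.canonical_key`
    so that SMILES-dialect differences cannot hide a known compound.
    """
    report = FilterReport("novelty")
    passing = []
    for mol in molecules:
        key = canonical_key(mol.smiles)
        if report.record(mol.id, REASON_KNOWN if key in reference_keys else None):
            passing.append(mol)
    report.check()
    return passing, report


def _aromatic_system(mol: Chem.Mol, start: int) -> set[int]:
    """Atoms of the fused aromatic ring system containing ``start``."""
    ri = mol.GetRingInfo()
    rings = [set(r) for r in ri.AtomRings()
             if all(mol.GetAtomWithIdx(i).GetIsAromatic() for i in r)]
    system = {start}
    grew = True
    while grew:
        grew = False
        for ring in rings:
            if ring & system and not ring <= system:
                system |= ring
                grew = True
    return system


def _ring_distances_from(mol: Chem.Mol, start: int, system: set[int]) -> dict[int, int]:
    """BFS bond distances from ``start`` restricted to the aromatic system."""
    dist = {start: 0}
    frontier = [start]
    while frontier:
        nxt = []
        for idx in frontier:
            for nbr in mol.GetAtomWithIdx(idx).GetNeighbors():
                j = nbr.GetIdx()
                if j in system and j not in dist:
                    dist[j] = dist[idx] + 1
                    nxt.append(j)
        frontier = nxt
    return dist


def is_snar_activated(
    mol: Chem.Mol, attachment_idx: int,
    rule: ElectrophilicityRule = DEFAULT_ELECTROPHILICITY_RULE,
) -> bool:
    """Is the aromatic carbon at ``attachment_idx`` SNAr-activated?"""
    atom = mol.GetAtomWithIdx(attachment_idx)
    if not atom.GetIsAromatic():
        raise ChemError("attachment atom is not aromatic")
    system = _aromatic_system(mol, attachment_idx)
    dist = _ring_distances_from(mol, attachment_idx, system)

    activating: set[int] = set()
    for idx in system:
        a = mol.GetAtomWithIdx(idx)
        # pyridine-type ring nitrogen: aromatic N contributing no H (not pyrrole-type)
        if a.GetAtomicNum() == 7 and a.GetIsAromatic() and a.GetTotalNumHs() == 0 \
                and a.GetDegree() == 2:
            activating.add(idx)
    for smarts in rule.ewg_smarts:
        patt = Chem.MolFromSmarts(smarts)
        for match in mol.GetSubstructMatches(patt):
            if match[0] in system:
                activating.add(match[0])

    return any(dist.get(idx) in rule.ring_distances for idx in activating)


def electrophilicity_filter(
    molecules: Iterable[AssembledMolecule],
    rule: ElectrophilicityRule = DEFAULT_ELECTROPHILICITY_RULE,
) -> tuple[list[AssembledMolecule], FilterReport]:
    """Pass molecules whose core-bridge attachment position is SNAr-activated.

    The attachment atom is recovered from enumeration provenance
    (``core_attachment_idx``); molecules without it fail with a distinct code.
    """
    report = FilterReport("electrophilicity")
    passing = []
    for mol in molecules:
        if mol.core_attachment_idx < 0:
            report.record(mol.id, REASON_NO_ATTACHMENT)
            continue
        rdmol = mol.mol()
        try:
            ok = is_snar_activated(rdmol, mol.core_attachment_idx, rule)
        except ChemError:
            report.record(mol.id, REASON_NOT_AROMATIC)
            continue
        if report.record(mol.id, None if ok else REASON_POOR_ELECTROPHILICITY):
            passing.append(mol)
    report.check()
    return passing, report


def availability_filter(
    molecules: Iterable[AssembledMolecule],
    catalog_keys: frozenset[str] | set[str],
    building_blocks: Mapping[str, FragmentRecord],
) -> tuple[list[AssembledMolecule], FilterReport]:
    """Pass products whose four source building blocks are all in the catalog.

    ``building_blocks`` maps fragment id -> fragment record (the provenance
    side); ``catalog_keys`` holds canonical keys of purchasable blocks, where
    a block's key is the canonical key of its fragment SMILES with attachment
    dummies hydrogen-capped (see :func:`building_block_key`).
    """
    report = FilterReport("availability")
    passing = []
    for mol in molecules:
        if not mol.fragment_ids:
            raise ChemError(f"product {mol.id} has no provenance; "
                            "availability filter requires enumeration metadata")
        missing = False
        for frag_id in mol.fragment_ids:
            frag = building_blocks.get(frag_id)
            if frag is None:
                raise ChemError(f"unknown fragment id {frag_id!r} in provenance of {mol.id}")
            if building_block_key(frag) not in catalog_keys:
                missing = True
                break
        if report.record(mol.id, REASON_BLOCK_UNAVAILABLE if missing else None):
            passing.append(mol)
    report.check()
    return passing, report


def building_block_key(frag: FragmentRecord) -> str:
    """Canonical key of a fragment's parent building block (dummies -> H)."""
    mol = frag.mol()
    editable = Chem.RWMol(mol)
    for atom in editable.GetAtoms():
        if atom.GetAtomicNum() == 0:
            atom.SetAtomicNum(1)
            atom.SetAtomMapNum(0)
    Chem.SanitizeMol(editable)
    return canonical_key(Chem.MolToSmiles(Chem.RemoveHs(editable.GetMol())))
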