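"""Seeded generator of synthetic test inputs.

Writes a self-contained input set for the funnel: fragment libraries
(acrylamide-class warheads; pyrrolidine / piperazine / piperidine bridges;
isoquinolinone / naphthyridinone / quinazoline cores; fluorophenol /
difluorophenyl heads), a pharmacophore model and pocket model derived from a
reference product conformer, a building-block catalog, a reference compound
database, and a synthetic covalent-complex PDB file.

Everything is deterministic for a fixed seed: running twice with the same
seed produces byte-identical files.  The structures emulate the chemistry of
the KRAS G12C switch-II pocket series at toy scale; the PDB complex is a
constructed stand-in (three pocket residues plus a ligand), not a crystal
structure.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
from rdkit import Chem
from rdkit.Chem import rdMolTransforms

from covhop import chemcore
from covhop.chemcore import FragmentRecord, Role, attachment_points
from covhop.enumeration import FragmentLibrary, assemble
from covhop.filters import building_block_key
from covhop.pharmacophore import (
    FeatureKind,
    PharmacophoreFeature,
    PharmacophoreModel,
    embed_conformers,
    perceive_features,
)
from covhop.pocket import ExcludedVolume, PocketModel, PocketSite, find_electrophile
from covhop.torsion import dihedral_reference_atoms, find_biaryl_bond

WARHEADS = {
    "wh-acrylamide": "C=CC(=O)[*:1]",
    "wh-fluoroacrylamide": "C=C(F)C(=O)[*:1]",
}
BRIDGES = {
    "br-piperazine": "[*:1]N1CCN([*:2])CC1",
    "br-pyrrolidin3yl": "[*:1]N1CCC([*:2])C1",
    "br-piperidin4yl": "[*:1]N1CCC([*:2])CC1",
}
CORES = {
    "co-quinazoline": "[*:2]c1ncnc2cc([*:3])ccc12",
    "co-isoquinolinone": "O=c1[nH]cc([*:2])c2cc([*:3])ccc12",
    "co-naphthyridinone-16": "O=c1[nH]cc([*:2])c2cc([*:3])cnc12",
    "co-naphthyridinone-26": "O=c1[nH]cc([*:2])c2cc([*:3])ncc12",
    "co-benzene": "[*:2]c1ccc([*:3])cc1",  # unactivated attachment position
}
HEADS = {
    "hd-fluorophenol": "Oc1cccc(F)c1[*:3]",
    "hd-difluorophenyl": "Fc1cccc(F)c1[*:3]",
}

_TINY = {"warheads": 1, "bridges": 2, "cores": 3, "heads": 2}   # 12 combinations
_SMALL = {"warheads": 2, "bridges": 3, "cores": 5, "heads": 2}  # 60 combinations


def fragment_records(role: Role, table: dict[str, str], n: int) -> list[FragmentRecord]:
    records = []
    for frag_id, smiles in sorted(table.items())[:n]:
        mol = chemcore.mol_from_smiles(smiles)
        records.append(
            FragmentRecord(id=frag_id, smiles=smiles, role=role,
                           attachment_points=attachment_points(mol))
        )
    return records


def fixture_libraries(scale: str = "tiny") -> list[FragmentLibrary]:
    sizes = {"tiny": _TINY, "small": _SMALL}[scale]
    return [
        FragmentLibrary(Role.WARHEAD, tuple(fragment_records(Role.WARHEAD, WARHEADS, sizes["warheads"]))),
        FragmentLibrary(Role.BRIDGE, tuple(fragment_records(Role.BRIDGE, BRIDGES, sizes["bridges"]))),
        FragmentLibrary(Role.CORE, tuple(fragment_records(Role.CORE, CORES, sizes["cores"]))),
        FragmentLibrary(Role.HEAD, tuple(fragment_records(Role.HEAD, HEADS, sizes["heads"]))),
    ]


def reference_product(seed: int = 2020) -> Chem.Mol:
    """ARS-1620-like reference product with one seeded 3D conformer."""
    parts = [
        fragment_records(Role.WARHEAD, WARHEADS, 1)[0],
        fragment_records(Role.BRIDGE, BRIDGES, 3)[0],  # piperazine
        fragment_records(Role.CORE, CORES, 5)[4],      # quinazoline
        fragment_records(Role.HEAD, HEADS, 2)[1],      # fluorophenol
    ]
    product = assemble(parts)
    return embed_conformers(product, n=1, seed=seed)


def fixture_pharmacophore(seed: int = 2020) -> PharmacophoreModel:
    """Toy model built from the reference conformer's own feature points."""
    mol = reference_product(seed)
    points = perceive_features(mol)
    chosen: list[PharmacophoreFeature] = []
    wanted = [
        (FeatureKind.COVALENT_ANCHOR, True, 1.5),
        (FeatureKind.AROMATIC_RING, True, 1.5),
        (FeatureKind.ACCEPTOR, True, 1.5),
        (FeatureKind.DONOR, False, 2.0),
    ]
    for kind, required, radius in wanted:
        for p in points:
            if p.kind is kind:
                chosen.append(
                    PharmacophoreFeature(kind, tuple(round(x, 3) for x in p.position),
                                         radius=radius, required=required)
                )
                break
    return PharmacophoreModel(tuple(chosen), name="switch2-toy")


def fixture_pocket(seed: int = 2020) -> PocketModel:
    """Toy pocket: anchor at bond distance from the reference electrophile."""
    mol = reference_product(seed)
    coords = mol.GetConformer().GetPositions()
    beta = find_electrophile(mol)
    points = perceive_features(mol)
    centroid = coords.mean(axis=0)
    direction = coords[beta] - centroid
    direction /= np.linalg.norm(direction)
    anchor = coords[beta] + 1.81 * direction
    sites = []
    for kind in (FeatureKind.ACCEPTOR, FeatureKind.AROMATIC_RING, FeatureKind.DONOR):
        for p in points:
            if p.kind is kind:
                sites.append(PocketSite(kind, tuple(round(x, 3) for x in p.position),
                                        radius=2.0, weight=2.0))
                break
    far = centroid + np.array([0.0, 0.0, 25.0])
    return PocketModel(
        anchor=tuple(round(float(x), 3) for x in anchor),
        sites=tuple(sites),
        excluded_volumes=(ExcludedVolume(tuple(round(float(x), 3) for x in far), 2.0),),
    )


def fixture_reference_db(scale: str = "tiny") -> list[str]:
    """SMILES of 'known' compounds: two enumerable products, one unrelated.

    One product is written kekulized to exercise dialect-independent novelty
    matching.
    """
    libs = {lib.role: lib.sorted_fragments() for lib in fixture_libraries(scale)}
    first = assemble([libs[Role.WARHEAD][0], libs[Role.BRIDGE][0],
                      libs[Role.CORE][0], libs[Role.HEAD][0]])
    second = assemble([libs[Role.WARHEAD][0], libs[Role.BRIDGE][-1],
                       libs[Role.CORE][-1], libs[Role.HEAD][-1]])
    kekulized = Chem.MolToSmiles(first, kekuleSmiles=True)
    return [kekulized, Chem.MolToSmiles(second), "CC(=O)Oc1ccccc1C(=O)O"]


def fixture_catalog(scale: str = "tiny") -> list[str]:
    """Building-block SMILES for all fixture fragments except one bridge.

    Leaving one block out makes the availability filter reject exactly the
    products that use it.
    """
    keys = []
    for lib in fixture_libraries(scale):
        for frag in lib.sorted_fragments():
            if frag.id == "br-piperidin4yl":
                continue
            keys.append(building_block_key(frag))
    return sorted(set(keys))


# --- synthetic covalent complex --------------------------------------------

def _pdb_atom_line(serial, name, res_name, chain, res_num, xyz, element, het=False):
    record = "HETATM" if het else "ATOM  "
    return (
        f"{record}{serial:>5d} {name:<4s}{res_name:>4s}{chain:>2s}{res_num:>4d}"
        f"    {xyz[0]:8.3f}{xyz[1]:8.3f}{xyz[2]:8.3f}  1.00 20.00"
        f"          {element:>2s}\n"
    )


def synthetic_complex_pdb(
    path: str | Path, seed: int = 2020, dihedral_deg: float = 146.0
) -> dict:
    """Write a synthetic covalent-complex PDB mirroring the pocket geometry.

    A naphthyridinone-series ligand conformer (core-head dihedral restrained to
    ``dihedral_deg`` under the file-side naming convention) is placed with:
    a CYS12 whose SG sits 1.80 A from the warhead beta-carbon, a GLY10 whose
    backbone N sits 2.9 A from the core carbonyl O, and a LYS16 whose NZ
    sits 2.9 A from the warhead carbonyl O.  Returns a manifest (ligand atom
    names of the biaryl bond, expected dihedral) for tests.
    """
    parts_smiles = "C=CC(=O)N1CCC(c2c[nH]c(=O)c3cnc(-c4c(O)cccc4F)cc23)C1"
    mol = embed_conformers(chemcore.mol_from_smiles(parts_smiles), n=1, seed=seed)
    mol_noh = Chem.RemoveHs(mol)

    # name heavy atoms: element symbol + per-element counter (C1, N1, O1 ...)
    counters: dict[str, int] = {}
    names = []
    for atom in mol_noh.GetAtoms():
        el = atom.GetSymbol()
        counters[el] = counters.get(el, 0) + 1
        names.append(f"{el}{counters[el]}")

    # set the biaryl dihedral using the same flanking-atom rule the PDB
    # reader applies (lowest atom name), so the file reads back dihedral_deg
    ci, hi = find_biaryl_bond(mol_noh)

    def ring_neighbors(center, exclude):
        return [n.GetIdx() for n in mol_noh.GetAtomWithIdx(center).GetNeighbors()
                if n.GetIdx() != exclude and n.IsInRing()]

    a = min(ring_neighbors(ci, hi), key=lambda k: names[k])
    d = min(ring_neighbors(hi, ci), key=lambda k: names[k])
    conf = mol_noh.GetConformer()
    rdMolTransforms.SetDihedralDeg(conf, a, ci, hi, d, float(dihedral_deg))
    coords = conf.GetPositions()

    beta = find_electrophile(mol_noh)
    carbonyl_o = mol_noh.GetSubstructMatches(
        Chem.MolFromSmarts("C=CC(=[OX1])N"))[0][3]
    # core lactam oxygen (exocyclic O on the aromatic 2-pyridone carbon)
    lactam_o = mol_noh.GetSubstructMatches(Chem.MolFromSmarts("[OX1]=c"))
    lactam_o = lactam_o[0][0] if lactam_o else carbonyl_o

    centroid = coords.mean(axis=0)

    def outward(idx, dist):
        v = coords[idx] - centroid
        v /= np.linalg.norm(v)
        return coords[idx] + dist * v

    sg = outward(beta, 1.80)
    gly_n = outward(lactam_o, 2.90)
    lys_nz = outward(carbonyl_o, 2.90)

    rng = np.random.default_rng(seed)

    def stub_residue(lines, serial, res_name, res_num, key_atom_name, key_xyz):
        """Minimal residue: N, CA, C, O backbone plus the key atom.

        The backbone is placed further along the outward direction so stub
        atoms cannot collide with the ligand.
        """
        away = key_xyz - centroid
        away = away / np.linalg.norm(away)
        base = key_xyz + 4.5 * away
        jitter = rng.normal(scale=0.05, size=(4, 3))
        backbone = {
            "N": base + np.array([0.0, 0.0, 0.0]) + jitter[0],
            "CA": base + np.array([1.45, 0.0, 0.0]) + jitter[1],
            "C": base + np.array([2.2, 1.2, 0.0]) + jitter[2],
            "O": base + np.array([3.4, 1.2, 0.0]) + jitter[3],
        }
        if key_atom_name in backbone:
            backbone[key_atom_name] = key_xyz
        for name in ("N", "CA", "C", "O"):
            lines.append(_pdb_atom_line(serial, name, res_name, "A", res_num,
                                        backbone[name], name[0]))
            serial += 1
        if key_atom_name not in backbone:
            lines.append(_pdb_atom_line(serial, key_atom_name, res_name, "A",
                                        res_num, key_xyz, key_atom_name[0]))
            serial += 1
        return serial

    lines: list[str] = ["REMARK   synthetic covalent complex fixture\n"]
    serial = 1
    serial = stub_residue(lines, serial, "GLY", 10, "N", gly_n)
    serial = stub_residue(lines, serial, "CYS", 12, "SG", sg)
    serial = stub_residue(lines, serial, "LYS", 16, "NZ", lys_nz)
    for idx, atom in enumerate(mol_noh.GetAtoms()):
        lines.append(
            _pdb_atom_line(serial, names[idx], "LIG", "A", 900, coords[idx],
                           atom.GetSymbol(), het=True)
        )
        serial += 1
    lines.append("END\n")
    Path(path).write_text("".join(lines))
    return {
        "ligand_het_code": "LIG",
        "core_atom": names[ci],
        "head_atom": names[hi],
        "dihedral_deg": float(dihedral_deg),
        "electrophile_atom": names[beta],
        "warhead_carbonyl_o": names[carbonyl_o],
        "core_lactam_o": names[lactam_o],
    }


def generate_fixtures(out_dir: str | Path, seed: int = 2020, scale: str = "tiny") -> dict:
    """Write the full fixture set; returns a manifest of paths and metadata."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    libs = fixture_libraries(scale)
    role_files = {}
    for lib in libs:
        path = out / f"{lib.role.value}s.smi"
        with path.open("w") as fh:
            for frag in lib.sorted_fragments():
                fh.write(f"{frag.smiles}\t{frag.id}\n")
        role_files[lib.role.value] = str(path)

    model = fixture_pharmacophore(seed)
    model.to_json(out / "pharmacophore.json")
    pocket = fixture_pocket(seed)
    pocket.to_json(out / "pocket.json")
    (out / "reference_db.smi").write_text(
        "".join(f"{s}\tref-{i}\n" for i, s in enumerate(fixture_reference_db(scale)))
    )
    (out / "catalog.smi").write_text(
        "".join(f"{s}\tblock-{i}\n" for i, s in enumerate(fixture_catalog(scale)))
    )
    complex_meta = synthetic_complex_pdb(out / "synthetic_complex.pdb", seed=seed)
    manifest = {
        "seed": seed,
        "scale": scale,
        "libraries": role_files,
        "pharmacophore": str(out / "pharmacophore.json"),
        "pocket": str(out / "pocket.json"),
        "reference_db": str(out / "reference_db.smi"),
        "catalog": str(out / "catalog.smi"),
        "complex_pdb": str(out / "synthetic_complex.pdb"),
        "complex": complex_meta,
    }
    (out / "fixtures.json").write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return manifest
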