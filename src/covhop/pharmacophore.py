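"""3D pharmacophore model and rigid match-and-align screening.

A pharmacophore model is a set of typed spheres (donor, acceptor, aromatic
ring, hydrophobe, covalent anchor) in the receptor frame.  A molecule matches
when one of its conformers admits a kind-consistent pairing of ligand feature
points onto all required features such that, after the optimal least-squares
rigid superposition (Kabsch, no scaling), every required feature holds its
paired point within its radius.  "Best alignment" is the lowest feature RMSD
over all conformers and pairings, which is the ranking used to retain the
top of the library (default cap 100000 in the funnel).

The pairing search is exhaustive over kind-consistent assignments with
pairwise-distance pruning, which is exact for the small feature counts
(<= 8) that pharmacophore models use in practice.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from rdkit import Chem, RDConfig
from rdkit.Chem import AllChem, ChemicalFeatures
from scipy.spatial.transform import Rotation

from covhop.chemcore import ChemError, MoleculeRecord, canonical_key


class FeatureKind(str, Enum):
    DONOR = "donor"
    ACCEPTOR = "acceptor"
    AROMATIC_RING = "aromatic_ring"
    HYDROPHOBE = "hydrophobe"
    COVALENT_ANCHOR = "covalent_anchor"


_FAMILY_MAP = {
    "Donor": FeatureKind.DONOR,
    "Acceptor": FeatureKind.ACCEPTOR,
    "Aromatic": FeatureKind.AROMATIC_RING,
    "Hydrophobe": FeatureKind.HYDROPHOBE,
}

#: electrophilic beta-carbon of an acrylamide Michael acceptor; this is the
#: atom that bonds the cysteine thiol and anchors the covalent pose
MICHAEL_BETA_CARBON = Chem.MolFromSmarts("[CH2]=[CH]C(=O)N")

_FEATURE_FACTORY = ChemicalFeatures.BuildFeatureFactory(
    str(Path(RDConfig.RDDataDir) / "BaseFeatures.fdef")
)


@dataclass(frozen=True)
class PharmacophoreFeature:
    kind: FeatureKind
    position: tuple[float, float, float]
    radius: float = 1.0
    required: bool = True

    def __post_init__(self):
        if self.radius <= 0:
            raise ValueError("feature radius must be positive")

    @property
    def xyz(self) -> np.ndarray:
        return np.asarray(self.position, dtype=float)


@dataclass(frozen=True)
class PharmacophoreModel:
    """A named set of typed features; screenable once it has >= 3 features."""

    features: tuple[PharmacophoreFeature, ...]
    name: str = "model"

    def __post_init__(self):
        anchors = [f for f in self.features if f.kind is FeatureKind.COVALENT_ANCHOR]
        if len(anchors) > 1:
            raise ValueError("at most one covalent_anchor feature per model")

    @property
    def screenable(self) -> bool:
        return len(self.features) >= 3

    def require_screenable(self) -> None:
        if not self.screenable:
            raise ValueError(
                f"model {self.name!r} has {len(self.features)} features; "
                "rigid alignment needs at least 3"
            )

    @classmethod
    def from_json(cls, path: str | Path) -> "PharmacophoreModel":
        data = json.loads(Path(path).read_text())
        feats = tuple(
            PharmacophoreFeature(
                kind=FeatureKind(f["kind"]),
                position=tuple(float(x) for x in f["xyz"]),
                radius=float(f.get("radius", 1.0)),
                required=bool(f.get("required", True)),
            )
            for f in data["features"]
        )
        return cls(features=feats, name=data.get("name", Path(path).stem))

    def to_json(self, path: str | Path) -> None:
        data = {
            "name": self.name,
            "features": [
                {"kind": f.kind.value, "xyz": list(f.position),
                 "radius": f.radius, "required": f.required}
                for f in self.features
            ],
        }
        Path(path).write_text(json.dumps(data, indent=2) + "\n")


@dataclass(frozen=True)
class LigandFeaturePoint:
    kind: FeatureKind
    position: tuple[float, float, float]
    atom_indices: tuple[int, ...]

    @property
    def xyz(self) -> np.ndarray:
        return np.asarray(self.position, dtype=float)


@dataclass
class MatchResult:
    matched: bool
    alignment_rmsd: float
    feature_pairing: list[tuple[int, int]] = field(default_factory=list)
    rotation: np.ndarray | None = None       # 3x3; ligand -> model frame
    translation: np.ndarray | None = None    # x_model = R @ x_lig + t
    conformer_id: int = -1

    def transform_points(self, coords: np.ndarray) -> np.ndarray:
        return coords @ self.rotation.T + self.translation


def perceive_features(mol: Chem.Mol, conf_id: int = 0) -> list[LigandFeaturePoint]:
    """Typed 3D feature points of one conformer.

    Donor/acceptor/aromatic/hydrophobe perception uses RDKit's base feature
    definitions; aromatic rings contribute their centroid.  The acrylamide
    beta-carbon is additionally emitted as a covalent_anchor point.
    """
    if mol.GetNumConformers() == 0:
        raise ChemError("molecule has no 3D conformer; embed first")
    conf = mol.GetConformer(conf_id)
    coords = conf.GetPositions()
    points: list[LigandFeaturePoint] = []
    for feat in _FEATURE_FACTORY.GetFeaturesForMol(mol, confId=conf_id):
        kind = _FAMILY_MAP.get(feat.GetFamily())
        if kind is None:
            continue
        if kind is FeatureKind.HYDROPHOBE and _isolated_carbon(mol, feat.GetAtomIds()):
            continue
        pos = feat.GetPos(conf_id)
        points.append(
            LigandFeaturePoint(kind, (pos.x, pos.y, pos.z), tuple(feat.GetAtomIds()))
        )
    for match in mol.GetSubstructMatches(MICHAEL_BETA_CARBON):
        beta = match[0]
        points.append(
            LigandFeaturePoint(FeatureKind.COVALENT_ANCHOR, tuple(coords[beta]), (beta,))
        )
    return points


def _isolated_carbon(mol: Chem.Mol, atom_ids: tuple[int, ...]) -> bool:
    """A one-atom hydrophobe with no heavy neighbor (e.g. methane) is noise."""
    if len(atom_ids) != 1:
        return False
    atom = mol.GetAtomWithIdx(atom_ids[0])
    return not any(n.GetAtomicNum() > 1 for n in atom.GetNeighbors())


def embed_conformers(
    mol: Chem.Mol, n: int = 10, seed: int = 2020, rms_threshold: float = 0.5,
    optimize: bool = True,
) -> Chem.Mol:
    """Embed up to ``n`` low-energy conformers, deterministic for a fixed seed.

    Returns a new molecule with explicit hydrogens and the embedded
    conformers (RMSD-pruned at ``rms_threshold`` angstroms, MMFF-relaxed when
    ``optimize``).  Raises :class:`ChemError` when embedding fails entirely.
    """
    molh = Chem.AddHs(Chem.Mol(mol))
    params = AllChem.ETKDGv3()
    params.randomSeed = int(seed)
    params.pruneRmsThresh = float(rms_threshold)
    params.numThreads = 1
    ids = AllChem.EmbedMultipleConfs(molh, numConfs=int(n), params=params)
    if len(ids) == 0:
        raise ChemError(f"conformer embedding failed for {Chem.MolToSmiles(mol)}")
    if optimize:
        AllChem.MMFFOptimizeMoleculeConfs(molh, numThreads=1)
    return molh


def kabsch(lig: np.ndarray, ref: np.ndarray) -> tuple[np.ndarray, np.ndarray, float]:
    """Optimal rigid superposition of ``lig`` onto ``ref`` (no scaling).

    Returns ``(R, t, rmsd)`` with ``x_ref ~ R @ x_lig + t``.
    """
    lig = np.asarray(lig, float)
    ref = np.asarray(ref, float)
    c_lig = lig.mean(axis=0)
    c_ref = ref.mean(axis=0)
    rot, rssd = Rotation.align_vectors(ref - c_ref, lig - c_lig)
    rmsd = rssd / np.sqrt(len(lig))
    R = rot.as_matrix()
    t = c_ref - R @ c_lig
    return R, t, float(rmsd)


def _candidate_pairings(
    model: PharmacophoreModel, points: Sequence[LigandFeaturePoint]
) -> Iterable[list[tuple[int, int]]]:
    """Kind-consistent injective assignments model-feature -> ligand point.

    Optional features are included in a pairing when a compatible point
    exists, but an assignment is produced as long as all *required* features
    are covered.  Pairwise model/ligand distance compatibility prunes the
    backtracking: two paired points must reproduce the inter-feature distance
    within the sum of the two feature radii.
    """
    candidates: list[list[int | None]] = []
    for feat in model.features:
        opts: list[int | None] = [
            i for i, p in enumerate(points) if p.kind is feat.kind
        ]
        if not feat.required:
            opts = opts + [None]
        if not opts:
            return  # a required feature has no candidate point at all
        candidates.append(opts)

    feats = model.features
    pts = points

    def backtrack(fi: int, used: set[int], partial: list[tuple[int, int]]):
        if fi == len(feats):
            if len(partial) >= 3:
                yield list(partial)
            return
        for choice in candidates[fi]:
            if choice is None:
                yield from backtrack(fi + 1, used, partial)
                continue
            if choice in used:
                continue
            ok = True
            for mj, pj in partial:
                d_model = np.linalg.norm(feats[fi].xyz - feats[mj].xyz)
                d_lig = np.linalg.norm(pts[choice].xyz - pts[pj].xyz)
                if abs(d_model - d_lig) > feats[fi].radius + feats[mj].radius:
                    ok = False
                    break
            if ok:
                partial.append((fi, choice))
                used.add(choice)
                yield from backtrack(fi + 1, used, partial)
                partial.pop()
                used.discard(choice)

    yield from backtrack(0, set(), [])


def match_and_align(mol_with_confs: Chem.Mol, model: PharmacophoreModel) -> MatchResult:
    """Best rigid superposition of the molecule's features onto the model.

    Searches all conformers and all kind-consistent pairings; returns the
    pairing with the lowest Kabsch RMSD among those satisfying every required
    feature within its radius (``matched=True``), else the lowest-RMSD
    attempt with ``matched=False``.
    """
    model.require_screenable()
    best = MatchResult(matched=False, alignment_rmsd=float("inf"))
    required_ids = {i for i, f in enumerate(model.features) if f.required}
    for conf_id in [c.GetId() for c in mol_with_confs.GetConformers()]:
        points = perceive_features(mol_with_confs, conf_id)
        for pairing in _candidate_pairings(model, points):
            paired_ids = {mi for mi, _ in pairing}
            if not required_ids <= paired_ids:
                continue
            ref = np.array([model.features[mi].xyz for mi, _ in pairing])
            lig = np.array([points[pi].xyz for _, pi in pairing])
            R, t, rmsd = kabsch(lig, ref)
            moved = lig @ R.T + t
            satisfied = all(
                np.linalg.norm(moved[k] - model.features[mi].xyz)
                <= model.features[mi].radius + 1e-9
                for k, (mi, _) in enumerate(pairing)
                if model.features[mi].required
            )
            better = (satisfied and not best.matched) or (
                satisfied == best.matched and rmsd < best.alignment_rmsd
            )
            if better:
                best = MatchResult(
                    matched=satisfied, alignment_rmsd=rmsd, feature_pairing=pairing,
                    rotation=R, translation=t, conformer_id=conf_id,
                )
    return best


def screen_top_n(
    molecules: Iterable[MoleculeRecord],
    model: PharmacophoreModel,
    cap: int = 100_000,
    n_conformers: int = 10,
    seed: int = 2020,
) -> list[tuple[MoleculeRecord, MatchResult]]:
    """Retain the ``cap`` matched molecules with the best (lowest) alignment RMSD.

    Molecules that fail embedding or do not match all required features are
    dropped.  Ties are broken by canonical key, so ranking is stable and
    independent of input order.
    """
    if cap < 1:
        raise ValueError("cap must be >= 1")
    model.require_screenable()
    hits: list[tuple[MoleculeRecord, MatchResult]] = []
    for record in molecules:
        try:
            molh = embed_conformers(record.mol(), n=n_conformers, seed=seed)
        except ChemError:
            continue
        result = match_and_align(molh, model)
        if result.matched:
            hits.append((record, result))
    hits.sort(key=lambda pair: (pair[1].alignment_rmsd, canonical_key(pair[0].smiles)))
    return hits[:cap]
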