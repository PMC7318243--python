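"""Covalent pose anchoring and surrogate pocket scoring.

This stage stands in for covalent docking with MM/GBSA rescoring, which the
design funnel uses to prioritize the top 10^4 candidates.  The pocket is
abstracted to an interaction model: the nucleophilic cysteine sulfur (anchor)
with an ideal covalent bond length, a set of weighted interaction sites, and
excluded-volume spheres.  A candidate is anchored by a rigid transform that
places its acrylamide beta-carbon at bond distance from the sulfur, then
oriented over a deterministic rotation grid (spin about the anchor axis plus
cone tilts) to maximize the interaction score.

The score is an explicit closed form: each site contributes
``weight * exp(-d^2 / (2 sigma^2))`` with ``sigma = radius / 2`` and ``d`` the
distance from the site to the nearest ligand feature point of matching kind;
each ligand heavy atom inside an excluded volume adds a flat penalty
(default -1.0).  Higher is better; the numbers are arbitrary units, not
kcal/mol.  Externally computed binding free energies (e.g. FEP or MM/GBSA run
elsewhere) can be attached from a CSV table and used as the final ranking.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from rdkit import Chem
from scipy.spatial.transform import Rotation

from covhop.chemcore import ChemError, MoleculeRecord, canonical_key
from covhop.pharmacophore import (
    FeatureKind,
    LigandFeaturePoint,
    MICHAEL_BETA_CARBON,
    perceive_features,
)

DEFAULT_CLASH_PENALTY = -1.0
DEFAULT_SC_BOND_LENGTH = 1.81  # S-C single bond, angstroms


@dataclass(frozen=True)
class PocketSite:
    kind: FeatureKind
    position: tuple[float, float, float]
    radius: float = 2.0
    weight: float = 1.0

    def __post_init__(self):
        if self.radius <= 0 or self.weight <= 0:
            raise ValueError("site radius and weight must be positive")

    @property
    def xyz(self) -> np.ndarray:
        return np.asarray(self.position, dtype=float)


@dataclass(frozen=True)
class ExcludedVolume:
    position: tuple[float, float, float]
    radius: float

    @property
    def xyz(self) -> np.ndarray:
        return np.asarray(self.position, dtype=float)


@dataclass(frozen=True)
class PocketModel:
    """Interaction-site abstraction of a covalent binding pocket."""

    anchor: tuple[float, float, float]
    ideal_bond_length: float = DEFAULT_SC_BOND_LENGTH
    sites: tuple[PocketSite, ...] = ()
    excluded_volumes: tuple[ExcludedVolume, ...] = ()
    clash_penalty: float = DEFAULT_CLASH_PENALTY

    @property
    def anchor_xyz(self) -> np.ndarray:
        return np.asarray(self.anchor, dtype=float)

    @property
    def axis(self) -> np.ndarray:
        """Unit vector from the anchor toward the pocket interior.

        Defined as the direction to the site centroid; +z when there are no
        sites.  The electrophile is placed on this axis at bond distance.
        """
        if not self.sites:
            return np.array([0.0, 0.0, 1.0])
        centroid = np.mean([s.xyz for s in self.sites], axis=0)
        v = centroid - self.anchor_xyz
        n = np.linalg.norm(v)
        return v / n if n > 1e-8 else np.array([0.0, 0.0, 1.0])

    @classmethod
    def from_json(cls, path: str | Path) -> "PocketModel":
        data = json.loads(Path(path).read_text())
        return cls(
            anchor=tuple(float(x) for x in data["anchor"]),
            ideal_bond_length=float(data.get("ideal_bond_length", DEFAULT_SC_BOND_LENGTH)),
            sites=tuple(
                PocketSite(FeatureKind(s["kind"]), tuple(map(float, s["xyz"])),
                           float(s.get("radius", 2.0)), float(s.get("weight", 1.0)))
                for s in data.get("sites", ())
            ),
            excluded_volumes=tuple(
                ExcludedVolume(tuple(map(float, v["xyz"])), float(v["radius"]))
                for v in data.get("excluded_volumes", ())
            ),
            clash_penalty=float(data.get("clash_penalty", DEFAULT_CLASH_PENALTY)),
        )

    def to_json(self, path: str | Path) -> None:
        data = {
            "anchor": list(self.anchor),
            "ideal_bond_length": self.ideal_bond_length,
            "sites": [
                {"kind": s.kind.value, "xyz": list(s.position),
                 "radius": s.radius, "weight": s.weight}
                for s in self.sites
            ],
            "excluded_volumes": [
                {"xyz": list(v.position), "radius": v.radius}
                for v in self.excluded_volumes
            ],
            "clash_penalty": self.clash_penalty,
        }
        Path(path).write_text(json.dumps(data, indent=2) + "\n")


@dataclass
class CovalentPose:
    """Anchored ligand pose: transformed heavy-atom coords and feature points."""

    coordinates: np.ndarray                     # (n_atoms, 3), heavy atoms
    features: list[LigandFeaturePoint]
    anchored_atom: int                          # index of the electrophilic carbon

    def electrophile_xyz(self) -> np.ndarray:
        return self.coordinates[self.anchored_atom]


@dataclass
class InteractionScore:
    total: float
    site_contributions: list[float]
    clash_penalty: float
    external_dg: float | None = None

    def check(self) -> None:
        assert math.isclose(
            self.total, sum(self.site_contributions) + self.clash_penalty,
            rel_tol=0, abs_tol=1e-9,
        )


def find_electrophile(mol: Chem.Mol) -> int:
    """Atom index of the acrylamide beta-carbon (the Cys-reactive position)."""
    matches = mol.GetSubstructMatches(MICHAEL_BETA_CARBON)
    if not matches:
        raise ChemError("no acrylamide Michael-acceptor warhead found")
    return matches[0][0]


def _heavy_coords_and_features(
    mol: Chem.Mol, conf_id: int
) -> tuple[np.ndarray, list[LigandFeaturePoint], np.ndarray]:
    coords = mol.GetConformer(conf_id).GetPositions()
    heavy = np.array([a.GetIdx() for a in mol.GetAtoms() if a.GetAtomicNum() > 1])
    feats = perceive_features(mol, conf_id)
    return coords, feats, heavy


def _orientation_grid(spin_step_deg: float = 10.0, cone_deg: float = 30.0):
    """Deterministic rotation grid: spins about z times cone tilts.

    Yields rotation objects in a fixed order (identity-tilt spins first).
    """
    spins = np.arange(0.0, 360.0, spin_step_deg)
    tilts = [(0.0, 0.0)] + [(cone_deg, az) for az in np.arange(0.0, 360.0, 60.0)]
    for tilt, azimuth in tilts:
        tilt_rot = Rotation.from_euler("zyz", [azimuth, tilt, -azimuth], degrees=True)
        for spin in spins:
            yield Rotation.from_euler("z", spin, degrees=True) * tilt_rot


def score_points(
    features: Sequence[LigandFeaturePoint] | None,
    heavy_xyz: np.ndarray,
    pocket: PocketModel,
    feature_xyz: np.ndarray | None = None,
    feature_kinds: Sequence[FeatureKind] | None = None,
) -> InteractionScore:
    """Closed-form interaction score for a set of placed ligand points."""
    if feature_xyz is None:
        feature_xyz = np.array([f.xyz for f in features]) if features else np.empty((0, 3))
        feature_kinds = [f.kind for f in features] if features else []
    contributions = []
    for site in pocket.sites:
        dists = [
            np.linalg.norm(feature_xyz[i] - site.xyz)
            for i, kind in enumerate(feature_kinds)
            if kind is site.kind
        ]
        if not dists:
            contributions.append(0.0)
            continue
        d = min(dists)
        sigma = site.radius / 2.0
        contributions.append(site.weight * math.exp(-(d * d) / (2.0 * sigma * sigma)))
    clash = 0.0
    for vol in pocket.excluded_volumes:
        inside = np.linalg.norm(heavy_xyz - vol.xyz, axis=1) < vol.radius
        clash += pocket.clash_penalty * int(inside.sum())
    total = sum(contributions) + clash
    return InteractionScore(total=total, site_contributions=contributions,
                            clash_penalty=clash)


def anchor_pose(
    mol_with_conf: Chem.Mol,
    pocket: PocketModel,
    conf_id: int = 0,
    electrophile_idx: int | None = None,
    spin_step_deg: float = 10.0,
    cone_deg: float = 30.0,
) -> CovalentPose:
    """Anchor the warhead at the nucleophile and pick the best orientation.

    A rigid transform places the electrophilic carbon at
    ``anchor + ideal_bond_length * axis``; the ligand is then rotated about
    the electrophile over a deterministic grid (``spin_step_deg`` about the
    anchor axis crossed with ``cone_deg`` tilts) and the orientation with the
    highest interaction score is kept (first in grid order on ties).
    """
    if electrophile_idx is None:
        electrophile_idx = find_electrophile(mol_with_conf)
    coords, feats, heavy_idx = _heavy_coords_and_features(mol_with_conf, conf_id)
    feat_xyz = np.array([f.xyz for f in feats]) if feats else np.empty((0, 3))
    feat_kinds = [f.kind for f in feats]

    target = pocket.anchor_xyz + pocket.ideal_bond_length * pocket.axis
    pivot = coords[electrophile_idx]

    # frame with z along the anchor axis, used for the rotation grid
    z = pocket.axis
    frame = _frame_from_z(z)

    best = None
    best_score = -np.inf
    for rot in _orientation_grid(spin_step_deg, cone_deg):
        R = frame @ rot.as_matrix() @ frame.T
        new_coords = (coords - pivot) @ R.T + target
        new_feat_xyz = (feat_xyz - pivot) @ R.T + target if len(feat_xyz) else feat_xyz
        score = score_points(
            None, new_coords[heavy_idx], pocket,
            feature_xyz=new_feat_xyz, feature_kinds=feat_kinds,
        )
        if score.total > best_score + 1e-12:
            best_score = score.total
            best = (new_coords, new_feat_xyz)
    new_coords, new_feat_xyz = best
    moved_feats = [
        LigandFeaturePoint(f.kind, tuple(new_feat_xyz[i]), f.atom_indices)
        for i, f in enumerate(feats)
    ]
    heavy_map = {int(a): k for k, a in enumerate(heavy_idx)}
    pose = CovalentPose(
        coordinates=new_coords[heavy_idx],
        features=moved_feats,
        anchored_atom=heavy_map[electrophile_idx],
    )
    assert abs(np.linalg.norm(pose.electrophile_xyz() - pocket.anchor_xyz)
               - pocket.ideal_bond_length) < 0.2
    return pose


def _frame_from_z(z: np.ndarray) -> np.ndarray:
    z = z / np.linalg.norm(z)
    ref = np.array([1.0, 0.0, 0.0]) if abs(z[0]) < 0.9 else np.array([0.0, 1.0, 0.0])
    x = np.cross(ref, z)
    x /= np.linalg.norm(x)
    y = np.cross(z, x)
    return np.column_stack([x, y, z])


def score_pose(pose: CovalentPose, pocket: PocketModel) -> InteractionScore:
    """Score an anchored pose against the pocket model (closed form above)."""
    score = score_points(pose.features, pose.coordinates, pocket)
    score.check()
    return score


def rank_top_n(
    scored: Iterable[tuple[MoleculeRecord, InteractionScore]], cap: int = 10_000
) -> list[tuple[MoleculeRecord, InteractionScore]]:
    """Keep the ``cap`` highest-scoring molecules; ties broken by canonical key."""
    if cap < 1:
        raise ValueError("cap must be >= 1")
    ranked = sorted(
        scored, key=lambda pair: (-pair[1].total, canonical_key(pair[0].smiles))
    )
    return ranked[:cap]


def import_external_scores(
    scored: Sequence[tuple[MoleculeRecord, InteractionScore]],
    table: str | Path | pd.DataFrame,
) -> list[tuple[MoleculeRecord, InteractionScore]]:
    """Attach externally computed binding free energies (kcal/mol) by id.

    ``table`` is a CSV (columns ``id``, ``dg``) or an equivalent DataFrame.
    Unknown ids in the table are skipped with a warning on stderr; malformed
    numbers raise.  Returns the stream with ``external_dg`` attached where
    available; rank by ``external_dg`` ascending for a final selection.
    """
    import sys

    if not isinstance(table, pd.DataFrame):
        table = pd.read_csv(table)
    dg_map: dict[str, float] = {}
    for _, row in table.iterrows():
        dg_map[str(row["id"])] = float(row["dg"])
    known_ids = {rec.id for rec, _ in scored}
    for mol_id in dg_map:
        if mol_id not in known_ids:
            print(f"warning: external score for unknown id {mol_id!r} skipped",
                  file=sys.stderr)
    out = []
    for rec, score in scored:
        if rec.id in dg_map:
            score = replace(score, external_dg=dg_map[rec.id])
        out.append((rec, score))
    return out


def rank_by_external_dg(
    scored: Sequence[tuple[MoleculeRecord, InteractionScore]], cap: int
) -> list[tuple[MoleculeRecord, InteractionScore]]:
    """Final-stage selection: lowest external binding free energy first."""
    annotated = [pair for pair in scored if pair[1].external_dg is not None]
    annotated.sort(key=lambda pair: (pair[1].external_dg, canonical_key(pair[0].smiles)))
    return annotated[:cap]
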