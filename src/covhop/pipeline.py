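"""Config-driven orchestration of the prioritization funnel.

Stage order mirrors the design workflow: combinatorial enumeration, 3D
pharmacophore screen (keep the best-aligned ``pharmacophore_cap``), covalent
anchoring with surrogate pocket scoring (keep the top ``score_cap``), the SNAr
electrophilicity filter, the building-block availability filter, and an
optional final selection by externally computed binding free energies.

Counts chain exactly across stages and never increase; runs are deterministic
for a fixed seed, and the manifest a run writes is byte-identical across
reruns of the same config (wall times are logged to stderr, not written to
the manifest).
"""

from __future__ import annotations

import hashlib
import json
import sys
import time
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from covhop import chemcore
from covhop.chemcore import ChemError, Role, read_fragment_library, read_smiles_file
from covhop.enumeration import enumerate_library
from covhop.filters import (
    availability_filter,
    electrophilicity_filter,
    novelty_filter,
)
from covhop.pharmacophore import PharmacophoreModel, embed_conformers, screen_top_n
from covhop.pocket import (
    PocketModel,
    anchor_pose,
    import_external_scores,
    rank_by_external_dg,
    rank_top_n,
    score_pose,
)


@dataclass
class FunnelConfig:
    warheads: str
    bridges: str
    cores: str
    heads: str
    pharmacophore: str
    pocket: str
    reference_db: str | None = None
    catalog: str | None = None
    external_scores: str | None = None
    pharmacophore_cap: int = 100_000
    score_cap: int = 10_000
    final_cap: int = 4
    n_conformers: int = 5
    seed: int = 2020

    def __post_init__(self):
        caps = [self.pharmacophore_cap, self.score_cap]
        if any(c < 1 for c in caps) or self.final_cap < 1:
            raise ValueError("stage caps must be positive")
        if self.pharmacophore_cap < self.score_cap:
            raise ValueError("caps must be nonincreasing along the funnel")

    @classmethod
    def from_file(cls, path: str | Path) -> "FunnelConfig":
        text = Path(path).read_text()
        data = yaml.safe_load(text)
        return cls(**data)

    def params_hash(self) -> str:
        payload = json.dumps(self.__dict__, sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


@dataclass
class StageReport:
    stage: str
    input_count: int
    output_count: int
    wall_time_s: float = 0.0

    def as_manifest_entry(self) -> dict:
        # wall time deliberately excluded: manifests must be byte-identical
        # across reruns of the same config
        return {"stage": self.stage, "input": self.input_count,
                "output": self.output_count}


class _Timer:
    def __enter__(self):
        self.t0 = time.perf_counter()
        return self

    def __exit__(self, *exc):
        self.elapsed = time.perf_counter() - self.t0


def run_funnel(config: FunnelConfig, out_dir: str | Path) -> tuple[list, list[StageReport]]:
    """Execute the full funnel; returns (final ranked list, stage reports).

    Writes ``manifest.json``, per-stage SMILES outputs, and a final CSV into
    ``out_dir``.  Any stage failure raises with the stage name; outputs of
    completed stages are left in place.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    reports: list[StageReport] = []

    def log(stage: str, n_in: int, n_out: int, elapsed: float):
        reports.append(StageReport(stage, n_in, n_out, elapsed))
        print(f"[covhop] {stage}: {n_in} -> {n_out} ({elapsed:.2f}s)", file=sys.stderr)

    def run_stage(stage: str, n_in: int, fn):
        try:
            with _Timer() as t:
                result = fn()
        except Exception as exc:
            raise RuntimeError(f"funnel stage {stage!r} failed: {exc}") from exc
        return result, t

    libraries = [
        read_fragment_library_as(config.warheads, Role.WARHEAD),
        read_fragment_library_as(config.bridges, Role.BRIDGE),
        read_fragment_library_as(config.cores, Role.CORE),
        read_fragment_library_as(config.heads, Role.HEAD),
    ]
    blocks = {f.id: f for lib in libraries for f in lib.fragments}
    model = PharmacophoreModel.from_json(config.pharmacophore)
    pocket = PocketModel.from_json(config.pocket)

    # enumeration
    (stream, manifest), t = run_stage("enumerate", 0, lambda: enumerate_library(libraries))
    with _Timer() as t:
        products = list(stream)
    log("enumerate", manifest.combinations, len(products), t.elapsed)
    _write_smiles(out / "stage1_enumerated.smi", products)

    # novelty (before the expensive 3D stages; molecule-level filters commute)
    if config.reference_db is not None:
        ref_keys = {chemcore.canonical_key(r.smiles) for r in read_smiles_file(config.reference_db)}
        (novel, report), t = run_stage(
            "novelty", len(products), lambda: novelty_filter(products, ref_keys))
        log("novelty", len(products), len(novel), t.elapsed)
        products = novel
        _write_smiles(out / "stage2_novel.smi", products)

    # pharmacophore screen
    (hits, ), t = run_stage("pharmacophore", len(products), lambda: (
        screen_top_n(products, model, cap=config.pharmacophore_cap,
                     n_conformers=config.n_conformers, seed=config.seed),))
    log("pharmacophore", len(products), len(hits), t.elapsed)
    _write_smiles(out / "stage3_pharmacophore.smi", [rec for rec, _ in hits])

    # covalent anchoring + surrogate scoring
    def score_all():
        scored = []
        for rec, _match in hits:
            molh = embed_conformers(rec.mol(), n=1, seed=config.seed)
            pose = anchor_pose(molh, pocket)
            scored.append((rec, score_pose(pose, pocket)))
        return rank_top_n(scored, cap=config.score_cap)

    ranked, t = run_stage("pocket_score", len(hits), score_all)
    log("pocket_score", len(hits), len(ranked), t.elapsed)
    _write_smiles(out / "stage4_scored.smi", [rec for rec, _ in ranked])

    # chemistry filters on the surviving, still-provenance-carrying records
    survivors = [rec for rec, _ in ranked]
    (passing, report), t = run_stage(
        "electrophilicity", len(survivors), lambda: electrophilicity_filter(survivors))
    log("electrophilicity", len(survivors), len(passing), t.elapsed)
    survivors = passing
    _write_smiles(out / "stage5_electrophilic.smi", survivors)

    if config.catalog is not None:
        catalog_keys = {chemcore.canonical_key(r.smiles) for r in read_smiles_file(config.catalog)}
        (passing, report), t = run_stage(
            "availability", len(survivors),
            lambda: availability_filter(survivors, catalog_keys, blocks))
        log("availability", len(survivors), len(passing), t.elapsed)
        survivors = passing
        _write_smiles(out / "stage6_available.smi", survivors)

    score_by_id = {rec.id: s for rec, s in ranked}
    final = [(rec, score_by_id[rec.id]) for rec in survivors]

    if config.external_scores is not None:
        annotated, t = run_stage(
            "external_dg", len(final),
            lambda: rank_by_external_dg(
                import_external_scores(final, config.external_scores), config.final_cap))
        log("external_dg", len(final), len(annotated), t.elapsed)
        final = annotated

    _check_chaining(reports)
    manifest_data = {
        "config_hash": config.params_hash(),
        "seed": config.seed,
        "enumeration": {
            "input_sizes": manifest.input_sizes,
            "combinations": manifest.combinations,
            "unique_products": manifest.unique_products,
            "duplicates": manifest.duplicates,
            "rejected_valence": manifest.rejected_valence,
        },
        "stages": [r.as_manifest_entry() for r in reports],
        "final_count": len(final),
    }
    (out / "manifest.json").write_text(
        json.dumps(manifest_data, indent=2, sort_keys=True) + "\n")
    _write_final_csv(out / "final_ranked.csv", final)
    return final, reports


def read_fragment_library_as(path: str, role: Role):
    from covhop.enumeration import FragmentLibrary

    return FragmentLibrary(role, tuple(read_fragment_library(path, role)))


def _check_chaining(reports: list[StageReport]) -> None:
    for report in reports:
        if report.stage == "enumerate":
            continue  # enumeration input is the combination count, not a stream
        assert report.output_count <= report.input_count, \
            f"stage {report.stage} increased counts"
    for prev, nxt in zip(reports, reports[1:]):
        assert prev.output_count == nxt.input_count, \
            f"count chain broken between {prev.stage} and {nxt.stage}"


def _write_smiles(path: Path, records) -> None:
    with path.open("w") as fh:
        for rec in records:
            fh.write(f"{rec.smiles}\t{rec.id}\n")


def _write_final_csv(path: Path, final) -> None:
    import csv

    with path.open("w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["id", "smiles", "total", "clash_penalty", "external_dg"])
        for rec, score in final:
            writer.writerow([rec.id, rec.smiles, f"{score.total:.6f}",
                             f"{score.clash_penalty:.6f}",
                             "" if score.external_dg is None else f"{score.external_dg:.3f}"])
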