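# Methods

This note documents the models, conventions and numerical choices behind
`covhop`, and what its synthetic fixtures do and do not establish.

## Molecular identity

All dedup, novelty and catalog lookups go through one canonical key: the
RDKit canonical SMILES of the standardized molecule (largest covalent
fragment, charges neutralized, stereochemistry preserved, default RDKit
aromaticity perception).  Tautomers are treated as distinct compounds by
default; `canonical_key(..., tautomer_insensitive=True)` switches to the
RDKit canonical tautomer for users who want tautomer-collapsed identity.
The choice matters for the novelty filter: reference databases must be keyed
with the same function, which the pipeline does automatically.

## Fragments and assembly

Attachment points are labeled dummy atoms (`[*:n]`); label `1` joins warhead
to bridge, `2` bridge to core, `3` core to head.  Fragmentation of an
annotated reference ligand severs the cut bonds, writes paired labels on both
ends, and assigns roles from the per-side annotations; reassembly zips
fragments at matching labels.  The round trip `fragment → reassemble` must
reproduce the parent's canonical key, which the test suite checks over 100
generated molecules.  Cut bonds are user annotations: which bonds to cut is a
design decision, not something the toolkit infers.

Enumeration iterates lexicographically by fragment id (warhead outermost),
streams products, and counts combinations = unique + duplicates +
sanitization rejects exactly.  Products failing valence/sanitization are
counted and skipped, never raised, so one bad combination cannot abort a
large run.  The core atom bonded to the bridge is tagged before assembly and
carried through as an atom index into the product's canonical SMILES; the
electrophilicity filter reads it from this provenance rather than
re-deriving it.

## Pharmacophore screen

Ligand feature points use RDKit's base feature definitions (donor, acceptor,
aromatic ring → centroid, hydrophobe; single-atom hydrophobes with no heavy
neighbor are dropped as noise) plus a `covalent_anchor` point at the
acrylamide β-carbon.  A model is a set of typed spheres with radii and
required flags; matching searches all conformers × all kind-consistent
injective pairings (exhaustive with pairwise-distance pruning — exact for the
≤ 8 features practical models use), superposes paired points by closed-form
least-squares rotation (Kabsch, no scaling), and accepts when every required
feature holds its point within its radius.  "Best alignment" means lowest
feature RMSD; ties in ranking break on canonical key so output order is
stable.  Conformers come from ETKDGv3 with a fixed seed (default 2020),
RMSD-pruned and MMFF-relaxed; matching is rigid — torsional fitting during
alignment is out of scope.

## Covalent pose score (surrogate)

The pocket model is an abstraction of the switch-II site: the nucleophilic
sulfur position with an ideal S–C bond length (default 1.81 Å), weighted
interaction sites, and excluded-volume spheres.  Anchoring places the
β-carbon at bond distance along the anchor axis (anchor → site centroid) and
searches orientations over a deterministic grid: 10° spins about the axis
crossed with cone tilts of 30° at six azimuths.  The score is

    total = Σ_sites  w · exp(−d² / 2σ²)  +  clash_penalty,   σ = radius / 2

where `d` is the distance from the site to the nearest kind-matching ligand
feature and each ligand heavy atom inside an excluded volume contributes a
flat −1.0.  The functional form is deliberately simple and fully unit-tested
(rigid-motion invariance; monotonicity in sites and volumes; zero for an
empty pocket).  It ranks poses by geometric complementarity only — no force
field, induced fit, solvation or entropy — which is why the stage caps are
generous and an external ΔG table (CSV `id,dg`, kcal/mol, ascending =
better) can replace the surrogate ranking for the final selection.

## SNAr electrophilicity rule

The funnel encodes the synthetic-tractability judgement "is the core–bridge
position electrophilic enough for SNAr?" as an explicit positional rule: the
aromatic attachment carbon passes when, inside its fused aromatic system, an
activating group sits at ring distance 1 (ortho) or 3 (para): a
pyridine-type ring nitrogen (aromatic N, no H, two ring bonds) or a ring
atom bearing an exocyclic carbonyl, nitro, nitrile or sulfonyl.  Distances
and SMARTS are configurable (`ElectrophilicityRule`).  This is a documented
interpretation of a judgement call, reproducible but not claimed to match
any particular chemist's eye; quinazoline C4 (ortho to N3) is the canonical
pass case, an unactivated benzene carbon the canonical fail.

## Torsion landscapes

`scan_torsion` performs a relaxed scan: on a uniform grid over [0°, 360°)
(default step 15°) the dihedral is harmonically restrained (10⁴ kcal/mol·rad²)
and all other degrees of freedom are MMFF94-minimized; the recorded energy is
the unrestrained MMFF single point of the relaxed geometry, normalized so the
scan minimum is zero.  Each grid point keeps the lowest energy over a fixed,
deterministic set of starts: `n_starts` seeded ETKDG conformers, a 180° flip
of every hydroxyl rotamer of each (hydroxyl orientation is a slow degree of
freedom that restrained minimization rarely crosses — without the flip the
lower envelope can depend on the embedding seed), and forward/backward
sequential continuation passes.  Failures at single grid points are
periodically interpolated with a warning.

The dihedral atom convention, fixed once and used everywhere: for the biaryl
bond i–j, the reference neighbor on each side is the ring neighbor with the
lowest canonical rank (for PDB ligands, the lowest atom name).  This pins the
0°/180° frame of reported angles; under it the 2,6-naphthyridinone/
fluorophenol fragment's internally H-bonded near-coplanar conformation reads
~180°, and its scan shows a flat well spanning 150–210°.  Claims are about
minima *locations* and scaffold *orderings* (window penalty of the
naphthyridinone ≤ isoquinolinone; ortho-decorated analogue worse than both);
MMFF94 relative energies are not quantitative barrier heights, and no QM
accuracy is implied.  A semi-empirical backend would slot in behind the
`method` parameter; only the force-field backend is implemented.

Intramolecular hydrogen bonds use: donor–acceptor heavy-atom distance
≤ 3.5 Å, D–H···A angle ≥ 120°, donor and acceptor ≥ 4 bonds apart, explicit
hydrogens required.  Pyridine-type nitrogens accept; pyrrole-type and amide
nitrogens do not.

## Complex analysis

PDB parsing uses gemmi; coordinates stay in the file's orthogonal Å frame
with the file's residue numbering.  The covalent link is geometric — the
closest Cys SG within 1.9 Å of a ligand heavy atom — independent of LINK
records and of atom order.  Ligand connectivity is rebuilt from a 1.75 Å
heavy-atom distance cutoff and ring membership from the cycle basis of that
graph.  Hydrogen bonds use the heavy-atom-only criterion (N/O pairs ≤ 3.5 Å,
no angle term), because crystal structures at typical resolution carry no
hydrogens; contacts are tagged backbone/sidechain by residue.

## Fixtures and what the tests show

All test inputs are generated by `covhop.fixtures` from a fixed seed:
fragment libraries mirroring the design series (acrylamide warheads;
piperazine/pyrrolidine/piperidine bridges; quinazoline, isoquinolin-1(2H)-one,
1,6- and 2,6-naphthyridinone and an unactivated benzene core; fluorophenol
and difluorophenyl heads), a pharmacophore and pocket model derived from a
reference product conformer, a catalog that deliberately omits one bridge,
a reference database containing two enumerable products, and a synthetic
covalent-complex PDB.  That PDB is a constructed stand-in, not a crystal
structure: a ligand conformer posed at a 146° core–head dihedral with three
stub residues (Cys12 SG at 1.80 Å from the β-carbon, Gly10 backbone N at
2.9 Å from the core carbonyl, Lys16 NZ at 2.9 Å from the warhead carbonyl).
Passing tests therefore demonstrate correct geometry, bookkeeping and
determinism of the implementation on realistic toy chemistry; they do not
validate scoring accuracy against experimental affinities, and funnel runs
at the fixture scale (12–60 compounds, caps 5–10) exercise the same code
paths as library-scale runs without their runtimes.

The acceptance script scans one fragment (24 grid points, ~10⁰ seconds); the
funnel tests run the tiny scale end-to-end in a few seconds on one CPU.

## Known limitations

- The pose score is geometric; it cannot rank subtle affinity differences
  and is not calibrated to kcal/mol.
- Rigid pharmacophore matching misses matches that small torsional
  adjustments would allow; raising `n_conformers` is the mitigation.
- MMFF94 underestimates some conjugation and H-bond effects; window
  *locations* are robust in our checks, barrier heights are not.
- The SNAr rule is positional only; it ignores leaving-group identity and
  deactivating substituents.
- No stereochemistry enumeration, reaction-based assembly, tautomer
  enumeration during assembly, or water-network analysis.
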