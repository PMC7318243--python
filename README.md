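# covhop

Fragment-based design toolkit for covalent allosteric inhibitors of
KRAS^G12C^-style targets.

Covalent KRAS^G12C^ inhibitors occupy the inducible switch-II pocket of
GDP-bound KRAS and alkylate the mutant cysteine (Cys12) through an acrylamide
Michael acceptor. `covhop` implements, as an open and testable toolkit, the
computational workflow used to scaffold-hop such an inhibitor: a known ligand
is deconstructed into four fragments — the acrylamide **warhead**, a saturated
amine **bridge**, a bicyclic heteroaromatic **core**, and a fluorophenol
**head group** — and fragment libraries for each role are recombined into a
virtual library that is pushed through a prioritization funnel:

1. **enumeration** — all warhead × bridge × core × head combinations, streamed
   and deduplicated by canonical key;
2. **novelty filter** — products found (by standardized canonical SMILES) in a
   reference compound database are discarded;
3. **3D pharmacophore screen** — must-match-all feature matching with
   closed-form rigid (Kabsch) alignment; the best-aligned *N* are retained
   (default cap 10⁵);
4. **covalent pose scoring** — the warhead's electrophilic β-carbon is
   anchored at covalent-bond distance from the nucleophilic sulfur and the
   pose is scored against a pocket interaction model (Gaussian site terms
   plus excluded-volume clash penalties); top *N* kept (default cap 10⁴);
5. **SNAr electrophilicity filter** — the core position bonded to the bridge
   must be activated toward nucleophilic aromatic substitution (ortho/para to
   a pyridine-type ring nitrogen or a strong electron-withdrawing group), a
   proxy for tractable synthesis of the core–bridge bond;
6. **building-block availability filter** — every required building block
   must occur in a purchasable catalog;
7. optional final ranking by externally computed binding free energies
   (ΔG table import).

Companion analysis modules cover the structure-based side of such a project:

- **torsion_landscape** (`covhop.torsion`) — relaxed MMFF94 torsion scans of
  the core–head biaryl bond, minima detection, intramolecular hydrogen-bond
  detection, and window-penalty comparison between scaffolds.  This
  quantifies the key design idea of the naphthyridinone series: a ring
  nitrogen ortho to the biaryl bond lets the fluorophenol OH form an
  intramolecular O–H···N hydrogen bond that stabilizes the near-coplanar
  active conformation (dihedral in the 150–210° window), whereas the plain
  isoquinolinone twists out of plane.
- **complex_analysis** (`covhop.complexes`) — parses covalent ligand–protein
  complexes from PDB files, detects the Cys–ligand linkage (S–C ≤ 1.9 Å),
  measures the core–head dihedral under a documented atom convention, and
  maps protein–ligand hydrogen bonds (heavy-atom ≤ 3.5 Å criterion), e.g.
  the Gly10-backbone contact and the Lys16 coordination of the warhead
  carbonyl that characterize the rotated binding mode.

The pose-scoring stage is an explicit, documented surrogate with a simple
closed form — it stands where a production campaign would run covalent
docking with MM/GBSA rescoring — and external ΔG import is the escape hatch
for higher-fidelity scores. See `docs/methods.md` for models, parameters,
conventions and limitations.

## Worked example

Generate the seeded toy input set and run the funnel:

```sh
covhop fixtures --out inputs --seed 2020 --scale tiny
covhop run --config funnel.yaml --out run
```

with `funnel.yaml`:

```yaml
warheads: inputs/warheads.smi
bridges: inputs/bridges.smi
cores: inputs/cores.smi
heads: inputs/heads.smi
pharmacophore: inputs/pharmacophore.json
pocket: inputs/pocket.json
reference_db: inputs/reference_db.smi
catalog: inputs/catalog.smi
pharmacophore_cap: 10
score_cap: 5
n_conformers: 3
seed: 2020
```

prints per-stage counts to stderr:

```
[covhop] enumerate: 12 -> 12 (0.01s)
[covhop] novelty: 12 -> 10 (0.01s)
[covhop] pharmacophore: 10 -> 10 (1.77s)
[covhop] pocket_score: 10 -> 5 (1.06s)
[covhop] electrophilicity: 5 -> 2 (0.00s)
[covhop] availability: 2 -> 2 (0.00s)
final selection: 2 compounds
```

The 1×2×3×2 toy library enumerates 12 products; 2 are known in the toy
reference database; all 10 survivors match the toy pharmacophore; the score
cap keeps 5; 3 fail the SNAr rule (unactivated core attachment); both
finalists use catalog-available building blocks.  `run/manifest.json` records
the chained counts (byte-identical on reruns with the same config) and
`run/final_ranked.csv` the ranked finalists with their scores.

The torsion analysis behind the coplanarity design idea:

```sh
covhop torsion-scan --smiles "O=c1[nH]ccc2cnc(-c3c(O)cccc3F)cc12" --out scan.csv
# global minimum at 150 deg (0.00 kcal/mol)
# local minimum at 210 deg (0.00 kcal/mol)
```

The 2,6-naphthyridin-1(2H)-one/fluorophenol fragment has a flat energy well
spanning 150–210° (the near-coplanar, internally H-bonded conformation);
the isoquinolinone analogue (`O=c1[nH]ccc2ccc(-c3c(O)cccc3F)cc12`) instead
prefers a ~60–75° twist.

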