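# hittriage

Post-docking hit triage for structure-based virtual screening campaigns
against a protein–protein interface, plus the downstream cell-based
decision cascade that promotes compounds to combination-therapy hits.

The package covers four analysis stages and the synthetic-data layer
that makes them testable without a commercial docking engine or wet-lab
plates:

- **`hittriage.chem`** — molecular descriptors (MW, HBD/HBA by
  Lipinski's N+O conventions, Crippen LogP, rotatable bonds), rule-of-five
  violation counting, 1024-bit Morgan fingerprints, Tanimoto similarity,
  Murcko scaffolds, and PAINS substructure filtering (the 480-pattern
  WEHI SMARTS set ships as plain-text package data).
- **`hittriage.triage`** — rank-and-cut on docking scores (top-5000 then
  score > 90 by default; 75 for approved-drug sources), drug-likeness and
  PAINS gates with per-rejection reasons, a required-contact gate against
  a key pocket residue and its neighbors, two-level scaffold clustering
  (exact Murcko grouping + single-linkage merging at Tanimoto ≥ 0.6),
  and deterministic t-SNE chemical-space maps.
- **`hittriage.structure`** — a PDB-subset reader/writer, Kabsch
  superposition, radius-based pocket definition, Shrake–Rupley buried
  interface area, and rule-based protein–ligand interaction typing
  (H-bond, hydrophobic, π-stacking, π–cation, salt bridge, halogen,
  water bridge) feeding a residues × compounds interaction matrix.
- **`hittriage.hitcalling`** — plate normalization to vehicle = 100%,
  the three-stage decision cascade (< 85% relative-to-cisplatin → pass;
  compound-alone viability < 30% → 10 µM retest branch; effect
  > 10 points → BEST), 4PL dose–response fitting with IC50, and
  2^−ΔCt relative expression.
- **`hittriage.synthetic_data`** — seeded generators for compound
  libraries (fragment grammar rejection-sampled to a drug-like
  descriptor box), score tables with a calibrated score/activity rank
  correlation, viability plates, toy complexes with exact-margin contact
  geometry, cisplatin concentration–response curves, Ct tables, and the
  packaged campaign fixture encoding the per-stage compound counts and
  identities.

## CLI

```
hittriage simulate --n-active 50 --n-inactive 50 --seed 7 --out sim/
hittriage triage --scores sim/scores.csv --library sim/library.smi --seed 7 --out out/
hittriage hitcall --plates sim/plates.csv --out decisions.tsv
hittriage interactions --structure complex.pdb --center-chain A --center-seq 293 --out contacts.tsv
hittriage run-all --scores sim/scores.csv --library sim/library.smi --plates sim/plates.csv --seed 7 --out out/
hittriage fixture            # cascade on the packaged campaign fixture
hittriage validate --library sim/library.smi
```

`run-all` writes per-stage manifests (`report.json`), the shortlist,
cluster and chemical-space tables, the decision TSV, and the serialized
`run_config.json`; re-running from that config reproduces the outputs
byte-for-byte.

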