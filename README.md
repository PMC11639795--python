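# pepforge

A toolkit for antibody-interface-derived peptide inhibitor design and
analysis. It covers the full in-silico loop around (but not including) the
external folding/docking/MD engines:

- **structure** — PDB reading/writing with insertion-code residue keys
  (53 < 53A < 54), altloc resolution, water/hetero filtering, ProtOr-style
  van der Waals radius assignment, chain/range selection.
- **sasa** — solvent-accessible surface area by two independent algorithms
  (deterministic test-point quadrature on expanded spheres, and z-slice
  accessible-arc integration), per-residue aggregation, bound/unbound
  delta-SASA at a binding site, interface-residue detection, and geometric
  hydrogen-bond detection.
- **design** — extraction of contiguous binding segments from an interface
  map, Gly–Ser linker sizing from the inter-segment gap (n = ceil(gap/3.8 Å)),
  peptide assembly, and exhaustive single-point saturation mutagenesis
  (19 variants per position).
- **screening** — Conjoint-Triad sequence encoding (7 physicochemical
  classes, 343 triad bins), peptide/target pair features, seeded 80:20
  splits, a uniform harness over four regressors (random forest, ridge,
  gradient boosting, xgboost*), shared R²/MSE/MAE/Pearson metrics, and
  top-K ranking of mutant libraries by predicted affinity.
- **energetics** — docked-pose rescoring by buried binding-site surface,
  largest-burial pose selection, and the MM-GBSA decomposition ledger
  (GGAS = EEL + VDWAALS, GSOLV = EGB + ESURF, ESURF = γ·SASA,
  ΔG = ΔH − TΔS) fed from external component tables.
- **traj** — Kabsch superposition, RMSD/RMSF series, radius of gyration,
  per-frame SASA and hydrogen-bond series, Cartesian PCA, and
  Boltzmann-inversion free-energy landscapes.
- **synth** — synthetic fixtures with known ground truth: two-chain toy
  complexes with a constructed buried patch, pose ensembles whose best pose
  is pose 0, affinity corpora with a linear truth over triad features, ideal
  helices, and harmonic/hopping trajectories.

\* xgboost is optional; without it the `xgboost` model kind falls back to
scikit-learn's gradient boosting with a warning.

## CLI

Every stage is a subcommand:

```sh
pepforge synth --what poses --out-dir fixtures   # write synthetic inputs
pepforge sasa --pdb complex.pdb
pepforge delta-sasa --pdb complex.pdb --receptor A --ligand B --site site.txt
pepforge interface-map --pdb complex.pdb --receptor A --ligand B
pepforge design --pdb complex.pdb --interface interface.txt
pepforge mutate --seq YIDPKHGGTGSNNEDLR --fasta library.fasta
pepforge encode --seq YIDPKHGGTGSNNEDLR
pepforge screen --train affinity.csv --library library.fasta \
                --target target.fasta --model ridge --top 20
pepforge select-pose --ensemble poses.pdb --receptor receptor.pdb --site site.txt
pepforge energetics --table energies.tsv --gamma 0.0072
pepforge run --config pipeline.yaml                 # full pipeline
```

The pipeline config is YAML validated against a strict schema (unknown keys
are rejected); see `tests/test_cli.py::TestPipeline` for a complete example.

## Site files

Interface/site lists are plain text, one residue per line:
`<chain> <resseq>[icode]`, e.g. `H 53A`.
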