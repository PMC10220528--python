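# polytraj

Trajectory analysis for aqueous solutions of thermoresponsive polymers with
an LCST-type phase transition. The package computes, from standard
topology + trajectory inputs:

- **Chain extension** — radius-of-gyration series and peak-detected
  distributions; time-averaged end-to-end length over the fully extended
  main-chain length (L̄/Lmax), compared against the ideal-chain reference
  1/√N to call coil vs globule; SD/CV fluctuation statistics.
- **Side-chain lengths** — per-residue anchor-to-terminal distances,
  time- and temperature-averaged, with SD and CV.
- **Hydration-shell RDFs** — water-oxygen radial distribution functions
  around side-chain terminal carbons (minimum-image, orthorhombic boxes),
  first-shell peak tracking across temperature, and the crossing
  temperature at which the first-peak intensity drops below bulk density
  (g = 1.0), found by linear interpolation between bracketing temperatures.
- **Hydrogen bonds** — geometric polymer–water hydrogen-bond counts
  (distance ≤ 3.5 Å, D–H···A angle ≥ 150° by default, both configurable),
  split by main-chain vs side-chain acceptor oxygens and normalised per
  oxygen; intrapolymer counts (exactly zero for donor-free ether polymers).

Because production MD trajectories are rarely shippable, a first-class
`synthetic_data` module generates inputs with planted ground truth: freely
jointed chain ensembles, uniform clouds, solvent clouds with a prescribed
Gaussian first-shell profile, hydrogen-bond fixtures with auditable
margins, and a small bead-spring Langevin toy simulator. Everything is
seed-reproducible and flows through the same I/O path as real data
(PDB + multi-frame XYZ; DCD optional via MDAnalysis).

## Command line

Each subcommand maps 1:1 to a library operation:

```sh
polytraj synth fjc --n 100 --b 1.0 --samples 1000 --seed 7 --out fjc/
polytraj synth shell --amplitude 2.0 --r0 3.6 --frames 200 --seed 1 --out shell/
polytraj simulate --temperature 0.5 --epsilon 2.0 --seed 1 --out toy/
polytraj rg    --topology shell/shell.pdb --trajectory shell/shell.xyz --roles shell/shell_roles.yaml
polytraj chain --topology ... --trajectory ... --roles ... --mode sum_of_bonds
polytraj rdf   --topology ... --trajectory ... --roles ... --out rdf.tsv
polytraj tcrp  --curve curve.tsv          # prints e.g. 325.0
polytraj hbonds --topology ... --trajectory ... --roles ...
polytraj report --config run.yaml         # full multi-temperature pipeline
```

The `report` config lists per-temperature topology/trajectory paths, a role
map (patterns over residue/atom names mapped to roles such as `backbone`,
`terminal_carbon`, `mainchain_oxygen`, `water_oxygen`), analysis parameters
and an optional experimental cloud-point constant; it writes one TSV per
table schema plus a run log with provenance headers. See
`tests/test_pipeline_cli.py::write_dataset` for a complete generated
example.

## Conventions

- Coordinates in Å, time in ps, temperature in K; orthorhombic boxes only.
- Rg is unweighted over selected atoms (mass weighting available but off).
- SD uses the sample (n−1) denominator; CV = SD / mean; table-style
  rounding is half-up at the printed precision.
- The ideal-chain reference is 1/√N (the tabulated reference column values
  equal 1/√N at two decimals for every chain length, e.g. 1/√28 → 0.19).
- Lmax defaults to the sum of backbone bond lengths (exact for the
  synthetic test chains); a zigzag mode (× sin(109.47°/2)) is provided for
  all-atom tetrahedral backbones.
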