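# aunphsab

Estimation of (thiolated) ligand binding to planar gold and to gold
nanoparticles in water, built on the HSAB (hard/soft acid–base) principle
and a free-electron-metal description of the gold surface.

The package computes:

* **Reactivity descriptors** — chemical potential `mu` and hardness `eta`
  from three-point finite differences of N−1/N/N+1 total energies, and
  condensed Fukui functions from per-atom charges of the three charge
  states (`aunphsab.descriptors`).
* **Binding energies** — the planar-gold quadratic
  `dE(inf) = −(mu_A − mu_G)² / (2 eta_A)` and the finite-radius rational
  form built on the spherical-capacitor nanoparticle hardness
  `eta_B = e²/(4 pi eps0 alpha r)` (`aunphsab.hsab_model`).
* **Ligand exchange** — reaction energies for one ligand displacing another
  on gold, pairwise exchange matrices, and binding-strength rankings
  (`aunphsab.exchange`).
* **Calibration** — recovery of the two free model parameters
  `(alpha, Ne²)` from reference finite-radius binding energies by an exact
  change-of-variables linear solve (least squares when overdetermined),
  with held-out validation (`aunphsab.calibration`).
* **Data** — packaged descriptor and reference-energy tables for 14
  ligands (alkanethiols, thiolated drug derivatives, citrate protonation
  states, acetate), synthetic-data generation, and CSV/JSON I/O
  (`aunphsab.datasets_io`).

No quantum-chemistry calculations are run: the model consumes precomputed
energies/descriptors only.

## CLI

All subcommands work end-to-end from the packaged fixtures (pass
`--ligands` to use your own table):

```bash
# planar binding energies for the packaged ligand set
aunp-hsab bind --r inf --out planar.csv

# calibrate (alpha, Ne2) on methanethiol + triply ionized citrate at r = 2.88 A
aunp-hsab calibrate --out calibration.json

# finite-radius binding energies with that calibration
aunp-hsab bind --r 2.88 --calibration calibration.json --out np.csv

# validate against held-out observations (CSV: ligand,observed_dE)
aunp-hsab validate --calibration calibration.json --holdout holdout.csv

# exchange energetics and ranking
aunp-hsab exchange --ligand1 "citrate COO^2− (-H-)" --ligand2 thiogenistein
aunp-hsab rank --out rank.csv --matrix matrix.csv

# dE(r) curve for one ligand
aunp-hsab curve --ligand thioabiraterone --calibration calibration.json \
    --out curve.csv --plot curve.png

# descriptors from finite-difference energies / Fukui functions from charges
aunp-hsab descriptors --energies energies.csv --out descriptors.csv
aunp-hsab fukui --charges charges.csv --scheme central --out fukui.csv

# reproducible synthetic ligand sets
aunp-hsab synth --n 50 --seed 7 --out-prefix scratch/syn
```

Global flags: `--config config.yaml` (keys `mu_g`, `alpha`, `ne2`) and
`--log-level DEBUG|INFO|...`. Ligand names are matched through a
normalisation layer, so `citrate COO^3−`, `citrate(COO−)3` and dash/case
variants all resolve to the same row.

## Units

Energies are eV internally; kcal/mol at the reporting boundary
(1 eV = 23.060548 kcal/mol, 1 hartree = 27.211386 eV). Radii are Angstrom;
`mu_G = −5.77 eV` by default.
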