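# nmrbind

Ligand-observed NMR binding analysis for transient protein–ligand
complexes: STD build-up initial rates, STD amplification-factor (STD-AF)
IC50 titrations, selective-T1 IC50 estimation, and a complete
relaxation/exchange-matrix forward simulator of STD intensities from a
complex structure. A synthetic-data module generates every pipeline input,
so all stages are verifiable by parameter recovery against known ground
truth.

## What it does

| Stage | Module | Method |
| --- | --- | --- |
| STD build-up | `nmrbind.std_buildup` | fit `a(1 − e^(−bt))` per proton; initial rate STD0 = a·b; relative STD0 scaled to 100 |
| STD-AF IC50 | `nmrbind.std_affinity` | AF = STD fraction × ligand excess; AF0 isotherm fitted to a Langmuir curve |
| Selective-T1 IC50 | `nmrbind.t1sel` | inversion-recovery fits, then the x-intercept of the line [P]0·T1obs vs [L]0 |
| STD forward simulation | `nmrbind.corcema` | dipolar relaxation matrix + two-site exchange, clamped saturated protein spins, matrix-exponential propagation |
| Equilibrium arithmetic | `nmrbind.binding_model` | 1:1 mass balance, bound fraction, exchange kinetics |
| Synthetic inputs | `nmrbind.synthetic` | seeded generators that are exact pushforwards of the estimator models |

## CLI

All commands are under the `nmrbind` entry point (exit codes: 0 success,
2 validation failure, 1 computational failure):

```sh
# synthesize inputs (deterministic per --seed)
nmrbind simulate buildup --a 0.6 --b 0.7 --sigma 0.02 --seed 1 -o buildup.csv
nmrbind simulate af-titration --ic50-mM 1.70 -o af.csv
nmrbind simulate t1-titration --ic50-uM 49.2 --traces -o t1.csv
nmrbind simulate complex --n-ligand 2 --n-protein 3 --seed 3 -o sys.json

# analyze
nmrbind fit-buildup buildup.csv -o std0_report.csv
nmrbind std-af-ic50 af.csv --protein-mM 0.019
nmrbind t1-ic50 --traces t1.csv --protein-uM 20
nmrbind corcema-predict --complex sys.json --tsat 0.5,1,2,3,4 -o std.csv

# full workflow from a validated YAML/JSON config
nmrbind run --config config.yaml
```

A minimal config:

```yaml
estimator: t1sel          # or std-af
seed: 1
synthetic:
  ic50_uM: 49.2
```

`corcema-predict` also accepts a protonated PDB of the complex
(`--complex complex.pdb`); structures without explicit hydrogens are
rejected — protonate upstream. Protein methyl protons are saturated by
default; any custom proton set can be selected through
`SpinSystem.saturate` in the API.

## File dialects

- STD build-up: CSV/TSV with `ligand_id, proton_label, t_sat_s, std_fraction`
  (a `-` intensity marks an unintegrable proton: skipped with a warning).
- STD-AF isotherm: `conc_mM, af0_per_s`.
- Inversion recovery: `ligand_id, l0_uM, delay_s, intensity`, or a
  pre-fitted `l0_uM, t1_obs_s` table.
- Spin systems: JSON `{label, owner, xyz, methyl_id, saturated}` records, or
  PDB.

Concentration units are explicit in column names; nothing is guessed.

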