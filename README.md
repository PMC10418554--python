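# pulmo1d

Subject-specific one-dimensional pulse-wave hemodynamics of pulmonary
arterial networks: a nonlinear 1D mass/momentum solver (two-step
Lax–Wendroff) on bifurcating vessel trees with an elastic tube-law wall,
prescribed inlet flow, three-element Windkessel outlets, multi-start
calibration of global Windkessel scaling factors against pressure/area/flow
targets, and wall-shear physiomarkers: TAWSS, OSI, and the combined
low-TAWSS/high-OSI network fraction φ.

Because no measurement data ship with the package, a synthetic-subject
generator produces fully specified pseudo-subjects (structured arterial
tree, ground-truth Windkessels, half-sine inflow, noisy pseudo-measurements)
in both a baseline state and a CTEPH-like diseased state (asymmetric,
left-dominant distal resistance increase with wall stiffening and reduced
cardiac output), so every pipeline stage is testable end to end.

## Layout

| module | contents |
| --- | --- |
| `pulmo1d.network` | vessel-tree data model, JSON/CSV serialization, validation, diastolic area scaling, Poiseuille resistance |
| `pulmo1d.wall` | tube law and its inversions, analytic stiffness Eh/r0, PVR/compliance estimation, nominal Windkessel construction |
| `pulmo1d.solver` | Lax–Wendroff network solver, characteristic boundary closures, junction coupling, Windkessel outlets, periodic convergence |
| `pulmo1d.calibration` | calibration data model, cost function, multi-start bounded least squares, R² reporting |
| `pulmo1d.shear` | signed wall shear stress, TAWSS, OSI, per-segment summaries and φ |
| `pulmo1d.synthetic` | tree/inflow generators, baseline and CTEPH synthetic subjects |
| `pulmo1d.pipeline` | end-to-end orchestration and baseline-vs-CTEPH comparison |
| `pulmo1d.cli` | `pulmo1d` command with verbs `synth`, `simulate`, `calibrate`, `metrics`, `run`, `compare` |

Internal unit system is CGS (cm, s, dyn); mmHg, mL/s, mL/mmHg are used at
I/O boundaries (1 mmHg = 1333.22 dyn/cm²).

## CLI quick start

```sh
# generate a synthetic subject's files (network, parameters, inflow, data)
pulmo1d synth --scenario baseline --seed 1 --out subj/

# run the full study replica: synth -> nominal init -> calibrate -> metrics
pulmo1d run --scenario baseline --seed 1 --out run_base/
pulmo1d run --scenario cteph    --seed 1 --out run_cteph/

# paired differences (stiffness, Windkessel totals, TAWSS/OSI, phi)
pulmo1d compare --baseline run_base/ --cteph run_cteph/

# forward simulation / metrics from files
pulmo1d simulate --network subj/network.json --parameters subj/parameters.json \
    --inflow subj/inflow.csv --out solution.csv
pulmo1d calibrate --network subj/network.json --data subj/calibration_data.json \
    --inflow subj/inflow.csv --seed 1 --out theta.json
```

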