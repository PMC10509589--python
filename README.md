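# haemopost

Post-processing toolkit for inlet-condition sensitivity studies of aortic
(dissection) haemodynamics.  It covers the full analysis chain around a CFD
solver — it does not solve the Navier–Stokes equations itself:

- **Inlet velocity profiles (IVPs)** — build the four canonical inlet
  boundary-condition variants from 4D-flow-MRI-like inlet data: full
  three-component (`4d`), spatially uniform (`flat`), through-plane (`tp`),
  and velocity-scaled (`scaled`, default +25%).  Contour registration uses a
  similarity Procrustes fit with an optional regularized Gaussian-kernel
  non-rigid refinement.
- **0D Windkessel calibration** — tune three-element Windkessel (RCR) outlet
  parameters of a lumped network so the simulated central systolic/diastolic
  pressures hit targets derived from a brachial cuff measurement
  (P_d = P_d′, P_s = 0.83 P_s′ + 0.15 P_d′).
- **Wall shear stress indices** — TAWSS, OSI, RRT and ECAP from velocity
  fields, plus circumferential profiles and case-difference statistics.
- **Helicity** — helicity density, local normalized helicity (LNH), and the
  bulk indices h1/h2/h3 per subdomain and cycle phase.
- **Snapshot POD** — volume-weighted proper orthogonal decomposition with
  energy spectra, rank-k reconstruction, and shear indices from truncated
  reconstructions.
- **Clinical comparison metrics** — transmural pressure, false-lumen
  ejection fraction, cross-sectional growth profiles, station alignment and
  Pearson correlations between cases.
- **Synthetic ground truth** — Womersley pipe flow, helical/Beltrami fields,
  an MRI-like inlet sampler and a two-lumen dissection phantom, each
  returning closed-form oracles used by the test suite.

## Quick start

```python
import numpy as np
from haemopost.windkessel import derive_pressure_targets, tune_wk3

targets = derive_pressure_targets(138.0, 81.0)   # central Ps ≈ 127 mmHg
t = np.linspace(0, 0.8, 64, endpoint=False)
q = 100 * (1 + 0.9 * np.sin(2 * np.pi * t / 0.8))  # ml/s
result = tune_wk3(t, q, 0.8, targets,
                  q_targets={"upper": 30.0, "lower": 70.0},
                  rho_split={"upper": 0.1, "lower": 0.1})
print(result.achieved_ps, result.achieved_pd)
```

Command line (see `haemopost --help` for all commands):

```sh
haemopost targets 138 81
haemopost wss results/velocity.h5 --out wss_indices.csv
haemopost run experiment.yaml --case 4d=results/4d.h5 --case flat=results/flat.h5
haemopost demo --out-dir demo_out        # fully synthetic end-to-end run
```

Fields are read/written as HDF5 bundles or legacy-ASCII VTK series
directories; waveforms as two-column CSV (`time_s,value`).  All internal
quantities are SI; clinical units (mmHg, ml/s, ml/mmHg) appear only at
interfaces and in the Windkessel module.

## Reproducibility

All randomness flows from caller-provided seeds.  Pipeline runs write a
fixed artefact set (CSV tables plus `provenance.json`) with deterministic
number formatting and no timestamps, so repeated runs are byte-identical.

## Development

```sh
pip install --no-build-isolation -e '.[test]'
python -m pytest -q tests/
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

`tests/test_acceptance.py` holds one test per acceptance criterion; all
numeric tests are checked against independent oracles (closed forms,
prescribed phantom quantities, or exact algebraic identities).  See
`docs/methods.md` for the numerical methods and conventions.
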