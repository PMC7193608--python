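# shuntfield

Quasi-static volume-conductor modelling and analysis for comparing
subcutaneous (skull-surface, "SES") and transcutaneous (scalp-surface,
"TES") electrical brain stimulation.  The central physical question is
*scalp shunting*: because the scalp is far more conductive per unit
geometry than the skull in the regime modelled here, current injected on
the scalp largely returns through the scalp, while current injected
beneath it (on the skull surface) is forced through the skull and
produces a several-fold larger electric field at depth for the same
injected current.

The package provides, end to end:

- **Forward solvers** for the quasi-static potential:
  - a 1-D layered **slab** (closed form, series-resistor),
  - an **analytic N-shell sphere** via a Legendre transfer-matrix series
    (the numerical oracle),
  - a 3-D **voxel finite-difference solver** (7-point stencil,
    preconditioned conjugate gradients) with partial-volume antialiasing
    of tissue boundaries.
- **Geometry builders** for slab, concentric-shell, and voxelised
  quasi-spherical head phantoms; electrode patches attachable to the
  scalp or directly to the skull surface; 8-contact depth strips.
- A **measurement chain** that turns strip-contact potentials into
  pairwise field estimates (bandpass, cycle averaging, peak-to-peak),
  plus per-milliamp slope fits, shunting ratios, required-current
  estimates, and frequency trends.
- **Conductivity calibration**: joint recovery of scalp and skull
  conductivity from strip-field measurements by log-space grid search
  with Nelder–Mead refinement, with a full grid audit trail.
- **iEEG spectral statistics**: Welch band power per recording phase,
  pre/post band-power change, and paired, Bonferroni-corrected
  between-condition tests.
- **Seeded synthetic generators** for stimulation waveforms, strip
  recordings, iEEG sessions (with an optional post-stimulation
  alpha/beta enhancement), and complete calibration datasets with
  sealed ground truth.

## Quick start

```python
import numpy as np
from shuntfield import forward, geometry

cs = geometry.optimized_conductivities()     # low-conductivity regime
model = geometry.build_voxel_head((45, 45, 45),
                                  {"scalp": 4, "skull": 4, "csf": 4},
                                  voxel_size_mm=2.0, conductivities=cs,
                                  gray_thickness_mm=None)

def pair(attachment, r):
    return geometry.place_montage(model, [
        geometry.ElectrodePatch((0, 0, r), 0.5, attachment, "active", 1.0),
        geometry.ElectrodePatch((0, 0, -r), 0.5, attachment, "reference", -1.0),
    ])

tes = forward.solve_voxel_potential(model, pair("scalp-surface", 45.0))
ses = forward.solve_voxel_potential(model, pair("skull-surface", 41.0))
probe = [(0.0, 0.0, 30.0)]
print(forward.sample_field_magnitude(ses, probe)
      / forward.sample_field_magnitude(tes, probe))   # > 1: SES wins
```

There is also a CLI:

```sh
shuntfield build-phantom --kind shells --config cfg.json --out model.json
shuntfield solve --model model.h5 --montage montage.json --out solution.h5
shuntfield analyze-fields --epochs epochs/ --out fields.csv
shuntfield calibrate --problem problem.json --out fit.json
shuntfield analyze-ieeg --sessions sessions/ --out bands.csv
shuntfield synth strip --spec spec.json --seed 1 --out epoch.h5
```

## Verification

`tests/` contains unit tests per module plus `tests/test_acceptance.py`,
which checks the headline claims: worked-example shunting ratios and
required currents, voxel-vs-analytic oracle agreement under refinement,
physics invariants (current conservation, reciprocity, linearity,
monotonicity in scalp conductivity), SES > TES at depth with a decaying
depth profile, calibration recovery of known conductivities under noise,
and type-I/power behaviour of the iEEG statistics.

```sh
python -m pytest -q tests/
python scripts/acceptance.py --seed 1 --out results.json
```

See `docs/methods.md` for the numerical methods and design decisions.
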