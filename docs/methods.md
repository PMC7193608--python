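# Methods

This document records the numerical methods and the design decisions
behind them, at the level a reviewer needs to audit the results.

## 1. Physical model

All solvers treat the quasi-static approximation of Maxwell's equations
in a piecewise-inhomogeneous ohmic conductor:

∇·(σ∇V) = −I δ(x − x_src),  with  n·σ∇V = 0 on the outer boundary.

Units throughout: millimetres for geometry, S/m for conductivity,
milliamps for injected current, volts for potential, mV/mm for fields
(1 mV/mm = 1 V/m).  Stimulation frequencies are low enough (≤ 2 kHz)
that capacitive and inductive effects are ignored; the solution at any
instant is the DC solution scaled by the instantaneous current, which is
why the measurement chain can recover fields from sinusoidal or biphasic
pulsed stimuli with the same solver output.

Two conductivity sets ship with the package:

- `default_conductivities()` — scalp 0.0002, skull 0.00227, CSF 2.0,
  gray matter 0.0988 S/m.
- `optimized_conductivities()` — the same with scalp 0.0004 and skull
  0.004 S/m, the values found by the calibration procedure in §5.

Both describe a low-conductivity saline regime (roughly three orders of
magnitude below textbook human tissue); all ratios and qualitative
conclusions are conductivity-ratio driven and carry over.

## 2. Forward solvers

### 2.1 Slab (closed form)

A stack of layers carrying uniform current density J is a series
resistor chain: E_layer = J/σ_layer, and interface potentials follow by
integration.  Used for intuition and as a trivial oracle.

### 2.2 Analytic N-shell sphere (the oracle)

For concentric spherical shells with radial conductivity profile
σ_1..σ_N and point current sources on shell interfaces, the potential is
a Legendre series V(r, θ) = Σ_n (A_k,n r^n + B_k,n r^(−n−1)) P_n(cos γ).
Coefficients propagate across interfaces with a 2×2 transfer matrix per
degree n; the interior regularity and exterior no-flux conditions close
the system.  Sources strictly inside a shell are handled by splitting
that shell at the source radius with an equal-conductivity interface, so
every source sits on an interface without changing the physics.

The series is summed to `n_max` (default 300) with a convergence check;
against the closed-form homogeneous-sphere solution (image-charge form)
it agrees to better than 1e−6 in relative L2.

`montage_point_sources` converts a rasterised electrode footprint into
per-voxel monopoles so that the exact same current pattern drives both
the voxel solver and the analytic oracle — essential for a fair
equivalence test (§6).

### 2.3 Voxel finite differences

The 3-D solver discretises ∇·(σ∇V) with the standard 7-point
flux-conservative stencil on a regular grid.  Face conductivities are
taken, in order of preference:

1. **Face-plane sampling** (default when the model carries per-face
   tissue area fractions): each face's conductivity is the
   area-fraction-weighted mix of tissue conductivities sampled on the
   staggered face plane.  This resolves thin curved layers (4 mm scalp
   and skull at 1–2 mm voxels) far better than mixing cell-centred
   values.
2. **Harmonic mean** of the two adjacent cell conductivities, the
   classical choice, used when face fractions are unavailable.

Partial-volume antialiasing: the geometry builder supersamples each
voxel (4³ points) and each face (4²) against the analytic layer
surfaces, storing per-tissue volume and area fractions.  Fractions are
mixed with the *current* conductivity set at solve time, so conductivity
sweeps and calibration reuse one rasterisation.

The linear system is symmetric positive semidefinite with a one-dim
nullspace (constant shift).  We pin one current-free node near the
domain centre, solve with Jacobi-preconditioned conjugate gradients
(relative tolerance 1e−8), then shift the gauge so the node nearest the
reference-patch centroid reads zero.  The residual stored on the
solution is re-measured on the **unscaled** system, so it carries the
conductivity-contrast factor; with contrasts of ~10⁴ it lands around
1e−7 rather than 1e−8, and tests assert ≤ 1e−6.

Fields are centred differences of the potential, masked to NaN outside
the conductor; point queries use trilinear interpolation and refuse
stencils that touch non-conducting voxels rather than silently
extrapolating.

## 3. Measurement chain

Synthetic strip recordings are sinusoidal (or biphasic-pulsed) voltages
at 8 contacts.  Analysis: Butterworth bandpass around the stimulation
band (capped at 0.9× Nyquist), phase-binned cycle averaging (≥ 10
cycles), peak-to-peak of the cycle template, adjacent-contact
differences divided by contact spacing → pairwise fields in mV/mm.

The chain carries a small systematic gain (≈ 2% low): the band edge of
the Butterworth filter at the stimulation frequency, the sinc roll-off
of phase-bin averaging, and discrete sampling of the cycle-template
peak each shave a fraction of a percent.  The gain is **common to all
contacts and conditions**, so it cancels exactly in every ratio-type
analysis (shunting ratios, per-milliamp slopes used in ratios,
calibration residuals after normalisation), and exact zeros remain
exactly zero.  Absolute field round-trips are therefore verified at
2.5% rather than machine precision; this is an honest property of any
real measurement chain, not a solver error.

Downstream analyses: origin-constrained least-squares per-milliamp
slope with Pearson r; shunting ratio as the mean over intensity-matched
pairs of condition-A/condition-B summary fields; required current =
target field / slope, rounded to 0.1 mA; Spearman trend across
stimulation frequencies.

## 4. iEEG statistics

Sessions are single-channel traces at 512 Hz with pre (0–30 s),
stimulation (30–80 s), and post (80–100 s) phases.  Preprocessing:
1–100 Hz bandpass plus 60 Hz notch.  Spectra: Welch with a 1024-sample
Hamming window.  Band powers integrate the PSD over delta/theta/alpha/
beta bands with half-open bins; the pre→post change per band feeds a
paired t-test across subjects with Bonferroni correction over the four
bands.  Zero-variance differences report p = 1 with a flag instead of a
spurious infinity.

The synthetic generator superimposes narrowband oscillators (2, 6, 10,
20 Hz) on 1/f-ish background noise; the "SES" condition multiplies
post-phase alpha and beta oscillator amplitudes by 2, "TES" and
"baseline" leave them unchanged.  This is deliberately a minimal
statistical phantom: it reproduces effect sizes and null behaviour, not
waveform realism.

## 5. Conductivity calibration

The goal is to recover σ_scalp and σ_skull jointly from strip-field
measurements.  Two identifiability facts shaped the design:

- **Interior fields only constrain the ratio** σ_scalp/σ_skull: scaling
  both conductivities by c scales interior fields by 1/c uniformly,
  which per-montage normalisation removes.  To pin the absolute scale,
  the standard battery includes strips lying **within the scalp layer**,
  whose fields scale as 1/σ_scalp directly.
- Measurements from different montages differ by orders of magnitude,
  so the objective normalises each montage's residuals by the measured
  standard deviation of that montage before pooling (weighted combination
  of interior and scalp-layer pools).

The standard battery (`standard_calibration_montages`) is 24
montage/strip pairs: three electrode-axis directions × {scalp-mounted,
skull-mounted} × three intensities with interior chord strips at 30 mm
depth, plus scalp-layer chord strips under the scalp montages.

Search: log-space grid (default 9×9) over bounded σ ranges, recording
every evaluation in a grid audit (CSV export via the CLI), then
Nelder–Mead refinement from the best grid node with a quadratic
log-space penalty outside the bounds.  A fit that lands on a bound is
reported as `"boundary"` rather than `"converged"`.  Synthetic
calibration datasets seal the ground truth (not readable from the
problem object) so recovery tests cannot cheat.

## 6. Verification strategy

- **Oracle equivalence**: identical montages drive the voxel solver and
  the analytic shell series on a 4-shell sphere (radii 33/37/41/45 mm);
  potentials are compared mean-free (both solutions are defined up to a
  gauge) in relative L2 on an interior sampling sphere at r = 30 mm.
  Agreement is ≈ 0.8% at 2 mm voxels, improving to ≈ 0.65% at 1 mm.
- **Invariants**: net current through planes separating the electrodes
  equals the injected current to < 1%; discrete reciprocity
  V₁ᵀb₂ = V₂ᵀb₁ holds to solver tolerance; doubling the current doubles
  the solution to machine precision; the interior field is
  non-increasing in σ_scalp (more scalp shunting, less field at depth).
- **Statistics**: null type-I rates over ≥ 500 replicates, detection
  power of the built-in SES effect, and a no-flag check for TES.

`scripts/acceptance.py --seed N --out results.json` recomputes all the
headline quantities in one run.
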