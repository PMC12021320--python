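# pbr2 — phase-based R2 mapping for liver iron quantification

Liver iron concentration is monitored clinically through the transverse
relaxation rate R2 = 1/T2 of liver tissue, but conventional spin-echo R2
mapping takes ~20 minutes and covers few slices. Phase-based R2 mapping
encodes R2 directly into the *phase* of a rapid 3D gradient-echo (GRE)
acquisition whose RF excitation phase is incremented quadratically,
φ(n) = φ(n−1) + n·θ with a small increment θ: the steady-state signal splits
into an FID-like (T1-weighted) and an echo-like (T2-weighted) quadrature
component, and the angle between them,

    φ_tissue = arctan(echo-like / FID-like),

falls monotonically from ≈90° toward 0° as R2 grows. Whole-liver R2 can then
be measured in a single breath-hold by inverting the measured phase through a
simulated phase-vs-R2 lookup table. This package provides everything needed
to study and run that method at desk scale, for MR physicists and
quantitative-imaging researchers:

- a Bloch isochromat **steady-state engine** for RF phase-modulated GRE
  (`pbr2.engine`);
- **lookup tables** with either a fixed R1 assumption or an R1–R2
  calibration line R1c(R2) = a·R2 + b that corrects the iron-driven R1 bias
  (`pbr2.lookup`);
- a six-peak **fat signal model** and fat-induced bias maps over
  (PDFF, R2) at 1.5 T and 3.0 T (`pbr2.fat`);
- **protocol optimization** simulators: worst-case R2 bias under B1
  inhomogeneity and worst-case R2 SD under noise over (flip angle, phase
  increment) grids, plus TR sensitivity (`pbr2.optimize`);
- a **volumetric reconstruction pipeline**: complex spatial averaging,
  background-cancelling two-pass combination ∠(S₊·S₋*)/2, voxelwise
  inversion, ROI statistics, NIfTI I/O (`pbr2.recon`);
- **synthetic digital phantoms** with ground truth — vial rings on an
  iron-mimicking R1–R2 line and liver-like volumes with vessels, fat and
  background phase (`pbr2.phantom`);
- **agreement statistics**: regression with CIs, Bland–Altman, ICC(2,1)
  (`pbr2.stats`).

The model, conventions and parameter choices are documented in
[docs/methods.md](docs/methods.md).

## Worked example

Simulate the steady-state signal of an iron-overloaded liver voxel
(R2 = 150 s⁻¹, R1 = 1 s⁻¹) at the short-TR protocol:

```sh
$ pbr2 simulate --tr 3.0 --te 1.0 --flip 18 --inc 2 --r1 1.0 --r2 150
{"real": 0.00454684632747326, "imag": 0.019761477755551267,
 "phase_deg": 12.95746345293921, "magnitude": 0.02027781582441276}
```

The echo-like component (`real`) is already much weaker than the FID-like
component (`imag`) at this R2, leaving a tissue phase of ≈13.0°. Inverting
that phase through a lookup table built with the same sequence parameters
recovers the relaxation rate:

```python
import numpy as np
from pbr2 import SequenceParams, build_lookup, invert_phase

seq = SequenceParams(tr=3.0, te=1.0, flip_angle=18.0, phase_increment=2.0)
lut = build_lookup(seq, r1_model=1.0, r2_grid=np.arange(10.0, 301.0, 5.0))
print(invert_phase(lut, 12.96))
# R2Estimate(r2=149.97481048914452, r1=None, clipped=False)
```

The estimate returns to 150 s⁻¹ to within a fraction of the 5 s⁻¹ grid
step; a phase pushed negative by noise would instead clip to the table
maximum with `clipped=True`, which is why the pipeline averages complex data
before extracting phase. End-to-end synthetic experiments (vial phantoms,
R1 correction, fat bias, protocol maps) are exercised in `tests/`, and the
CLI exposes each stage: `pbr2 simulate`, `build-lut`, `fat-bias`,
`optimize`, `phantom`, `map`, `agree`.

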