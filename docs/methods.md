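# Methods

## The measurement principle

`pbr2` implements phase-based R2 mapping: quantification of the transverse
relaxation rate R2 = 1/T2 (s⁻¹) of liver tissue — a validated surrogate for
liver iron concentration — from the *phase* of a 3D gradient-echo (GRE)
acquisition whose RF excitation phase follows a quadratic schedule,
φ(n) = φ(n−1) + n·θ, with a small increment θ of 1–5°.

In this partially spoiled regime the demodulated steady-state signal contains
two quadrature components: an FID-like component formed by freshly excited
magnetization (T1-weighted) and an echo-like component formed by
magnetization stored over previous repetition intervals (T2-weighted, with a
guideline effective echo time of 2·TR). The tissue phase

    φ_tissue = arctan(echo-like / FID-like)

decreases monotonically from near 90° toward 0° as R2 grows, because the
echo-like pathway decays as roughly exp(−2·TR·R2) relative to the FID. A
single ~10 s breath-hold acquisition per increment sign therefore encodes
whole-liver R2 in phase, and a precomputed phase-vs-R2 lookup table inverts
it voxel by voxel.

## The steady-state engine

The steady state is computed by iterating the Bloch recursion over an
ensemble of isochromats (default 1000) whose per-TR intravoxel gradient
dephasing is uniformly spaced over 2π:

1. RF rotation by flip angle α about a transverse axis at the quadratic
   schedule phase;
2. readout immediately after excitation, demodulated by the transmit phase;
3. transverse relaxation exp(−R2·TR), per-isochromat precession, and
   longitudinal recovery over TR.

Readout models an ideal gradient echo: at the echo center the net gradient
moment since the most recent excitation is zero for every coherence pathway,
so the sampled ensemble signal is the post-excitation state attenuated by
pure T2 decay over TE. TE therefore affects magnitude (and the fat spectral
phase factor) but not the water phase, consistent with a steady-state signal
expression in which TE does not appear. An optional R2′ term is not included;
at TE ≈ 1 ms reversible dephasing is a second-order effect (≈37 % of signal
remains even at T2* = 1 ms, which is still ample for phase estimation).

Demodulating by the transmit schedule makes the ensemble signal stationary
(shifting every isochromat's effective off-resonance by θ per excitation
merely relabels a uniform ensemble), so the steady state is a single complex
number. Convergence is declared when the block-averaged complex signal
(blocks of 100 excitations) changes by less than 1 part in 10⁶ between
consecutive blocks, capped at 20 000 excitations; under liver-imaging
parameters the RF-driven saturation shortens the transient to a few hundred
excitations and convergence typically occurs within ~1500–2500. The result
is invariant (to < 10⁻³ degree) under tightening the tolerance to 10⁻⁸ or
raising the isochromat count to 10⁴, and matches an independently coded
rotation-matrix simulation to better than 10⁻⁴ degree.

Orientation conventions: the canonical complex signal places the FID-like
component on the positive real axis and the echo-like component on the
positive imaginary axis, so the standard complex argument is the tissue
phase. Reversing the increment sign conjugates the canonical signal exactly
(verified as a test invariant); this corresponds to a fixed receiver phase
offset on the negative-increment pass. Angles are degrees externally and
radians internally; voxel indexing is 0-based.

## Lookup inversion and R1 correction

A lookup table stores the noiseless phase over an R2 grid (default 10–300
s⁻¹ at 1 s⁻¹ spacing; linear interpolation between nodes; equidistant ties
resolve to the lower R2). Because one phase cannot determine (R1, R2)
jointly, each table bakes in an R1 model:

- **fixed R1** (uncorrected variant): T1 = 1000 ms for phantom work, 576 ms
  at 1.5 T and 812 ms at 3.0 T in vivo;
- **calibration line** R1c(R2) = slope·R2 + intercept, reflecting the
  empirical coupling of both rates to iron. Shipped lines: literature liver
  calibration 6.5×10⁻³·R2 + 1.23 (1.5 T) and 3.8×10⁻³·R2 + 0.89 (3.0 T),
  and MnCl₂-agarose vial-phantom lines 0.14·R2 + 0.59 (1.5 T) and
  9.2×10⁻²·R2 + 1.3 (3.0 T). The literature slopes are interpreted with
  ×10⁻³ scale; positive-exponent readings would put liver R1 near 10⁵ s⁻¹,
  far outside the physiological range the same sources report.

Inversion maps a measured phase to the R2 whose table phase matches it.
Non-physical phases at or below the table minimum (including negative
phases produced by noise) map to the table maximum with a `clipped` flag —
this deliberate convention is what makes noise at high R2 pile estimates at
the lookup ceiling, and is why complex-domain averaging matters. A
calibrated table also returns the derived R1 estimate through the same line.
When the true R1 exceeds a fixed-R1 assumption (iron overload), the FID-like
component is stronger than the table assumes, the phase is lower, and the
fixed-R1 inversion overestimates R2; the calibrated table removes this bias.

## Two-pass combination and spatial averaging

The acquisition is repeated with increments +θ and −θ. Tissue phase is
antisymmetric in the increment sign; background phase (coil, B0, eddy
currents) is common. The half-angle of the conjugate product,
∠(S₊·S₋*)/2, cancels any common multiplicative phase field exactly and is
the adopted combination. Averaging of complex data (default 3×3 in-plane
uniform kernel, shrink-to-valid renormalization at edges) is applied to each
pass *before* combination and phase extraction; averaging magnitude or phase
images instead would not remove the negative-phase artifact. With k > 1
kernels the background cancellation is exact only up to the intra-kernel
variation of the background field, which is negligible for smooth fields.
The effective in-plane footprint after a k×k kernel is k× the voxel pitch
per axis and is recorded in map provenance. Voxels below 5 % (configurable)
of the volume's 99th-percentile magnitude are masked.

## Fat model

Tissue with proton density fat fraction (PDFF) p is modeled as

    S = (1−p)·S_water(R1w, R2w) + p·S_fat(R1f, R2f)·Σ_p u_p·exp(j2πf_p·TE)

where each compartment is its own steady-state solution and the six-peak
spectrum (ppm offsets −3.80, −3.40, −2.60, −1.94, −0.39, +0.60 relative to
water; amplitudes 0.087, 0.693, 0.128, 0.004, 0.039, 0.048, normalized) is
converted to Hz by 42.5775·B0 MHz. Fat relaxation defaults: T1 = 288 ms
(1.5 T) / 382 ms (3.0 T), T2 = 58 ms; all values config-overridable, since
amplitude normalization conventions differ between spectroscopy sources.
Fat off-resonance within the steady-state recursion is ignored; it enters
only through the TE phase factor, exactly as the signal model is written.

The bias simulator models the measurement the way the pipeline makes it:
both increment signs are composed and the two-pass phase is inverted through
a fat-free fixed-R1 table. This is scientifically important: the fat
spectral phase factor is common to both passes and largely cancels in the
conjugate-product combination, so at low R2 (where fat and water
steady-state phases are similar) the method is nearly fat-immune, while at
high R2 the steady-state phase difference between compartments produces
biases that exceed the 20 % exclusion threshold at lower PDFF at 3.0 T than
at 1.5 T. Inverting the single-pass phase instead would predict large
spurious bias at all R2. The 20 % |bias| exceedance contour is exported as
the exclusion criterion for fat-confounded measurements.

## Protocol optimization simulators

Grid searches over flip angle (default 4–24° in 2° steps) and phase
increment (1–5° in 0.5° steps) at TR = 3 ms, R1 = 1 s⁻¹, score each cell
by:

- **worst-case normalized bias** under B1 inhomogeneity: signals simulated
  at actual flip γ·α for γ ∈ [0.6, 1.2] and R2 ∈ {50…450} s⁻¹, inverted
  through the cell's nominal-flip table; value = max |R̂2−R2|/R2. The
  interior spacing of both grids is a configuration choice; the endpoints
  are the studied ranges.
- **worst-case normalized SD** under complex Gaussian noise at SNR = 20
  (σ = |signal|/SNR), 2000 Monte-Carlo replicates per cell by default, each
  replicate inverted individually; value = max over R2 of σ(R̂2)/R2, with
  the Monte-Carlo standard error reported alongside.

A single standard-normal draw block is shared across cells so that
comparisons across settings (e.g. doubled SNR) ride on common random
numbers. The TR-sensitivity study reports Monte-Carlo bias and CV
(SD/true R2) versus TR ∈ {3, 6, 9} ms and SNR, with and without a 9-sample
complex-averaging surrogate for the 3×3 kernel (averaging independent noisy
replicates of one voxel; it ignores the spatial correlation a real kernel
sees at structure boundaries).

At the study conditions (R2 = 150 s⁻¹, SNR = 20, TR = 3 ms) the
negative-phase probability of a single voxel is ≈3×10⁻⁶ (the phase sits
4.5σ above zero), so negative draws are demonstrable only with millions of
replicates; the phenomenon becomes prominent at longer TR or lower SNR,
which is the regime the averaging strategy targets.

## Synthetic phantoms

The vial phantom emulates an 11-vial MnCl₂-agarose arrangement: 100×100×10
matrix, 4.8×4.8×10 mm voxels, vials of 15 mm radius on a 150 mm ring, R2
evenly spaced over 50–300 s⁻¹ with R1 on the field's vial calibration line.
Degradations: a smooth per-slice quadratic background phase (amplitude ±90°
by default when enabled) applied identically to both passes, and complex
Gaussian noise added independently per pass with σ = (mean in-vial
magnitude)/SNR, so the requested SNR is met at the mean vial signal and
per-vial effective SNR falls with R2 as it does physically. Ground-truth
maps are copied from the specification, never simulated.

Liver-like volumes take a smooth positive R2 field; per-voxel signals are
interpolated component-wise from a dense steady-state curve (≤1 s⁻¹ node
spacing — the curve is analytic in R2, so interpolation error is far below
the noise floor). Optional long-T2 vessel inclusions receive an explicit
magnitude attenuation (default 0.4): on scanners, partial spoiling
suppresses long-T2 blood through diffusion damping of high-order coherences,
a mechanism a diffusion-free isochromat ensemble does not produce, so the
generator emulates its consequence rather than its cause. An optional PDFF
field routes through the fat model.

What the synthetic data do *not* contain: motion/ghosting, k-space or
parallel-imaging artifacts, coil sensitivities, slice-profile effects, B0
drift, and diffusion. Passing recovery tests therefore demonstrates the
correctness of the encoding/inversion pipeline under its own forward model,
not robustness to those confounders.

## Agreement statistics

Ordinary least-squares regression (t-based 95 % CIs, via statsmodels),
Bland–Altman bias and 95 % limits of agreement (bias ± 1.96·SD of paired
differences), and test–retest ICC. The ICC variant is ICC(2,1) — two-way
random effects, absolute agreement, single measurement — computed from the
ANOVA decomposition and cross-checked against an independent implementation
in the test suite; degenerate tables (no variance anywhere) return 0 by
definition rather than raising. The variant is recorded in CLI output.

## Numerical and scale choices

- Simulation batches are vectorized over (flip, increment, R1, R2) tuples
  and chunked (2048 tuples) to bound the working set.
- Test-suite problem sizes: lookup tables at 1–2 s⁻¹ spacing for recovery
  tests and 10 s⁻¹ for optimization maps; optimization grids of 11 flips ×
  6 increments with 5 R2 and 5 γ values and 800 noise trials; noise-skew
  demonstrations with 2.25×10⁶ draws. These sizes were chosen so the full
  characterization of the method remains a desk-scale computation while
  keeping Monte-Carlo standard errors well inside the asserted margins.
- The dynamic-range figure of merit (R2 at which the TR = 3 ms phase curve
  crosses a 5° noise floor) evaluates to ≈288 s⁻¹ in this implementation;
  the corresponding published figure reading is "approximately 250 s⁻¹".
  Both anchors of that comparison are approximate figure readings; the
  implementation's value is reported as computed (see `scripts/acceptance.py`).

## Known limitations

- No scanner pulse-sequence export, k-space reconstruction, or
  parallel-imaging handling; inputs are reconstructed complex volumes.
- No joint (R1, R2) inversion from a single phase — it is underdetermined;
  R1 estimates exist only through the calibration line.
- Fat-bias conclusions inherit the configurable spectrum and fat relaxation
  defaults; absolute bias values shift with those choices even though the
  structural findings (low-R2 immunity, field ordering) are robust.
- In vivo agreement coefficients require acquired patient data and are out
  of scope for the synthetic validation here.
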