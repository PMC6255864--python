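# Methods

This note documents the models implemented in `hsafm`, the defaults and
why they were chosen, the numerical decisions, and what the synthetic
data does and does not emulate.

## Measurement model

A height-spectroscopy record is modelled as

1. **Geometry.** Particles are hard disks of footprint diameter d_p
   diffusing on a periodic square membrane patch; the tip is a disk of
   radius r_tip = 1 nm fixed at the patch centre.  The tip reports a
   particle whenever the disks overlap, i.e. centre distance
   < w/2 with w = d_p + 2 r_tip.  The default trimer footprint is
   d_p = 8.3 nm, giving w = 10.3 nm — the width that connects the
   trimer's 33 µs dwell scale to D = 0.8 µm² s⁻¹ through τ = w²/4D.
   Oligomers of n units use d_p(n) = 8.3·√n nm (area linear in n).
   When several particles are under the tip the ideal height is the
   *maximum* of their event heights, not a sum: the tip senses
   topography, not occupancy count.
2. **Dynamics.** Free Brownian propagation at the sampling interval
   (Gaussian steps of per-axis s.d. √(2DΔt), periodic wrapping).  There
   is no inter-particle excluded volume: crowding effects enter only as
   user-supplied density-dependent D values, which matches how they are
   quantified experimentally (~10% slow-down).
3. **z-feedback.** A single-pole low-pass on the ideal occupancy height
   signal.  Its time constant is *calibrated*, not free: a 2.7 µs
   occupancy pulse must peak below the 5σ threshold in the noise-free
   limit (lower bound τ > 4.9 µs) while a 10 µs pulse must peak far
   enough above it to be detected essentially always under default noise
   (upper bound τ < 10.3 µs).  The default is the geometric mean of the
   feasible interval, τ_fb ≈ 7.1 µs.  Both boundary conditions are
   asserted in the test suite.
4. **Noise.** Zero-mean white Gaussian noise of RMS σ = 0.17 nm added
   after filtering, matching the protein-free baseline at 625 kHz.

Units are fixed throughout: heights and molecular lengths in nm, time in
s, D in µm² s⁻¹, surface densities in µm⁻², energies in k_BT (the
temperature never appears separately).

### What the simulator does not emulate

Cantilever oscillation and amplitude-channel physics, tip-shape
convolution beyond the disk radius, membrane mechanics, noise
correlations introduced by the feedback loop, and stage drift.  Passing
tests therefore validate the *analysis logic* under idealized instrument
statistics, not performance on every artefact of real traces.

### Dwell-time caveat (important)

The analytic relation τ_D = w²/4D is an effective, FCS-style timescale.
Microscopic sojourn times of a point-sampled hard contact are shorter:
the mean exit time from a disk of radius w/2 is (w/2)²/4D from the
centre, and boundary entries mostly leave again immediately.  The
feedback filter bridges sub-µs re-entries and extends detected events by
a few µs, which partly compensates, but at the default geometry the
dominant detected dwell component sits at ~15–25 µs rather than 33 µs,
and the mean detected dwell converted through τ = w²/4D *overestimates*
D by roughly 2–3×.  The occupied-*time-fraction* (and hence the
concentration pipeline) is unaffected by this bias.  This is a genuine
property of the microscopic model, documented rather than hidden; the
test suite asserts the dominant dwell peak inside the experimentally
observed 33 ± 26 µs band, not at its centre.

## Event analysis

* **Noise estimate**: median absolute deviation scaled to the Gaussian
  s.d., with three clipping iterations (discard samples more than 3σ̂
  above the median) so that up to ~20% one-sided event contamination
  biases the estimate by <5%.
* **Threshold**: H_T = kσ with k = 5 by default; the reported
  false-positive probability is the two-sided tail erfc(k/√2).
* **Events**: maximal runs strictly above H_T.  No gap merging and no
  minimum duration by default (the feedback already suppresses
  sub-resolution events); both exist as options.
* **Concentration**: c = (t_above/t_total)/d_p², with d_p the molecule
  footprint as printed in the source procedure.  Passing the detection
  width w instead is supported and is what the simulation-facing
  recovery uses (the detected fraction reflects the contact area).
* **Windows**: half-open [kT, (k+1)T) windows of 1 s default; events
  belong to the window containing their first sample; the dwell mixture
  is fitted globally and reused per window so class boundaries are
  consistent over time.

## Dwell-mixture deconvolution

Components are Gaussians truncated to positive dwells, integrated over
histogram bins (not sampled at centres).  Binning is Freedman–Diaconis
on the log-dwell axis, with the lower edge at the 0.2% quantile and the
bin count capped at √N.  The fit minimises Poisson-weighted squared
residuals (σ_i = √max(count,1)) with a deterministic multi-start
schedule: quantile-spaced means, histogram-mode multiples, and greedy
growth from the (n−1)-component solution.  Model selection walks n
upward and accepts a larger model only when it lowers χ² by more than 3
per extra parameter (noise alone absorbs ≈1 per parameter), and ignores
solutions containing components with under 2% of the events.  The
procedure is fully deterministic given the data.

Identifiability limit: three equal-weight components at 33/80/130 µs
with s.d. 25–34 µs overlap by more than one s.d.; at 10⁴ events even
unbinned maximum likelihood misses the component means by >10%.  The
suite therefore asserts exact recovery for resolvable widths and only
multi-modality detection at the strongly overlapped ones.

Classification assigns each event to the component of maximal posterior
responsibility, ties to the smaller component; unit fractions weight
component i by i base units, pooling i ≥ 5 into one higher-order class.

## Oligomerization equilibria

The assembly pathway is stepwise monomer addition,
[A_n] = [A_1][A_{n−1}]/K_d(1, n−1), using the monomer row of the K_d
matrix (220, 170, 650, 200 µm⁻²), extended by repeating the last
constant up to n_max = 10 with n ≥ 5 pooled.  The full matrix is
thermodynamically over-determined and mutually inconsistent, so no
multi-pathway reconciliation is attempted.  The free monomer density is
found by bracketed root finding (Brent) on the monotone mass constraint;
conservation holds to <10⁻⁹ relative across the tested range.

Free energies: ΔG = ln(c_n/c_m) between oligomer states.  Membrane
binding uses the partition coefficient P = [c_solution]/[c_surface] with
the surface density volumized by a slab of h = 2.0 nm (the bound
molecule's height); h is a parameter and is recorded in every output.
The slab convention reproduces the trend and approximate magnitude of
the measured binding energies (−1.9 k_BT vs −1.7 k_BT at the dilute
condition); the original unit convention is not stated precisely enough
to match beyond that.

The size dependence of diffusion is fitted as D = a·ln(b/r_p), linear in
(a, a ln b) and hence solved exactly by least squares.  Surface
concentration versus bulk calcium is fitted as a log-linear exponential;
the critical-coverage crossing follows analytically.

## Rotation analysis

* **Idealization**: boxcar filter (30 samples by default, matching how
  such traces are displayed), state levels from the two most prominent
  modes of the filtered-height histogram (zero-padded so edge modes
  count), nearest-level assignment with a hysteresis band of half the
  level separation, and suppression of excursions shorter than five
  filter widths (240 µs at the defaults — the same floor as the
  shortest dwells resolved experimentally).  With this floor the mean
  dwell bias stays below 10% for signal-to-noise ratios (level
  separation over filtered noise s.d.) from 3 to 10.  A hidden-Markov
  idealizer would handle per-dwell level jitter comparable to the level
  separation better; with the default jitter (0.10/0.07 nm against a
  0.28 nm separation) the threshold idealizer mislabels dwells whose
  plateau happens to fall near the midpoint, a documented limitation.
* **Kymograph traces**: the 0°/60° rows are sampled once per line; their
  difference doubles the signal and cancels common-mode errors and is
  idealized with the same machinery.
* **Transitions**: the per-line lobe position (sub-pixel parabolic
  argmax) is idealized two-state; a transition spans the lines strictly
  between the last line within 10% of the separation around the
  departure level and the first line within the arrival band.  The line
  count is scaled by 1/(1 − 2·0.1) to undo band erosion, making the
  duration estimate unbiased with ±1-line quantization.  Direction uses
  the transit topology: one rotation sense sweeps the detected lobe
  *between* the plateau positions, the opposite sense overshoots past
  the departure plateau while the next lobe enters from beyond the far
  side; comparing the overshoot fraction with the displacement sign
  yields the sense, 100% correctly on noise-free kymographs.
* **Energetics**: ΔG = −ln(τ_rotation/τ_state) k_BT, velocity
  60°/τ_rotation.  When both height-spectroscopy and line-scan dwell
  estimates exist, the line-scan τ_state is the default reference
  (0.665 ≈ 0.7 k_BT arises from 18/35 ms, not 18/26 ms).

### Rotor generator geometry

The rotor is three Gaussian lobes (peak 2.0 nm, s.d. 1.6 nm) at 3 nm
from the centre, with the scan line tangent to the lobe circle so the
two preferred orientations put a lobe at scan positions 3 nm apart —
the experimentally observed state separation.  This tangent geometry is
what makes the two rotation senses optically distinguishable; its
inter-lobe saddle is deeper than the ~0.3 nm height modulation seen on
real trimers, a deliberate trade of profile realism for direction
observability.  Kymograph noise defaults to 0.10 nm per pixel (line-rate
sampling averages the fast z-noise).

## Problem sizes in tests and the acceptance script

Simulated validation uses 2–30 s traces at 625 kHz with up to ~175
particles, and a 60 s, 4-particle (2 µm box) run for the dilute-
condition pipeline; these sizes give counting errors comfortably inside
the asserted tolerances while keeping the full suite and the acceptance
script each within a few minutes on one CPU.
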