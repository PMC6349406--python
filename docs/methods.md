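# Methods

## The model

The package studies passive electrotonus in single unbranched neurites.
A cable of length L (default 1000 µm) with diameter profile d(x) —
uniform, linearly tapered from a proximal diameter d0 to a distal
diameter d1, or an abrupt step — is discretized into cylindrical
compartments of width dx.  Each compartment i carries membrane area
A_i = π·d_i·dx, leak conductance A_i/Rm toward E_leak and capacitance
Cm·A_i; neighbors couple through the series combination of their
half-compartment axial conductances g = (π d²/4)/(Ra·dx/2), which keeps
axial current continuous across a diameter step instead of averaging
diameters.  Both ends are sealed (zero axial flux); an optional
*proximal load* — an equivalent cylinder (default 20 µm × 200 µm)
attached before x = 0 — stands in for the current sink of the rest of a
neurite tree.

Synapses are conductance events with instantaneous rise and
single-exponential decay, g(t) = g_max·e^{−(t−onset)/τ}, driving current
g·(E_rev − V).  The canonical inhibitory event used by all protocols is
E_rev = −75 mV, τ = 70 ms, g_max = 10 nS.  Current-clamp steps provide
holding currents and linear-superposition controls.

Units are mV / ms / µm / µS / nA / nF throughout, which makes the
membrane equation conversion-free; only the specific constants
(Ra in Ω·cm, Rm in Ω·cm², Cm in µF/cm²) are converted, in one module.

### Numerics

The spatially discretized system is tridiagonal and integrated with the
Crank–Nicolson scheme (backward Euler available), one Thomas solve per
step.  Time-varying synaptic conductances enter the implicit diagonal at
the step endpoints.  Two details matter in practice:

* **Event onsets are right-continuous and grid-snapped.**  The implicit
  endpoint of the step that lands exactly on an onset must not see the
  event, or the event leaks one step backward — with a settle period
  this corrupts the baseline sample.  Onsets are snapped to exact
  multiples of dt so activation comparisons are exact, which is what
  makes the current-clamp superposition control hold to ~1e−12 mV·s.
* **Holding currents are initialized exactly.**  The steady state under
  clamps with negative onset is a banded linear solve; integration
  starts there, so the baseline at t = 0 is converged regardless of
  settle time (the default 200 ms settle is retained as a guard).

Defaults are dx = 2 µm, dt = 0.025 ms, with recording decimated to
0.25 ms.  The canonical event is stiff at its compartment (the 10 nS
conductance on a 0.5 µm cable gives a local time constant of ~3 µs and
nearly clamps the site toward E_rev); the resulting profiles are
nevertheless converged at the defaults — halving dx and dt moves peak
amplitudes by <0.5% (tested), and the classic-cable length constant by
<0.2% down to dx = 0.5 µm, dt = 6.25 µs.  Batch sweeps use a coarser
profile (dx = 4 µm, dt = 0.05 ms, 50 ms settle) that agrees with the
defaults to ~0.3% on λ_effective and ~0.5% on summation statistics; the
full 720-model batch then runs at desk scale on one CPU.  Steady-state
profiles and input resistances match the sealed-cable closed forms
(cosh/coth in λ = √(Rm·d/(4Ra))) within 1%, and steady transfer
resistance is reciprocal to 1e−9.

## Measurement protocols

**Electrotonus.**  The canonical event is evoked at the proximal (d0)
end and the spatial amplitude profile measured along the cable.
λ_effective is the first distance (linear interpolation between grid
points) at which amplitude falls to e⁻¹ of the activation-site value; a
profile that never crosses is *censored* and reported as an explicit
flag with the maximum recorded distance as a lower bound, never a
sentinel number.  Two readout conventions are provided:

* `at_site_peak` (default): the profile is read at the instant the
  activation-site response peaks — a single-cursor measurement across
  overlaid traces.  On the classic thin cable (uniform 0.5 µm,
  Rm = 1e4 Ω·cm², Ra = 100 Ω·cm) it gives λ_effective ≈ 310 µm,
  matching published values for this configuration; on the 20→0.5 µm
  taper the profile stays above threshold over the full millimeter.
* `per_site_peak`: each position's own largest deviation from baseline.
  Timing dispersion then lengthens the measure (≈355 µm on the same
  classic cable, close to the steady-state cosh-profile crossing at
  365 µm).  Both conventions agree on every qualitative trend.

Activating proximally and reading distally is, by the reciprocity of
passive cables, equivalent to the experimentally accessible quantity —
the somatic response to events evoked at increasing distances — from a
single simulation.  The choice of end matters for tapered cables:
activation at the thin tip instead produces a sharp local cusp (high
local input impedance) followed by a plateau, and the cusp-normalized
ratio profile is not the published measure.

**Five-site summation.**  Events are evoked at five sites (default
500–900 µm from a recording electrode 100 µm from the d0 end)
individually and sequentially at 5 Hz, in the inward (farthest site
first) and outward orders.  Integrals of the recording-site deviation
(trapezoid, mV·s, positive for hyperpolarization) run from the first
onset to last onset + 5τ + 800 ms so events decay ≥99.9% — the
statistics are window-sensitive, so the window is part of the protocol
definition.  Directional bias = inward − outward integral; linearity =
inward − arithmetic-sum integral, where the arithmetic sum shifts the
individually evoked responses to the sequence onsets (the sum of
individual integrals equals the summed-trace integral to 1e−9 by
construction).  Positive linearity means supralinear summation; the
sign convention is chosen so the classic thin cable is sublinear.

With this full-decay window the *linearity* statistic reproduces every
published contrast: the thin cable is strongly sublinear (−0.74 mV·s at
the reference passive values), moves monotonically toward 0 as Rm falls
or Ra rises, and the tapered cable integrates near-linearly (≈5% of the
thin-cable magnitude).  The *bias* statistic, in contrast, reduces to a
conductance-interaction residual once events decay completely: both
cables come out direction-insensitive by integral measure (bias ≈0.1%
of the integral; thin-cable sign positive/inward at the reference
values).  Published directional-bias plots show a larger, cleanly
trending quantity, which evidently depends on an analysis detail
(window or normalization) not recoverable from the available
description; the package reports the faithful windowed definition and
its acceptance test records the discrepancy rather than emulating an
unknown pipeline.

**Gradual vs step taper.**  For proximal diameters d0 with a fixed
fractional reduction (default 80%: d1 = 0.2·d0), λ_effective is
compared between a full-length linear taper and step profiles at
configurable positions (default 100/500/900 µm).  Replacing the taper
by an early step to the thin diameter shortens λ_effective, the classic
taper advantage.  Two caveats found by simulation and worth knowing:
a *late* step to a sub-µm stub can lengthen λ_effective beyond the
gradual taper (the stub unloads the proximal section), and claims about
steps killing propagation are direction-dependent — absolute transfer
is reciprocal-symmetric, but λ_effective normalizes by the
activation-site amplitude, which breaks that symmetry.

## The model library

The default grid crosses d0 ∈ {0.5, 2, 5, 10, 20} µm with
d1 ∈ {0.5, 2, 5, 10} µm (the full 5×4 geometry matrix, endpoints
matching the stated ranges), Ra ∈ {10, 50, 100, 150, 200, 300} Ω·cm and
Rm ∈ {2e4, 1.6e4, 1e4, 5e3, 1e3, 1e2} Ω·cm²: 720 models, Cm = 1 µF/cm²,
length 1 mm.  Anti-tapered members (d1 > d0) are simulated like any
other.  Sweeps are deterministic, resumable (completed model ids in the
output CSV are skipped), capture per-model failures as rows, and write
a config-hash sidecar.  On the sweep profile the full batch with both
protocols takes roughly ten minutes on one CPU.

## Ephys statistics

Per uncaging site, the apparent reversal potential is the x-intercept
(−intercept/slope) of the OLS fit of response amplitude ΔV on holding
potential V_m, with a quality flag at |R| > 0.85.  Per neuron:
OLS regressions of amplitude or apparent E_rev on site distance
(two-sided t test on the slope; MSE = RSS/n), and within-neuron
normalizations (amplitude to the per-neuron maximum, negated so −1 is
the largest response; E_rev to the per-neuron mean).  Groups are
summarized as mean, sample SD (n−1) and CV = SD/|mean| — membrane
potentials are negative, printed CVs positive.  Cell types are compared
by classical one-way ANOVA; identity-line agreement is RMSE of (x, y)
pairs against y = x.

The packaged per-neuron summary table (21 neurons: 6 PD, 5 LP, 5 VD,
5 GM) ships as a CSV fixture.  ANOVA on CVs recomputed from the printed
mean/SD at 4 significant figures — closer to the unrounded inputs than
the 2-decimal CV column — reproduces F(3,17) = 1.20, p = 0.341, and on
per-neuron mean reversals F(3,17) = 2.29, p = 0.115; recomputed group
means match the printed summary rows to 2 decimals.

## Synthetic data

The statistical generator draws, per site, a distance (uniform,
50–1000 µm), a true reversal (Normal around −70 mV, between-site SD
3 mV), a response slope (uniform 0.05–0.2 per mV of driving force) and
responses ΔV = g·(E_rev − V_m) + ε with Gaussian amplitude noise at 8
holding levels evenly spaced in [−100, −40] mV.  It emulates the
*structure* of uncaging datasets — a linear ΔV–V_m relation per site and
no amplitude–distance trend — not their biophysics: passing closed-loop
tests shows the estimators recover generative parameters at OLS-theory
error, not that real neurons behave this way.  The in-silico generator
supplies the biophysics instead: holding currents at the recording
compartment (computed exactly from the input resistance; the passive
system is linear, so bisection is unnecessary) plus the canonical event
at a distal site.  On the tapered model the apparent reversal stays
within ~2 mV of the synaptic −75 mV across sites 100–900 µm away
(CV ≈ 0.01); on the thin cable it runs tens of mV in the
hyperpolarized direction, because the distal driving force barely
follows the somatic holding potential and the x-intercept extrapolates
far beyond the data.

Voxel tubes are straight (optionally rotated, optionally
surface-jittered) tapered cylinders voxelized on an isotropic or
anisotropic grid, with an axis skeleton (nodes every 1 µm, sequential
parent links) and ground-truth diameters attached.  They exercise the
morphometry pipeline with known truth; they do not contain branching,
curvature, staining artifacts or segmentation noise of real confocal
reconstructions.

## Morphometry

Surface voxels (foreground with a background 6-neighbor; anisotropic
voxel sizes honored) are extracted once per volume.  At each node of a
root-to-tip path, the local axis is the central difference of the
neighboring path nodes (one-sided at the ends); surface points within
0.5 µm of the orthogonal plane and within a configurable maximum radius
(3 µm default, 11 µm for thick branches — an explicit per-call switch,
not auto-detected) are projected into the plane, ordered by polar angle
about their centroid (the standard convexification for near-circular
sections), and measured with the shoelace formula.  The
circular-equivalent diameter is 2·√(area/π).  Sections with fewer than
three candidate points are flagged (area undefined, not zero) and
excluded from the 3-node centered running average.  On synthetic
tapered tubes at 0.25 µm voxels the smoothed profile recovers truth
within ~11% away from the tips and is rotation-invariant to about two
voxels.

## Known limitations

* Single unbranched cables only: no trees, active conductances, or
  multi-neuron circuits.
* The directional-bias statistic under the full-decay window is an
  interaction residual (see above); published bias magnitudes are not
  reproduced.
* λ_effective conventions matter at the ~15% level (readout mode) and
  qualitatively (activation end on tapered cables); both knobs are
  explicit parameters.
* Non-convex cross sections are convexified by the angular sort;
  heavily multi-lobed sections would be overestimated and are only
  flagged when nearly empty.
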