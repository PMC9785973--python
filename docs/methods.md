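# Methods

This note documents the estimators, conventions and design choices behind
hydrolayer, and what the synthetic test fixtures do and do not establish.

## Units and conventions

Internal units are Å, fs, amu, elementary charge; wavenumbers ν̃ in cm⁻¹
with ν̃ = ω/(2πc), c = 2.99792458·10⁻⁵ cm/fs; densities in g·cm⁻³
(amu/ų × 1.66053906660). Frames are 0-indexed; times are absolute fs from
the first stored frame. Boxes are orthorhombic; triclinic inputs are
rejected. All distance bins and layer intervals are half-open `[a, b)`, so a
distance exactly on a boundary belongs to the outer layer.

The stored sampling interval Δt of the trajectory is treated as
authoritative. Its Nyquist limit is ν̃max = 1/(2cΔt); resolving the O–H
stretch region up to 3750 cm⁻¹ requires Δt ≤ ~4.4 fs, and the harmonic
generator refuses mode wavenumbers above the limit of the requested Δt.

## Distance coordinate and density estimation

The layering coordinate of a water molecule is the minimum-image distance
of its **oxygen** to the nearest solute **heavy** atom (solute hydrogens can
be included with a flag). This is the common convention and matches the
~1.8 Å first-peak scale of protein hydration shells; distances to a
solvent-excluded surface are out of scope.

Two density estimators are provided:

* `voronoi` — generators are water oxygens plus solute heavy atoms; the
  tessellation is computed with periodic images within an automatically
  chosen margin, and volume conservation (Σ cells = box volume to 1e-9
  relative) is verified, escalating to the full 27-image set if needed.
  Density in bin b is Σ(molecule masses with oxygen in b) / Σ(their cell
  volumes), with mass and volume sums pooled over frames before the ratio
  (more stable than averaging per-frame ratios in thin bins). Each
  molecule's full mass sits in its oxygen's cell.
* `bin_volume` — mean molecule count per frame × molecule mass / shell
  volume, with the shell volume analytic for a single-site solute and
  Monte-Carlo (seeded, deterministic) for extended solutes.

A caveat documented here because it shapes the tests: Voronoi cells of
liquid-density water are ~3 Å across, so the Voronoi estimator low-pass
filters density features narrower than a cell — a 1 Å-wide step is
partially washed out even with perfect statistics. Planted-step recovery is
therefore validated with the unbiased `bin_volume` estimator, while the
Voronoi estimator is validated on homogeneous boxes (flat far-field within
5 %) and through volume conservation. On real hydration profiles, whose
features are produced by the same molecules that define the cells, this
smoothing is part of the method, as in the original Voronoi-profile
approach.

## Boundary detection

The profile is smoothed with a centred moving average (default 5 bins).
The far-field level is the mean over the outermost fifth of the bins; the
bulk onset is the first distance beyond which the smoothed profile stays
within `bulk_tolerance` (default 5 %) of that level. Boundaries are bin
centres of local minima between the first populated bin and the onset,
found with `scipy.signal.find_peaks` under a prominence floor of
`min_prominence` (default 5 %) × far-field level — the floor suppresses
sampling-noise minima; planted physical dips in hydration profiles have
prominences several times larger. Plateau ties resolve to the smaller
distance. The bulk-onset distance is appended as the final boundary. The
procedure is invariant to uniform rescaling of the density axis because all
thresholds are relative. Degenerate cases: a profile indistinguishable from
bulk yields a single layer ending at the maximum profiled distance; no
interior minima yields a single boundary at the bulk onset (both with
warnings, not errors). When detection is not run, the package's default
partition is {2.2, 3.4, 4.5, 7.0} Å — four layers bracketing the typical
first peak (~1.8 Å), second peak (~2.6 Å), a narrow third region and a
bulk onset near 7 Å — always user-overridable.

## Residence membership and interval scheme

A molecule belongs to layer k for an interval iff its occupancy (fraction
of interval frames labelled k) is ≥ the threshold (default 0.90).
Occupancies are recorded for all molecules. Raising the threshold never
adds members. At thresholds ≤ 0.5 a molecule could qualify for two layers;
the smallest layer index wins (BULK last), keeping member sets disjoint —
irrelevant at the 0.90 default, but defined and tested.

The analysis window defaults to the final 200 ps of the trajectory, tiled
contiguously per layer: 20 ps intervals for layers 1–2, 5 ps for outer
layers, with the first `n_intervals` (default 10) tiles averaged. At 5 ps
the window holds 40 tiles; which 10 a study should average is a free
choice, so the package averages the first 10 by default and exposes
`n_intervals`.

## ACF and spectrum estimators

ACFs use all time origins, evaluated via FFT (zero-padded, power spectrum,
inverse transform) and normalised per lag by the number of origins; the
estimator is identical to the direct O(N²) lag sum to ≈1e-16 and is tested
against it. For the velocity ACF the three Cartesian components of all
selected atoms are pooled, so the ACF of a union of equal-size disjoint
selections is exactly the mean of the selections' ACFs. Normalised ACFs are
exactly 1 at zero lag. The flux ACF sums (dot product) rather than averages
components and is unnormalised by default. `max_lag` defaults to half the
interval.

The cosine transform discretises ∫₀^∞ Z(t)cos(ωt)dt with the trapezoidal
rule — half weight on the zero-lag sample — on the grid
ν̃_m = m/(2cKΔt·zpf) for K lags and zero-pad factor `zpf`. The half weight
matters: with rectangular weights the transform of exp(−t/τ) acquires a
constant offset Δt/2 that dominates the Lorentzian tail; with the
trapezoidal rule the error is O((Δt/τ)²). Both an FFT path and an explicit
cosine-sum path are implemented and agree to 1e-10 relative (tested). A
Hann taper on the lag axis (default for production spectra, off for
analytic tests) suppresses truncation ringing; the window name is recorded
in the spectrum metadata. For the rectangular window the discrete sum rule
Δν̃·Σ_m S(ν̃_m) = ½Z(0)·1/(2c) holds to O(1/K) and is tested at 2 %.

## Per-layer and cumulative spectra

Per-layer spectra are computed per interval over that interval's resident
members only — H atoms, O atoms, or whole molecules for IR — then averaged
(unweighted) over the marked intervals; member counts and interval counts
are recorded in the metadata. Empty intervals are skipped with a warning;
an all-empty layer is an error.

Per-layer IR uses the **collective** flux of the layer's members
(cross-molecular dipole correlations within the layer retained, cross-layer
excluded); a `molecular` mode (per-molecule flux ACFs averaged, then
transformed) is available since either reading of "average-summation of the
molecules' spectra" is defensible. Collective is the default because the
flux–flux form is defined for the selection's total dipole derivative.

Cumulative ("summation of layers") spectra pool the union of members of
layers 1..k per interval and transform the pooled selection, then average
over intervals; member sets must be disjoint per interval and share one
interval scheme. Because layers 1–2 and 3–4 use different interval lengths,
the pipeline recomputes membership on a common scheme (the inner, 20 ps
interval length) for cumulative spectra. With all layers plus bulk included
the pooled selection is every water molecule, and the cumulative spectrum
equals the whole-selection spectrum identically (tested at 1e-10).

VDOS is reported separately for H and O atoms, mass-unweighted. Intensity
units are arbitrary; IR scales exactly quadratically with the charges
(tested: doubling all e_j multiplies I by 4) and a neutral rigidly
translating selection has identically zero flux.

## Band summaries

Default bands: acoustic [0, 130), libration [130, 1300), bend [1400, 1800),
stretch [3250, 3750] cm⁻¹ (the 130 cm⁻¹ split separates the peak-free
sub-acoustic region from the librational components). Per band: argmax
position and intensity, FWHM by linear interpolation at half maximum, and
shoulders as curvature minima (Savitzky–Golay second derivative, default
window 11 points) or secondary local maxima, excluding the main peak's
immediate neighbourhood and merging candidates closer than the exclusion
radius. All-zero bands yield null metrics. A Gaussian of σ = 40 cm⁻¹ is
recovered with FWHM 2√(2 ln 2)σ ≈ 94.2 cm⁻¹ within 5 cm⁻¹, and a 0.35-weight
satellite 150 cm⁻¹ below a major peak is flagged within 20 cm⁻¹ (tested).

## Synthetic generators: what they emulate, what they don't

All generators are bit-deterministic under a fixed seed (numpy PCG64) and
record their parameters and seed in a JSON sidecar when written to disk.

* `gen_harmonic_waters` — neutral 3-site waters (default charges −0.82/+0.41,
  SPC-like) whose atomic velocities are exact cosine superpositions with
  per-molecule random phases and (optionally) random unit displacement
  patterns; positions are the analytic integrals. The default mode set
  {50, 250, 1650, 3300, 3650} cm⁻¹ spans the acoustic and librational
  features, the bend, the bound-OH shoulder and the free-OH stretch of
  flexible-water spectra. The fixture carries no force field, hydrogen-bond
  network, anharmonicity or mode mixing — it validates frequency recovery
  and linearity, not lineshapes of real water.
* `gen_ou_gas` — monatomic atoms with the exact Ornstein–Uhlenbeck update
  v(t+Δt) = v e^{−Δt/τ} + ξ at stationary variance kT/m, hence VACF
  exp(−t/τ) and Lorentzian VDOS 2τ/(1+(ωτ)²)·(shape); the diffusive
  stand-in for translational (oxygen-dominated) motion.
* `gen_layered_box` — static frames whose oxygen positions are drawn from a
  prescribed piecewise radial density around a solute proxy (molecule count
  fixed at the profile's expectation; positions re-sampled independently
  per frame). Velocities are zero: it is a geometry-only fixture for the
  density/boundary stages.
* `gen_scripted_layers` — label matrices written directly from a script, to
  exercise the residence rule against one-line brute-force counts.
* `gen_harmonic_hydration_box` — harmonic waters pinned inside prescribed
  distance shells around a central solute atom, giving an end-to-end
  fixture in which layer populations and their spectra are known exactly.

Passing tests on these fixtures establish the estimators and bookkeeping
(frequency recovery to one grid step, closed-form ACF/spectrum agreement,
conservation laws, membership logic), not the physics of any particular
water model or protein surface.

## Problem sizes in the checks

The property checks run at sizes chosen to put sampling error comfortably
below the asserted tolerances on one CPU: 100 molecules × 10 ps at 1 fs for
frequency recovery; 2000 OU atoms × 400τ for the Lorentzian shape (max
relative deviation ≈2 % against a 5 % bound); 3000 static frames of a ~460-
molecule box for per-bin step-profile recovery (observed ≤2.2 % against a
5 % bound); 50-site frames for volume conservation; 1000 scripted molecules
for residence bookkeeping.

## Known limitations

* Orthorhombic boxes only; no triclinic minimum image.
* Classical spectra: no quantum/harmonic correction factors, no absolute IR
  absorption coefficients, no Raman, no protein–water cross-correlations.
* The Voronoi density estimator smooths sub-cell-width features (see above).
* GRO-series reading requires either `t=` titles or an explicit Δt; XTC is
  rejected by design (no velocities).
* Hydrogen-bond kinetics, exchange-event tracking and solvent-excluded
  surface distances are out of scope.
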