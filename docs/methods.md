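# Methods

## Scattering models

The package treats a gelling amylose solution as two coexisting
populations: dissolved chains and a solid-like aggregate phase, with
intensities in arbitrary units (no absolute calibration).

**Rod term.** Dissolved amylose behaves as a long thin rod on the probed
length scales, contributing the cross-section factor
`A (1/q) [J₁(qR_c)/(qR_c)]²`. Because the printed model is a
proportionality, the rod carries an explicit free prefactor `scale_rod`
(`A`); arbitrary units require one free scale per component. The term
diverges at q = 0 and is only evaluated on q > 0 grids. In Kratky
representation it rises as `q·A/4` at low q and turns over near
`qR_c ≈ 1.26`, which for R_c ≈ 0.6 nm places the first Kratky maximum
near q = 2 nm⁻¹ — the same feature the helical-chain model reproduces.
J₁ comes from scipy.special (relative accuracy far better than the 1e-12
we rely on over qR_c ∈ [0, 50]).

**Aggregate terms.** Either a stretched exponential
`I(0)_ex·exp[−(qΞ)ˣ]` — Ξ the mean solid-like non-uniformity size, x ∈
(0, 2] with the Gaussian/Guinier limit at x = 2 — or the Debye–Bueche
random-two-phase form `I(0)_DB/(1+a²q²)²` with inhomogeneity length a.
The Debye–Bueche denominator exponent is 2 (the standard form; a
linearity check of `I^(−1/2)` vs `q²` is in the test suite). An
Ornstein–Zernike Lorentzian is provided for comparison but not used by
the default pipeline. An optional flat background (default 0) is
available because real excess-scattering curves often keep a flat
residual; the default keeps the bare two-component form.

## Fitting

Single-curve fits minimize Kratky-space residuals
`q²I_model − q²I_obs` (weighted by `1/(q²σ)` when uncertainties are
present) with scipy's trust-region reflective least squares
(`xtol = ftol = gtol = 1e-14`). Gel fits are conventionally judged in
Kratky representation, where the mid-q region that discriminates the
aggregate terms carries the most weight; a linear-space objective is
available and labelled in the result. The stretched exponent creates
shallow local minima, so fits are multi-started: the caller's init plus
eight deterministic seeds (four log-spaced correlation lengths in
1–40 nm crossed with exponent values 0.7/1.5 for the stretched model, or
crossed with two rod radii for the Debye–Bueche model), prefactors
initialized from the data (lowest-q intensity; median of q·I for the rod
scale). Lowest residual wins; ties go to the first encountered.

Default window q ∈ [0.1, 3.5] nm⁻¹ excludes the crystal diffraction
peaks at 4 and 7 nm⁻¹, which the two-component models do not describe.
Bounds — R_c ∈ [0.1, 2] nm, Ξ and a ∈ [0.1, 100] nm, x ∈ [0.2, 2],
prefactors ≥ 0 — bracket all reported values by about an order of
magnitude; x's lower bound keeps the exponent well-conditioned.
Parameters may be fixed (pinned exactly, excluded from the Jacobian);
fixing can only increase the residual, which the suite asserts.
Standard errors come from the Jacobian-based covariance scaled by the
residual variance, reported as NaN when the covariance is singular.

Series are fitted frame by frame in time order. Warm starting (each
frame initialized at the previous solution) is the default; the first
frame, and any frame whose constraint set changes, still gets the full
multi-start. Constraint rules `(t_start, t_end, {name: value})` pin
parameters over time windows — the canonical use is fixing
R_c = 0.45 nm after 50 min, when the aggregate term has grown so large
that the rod radius is no longer identifiable (the fitted R_c otherwise
drifts upward by several percent even on noise-free data). Degenerate
frames are recorded and skipped, not fatal.

**Gel-point detector.** Per frame, I(q) is integrated (trapezoid) over
q ∈ [0.1, 0.8] nm⁻¹; the rate of change is formed by centered finite
differences and the time of maximum rate is refined with a parabola
through the neighbouring rate samples. A flat trace (max rate below
1e-9 of the largest frame integral — effectively numerical noise)
raises a no-gel-point error; a nearly constant rate (spread below 5% of
its maximum, e.g. linear-in-time growth) returns the interior argmax
with a flat-rate warning.

## Synthetic gelation series

The generator is a forward model of the analysis assumptions, so every
pipeline stage can be tested against known truth. Structural parameters
follow logistic sigmoids centered at the gel time; `transition_width`
(default 3 min) is the 10–90% rise time, matching the observed "sudden"
transition while keeping a named width. Defaults:

| system | model | gel time | trajectory |
|---|---|---|---|
| AM_L | rod + stretched exp | 37 min | R_c 0.6 nm const; Ξ 3→17 nm; x 0.70→0.85 |
| AM_H | rod + Debye–Bueche | 32.5 min | R_c 0.6 nm const; a 3→10 nm |

Pre-gel sizes ("several nm") are rendered as 3 nm. The aggregate
prefactor scales with the correlation volume,
`I0(t) = (size(t)/size(0))³` (from 1 to ≈ 182 for AM_L, ≈ 37 for AM_H):
for a random two-phase medium the forward-scattering power grows with
the inhomogeneity volume. This is what produces the sharp low-q
(0.1–0.8 nm⁻¹) intensity rise at the gel point that the detector keys
on; with a fixed prefactor, a growing Ξ would *suppress* the low-q
window and contradict the observed behaviour.

Crystal diffraction peaks are phenomenological pseudo-Voigt profiles
(η = 0.5, FWHM 0.3 nm⁻¹) at 4 and 7 nm⁻¹ whose heights ramp linearly
from zero at the gel time to 0.02 and 0.01 at the final frame. The
final heights are deliberately small on the scale of the diffuse
scattering: the Lorentzian half of a pseudo-Voigt decays slowly, and
peaks of order-unity height would leak ≈ 0.08 intensity into the fit
window at q = 3.5 where the model is ≈ 0.02, visibly biasing R_c and Ξ
even on noise-free data. At the chosen heights the peaks still stand
out clearly (≈ 2× the local rod baseline in I(q), ≈ 4× in Kratky) and
in-window contamination stays below 4% of the local model, keeping
worst-case noise-free trajectory recovery within 5% (R_c, the least
identifiable parameter post-gel) and below 0.5% for all others.

Noise is multiplicative Gaussian, `I → I(1+ε)`, ε ~ N(0, 2%) by default
— intensities are arbitrary units, so counting statistics are not
modelled — and fully seeded. Noisy curves carry σ equal to the
generating noise scale. Frames default to 1–60 min at 1-min spacing on
q ∈ [0.1, 8] nm⁻¹ (240 points), covering the low-q window, the fit
window, and both peaks.

What the generator does *not* emulate: instrument smearing, background
mismatch, detector artifacts, the post-gel decrease of Ξ seen in real
data (the default sigmoid is monotone), Avrami-type crystallization
kinetics, and lamellar features (absent at 10% concentration). Passing
roundtrip tests therefore demonstrate the estimator's correctness under
the model's own assumptions, not robustness to real-beamline
systematics.

## Molecular chain model

A glucose residue is a rigid coarse template: the pyranose ring heavy
atoms C1–C6, ring oxygen and glycosidic oxygen (8 sites) in an
idealized chair (hexagon radius 0.148 nm, ±0.026 nm pucker), hydrogens
absorbed into united-atom van der Waals radii (C 0.20 nm, O 0.16 nm).
Successive residues are joined about the α-1,4 linkage with fixed bond
geometry (C1–O–C4 angle 117°) and exactly two degrees of freedom per
linkage, the glycosidic dihedrals φ = O5–C1–O1–C4′ and
ψ = C1–O1–C4′–C5′, placed by natural-extension (NeRF) construction
followed by a rigid three-point superposition of the template. The
construction closes exactly: the template's attachment anchor lands on
the previous residue's glycosidic oxygen.

Dihedral pairs are sampled independently per linkage from the Boltzmann
weight `exp(−E/kT·temperature_scale⁻¹)` over a discrete 5° map grid —
no interpolation, so chains are exactly reproducible given a seed.

**The default energy map is a synthetic stand-in.** Published maltose
conformational-energy maps are not available in machine-readable form,
so the default is a two-Gaussian-well analytic surface whose free
constants were calibrated once against the experimentally observed
Kratky maximum of amylose in alkaline solution (q ≈ 2 nm⁻¹): main well
at (φ, ψ) = (−40°, 175°), σ = 15°, 16 kT deep relative to a 20 kT
plateau; minor well at (−80°, −80°), 4 kT above the main minimum,
injecting occasional kinks (≈ 2% of linkages). The main well generates
a regular helix of ≈ 5.9 residues/turn (rise 0.065 nm/residue,
residue-centroid orbit radius 0.43 nm, effective cylinder radius
≈ 0.6 nm with the atom envelope). Two calibration details matter: the
template substituent tilts had to be set near the ring plane — with
strongly axial glycosidic geometry the construction cannot produce
helices wider than ≈ 0.24 nm and the Kratky maximum lands at
3–4 nm⁻¹ — and the calibration targets the *thermal ensemble* (40-seed
mean 2.00 ± 0.10 nm⁻¹), which sits ≈ 0.1 nm⁻¹ above the rigid
single-model value because dihedral wobble and kinks decohere the
helix. `scripts/calibrate_chain_map.py` reproduces the scan. Any
literature-accurate map can be supplied as a text grid file instead.
Scattering is computed by the Debye formula over all atom pairs with
uniform-density sphere amplitudes (equal scattering-length density for
all atoms — the model is qualitative); handedness does not affect the
curve, since only pairwise distances enter.

A DP-50 chain is 400 spheres; the O(N²) Debye sum over a 200-point q
grid takes well under a second. Ensemble averaging over seeds is
available; single-model curves are the default, and their deviation
from ensemble behaviour is part of what the model illustrates.

## Numerical choices

- Sphere amplitude: series expansion below qR = 1e-3 to avoid
  cancellation; q = 0 handled by the analytic limits f(0) = V and
  I(0) = (Σf)².
- Kratky-maximum location: first interior discrete local maximum,
  refined by a quadratic through its neighbours (shift clamped to half
  a grid step); absence raises a distinct signal rather than returning
  a boundary value.
- Curve files store 17 significant digits, so float64 values round-trip
  exactly; report tables use 9 significant digits.
- Grid comparisons in solvent subtraction use relative tolerance 1e-6
  with no silent interpolation (an explicit opt-in flag resamples).
- Multi-start winners are compared on the raw sum of squared residuals;
  starting points are clipped strictly inside the bounds for the
  reflective solver.

## Problem sizes

The test suite and the acceptance script run the full pipeline at the
study scale: 60-frame series at 240 q points, 80-point single-curve
roundtrips, 20-replicate noise studies, DP-50 chains with 10-seed
ensembles. The complete suite finishes in well under a minute on one
core.

## Known limitations

- The energy map is calibrated, not derived; absolute conformational
  populations carry no physical meaning beyond the helix geometry they
  encode.
- Post-gel R_c is weakly identifiable whenever the aggregate term
  dominates — the reason the fixed-R_c constraint exists — so unpinned
  post-gel R_c values should be read with their (large) standard
  errors.
- The stretched-exponential and Debye–Bueche fits share the rod term;
  model selection between them is left to the user (residual
  comparison), not automated.
- Uncertainties are local (covariance at the optimum); no posterior
  sampling.
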