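# amylogel

Analysis tools for time-resolved small-angle X-ray scattering (tr-SAXS) of
gelling amylose solutions.

Amylose — the linear α-1,4-linked glucan of starch — dissolves molecularly
in alkaline solution and gels when the pH is lowered slowly (in situ
neutralization, e.g. by formamide hydrolysis). During gelation the chains
aggregate into crystalline junction zones, which shows up in tr-SAXS as a
sharp rise of the low-q intensity (q ≈ 0.1–0.8 nm⁻¹) around the gel point
and the appearance of diffraction peaks near q = 4 and 7 nm⁻¹. This package
is for scattering scientists who want to turn such frame series into
structural parameter trajectories — and for anyone who wants to test that
pipeline without beamline data.

## The models

Each frame is described as a two-component system: dissolved rod-like
chains plus a solid-like aggregate phase.

Low-molecular-weight systems (rod + stretched exponential):

    I(q) = A · (1/q) · [J₁(qR_c)/(qR_c)]² + I(0)_ex · exp[−(qΞ)ˣ]

High-molecular-weight systems (rod + Debye–Bueche):

    I(q) = A · (1/q) · [J₁(qR_c)/(qR_c)]² + I(0)_DB / (1 + a²q²)²

where R_c is the rod cross-sectional radius (≈ 0.6 nm for a single amylose
chain), Ξ the mean size of the solid-like non-uniformity with stretching
exponent x (x = 2 is the Gaussian/Guinier limit), and a the Debye–Bueche
inhomogeneity length. Fits are judged and (by default) performed in the
Kratky representation q²I(q).

The package also builds a Monte Carlo molecular model: a DP-50 amylosic
chain whose glycosidic dihedrals (φ, ψ) are drawn from the Boltzmann weight
of a conformational energy map, with scattering computed atom-pairwise by
the Debye formula (atoms as van der Waals spheres). Its Kratky curve shows
a first maximum near q = 2 nm⁻¹, the helical-chain signature seen
experimentally for amylose in NaOH.

Modules: `curves` (curve container, .dat/manifest I/O, Kratky transform,
solvent subtraction), `models` (the closed-form terms above), `chain`
(Monte Carlo chain + Debye scattering), `fitting` (multi-start least
squares, series fitting, gel-point detection), `simulate` (synthetic
gelation series generator), `cli` (command line).

## Worked example

Simulate the default low-molecular-weight (AM_L) gelation series — 60
one-minute frames, parameter sigmoids centered at the 37-min gel point, 2%
multiplicative noise — then fit every frame and report the trajectories:

```
$ amylogel simulate --system AM_L --out series/ --noise 0.02 --seed 1
series/series.tsv
$ amylogel fit-series --manifest series/series.tsv --model eq1 --out report.tsv
report.tsv
```

`report.tsv` starts with

```
# amylogel_version: 0.1.0
# gel_time_estimate_min: 36.7631954
time_min  scale_rod  rc_nm      i0_ex      xi_nm      x          ...
1         1.02029114 0.60012976 0.95850427 2.98196796 0.70661063 ...
...
37        0.99138642 0.59828929 37.4966381 10.1253280 0.77032430 ...
38        0.99686170 0.60200795 119.191124 15.2706315 0.80440545 ...
```

Reading: the low-q rise detector places the gel point at 36.76 min (the
generator's truth is 37, frames are 1 min apart); the rod radius stays at
≈ 0.6 nm throughout (dissolved chains persist); the correlation length Ξ
jumps from ≈ 3 nm to ≈ 15–17 nm across the gel point while the aggregate
prefactor grows by two orders of magnitude — the aggregation signature.

The molecular model:

```
$ amylogel model-scatter --dp 50 --seed 0 --out model.dat
INFO amylogel: first Kratky maximum at q = 2.012 nm^-1
```

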