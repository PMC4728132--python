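# Methods

## The model

Polarity establishment is modelled as a mass-conserved reaction-diffusion
system for the GTPase Cdc42 and the Bem1-GEF complex on a square membrane
patch with periodic boundaries (a torus of area A = 25π µm², side
L = √A ≈ 8.86 µm), coupled to a well-mixed cytoplasm. Four membrane fields
(GTP-Cdc42 `Cdc42T`, membrane GDP-Cdc42 `Cdc42Dm`, the Cdc42-bound complex
`BemGEF42`, free membrane complex `BemGEFm`) diffuse with a common
coefficient Dm and react by mass action; two cytoplasmic pools (`Cdc42Dc`,
`BemGEFc`) exchange with the membrane. Positive feedback arises because
membrane GTP-Cdc42 recruits cytoplasmic Bem1-GEF (rate k7), which activates
neighbouring Cdc42; GAP activity (k2b) and GDI-mediated extraction
(k5a/k5b) oppose it. The membrane Bem1-GEF equation carries additive
Gaussian white noise of strength s, balanced by an equal-and-opposite term
in the cytoplasmic pool so that noise never creates or destroys material.

Membrane fields are shell concentrations in µM; η = 0.01 is the
membrane-to-cytoplasm volume ratio. The conserved totals are
cytosol-equivalent:

    total Cdc42  = η·⟨Cdc42T + Cdc42Dm + BemGEF42⟩ + Cdc42Dc  (= 1 µM)
    total BemGEF = η·⟨BemGEFm + BemGEF42⟩          + BemGEFc  (= 0.017 µM)

with ⟨·⟩ the spatial mean. This convention is the unique one under which
summing the governing equations (cytosolic equations carrying the η/A
integral prefactor) gives identically zero; it implies peak shell
concentrations of order 10²–10³ µM, which is the regime the dwell-time
analyses probe (70–450 µM).

Two sign slips in the typeset equations are repaired on physical grounds:
membrane Bem1-GEF *loses* k1b·BemGEFm to the cytoplasm (k1b is the
detachment rate), and all four membrane species diffuse with +Dm·Δ. Both
repairs are pinned by the machine-precision conservation checks.

## Homogeneous steady state

The uniform fixed point is found by solving the four membrane reaction
balances together with the two conservation constraints (the cytosolic
balances are linearly dependent on these). The root search starts from an
analytic guess built from the two exchange balances and, if needed, first
relaxes the well-mixed six-variable ODE system to large time before
polishing — this is what makes the solver robust at scaled abundances,
where the naive guess is far off. Residual tolerance: 1e-12 µM/s.

## Numerical integration

Default stepper (`imex`), per time step of dt = 0.01 s:

1. **Reactions** — linearized backward Euler, solved pointwise as a 4×4
   linear system with the cytosolic pools frozen. This removes the
   stability bound imposed by the fast binding/unbinding reactions
   (k4a·Cdc42T approaches 4·10³ 1/s inside a peak, which would force an
   explicit dt below ~5·10⁻⁴ s).
2. **Diffusion** — exact exponential of the discrete 5-point Laplacian,
   applied in Fourier space. Using the discrete operator's eigenvalues
   (not −q²) means both steppers integrate the same semi-discretization.
3. **Noise** — Euler-Maruyama: each grid cell of `BemGEFm` receives
   s·N(0,1)·√dt/h (white-noise scaling in space and time; the strength s
   from the parameter table is treated as the amplitude multiplying
   unit-variance space-time white noise, the discretization being a
   simulator choice).

After the reaction and noise substeps the cytoplasmic pools are updated by
exact bookkeeping: the η-weighted mean membrane gain is removed from the
corresponding pool. Because internal reactions cancel within each total and
the diffusion substep conserves each field's mean exactly (the q = 0 mode
is untouched), both totals are conserved to machine precision regardless of
step size, noise on or off. Observed drift over 600 s: ~10⁻¹⁴ relative.

Negative excursions smaller than 1e-9 µM are clamped to zero (charged to
the cytosol so conservation is untouched); anything larger aborts the run
as a step-size failure. Noise excursions below zero in near-empty
background regions (where `BemGEFm` ~ 10⁻³ µM) are reflected at zero with
only the realized increment charged — expected behaviour, not an error.

Validation: an explicit Euler-Maruyama stepper is retained and agrees with
the split scheme on noise-free runs (≤0.2% field difference over 2 s);
halving dt changes the relaxed peak height by ~10⁻⁵ relative; halving the
grid spacing (N = 48 → 96) changes it by 0.7%. Default grid N = 64
(h ≈ 0.138 µm) resolves the peak (waistline radius ≈ 0.67 µm); the
competition experiments in the tests and the acceptance script run at
N = 48, where the same quantities differ from N = 96 by under 1%.

## Excitability versus linear instability

At table-default abundances the homogeneous state is *linearly stable* for
every admissible torus mode (leading growth rate ≈ −0.65 1/s, dominated by
GDI extraction): polarization is excitable, not Turing-type. A localized
GTP-Cdc42 seed of ≳10–20 µM (over ~0.6 µm) nucleates a stable peak of
~550 µM summed membrane Cdc42 that depletes the cytoplasmic Bem1-GEF pool
~17-fold, while smaller seeds decay. Zero-mean noise cannot polarize the
base system because the active species' uniform level (0.08 µM) caps any
mass-neutral fluctuation far below threshold.

A genuinely unstable band opens once total abundances are scaled up by
≳1.6×. The biologically motivated operating point for the linear analyses
is therefore the 5.86-fold volume correction (258 fL model sphere versus a
44 fL haploid cell), where many modes grow and the linear machinery can be
cross-validated against the simulator: seeded single-Fourier-mode growth
rates match the dispersion-relation eigenvalues to better than 1% (10%
asserted). The unstable-mode count falls monotonically as Dm rises from
0.0025 to 0.03 µm²/s; abundance is compared at the two levels the volume
correction defines (1× versus 5.86×) because the count is not monotone on
a fine abundance grid (the band is widest near 2×).

For wavenumber q > 0 the well-mixed cytosol does not respond (zero-mean
modes), so the dispersion relation uses the 4×4 membrane Jacobian shifted
by −Dm·q²; the q = 0 mode uses the full six-variable Jacobian, whose two
exact zero eigenvalues (the conservation laws) are excluded. The torus
mode lattice counts independent integer pairs (m, n), keeping
symmetry-degenerate modes individually.

The spherical scaffold generalizes the analysis to finite cytoplasmic
diffusion: cytosolic perturbations are modified spherical Bessel profiles
i_l(κr) matched to the membrane equations through the boundary flux, and
eigenvalues are roots of the resulting characteristic determinant, scanned
on a two-sided logarithmic grid (resolving the physically relevant roots
near zero even when reaction rates span four decades) with pole rejection
on the oscillatory branch. The kinetics are pluggable; the shipped instance
is this package's model with shell-thickness scaling ηR/3, which reduces
to the torus analysis in the fast-diffusion limit (verified to 2%).

## Competition analysis

The two-peak experiment seeds identical Gaussian perturbations (default
20–30 µM amplitude, 0.6 µm width — the values are not critical, any
suprathreshold seed relaxes to the same state) at diametrically opposite
torus points, relaxes 300 s without noise to the symmetric stationary
state, then switches noise on until one peak falls below twice the
homogeneous summed-membrane-Cdc42 level (extinction) plus a 50 s settling
window. The relaxed state is exactly mirror-symmetric (≤10⁻¹³ relative),
so the eventual winner is decided by the noise realization alone; observed
coexistence times at default noise are ~600–900 s, with cytoplasmic pools
constant to <0.2% until the final consolidation phase, when the winner
drains the Bem1-GEF pool further.

The *waistline* of a peak is the radius at which the azimuthally averaged
summed membrane Cdc42 profile (computed in half-cell radial bins around
the intensity-weighted centroid) first falls to half the peak value.
Diffusive escape across the waistline is evaluated with the divergence
theorem, −Dm·Σ(Δ₅C)·h² over the enclosed grid cells with the simulator's
own 5-point Laplacian: at a discrete stationary state this makes the
diffusive loss equal the net cytoplasmic recruitment
∫(k5a·Cdc42Dc − k5b·Cdc42Dm)dA over the disc *identically*, mirroring the
continuum balance (observed residual 0.02%; the analytic-Gaussian check of
the same flux agrees with the closed form to 0.3%). "Membrane Cdc42" means
Cdc42T + Cdc42Dm + BemGEF42 throughout (all Cdc42-carrying species;
switchable to Cdc42T only).

Rate-balance curves report, per snapshot and peak, recruitment and
diffusive loss versus waistline content normalized to the final winner's;
the balance points sit at the two-peak content (~0.52 normalized, unstable)
and at 1.0 (stable), with the net flux negative below the unstable point
and positive above it.

## Dwell times

Both clamped-point subsystems are linear 2×2 systems and are integrated
exactly by eigendecomposition on 2000 time points spanning 10× the
closed-form half-time; the half-time is the interpolated first crossing of
half the initial pool. The closed forms are the fast-exchange
(quasi-steady-state) limits; at table rates the simulated half-times track
them pointwise to ≤1% (BemGEF sweep, 0–450 µM Cdc42T) and ≤5% (Cdc42
sweep), and converge to them when the fast rates are scaled 100×.

The initial pool starts in the *unbound* membrane form (BemGEFm,
resp. Cdc42Dm). This is the choice under which the measured half-time obeys
the closed-form law: starting from the bound or pre-equilibrated pool
counts the protected fraction from t = 0 and shifts every half-time upward
by ≈ ln2/k4b (resp. the analogous k5b term), a sensitivity that is tested
explicitly and available through `initial_partition=`.

Line fits of half-time versus partner concentration minimize *relative*
residuals (weights 1/y²): the data span more than two decades while the
intercept equals the smallest value in the sweep, so an unweighted
intercept estimate is ill-conditioned (a uniform −1% deviation at the
large end moves it by ~30%). R² is reported on the raw data.

## Imaging quantification

Spot segmentation applies two thresholds — the lower separates cells from
background, the upper defines spots within the cell mask — and discards
connected components below the filter size. Tracking is greedy
nearest-neighbour within a target radius, processing spots in descending
intensity with ties broken by lowest track id; blink bridging re-links
across gaps of at most `max_gap` frames when enabled. Vicinity traces take
the mean or sum over non-background pixels (a pixel belongs to the circle
when its center is within the radius) around the track centroid, carrying
the last known centroid across gaps; the background reference is the mean
in-cell intensity one frame before first detection, falling back to the
per-frame cell-interior median for tracks present from frame 0.
Coexistence time is (first frame back at exactly one spot − first frame
with more than one) × frame interval, with undefined and censored outcomes
distinguished.

FRAP traces are background-subtracted, normalized to the pre-bleach mean
(≥3 frames) and fit with y0 + A1(1−e^(−k1·t)) + A2(1−e^(−k2·t)),
parameterized as k1 = k2 + δ, δ ≥ 0 so the rate ordering is built into the
fit; the half-time is ln2/k2 from the slower rate (membrane exchange; the
faster component absorbs cytoplasmic recovery inside the bleach zone).
Degenerate single-exponential data collapse the two components without
harming the half-time. FLIP traces are normalized as
(focus − background)/(neighbor − background), which cancels affine
intensity rescaling and indirect bleaching.

## Synthetic data

Movies render isotropic Gaussian spots (no z-dimension; summed projections
are assumed) on a constant background with additive Gaussian noise
(optional Poisson), with per-spot birth/death/blink schedules, per-frame
centroid and amplitude paths, and channel delay/scale for two-colour
experiments; the truth table carries exact counts, centroids and
integrated intensities. The competition preset keeps the loser's amplitude
well above threshold until its scripted death so that detection and script
agree frame-for-frame; its SNR convention is (weakest visible spot
amplitude)/(noise sd), with thresholds set midway between the noise
ceiling and the weakest spot (cell threshold 20, spot threshold
background + 40, filter 4 px² at SNR 5). What the recovery tests show is
that the pipeline is exact under its stated assumptions — stationary
background, isolated diffraction-limited spots, uniform frame interval —
not that it is robust to crowded fields, drift or photobleaching, which
real movies exhibit and the generator deliberately omits.

FRAP/FLIP generators produce the corresponding plateau/bleach/recovery and
repeated-bleach-decay traces with scripted kinetics plus fractional
Gaussian noise; recovery accuracy is ~1% bias at 1% noise across slow
rates 0.05–1 1/s.

## Problem sizes

Unit and property tests run at N = 32–48 grids and seconds-to-minutes
simulated time; the competition suite uses ten seeds at N = 48 sharing one
noise-free relaxation (the relaxation is seed-independent); the acceptance
script uses five seeds, a 300 s conservation run, three seeded-mode growth
experiments at N = 64, ten movies and one hundred FRAP fits. These sizes
were chosen so the full analysis reproduces every qualitative result at
desk scale; all convergence-sensitive quantities are backed by the
refinement checks above.

## Known limitations

* The cytoplasm is well mixed; finite cytoplasmic gradients appear only in
  the spherical linear analysis, not in simulation.
* Geometry is a flat torus; curvature effects and cell-shape changes are
  out of scope.
* The negative-feedback (GEF phosphorylation) extension and explicit
  GAP/GDI species are not modelled.
* Noise-dependent quantities (coexistence-time distributions) are
  validated qualitatively, since the spatiotemporal discretization of the
  noise term is a simulator convention.
* The imaging pipeline quantifies summed projections with threshold-based
  segmentation; no PSF fitting or deconvolution.
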