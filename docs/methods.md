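# Methods

This note documents the models behind each module, the parameters that
matter, what the synthetic-data generators do and do not emulate, the
numerical choices, and known limitations.

## Transient-confinement detection

### Model

A membrane-bound molecule diffusing over a filament network alternates
between free 2D diffusion and transient trapping on filament-bound binding
sites. The packing coefficient of a trajectory window of `n` displacements
starting at time point `i` is

    p_i = Σ_{j=i}^{i+n−1} [(x_{j+1}−x_j)² + (y_{j+1}−y_j)²] / S_i²

where `S_i` is the convex-hull area of the `n+1` positions `i … i+n`. The
numerator is the summed squared Euclidean step length; with coordinates in
µm, `p` is in µm⁻². `p` compares path length to explored area and is
therefore sensitive to confinement independently of the molecule's global
diffusivity — unlike an MSD classification, which averages transient events
away. Degenerate windows (collinear positions, hull area < 1e−12 µm²) map
to `p = +∞`; windows spanning frame gaps yield no value.

Confinement events are runs of windows with `p ≥ p_thresh` containing at
least `ceil(t_thresh/Δt)` above-threshold windows. Defaults:
`p_thresh = 1000 µm⁻²` (for micrometre coordinates this sits at the ~50 nm
confinement scale) and `t_thresh = 0.25 s` (5 frames at 51 ms, 8 frames at
32 ms). Both thresholds exist to suppress the apparent confinement that
pure Brownian motion produces by chance; on plain Brownian tracks
(D = 0.2 µm²/s, 51 ms frames, ~5 s tracks) the false-event rate per track
is below 5%. The window size defaults to `ceil(t_thresh/Δt)` so that it
adapts to the acquisition rate.

### Event-boundary handling (two deliberate refinements)

1. **Sub-resolution gaps are bridged.** Localization noise makes `p` dip
   below threshold occasionally inside a genuinely confined stretch (at
   20 nm precision roughly 2% of confined windows), which would fragment
   long events. A sub-threshold gap shorter than the minimum run is — by
   the detector's own resolution argument — indistinguishable from
   continued confinement, so such gaps do not split an event
   (`max_gap_frames`, default `min_run − 1`; set 0 for strict runs).
2. **Spatial boundary trimming.** Threshold runs systematically overhang
   the truly confined interval by one to two frames per side, because a
   window containing a single large free boundary step keeps a high `p`
   (the step enters the numerator quadratically but grows the hull only
   linearly). Since an event localizes the molecule in space, the span is
   trimmed to the first and last position within `spatial_cut` (default 2)
   times the median distance from the event's median position; flanking
   free positions sit a full free step away and are cleanly excluded.
   Without this trim, detected durations are biased long by ≈ 2.5 frames;
   with it the residual bias is a fraction of a frame.

Mean confinement times are estimated by fitting `A·e^(−t/τ)` to the
histogram of event durations (Poisson-weighted least squares; default bin
width ≈ span/√n rounded to the frame quantum). The confined fraction is
the percentage of analysed tracks with at least one event. Tracks shorter
than 1 s and, optionally, non-moving tracks are filtered out first.

### Simulation validation

The two-state generator places `n_molecules = 50` per field of view
(10×10 µm, reflecting boundaries). Free molecules (D = 0.2 µm²/s) bind at
rate `k_bind` only while inside a trap zone; trapped molecules diffuse with
`d_trapped` reflected inside a 25 nm disk around their binding position and
unbind at rate `k_unbind`. Transitions are evaluated once per frame (one
transition per molecule per frame; sub-frame switching is ignored, matching
the frame-based detection resolution). Observed positions add Gaussian
localization noise of 20 nm sd per axis, a typical TIRF single-molecule
precision. Trap zones default to a random network of 30 filament segments
with 25 nm capture radius (~10–15% area coverage): point-like 25 nm disks
would give vanishing encounter rates at these binding rates, while a
filament network mirrors the physical situation of binding sites lined up
along cytoskeletal polymers. The trapped-motion disk is anchored at the
binding position regardless of zone geometry, which realises sub-50 nm
confinement areas. The `crossing_probability` parameter (default 1) lets
zones act as partial barriers to free molecules.

The benchmark (`slbkit.benchmarks.confinement_validation`, also run by
`scripts/acceptance.py` and `analysis/02_confinement_benchmark.py`)
simulates the 3×3 grid of binding rates {0.1, 0.3, 0.5} s⁻¹ × unbinding
rates {0.5, 1.5, 3} s⁻¹ at 800 frames of 51 ms per cell, detects with the
default thresholds, matches detected to true events by temporal overlap
(greedy, one-to-one, per track), excludes truth events censored by the
movie boundaries, pools matched durations across the grid and reports
|mean detected − mean true| duration. Problem sizes (800 frames, one field
of view per cell, ~400 matched events per regime) were chosen so the whole
benchmark runs in well under a minute while keeping the duration-error
estimate stable to a few milliseconds across seeds.

What this validation does *not* show: performance on real data with
heterogeneous localization precision, blinking fluorophores, tracking
errors (the tracks here are perfect identities), moving filaments, or
multiple molecules merging into one spot.

## Photobleach-corrected residence times

Per observed frame, a molecule disappears with probability
`1 − exp(−(k_off·τ_tl + k_b·τ_int))`: unbinding acts throughout the lapse
interval τ_tl, bleaching (rate k_b) only during the exposure τ_int. The
number of observed frames is geometric. `apparent_off_rate` uses the
geometric MLE (`q̂ = 1/mean frames`, `k_eff = −ln(1−q̂)/τ_tl`), which makes
`k_eff·τ_tl` estimate the per-frame exponent without the upward bias the
continuous-exponential estimator acquires at long intervals; the shifted
continuous fallback `k_eff = 1/(mean − τ_tl)` is available as
`method="shifted_mean"`. `bleach_corrected_lifetime` regresses
`k_eff·τ_tl` on τ_tl over ≥ 3 distinct intervals: slope = `k_off`
(lifetime = 1/slope), intercept = bleaching number `k_b·τ_int`. A negative
slope is flagged: bleaching dominates and the lifetime is unresolvable at
those intervals. The standard interval set follows the 0.1–2 s
acquisition-rate range ({0.125, 0.25, 0.5, 1, 2} s at 50 ms exposure).

Per-track diffusion: time-averaged MSD over integer frame lags, linear fit
`MSD = 4Dτ + offset` using at least 3 and at most 5 lags (long-lag
time-averaged MSD values are strongly correlated; capping the fit at short
lags several-fold reduces the per-track estimator variance). The intercept
absorbs static localization error (≈ 4σ²); D is floored at 0. Tracks
shorter than 0.4 s are skipped with a recorded reason.

## FRAP decomposition and FRET

### Recovery model

Fluorescence (as a fraction `f` of the pre-bleach steady state) in a
bleached stripe on an SLB obeys

    ∂f/∂t = D ∂²f/∂x² + k_off (1 − f)

with zero-flux boundaries at the ends of the extracted profile (the field
of view, not the bleach window). The exchange term assumes a large
unbleached solution reservoir: rebinding molecules are fluorescent, so
exchange relaxes `f` toward 1 uniformly, while diffusion reshapes the
profile. Pure exchange leaves the profile shape unchanged
(`f = 1 − depth(x)·e^(−k_off·t)`); diffusion changes the slope of the
stripe borders. This shape difference is what makes (D, k_off) jointly
identifiable from profile data.

Profiles are extracted from movies by mean-projecting the bleach ROI's
extent across the non-selected axis, normalizing to the mean pre-bleach
profile, with optional reference-ROI bleach correction and optional
mirroring about the bleach-window center for asymmetric bleaches. Frame
times are mid-exposure.

### Numerics

Two independent integrators implement the model. The synthetic-profile
generator uses Crank–Nicolson implicit finite differences with a
conservative (flux-form) Neumann Laplacian, so the k_off = 0 spatial mean
is conserved to machine precision. The fitter uses the exact eigenfunction
solution: with `f = 1 − g`, `g` evolves by damping each zero-flux cosine
mode (DCT) of the initial deficit with `exp(−(D(πm/L)² + k_off)t)` — exact
on the sample grid, no time discretization and no grid-refinement loop,
and orders of magnitude faster inside the least-squares iteration. The two
routes agree to < 5e−3 on step-bleach profiles (tested), so round-trip
tests of the fitter are not self-confirming. The fit takes the first
post-bleach profile as the initial condition and least-squares all later
(x, t) samples over (D, k_off) ≥ 0.

Uncertainty on D includes a resolution floor `D_res = dx²/(8T)` (added in
quadrature to the Gauss–Newton stderr): a diffusion length below half a
sample spacing over the whole observation window is unresolvable, and
fitting the measured (noisy) initial profile biases D upward by about this
much — a small D "denoises" the initial condition. On pure-exchange data
the fitted D is therefore reported with an interval that includes 0 and a
flag, rather than a spuriously significant 1e−5 µm²/s. No immobile
fraction is modelled; add one only if residuals demand it.

### FRET estimators

Acceptor photobleaching: `E[%] = 100·(I_post − I_pre)/I_post` on the
background-subtracted donor trace, equivalently `gain/(gain + I_pre)` with
`gain = I_post − I_pre`. The function refuses traces whose acceptor does
not drop by ≥ 50% at the bleach frame, and clips E to [0, 100]. A literal
variant `100·I_post/(I_post + I_pre)` (baseline 50% for no donor change)
is available behind `literal=True` for reproduction studies only.
Spectral (cuvette) FRET: `E[%] = 100·F_a/(F_d + F_a)` with peak donor
emission read at 565 nm and acceptor at 670 nm (nearest sample),
background-corrected upstream. No crosstalk or spectral-bleedthrough
correction is applied.

## Colocalization statistics

PCC is the plain Pearson correlation over ROI pixels (default ROI: centered
rectangle covering 80% of each dimension; no intensity thresholding).
Differential movies subtract frames at lag 1 (configurable) and clip
negative differences to zero so only growth fronts remain; PCC_diff is the
per-frame PCC between the two differential movies, with zero-variance
frames skipped and counted. Bleach correction divides each frame by its
spatial mean. The temporal autocorrelation is anchored at frame 0 as the
reference (an all-pairs averaged variant is available behind
`averaged=True` for noisy data); its monoexponential fit reports
`half_time = ln2/b`. The intensity-slope regression subtracts each
channel's 1st percentile by default (camera offset removal without
clipping structure). Channel alignment is assumed done upstream; a
translation-only FFT cross-correlation aligner is provided as a
convenience, not a feature-based registration.

The filament-movie generator renders treadmilling as whole-filament
translation at constant length (front grows, rear shrinks at the same
speed), Gaussian-PSF blurring, a channel-2 mixture
`coupling·density + (1−coupling)·uniform`, and Poisson+Gaussian noise. It
emulates the coupling/decoupling contrast and pattern turnover, not
filament nucleation, bundling, crossing dynamics or photobleaching decay.

## Binding curves and packing geometry

Hill fits run through lmfit with bounds `n ∈ [0.2, 10]`, `k > 0`,
initialized at S = first response, E = last, k = median concentration,
n = 1. Responses are used with their sign (QCM-D frequency shifts are
negative on binding, so E < S). Results are flagged when the Hill
coefficient lands on a bound or the fitted k/EC50 lies outside the sampled
concentration range. With n = 1 the QCM-D form reduces to a Langmuir
isotherm and the fitted k equals the analytic K_d (tested to 1e−8).

Geometry: area per molecule on a hexagonal lattice,
`(2/√3)/(6.022·x·0.001)` nm² at density x pmol/cm²; a molecule of
footprint A covers `A/0.5` lipids (0.5 nm² per lipid), and the saturating
anchor-lipid percentage is `100/(A/0.5)`. For a 30 nm² footprint this
gives 60 lipids and 1.6̅% (1.67 at two decimals); the exact ratio is kept
internally. Note that for a ~7 nm² footprint the formula gives ≈ 7.1%,
not 5% — the formula's result is reported.

## Reproducibility plumbing

All generators take integer seeds and are byte-reproducible. Pipeline runs
(`slbkit run config.yaml`) echo the full configuration and its SHA-256 into
a manifest; unknown configuration keys or stage names are rejected before
any stage executes. Track files round-trip through CSV
(`track_id, frame, t_s, x_um, y_um`) and TrackMate-dialect XML; images
through ImageJ-compatible TIFF with a JSON sidecar carrying pixel size and
frame interval (explicit arguments override file metadata, with a logged
warning on conflict). ImageJ `.roi` files are supported for rectangles
only. Frames are 0-based, coordinates physical µm with origin top-left,
ROIs half-open.

## Known limitations

- The trapped-state model is reflected diffusion in a disk, not a harmonic
  well; detector performance on harmonically confined molecules may differ
  slightly.
- No blinking/photophysics beyond single-step disappearance in the dwell
  generator; gap bridging in dwell extraction is configurable but defaults
  to none.
- The FRAP model is 1D; strongly non-stripe bleach geometries need the
  mirroring/projection options and are not fully modelled.
- Dwell-time datasets mixing two populations are not resolved (single
  exponential only), and diffusion analysis is not state-resolved.
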