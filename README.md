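# slbkit

Quantitative analysis of membrane-bound cytoskeletal dynamics on supported
lipid bilayers (SLBs), imaged by TIRF microscopy. The package targets in
vitro reconstitution experiments in which treadmilling filaments (e.g.
bacterial FtsZ) pattern membrane-bound partner proteins (e.g. the membrane
anchor FtsA and the peptide FtsN): it quantifies how strongly and how
dynamically two fluorescence channels colocalize, when and where single
diffusing molecules are transiently confined, how long molecules stay on the
membrane once photobleaching is corrected for, how membrane turnover splits
into lateral diffusion and exchange with solution, and how tightly proteins
can pack on the membrane.

It is written for experimentalists doing single-particle tracking, FRAP/FRET
and binding assays on SLBs, and comes with seeded synthetic-data generators
that emulate each experiment with known ground truth, so every estimator in
the package is validated end to end.

## What it computes

**Colocalization and co-treadmilling** (`slbkit.coloc`). The Pearson
correlation coefficient (PCC) between two channels measures static overlap.
Subtracting consecutive frames (keeping only intensity gains) isolates the
growing ends of treadmilling filament bundles; the PCC between the two
differential movies (PCC_diff) measures co-movement of those growing ends.
Pattern-reorganization dynamics are quantified by the temporal
autocorrelation PCC(frame 0, frame k) and its monoexponential decay
`y = a·e^(−bt) + k`; recruitment kinetics by `y = a·(1 − e^(−bt)) + c`
fitted to PCC vs time; relative binding capacity by the pixel-wise
intensity slope `y = kx + d`.

**Transient confinement** (`slbkit.confinement`). For each sliding window of
`n` displacements the packing coefficient is

    p_i = Σ_{j=i}^{i+n−1} [(x_{j+1}−x_j)² + (y_{j+1}−y_j)²] / S_i²

with `S_i` the convex-hull area of the window's `n+1` positions (µm, so `p`
is in µm⁻²). A trapped molecule keeps stepping but stops exploring area, so
`p` rises sharply during confinement regardless of the molecule's global
diffusivity. Events are runs of `p ≥ p_thresh` (default 1000 µm⁻², the
~50 nm confinement scale) lasting at least `t_thresh` (default 0.25 s, i.e.
5 frames at 51 ms or 8 frames at 32 ms), with sub-resolution gaps bridged
and event boundaries refined spatially. The detector is validated against
simulated two-state tracks with known trapped intervals.

**Residence times** (`slbkit.kinetics`). Apparent single-molecule dwell
times conflate unbinding and photobleaching. Imaging at several time-lapse
intervals τ_tl with fixed exposure τ_int separates them through
`k_eff·τ_tl = k_off·τ_tl + k_b·τ_int`: regressing the per-frame
disappearance exponent against τ_tl gives the true off-rate `k_off` as the
slope (corrected lifetime = 1/slope) and the bleaching number `k_b·τ_int`
as the intercept. Per-track diffusion comes from a short-lag linear MSD fit
`MSD = 4Dτ + offset`.

**FRAP and FRET** (`slbkit.frapfret`). Recovery into a bleached stripe on an
SLB mixes exchange with the unbleached solution reservoir (lifts the profile
uniformly) and lateral diffusion (rounds the stripe edges). Fitting the full
space–time profile to `∂f/∂t = D·∂²f/∂x² + k_off·(1 − f)` with reflecting
boundaries separates `D` from `k_off`. Acceptor-photobleaching FRET is
`E = (I_post − I_pre)/I_post` on the background-subtracted donor trace;
spectral FRET is `E = F_a/(F_d + F_a)` from donor/acceptor emission peaks.

**Binding and geometry** (`slbkit.binding_geom`). Hill fits for QCM-D
isotherms `y = S + (E−S)·xⁿ/(kⁿ+xⁿ)` and MST titrations
`y = U + (B−U)/(1+(EC50/C)ⁿ)`; hexagonal lattice spacing from surface
density; lipids-per-molecule and the saturating anchor-lipid percentage
from a molecular footprint.

**Synthetic data** (`slbkit.simgen`). Seeded generators for two-state
tracks (free/trapped diffusion with binding zones), multi-interval dwell
observations with bleaching, dual-colour treadmilling movies with tunable
channel coupling, FRAP profiles, FRET traces and binding curves — all with
recorded ground truth.

## Worked example

Detect confinement in a synthetic single-molecule experiment:

```
$ slbkit simulate --kind tracks --seed 1 --out-dir sim
50 tracks, 64 ground-truth events -> sim

$ slbkit confine sim/tracks.csv --p-thresh 1000 --t-thresh 0.25
38 events in 50 tracks; confined fraction 50.0%
mean confinement time = 0.678 +/- 0.164 s
```

50 molecules were simulated for 30.6 s switching between free diffusion
(0.2 µm²/s) and confinement on a filament network (binding 0.3 s⁻¹,
unbinding 1.5 s⁻¹), so true confinements last 1/1.5 ≈ 0.67 s on average.
The detector calls 38 events above its 0.25 s duration floor and the
monoexponential fit to their duration histogram estimates a mean
confinement time of 0.68 s, matching the simulated truth.

The same pipeline runs declaratively from a config:

```
$ slbkit run examples/demo_config.yaml
```

which simulates tracks, detects confinement, estimates a photobleach-
corrected lifetime (`k_off = 0.0524 ± 0.0015 s⁻¹`, i.e. 19.1 s for a true
20 s lifetime under a bleaching number of 0.2) and writes a manifest that
reproduces the run bit-for-bit.

The numbered scripts under `analysis/` run the full validation studies and
write their tables under `results/`:

```
$ python analysis/02_confinement_benchmark.py
trapped D = 0.002 um^2/s: duration error 0.021 s over 397 matched events (recall 0.62, precision 0.94)
trapped D = 0.008 um^2/s: duration error 0.029 s over 383 matched events (recall 0.62, precision 0.94)

$ python analysis/04_frap_decomposition.py
slow_exchange_mobile: D 0.14 -> 0.139 um^2/s, k_off 0.04 -> 0.0403 /s
fast_exchange: D 0.01 -> 0.0106 um^2/s, k_off 0.37 -> 0.371 /s
pure_exchange: D 0.0 -> 1.64e-05 um^2/s, k_off 0.1 -> 0.101 /s  [D indistinguishable from 0 (pure exchange regime)]
pure_diffusion: D 0.2 -> 0.199 um^2/s, k_off 0.0 -> 0.000263 /s
```

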