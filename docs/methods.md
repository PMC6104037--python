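# Methods

## Contact mechanics and surface detection

The analysis assumes Hertzian spherical contact of a rigid tip on an
incompressible (ν = 0.5), flat half-space: F = (4/3)·E/(1−ν²)·√R·h^{3/2},
contact radius a = √(hR), contact area A = πhR, and indentation strain
ε = 0.2·a/R. These relations are valid for small strain (ε < 0.08, i.e.
h/R < 0.16); the strain bin used for comparative analysis (7.3 ± 0.5%) is
chosen to sit inside that region. Adhesion is neglected: at working depths
of 8–11 μm with 60–105 μm tips the nominal contact area dominates, and the
resulting contact radii (≈22–34 μm) set the lateral length scale actually
probed.

The depth channel is piezo-referenced, so the surface position is unknown
by one additive offset. `detect_surface` fits
F = c·max(h_raw − offset, 0)^{3/2} to all samples up to the first crossing
of the threshold load (default: the 15 nN trigger). The prefactor c is
linear given the offset and is profiled out in closed form, reducing the
problem to a 1-D search over the offset: a 256-point bracketing grid over
the sampled depth range followed by bounded scalar minimization
(xatol = 1e-13 m). This is deterministic, has no starting-value
sensitivity, and is exact on noise-free data. Pre-contact samples
contribute zero model force rather than being discarded, which anchors the
offset near contact. The fit also yields an apparent quasi-static modulus
E = 3c(1−ν²)/(4√R) and an R²; a failed search is returned as a flagged
(non-converged) fit, never an exception, so grid maps render failures as
gaps.

Records that started in contact carry no zero-load baseline: the mean load
over the first half of the pre-trigger segment is compared against
k·σ (default k = 5), with σ estimated from the linearly detrended baseline
residual. Records with fewer than 10 pre-trigger baseline samples are
conservatively flagged. Flagged records still produce moduli points, all
marked `qc_pass = False`.

## Oscillation analysis

Windows: on the oscillatory ramp, consecutive non-overlapping 5-cycle
windows (the contact area changes along the ramp, so the window-mean depth
is used per block); in the frequency sweep, one window per frequency after
the loading and relaxation segments, discarding the first cycle of each
block as settling. Window placement is derived from the protocol timing
anchored at the detected trigger crossing; the final sweep window is
trimmed to the record end and kept if no more than one cycle is missing,
which makes segmentation robust to one-sample trigger-detection jitter.

Each window is fit per channel with y = A·cos(2πft + φ) + b (+ m·t on ramp
windows, where the advancing ramp would otherwise bias the amplitude). The
fit is linear in (A cos φ, A sin φ, b, m) and solved by lstsq — no
iteration, no tuning. The phase lag is δ = φ_load − φ_depth wrapped to
(−π, π]; δ < −0.1 rad is flagged unphysical. Moduli follow from
E′ = (1−ν²)(F₀/h₀)cos δ/(2a), E″ likewise with sin δ, with a evaluated at
the window-mean corrected depth; E″/E′ = tan δ holds identically. QC
rejects a window if either channel's R² ≤ 0.7 (the conservative reading of
an "all cosine fits" rule), and every point records its rejection reason;
passed + rejected = total windows by construction.

In the elastic limit the dynamic estimate is consistent with the
quasi-static Hertz fit because the contact stiffness is dF/dh = 2aE/(1−ν²):
the same factor 2a appears in the oscillatory conversion, so a noise-free
elastic round trip returns E′ = E exactly and E″ = 0.

## Forward simulator

The simulator emulates the instrument per record: free approach at 30 μm/s,
Hertzian loading to the 15 nN trigger (the trigger depth is solved by root
finding on the quasi-static load), a 50 ms settling dive to an uncontrolled
initial depth drawn uniformly from 1–3 μm, then the protocol trajectory.
The depth channel is treated as perfectly feedback-controlled — the
technique's premise is depth control, and modelling the control loop would
entangle contact-mechanics testing with servo dynamics. Measurement noise
is additive white Gaussian on the load channel (default σ = 0.5 nN,
reflecting interferometric readout noise) plus optional linear drift.

Load synthesis mirrors the analysis stage's quasi-static approximation on
purpose. Within each ramp 5-cycle block the quasi-static part is
linearized about the block-mean depth with the exact Hertz tangent
stiffness k_c = 2aE′/(1−ν²), and the oscillatory response is
(2a·h₀/(1−ν²))·(E′ cos ωt − E″ sin ωt). Because depth and load then share
the same quadratic-in-time ramp contamination scaled by k_c, the
amplitude-ratio estimate cancels it and noise-free round trips recover the
phantom moduli to ~1e-6 relative. The sweep's loading segment runs at
10 μm/s to the 10 μm operating depth and holds for the nominal loading
duration, so analyzer and generator agree on segment boundaries without
the analyzer knowing the (random) initial depth.

Phantom rheologies: elastic (E′ = E₀, E″ = 0), Kelvin–Voigt (E″ = ωη), and
a soft-glassy power law (|E*| = E₀(ω/ω_ref)^β, loss tangent tan(πβ/2)).
Strain stiffening is multiplicative on the elastic part,
E_eff = E₀(1 + c·ε) — the simplest form producing the monotone stiffening
with depth seen in tissue. Spatial heterogeneity is an ordered list of
labelled polygons (first listed wins on overlap) over a background model.

Simulation defaults are the experimental conditions: h₀ = 0.2 μm;
5.62 Hz and 0.01 /s for the ramp; 10 μm at 10 μm/s, 30 s relaxation and
{1, 1.78, 3.2, 5.62, 10} Hz for the sweep; grids with ≥50 μm spacing so
deformed areas do not overlap. Unstated acquisition parameters were fixed
once at field-typical values: sample rate 50× the highest oscillation
frequency (well above the 10× aliasing floor, which is enforced), 10
cycles per sweep frequency (one discarded), ramp termination at 10%
strain, and a 20 μm default free-approach distance. The ramp strain rate
is interpreted as per-second.

What the generator does **not** emulate: control-loop residual error,
thermal/interferometer drift beyond a linear load term, poroelastic or
conditioning effects, surface tilt or roughness, and adhesion hysteresis
on retraction. Passing recovery tests therefore demonstrates correctness
of the analysis chain under the stated contact model, not robustness to
every artifact of live-tissue recordings. The synthetic nuclei mask
generator drops random disks until a target areal coverage is reached; it
supports testing of the relative-area computation and density grouping,
not nucleus morphology.

## Aggregation, mapping, statistics

Points are assigned to regions by point-in-polygon with a first-listed
tie-break on shared boundaries (deterministic, half-open edges);
coordinates follow the image convention (origin top-left, y down).
Comparative analysis uses QC-passing points in the 7.3 ± 0.5% strain bin
at 5.62 Hz. Per-(slice, region, method) cells get the arithmetic mean and
SE (SE = 0 and a flag for single-point cells); cross-slice summaries use
point-count weights wᵢ = nᵢ, making the weighted mean equal to the pooled
mean over all points — inverse-variance weighting is available behind a
switch. Region maps are rasters of the regional weighted means; NaN
(unmeasured or failed) renders gray.

Relative nuclear area A_rel = A_nuclei/A_total is computed from a supplied
binary mask within each region polygon; the low/high density split is at
0.5, chosen inside the wide empty interval between typical sparse (<~0.3)
and dense (>~0.7) layers, so any threshold in that interval is equivalent.

Reproducibility statistics treat (slice, method) combinations within a
region as groups: Shapiro–Wilk per group (requires n ≥ 3); if all pass at
α, one-way ANOVA with pairwise pooled-variance t-tests at the Bonferroni
level α/k; otherwise Kruskal–Wallis with Dunn's rank z-tests (tie
corrected) at the Šidák level α₁ = 1−(1−α)^{1/k}. Significance is strict
(p < threshold). Dunn's test is implemented in-package (no installed
dependency provides it); the other tests delegate to scipy. The reported
fraction of significant pairs is controlled at ≤ α under the null, which
the test suite verifies by simulation (500 replicates).

## Problem sizes and determinism

The bundled demo and the acceptance computations use small grids (tens of
records), 50-seed noise studies and 500-replicate null simulations — sizes
at which every estimate above is stable to well within its assertion
tolerance while keeping a full run in seconds. All randomness flows from
explicit seeds through `numpy.random.SeedSequence` spawning (per-point
seeds derived from the master seed), so identical configuration + seed
yields byte-identical value tables; the run manifest records a sha256 per
artifact to make this checkable.

## Known limitations

- The Hertz surface fit assumes the approach segment is long enough to
  estimate a baseline; very shallow surfaces (< ~1 μm free approach) are
  rejected rather than fit.
- Strain attribution uses the window-mean depth; within a 5-cycle ramp
  window the strain spans a small range that is not propagated as an
  uncertainty.
- The power-law phantom's quasi-static load uses the storage modulus at
  the drive frequency, so its ramp round trip is approximate (the elastic
  and Kelvin–Voigt round trips are exact).
- Maps average per region; intra-region gradients are visible only in the
  per-point scatter maps, not the reconstructed rasters.
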