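# Methods

This note documents the models and estimators implemented in `spherotox`,
the defaults and why they were chosen, and what the synthetic-scene
validation does and does not establish about real microscopy data.

## 1. The synthetic co-culture model

### Geometry and agents

A scene is a 3D gel slab (default 600 × 600 × 400 μm) containing spherical
tumor spheroids (default one spheroid, radius 120 μm, 200 cells placed
uniformly in the sphere) and point-like effector agents. Effectors are
seeded either uniformly in the gel volume (`gel`) or on the upper slab face
(`top`); the agent count is `effector_density` (cells/mL) × slab volume.
The helper `effector_density_for_unit_ratio` computes the density that
places one effector per target cell in a 300 μm shell around a spheroid —
the standard way an effector:target ratio of 1:1 is expressed in 3D
(≈ 4.1 × 10⁶ cells/mL for a 200 μm spheroid of 2000 cells).

### Motility

Free agents perform a persistent random walk: the heading unit vector
relaxes with timescale `persistence_time` (heading perturbed by
√(2Δt/τ_p) Gaussian increments, renormalized), and within `sensing_range`
of a spheroid surface it is blended toward the nearest spheroid center with
weight `bias_strength`. There is deliberately **no density feedback and no
agent–agent interaction**: recruitment is therefore linear in seeding
density and per-agent arrival statistics are density-invariant *by
construction*, which is exactly the property the density-response analysis
must recover. The chemotactic cue is this deterministic bias rather than an
explicit diffusing chemokine field, because the data being emulated show
directional migration without measuring any gradient.

Defaults — speed 30 μm/h, persistence 0.5 h, bias 0.5, sensing range
100 μm — were calibrated once so that gel-embedded effectors reach the
spheroid with median first-arrival ≈ 6 h while top-seeded effectors take
≈ 25 h, the contrast regime characteristic of these co-cultures. Slab
boundaries reflect.

### Attachment, infiltration, killing

An agent within `attachment_radius` (8 μm, about one cell radius) of a
surface becomes *attached* (snapped to the surface point; states only ever
progress free → attached → infiltrated). Attached agents infiltrate at rate
`infiltration_rate`; an infiltrating agent crawls inward at 0.3 × speed to a
stop radius drawn uniformly from 0.4–0.95 of the spheroid radius —
penetration of a few cell layers with most effectors remaining on outer
shells. Attached or infiltrated agents kill the nearest surviving tumor
cell of their spheroid at rate `kill_rate`; `uniform_kill_rate` kills cells
independently of agents (a drug-treatment control mode). Each cell dies at
most once; effectors neither die nor divide.

Time stepping: frames at `frame_interval` (default 1 h) are subdivided so
that one substep moves an agent at most ~`attachment_radius` and resolves
the heading relaxation; all stochasticity flows from a single
`numpy.random.Generator` seeded from `rng_seed`, so identical configs are
bit-identical.

### Rendering

Three channels on a pixel grid (default 4 μm/px):

- **BF** — bright background (0.85) with a dark, speckle-textured disk per
  spheroid (0.40 ± 0.12 texture): label-free contrast carried by local
  variance, as in real brightfield.
- **EFF** — one Gaussian point spread per agent (σ = 5 μm), amplitude
  decaying as e^(−t/`bleach_decay`) (default 72 h — transient membrane dyes
  fade over ~3 days).
- **NUC** — intact nuclei as Gaussian blobs (σ = 5 μm) for living cells;
  each dead cell is replaced by 3–6 apoptotic-body dots (1/4 the nucleus
  diameter, scattered within ~2 nucleus diameters) whose amplitude decays as
  e^(−Δt/`fragment_decay`) (default 24 h — the empirical stability of the
  fragment signal).

Fluorescence is *additive* along z (widefield-like integration), so summed
effector intensity is exactly conserved up to bleaching, boundary loss and
noise — the photometric conservation law the render tests assert. An
optional `z_section` restricts rendering to a z-slab, emulating a confocal
optical section; this is the mode used for infiltration profiles, because in
a full projection the spherical surface projects signal over the whole disk
(poles project to the center) and rim structure is geometrically
unresolvable. Amplitudes are fixed constants in [0, 1] full-scale units
(integrated intensity per emitter: effector 0.5, nucleus 1.2, fragment 0.5)
with **no per-stack normalization** — cross-scene comparability and
linearity in emitter count depend on this. Additive Gaussian noise
(`noise_sd`, default 0.02) is applied last and clipped to [0, 1]; clipping
gives dark regions a small positive pedestal (≈ 0.4 × noise_sd), which is
why estimators below avoid assuming a zero background.

Ground truth frozen at simulation time: per-frame agent positions/states,
death events, spheroid disk masks, and the analytic fragmented-signal area
(fragment footprint × decay, summed over deaths) per frame and spheroid.

## 2. Estimators

### Segmentation

Default backend: local standard deviation (uniform window 12 μm), smoothed
once more, Otsu-thresholded, morphologically closed (8 μm), hole-filled,
minimum-area filtered (default: area of a 50 μm disk; smaller objects are
debris). Otsu on raw local *variance* fails on heavy-tailed variance maps —
thresholding the smoothed SD map is the robust variant. A guard rejects
frames whose foreground/background SD contrast is < 2× (returns an empty
label map rather than hallucinating objects on uniform frames). An
already-binary frame is treated as a mask rendering and labeled directly,
making segmentation idempotent on its own output. The trainable backend
(random forest over Gaussian intensity, gradient magnitude and local
variance at 3 scales, fit from scribbles) honors the pixel-classification
workflow used with interactive tools; both backends share the morphological
cleanup and output contract.

Tracking is greedy nearest-centroid linking (default gate 50 μm) with **no
gap closing**: spheroids are essentially immobile in gel, so a disappearing
object is a segmentation failure worth surfacing, not a gap to paper over.
Size metric: equivalent diameter of the equal-area circle.

### Recruitment

Per frame, background = median intensity outside all masks dilated by a
20 μm guard band (median resists stray effectors); recruitment value = mean
in-mask intensity − background. Missing masks yield NaN, never 0. The
measurement is invariant to additive offsets and equivariant under
multiplicative rescaling.

The sigmoid y = a + b·expit(k(t−τ)) is fitted by bounded trust-region least
squares (b ≥ 0, k ∈ [0, 50] h⁻¹, τ within one observation span of the
window), multi-started over τ seeds at observed times (all of them up to 16
points, 12 evenly subsampled beyond) × k ∈ {0.05, 0.2, 1} h⁻¹; lowest RSS
wins, ties to smaller k then smaller τ. A fit is flagged non-identifiable
when b < 3 × residual SD or τ falls outside the observed window; flat
curves return a degenerate fit rather than raising. k is constrained ≥ 0:
declining curves are non-identifiable, not "de-recruitment".

Design note on accuracy: with noise at 10% of the amplitude, the Cramér–Rao
bound for τ and k depends strongly on the design. For a transition early in
an hourly-sampled window (τ ≈ 6 h, k ≈ 0.29 h⁻¹) the bound alone exceeds
30% for τ — no estimator can do better. The noisy-recovery benchmark
therefore uses a 15-min cadence with the transition mid-window, where the
fit achieves ~2% (τ) and ~5% (k) median error; noiseless recovery is exact
(< 10⁻⁴ relative) across the full (a, b, k, τ) grid either way.

### Density response and clustering control

The headline proportionality statistic regresses *per-density mean*
amplitude b on density (R² reported); the per-fit regression R² is also
returned. Recruitment-time similarity across densities is summarized by
pairwise two-sample KS distances over identifiable fits. Note the KS
statistic's sampling floor: even identical continuous distributions give
D ≈ 1.36·√(2/n), i.e. ~0.3 at n = 20 per group — with cohorts of tens of
fits the KS distance measures sample size, not dissimilarity. The
simulator-level check (pooled per-agent first-attachment times, n ≈ 1500)
is reported alongside and sits near 0.02.

The clustering control computes the pair-correlation g(r) on 5 μm bins with
a 95% Monte-Carlo envelope from uniform resamplings in the same window; the
clustering length is the outer edge of the *contiguous* significant run
from r = 0 (isolated distant exceedances are the envelope's expected 5%
false positives). Spontaneous clustering of unbiased agents stays at the
single-bin scale, while recruitment manifests at the spheroid scale.

### Fragmentation scoring

*High resolution* (nucleus ≥ 6 px across): in-mask nuclear signal is
normalized by its maximum (scale invariance), Otsu-thresholded, and
decomposed into connected objects; objects with equivalent diameter below
the fragment cutoff (default: half the 10 μm intact-nucleus diameter) and
solidity ≥ 0.8 count as fragmented; score = fragmented / total nuclear
area. Missing (NaN) on empty masks, dark frames, or nuclear area below a
20 px floor.

*Low resolution* (4× scale, ~2 μm/px): unsharp mask (subtract Gaussian
blur, σ = nucleus radius, gain 1), then threshold at
median + z × (lower-side MAD scale) of in-mask sharpened values (default
z = 3); score = positive area / mask area. The one-sided robust scale is
the load-insensitive choice: apoptotic bodies only add positive residuals,
so a two-sided mean/SD threshold self-normalizes and flattens the response
(adding fragments inflates the SD as fast as the signal). z = 2 sits inside
the additive-noise tail at the default noise level; z = 3 separates cleanly.
Both scorers measure *instantaneous* fragmented area — the fragment signal
itself decays (~24 h), so cumulative death counts are only available from
ground truth.

Specific lysis: control interpolated onto the treated grid,
L = 100·clamp[(F_T−F_C)/(1−F_C), 0, 1]; missing where the control is fully
fragmented. The clamp truncates negative "protection" values — this is a
surrogate, not an estimator of killed-cell counts.

Coupling: both series interpolated onto the union grid over their overlap;
lag = t½(fragmentation) − t½(recruitment), where t½ is the first crossing
of half the series' own maximum *rise above its initial value*. The
baseline correction matters: the low-res scorer has a small false-positive
floor, and without it the landmark fires spuriously at t = 0.

### Infiltration

Radial profiles assign pixels (pixel-center distance from the track
centroid) to uniform-width annuli; empty bins carry NaN. The boundary is
drawn at the mask-equivalent radius. Depth at a time point =
boundary_radius − r*, with r* the *lower edge* of the innermost interior
bin whose mean reaches half the interior peak (so uniform signal ⇒ depth =
boundary radius; rim-only signal ⇒ one bin width). Interior fraction =
intensity-weighted share of signal inside the boundary. Profiles for
infiltration analysis are computed on optical-section renders (± 25 μm
about the spheroid center plane) with bright effector labeling and low
noise — the confocal regime in which rim-resolved profiles are actually
acquired; in widefield projections the depth landmark is geometrically
confounded (see §1).

## 3. Validation experiments and their scope

`spherotox.validation` runs the benchmark experiments summarized by
`scripts/acceptance.py`; scene sizes are scaled for single-CPU minutes
(frames 150–450 px across, 30–60 hourly frames, 60–600 agents, 50–200
cells/spheroid, 10–40 scenes per experiment — stated here as the package's
operating sizes).

What passing shows: the estimators are unbiased against exhaustive
per-pixel oracles; segmentation holds IoU ≥ 0.8 and recovers cohort size
dispersion within 20% under noise; recruitment amplitude is linear in
density while arrival timing is density-invariant; top seeding delays and
disperses recruitment relative to gel; killing follows recruitment
(positive lag in 10/10 kill-on-contact replicates) and a uniform-kill
control fragments without any recruitment signal; the low-res scorer ranks
true fragment load with Spearman ≥ 0.9; the pipeline is byte-deterministic.

What passing does **not** show: the simulator's nuclei are Gaussian blobs,
not textured chromatin; collagen fibers, nutrient gradients, tumor growth,
effector proliferation/exhaustion and stromal components are absent;
brightfield texture is stationary speckle rather than cell-scale structure;
real deconvolution artifacts, drift and illumination gradients are not
emulated. Results on real microscopy require the usual per-dataset
parameter review (segmentation minimum area, nucleus diameter, thresholds —
all exposed on the parameter dataclasses).

Known limitations: recruitment curves from uniformly seeded gels are
intrinsically concave-early (nearest effectors arrive first), so τ
estimates cluster near the window start and occasionally fall just outside
it (flagged non-identifiable); the KS criterion on fitted recruitment times
is sample-size-limited (see above); fragment scoring saturates when
apoptotic bodies crowd beyond the unsharp filter's resolving density; and
the half-peak infiltration depth is threshold-like — it distinguishes
rim-bound from infiltrating effectors sharply but saturates between strong
infiltration rates, where the interior signal fraction is the graded
readout.
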