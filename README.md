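# spherotox

Quantitative imaging analysis of HLA-independent killer-lymphocyte activity
against 3D tumor spheroids — and an agent-based synthetic co-culture
simulator that makes every analysis stage verifiable against ground truth.

## The problem

Adoptive cell therapies (CIK cells, NK-92) kill tumor cells without HLA
restriction, but evaluating them in 3D requires more than an endpoint
read-out: effectors must *reach* the spheroid (recruitment), *enter* it
(infiltration) and *kill* inside it (cytotoxicity), each with its own
kinetics. This package implements the image-analysis pipeline for
multi-channel time-lapse co-cultures of melanoma spheroids embedded in
collagen with killer lymphocytes:

- **Segmentation** — spheroids are segmented from the brightfield channel by
  local-variance texture thresholding (or a trainable random-forest pixel
  classifier), linked over time by nearest-centroid tracking, and summarized
  by cohort size statistics (relative dispersion = 100·sd/mean of equivalent
  diameters).
- **Recruitment kinetics** — recruitment on each spheroid is the
  background-subtracted mean effector fluorescence inside its mask. Each
  curve is fitted with the four-parameter sigmoid

  y(t) = a + b·e^{k(t−τ)} / (1 + e^{k(t−τ)})

  with baseline *a*, maximum recruitment *b*, recruitment rate *k* (h⁻¹) and
  recruitment time (delay) *τ* (h). Cohort analyses cover the density
  response (amplitude ∝ seeding density, recruitment time invariant) and a
  pair-correlation clustering control against complete spatial randomness.
- **Cytotoxicity** — nuclear fragmentation is the apoptosis proxy: dying
  cells collapse into small bright apoptotic bodies. A high-resolution
  scorer decomposes nuclear signal into intact vs fragmented objects; a
  low-resolution scorer (unsharp masking + robust threshold) works at 4×
  magnification for multi-spheroid throughput. Specific lysis is the
  control-normalized surrogate L = 100·clamp[(F_T−F_C)/(1−F_C), 0, 1],
  and the recruitment→cytotoxicity coupling lag is the difference between
  the half-rise times of the two series.
- **Infiltration** — radial fluorescence profiles around the spheroid
  centroid, with the boundary at the mask-equivalent radius; infiltration
  depth is the half-peak penetration distance.

Because the original microscopy data are not public, the package ships a
**scene simulator**: effector agents perform a biased persistent random walk
toward spheroid surfaces (no density feedback, by construction), attach,
infiltrate, and kill on contact; dead cells render as decaying apoptotic
bodies (~24 h signal stability) and the effector dye bleaches (~72 h). The
simulator emits both calibrated image stacks and complete ground truth
(trajectories, states, death events, masks), so segmentation accuracy, fit
recovery, scorer validity and the qualitative orderings (top vs gel seeding,
killing lags recruitment) are all testable.

## Worked example

```python
import spherotox as st

scene = st.validation.demo_scene(seed=3)          # 2 spheroids, gel seeding,
bundle = st.run_pipeline(                          # kill-on-contact, 48 h
    st.AnalysisConfig(out_dir="demo_out", scene=scene, rng_seed=3)
)
for f in bundle.fits:
    print(f"spheroid {f.spheroid_id}: b={f.b:.4f} a.u., "
          f"k={f.k:.2f}/h, tau={f.tau:.1f} h")
for sid, _, lag in bundle.couplings:
    print(f"spheroid {sid}: cytotoxicity lags recruitment by {lag:.1f} h")
```

prints (seed 3):

```
spheroid 1: b=0.0052 a.u., k=0.26/h, tau=-0.4 h
spheroid 2: b=0.0061 a.u., k=0.31/h, tau=-0.5 h
spheroid 1: cytotoxicity lags recruitment by 18.3 h
spheroid 2: cytotoxicity lags recruitment by 17.2 h
```

Gel-embedded effectors are recruited essentially immediately (τ ≈ 0 h —
the delay is below the 1 h frame interval, whereas top-seeded effectors
take tens of hours), at a rate k ≈ 0.3 h⁻¹, while the bulk of the killing
follows recruitment by ~18 h — the recruitment-before-cytotoxicity
ordering the pipeline is built to quantify. All stage outputs (tracks, curves, fits,
fragmentation, radial profiles, lags) are written as unit-annotated CSVs
plus a provenance record; the same run is available from the shell as
`spherotox demo --out demo_out --seed 3`, and the other CLI verbs
(`simulate`, `segment`, `recruitment`, `fit`, `cytotox`, `lysis`,
`infiltration`, `run-all`) expose each stage separately.

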