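# Methods

This note documents the models, parameters and numerical choices behind
`strandscan`, and what the synthetic-scene experiments do and do not
demonstrate about real imagery.

## The detection problem

A stranded baleen whale carcass at 2 m multispectral resolution is a
3–10 pixel elongated blob on the waterline. Decomposition turns the
skin pink/orange/white, giving carcasses elevated red and near-infrared
radiance relative to drift logs and wave foam — but also making each
carcass spectrally heterogeneous (sun-bleached back, shadowed flank,
wet/dry skin). The pipeline exploits the first property (spectral-shape
target detection) and is limited by the second, exactly the regime a
desk analyst faces.

## Spectral Angle Mapper

For pixel spectrum `x` and end-member mean `t` (both 8-vectors of TOA
radiance), the score is `θ = arccos(⟨x,t⟩/(‖x‖‖t‖))`, invariant to
positive rescaling of either argument, so differences in illumination
and sun angle cancel. Classification rule: a pixel is a candidate iff

* it is valid (non-nodata, nonzero norm) and inside the analysis mask,
* its minimum angle over all *target* signatures is ≤ `max_angle_rad`,
* and that angle is strictly smaller than its angle to every
  *exclusion* signature (exclusions let bright confounders such as
  cloud be claimed away from the whale targets).

Only the signature's per-band **mean** enters the angle; min/max/sd are
descriptive statistics reported alongside (standard end-member
formulation). Ties across targets resolve to the first-listed target.

**Likelihood.** The 0–100 score is `100·(1 − θ/θ_max)`, clipped. A
linear map is the simplest monotone choice; the score scale of the
original commercial tooling is not publicly defined, so these
likelihoods are comparable *within* a run, not across tools. Likelihood
strata in reports are `likelihood ≥ threshold`; with a continuous angle
distribution the boundary case has measure zero, so `≥` vs `>` is
immaterial in practice.

**Angle threshold.** `max_angle_rad` defaults to 0.10 rad and is a
required, logged configuration value; there is no principled universal
default, and every run manifest records the value used.

## NDWI coastline and metric buffer

Water is `NDWI = (G − NIR1)/(G + NIR1) > 0` (bands 3 and 7 by default;
threshold configurable, 0 is the standard zero-crossing). The coastline
is the set of land pixels 4-adjacent to water. The buffer contains
every pixel whose **center** lies within `distance_m` (Euclidean,
center-to-center, computed by exact distance transform) of a coastline
pixel center; `side` restricts it to the landward or seaward strip.
Defaults: 5 m, both sides — carcasses are beached *or* partially
floating, and a one-sided or too-thin buffer is known to miss whales
stranded high on beaches, which is why both parameters are exposed.

## Gram-Schmidt pan-sharpening

The multispectral bands are bilinearly upsampled to the pan grid
(pixel-center registration), a low-resolution pan is simulated as a
weighted band sum (default: visible + NIR1 bands, matching a typical
VHR pan passband), and the real pan is matched to it in mean and
standard deviation. With the simulated pan as first Gram-Schmidt
component and all other components untouched, the inverse transform
reduces to covariance-gain injection
`out_b = MS_b + g_b·(pan_matched − pan_sim)`,
`g_b = cov(MS_b, pan_sim)/var(pan_sim)`. A final step injects each
band's block-mean residual so that averaging the sharpened band back to
the coarse grid reproduces the input band *exactly* (to float
precision): spectral consistency is the contract downstream analysis
relies on, and component substitution alone leaves that low-frequency
term free. Degenerate inputs (zero-variance simulated pan, i.e.
constant imagery) get zero gains, making constant images a fixed point.
Nodata in any input band or the pan propagates to all output bands at
that location.

SAM runs on the 2 m multispectral grid by default
(`use_pansharpened: false`): signatures are drawn at native resolution
and sharpening adds no spectral information, only spatial detail. The
sharpened path is available as a config choice.

## Object grouping and confidence classes

Candidates group under 8-connectivity by default (diagonal carcass
orientations at coarse pixels; 4-connectivity available). Length/width
are the spans of member pixel centers along the principal axes (SVD)
plus one pixel, so a single pixel measures one pixel in each direction.
Confidence grading codifies the manual criteria: class 1 requires
length within 7–20 m (adult baleen-whale scale) and elongation ≥ 2.5;
class 2 relaxes to 5–25 m and elongation ≥ 1.5; class 3 is everything
else. The numeric class-2/3 cutoffs are *non-canonical* configuration —
the original grading was expert judgment — and "fluke visible", part of
the manual class-1 definition, cannot be assessed at these resolutions
and is deliberately dropped. Adjacent or overlapping carcasses merge
into one object by design; no splitting heuristic is attempted, so
crowded strandings under-count, mirroring the known bias of image
surveys.

## Evaluation conventions

A candidate pixel counts as a *whale pixel* if it lies on, or within 1
multispectral pixel (Chebyshev, 2 m) of, a truth footprint —
georeferencing-jitter tolerance, configurable. A whale is *identified*
at a stratum if ≥ 1 candidate in that stratum associates with it; a
whale claimed by several separate pixel groups counts once. Report
identities: whale pixels + commissions = total flagged pixels, and
identified + omissions = truth whales, at every stratum. Percentages
are rounded half-up: one decimal in threshold-stratified tables,
nearest integer in narrative summaries (distance concordance, count
excess) — the mixed precision used in survey reporting. Count
comparisons validate that per-class counts sum to the satellite total
and surface any mismatch as a recorded discrepancy rather than
resolving it silently; a zero ground count flags the excess percentage
as undefined instead of dividing.

## Synthetic scene generator

The simulator emulates the statistical structure the detector assumes,
on a WorldView2-like band set (8 bands, centers 427–949 nm, NIR1 at
833 nm; 2 m MS over 0.5 m pan) with dimensionless TOA-like radiance on
a 0–80 scale:

* **Coastline** — a smoothed random-walk boundary, land west / water
  east, with a sand strip (4 px) along the shore, vegetated interior
  and rock patches.
* **Carcasses** — rotated ellipses, aspect 3:1–6:1, placed with
  centers within `whale_max_dist_to_coast_m` (default 5 m) of the
  boundary. Target lengths are drawn uniformly from 7–20 m and the
  semi-axes iteratively adjusted so that the *rasterized* footprint's
  principal-axis length stays within the configured range. Each whale
  draws a decay state — fresh-dark, pink, orange, bleached (weights
  0.15/0.35/0.35/0.15) — whose mean spectra keep a slight NIR1 peak
  and, for the bright states, radiance above 60. Within-carcass scatter
  defaults to sd 6 (wide, matching observed carcass heterogeneity).
  Non-overlapping whales keep a ≥ 1-pixel Chebyshev gap
  (`min_separation_px`) so distinct carcasses remain distinct under
  8-connected grouping; `allow_overlap` disables this to emulate
  crowded strandings.
* **Confounders** — logs (dark, thin, low red/NIR), wave streaks
  (bright blue-green foam falling off into the NIR), cloud discs
  (bright, flat). Under the default model the decay-weighted mean whale
  spectrum exceeds logs and waves in the red and NIR1 bands — the
  separability the method relies on — while *bleached* carcasses are
  deliberately shape-close to sand and cloud (angles ~0.06 rad), which
  is what drives realistic commission errors.
* **Pan band** — the band-weighted MS brightness replicated to the
  fine grid plus noise, so block-averaged pan correlates > 0.9 with MS
  brightness by construction.
* **Noise** — additive Gaussian per band (sd 1 by default), clipped at
  zero; all randomness flows through one seeded generator, so scenes
  are bit-reproducible from (config, seed).

What the simulator does **not** model: atmospheric/radiative-transfer
effects, sun-angle and shadow geometry (shadowed whales appear only as
the dark decay state), tides, surf texture, mixed pixels at the
waterline, and sensor PSF/MTF. Passing tests on synthetic scenes
therefore demonstrate the *algorithmic* correctness and the qualitative
error structure (threshold trade-off, confounder commissions), not
field performance on commercial imagery.

## Canonical experiment presets

Two frozen configurations define the quantitative experiments:

* `noise_free_config` — every class renders its exact mean spectrum
  (all sds 0), whales all "orange", log/wave confounders present. With
  the orange spectrum as target, every whale pixel scores angle 0 and
  the nearest non-whale class (sand) sits at 0.21 rad, far above
  `θ_max` = 0.10: recall is 100% with zero commission inside the
  buffer.
* `separable_config` — carcass sd 2 plus sensor noise sd 1 give a
  noise-induced angle spread ≈ 0.045 rad at these radiance levels,
  under a third of the 0.21 rad whale-to-sand separation: the regime
  where pixel-level target detection is expected to work. Ten seeded
  200×200 scenes with 20 separated whales each are the scaled-down
  stand-in for a full-scene survey (desk-scale: each scene runs in
  well under a second).

Both presets place whales within 2 m of the coast and evaluate inside a
10 m buffer so that footprints are reachable; the 5 m default remains
for survey-faithful runs.

## Reproducibility and provenance

`run_pipeline` threads one integer seed through scene generation;
every run writes a manifest with the configuration (hashed), the seed,
and each gap-filling default actually used (`θ_max`, NDWI threshold,
buffer side and distance, likelihood mapping), so identical
config + seed yields byte-identical reports. Raster I/O is float32
GeoTIFF with standard geo tags; truth, candidates and objects travel as
GeoJSON + CSV in a projected meter-unit CRS with north-up, pixel-center
registration.

## Known limitations

* Likelihood values are tool-internal; only their ordering and the
  nesting of threshold strata are meaningful.
* The confidence-class cutoffs and the SAM angle threshold are
  documented defaults, not field-calibrated constants.
* Heterogeneous (multi-decay-state) carcasses defeat a single-target
  SAM by design; covering each decay state with its own signature
  (`per_decay_state`) recovers them on synthetic scenes but has no
  claim to completeness on real carcasses.
* Sub-pixel and waterline-mixed carcass pixels are not modeled; at 2 m
  pixels a 7 m whale is near the detection floor.
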