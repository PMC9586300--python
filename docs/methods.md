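# Methods

`spinetrack` analyses longitudinal two-photon imaging of dendritic segments:
it detects dendritic spines in each session's 3D stack, assigns persistent
spine identities across sessions, and computes the turnover and persistence
metrics used in chronic-imaging studies of cortical structural plasticity.
Because real chronic-window datasets are rarely shareable, the package ships
a first-class synthetic-data generator that emulates the whole measurement
chain, so every stage is validated end to end against known ground truth.

## Generative model

Each dendritic segment (length drawn uniformly from 50–100 µm) starts with
spines placed at a baseline density (default 0.4 µm⁻¹) with a minimum
spacing of 0.6 µm (1.2 µm between same-side spines, so that neighbouring
protrusions remain optically resolvable). Dynamics run in **daily steps**
between imaging sessions (default calendar: days 11, 13, 15, 18, 25
post-injury), because the session intervals are uneven (2, 2, 3, 7 days)
and per-interval rates would not compound correctly:

- **Birth.** Each surviving baseline ("preexisting") spine spawns a newborn
  spine on each day with probability *r* (the formation rate per
  preexisting spine per day). Newborns are placed at new locations only —
  never at a previously occupied site.
- **Death.** Each spine survives each day independently: preexisting
  spines with probability *p*ₚ (default 0.998/day, i.e. rare elimination)
  from baseline on, newborns with *p*ₙ from their **first observation**
  on — a newborn's persistence kinetics are defined relative to the
  session at which it is first seen, so every interval birth is observed
  at the next session and its two-day persistence from that session is
  *p*ₙ².
- **Reappearance.** On elimination, with probability 0.05 the spine
  re-emerges at the same location one session later, producing the
  1, 0, 1 presence pattern the analysis must merge back into one identity.
- **Treatment epochs.** A group can switch (*r*, *p*ₙ) at a stated day
  (default 14), emulating a four-day drug course beginning then.

Group presets encode the two regimes of interest: the control-like preset
(*r* = 0.1/day, *p*ₙ = 0.94868/day, i.e. two-day persistence 0.9) and the
injury-like preset (*r* = 0.25/day, *p*ₙ = 0.63246/day, two-day
persistence 0.4). Over the 2-day baseline interval the expected formation
fraction is *g*·*r* = 0.2 and 0.5 new spines per preexisting spine, and
the expected number of newborns present after a gap of *g* days is
*n*·*r*·*g* per segment of *n* preexisting spines — the closed forms used
as oracles in the tests. The survival index of a cohort *h* days after
its first observation is *p*ₙʰ (0.9 and 0.4 at the two-day follow-up).

## Image formation

Stacks mimic the stated microscope geometry: 0.1513 µm lateral pixels,
1 µm z-steps. The scene is in-plane (backbone and spines share one
z-plane; transcranial imaging resolves lateral protrusions best, and this
keeps length measurement well defined under the 6.6× z-anisotropy). The
dendrite is a tube of radius 0.35 µm; each spine is a 0.15 µm neck ending
in a 0.4 µm-radius head whose far edge lies at the spine's length from the
backbone centreline. Rendering draws each structure class as a
soft-edged 2D intensity layer (sub-pixel positions shift the image
smoothly), applies the lateral PSF (Gaussian, σ = 0.3 µm), and distributes
intensity across z-slices with the analytic axial profile of the
structure's thickness under the axial PSF (σ = 1.0 µm) — a Gaussian
convolved with a box. This matters: a naive boolean voxelization loses
thin structures entirely when axial jitter places them between z-planes.
Shot noise is Poisson on (gain × blurred scene + background); the default
gain of 150 counts reflects the high effective photon counts of 25-frame
frame-averaged YFP imaging, and the background is 2 counts. Each
non-baseline session is translated by a uniform sub-voxel jitter (default
amplitude 1 µm per axis, bounded by 2 µm); the true offset is recorded for
validation.

Spine lengths are everywhere **tip-to-backbone-centreline** distances.
The 0.55 µm spine criterion is applied to this length with a strict
inequality (a 0.55 µm protrusion is excluded; 0.56 µm counted), and
morphology is never a criterion.

## Detection

Per stack: a 3×3 in-plane median filter (shot-noise suppression), Otsu
threshold, largest connected component. Because the stacks are only a few
z-steps thick — a regime where 3D thinning degenerates — the backbone is
skeletonized on the in-plane projection; skeleton pixels lying in thin
structures (necks) are pruned by an Otsu split of the local mask
half-thickness, with a fallback to the unpruned skeleton whenever pruning
destroys ≥ 5 % of the spanning extent (spineless segments have unimodal
thickness). The longest geodesic path through the pruned skeleton is
extended to the mask boundary at both ends, smoothed, snapped to the
sub-voxel intensity ridge (an intensity-weighted centroid along the local
normal and across z, which also recovers the continuous axial coordinate),
and resampled at 0.5 µm. Traced lengths on rendered segments are accurate
to ±0.5 µm; segments whose largest component spans < 48 µm are rejected.

Protrusion candidates are foreground pixels beyond the shaft rim, where
the rim is measured from the image itself: the median mask half-thickness
along the backbone, smoothed along the arc, plus one pixel (a fixed radius
can be supplied instead). Candidate pixels are parameterized by arc
position and side; per side, contiguous support runs are split at valleys
of the smoothed maximal-lateral-extent profile, so neighbouring spines
separate while one spine's blur apron and axial bleed stay one candidate.
Near-coincident same-side candidates (< 0.8 µm) are re-merged, opposite-
side "ghosts" (the blur apron of a bright spine leaking across the shaft)
are suppressed, and pixels within 0.75 µm of the trace end caps are
ignored (the tube continues a little past the traced backbone). A
candidate's length is its maximal lateral distance from the backbone; its
tip is the intensity-weighted centroid of the near-maximal pixels, which
keeps the coordinate stable across sessions at roughly a third of a pixel.

Under this imaging model the shaft's thresholded mask itself extends
≈ 0.75 µm laterally, so protrusions below ≈ 0.9 µm are at the resolution
limit; detection recall and precision are 1.0 on noiseless renderings for
spines ≥ 1.0 µm (the generator's minimum length) at ≥ 1 µm separation.

## Registration and identity tracking

Sessions are aligned to the day-11 baseline by translation only
(chronic-window fields shift approximately rigidly): the integer-voxel
shift maximizing the FFT cross-correlation within a ±5 µm window, refined
to sub-voxel precision in x/y by quadratic interpolation; the score is the
Pearson correlation at the integer shift, and scores below 0.2 raise a
registration error. Recovered offsets match applied jitter to < 0.05 µm
laterally (z remains integer-step, so up to half a z-step of residual).

Identities are chained between **consecutive** sessions (11→13→15→18→25) —
baseline coordinates anchor the frame, consecutive chaining avoids drift
accumulation — by greedy mutual-nearest-neighbour assignment within a
1.0 µm tolerance (≈ one z-step, ≈ 6.6 lateral pixels; the literature
states no tolerance for "the same location", so it is an explicit
parameter). The globally closest remaining pair is mutually nearest by
construction, and on small instances with spacing ≥ 2× tolerance this
greedy scheme equals the exhaustive minimum-cost assignment (asserted
against a brute-force oracle). Unmatched observations start new tracks;
the cohort label (S11/S13/S15/S18) is the session of first observation.

Two corrective passes mirror the coordinate-carrying bookkeeping of a
baseline-referenced workflow:

- **Reappearance merging.** A track ending at session *i* and a track
  starting at session *i* + 2 at the same location (within tolerance) are
  one spine; the return is a reappearance of the original — never a new
  formation. Only single-session gaps merge: a spine absent for two or
  more consecutive sessions that returns starts a new identity, since
  unbounded gap-merging would conflate distinct spines.
- **Retrospective presence check.** Before a mid-series track is accepted
  as newly formed, earlier sessions are re-examined at its location; if
  ≥ 3 foreground pixels already protrude beyond the shaft rim there (the
  spine existed but was lost in segmentation, e.g. merged with a
  neighbour), presence is back-filled and the spine is not scored as a
  formation.

## Metrics

All metrics operate on the binary spines × sessions presence matrix and
aggregate dendrite → mouse → group, with the mouse as the statistical
unit.

- **Formation fraction** at day *t*: tracks first observed after the
  baseline day and present at *t* (not cumulative births), divided by the
  baseline-present count. Reappearance-merged originals carry the
  baseline cohort and are excluded from the numerator.
- **Elimination fraction**: baseline tracks with no presence at any
  session ≥ *t*, over the baseline count — a gap followed by a return is
  not an elimination.
- **Newborn count per segment**: tracks whose cohort equals *t*.
- **Survival index** of a cohort at day *t*: the fraction present at
  every session from first observation through *t* (a newborn that
  vanished and returned is short-lived, hence counts as absent), per
  dendrite, averaged per mouse. It is evaluated at each named session
  (per-day curves); the all-sessions conjunction is the separate
  long-/short-lived classification, where long-lived means present at
  every session after birth through the end with no reappearance event.
- **Density**: spines per µm of traced dendrite (primary, dimensionally
  meaningful), with the baseline-to-session count ratio as a secondary
  output (`density_ratio`) since both bookkeeping conventions circulate.
- **Reverse-time validation**: formation/elimination recomputed with
  day 18 as the reference and earlier days as targets, by reversing the
  session order and re-deriving cohorts; verified exactly against forward
  metrics on the hand-flipped matrix.
- **Conservation check**: present(*t*) = baseline − (baseline absent at
  *t*) + (post-baseline cohorts present at *t*), asserted exactly per
  dendrite as a bookkeeping integrity test.
- **Discrimination index** (novel-object recognition):
  DI = (t_novel − t_familiar)/(t_novel + t_familiar). "Total time" is the
  summed object-interaction time — the only reading under which DI is
  bounded in [−1, 1]. Zero-total trials are unscoreable and flagged.

Dendrites with no baseline spines (formation/elimination) or an empty
cohort (survival) are undefined and excluded with a warning rather than
counted as zero, and the counts are reported.

## Statistical layer

Equal-variance Student *t* by default (Welch behind a flag), ordinary
one-way ANOVA with Tukey HSD via the studentized-range distribution,
paired *t* for within-animal day comparisons, and a two-sided Grubbs test
(critical value from the *t* distribution) that excludes **at most one**
animal per cohort — re-application is a recorded no-op. The two sham arms
are pooled into "Sham ± ISRIB" whenever they do not differ at α = 0.05,
decided metric-by-metric and day-by-day; downstream comparisons then use
the pooled series. Significance is 0.05 throughout.

## Problem sizes and validation regime

The cohort-recovery checks run 12 mice × 40 dendrites per regime with
50 µm segments at 0.4 spines/µm (~20 baseline spines each; ~480 segments,
~9,600 spines per regime), the scale at which the mouse-level standard
error of the formation fraction is ≈ 0.006. Formation regimes run through
the full image-level pipeline; survival regimes run at the
presence-matrix level (the survival index is a pure bookkeeping quantity
once identities exist) with an imaging spot-check at reduced scale.
Parameter recovery holds across a grid of formation rates
{0.05, 0.1, 0.25}/day × newborn survival {0.4, 0.7, 0.95}/day within
3 Monte-Carlo SE.

## What the simulation does and does not show

The generator reproduces the statistical structure the analysis relies on
— birth/death kinetics compounding over uneven intervals, reappearances,
session-to-session jitter, shot noise, anisotropic sampling — so passing
tests demonstrate that the pipeline recovers known dynamics through a
realistic measurement chain. It does not model: curved or branching
dendrites (straight segments only; the tracer itself handles bends),
out-of-plane spines, morphological change, photobleaching or brightness
drift between sessions (only "similar fluorescence levels" are emulated
via a fixed gain), within-session motion, or deformable tissue warping.
Real-data performance therefore depends on translation-rigidity and
brightness stability assumptions that these simulations do not stress.

## Known limitations

- Spines below ≈ 0.9 µm are undetectable under the default optics, so the
  0.55 µm counting rule is only exercised down to the resolution limit.
- Same-side neighbours closer than ≈ 1.4 µm may merge into one candidate;
  the retrospective presence check keeps this from biasing formation, but
  per-segment absolute counts can be slightly low on crowded dendrites.
- Axial localization is limited to roughly half a z-step; the matching
  tolerance (1 µm) absorbs this but close spines stacked axially would
  not be separable (none are generated).
- The elimination fraction of the image-level pipeline carries a small
  positive floor (≈ 0.02) from residual segmentation flicker of marginal
  spines; at the regimes studied this is well below the biological effect
  sizes of interest.
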