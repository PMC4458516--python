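# Methods

This note documents the models, estimators and numerical choices behind
`rodmap`, and what the synthetic benchmarks do and do not establish
about real microscopy data.

## Steady-state population model

A culture in balanced exponential growth has a time-invariant
distribution of cell-cycle ages. With age a ∈ [0, 1] (0 = birth,
1 = division) and every division replacing one mother with two
daughters, the age density is

    p(a) = 2 ln2 · 2^(−a),      F(a) = 2 (1 − 2^(−a)),

so newborns are twice as frequent as dividing cells. Single cells grow
exponentially in length, L(a) = L₀ · 2^a, making length a monotone proxy
for age. `synthgen.sample_population` draws ages by inverse-CDF sampling
and lengths from the growth law with multiplicative lognormal noise
(`length_noise_cv`, default 0.05 — a typical between-cell length
variability for balanced cultures).

Age assignment (`cyclemap.assign_ages`) inverts this construction from
length ranks alone: F = (rank − ½)/n (mid-rank, avoiding the F ∈ {0, 1}
singularities) and a = −log₂(1 − F/2). Ranks tie-break by cell id so the
assignment is deterministic. On synthetic populations the assigned ages
correlate with the true ages at r ≈ 0.97 (n = 10⁴, 5% length noise);
the residual scatter, σ_a ≈ 0.07, is the resolution floor for any
timing statistic derived from length ranks, and is why initiation /
moment recovery is resolved to one 10% age class rather than finer.

## Geometry of a synthetic cell

Cells are capsules (spherocylinders) of width `width_um` (default
1.0 µm) and pole-to-pole length L. Past `constriction_onset_age`
(default 0.6) the mid-cell radius is pinched by a Gaussian notch
(σ = 0.25 µm) whose depth ramps linearly to `constriction_depth`
(default 0.5) at division — a simple stand-in for septal invagination.

The phase-like channel renders each cell as an intensity depression
whose depth is proportional to the local radius, on a bright background;
a constricted mid-cell therefore reads as a shallower depression. The
per-cell `phase_profile` extracted by the segmenter is the *depression*
(background − intensity), so it decreases at constrictions just like the
geometric diameter and serves as the phase-based cell-width proxy that
the width profile map displays.

Fluorescence classes per channel (`ChannelModel.kind`):

* `cytoplasmic` — constant per-pixel amplitude inside the mask;
* `contour` / `periplasmic` — a band of signal along the envelope,
  rendered just inside the cell outline (half-width `ring_halfwidth_um`,
  default 0.08 µm ≈ 1.25 px). Placing the ring inside the outline
  matters: envelope signal outside the mask would be indistinguishable
  from extracellular puncta to the bleb detector;
* `septal` — a uniform base (`base_amplitude`) plus a transverse
  Gaussian band at mid-cell (σ = `septal_sigma_um`, default 0.15 µm) for
  cells past `septal_onset_age`. The band's amplitude is age-dependent:
  zero before onset, rising linearly to `amplitude` at `septal_peak_age`
  (default 0.65), then declining to `amplitude · septal_end_fraction`
  at division. An age-constant band would have no defined moment of
  peak localization; the triangular course is the simplest shape with
  both an onset and a peak.

Every channel applies lognormal between-cell expression variability
(`cell_cv`, default 0.1), additive per-pixel Gaussian noise
(`noise_sd`) and a constant background. Poisson noise, PSF convolution
(beyond an optional Gaussian blur), 3D effects, and touching/chained
cells are deliberately out of scope; cells are placed by rejection
sampling with a ≥ 5 px separation so segmentation tests do not depend on
resolving contacts. Defaults (amplitude 100, noise 2–5, background 10,
200-count phase background with 100-count depression) emulate a
well-exposed wide-field image at 0.064 µm/px.

`analytic_profiles` produces the same per-cell axial profiles as exact
bin integrals of the intensity model, bypassing rendering. The demograph
statistics are tested at n = 3000–10⁴ through this path; rendering-based
tests use hundreds of cells. This keeps the full suite under a minute
without weakening the rendered-image checks, which exercise the same
code paths at smaller n.

## Segmentation and medial axis

`segment_cells`: Gaussian smoothing (σ = 1 px) → intensity inversion →
global Otsu threshold → hole filling → connected components → area,
solidity and elongation filters. A global threshold (rather than a
local/adaptive one) is appropriate for the flat-illumination fields this
package targets and does not fire on blank or pure-noise images, which
are additionally rejected by a contrast guard (Otsu threshold must clear
the background median by 5 robust σ). Users with uneven illumination or
touching cells should segment externally and enter through
`from_labels`, which preserves label ids and is otherwise identical
downstream.

The medial axis is the longest geodesic path through the mask skeleton
(Lee's thinning; the classic Zhang variant can collapse capsules at some
orientations to a point), smoothed by a 5-sample moving average and
extended to the poles by marching along the end directions to the mask
boundary. Cell length is the arc length of this polyline; on noiseless
rendered rods the mean absolute error is ≈ 0.4 px. The diameter profile
is twice the Euclidean distance transform sampled on the axis — the
inscribed-circle diameter, which equals the perpendicular width for a
rod and dips at constrictions. It necessarily tapers at the rounded
poles; mid-cell comparisons should use interior bins. Objects with
length/width < 1.5 (default) raise a shape error naming the cell rather
than being silently dropped.

## Profiles and mid-cell statistics

Axial profiles assign every mask pixel to one of `n_bins` (default 50)
equal axial bins by orthogonal projection onto the axis polyline
(boundary ties go to the lower bin) and sum background-subtracted
intensities; the per-field background is the median intensity outside
all cell masks. Mass conservation (Σ bins = background-subtracted mask
total) holds to < 1% by construction. Contour traces resample the
closed sub-pixel contour by arc length at 0.064 µm and read the image by
bilinear interpolation; whether the field background is subtracted
before tracing is a pipeline switch (`subtract_contour_background`,
default on — percentile thresholds across fields assume comparable
baselines), while the function-level default leaves raw intensities.

Ring fraction and FCplus both use an absolute 0.8 µm mid-cell window
(applied before any length normalization), with partially covered bins
weighted pro rata. FCplus subtracts a baseline estimated as the mean
per-µm signal in two 0.8 µm windows flanking the mid-cell window, and is
clipped at zero; cells shorter than window + 2 × flank (2.4 µm) return
NaN, flagged and propagated, never dropped silently. On noiseless
profiles FCplus recovers an injected band mass within ≈ 1% (the residual
is the Gaussian tail mass that falls in the flanks).

**Initiation** is the earliest 10% age class whose mean FCplus exceeds
the pooled mean of all earlier classes by 2 combined standard errors,
with all later classes also above threshold. Two refinements proved
necessary at realistic population sizes: the zero-clipping of FCplus
gives pre-onset classes a small positive mean (≈ σ/√2π), and rank-age
smear leaks a little genuine signal one class early, so the pure
significance rule can fire a class or two before the true onset. The
threshold therefore also includes a practical-significance floor:
`min_rel_excess` (default 0.05) times the dynamic range (largest class
mean above the pooled baseline). With both terms, recovery is within one
age class of the generating onset for onsets 0.3–0.5 at n = 3000 across
seeds. **Moment** is the midpoint of the age class with the largest mean
FCplus (undefined below 10 defined cells or when all classes are zero);
no smoothing over classes is applied.

## Defect classifiers

Both classifiers calibrate a quantile on a reference population
(`numpy` linear-interpolation convention, fixed for reproducibility;
minimum 50 reference cells) and then apply fixed rules:

* **Leakage** — threshold = 98th percentile of the reference
  population's per-cell median contour fluorescences; a cell is leaky
  iff its median is strictly below the threshold. By construction ≈ 98%
  of the reference itself is called leaky. On mixed scenes
  (30% leaky, 5× signal attenuation, 5% noise) sensitivity and
  specificity are ≥ 0.98 — the two median distributions are separated
  by ~5× while the threshold sits at the top of the leaky one.
* **Blebs** — reference brightness is the 99.7th percentile of pooled
  per-pixel intensities inside reference masks (per-pixel rather than
  per-cell means because puncta are pixel-scale objects; a
  `per_cell_mean` mode is available). Candidates are 8-connected
  components of supra-threshold pixels outside all masks ("isolated" is
  interpreted as: a distinct connected component, with no extra
  separation radius); accepted calls additionally require component
  mean brightness above threshold (not background-subtracted), area
  strictly below 4 µm², and minimum distance from component pixels to
  the nearest cell-contour polyline of at most 0.3 µm, computed
  sub-pixel via shapely. Each bleb is assigned to its nearest cell.

## Problem sizes and determinism

Everything is deterministic under a fixed integer seed: population
draws, placement, noise and bleb injection all run off one
`numpy.random.default_rng`. The test suite and the acceptance script use
populations of 3000–10,000 cells for rank/age statistics (where only
profiles are needed) and rendered fields of 60–500 cells for
image-level checks — sizes at which every targeted effect is detectable
with comfortable margin while a full run stays in the tens of seconds.

## Limitations

* The synthetic scenes have flat illumination, Gaussian noise and
  hard-edged masks; passing tests demonstrate correctness of the
  estimators under the stated model, not robustness to focus drift,
  shading, Poisson statistics or segmentation bias on real images.
* Age assignment assumes a steady-state culture and exponential length
  growth; on perturbed or filamenting populations the rank→age map is
  not meaningful.
* The FCplus baseline definition (flanking windows of one window-width)
  is one reasonable formalization of "extra mid-cell fluorescence";
  absolute FCplus values are definition-dependent and should only be
  compared within one pipeline configuration.
* Touching cells are not split; curved cells are handled only to mild
  curvature by the skeleton-path axis.
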