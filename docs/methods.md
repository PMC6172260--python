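# Methods

This note records the models, parameter choices and numerical decisions
behind `cosiquant`, and what the synthetic-data tests do and do not show
about real data.

## The comparative model

The method assumes that (i) the synaptosome standard and the sample of
interest are immunostained equally well (same antibodies, same master mix,
same imaging settings), and (ii) immunofluorescence intensity is
proportional to the number of bound antibodies, hence to protein copies.
Under these assumptions the per-synapse copy number is

    copies_i = I_i / mean(I_synaptosome) * N_ref,

a mean-of-ratios estimator: each synapse is divided by the *mean*
synaptosome intensity and the resulting per-synapse copy values are then
summarised (mean ± SEM). The alternative ratio-of-means reading gives the
same headline mean but no per-synapse values; the per-synapse form was
chosen because the method's output is intrinsically per-synapse. The
reference table's own SEM is reported alongside, never propagated into the
headline SEM — there is no principled propagation rule for a ratio of a
log-normal-ish sample against an external standard, and conflating the two
dispersions would overstate precision.

"Intensity" is always the fitted integrated (volume) intensity
`2π·A·σ₁·σ₂`, which is robust to focus-dependent trade-off between
amplitude and width; amplitude-based summaries are available via
`measure="amplitude"` for sensitivity analysis.

## Detection

* Smoothing kernel: isotropic Gaussian, σ = 480 nm (3 px at the canonical
  160 nm pixel). Boundary mode is *reflect*: it preserves constant images
  and avoids edge dimming that would bias threshold decisions.
* Threshold: by default `median + k·1.4826·MAD` of the smoothed marker
  raster with k = 5. The 1.4826 factor makes MAD a consistent estimator of
  σ under Gaussian noise, so k is interpretable as a z-score. An absolute
  threshold override exists for operator-chosen cuts. The default is
  deliberately permissive — the R² filter downstream removes false
  positives, so missing a dim real synapse is the costlier error.
* Local maximum: strictly greater than all pixels of a (2r+1)² neighbourhood
  with r = round(480 nm / pixel size); a perfectly flat patch is not a
  maximum. On ties, the earlier pixel in row-major order wins and the
  duplicate is suppressed; dimmer maxima within r of a brighter one are
  suppressed. Maxima closer to the border than half the fitting ROI are
  dropped so that every candidate can be fitted.

## Gaussian fitting

* Model: rotated elliptical 2D Gaussian with constant offset; the offset
  absorbs local background, so no separate background subtraction is
  performed. Orientation is canonicalised to σ_major ≥ σ_minor, θ ∈ [0, π),
  with the major axis along (cos θ, sin θ).
* ROI: square, 2.2 µm side, centred on the candidate pixel (15 px at
  160 nm/px). Overlapping ROIs of nearby candidates are fitted
  independently — there is no joint multi-spot model; crowded or fused
  puncta produce poor single-Gaussian fits and are removed by the R²
  filter, which is the intended behaviour.
* Optimiser: bounded trust-region least squares (plain, unweighted
  residuals, matching the plain-R² quality criterion). Two starts are
  tried and the lower-SSE solution kept: a moment-based start (intensity-
  weighted centroid and principal axes of the offset-subtracted ROI) and a
  simple start (ROI centre, σ = smoothing σ, θ = 0). The moment start alone
  is occasionally poor on noisy ROIs, the simple start alone occasionally
  lands in a local optimum on strongly elliptical spots; together they make
  non-convergence on real spots rare.
* Bounds: centre inside the ROI; σ ∈ [0.5 px, ROI side/2]; amplitude ≥ 0.
  These prevent degenerate "fits" of flat noise from reporting enormous
  integrated intensities.
* Failure handling: a non-converged fit, or one whose ROI has zero data
  variance (R² undefined), carries R² = −∞ / NaN and can never pass a
  threshold.

## Filtering

R² thresholds (marker 0.85, active zone 0.70, POI 0.60) are inclusive: a
fit exactly at the threshold passes ("below ... discarded" read literally).
The rejected record names every failing channel.

One consequence worth knowing: the filter preferentially removes *dim* POI
spots (low SNR → low R²), so when the sample of interest is substantially
dimmer than the standard, the accepted-population mean is biased slightly
upward — ~3% at a true culture/synaptosome ratio of 0.5 under the
simulator's default conditions. This is a property of the method itself,
not of this implementation.

## Single-antibody calibration

* Bandpass: difference of Gaussians with σ_small = PSF σ and
  σ_large = 3 × PSF σ (scales not prescribed anywhere; a 3:1 DoG is the
  common spot-detection default).
* Size filter: spots with fitted FWHM (geometric-mean σ) above 50 nm are
  discarded as dirt — but only when pixel size ≤ 25 nm, since at
  conventional epifluorescence sampling a 50 nm cutoff is unresolvable;
  there an adaptive bound of 2× the population's median FWHM is applied
  instead.
* Population estimate: least-squares single-Gaussian fit to the
  Freedman–Diaconis histogram of integrated intensities; the fitted peak
  is the reported mean single-antibody intensity, with the median reported
  alongside as a robust cross-check. A population fit R² < 0.5 sets a
  warning flag (multimodal population, likely antibody clusters). Fewer
  than 10 retained spots is an error, not a silent estimate.

## Synthetic data

The simulator renders isotropic Gaussian spots (an idealised
diffraction-limited PSF, default σ 204 nm ≈ 480 nm FWHM) at uniformly
random, minimum-separated positions on a constant background (default 50
counts), with per-spot per-channel amplitudes drawn log-normally around the
channel means (default CV 0.5, reflecting the broad per-synapse spread of
real stainings) and Poisson shot noise. Defaults use 160 nm pixels so that
800 nm spans exactly 5 px. A field is bit-reproducible from its seed.

What it does **not** emulate: optics-accurate PSFs (Airy rings,
aberrations), camera gain/read-noise structure, uneven illumination,
off-target staining, overlapping/fused synapses, or spatial correlation of
synapses along neurites. Passing tests therefore demonstrate correctness of
the *analysis* under the stated imaging model — recovery of planted copy
ratios within 10%, detection recall ≥ 95% at SNR 5 with zero false
positives — not performance on arbitrary real micrographs, where fused
puncta and background structure are handled only via R² rejection.

Problem sizes in the acceptance checks (hundreds of accepted synapses per
sample, a few hundred calibration spots) were chosen so that the sampling
spread of each estimator (~0.5·sqrt(2/n) for the intensity-ratio at CV
0.5) sits well below the tolerance being asserted.

## Configuration and provenance

One flat, versioned JSON document carries every tunable (smoothing σ, ROI
side, R² thresholds, threshold mode/value, minimum separation, seed). A
comparative run uses a single configuration for both samples; the only
per-sample override permitted is the detection threshold, because
background levels genuinely differ between a synaptosome lawn and a neuron
culture, while everything downstream must be identical for the comparison
to be valid.

## Reference table

The packaged CSV holds 120 antibody/target rows. Copy numbers carry a
provenance flag: `measured` (numeric value + SEM), `estimated_by_authors`
(textual estimates such as "~100–200" or "<100", stored as structured
ranges with a qualifier rather than invented floats), `not_determined`.
Two targets noted only as "presumably similar to ChromograninB" are stored
as estimates with that qualifier and no numbers. Duplicate targets
(multiple vendors or dilutions) are disambiguated at lookup by catalog
number, dilution or dispersion kind; ambiguous queries enumerate the
candidate rows instead of guessing.

## Known limitations

* Single-Gaussian fits only; fused synapse pairs are rejected, not split.
* The R²-filter selection bias described above (few percent for strongly
  dim samples).
* The calibration's histogram-Gaussian peak slightly underestimates the
  mean for strongly skewed intensity populations; the reported median
  provides the cross-check.
* The reference table transfers only under the exact staining conditions
  recorded in it.
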