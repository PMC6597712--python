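# Methods

This note documents the models, conventions and numerical choices behind
each synquant module: what is computed, which parameters matter, what the
synthetic-data generators do and do not emulate, and where the design was
genuinely open.

## Percent exocytosis from pHluorin traces

A trace is modeled as three epochs: basal (reporter mostly quenched inside
acidic vesicles), stimulated (exocytic dequenching raises fluorescence
toward a plateau), and NH4Cl (all compartments neutralized, total reporter
fluorescence revealed). Percent exocytosis is the ratio of the stimulated
rise to the total dynamic range, from three window means:

* **basal window** — the whole pre-stimulation epoch by default;
* **stimulated window** — the final 60 s before NH4Cl addition. The source
  convention averages "stimulated fluorescence" over an unstated interval;
  we default to the plateau tail because it is insensitive to rise
  kinetics, and the window is configurable for users who want the whole
  stimulation epoch instead;
* **NH4Cl window** — 30 s starting 10 s after addition, skipping the
  mixing/diffusion transient.

Degenerate traces (dead or inverted cells) are rejected rather than
normalized: the NH4Cl mean must exceed the basal mean by at least five
robust (MAD-based) basal SDs. Negative percentages from noisy controls are
clipped to 0 and flagged; values above 100 are retained and flagged, since
they are diagnostically meaningful. The computation is invariant to any
positive affine rescaling of the raw trace.

Spontaneous (unstimulated) release applies the same ratio with a
pre-stimulus drift window substituted for the stimulated window. A
bafilomycin comparison helper reports the difference in percent exocytosis
between a proton-pump-inhibited trace and its control; a nonzero difference
indicates endocytic reacidification during the measurement.

## TIRF flash detection

Single fusion events appear as ~2 px-sigma Gaussian flashes that decay over
a few frames. Historically these are counted manually; the detector
automates the count:

1. per-pixel rolling temporal median (window 11 frames) as background;
2. background subtraction, then per-frame Gaussian smoothing with sigma
   equal to the expected flash sigma (default 1.5 px);
3. 3-D local maxima of the smoothed residual above `5 ×` the robust SD of
   the whole stack. On noise-free stacks the robust SD is 0 and the
   threshold falls back to 5% of the peak residual;
4. border exclusion: maxima within the smoothing support (3 sigma) of the
   image border are discarded, because reflection padding inflates the
   noise variance there;
5. persistence: the same pixel one frame after onset must remain at or
   above 25% of the peak **and** above half the detection threshold. A real
   flash decaying with a time constant of ≥ 1 frame retains ≥ 37% of its
   peak; a single-frame noise spike leaves only independent noise, which
   clears half the threshold (2.5 robust SDs) rarely. This is what pushes
   the false-positive rate to effectively zero at the 5-SD operating point
   without raising the threshold;
6. greedy deduplication within an exclusion radius of (3 frames, 4 px),
   keeping the brightest.

Detected onsets land on the true onset frame at zero noise because the
flash intensity is strictly maximal there. The cumulative event curve is a
nondecreasing step function ending at the event count; the mean release
rate divides the count by the stimulated-epoch duration.

## Membrane-proximal shells and colocalization

The membrane-proximal region is the outer band of the cell mask:
`shell = mask − erosion(mask, r)` with `r = round(shell_width / pixel_size)`
pixels, computed via the Euclidean distance transform so the shell is
isotropic rather than square. The default width is 800 nm, which is 8 px at
the default 100 nm/px sampling. Sub-pixel shells are an error; a cell
thinner than the shell degrades to shell = mask with a flag. The
membrane-proximal fraction divides shell-summed intensity by mask-summed
intensity, so on uniform images it equals the pixel-count area ratio
exactly. The released fraction divides post-stimulation shell intensity by
post-NH4Cl shell intensity of the same registered cell; it is invariant to
a common scalar and flagged when above 1.

The Manders overlap coefficient is evaluated inside the cell mask by
default (excluding extracellular background), with a whole-field flag,
since tooling conventions differ on whether overlap is computed over whole
split-channel images or thresholded regions; neither mode is claimed as
"the" published convention. A mode-of-histogram background estimator
(robust for puncta-sparse images) is provided for channels that arrive
without background subtraction. Line profiles are bilinear samples averaged
across a perpendicular width, with the distance axis in nm.

Colocalized-puncta counting detects local maxima in one channel (Gaussian
smoothing at the puncta scale, robust threshold with the same noiseless
fallback as the TIRF detector) and counts those whose label-channel mean
within one sigma exceeds a multiple (default 2×) of the label background
(in-mask median). Counting is per 2-D plane; volumetric counts are obtained
by summing planes, which may differ from a true 3-D segmentation when
puncta overlap in z.

## NMR profiles

Amide chemical-shift deviations between two states use
`sqrt(½(Δδ_HN² + Δδ_N²/25))`; the factor 25 down-weighting the nitrogen
difference is a fixed constant of the formula, not a parameter. Residues
missing an amide entry in either table (prolines, unassigned) propagate as
absent, never as zero — zeros would fabricate null deviations. Profiles
default to residues 1–102 because the acidic C-terminal tail does not
contact the micelle; the range is configurable.

Secondary carbon shifts subtract a sequence-corrected random-coil
reference. The packaged reference table carries the standard random-coil
CA/CB values per amino acid with optional nearest-neighbor corrections
(columns on the residue table) and linear temperature coefficients
(defaulting to zero); the whole table is swappable by config, since several
published coefficient sets exist.

Carbon re-referencing aligns a mutant dataset's carbon dimension to wild
type by the signed mean of (wt − mut) over all CA/CB shifts in a C-terminal
window (default residues 111–130, far from any structural perturbation),
requiring at least five carbon-bearing residues. The signed mean is used —
"minimizing the average difference" is read as zeroing it — which makes the
correction idempotent to rounding. Only carbon columns are shifted.

Lipid/free intensity ratios estimate the unbound fraction per residue:
vesicle-bound segments tumble with the vesicle and broaden beyond
detection. Residues whose lipid-free intensity falls below a floor are
excluded and listed; ratios above 1.1 are flagged. A four-parameter
logistic fit (bound level, unbound level, midpoint, width) locates a
binding boundary; the midpoint is the residue at which membrane attachment
is lost. Helix-region summaries default to helix-1 = 3–37 and
helix-2 = 45–92; these are labeled conventions for the broken-helix state,
not measured boundaries, and are fully configurable.

## Densitometry chain

Lane loading is corrected by the mean of three nonspecific-band densities:
each band density is scaled by (grand mean of lane loading means)/(lane
loading mean), with factors off by more than 25% flagged. Calibration is
ordinary least squares with a free intercept — blots commonly carry a
background offset — with a through-origin option. Interpolated
concentrations outside the standard range are flagged as extrapolation and
negative values floored at 0. The per-cell amount divides the lane's
protein mass (concentration × loaded volume) by its cell equivalents;
cellular concentration divides by the mean cell volume (default 2627 µm³,
an imaging-derived average; 1 pg/µm³ ≡ 1 g/ml) and the molar value by the
sequence molecular weight.

Molecular weights use average (not monoisotopic) residue masses minus one
water per peptide bond; extinction coefficients at 280 nm use 5500 per Trp,
1490 per Tyr and 125 per cystine with cystines defaulting to zero
(reduced protein) — consistent with the a-syn value 5960 = 4 × 1490. The
human a-syn sequence (UniProt P37840) ships as a packaged constant. Note
that 300 µg/ml converts to 20.7 µM at 14,460 Da while the commonly quoted
high-expression figure is the rounded 20 µM; the package reports full
precision plus a nearest-integer convenience field.

## Endocytosis quench curves

Curves are normalized so the pre-stimulation (t < 0) mean is 1. The
fractional quench is 1 minus the mean fluorescence over the final window
(default 100 s of a ~1500 s course); a final-window mean was chosen over a
single-point read for noise robustness, and an integrated (time-averaged)
statistic is available as an alternative that weights the whole course.
Relative endocytosis reports a test curve's fractional quench as a
percentage of its paired control's. Inputs are population-mean curves;
single-event cytometry streams, gating and compensation are out of scope.

## Synthetic-data generators

Each generator draws from one `numpy` Generator seeded by its config —
identical configs give bit-identical output, and `noise_sd = 0` gives the
noiseless model exactly. Defaults encode the study conditions: traces
sampled at 2 s over 600 s with stimulation at 20 s and NH4Cl at 420 s;
images at 100 nm/px so the 800 nm shell is 8 px; blot standards at 2, 3.5,
5, 6.5 and 8 µg/ml with 25 µl lanes of 7.5 × 10⁶ cell-equivalents/ml
lysate; quench courses of ~1500 s. Where the sources give no kinetic
constants (the stimulated rise, the quench rate, flash decay), generator
defaults are free parameters chosen at plausible scales and documented in
signatures, not measurements.

Specific modeling choices:

* the stimulated rise is a linear ramp (default 60 s) clamping exactly at
  its plateau, so noiseless percent-exocytosis closure is exact rather
  than asymptotic; an optional exponential reacidification term (suppressed
  by the bafilomycin flag) models endocytic re-uptake;
* puncta and flashes are symmetric Gaussians rendered by analytic
  integration over pixels (erf differences), giving exact sub-pixel mass
  ground truth; rendering windows are truncated at 4 sigma, which is what
  makes "disjoint supports" exactly disjoint;
* cell images place `round(f·n)` puncta centered in the shell band and the
  rest in the deep interior; tail leakage across the shell boundary makes
  the achieved intensity fraction deviate slightly from the target, so the
  generator records both the target and the fraction realized by the
  rendered noiseless image;
* mutant shift tables add a Gaussian bump (proton magnitude at the peak,
  nitrogen 5× — comparable weight under the 1/25 formula) plus a constant
  carbon offset emulating mis-referencing; binding profiles follow a
  logistic transition (width 1.5 residues) between the bound and unbound
  intensity-ratio levels;
* blot lanes share a multiplicative loading factor (CV configurable)
  encoded in the three nonspecific bands, so the loading correction can
  remove it exactly at zero band noise.

Noise is additive Gaussian only. The generators do **not** emulate
photobleaching, blinking, detector-specific noise (Poisson shot noise,
read noise), 3-D point-spread functions, cell-to-cell morphological
variability, or spectral bleed-through — so passing recovery tests
demonstrates the correctness of the estimators under the stated model, not
robustness to every artifact of real acquisitions.

## Validation problem sizes

The test suite and the acceptance script run the chains at desk scale:
50-seed trace ensembles at 2% noise, 20-seed TIRF movies (12 events each,
128×128×80 frames, SNR 10), 20-seed binding profiles at 3% intensity
noise, 10-seed blots at 5% loading CV with ~2% band noise, and single
noiseless fixtures for the exact oracles. These sizes were chosen to make
Monte-Carlo recovery statistics stable while keeping a full run in tens of
seconds.

## Known limitations

* The TIRF detector assumes temporally isolated, spatially sparse flashes
  on a quasi-static background; it is not a motion-corrected or
  crowded-field detector.
* Shell geometry is 2-D; confocal mid-plane sections are assumed
  representative, and no 3-D shell is computed.
* The binding-boundary fit assumes a single monotone transition; profiles
  with two detachment regions (e.g. a double proline mutant) need
  per-segment fits.
* The densitometry model is linear; chemiluminescence saturation and
  nonlinearity are the user's responsibility to avoid.
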