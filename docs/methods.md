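# Methods

## Measurement model

A Golgi stack is treated as three parallel fluorescent layers — the
cis-/medial marker, TGN38, and the protein of interest (POI) — offset along
the stack axis.  A line ROI drawn across the stack yields one intensity
profile per channel; each profile has a single dominant peak, and the
quantity of interest is the signed arc-length between peaks.

Orientation is fixed per stack by the cis→TGN direction: with s(c) the peak
arc-length of channel c and σ = sign(s_tgn − s_cis),

    d_ab = σ · (s_b − s_a),

which makes d_cis→tgn positive by construction, makes all three distances
invariant to the direction the line was drawn, and gives the exact identity
d_cis→poi = d_cis→tgn + d_tgn→poi.  Distances are reported in nm end to
end; the px→nm conversion comes from image metadata and fails loudly when
absent.

Out-of-plane tilt compresses every projected distance by cos(tilt), so
absolute inter-layer distances are unmeasurable from single sections; the
pipeline only ever interprets distances relative to TGN38 and to the
dataset-wide cis→TGN38 mean.  Tilt correction exists only inside the
simulator, where the tilt is known.

## Profile extraction

- Sampling: bilinear interpolation along the line at 0.5 px steps
  (configurable), averaged over `width_px = 3` parallel lines at unit
  perpendicular spacing.  Pixel centers sit at integer coordinates, origin
  top-left, x rightward, y downward.
- The sampling grid is anchored at the lexicographically smaller endpoint,
  so swapping the endpoints samples identical physical points and reverses
  the profile bit-exactly; peak positions are reported along this canonical
  orientation, making peak-to-peak distances bit-identical under line
  reversal.
- Normalization: per channel, per ROI, (I − min)/(max − min).  A constant
  channel maps to zeros and is flagged degenerate (not an error); any
  downstream peak request on it is an error.
- Smoothing: centered moving average, default window 5 samples, reflect
  padding, accumulated in symmetric pairs (so a reversed profile smooths to
  the bit-exact reversal).  The published protocol says only "normalized and
  smoothed"; method and window are explicit, configurable stand-ins recorded
  in output metadata.

## Peak localization and QC

The peak is the global maximum of the smoothed normalized trace, refined by
a three-point parabolic fit (displacement clipped to ±half a sample); a
plateau of exactly tied maxima returns the centroid of the tied run.
Prominence is peak height minus the higher of the two minima separating it
from the profile ends.

QC rejects a stack when any channel's prominence falls below 0.3
(normalized units), when a channel shows a secondary peak with at least 0.5
of the primary prominence (non-separated stacks), when the projected
cis→TGN axis is shorter than 2 pixels (edge-on stack), or when cis and TGN
peaks coincide exactly (orientation undefined).  The original exclusions
were made by eye; these thresholds are operational stand-ins and are
config-exposed.  Cells aggregate as the unweighted mean over their
QC-passing stacks (one data point per cell); cells with no passing stacks
are dropped with a logged exclusion.

## Classification relative to TGN38

Cell-level d_tgn→poi values are tested against zero: one-sample t-test when
Shapiro–Wilk p ≥ α, Wilcoxon signed-rank otherwise.  A protein is labeled
*overlapping* when the test is non-significant **and** |mean| is below
`overlap_fraction × reference` (reference = dataset-wide mean cis→TGN38
distance, computed separately per cis-marker identity); otherwise
*downstream* (mean > 0) or *upstream* (mean < 0).  Defaults α = 0.05,
`overlap_fraction = 0.25`.  No numeric rule is published for the three-way
grouping — it was read off pairwise comparisons — so this conjunction is
this package's operationalization; a significant but tiny offset is labeled
by its sign, and the decision record stores the p-value, effect floor and
mean so either reading of such borderline cases can be re-derived.  At
least 3 cells are required; fewer is an error.

## Group statistics

Per protein, the three distance samples (TGN38–POI, cis–TGN38, cis–POI) are
compared as independent groups (the published analysis ran unpaired
three-group tests even though the samples share cells — a caveat inherited
here).  Per-group Shapiro–Wilk at α = 0.05 gates the family: ANOVA + Tukey
when every group passes, otherwise Kruskal–Wallis + Dunn.  A constant group
has no defined Shapiro–Wilk statistic and routes to the nonparametric
family; a group with n < 3 is a hard error rather than a silent fallback.

The KW H statistic (tie-corrected, χ² reference with k−1 df), Dunn's
pairwise z tests (mean-rank differences with the pooled tie term, two-sided
normal p, Bonferroni over the 3 pairs — emulating the "Dunn's multiple
comparisons test" of common graphing software, which does not document its
adjustment), and the Tukey–Kramer studentized-range procedure are authored
in this package; scipy supplies only Shapiro–Wilk and the reference
distributions.  This keeps scipy's `kruskal`, `f_oneway` and `tukey_hsd`
available as independent cross-checks in the tests.  Significance stars
follow the ns/*/**/***/**** convention at 0.05/0.01/0.001/0.0001.

## Synthetic data generator

Each layer is an anisotropic 2D Gaussian (short axis σ = `ridge_sigma_nm`
along the stack axis, long axis set by `ridge_length_nm`).  Because a
Gaussian layer convolved with a Gaussian PSF is again Gaussian, layers are
rendered directly at the summed covariance — exact for this model and
fast.  Detection is Poisson photon counting plus additive Gaussian read
noise, emulating photon-counting confocal acquisition; `noise=False`
returns the expectation image for exact tests.  Tilt compresses offsets
only; intensity foreshortening is ignored (second order for thin layers).

Defaults, chosen once as plausible study conditions (none are published):

| parameter | default | rationale |
|---|---|---|
| pixel size | 40 nm/px | Nyquist-ish sampling for confocal at NA 1.4 |
| PSF σ | 90 nm (≈210 nm FWHM) | typical confocal lateral resolution |
| cis→TGN38 axial offset | 400 nm | sets the dotted-line reference distance |
| ridge length / σ | 600 / 60 nm | sub-µm stack footprint, thin layers |
| peak photons / background / read σ | 100 / 10 / 2 | peak SNR ≈ 10 |
| tilt | Uniform(0°, 30°) | stacks were hand-picked to lie near the image plane; E[cos tilt] ≈ 0.955 |
| per-stack layer jitter σ | 20 nm | biological variability between stacks |
| cells × stacks/cell | 15 × 3 | matches the published per-protein n of 14–18 cells; lines-per-cell unstated, 3 chosen |

Auto-generated ROIs run through the true stack center along the true
projected axis with a 600 nm margin beyond the outermost layer — fixed
before any measurement, mirroring how lines were drawn from the marker
channels without viewing the POI channel.

What the simulator does **not** emulate: 3D z-stacks, spectral
bleed-through, chromatic aberration, neuronal morphology, glial Golgi
overlap, antibody labeling stochasticity.  Passing tests therefore
demonstrate the *measurement machinery* is unbiased and calibrated under a
faithful geometric/noise model — not that any specific biological dataset
would reproduce.

## Validation experiments (benchmarks module)

- Noiseless, tilt-0 sweep over 25–400 nm offsets: recovered TGN→POI within
  max(0.5 px, 2%) of truth (observed max error < 0.01 px).
- Projection law: measured/true ratio within 0.02 of cos(tilt) for tilts up
  to 75°.
- Cohort recovery: truth +150 nm, 15 cells × 3 stacks, SNR ≈ 10, 100 seeded
  replicates — cohort mean within ±20 nm of truth × E[cos tilt] and
  classified downstream, each in ≥ 95% of replicates.
- Specificity: truth 0 labeled overlapping in ≥ 90% of replicates (the
  residual is the test's α plus rare jitter-driven excursions).
- Ordering: 50/100/200 nm proteins recover the rank order of cohort means
  in ≥ 95% of replicates.
- Null calibration: three groups from one Normal, 2,000 replicates —
  any-significant-pair rate within [0.03, 0.07].

Replicate counts (100 for cohort experiments, 2,000 for the null
calibration) are the package's chosen experiment sizes: large enough that
the rate estimates have standard errors of ~2 and ~0.5 percentage points
respectively, while keeping the full validation run in the low minutes on
one CPU.

## Numerical notes and limitations

- Bit-exactness guarantees (profile reversal, distance invariance) rely on
  the canonical-anchor sampling and symmetric pairwise accumulation above;
  they hold for any endpoints, and the default 0.5 px step is exactly
  representable so sample positions are exact.
- The parabolic refinement is biased toward the grid for very narrow peaks
  (σ ≲ 1 sample); with the default PSF and sampling, peaks span ≳ 5 samples
  and the bias is far below a nanometre.
- ImageJ `.roi` support covers straight-line ROIs only (best-effort
  adapter); CSV/JSON are the first-class ROI formats.
- The three group samples per protein are correlated through shared cells;
  the unpaired tests inherited from the original analysis are slightly
  conservative for the cis–TGN vs cis–POI contrast.
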