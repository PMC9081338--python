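# Methods

This note documents the models behind `fucci-cycle`: what the synthetic
data emulate, how each analysis stage works, which parameters matter, and
what the package's passing tests do and do not demonstrate about real data.

## Trace kinetics model

A FUCCI trace is generated as a piecewise deterministic profile plus noise.
The reporters show *patterns*, not published rate equations, so the simplest
shape reproducing all three cycling signatures is used:

- **G1** — mCherry at full scale, mVenus at zero, for a G1 duration drawn
  log-normal (mean `g1_duration_mean_h`, CV `duration_cv`).
- **G1/S hand-over** — over `onset_overlap_h` (default 1 h) mCherry falls
  linearly to zero while mVenus rises linearly to its plateau. This is the
  transient double-positive (YELLOW) window.
- **S/G2(/M)** — mVenus plateau for a fate-specific duration drawn
  log-normal with means 16.38 h (division), 17.29 h (binucleation) and
  24.5 h (polyploidization), CV `duration_cv` (default 0.15, chosen so the
  population SD is of the order of the reported between-cell spread).
- **Exit** — mitotic fates: linear mVenus collapse over `sharp_drop_h`
  (default 0.5 h), then mCherry recovery as daughters re-enter G1;
  G2 arrest: exponential mVenus decay with time constant `slow_decay_tau_h`
  (default 8 h) and linear mCherry re-accumulation starting at arrest, so
  Cdt1 reappears well before mVenus is lost.

Sampling is every 20 min (`sampling_interval_h = 1/3`) over 72 h. Noise is
multiplicative Gaussian on the signal (`noise_sd_frac`, default 0.1) plus a
residual background term (`background_level · N(0, noise_sd_frac)`), i.e.
traces are stored background-subtracted and may go slightly negative.

**Ground-truth boundary convention.** True onset/offset times are defined
as the instants the noiseless mVenus profile crosses 20% of its plateau
(`DETECTION_FRAC`), and the piecewise segments are placed so that the
configured S/G2(/M) duration is exactly that onset-to-offset span. This
makes "configured duration" and "operationally detectable duration"
coincide: a noiseless trace reproduces its configured boundaries at grid
resolution, with no hidden estimator bias from the finite rise and fall
times. The classifier's default `onset_frac`/`offset_frac` of 0.2 mirror
the same detectability convention but are independent settings.

Division and binucleation are kinetically identical (the measured durations
differ by less than their spread, and the trace shapes are the same); the
generator differentiates them only through the `post_mitosis_daughters`
annotation, exactly as an observer differentiates them by watching the
movie frames after mitosis.

Default fate mixture: 90.4 / 5.1 / 3.2 / 1.4 % (non-cycling / division /
binucleation / polyploidization), renormalized to sum to one (the printed
values sum to 100.1%). The G1 duration mean (10 h) is a free parameter with
no measured counterpart for these cells; it only needs to leave the cycle
comfortably inside the 72-h window.

## Phase-boundary detection and fate calling

Traces are smoothed with a centered 3-point median filter (removes
single-frame spikes without shifting crossings more than one interval).
The plateau reference is the mean of samples within 20% of the maximum —
using the raw maximum would inflate the reference by the expected extreme
of the noise and bias the crossing times (for the exponential tail, by
`tau·ln(peak_hat/peak)`, several tenths of an hour at 10% noise).

A trace is non-cycling when the plateau reference does not exceed a noise
floor of 5 robust sigma, where sigma is estimated from first differences
(`1.4826·median|Δ|/√2`), a shape-agnostic estimator.

Onset is the first crossing of `onset_frac`·plateau, offset the first fall
below `offset_frac`·plateau after the peak, and S/G2(/M) duration their
difference. Drop sharpness — the time from the last half-plateau sample to
offset — separates the mitotic collapse (0.3·`sharp_drop_h` ≈ 0.15 h,
quantized to ≤ 2 frames) from the G2-arrest decay (`tau·ln(0.5/0.2)` ≈
7.3 h at the default tau). The cuts (`sharp_drop_max_h` = 1 h,
`slow_decay_min_h` = 5 h) sit an order of magnitude apart from both
signatures, so classification is robust to the exact values. mCherry
re-entry — an upward crossing of the mCherry threshold strictly between
onset and offset — is an independent second vote for G2 arrest.

A trace whose mVenus is still high at the end of the movie has an
unobserved offset and is reported `mitotic-unresolved` rather than guessed.

## Snapshot images and quantification

Snapshots are discs of radius 5–8 px on a 640×480 default canvas (the
acquisition's binned frame size), placed without overlap by rejection
sampling (1000 tries per nucleus, then an error suggesting a larger image).
Channel levels: background 100, nuclear signal 1000, additive Gaussian
noise sd 20 (SNR 50 by default; tests also exercise SNR 5), optional linear
illumination gradient. No PSF, photobleaching or cell-shape model — these
images verify the *logic* of segmentation, background subtraction and
classification, not optical realism. Results on real micrographs depend
additionally on focus, overlap and staining variation that the generator
deliberately omits.

Segmentation ("adaptive") subtracts a Gaussian-smoothed background (scale
`block_size`) before Otsu thresholding, tolerating uneven illumination;
`global-otsu` thresholds the raw image. Objects outside
[`min_area_px`, `max_area_px`] are rejected, and border-touching objects
are discarded by default (they are partial and, after background
subtraction, edge artifacts can form thin border ridges). A
distance-transform watershed split for touching nuclei exists but is off by
default; the verification fixtures avoid overlap by construction.

Intensity measurement: per-nucleus mean minus a background estimate, floored
at zero. `local-annulus` (default) takes the mean over a ring of
non-nuclear pixels grown `annulus_px` = 3 px beyond each nucleus
(`skimage.segmentation.expand_labels` keeps the rings disjoint);
`global-percentile` uses the 5th percentile of non-nuclear pixels. Both are
automatable equivalents of drawing a background region per cell.

## FUCCI thresholds and states

Per-channel thresholds come from the intensity histogram. The default,
`otsu-on-log`, applies Otsu's criterion to `log(x + δ)` with
δ = 10⁻³·max(x) — the offset keeps floored zeros finite and compresses
sub-noise values without distorting the positive modes.
`quantile-mixture` fits a two-component Gaussian mixture on the log scale
and cuts at the equal-posterior boundary; if the fitted mixture has no
density dip between its component means (i.e. the histogram is unimodal),
it falls back to otsu-on-log with a warning. Values exactly at a threshold
classify negative — a deterministic tie rule.

The main parameter counts YELLOW nuclei as mVenus⁺ (they are, by the truth
table); `include_yellow=False` restores a GREEN-only numerator since the
convention used in the original screen is not stated.

## Screen pipeline

- **Site QC** — within each plate × timepoint, drop sites with
  `n_nuclei < mean − 2·SD` (one-sided: only low counts indicate focus
  failure). The averaging group is plate × timepoint; groups under 3 sites
  are passed through with a warning. SD is the sample SD (n−1) throughout.
- **Well aggregation** — main parameter on counts summed over retained
  sites (unbiased under unequal site populations); `site_combine="mean"`
  restores a mean-of-site-percentages convention. The two agree exactly on
  homogeneous sites.
- **Normalization** — percent of the plate-and-timepoint control-well mean;
  per-plate normalization protects against plate effects in the
  template/triplicate structure.
- **Treatment QC** — exclude a compound-timepoint when replicate SD exceeds
  half the replicate mean (equality retains; single replicates are flagged,
  not judged).
- **Timepoint selection** — argmin of control-well CV (100·SD/mean of the
  normalized values) across timepoints, ties toward the earlier timepoint.
  The 0-h baseline acquisition (pre-treatment) is excluded from selection.
- **Ranking** — descending normalized mean; ties by lower SD, then
  compound id.

The plate generator fills the 60 inner wells of a 96-well plate (outer
wells unused), 5 sites/well, Poisson(150) nuclei per site, acquisitions at
0/24/48/72 h, 3 replicate plates sharing the layout. Per site, states are
multinomial with a 5% reporter-negative fraction and a 10% baseline cycling
fraction of FUCCI⁺ (split 70/30 green/yellow); a compound's effect
multiplies the cycling probability at post-treatment timepoints. Dropout
sites (probability 0.02 by default, drawn per site-timepoint) have counts
scaled to 10% of the mean, far below the 2-SD cut.

## Ploidy analysis

DNA intensities of gated nuclei (marker⁺, optionally Ki-67⁻, thresholds
from the same histogram machinery) are modelled log-normal with class means
1:2:4. Boundaries come from a Gaussian KDE (Silverman bandwidth) on log
intensity: the dominant mode is the 2N reference; each boundary is the
density minimum between the expected positions of successive modes, or the
geometric mean (√2·mode, 2√2·mode) when no interior minimum exists (e.g.
an empty 8N class). 8N+ is open-ended; boundary values fall into the lower
class. Everything operates on ratios of intensities, so the analysis is
scale-equivariant and integrated vs. mean intensity only matters through
nuclear-area variation, which the generator does not model.

The population generator emits a fixed 5% marker-negative contamination so
that marker-channel thresholding is well-posed; binucleated cells
contribute two nuclei sharing a cell id, and per-cell nucleus counts give
the binucleation fractions.

## Reproducibility and problem sizes

Every generator is a pure function of (spec, seed); substreams are derived
with `SeedSequence` spawn keys so adding consumers never perturbs existing
draws. Both umbrella workflows are bit-reproducible from (config, seed).

The default verification sizes — 570-cell cohorts, 100 traces per fate for
duration estimates, 2000-nucleus snapshots, 96-well triplicate plates, and
100-fold seeded power simulations — were chosen to make binomial/multinomial
sampling error small relative to the tolerances tested while keeping the
whole suite a desk-scale computation (tens of seconds on one core).

## Known limitations

- The trace model has no track-breaking, migration, photobleaching or focal
  drift; real live-imaging fate calling inherits errors from tracking that
  are out of scope here.
- Division vs. binucleation requires the daughter annotation; the package
  never infers it from intensities.
- Snapshot realism is limited to what segmentation/classification logic
  needs; segmentation accuracy on real data is not predicted by these tests.
- The screen generator models compound action as a constant multiplier on
  cycling probability from 24 h on — no pharmacokinetics, toxicity or
  time-course shape.
- The G1 duration default and the sharp/slow cut values are declared
  package choices, not measured quantities.
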