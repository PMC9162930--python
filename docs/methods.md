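# Methods

## Measurement model

A stained biofilm imaged in cross-section yields, per region of interest
(ROI), a line profile of fluorescence intensity versus depth *z*. The
model assumed throughout is piecewise: a background plateau on the
electrode side (reflections and substrate autofluorescence), a bright
slab where the biofilm is, a second background plateau on the buffer
side, and optionally narrow bright spikes above the slab caused by
planktonic cells. The two backgrounds generally differ in level, which is
why all background handling is side-specific, split at the profile peak.

The biofilm is the set of samples whose intensity exceeds
`multiplier × mean(background)` for their side. Detectability therefore
requires `background < amplitude / multiplier`; when that fails (bright
substrates), the multiplier must be lowered (2 is the conventional
fallback) or the measurement is impossible and is reported as missing
(`no_signal`), never as zero.

## Boundary detection

1. **Pivot (anchor) selection.** Boundaries are searched outward from a
   pivot inside the biofilm. The raw intensity argmax is the natural
   pivot but is wrong whenever a planktonic speck outshines the slab, so
   the pivot is the peak of the contiguous bright run with the largest
   *integrated* intensity; a slab tens of samples long dwarfs any
   few-sample speck in summed signal. "Bright" for this step means above
   a coarse cut at `min + 0.25 · (max − min)`: background must sit below
   ⅓ of the slab amplitude for the measurement to be possible at all,
   and specks are bounded by a few times the slab amplitude, so the
   quarter-range level always falls strictly between background and
   slab. For speck-free profiles the pivot is exactly the argmax. Peak
   ties break to the smallest index (deterministic, matching a single
   stored peak column).
2. **Background means.** Each side's background is the mean over the
   outermost `background_window_fraction` (default 0.10, ≥ 1 sample) of
   that side's *sub-cut* samples. Restricting the window to sub-cut
   support keeps two artifacts out of the mean: the slab itself when the
   electrode margin is thinner than the window, and planktonic specks
   drifting through the outer buffer. Without a usable support (flat or
   near-flat profiles) the plain edge window is used. An optional
   iterative mode re-estimates the mean over all sub-threshold samples
   of the side to a fixed point.
3. **Thresholds.** `threshold = multiplier × mean(background)` per side;
   default multiplier 3. Comparisons are strict (`>` above, so boundary
   membership requires exceedance). Thresholds scale with the signal, so
   results are invariant under intensity rescaling.
4. **Upper boundary** (biofilm/buffer): the last sample of the contiguous
   above-threshold run containing the pivot. Bright samples beyond the
   first sub-threshold gap are planktonic artifacts: flagged
   `spike_rejected`, never included. Equivalent to scanning a
   consecutive row-number column of surviving samples for the first
   difference ≠ 1 past the peak (the data-table idiom with a duplicated
   first row); the test suite verifies this equivalence exhaustively.
5. **Lower boundary** (electrode/biofilm): by default the start of the
   same contiguous run — the gap-rejection principle applied to the
   electrode side. The alternative first-exceedance rule (first sample
   above threshold scanning from the electrode edge,
   `require_contiguity_below=False`) is the more literal reading of the
   historical definition but is fragile under noise: with detector noise
   at 5% of the slab amplitude it produces false-early boundaries on
   roughly a quarter of profiles (+1.6 µm mean bias in the validation
   runs), because a single noisy background sample above threshold
   captures the boundary. Both rules agree exactly on noise-free data;
   the run-based default simply refuses detached single-sample runs, for
   the same reason the upper boundary refuses detached specks.
6. **Thickness** = `z(upper) − z(lower)` in µm, orientation-normalized
   (electrode may sit at low or high *z*; boundaries are reported in
   z-order). If either boundary is undetectable the thickness is missing
   and the result flagged. `boundary_at_edge` marks runs touching the
   profile ends (truncated biofilms); `saturated` marks profiles
   reaching a configured detector full-scale.

Thickness spans the index difference in z-units (not the inclusive pixel
extent); at 0.5 µm sampling the distinction is half a step and the
convention is stated here once so numbers are comparable.

## Aggregation and statistics

- Image level: mean, sample SD (n−1), median, quartiles (linear
  interpolation), min/max over the measured ROIs of one z-image; missing
  ROIs are excluded and counted.
- Electrode level: unweighted mean of image means; SD across image means
  — the spread over sections scattered across the electrode, i.e. a
  coverage-homogeneity measure, deliberately not the pooled ROI SD.
- Condition level: mean ± SD across replicate electrodes.
- Correlation: Pearson *r* with two-sided p from
  `t = r·sqrt((n−2)/(1−r²))`, df = n−2 — the classical test used by the
  standard statistical routines; constant input is an error.
- Homogeneity report: per-position five-number summaries plus a
  descriptive flag for positions whose median falls outside the Tukey
  fences (Q1 − 1.5·IQR, Q3 + 1.5·IQR) of the pooled per-image medians.
  This is an exploratory indicator, not a hypothesis test.

## Synthetic data

The generator draws profiles from the same piecewise model the detector
assumes, which is exactly what makes it a ground-truth oracle and also
what limits it:

- Defaults mirror the study geometry: 185 µm image width, 10 ROIs,
  0.5 µm z-sampling over 80 µm, slab thickness in the 20–40 µm range,
  slab amplitude 100 with backgrounds 5 (electrode) and 8 (buffer) in
  arbitrary detector units — distinct levels chosen near the few-percent
  background typical of a well-exposed 8-bit acquisition.
- Noise is additive Gaussian, clipped at zero. Spikes are rectangular
  bumps on the buffer side, each separated from the slab by at least one
  background sample and placed pairwise disjoint (distinct floating
  cells; overlapping spikes would merge into a structure the model does
  not claim to represent).
- `recovery_experiment` snaps the true boundaries to the sampling grid
  by default: a boundary between two acquired planes is not representable
  in the data, and off-grid truths would charge the estimator up to one
  z-step per boundary of discretisation error no algorithm could remove.
  `snap_to_grid=False` includes that error for users who want it.
- Validation problem sizes: 200 profiles for noise-free recovery and
  spike robustness, 100 for noisy recovery, ~89 000 boundary scenarios
  for the oracle-equivalence grid (full value grid to length 7; one
  representative per above-threshold-mask × peak-position class to
  length 12, which exhausts every distinct boundary-search behaviour at
  a fixed threshold).

What passing these tests does **not** show: real profiles have sloped
backgrounds, depth-dependent attenuation, optical blur at the interfaces
and non-Gaussian detector statistics. The synthetic results validate the
logic (thresholding, gap rejection, aggregation), not the optics; on real
data the method's accuracy is bounded by how well the two-background slab
model fits.

## Numerical and degenerate-input choices

- Flat profiles: peak defaults to index 0, result is `no_signal` with
  missing thickness.
- Background windows never shrink below one sample; when a side has no
  background at all (biofilm touching the profile edge) the dimmest
  support samples available are borrowed and the result carries
  `boundary_at_edge`.
- Increasing the multiplier can only shrink the above-threshold run, so
  reported thickness is monotone non-increasing in the multiplier; this
  is property-tested.
- All RNG use is through explicitly passed seeds; there is no hidden
  global state, and seeded runs are byte-reproducible (the CLI writes a
  manifest with config, versions and input hashes).

## Known limitations

- One-dimensional by design: no biovolume, roughness or 3-D
  segmentation; thickness only.
- The two-background assumption fails for strongly sloped or drifting
  backgrounds; no detrending is applied (and none is part of the
  method).
- Proprietary microscope containers are out of scope; inputs are
  delimited-text exports (any common encoding/delimiter/decimal) or
  grayscale TIFF xz-sections.
- The deposited real-image line profiles are not redistributed here; the
  benchmark against their published per-condition means runs only after
  that dataset is downloaded (see `tests/test_acceptance.py`).
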