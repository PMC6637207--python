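# Methods

## Binding model

The fluorogenic probe is treated as a ligand L binding F-actin sites R
reversibly, L + R ⇌ C, with the bound complex C carrying essentially all of
the fluorescence (detachment quenches the probe >100-fold, so free ligand is
invisible). Two observation regimes are modeled:

* **Dissociation** (probe washed out at t0, signal normalized to the first
  frame): `dC/dt = kf·R_T·(C0 − C) − kr·C` with binding sites `R_T` in
  excess. Closed form: `C(t) = C∞ + (C0 − C∞)·e^(−(kf_d + kr)t)` with
  `C∞ = kf_d·C0/(kf_d + kr)` and `kf_d = kf·R_T`.
* **Association** (unstained cells, probe supplied in excess `L_T`):
  `dC/dt = kf_d·L_T − kr·C`, giving `C(t) = Ceq + (c_init − Ceq)·e^(−kr·t)`
  with `Ceq = kf_d·L_T/kr`, and the `kr = 0` limit is the linear ramp.

`kf` and `R_T` enter both equations only through their product, so they are
structurally unidentifiable separately; the package estimates the composite
`kf_d` and reports `kr/kf_d` as the turnover index (smaller = slower
turnover). Units are 1/min throughout; `C` is dimensionless after t0
normalization, `C0` is fixed at 1 for fitting (a free-`C0` option exists
for un-normalized data).

### Fitting

Estimation is sequential: `(kf_d, kr)` by least squares on dissociation
data, then `L_T` on association data with the rates held fixed — the
association solution is linear in `L_T`, so that step is a closed-form
one-parameter regression. The dissociation fit uses bounded
trust-region-reflective least squares from a fixed 5×6 start grid
(`kf_d` log-spaced over [1e-3, 10]/min; `kr` the same plus a 0 boundary
start covering the no-decay case). The grid is fixed so fits are
deterministic without a seed; the best SSE wins and SSE ties (within
`1e-10 + 1e-6·SSE`) resolve to the smaller `kr`. Standard errors are
linearized (Jacobian-based) at the optimum. Non-convergence and
unidentifiable `L_T` (when `kf_d = 0`) are flagged on the result, never
raised.

## Ratiometric decay pipeline (SMAT)

The measurement unit is the field of view: mean gray value over the whole
frame per timepoint (a per-mask option exists), no background, drift, or
photobleaching correction by default — the assay is a ratio, and an optional
constant background subtraction is available for synthetic stacks. Each
field trace is normalized to its own first timepoint (so every curve starts
at exactly 1 and the t0 SEM is 0), then replicate×field traces are averaged
pointwise with SEM (ddof = 1).

Statistics: a two-way ANOVA (condition × time, field traces as
observations) provides the omnibus test; the per-timepoint read-out is a
pooled-variance two-sample t-test of each condition against the reference
at every timepoint, Bonferroni-multiplied by the number of timepoints, with
the conventional star annotation (\*, \*\*, \*\*\* at 0.05/0.01/0.001).
This mirrors the per-timepoint posttest convention of common GraphPad-style
analyses of grouped time courses. Whether the ANOVA observation should be
the well or the field is ambiguous in such designs; the package treats each
field trace as an observation. For media-switch experiments the post-switch
window is re-normalized to the switch frame before comparison — the curves
have usually decayed substantially by the switch, and the scientific
question is how decay proceeds after the cue changes; a switch at t0
degenerates to the plain comparison.

## Dual-stain single-cell analysis (HCIA)

Segmentation: nuclei by Otsu threshold on the nuclear channel plus
connected components (small objects removed); cytoplasm by Otsu on the
summed SA+phalloidin signal; cells by watershed on the inverted distance
transform seeded by nuclei, so touching cells with separate nuclei are
split. Border-touching cells are excluded and counted.

The 41-feature panel (version `sa-ph-41-v1`) is a reconstruction — the
original descriptor list for this kind of assay is not public — fixed as
9 shape (area, perimeter, eccentricity, solidity, extent, major/minor axis
lengths, form factor `4πA/P²`, compactness `P²/4πA`), 3 intensity per
channel (mean, integrated, sd), and 13 Haralick co-occurrence statistics
per channel. Haralick settings: per-cell min-max quantization to 8 gray
levels inside the mask, distance 1, the 4 standard directions computed
separately and averaged; background pixels never contribute pairs (level 0
is reserved and its row/column discarded before normalization). Natural
logs; correlation and the information measures defined as 0 on
zero-variance patches; degenerate (e.g. single-pixel) regions yield NaN
texture and the cell is dropped with a logged reason. Note one exact
identity on symmetric co-occurrence matrices — sum variance = 4·variance −
contrast — which makes the full panel rank-deficient by one per channel;
downstream code is built to tolerate this (see below).

LDA is canonical discriminant analysis: features are z-scored with
training statistics (heterogeneous units would otherwise dominate the
scatter matrices), then the generalized symmetric eigenproblem
`S_B·a = λ·S_W·a` is solved; components are ordered by decreasing λ and
scaled so canonical scores have identity pooled within-group covariance,
with a deterministic sign convention. A singular `S_W` (the rank
deficiency above) triggers a ridge-regularized fallback, flagged on the
model. Classification is nearest group centroid in canonical space with
equal priors; percent correct is resubstitution by default (fit and score
on the same cells) with a stratified k-fold variant available — which of
the two an interactive stats package reports is not always stated, so both
are exposed and labeled. Ties go to the lowest group index.

Wilks' lambda is `det(S_W)/det(S_T)` with Rao's approximate F
transformation (for one feature and two groups it reduces exactly to the
one-way ANOVA F). It requires `n − groups > features`; the CLI falls back
to a full-rank feature subset (pivoted QR on standardized features, then
forest-ranked top-k if cells are still too few) and records the subset
size. Contour ellipses are bivariate-normal covariance ellipses of the
first two canonical scores, scaled to the χ²₂ quantile of the requested
coverage (0.5 by default, the "contains roughly half the cells"
convention). Predictor ranking is mean impurity-based importance over an
ensemble of bootstrap-resampled decision trees (200 by default),
deterministic given the seed.

## Synthetic data

The generators define the study conditions used by all tests:

* **Kinetics presets** (rates in 1/min, chosen to give late-time retained
  intensity AD > CH > OS ≈ BA and turnover index AD < CH < OS ≈ BA):
  BA (0.003, 0.030), OS (0.003, 0.027), CH (0.006, 0.018), AD
  (0.010, 0.010); `L_T = 1` for association runs. Drug, serum-switch,
  media-switch, passage (P12 slower than P5), and null (identical
  conditions) presets follow the same pattern. Switches change parameters
  mid-course with a continuous signal.
* **Trace noise**: additive Gaussian, sd 0.02 on the normalized signal,
  truncated at 0 — chosen once to give SEM bars of a few percent of the
  mean with 3 replicates × 4 fields, the realistic scale for field-level
  fluorescence ratios.
* **Time-lapse stacks**: 512×512 fields of ~30 textured elliptical cells
  (anisotropic Gaussian body × oriented stripe pattern) whose brightness
  follows the condition trajectory, multiplied by a per-frame illumination
  fluctuation (sd = trace noise) plus Poisson shot noise; the washed-out
  probe background is 1% of the mean initial field intensity, far below
  the 1% of per-pixel cell brightness implied by the probe's >100-fold
  fluorogenic contrast. Row-major, origin top-left, 0-based pixels; uint16
  multi-page TIFF, page order = time order.
* **Dual-stain populations**: each cell draws a 2-D latent (intensity
  balance, texture coarseness) around its condition's unit direction
  scaled by the per-timepoint effect size (default schedule 0.5 / 1.25 /
  2.5 latent units at pseudo-timepoints 1 h / 8 h / 24 h, condition
  directions BA at the origin and AD/OS/CH on the unit circle). The
  balance latent moves SA up and phalloidin down — the competing-probe
  logic, which makes per-cell SA and Ph totals anticorrelated — and the
  texture latent changes stripe wavelength. Shape parameters are
  condition-independent by design, so intensity/texture features, not
  shape, carry the class signal.

Determinism: every generator derives its stream from
`(scenario seed, stage key)` and iterates conditions in sorted order, so
outputs are byte-identical under a fixed seed, including after a scenario
YAML round-trip.

What the generator does **not** emulate: optics (no PSF convolution,
off-by-default by design), cell motility, division, focus drift,
illumination gradients, segmentation-hostile confluent layers, or
biological heterogeneity beyond the stated latents. Passing tests
therefore demonstrate the correctness and calibration of the *analysis*
under the stated noise model, not robustness to every real-microscopy
artifact.

## Problem sizes

Image-based tests and the acceptance script run scaled-down scenarios
(256×256 or smaller frames, 2 replicates × 2 fields, ~10–11 timepoints,
4 dual-stain fields per condition) so the whole suite completes in about a
minute; the package defaults remain the full-scale values above. Monte
Carlo sizes: 200 replicates for parameter recovery (noise sd 0.02, 15
timepoints), 500–1000 null simulations for calibration checks.

## Known limitations

* The 41-descriptor panel is a faithful reconstruction of the stated
  categories, not a verified copy of any specific instrument's list; exact
  feature-ranking reproduction is not claimed.
* The binding model is a whole-field scalar; no spatially resolved
  kinetics.
* Bonferroni posttests are conservative (the observed null flag rate is
  well below nominal), which is inherent to the convention, not a defect.
* `R_T` and `kf` cannot be separated by any fit to these data; only
  `kf_d = kf·R_T` is reported.
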