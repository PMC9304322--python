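# Methods

This note documents the models, conventions and numerical choices behind
`cmakit`, and what the synthetic validation does and does not establish.

## CMA activation index

Chaperone-mediated autophagy (CMA) activity cannot be measured directly in
bulk tissue, but the transcriptional state of the CMA gene network tracks
it.  The activation index for sample *j* is the weighted, direction-signed
average over the network genes:

    S_j = Σ_i d_i · w_i · z_ij / Σ_i w_i

with `w_i > 0` a per-gene weight (2 for the rate-limiting lysosomal
receptor LAMP2A, 1 for every other component), `d_i ∈ {+1, −1}` the known
effect of gene *i* on CMA (effectors positive, inhibitors such as RARα
negative), and `z_ij` the gene-wise z-scored expression.  Design choices:

- **Weighted denominator.** Dividing by `Σ w_i` rather than the gene count
  makes S a weighted average, giving the bound `|S| ≤ max|z|` and making
  subnetwork renormalization exact: scoring a matrix missing gene *g*
  equals scoring with the network minus *g*.
- **z-scores as input.** Standardizing each gene before averaging puts
  genes on a common scale so the signs are comparable; the scorer refuses
  matrices not in `zscore` state unless the caller explicitly overrides.
- **Missing genes** renormalize over the genes present, with a warning
  (`missing_policy="renormalize"`); a strict mode errors instead, for
  audits.
- **The packaged network table** (`data/cma_network_example.tsv`, 17
  entries) is an editable illustration.  The receptor weighting and the
  signs of the RARα axis follow the field's conventions; the remaining
  membership and directions are plausible but intentionally user-replaceable,
  and no claim is made that this exact table reproduces any published index
  values.

The co-repressor/receptor ratio (default NCOR1/RARA) is an element-wise
ratio on linear-scale expression; samples with non-positive denominators
are flagged, never dropped silently, and z-scored input is refused because
ratios of standardized values are meaningless.

## Expression preprocessing

- **IQR filter**: keep genes whose across-sample interquartile range
  strictly exceeds the threshold (default 0.5).  Quartiles use linear
  interpolation between order statistics (numpy's default, the common
  "type 7" rule) — stated here because different conventions move genes
  across the boundary.
- **z-scoring** uses the sample SD (n−1 denominator); `log_first` applies
  `log2(x+1)` for counts.  Zero-variance genes become all-zero rows with a
  warning.  An optional `reference_samples` argument standardizes by the
  mean/SD of a designated control group, expressing treatment shifts in
  control-noise units.
- **ΔΔCt**: technical replicates are averaged on the Ct scale first, then
  ΔCt = Ct_target − Ct_housekeeping per sample, ΔΔCt against the reference
  group's mean ΔCt, fold = 2^(−ΔΔCt).  Amplification efficiency is fixed at
  2 (no efficiency correction).  Fold changes are invariant to per-sample
  plate offsets by construction.

## Synthetic expression data and effect recovery

The generator draws per-gene log-scale baselines uniformly on [4, 12] and
adds Gaussian noise of SD `noise_sd`; treated samples are shifted by
`effect × noise_sd`, i.e. **effects are specified in z units**.  With
truth-standardization (`standardize="truth"`, dividing by the true
baseline/SD), the expected treated-minus-control score difference has the
closed form `Σ d_i w_i shift_i / Σ w_i`, which the Monte-Carlo recovery
check verifies over 200 datasets of 50 + 50 samples.

Why truth-standardization for this check: empirically z-scoring a matrix
that contains a real group shift absorbs part of the shift into the
per-gene SD (the between-group variance inflates it — a +1 z-shift with
balanced groups inflates the SD by ≈ √1.25), so no closed form holds for
the empirical pipeline; standardizing against the control group alone
removes that but leaves an O(1/n) small-sample bias from the estimated SD.
The empirical z-scoring path is therefore validated by its own exact
invariants (row means/SDs, filter/z-score commutation) rather than by the
closed-form recovery, which isolates the scoring algebra and generator
calibration.

## Reporter-field simulation and puncta quantification

The generator emulates two-channel high-content fields of a photoswitchable
KFERQ reporter: nuclei (disks, radius 6 px, dart-thrown so cells never
overlap) and reporter (diffuse cytosolic disk, radius 20 px, for expressing
cells; Gaussian puncta of σ = 2 px placed ≥ 5 px apart in the cytosolic
annulus).  SNR is defined as (punctum peak − cytosol mean)/noise SD, with
Gaussian read noise (SD 20 counts) on a 100-count offset, 16-bit output.
The expressing fraction sets an exact number of expressing cells; ground
truth lists every cell and punctum.

The analysis pipeline:

1. **Nuclei segmentation** — Gaussian smoothing (σ = 2), Otsu threshold,
   minimum-area filter (30 px), distance-transform watershed to split
   touching nuclei.
2. **Expressing-cell gate** — cytosol proxy is a 5 px annulus by label
   expansion (neighbors never share pixels); expressing iff the mean
   annulus intensity exceeds background mean + 3 SD, with background taken
   ≥ 24 px from any nucleus.
3. **Puncta detection** — scale-normalized Laplacian-of-Gaussian response
   (σ = 1.6), centered per cell on the annulus median and scaled by the
   field-wide robust MAD of the response; local maxima above 6 robust SDs
   within the cell's territory (expansion to 17 px, nucleus excluded) count
   as puncta, with a 2 px non-maximum-suppression radius.  The field-wide
   noise scale assumes spatially uniform detector noise; it is what makes
   counts exactly invariant under affine intensity rescaling.  A per-cell
   scale was rejected because punctum footprints can cover most of a small
   cytosol and defeat any robust local estimator.
4. **CMA+ classification** — strictly more than 3 puncta (4 counts, 3 does
   not); the percentage is computed over expressing cells only.  Reference
   per-line baseline counts (3–4 puncta/cell for NIH3T3/N2a, 5 for primary
   human fibroblasts) are retained as documentation constants, not gates.
5. **Field QC** — a field passes iff its nuclei count is at least 1/10
   (configurable) of the mean count across untreated control fields,
   boundary inclusive; applied per field.  This implements the stated
   purpose of the rule — excluding fields thrown out of focus by
   drug-induced changes in cell volume or adherence.
6. **Tandem reporter** — red-channel puncta are dual (autophagosome) iff
   their mean green intensity within 2 px beats the green background gate
   (median + 3 robust SD away from all puncta), else red-only
   (autolysosome); dual + red-only always equals total.

Detector parameters (σ, threshold, suppression radius) were tuned once
against the generator and frozen in `DetectorParams`.  On held-out seeds
the defaults give exact per-cell count agreement ≈ 97–100% at SNR 8 and
punctum precision/recall ≈ 0.98–1.0 at SNR 5.  What this does *not* show:
the generator renders symmetric Gaussian puncta on flat cytosols with
uniform Gaussian noise and non-overlapping cells; real fields have textured
cytoplasm, autofluorescence, overlapping cells and focal drift, so these
numbers are upper bounds on real-data performance, and no numerical
agreement with any published per-tissue puncta counts is claimed.

## Binding and pharmacokinetic models

- **FP titration**: default grid mirrors the bench protocol — top 10 µM,
  two-fold serial dilution, 12 points, 5 nM fluorescein-labeled probe.
  The default fit is the 4-parameter logistic in log concentration; the
  `one-site-depletion` model solves the exact binding quadratic for the
  bound fraction (relevant when receptor approaches the probe
  concentration at the curve foot) and reports EC50 = Kd + probe/2, the
  receptor concentration at half-maximal bound fraction.  Fits are flagged
  `extrapolated` when EC50 leaves the tested range and `unreliable` when
  the dynamic range is < 5× the residual SD.  Optional residual-bootstrap
  95% CI (seeded).
- **NCA**: Cmax/Tmax by inspection; AUC_last by linear trapezoid; terminal
  slope by least squares on log concentration over the last k points
  (k explicit, default 3, chosen for reproducibility over automated
  best-fit selection); t½ = ln 2/|slope|; AUC_inf = AUC_last +
  C_last/|slope|.  A non-negative terminal slope leaves t½/AUC_inf
  undefined and flags the result.
- **Unit conversion**: ng/g → µM as conc × density / MW (density default
  1 g/mL; molecular weights are user inputs).  Exact round-trip inverse
  provided.
- **Proteolysis**: percent degradation = 100 × acid-soluble /
  (acid-soluble + acid-precipitable) at the same chase time (the standard
  pulse-chase convention for the denominator); pathway fractions are
  plain differences of percentages, with negative differences flagged
  rather than clamped.

## Problem sizes

Validation runs use 200 expression datasets of 50 + 50 samples, 3–4 image
fields of 25 cells per SNR level, 100 noisy titration replicates and
~200-point PK grids — sizes at which every Monte-Carlo margin reported
above is several standard errors wide while the whole suite runs in well
under a minute per stage.

## Known limitations

- The shipped network table is illustrative; index values depend on the
  curated membership/direction table supplied by the user.
- The puncta detector assumes spatially uniform noise and 2-D fields; no
  3-D stacks, deconvolution or learned segmentation.
- PK noise is i.i.d. log-normal per time point; no between-animal
  variability structure.
- No hypothesis testing anywhere — the package computes estimates and
  flags, and leaves inference to the caller.
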