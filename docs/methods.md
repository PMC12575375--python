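# Methods

## Scope and model

`htpore` detects and quantifies circular, low-refractive-index (low-RI)
structures — pore-like transcellular regions — in holotomography (HT)
z-stacks of cultured endothelial cells, together with the nuclei and
nucleoli needed to express detections per cell. The pipeline is classical
pixel-level machine learning, not deep learning:

1. **Focus selection.** Each slice of a z-stack gets a scalar focus
   measure, the mean absolute response of the 2D Laplacian. Slices are
   selected when the measure exceeds `mean + n·std` of the whole stack,
   with `n` chosen as the largest of {3, 2, 1, 0} that selects at least one
   slice; a flat metric falls back to the argmax slice.
2. **Features.** Each selected slice is expanded into 34 per-pixel
   channels: the raw RI image; Gaussian-smoothed intensity at sigmas
   0.5–1024 px (doubling ladder, 12 scales); Gaussian gradient magnitude at
   0.5–32 px (7 scales); and the two eigenvalues of the Hessian of the
   smoothed image at 0.5–32 px (14 channels). "Kernel size" means Gaussian
   sigma in pixels.
3. **Classification.** A 200-tree random forest assigns each pixel one of
   four classes: background, circular structure (pore), nucleus, nucleolus.
   The pore class is thresholded on its probability map; nucleus and
   nucleolus masks use the per-pixel argmax.
4. **Calibration.** The pore threshold is the lowest point of the grid
   {0.01, …, 0.99} that maximizes the pixelwise F1 score of pore detection
   on a validation set.
5. **Instances.** The pore mask is labeled by a watershed on the negated
   Euclidean distance transform (seeds at distance maxima ≥ 5 px apart);
   labels with moment-ellipse eccentricity > 0.8 are discarded as false
   detections. Among the selected slices, only the one with the most
   structures is retained, so each field of view contributes one
   independent measurement.
6. **Quantification.** Cell number is the count of connected components of
   the nucleus ∪ nucleolus mask with area strictly greater than 185 µm²;
   per-field output is structure count, cell count, structures per cell,
   and the retained-slice area distribution in µm².

## Numerical choices

- *Focus measure.* "Mean of the 2D Laplacian" is read as the mean of its
  absolute value: the signed mean is ≈ 0 on any interior-dominated image
  and cannot rank sharpness. The variance is available as a config option.
  The standard deviation in the selection rule is the population (ddof = 0)
  one; the inequality is strict. Laplacian boundary handling is reflective.
- *Feature filters.* All Gaussian filters use reflective boundaries.
  Second derivatives for the texture channels are central differences of
  the smoothed image (gradient-of-gradient): unlike truncated
  derivative-of-Gaussian kernels, differencing exactly annihilates
  constant offsets, so a constant image yields exactly zero texture. Sigmas
  larger than the image extent are clamped to it with a warning.
- *Threshold grid.* Ties in the F1 search resolve to the lowest grid
  value. Positive prediction is `probability ≥ threshold`.
- *Eccentricity filter.* Strict `> 0.8`; single-pixel labels (degenerate
  moments) are removed with a logged reason. A minimum pore area (default
  4 px) is applied before the watershed to suppress single-pixel noise.
  When the minimum credible structure size is known — as it is for the
  synthetic fields, whose pore radii are drawn from a stated range — the
  recommended setting is about half the smallest structure's pixel area;
  the end-to-end tests use that rule.
- *Cell counting.* Components are 8-connected by default (4-connected
  available). The strict "more than 185 µm²" comparison carries a 1e-9
  relative guard so an area that equals the threshold in real arithmetic
  cannot leak through float round-off; one pixel is always many orders of
  magnitude larger than the guard.
- *Background subsampling.* Training uses every annotated pixel unless
  background outnumbers the rarest annotated class by more than 50:1, in
  which case background is subsampled with the model seed. Forest
  hyperparameters other than `n_estimators = 200` stay at scikit-learn
  defaults and are serialized with the model.

## The synthetic phantom

Real annotated HT crops are not distributable, so the package ships a
generator whose output is fully annotated by construction. One field of
view renders non-overlapping adherent cells on a virtual coverslip as a
float32 RI stack (default 70 slices, 0.2 µm XY and 1 µm Z pitch):

- watery background, RI 1.337; cytoplasm slab 1.365; nucleus 1.355 with
  1–3 nucleoli at 1.39; bright lipid-like vesicles at 1.42 as distractors;
- pore-like structures as circular cylinders of background RI spanning the
  whole z-extent of their parent cell (transcellular), radii uniform in
  0.5–1.5 µm, count per cell Poisson with mean 15;
- cells as radially perturbed ellipses (radius 13–16 µm) sitting on a
  common substrate two slices below the focal plane, thickness 6–12
  slices; nuclei 205–250 µm², i.e. above the 185 µm² counting rule;
- optics: slice `z` is blurred laterally with
  `sigma = 0.6 px + 0.5 px · |z − focal|` (normalized Gaussian, reflective
  boundary, per-slice mean preserved), then additive Gaussian RI noise
  (sd 0.003) is applied.

The RI values are design choices following the qualitative ordering seen
in holotomograms of these cells (pores ≈ background < nucleus < cytoplasm
< nucleolus ≤ vesicle); magnitudes are typical of quantitative phase
imaging of mammalian cells and are configurable everywhere.

All randomness derives from one master seed through named
`numpy.random.SeedSequence` child streams (cell geometry, pores, vesicles,
noise), so identical specs give bit-identical stacks and truth.

What the phantom does **not** emulate: coherent/speckle noise, the true HT
transfer function (defocus is a Gaussian stand-in), cell-to-cell RI
heterogeneity, organelle texture inside compartments, touching or
overlapping cells, and sub-resolution fenestrae (50–300 nm); generated
pores are ≥ 0.5 µm so they are resolvable at the stated pixel pitch.
Passing benchmarks on phantoms therefore demonstrates the correctness and
stability of the pipeline machinery, not transferability to real
microscope data, which requires retraining on hand-annotated crops.

## The synthetic benchmark

`htpore.benchmark.run_benchmark` emulates the train/validate/test design
used with hand-segmented crops: 8 training fields, 1 validation field
(threshold calibration) and 1 held-out test field, all with the default
spec above and per-field seeds derived from one master seed (42 in the
shipped configuration). The annotated slice of each field is its focal
slice. Reported numbers are one-vs-rest AUROCs over the pooled test-field
pixels for the pore, nucleolus and nucleus classes, at roughly 240/30/30
annotated structures across the three splits — a deliberately scaled-down
problem size chosen so the whole benchmark trains in minutes on one CPU.
The acceptance tests assert the AUROC floors 0.95 (pore), 0.88
(nucleolus) and 0.76 (nucleus); on the shipped configuration all three
classes exceed them with a wide margin.

## Known limitations

- Nuclei touching each other merge into one counted component; no
  watershed is applied to nuclei.
- The classifier is slice-wise 2D; no 3D features or 3D instance linking.
- Evaluation pools pixels, so AUROC is dominated by large classes'
  boundaries; per-structure detection rates are only exercised by the
  end-to-end count-recovery tests.
- Real HT data must carry pixel-size metadata or an explicit override;
  areas are refused otherwise.
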