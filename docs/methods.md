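# Methods

## Problem and model

`ihcquant` quantifies the amount of DAB (3,3′-diaminobenzidine) chromogen in
brightfield images of hematoxylin-counterstained, immunostained tissue and
compares the resulting per-sample signal between normal and tumor groups.
The target use case is stromal markers (e.g. proteoglycans such as decorin)
whose expression differs between normal connective tissue and the tumor
microenvironment; the pipeline itself is stain-target-agnostic.

The optical model is the Beer–Lambert law in base-10 optical density (OD).
With background (glass) intensity `I0` and transmitted intensity `I_c` in
channel `c`,

    OD_c = log10(I0 / I_c) = sum_s  a_s * M[s, c]

where `a_s` is the amount of stain `s` at that pixel and `M` is a 3×3 matrix
of unit-length stain OD vectors (hematoxylin, DAB, residual). Unmixing
("color deconvolution") recovers `a = OD · M⁻¹` per pixel; the DAB plane of
that concentration image is the quantified signal. The default basis is the
standard published H-DAB calibration, hematoxylin ≈ (0.65, 0.70, 0.29) and
DAB ≈ (0.27, 0.57, 0.78), with the residual axis their normalized cross
product; a user matrix can be loaded from a 3×3 CSV. Blind stain-vector
estimation (Macenko/NMF) is out of scope.

Per image the measurement chain is:

1. **Tissue mask** — pixels whose summed OD exceeds `tissue_od_threshold`
   (default 0.06), holes filled, components < 64 px dropped. This separates
   tissue from blank glass so area fractions have a denominator.
2. **Unmixing** — OD conversion with the white point fixed at 255 (no
   per-image white estimation, for determinism), then `OD · M⁻¹`.
   Small negative concentrations caused by noise are kept at this stage so
   unmixing stays exactly linear; they are clipped to 0 at quantification.
3. **Automatic threshold** — Otsu's method on the DAB concentrations of
   tissue pixels, 256 bins: the histogram bin edge maximizing the
   between-class variance `w0·w1·(μ0−μ1)²`, ties broken toward the lower
   edge. Ties arise whenever candidate edges are separated only by empty
   bins; a 1e-10 relative tolerance on the maximum keeps summation-order
   noise from deciding such a tie. A triangle-method threshold and a fixed
   threshold are available as configuration options.
4. **Threshold floor** — automatic thresholds are floored at 0.05 OD.
   8-bit quantization perturbs a channel's OD by up to `0.5/(I·ln10)`, and
   the H-DAB inverse amplifies that by at most ≈ 2.81 (its largest column
   L1 norm), giving ≈ 0.024 OD of unmixing residue at worst. In a sample
   with no real DAB an unfloored automatic threshold would split that
   residue and call noise positive; 0.05 OD sits above the residue and an
   order of magnitude below chromogen signal (~0.5–1.5 OD).
5. **Segmentation and particles** — positive pixels are
   `(DAB > threshold) ∧ tissue`; connected components (8-connectivity by
   default) smaller than `min_particle_size` (default 4 px, suppressing
   single-pixel noise) are discarded. Each particle carries pixel count,
   centroid, and integrated OD.
6. **Sample metrics** — particle count, DAB area fraction (positive px /
   tissue px), mean OD per positive pixel, integrated OD, tissue area, and
   the threshold used.

An `invert_signal` operation (`max − x`) is provided for intensity-space
workflows where DAB appears dark; in the OD pipeline the concentration
plane is already signal-positive, so inversion is not applied there. Note
that double inversion returns `x − min(x)`, i.e. it is an exact involution
only for images whose minimum is 0.

## Cohort comparison

Per-sample metrics are aggregated into a montage-ordered table (normal
sample first within each tissue). For each tissue the normal and tumor
groups are contrasted by arithmetic means of the DAB area fraction
(integrated OD selectable), their difference and ratio, and a descriptive
two-sided rank-sum p-value (exact when the smaller group has ≤ 8 samples,
normal approximation otherwise). No multiple-testing correction or
significance threshold is applied: the p-value is reported, not judged.
The area fraction is the primary metric because it is robust to
illumination scale; integrated OD is an option for intensity-weighted
questions. Two figures summarize the cohort: a 3-D surface of the DAB
concentration planes block-averaged onto the montage grid, and a
per-sample bar chart in montage order, in which (for the expected biology)
every within-tissue peak is the normal sample.

## Synthetic data generator

The generator emulates one tissue-microarray core: a centered tissue disc
(radius fraction 0.9 of the half-frame) on a white background, elliptical
hematoxylin nuclei (default 80 per 512×512 frame, semi-axis ≈ 5 px, OD
0.8), a faint uniform hematoxylin wash over the disc (OD 0.12 — an
unstained disc would be invisible in brightfield, and real stroma always
carries some counterstain), and diffuse DAB regions formed as the union of
discs whose common radius is bisected until the union covers the requested
fraction of tissue area (tolerance: 0.5% of tissue area, tightened to 5%
of the target for very small targets). Concentrations add where nuclei and
DAB overlap, which exercises the unmixing rather than mask logic.
Rendering follows the same Beer–Lambert model as the analysis, so
generator and unmixer are exact inverses up to 8-bit quantization;
acquisition noise is additive Gaussian in intensity space (clipped to
[0, 255]), with shot noise out of scope. A `dab_disjoint` mode enforces a
minimum separation between blob centers so the true blob count is exact
ground truth for particle counting.

Ground truth per sample: the DAB and tissue masks, their exact area ratio,
the connected-blob count, and the true concentration maps. Everything is
driven by `numpy.random.default_rng(seed)`, so identical configurations
give bit-identical images; cohort generation draws per-sample seeds from
the cohort seed.

The default synthetic cohort mirrors the normal-versus-tumor design being
emulated: 12 tissues (bladder, breast, cervix, colon, kidney, ovary,
pancreas, prostate, rectum, skin, stomach, testis), one normal and three
tumor samples per tissue, stromal DAB fraction 0.4 in normal and 0.1 in
tumor samples, noise SD 5 intensity units.

What the generator does **not** emulate: real tissue texture and
morphology, stain heterogeneity within a deposit (DAB OD is uniform inside
a region), chromatic camera effects, JPEG artifacts, and out-of-focus
blur. Passing tests therefore demonstrate the correctness of the
measurement chain under the stated optical model, not robustness to every
property of real histology; on real images the dominant additional error
sources are stain-vector mismatch and compression.

## Numerical choices

- **Quantization bound.** Rounding to 8 bits perturbs a channel OD by at
  most `0.5/(I·ln10)`; through the H-DAB inverse the per-stain error is
  bounded by ≈ 2.81× that. Concentration round trips are therefore
  verified to < 0.02 OD for per-stain amounts up to 0.75 (max channel OD
  ≈ 0.95, worst-case predicted error ≈ 0.017, measured ≈ 0.014); at
  channel OD 2 the same quantization already costs ≈ 0.085 OD per channel,
  so no sub-0.02 claim is possible there.
- **Zero-intensity regularization:** intensities are clamped to ≥ 1 before
  the log, bounding OD at log10(255) ≈ 2.41.
- **Stain matrices** are validated at construction: unit rows to 1e-6 and
  condition number below 1e6, otherwise a named error.
- **Degenerate thresholds:** a constant plane has no Otsu threshold and
  raises; the pipeline maps that case to the 0.05 OD floor (nothing is
  positive in a flat, signal-free plane).
- **Determinism:** figures are written without timestamp metadata; CSVs
  carry `# seed=… # config_hash=…` headers, with output directory and log
  level excluded from the hash so identical analyses hash identically.

## Problem sizes

Unit and acceptance checks run at desk scale, chosen as the package's own
test design: 64×64 frames for unmixing round trips and threshold-oracle
comparisons, 160×160 frames (≈ 16,300-pixel tissue discs, 20–30 nuclei)
for recovery, ladder, and cohort properties, and 128×128 frames for the
end-to-end determinism rerun. The generator's own defaults (512×512, 80
nuclei) are used by the CLI.

## Known limitations

- The two-stain + residual model cannot separate a third real chromogen;
  more than three stains are out of scope.
- Otsu assumes a roughly bimodal DAB histogram within tissue; a tissue
  that is entirely DAB-positive (no negative class) will be
  under-thresholded. The fixed-threshold mode covers that case.
- Per-image thresholds maximize within-image contrast but are not
  comparable across images in absolute terms; a global-threshold mode via
  `threshold_mode: fixed` is the cross-sample alternative.
- The rank-sum p-value with 1 normal vs 3 tumor samples has a minimum of
  0.5; with the emulated montage design it is descriptive only.
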