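# ihcquant

Quantification of DAB immunostaining in brightfield histology images, with
normal-versus-tumor comparison of stromal protein expression.

Immunohistochemistry marks a protein with the brown chromogen DAB
(3,3′-diaminobenzidine) on tissue counterstained blue-purple with
hematoxylin. For stromal markers — e.g. small leucine-rich proteoglycans
such as decorin, deposited by fibroblasts in connective tissue — a central
question is how much signal a sample carries and how that amount differs
between normal tissue and the tumor microenvironment. `ihcquant` answers it
with a fully automatic, deterministic pipeline:

1. **Stain separation.** Under the Beer–Lambert law, optical density
   `OD_c = log10(I0 / I_c)` is linear in stain amounts:
   `OD = a · M`, where `M` is a 3×3 matrix of unit stain vectors
   (hematoxylin, DAB, residual). Color deconvolution `a = OD · M⁻¹`
   recovers the per-pixel DAB concentration.
2. **Automatic thresholding.** Otsu's method (maximal between-class
   variance, ties toward the lower edge) on the DAB plane over tissue
   pixels defines DAB-positive pixels.
3. **Particle analysis.** Connected components of the positive mask are
   counted and measured (area, centroid, integrated OD) and summarized per
   sample as particle count, DAB area fraction, mean and integrated OD.
4. **Cohort comparison.** Per-tissue normal-vs-tumor means, differences,
   ratios and descriptive rank-sum p-values, plus a surface plot of the
   DAB signal over the sample montage and a per-sample chart in which each
   within-tissue peak is — for the expected biology — the normal sample.

A synthetic H-DAB generator renders tissue-microarray-style cores (tissue
disc, nuclei, diffuse stromal DAB with a controlled area fraction) through
the same optical model, providing exact ground truth for every stage; see
`docs/methods.md` for the model, parameters and limitations.

## Worked example

```python
from ihcquant import SyntheticConfig, generate_sample, quantify_image

cfg = SyntheticConfig(image_height=160, image_width=160, nucleus_count=30,
                      dab_target_fraction=0.4, noise_sd=5.0, seed=11)
img, truth = generate_sample(cfg)           # synthetic "normal stroma" core
metrics, dab_plane, mask = quantify_image(img)

print(f"true fraction      {truth.true_dab_fraction:.4f}")
print(f"measured fraction  {metrics.dab_area_fraction:.4f}")
print(f"particles          {metrics.particle_count}")
print(f"threshold (OD)     {metrics.threshold_used:.3f}")
print(f"mean DAB OD        {metrics.mean_dab_od:.3f}")
print(f"tissue area (px)   {metrics.tissue_area}")
```

prints

```
true fraction      0.3989
measured fraction  0.3981
particles          2
threshold (OD)     0.515
mean DAB OD        1.016
tissue area (px)   16292
```

The generator placed DAB over 39.89% of the tissue disc; the pipeline,
given only the noisy rendered image, measured 39.81% — the Otsu threshold
(0.515 OD) sits midway between the background and the ~1.0 OD deposits,
whose mean measured density is 1.016.

The same chain runs from the shell. `ihcquant run` simulates a 12-tissue
cohort (1 normal + 3 tumor samples per tissue, stromal DAB fraction 0.4
vs 0.1), quantifies every image, and writes `metrics.csv`,
`contrasts.csv`, a chart and a surface plot:

```sh
ihcquant run --out demo_run --seed 1
ihcquant quantify --manifest demo_run/manifest.csv --out my_metrics.csv
ihcquant compare --metrics demo_run/metrics.csv --out demo_cmp
```

Real images are analyzed by pointing `ihcquant quantify` at a manifest CSV
with columns `sample_id, tissue, group, path` (group ∈ normal | tumor); a
custom stain basis can be supplied with `--stain-matrix basis.csv`.

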