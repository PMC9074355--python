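# ki67flow

Digital assessment of the Ki-67 proliferation index in brightfield
H-DAB immunohistochemistry, built as a reproducible pipeline with a
synthetic-tissue test bench.

## The problem

Ki-67 is a nuclear antigen expressed by proliferating cells; the
fraction of Ki-67-positive tumour cell nuclei is a prognostic marker in
breast cancer. Scoring it is notoriously method-sensitive: a
pathologist counting 500 cells at the microscope in a visually chosen
hotspot (visual assessment, VA) and software counting 500 cells in a
digitally identified hotspot (digital image analysis, DIA) can put the
same tumour on different sides of a treatment cut-off. This package
implements the digital arm end to end and the statistics used to
compare scoring arms on a cohort, so the behaviour of the workflow can
be studied quantitatively on data with known ground truth.

The pipeline follows the QuPath-style workflow:

1. **Colour deconvolution.** Transmitted intensity follows
   Beer–Lambert: `I_c = I0 · 10^(−Σ_s c_s v_{s,c})` for stains *s* with
   unit optical-density vectors `v_s`. Converting to optical density
   `OD_c = −log10(I_c / I0)` makes pixels linear in stain amounts;
   inverting the 3×3 stain matrix (hematoxylin, DAB, residual) gives
   per-stain concentration maps. Per-image stain vectors can be
   re-estimated from the image itself.
2. **Watershed nucleus detection** on the OD-sum channel with the
   published parameter set (requested pixel size 0.4 µm, background
   radius 8 µm, median radius 1.5 µm, Gaussian σ 1.5 µm, area
   10–350 µm², threshold 0.02, max background intensity 3.0, cell
   expansion 5 µm), then per-nucleus shape and stain features and their
   spatially smoothed variants (25/50/100 µm).
3. **Two-class classification** (tumour vs non-tumour nuclei) with a
   random-forest ensemble trained on annotated nuclei using a 67/33
   equally spaced train/test split.
4. **Positivity calling**: a nucleus is Ki-67 positive iff its mean
   nuclear DAB OD ≥ 0.15.
5. **Hotspot scoring**: a heat map of the 50 µm-smoothed nuclear DAB OD
   seeds five disjoint, density-ordered increments of 100 tumour
   nuclei; the cumulative percentage after k increments is the
   Ki-67 score at 100k cells.
6. **Cut-offs and cohort statistics**: St. Gallen-style in-house
   cut-offs at the cohort median ± 10 percentage points
   (Low < median−10, High > median+10, Intermediate between,
   boundaries inclusive to Intermediate); reclassification transition
   tables; Bland–Altman agreement; Pearson χ²; Aalen–Johansen
   cumulative incidence of breast-cancer death with other-cause death
   as a competing event; Gray's test; cause-specific Cox models;
   Harrell's C.

Because no suitable public dataset pairs IHC images with per-nucleus
ground truth, the package ships a first-class synthetic generator:
stained scenes with tumour/stroma/lymphocyte nuclei, a spatial
positivity field with hotspots, and exact per-nucleus truth; plus
patient cohorts with grade, mitotic count and cause-specific survival
linked to true Ki-67.

## Worked example

```python
import ki67flow as kf

config = kf.SceneConfig(width_um=450.0, height_um=450.0, n_tumour=700,
                        n_stroma=250, n_lymph=150, base_positivity=0.15,
                        hotspots=(((150.0, 150.0), 90.0, 0.85),),
                        noise_sd=2.0, seed=11)
rgb, truth = kf.simulate_scene(config)
od = kf.rgb_to_od(rgb, pixel_size_um=config.pixel_size_um)

detections = kf.detect_nuclei(od)
kf.measure_features(detections, od)
kf.smooth_features(detections)
# ... train on truth-matched labels, classify, call positivity ...
heatmap = kf.build_heatmap(detections)
sets = kf.select_increments(detections, heatmap)
print([s.n_positive for s in sets])
print(kf.cumulative_percentages([s.n_positive for s in sets]))
```

Running `examples/03_classify_and_hotspot.py` (the full version of the
snippet) prints:

```
classifier held-out accuracy: 99.1% (948 training objects, 67/33 equally spaced split)
hotspot found at (147, 147) um (true hotspot centre at (150, 150) um)
positive counts per 100-cell increment (rank 1..5): [46, 17, 21, 15, 12]
cumulative Ki-67 %: (46.0, 31.5, 28.0, 24.8, 22.2)
```

The hotspot is localized to within one grid cell of the true centre,
and the cumulative Ki-67 percentage falls from 46% after the first
(hottest) 100 cells to 22% after 500 — the count-depth dependence that
makes cut-off calibration method-specific. The other scripts in
`examples/` walk through simulation, deconvolution/detection, cohort
scoring with median-derived cut-offs, and the competing-risks survival
statistics.

A thin CLI mirrors the library:
`ki67flow simulate-image | simulate-cohort | detect | train | classify |
hotspot | score | stats | run`, each taking `--config`, `--seed`,
`--out`.

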