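# Methods

This note documents the models, parameter choices and numerical
conventions behind ki67flow, and what its synthetic experiments do and
do not establish about real tissue.

## Stain model and colour deconvolution

Brightfield transmission is modelled by Beer–Lambert absorption:
`I_c = I0 · 10^(−OD_c)` with `OD = c_H v_H + c_DAB v_DAB` for unit
stain vectors `v`. `rgb_to_od` computes
`OD_c = −log10(clip(I_c, ε, I0)/I0)` with ε = 1 intensity unit; ε only
guards `log(0)` at fully absorbed pixels (the additive form
`(I+ε)/I0` would bias every OD value by up to ~0.004 and break the
exact inverse relationship with rendering). Deconvolution solves the
3×3 system per pixel; negative concentrations are clipped to zero and
the clipped fraction logged, rather than reprojected — clipping is
monotone and easy to reason about.

The default H-DAB basis is the standard published one
(H ≈ (0.65, 0.70, 0.29), DAB ≈ (0.27, 0.57, 0.78)). The residual
vector is the *true* normalized cross product of the two dye vectors,
which carries one negative component. Forcing it nonnegative (taking
absolute values) pushes it back toward the dye plane and raises the
stain-matrix condition number from ~3 to ~140, amplifying unmixing
noise ~50-fold; the dye vectors themselves remain nonnegative.

`estimate_stain_vectors` assigns foreground pixels
(OD-sum > 0.15) to their dominant stain under the default basis,
keeps the purest quartile of each group (pixels whose dominant
concentration share is highest), and takes the angularly trimmed
(default 5%) mean direction. On tissue where every DAB-positive
nucleus also carries counterstain there are no pure DAB pixels, and
any estimator of this family is biased toward the mixture direction;
recovery to ~2° requires near-pure pixels of each stain, which the
tests provide through a calibration-style fixture.

## Synthetic scenes

Nuclei are ellipses placed by a hard-core point process (sequential
rejection on a neighbour grid; the required centre distance between
two nuclei is the mean of their class spacings). Class morphology
defaults are histologically motivated: tumour nuclei ~80 µm²
(40–180), eccentricity 0.3–0.7, spacing 9 µm; stromal nuclei ~40 µm²,
elongated (0.85–0.93), spacing 8 µm; lymphocytes ~33 µm², round,
spacing 6 µm. Staining: hematoxylin ~N(0.70, 0.08) (tumour),
N(0.55, 0.08) (stroma), N(0.90, 0.08) (lymphocytes); Ki-67-positive
tumour nuclei add DAB ~N(0.55, 0.08) truncated at 0.30, negatives
carry none. The bimodal DAB distribution (0 vs ≥ 0.3) makes the
0.15 positivity threshold unambiguous on clean renders.

Tumour positivity is Bernoulli in a spatial field: a base rate plus
Gaussian hotspot bumps `(peak − base) · exp(−d²/(2(r/2)²))` for a
hotspot of nominal radius r. Rendering rasterizes per-nucleus
concentrations (overlaps add, as projected absorbance does), applies
Beer–Lambert per pixel at 0.23 µm/pixel (the scanner resolution the
workflow targets), and optionally adds Gaussian RGB noise
(σ = 2 intensity units in most experiments). Rendered images are kept
as floats; quantizing to 8 bits costs the exact round-trip identity
but nothing else.

What the generator does **not** emulate: chromatin texture,
out-of-focus blur, folds and staining artefacts, nucleoli, overlapping
3-D tissue, uneven illumination. Passing tests therefore demonstrate
correctness of the algorithms under the stated stain model, not
segmentation robustness on real slides.

## Detection

The pipeline resamples the OD-sum channel to 0.4 µm, estimates
background by morphological opening (8 µm radius disk, sequence
decomposition) and subtracts it, excludes pixels whose background
exceeds 3.0 (dense artefacts), median-filters (1.5 µm), Gaussian
smooths (σ 1.5 µm) and thresholds at 0.02. The object mask comes from
the *median-filtered* channel (edge-preserving, so boundaries stay on
the stained area); the Gaussian-smoothed channel additionally gates
foreground. Touching nuclei are split by a marker-controlled watershed
on the smoothed Euclidean distance transform of the mask, markers
being its local maxima with ≥ 4 µm separation. A distance transform
rather than image intensity drives the split deliberately: absorbance
is additive, so where two nuclei overlap the image is *brighter* than
either nucleus and intensity watershed lines cannot form between them.
Components are filtered to 10–350 µm² and traced to counterclockwise
polygons in physical micrometres (origin top-left, y down).

Cell expansion dilates each nucleus by 5 µm clipped against the
nearest-nucleus partition (computed on a 0.4 µm raster via the exact
Euclidean distance transform), so cell polygons never overlap and
shared boundaries are equidistant. Intensity features are measured
over the nucleus mask eroded by 0.3 µm: polygon tracing overshoots by
a fraction of a pixel and the background ring would otherwise dilute
per-nucleus stain means by ~5%. Perimeter (and hence circularity
4πA/P²) uses the Crofton estimate to correct the ~5% staircase bias
of traced contours. Feature smoothing over neighbours uses weights
`exp(−d²/(2(r/2)²))` for radii 25/50/100 µm, self included, making
smoothed values convex combinations of raw ones; the r/2 scale is
recorded so smoothed features are reproducible.

## Classification and positivity

The two-class (tumour vs other) classifier is a random forest
(200 trees, fixed seed) over all measured features and their smoothed
variants. The "equally spaced" train/test split takes every k-th
object by index as test (k = round(1/(1−split fraction)), offset =
seed mod k), covering and disjoint by construction. Positivity is
`nucleus_dab_od_mean ≥ 0.15`, inclusive at the boundary, applied to
the raw (unsmoothed) measurement of every detection; tumour filtering
happens downstream. Training-set augmentation retrains from the union
of stored and new objects under the same split rule and seed.

## Hotspot and increments

The heat map grid (25 µm cells, half the 50 µm smoothing radius) holds
the Gaussian-weighted mean nuclear DAB OD of tumour nuclei near each
cell centre; cells with no nucleus within twice the smoothing radius,
outside the tumour region, or inside an exclusion polygon are masked
and can neither seed hotspots nor contribute members. All
tumour-classified nuclei (not only positive ones) feed the map,
matching a smoothed-measurement map rather than a positive-cell
density; a flag admits unclassified nuclei for map-before-classify
workflows.

Manual hotspot delineation is replaced by a deterministic greedy rule:
seed at the hottest unmasked cell, take the 100 nearest unassigned
tumour nuclei, recompute the map from the remainder, repeat five
times. Counting is thus in decreasing order of local positive-staining
density, and the construction is reproducible — the one part of the
original protocol (a human with a brush tool) that cannot be specified
exactly. The emulated visual arm runs the analogous oracle on ground
truth: a positivity-fraction heat map, a hotspot seed perturbed by a
Gaussian offset (default SD 75 µm, the imprecision of eyeballing a
hotspot), then five concentric 100-cell sets by distance.

## Scoring and cut-offs

Cumulative percentages use exact rational arithmetic
(`100·Σ_{j≤k} n_j / (100k)`), rounded to one decimal only for
reporting. Cohort cut-offs sit at the 500-cell median ± 10 percentage
points; Low is strictly below, High strictly above, boundaries belong
to Intermediate. Medians outside [10, 90] warn and clip the cut-offs
into [0, 100]. Transition tables cross-tabulate categories at two
counting depths; marginals equal the per-depth category counts by
construction.

## Cohort model and statistics

Simulated patients draw true Ki-67 from grade-specific Beta
distributions (means ≈ 0.10/0.20/0.42 for grades 1/2/3, grade
prevalence 6.5/52.8/40.7%), a negative-binomial mitotic count with
mean 2 + 28·Ki-67, and cause-specific exponential event times with
log-linear hazards (base 0.045/yr breast-cancer death with coefficient
2.5 per unit Ki-67, centred at 0.25; base 0.055/yr other-cause death,
coefficient 0), administratively censored at 25 years — long
follow-up with most patients dead, so competing risks matter. The
per-case scene emulation ties the positivity field to the patient:
base rate 0.75·Ki-67 with one 100 µm hotspot peaking 0.40 above base,
600 tumour nuclei in a 330 µm field.

Statistics: Pearson χ² without continuity correction; Bland–Altman
with n−1 SD and 1.96 limits plus the slope of differences on means
(proportional bias); the Aalen–Johansen estimator implemented directly
(`CIF(t) = Σ S(t_j−)·d_1j/n_j`) with the delta-method
(Marubini–Valsecchi) variance and log(−log) pointwise intervals —
without competing events it reduces exactly to 1 − Kaplan–Meier;
Gray's test delegated to R's `cmprsk::cuminc` (ρ = 0), the reference
implementation, via a subprocess; cause-specific Cox models through
statsmodels PHReg (Efron ties by default, Breslow switchable),
competing events censored at their time, Wald intervals; Harrell's C
via lifelines with ties at 0.5, cause-specific by default with an
all-cause flag. The Python Aalen–Johansen point estimates are
cross-checked against lifelines' fitter in the tests; Cox against both
a brute-force partial-likelihood grid search and lifelines.

## Reproducibility and problem sizes

Every stochastic component takes an explicit seed; the pipeline driver
fans a single seed into per-stage seeds via `SeedSequence.spawn` and
records them in a run manifest, so each stage is independently
reproducible and repeated runs are byte-identical. Experiment sizes
were chosen to keep a full validation run on a single CPU comfortable:
classifier training uses two 450 µm scenes (≈ 3000 labeled nuclei),
pipeline recovery one 600 µm scene (1500 nuclei), and the
reclassification study 100 cohorts of 25 cases scored at the
nucleus level without rendering.

## Known limitations

- Stain-vector estimation is biased on tissue without near-pure DAB
  pixels (see above); the default basis is used unless estimation is
  explicitly requested.
- The classifier's near-perfect accuracy on synthetic nuclei reflects
  the generator's cleanly separable class morphology; real annotation
  noise and morphology overlap would lower it substantially.
- The visual-assessment arm is an oracle emulation, not a model of
  human counting error beyond hotspot mislocation.
- The watershed splits convex touching nuclei; heavily overlapping or
  concave aggregates beyond what the hard-core process produces are
  untested.
- Gray's test requires an R installation with `cmprsk`; there is no
  pure-Python fallback.
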