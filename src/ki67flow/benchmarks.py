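"""Self-contained benchmark experiments on synthetic data.

Each function regenerates its inputs from a seed and runs the relevant
slice of the pipeline, so results are reproducible from a single
integer.  They back the package's validation suite and the
reproduction script.
"""

from __future__ import annotations

import numpy as np

from .classify import call_positivity, classify_nuclei, train_classifier
from .detect import (detect_nuclei, match_to_truth, measure_features,
                     smooth_features)
from .hotspot import build_heatmap, select_increments, truth_to_detections
from .pipeline import CaseSimParams, simulate_case_scores
from .scoring import (CaseScore, classify_case, cohort_median,
                      cumulative_percentages, derive_cutoffs)
from .stains import rgb_to_od
from .synthetic import SceneConfig, simulate_cohort, simulate_scene, CohortConfig

__all__ = [
    "classifier_holdout_benchmark",
    "pipeline_recovery_benchmark",
    "cohort_reclassification_benchmark",
]


def _labeled_scene(seed: int):
    """One annotated training image: ground-truth nuclei with measured
    morphology, staining and smoothed features, plus true class labels."""
    cfg = SceneConfig(width_um=450.0, height_um=450.0, n_tumour=800,
                      n_stroma=400, n_lymph=300, base_positivity=0.3,
                      noise_sd=2.0, seed=seed)
    rgb, truth = simulate_scene(cfg)
    od = rgb_to_od(rgb, pixel_size_um=cfg.pixel_size_um)
    dets = truth_to_detections(truth)
    for d in dets:
        d.features = {}
    measure_features(dets, od)
    smooth_features(dets)
    for d, t in zip(dets, truth):
        d.class_label = "tumour" if t.class_label == "tumour" else "other"
    return dets


def classifier_holdout_benchmark(seed: int, n_objects_min: int = 3000,
                                 split_fraction: float = 0.67) -> dict:
    """Held-out accuracy of the tumour/non-tumour classifier.

    Annotated scenes are generated until at least ``n_objects_min``
    labeled nuclei are available; the ensemble is trained with the
    equally spaced split and its held-out accuracy reported in percent.
    """
    rng = np.random.default_rng(seed)
    labeled = []
    while len(labeled) < n_objects_min:
        labeled.extend(_labeled_scene(int(rng.integers(0, 2**31))))
    model = train_classifier(labeled, split_fraction=split_fraction,
                             seed=int(rng.integers(0, 2**31)))
    return {"accuracy_pct": 100.0 * model.holdout_accuracy,
            "n_objects": model.n_objects}


def pipeline_recovery_benchmark(seed: int) -> dict:
    """Full digital arm vs ground truth on one clean hotspot scene.

    Renders a noise-free scene with >=1000 tumour nuclei and one strong
    hotspot, runs detection -> classification -> positivity -> heat map
    -> density-ordered increments, and compares the 500-cell Ki-67
    percentage with the same increment procedure run on the ground
    truth.  Also reports detection F1.
    """
    cfg = SceneConfig(width_um=600.0, height_um=600.0, n_tumour=1000,
                      n_stroma=300, n_lymph=200, base_positivity=0.15,
                      hotspots=(((200.0, 200.0), 110.0, 0.85),),
                      noise_sd=0.0, seed=seed)
    rgb, truth = simulate_scene(cfg)
    od = rgb_to_od(rgb, pixel_size_um=cfg.pixel_size_um)

    dets = detect_nuclei(od)
    measure_features(dets, od)
    smooth_features(dets)
    pairs, metrics = match_to_truth(dets, truth)

    labeled = []
    for di, ti in pairs.items():
        dets[di].class_label = ("tumour"
                                if truth[ti].class_label == "tumour"
                                else "other")
        labeled.append(dets[di])
    model = train_classifier(labeled, seed=seed)
    classify_nuclei(model, dets)
    call_positivity(dets)

    hm = build_heatmap(dets)
    sets = select_increments(dets, hm)
    dia = cumulative_percentages([s.n_positive for s in sets],
                                 decimals=None)

    truth_dets = truth_to_detections(truth)
    hm_t = build_heatmap(truth_dets)
    sets_t = select_increments(truth_dets, hm_t)
    oracle = cumulative_percentages([s.n_positive for s in sets_t],
                                    decimals=None)
    return {"dia500_pct": dia[4], "oracle500_pct": oracle[4],
            "abs_error_pp": abs(dia[4] - oracle[4]),
            "detection_f1": metrics["f1"]}


def cohort_reclassification_benchmark(seed: int, n_cohorts: int = 100,
                                      n_cases: int = 25) -> dict:
    """Reclassification behaviour of density-ordered digital counting.

    Simulates heterogeneous cohorts, scores each case digitally, and
    measures how often (a) the cohort's cumulative medians decrease
    monotonically from the first to the fifth 100-cell increment and
    (b) the Ki-67 High count at 100 cells is at least the High count at
    500 cells under the cohort's own median +/- 10 pp cut-offs.
    """
    master = np.random.default_rng(seed)
    monotone = 0
    high_flow = 0
    for _ in range(n_cohorts):
        s = int(master.integers(0, 2**31))
        records = simulate_cohort(CohortConfig(n_patients=n_cases, seed=s))
        _, dia = simulate_case_scores(records, seed=s + 1,
                                      methods=("DIA",))
        medians = [float(np.median([sc.cumulative_at(k) for sc in dia]))
                   for k in range(1, 6)]
        if all(a >= b - 1e-9 for a, b in zip(medians, medians[1:])):
            monotone += 1
        scheme = derive_cutoffs(cohort_median(dia, 5), "DIA")
        high1 = sum(classify_case(sc.cumulative_at(1), scheme) == "High"
                    for sc in dia)
        high5 = sum(classify_case(sc.cumulative_at(5), scheme) == "High"
                    for sc in dia)
        if high1 >= high5:
            high_flow += 1
    return {"n_cohorts": n_cohorts,
            "frac_monotone_medians": monotone / n_cohorts,
            "frac_high_k1_ge_k5": high_flow / n_cohorts}
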