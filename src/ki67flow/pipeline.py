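"""End-to-end pipeline driver and the in-silico study emulation.

Two levels of composition:

* :func:`run_pipeline` — one full run: simulate (or load) a scene,
  detect and classify nuclei, find the hotspot, score the five 100-cell
  increments, then emulate a whole scored cohort and compute the
  cohort statistics.  Every intermediate artifact and a machine-readable
  manifest are written to the run directory.

* :func:`simulate_case_scores` — the fast cohort emulation: for each
  simulated patient a nucleus-level scene (no rendering) whose
  positivity field follows the patient's true Ki-67, scored by both
  arms — digital (density-ordered increments from the DAB heat map) and
  emulated visual counting (ground-truth oracle with a perturbed
  hotspot seed).

One global seed fans out to per-stage integer seeds through
``numpy.random.SeedSequence(seed).spawn``, so each stage is
independently reproducible from the manifest.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as kio
from .classify import (PositivityRule, call_positivity, classify_nuclei,
                       train_classifier)
from .detect import (DetectionParams, detect_nuclei, detections_to_dataframe,
                     expand_cells, match_to_truth, measure_features,
                     smooth_features)
from .hotspot import (build_heatmap, select_increments, truth_to_detections,
                      va_oracle_increments)
from .scoring import (CaseScore, cohort_median, derive_cutoffs, classify_case,
                      transition_table)
from .stains import StainProfile, deconvolve, rgb_to_od
from .stats import (bland_altman, cohort_to_dataframe, cox_ph,
                    cumulative_incidence, harrell_c, pearson_chi2)
from .synthetic import (CohortConfig, SceneConfig, simulate_cohort,
                        simulate_nuclei, simulate_scene)

__all__ = ["PipelineConfig", "CaseSimParams", "simulate_case_scores",
           "run_pipeline", "stage_seeds"]


def stage_seeds(global_seed: int, n: int = 8) -> list[int]:
    """Fan one global seed out to independent 31-bit stage seeds."""
    ss = np.random.SeedSequence(global_seed)
    return [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(n)]


@dataclass(frozen=True)
class CaseSimParams:
    """Nucleus-level scene settings for one emulated patient case.

    The positivity field follows the patient's true Ki-67 level p:
    base rate ``base_scale * p`` with ``n_hotspots`` Gaussian bumps of
    the given radius peaking ``hotspot_boost`` above base (clipped to
    1), capturing intratumoural proliferation heterogeneity.
    """

    n_tumour: int = 600
    field_um: float = 330.0
    base_scale: float = 0.75
    hotspot_boost: float = 0.40
    hotspot_radius_um: float = 100.0
    n_hotspots: int = 1
    va_seed_offset_sd_um: float = 75.0


def _case_scene_config(true_ki67: float, params: CaseSimParams,
                       seed: int, rng) -> SceneConfig:
    base = float(np.clip(params.base_scale * true_ki67, 0.0, 1.0))
    peak = float(np.clip(base + params.hotspot_boost, base, 1.0))
    hotspots = []
    margin = params.hotspot_radius_um / 2
    for _ in range(params.n_hotspots):
        cx = rng.uniform(margin, params.field_um - margin)
        cy = rng.uniform(margin, params.field_um - margin)
        hotspots.append(((cx, cy), params.hotspot_radius_um, peak))
    return SceneConfig(width_um=params.field_um, height_um=params.field_um,
                       n_tumour=params.n_tumour, n_stroma=0, n_lymph=0,
                       base_positivity=base, hotspots=tuple(hotspots),
                       seed=seed)


def simulate_case_scores(records, params: CaseSimParams | None = None,
                         rule: PositivityRule | None = None,
                         n_sets: int = 5, set_size: int = 100,
                         seed: int = 0, methods=("VA", "DIA")):
    """Score every simulated patient with the requested arms.

    Returns ``(va_scores, dia_scores)`` lists of :class:`CaseScore`
    aligned with ``records`` (an arm not in ``methods`` comes back
    empty).
    """
    if params is None:
        params = CaseSimParams()
    if rule is None:
        rule = PositivityRule()
    master = np.random.default_rng(seed)
    va_scores, dia_scores = [], []
    for rec in records:
        case_seed = int(master.integers(0, 2**31))
        rng = np.random.default_rng(case_seed)
        cfg = _case_scene_config(rec.true_ki67, params,
                                 int(rng.integers(0, 2**31)), rng)
        nuclei = simulate_nuclei(cfg)
        cid = str(rec.patient_id)
        if "DIA" in methods:
            dets = truth_to_detections(nuclei)
            hm = build_heatmap(dets, smoothing_radius_um=50.0, grid_um=25.0)
            dia_sets = select_increments(dets, hm, n_sets=n_sets,
                                         set_size=set_size, rule=rule)
            dia_scores.append(CaseScore(case_id=cid, method="DIA",
                                        n_positive=[s.n_positive
                                                    for s in dia_sets]))
        if "VA" in methods:
            va_sets = va_oracle_increments(
                nuclei, n_sets=n_sets, set_size=set_size,
                seed_offset_sd_um=params.va_seed_offset_sd_um, rng=rng)
            va_scores.append(CaseScore(case_id=cid, method="VA",
                                       n_positive=[s.n_positive
                                                   for s in va_sets]))
    return va_scores, dia_scores


@dataclass(frozen=True)
class PipelineConfig:
    """Everything one reproducible run needs."""

    scene: SceneConfig = field(default_factory=lambda: SceneConfig(
        width_um=450.0, height_um=450.0, n_tumour=700, n_stroma=250,
        n_lymph=150, base_positivity=0.2,
        hotspots=(((150.0, 150.0), 80.0, 0.8),)))
    cohort: CohortConfig = field(default_factory=CohortConfig)
    detection: DetectionParams = field(default_factory=DetectionParams)
    positivity: PositivityRule = field(default_factory=PositivityRule)
    case_sim: CaseSimParams = field(default_factory=CaseSimParams)
    smoothing_radii_um: tuple = (25.0, 50.0, 100.0)
    heatmap_radius_um: float = 50.0
    heatmap_grid_um: float = 25.0
    n_sets: int = 5
    set_size: int = 100
    seed: int = 0


def _stage(name):
    def deco(fn):
        def wrapper(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except Exception as exc:
                raise RuntimeError(f"pipeline stage '{name}' failed: {exc}"
                                   ) from exc
        return wrapper
    return deco


def run_pipeline(config: PipelineConfig, out_dir) -> Path:
    """Execute simulate -> detect -> classify -> hotspot -> score -> stats.

    Writes every intermediate artifact plus ``manifest.json`` into
    ``out_dir`` and returns it.  Identical config gives byte-identical
    CSV outputs.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seeds = stage_seeds(config.seed)
    profile = StainProfile.default_hdab()

    # --- simulate -----------------------------------------------------
    @_stage("simulate")
    def do_simulate():
        scene_cfg = replace(config.scene, seed=seeds[0])
        rgb, truth = simulate_scene(scene_cfg, profile)
        cohort_cfg = replace(config.cohort, seed=seeds[1])
        records = simulate_cohort(cohort_cfg)
        kio.write_image(out / "scene.tiff", rgb)
        kio.write_truth_geojson(out / "truth.geojson", truth)
        kio.write_truth_csv(out / "truth.csv", truth)
        kio.write_cohort_csv(out / "cohort.csv", records)
        return rgb, truth, records, scene_cfg

    rgb, truth, records, scene_cfg = do_simulate()

    # --- detect -------------------------------------------------------
    @_stage("detect")
    def do_detect():
        od = rgb_to_od(rgb, i0=profile.i0,
                       pixel_size_um=scene_cfg.pixel_size_um)
        conc = deconvolve(od, profile)
        dets = detect_nuclei(od, config.detection)
        dets = expand_cells(dets, config.detection.cell_expansion_um)
        dets = measure_features(dets, od, concentrations=conc)
        dets = smooth_features(dets, radii_um=config.smoothing_radii_um)
        return dets

    detections = do_detect()

    # --- classify -----------------------------------------------------
    @_stage("classify")
    def do_classify():
        pairs, metrics = match_to_truth(detections, truth)
        labeled = []
        for di, ti in pairs.items():
            det = detections[di]
            det.class_label = ("tumour"
                               if truth[ti].class_label == "tumour"
                               else "other")
            labeled.append(det)
        model = train_classifier(labeled, seed=seeds[2])
        classify_nuclei(model, detections)
        call_positivity(detections, config.positivity)
        return model, metrics

    model, det_metrics = do_classify()

    # --- hotspot + image-case scoring --------------------------------
    @_stage("hotspot")
    def do_hotspot():
        hm = build_heatmap(detections,
                           smoothing_radius_um=config.heatmap_radius_um,
                           grid_um=config.heatmap_grid_um)
        sets = select_increments(detections, hm, n_sets=config.n_sets,
                                 set_size=config.set_size,
                                 rule=config.positivity)
        kio.write_detections_geojson(out / "detections.geojson", detections)
        detections_to_dataframe(detections).to_csv(
            out / "detections.csv", index=False)
        pd.DataFrame([{"case_id": "scene0", "rank": s.rank,
                       "n_positive": s.n_positive}
                      for s in sets]).to_csv(out / "increments.csv",
                                             index=False)
        return sets

    image_sets = do_hotspot()

    # --- cohort scoring ----------------------------------------------
    @_stage("score")
    def do_score():
        va, dia = simulate_case_scores(records, config.case_sim,
                                       config.positivity,
                                       n_sets=config.n_sets,
                                       set_size=config.set_size,
                                       seed=seeds[3])
        kio.write_scores_csv(out / "scores.csv", va + dia)
        report = {}
        tables = {}
        for method, scores in (("VA", va), ("DIA", dia)):
            med = cohort_median(scores, k=5)
            scheme = derive_cutoffs(med, method)
            tt = transition_table(scores, scheme, k_from=1, k_to=5)
            report[method] = {
                "median_k5": round(med, 1),
                "cutoffs": [scheme.low_below, scheme.high_above],
                "start_counts": tt.start_counts,
                "end_counts": tt.end_counts,
            }
            tt.counts.to_csv(out / f"transitions_{method}.csv")
            tables[method] = (scores, scheme)
        (out / "scoring_report.json").write_text(json.dumps(report, indent=2))
        return tables

    score_tables = do_score()

    # --- statistics ---------------------------------------------------
    @_stage("stats")
    def do_stats():
        df = cohort_to_dataframe(records)
        stats_report = {}
        for method, (scores, scheme) in score_tables.items():
            for k in (1, 5):
                col = f"{method.lower()}{k}00_cat"
                vals = {s.case_id: classify_case(s.cumulative_at(k), scheme)
                        for s in scores}
                df[col] = df["patient_id"].astype(str).map(vals)
        va500 = np.array([s.cumulative_at(5)
                          for s in score_tables["VA"][0]])
        dia500 = np.array([s.cumulative_at(5)
                           for s in score_tables["DIA"][0]])
        ba = bland_altman(va500, dia500)
        stats_report["bland_altman_dia500_vs_va500"] = {
            "bias": ba.bias, "loa": [ba.loa_low, ba.loa_high],
            "slope": ba.slope_diff_on_mean}
        for col in ("va100_cat", "va500_cat", "dia100_cat", "dia500_cat"):
            cif = cumulative_incidence(df, group_col=col)
            stats_report[f"cif5y_{col}"] = {
                str(g): round(100 * c.at(5.0), 1) for g, c in cif.items()}
            tab = pd.crosstab(df["grade"], df[col])
            stat, dfree, p = pearson_chi2(tab.to_numpy())
            stats_report[f"chi2_grade_{col}"] = {"stat": stat, "p": p}
            dummies = pd.get_dummies(df[col])
            for cat in ("Intermediate", "High"):
                if cat in dummies:
                    df[f"{col}_{cat}"] = dummies[cat].astype(float)
            covs = [c for c in (f"{col}_Intermediate", f"{col}_High")
                    if c in df]
            # fit only when every level carries enough events for a
            # stable Wald covariance
            events = df["event"] == "bc_death"
            if covs and all(df.loc[events, c].sum() >= 5 for c in covs):
                hr = cox_ph(df, covs)
                if np.isfinite(hr[["coef", "se"]].to_numpy()).all():
                    stats_report[f"cox_{col}"] = {
                        c: round(float(hr.loc[c, "hr"]), 2) for c in covs}
            rank = df[col].map({"Low": 0, "Intermediate": 1, "High": 2})
            stats_report[f"harrell_c_{col}"] = round(
                harrell_c(df, rank.to_numpy()), 2)
        (out / "stats_report.json").write_text(
            json.dumps(stats_report, indent=2))
        df.to_csv(out / "cohort_with_categories.csv", index=False)

    do_stats()

    manifest = {
        "seed": config.seed,
        "stage_seeds": seeds,
        "config": json.loads(json.dumps(
            dataclasses.asdict(config), default=str)),
        "detection_metrics": det_metrics,
        "classifier_holdout_accuracy": model.holdout_accuracy,
        "image_case_increments": [s.n_positive for s in image_sets],
        "versions": _versions(),
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return out


def _versions() -> dict[str, str]:
    import lifelines
    import shapely
    import sklearn
    import skimage
    import scipy

    return {"numpy": np.__version__, "scipy": scipy.__version__,
            "pandas": pd.__version__, "scikit-image": skimage.__version__,
            "scikit-learn": sklearn.__version__,
            "shapely": shapely.__version__,
            "lifelines": lifelines.__version__}
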