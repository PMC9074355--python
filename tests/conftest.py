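import numpy as np
import pytest

import ki67flow as kf


@pytest.fixture(scope="session")
def default_profile():
    return kf.StainProfile.default_hdab()


@pytest.fixture(scope="session")
def noisy_scene():
    """Mixed-class scene with realistic noise, plus its OD image."""
    cfg = kf.SceneConfig(width_um=200.0, height_um=200.0, n_tumour=100,
                         n_stroma=40, n_lymph=25, seed=2,
                         base_positivity=0.4, noise_sd=2.0)
    rgb, truth = kf.simulate_scene(cfg)
    od = kf.rgb_to_od(rgb, pixel_size_um=cfg.pixel_size_um)
    return cfg, rgb, truth, od


@pytest.fixture(scope="session")
def clean_scene():
    """Noise-free scene (exact Beer-Lambert identities hold)."""
    cfg = kf.SceneConfig(width_um=150.0, height_um=150.0, n_tumour=60,
                         n_stroma=25, n_lymph=15, seed=3,
                         base_positivity=0.4, noise_sd=0.0)
    rgb, truth = kf.simulate_scene(cfg)
    od = kf.rgb_to_od(rgb, pixel_size_um=cfg.pixel_size_um)
    return cfg, rgb, truth, od


@pytest.fixture(scope="session")
def detected_scene(noisy_scene):
    """Full measurement pipeline on the noisy scene."""
    cfg, rgb, truth, od = noisy_scene
    dets = kf.detect_nuclei(od)
    dets = kf.expand_cells(dets, 5.0)
    dets = kf.measure_features(dets, od)
    dets = kf.smooth_features(dets)
    return cfg, truth, od, dets


@pytest.fixture(scope="session")
def labeled_truth_detections(clean_scene):
    """Ground-truth nuclei of the clean scene with measured features and
    true class labels — a small annotated training set."""
    cfg, rgb, truth, od = clean_scene
    dets = kf.truth_to_detections(truth)
    for d in dets:
        d.features = {}
    dets = kf.measure_features(dets, od)
    dets = kf.smooth_features(dets)
    for d, t in zip(dets, truth):
        d.class_label = "tumour" if t.class_label == "tumour" else "other"
    return dets


@pytest.fixture(scope="session")
def cohort_df():
    records = kf.simulate_cohort(kf.CohortConfig(n_patients=300, seed=3))
    return kf.cohort_to_dataframe(records)
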