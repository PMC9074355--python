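"""File formats: images, GeoJSON detections, CSV tables, profiles, configs.

Detections interchange as GeoJSON FeatureCollections (one polygon
feature per nucleus with a ``measurements`` property map), the format
digital-pathology platforms exchange cell detections in.  Coordinates
are physical micrometres, origin at the image top-left, y increasing
downward.  All writers round-trip: ``read(write(x)) == x`` on every
field.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
from PIL import Image
from shapely.geometry import Polygon, mapping, shape

from .detect import NucleusDetection
from .scoring import CaseScore
from .stains import StainProfile
from .synthetic import GroundTruthNucleus

__all__ = [
    "write_image", "read_image",
    "write_detections_geojson", "read_detections_geojson",
    "write_truth_geojson", "read_truth_geojson",
    "write_truth_csv",
    "write_cohort_csv", "read_cohort_csv",
    "write_scores_csv", "read_scores_csv",
    "write_stain_profile", "read_stain_profile",
    "load_strict_yaml",
]


# ---------------------------------------------------------------------------
# Images


def write_image(path, image: np.ndarray) -> None:
    """Write an RGB image as 8-bit TIFF or PNG (by extension)."""
    path = Path(path)
    arr = np.clip(np.asarray(image), 0, 255).astype(np.uint8)
    if path.suffix.lower() in (".tif", ".tiff"):
        tifffile.imwrite(path, arr)
    else:
        Image.fromarray(arr).save(path)


def read_image(path) -> np.ndarray:
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        return tifffile.imread(path)
    return np.asarray(Image.open(path).convert("RGB"))


# ---------------------------------------------------------------------------
# Detections GeoJSON


def _detection_feature(det: NucleusDetection) -> dict:
    props = {
        "object_id": det.id,
        "class_label": det.class_label,
        "ki67_positive": det.ki67_positive,
        "increment_rank": det.increment_rank,
        "centroid_um": list(det.centroid_um),
        "measurements": det.features,
        "smoothed": {f"{name}|{r:g}": v
                     for (name, r), v in det.smoothed.items()},
    }
    if det.cell_polygon is not None:
        props["cell_polygon"] = mapping(det.cell_polygon)
    return {"type": "Feature", "geometry": mapping(det.nucleus_polygon),
            "properties": props}


def write_detections_geojson(path, detections) -> None:
    fc = {"type": "FeatureCollection",
          "features": [_detection_feature(d) for d in detections]}
    Path(path).write_text(json.dumps(fc))


def read_detections_geojson(path) -> list[NucleusDetection]:
    data = json.loads(Path(path).read_text())
    if data.get("type") != "FeatureCollection":
        raise ValueError(f"{path}: not a GeoJSON FeatureCollection")
    out = []
    for i, feat in enumerate(data["features"]):
        try:
            props = feat["properties"]
            det = NucleusDetection(
                id=props["object_id"],
                nucleus_polygon=shape(feat["geometry"]),
                centroid_um=tuple(props["centroid_um"]),
                class_label=props.get("class_label"),
                ki67_positive=props.get("ki67_positive"),
                increment_rank=props.get("increment_rank"),
            )
            det.features = dict(props.get("measurements", {}))
            for key, v in props.get("smoothed", {}).items():
                name, r = key.rsplit("|", 1)
                det.smoothed[(name, float(r))] = v
            if "cell_polygon" in props:
                det.cell_polygon = shape(props["cell_polygon"])
            out.append(det)
        except (KeyError, TypeError) as exc:
            raise ValueError(f"{path}: malformed feature {i}: {exc}") from exc
    return out


# ---------------------------------------------------------------------------
# Ground truth


def write_truth_geojson(path, nuclei) -> None:
    feats = []
    for nuc in nuclei:
        feats.append({
            "type": "Feature", "geometry": mapping(nuc.polygon),
            "properties": {
                "object_id": nuc.id,
                "class_label": nuc.class_label,
                "ki67_positive": nuc.ki67_positive,
                "dab_concentration": nuc.dab_concentration,
                "hematoxylin_concentration": nuc.hematoxylin_concentration,
            }})
    Path(path).write_text(json.dumps(
        {"type": "FeatureCollection", "features": feats}))


def read_truth_geojson(path) -> list[GroundTruthNucleus]:
    data = json.loads(Path(path).read_text())
    out = []
    for i, feat in enumerate(data["features"]):
        try:
            p = feat["properties"]
            out.append(GroundTruthNucleus(
                id=p["object_id"], class_label=p["class_label"],
                polygon=shape(feat["geometry"]),
                ki67_positive=p["ki67_positive"],
                dab_concentration=p["dab_concentration"],
                hematoxylin_concentration=p["hematoxylin_concentration"]))
        except (KeyError, TypeError) as exc:
            raise ValueError(f"{path}: malformed feature {i}: {exc}") from exc
    return out


def write_truth_csv(path, nuclei) -> None:
    rows = []
    for nuc in nuclei:
        x, y = nuc.centroid_um
        rows.append(dict(object_id=nuc.id, class_label=nuc.class_label,
                         centroid_x_um=x, centroid_y_um=y,
                         ki67_positive=nuc.ki67_positive,
                         dab_concentration=nuc.dab_concentration,
                         hematoxylin_concentration=nuc.hematoxylin_concentration))
    pd.DataFrame(rows).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Cohort and score tables

COHORT_COLUMNS = ["patient_id", "true_ki67", "age_at_diagnosis", "grade",
                  "mitoses_10hpf", "subtype", "time_years", "event"]


def write_cohort_csv(path, records) -> None:
    pd.DataFrame([vars(r) for r in records])[COHORT_COLUMNS].to_csv(
        path, index=False)


def read_cohort_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in COHORT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required column(s) "
                         f"{', '.join(missing)}")
    return df


def write_scores_csv(path, scores) -> None:
    rows = []
    for s in scores:
        row = {"case_id": s.case_id, "method": s.method}
        for k, n in enumerate(s.n_positive, start=1):
            row[f"k{k}"] = n
        for k, c in enumerate(s.cumulative_pct, start=1):
            row[f"cum{k}"] = round(c, 1)
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)


def read_scores_csv(path) -> list[CaseScore]:
    df = pd.read_csv(path)
    required = ["case_id", "method"] + [f"k{k}" for k in range(1, 6)]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required column(s) "
                         f"{', '.join(missing)}")
    return [CaseScore(case_id=str(r["case_id"]), method=str(r["method"]),
                      n_positive=tuple(int(r[f"k{k}"]) for k in range(1, 6)))
            for _, r in df.iterrows()]


# ---------------------------------------------------------------------------
# Stain profiles


def write_stain_profile(path, profile: StainProfile) -> None:
    data = {"hematoxylin": list(profile.vec_hematoxylin),
            "dab": list(profile.vec_dab),
            "residual": list(profile.vec_residual),
            "i0": profile.i0}
    Path(path).write_text(json.dumps(data, indent=2))


def read_stain_profile(path) -> StainProfile:
    data = json.loads(Path(path).read_text())
    return StainProfile(data["hematoxylin"], data["dab"],
                        data.get("residual"), i0=data.get("i0", 255.0))


# ---------------------------------------------------------------------------
# Strict config parsing


def load_strict_yaml(path, allowed_keys) -> dict:
    """Load a YAML mapping, rejecting unknown keys by name."""
    import yaml

    data = yaml.safe_load(Path(path).read_text()) or {}
    if not isinstance(data, dict):
        raise ValueError(f"{path}: expected a mapping at top level")
    unknown = sorted(set(data) - set(allowed_keys))
    if unknown:
        raise ValueError(f"{path}: unknown key(s): {', '.join(unknown)}")
    return data
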