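"""Synthetic H-DAB stained tissue scenes and patient cohorts.

No public image or cohort accompanies the digital Ki-67 workflow this
package implements, so every downstream stage is exercised on synthetic
data with exact ground truth:

* **Scenes** — tumour, stromal and lymphocyte nuclei placed by a
  hard-core (minimum centre spacing) point process inside a physical
  field of view.  Nuclei are ellipses with class-specific area and
  eccentricity (tumour: large, round-to-oval; stroma: elongated;
  lymphocyte: small, round).  Tumour nuclei are Ki-67 positive with a
  probability given by a spatial field: a base rate plus Gaussian
  hotspot bumps.  Positive nuclei carry a DAB concentration; everything
  carries hematoxylin.  Rendering inverts the colour-deconvolution
  model (Beer-Lambert transmission through the stain vectors).

* **Cohorts** — per-patient true Ki-67 level drawn by grade, mitotic
  count linked to Ki-67, and cause-specific exponential event times
  (breast-cancer death vs other-cause death) log-linear in true Ki-67,
  with administrative censoring.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from shapely.geometry import Polygon
from skimage.draw import polygon as draw_polygon

from .stains import StainProfile

__all__ = [
    "SceneConfig",
    "GroundTruthNucleus",
    "CohortConfig",
    "CohortRecord",
    "simulate_scene",
    "simulate_nuclei",
    "render_scene",
    "rasterize_concentrations",
    "simulate_cohort",
    "DEFAULT_CLASS_PARAMS",
]

CLASS_LABELS = ("tumour", "stroma", "lymphocyte")

# Morphology and staining per nucleus class.  Areas in um^2; stain
# concentrations in OD units of the corresponding unit stain vector.
DEFAULT_CLASS_PARAMS: dict[str, dict[str, float]] = {
    "tumour": dict(area_mean=80.0, area_sd=20.0, area_min=40.0,
                   area_max=180.0, ecc_min=0.30, ecc_max=0.70,
                   min_spacing_um=9.0,
                   hematoxylin_mean=0.70, hematoxylin_sd=0.08,
                   dab_mean=0.55, dab_sd=0.08, dab_min=0.30),
    "stroma": dict(area_mean=40.0, area_sd=10.0, area_min=20.0, area_max=80.0,
                   ecc_min=0.85, ecc_max=0.93, min_spacing_um=8.0,
                   hematoxylin_mean=0.55, hematoxylin_sd=0.08,
                   dab_mean=0.0, dab_sd=0.0, dab_min=0.0),
    "lymphocyte": dict(area_mean=33.0, area_sd=6.0, area_min=20.0,
                       area_max=50.0, ecc_min=0.0, ecc_max=0.30,
                       min_spacing_um=6.0,
                       hematoxylin_mean=0.90, hematoxylin_sd=0.08,
                       dab_mean=0.0, dab_sd=0.0, dab_min=0.0),
}


@dataclass(frozen=True)
class SceneConfig:
    """Physical layout and staining statistics of one synthetic scene.

    ``pixel_size_um`` defaults to 0.23, the scanner resolution the
    workflow is calibrated for.  ``hotspots`` is a list of
    ``((x_um, y_um), radius_um, peak_positivity)`` Gaussian bumps added
    to ``base_positivity`` (bump scale sigma = radius/2).
    """

    width_um: float = 300.0
    height_um: float = 300.0
    pixel_size_um: float = 0.23
    n_tumour: int = 600
    n_stroma: int = 200
    n_lymph: int = 120
    base_positivity: float = 0.3
    hotspots: tuple = ()
    nucleus_size_params: dict = field(
        default_factory=lambda: {k: dict(v) for k, v in
                                 DEFAULT_CLASS_PARAMS.items()})
    noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if min(self.width_um, self.height_um, self.pixel_size_um) <= 0:
            raise ValueError("scene geometry must be positive")
        if not 0.0 <= self.base_positivity <= 1.0:
            raise ValueError("base_positivity must lie in [0, 1]")
        for (_, radius, peak) in self.hotspots:
            if radius <= 0:
                raise ValueError("hotspot radius must be positive")
            if not 0.0 <= peak <= 1.0:
                raise ValueError("peak_positivity must lie in [0, 1]")
            if peak < self.base_positivity:
                raise ValueError(
                    "peak_positivity must be >= base_positivity")
        if min(self.n_tumour, self.n_stroma, self.n_lymph) < 0:
            raise ValueError("nucleus counts must be nonnegative")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be nonnegative")


@dataclass
class GroundTruthNucleus:
    """One simulated nucleus with its exact stain content and label."""

    id: int
    class_label: str
    polygon: Polygon
    ki67_positive: bool
    dab_concentration: float
    hematoxylin_concentration: float

    @property
    def centroid_um(self) -> tuple[float, float]:
        c = self.polygon.centroid
        return (c.x, c.y)


def _ellipse_polygon(cx, cy, a, b, theta, n_vertices=24) -> Polygon:
    """Counterclockwise ellipse polygon with semi-axes a >= b."""
    phi = np.linspace(0.0, 2 * np.pi, n_vertices, endpoint=False)
    x = a * np.cos(phi)
    y = b * np.sin(phi)
    ct, st = math.cos(theta), math.sin(theta)
    xs = cx + ct * x - st * y
    ys = cy + st * x + ct * y
    return Polygon(np.column_stack([xs, ys]))


def _place_hardcore(counts_and_spacing, width, height, margins, rng,
                    attempts_per_point=200):
    """Sequential hard-core placement on a neighbour grid.

    ``counts_and_spacing`` is a list of (class_label, n, spacing_um);
    the required spacing between two points is the mean of their class
    spacings.  Raises when a class cannot be placed.
    """
    max_spacing = max((s for _, n, s in counts_and_spacing if n > 0),
                      default=1.0)
    cell = max(max_spacing, 1e-6)
    grid: dict[tuple[int, int], list[tuple[float, float, float]]] = {}
    placed = []  # (x, y, class_label)

    for label, n, spacing in counts_and_spacing:
        margin = margins[label]
        lo_x, hi_x = margin, width - margin
        lo_y, hi_y = margin, height - margin
        if n > 0 and (hi_x <= lo_x or hi_y <= lo_y):
            raise ValueError(
                f"scene too small for {label} nuclei (margin {margin:.1f} um)")
        n_placed = 0
        budget = attempts_per_point * max(n, 1)
        while n_placed < n:
            if budget <= 0:
                raise ValueError(
                    f"could not place {n} {label} nuclei with spacing "
                    f"{spacing} um in {width:.0f}x{height:.0f} um "
                    f"(placed {n_placed}); reduce the count or spacing")
            budget -= 1
            x = rng.uniform(lo_x, hi_x)
            y = rng.uniform(lo_y, hi_y)
            gi, gj = int(x / cell), int(y / cell)
            ok = True
            for di in (-1, 0, 1):
                for dj in (-1, 0, 1):
                    for (px, py, ps) in grid.get((gi + di, gj + dj), ()):
                        req = 0.5 * (spacing + ps)
                        if (x - px) ** 2 + (y - py) ** 2 < req * req:
                            ok = False
                            break
                    if not ok:
                        break
                if not ok:
                    break
            if ok:
                grid.setdefault((gi, gj), []).append((x, y, spacing))
                placed.append((x, y, label))
                n_placed += 1
    return placed


def positivity_field(config: SceneConfig, x, y):
    """Probability that a tumour nucleus at (x, y) is Ki-67 positive."""
    p = np.full(np.broadcast(x, y).shape, config.base_positivity, dtype=float)
    for (cx, cy), radius, peak in config.hotspots:
        sigma = radius / 2.0
        d2 = (np.asarray(x) - cx) ** 2 + (np.asarray(y) - cy) ** 2
        p = p + (peak - config.base_positivity) * np.exp(-d2 / (2 * sigma**2))
    return np.clip(p, 0.0, 1.0)


def simulate_nuclei(config: SceneConfig, rng=None):
    """Draw the ground-truth nucleus list for a scene (no rendering)."""
    if rng is None:
        rng = np.random.default_rng(config.seed)
    params = config.nucleus_size_params

    # Margin keeps whole ellipses inside the scene: worst-case semi-major
    # axis given the class's max area and max eccentricity.
    margins = {}
    for label in CLASS_LABELS:
        p = params[label]
        bmin = math.sqrt(1 - p["ecc_max"] ** 2)
        margins[label] = math.sqrt(p["area_max"] / (math.pi * bmin)) + 0.5

    counts = [("tumour", config.n_tumour, params["tumour"]["min_spacing_um"]),
              ("stroma", config.n_stroma, params["stroma"]["min_spacing_um"]),
              ("lymphocyte", config.n_lymph,
               params["lymphocyte"]["min_spacing_um"])]
    centres = _place_hardcore(counts, config.width_um, config.height_um,
                              margins, rng)

    nuclei: list[GroundTruthNucleus] = []
    for idx, (x, y, label) in enumerate(centres):
        p = params[label]
        area = float(np.clip(rng.normal(p["area_mean"], p["area_sd"]),
                             p["area_min"], p["area_max"]))
        ecc = float(rng.uniform(p["ecc_min"], p["ecc_max"]))
        b_over_a = math.sqrt(1 - ecc**2)
        a = math.sqrt(area / (math.pi * b_over_a))
        b = area / (math.pi * a)
        theta = float(rng.uniform(0, math.pi))
        poly = _ellipse_polygon(x, y, a, b, theta)

        hema = max(0.05, float(rng.normal(p["hematoxylin_mean"],
                                          p["hematoxylin_sd"])))
        if label == "tumour":
            prob = float(positivity_field(config, x, y))
            positive = bool(rng.random() < prob)
        else:
            positive = False
        if positive:
            dab = max(p["dab_min"],
                      float(rng.normal(p["dab_mean"], p["dab_sd"])))
        else:
            dab = 0.0
        nuclei.append(GroundTruthNucleus(
            id=idx, class_label=label, polygon=poly, ki67_positive=positive,
            dab_concentration=dab, hematoxylin_concentration=hema))
    return nuclei


def simulate_scene(config: SceneConfig,
                   profile: StainProfile | None = None):
    """Simulate one stained scene.

    Returns ``(rgb_image, nuclei)``: a float RGB image in [0, 255] and
    the ground-truth nucleus list.  Identical config (and seed) gives
    bit-identical output.
    """
    rng = np.random.default_rng(config.seed)
    if profile is None:
        profile = StainProfile.default_hdab()
    nuclei = simulate_nuclei(config, rng=rng)
    rgb = render_scene(nuclei, profile, config.width_um, config.height_um,
                       config.pixel_size_um, config.noise_sd, rng=rng)
    return rgb, nuclei


def rasterize_concentrations(nuclei, width_um, height_um, pixel_size_um):
    """Per-pixel hematoxylin/DAB concentration maps (overlaps add)."""
    h_px = int(round(height_um / pixel_size_um))
    w_px = int(round(width_um / pixel_size_um))
    hema = np.zeros((h_px, w_px), dtype=float)
    dab = np.zeros((h_px, w_px), dtype=float)
    for nuc in nuclei:
        xs, ys = nuc.polygon.exterior.xy
        rows = np.asarray(ys) / pixel_size_um
        cols = np.asarray(xs) / pixel_size_um
        rr, cc = draw_polygon(rows, cols, shape=(h_px, w_px))
        hema[rr, cc] += nuc.hematoxylin_concentration
        dab[rr, cc] += nuc.dab_concentration
    return {"hematoxylin": hema, "dab": dab}


def render_scene(nuclei, profile: StainProfile, width_um, height_um,
                 pixel_size_um=0.23, noise_sd=0.0, rng=None) -> np.ndarray:
    """Render nuclei to a float RGB image via Beer-Lambert transmission.

    ``I_c = i0 * 10**(-(c_h * v_h + c_dab * v_dab)_c)`` plus optional
    additive Gaussian noise, clipped to [0, i0].
    """
    conc = rasterize_concentrations(nuclei, width_um, height_um,
                                    pixel_size_um)
    od = (conc["hematoxylin"][..., None] * profile.vec_hematoxylin
          + conc["dab"][..., None] * profile.vec_dab)
    rgb = profile.i0 * np.power(10.0, -od)
    if noise_sd > 0:
        if rng is None:
            rng = np.random.default_rng()
        rgb = rgb + rng.normal(0.0, noise_sd, size=rgb.shape)
    return np.clip(rgb, 0.0, profile.i0)


# ---------------------------------------------------------------------------
# Cohort simulation


@dataclass(frozen=True)
class CohortConfig:
    """Generative model for a synthetic breast-cancer cohort.

    True Ki-67 (a fraction in [0, 1]) is Beta-distributed within
    histological grade; the mitotic count is negative-binomial with
    mean linear in Ki-67; breast-cancer and other-cause death have
    cause-specific exponential hazards log-linear in centred Ki-67.
    """

    n_patients: int = 248
    grade_probs: tuple = (0.065, 0.528, 0.407)
    ki67_beta_by_grade: dict = field(default_factory=lambda: {
        1: (2.5, 22.5),   # mean 0.10
        2: (3.2, 12.8),   # mean 0.20
        3: (4.6, 6.4),    # mean 0.42
    })
    mitoses_dispersion: float = 2.5
    mitoses_intercept: float = 2.0
    mitoses_slope: float = 28.0
    subtype_probs: dict = field(default_factory=lambda: {
        "LuminalA": 0.444, "LuminalB_HER2neg": 0.331,
        "LuminalB_HER2pos": 0.113, "HER2": 0.048, "TN": 0.064})
    hazard_bc_base: float = 0.045      # events / year at ki67 = 0.25
    hazard_bc_coef: float = 2.5        # log-hazard per unit ki67
    hazard_other_base: float = 0.055
    hazard_other_coef: float = 0.0
    ki67_center: float = 0.25
    admin_censor_years: float = 25.0
    seed: int = 0

    def __post_init__(self):
        if self.n_patients < 0:
            raise ValueError("n_patients must be nonnegative")
        if abs(sum(self.grade_probs) - 1.0) > 1e-9:
            raise ValueError("grade_probs must sum to 1")
        if self.hazard_bc_base <= 0 or self.hazard_other_base <= 0:
            raise ValueError("baseline hazards must be positive")
        if self.admin_censor_years < 0:
            raise ValueError("admin_censor_years must be nonnegative")


@dataclass
class CohortRecord:
    """One simulated patient."""

    patient_id: int
    true_ki67: float
    age_at_diagnosis: float
    grade: int
    mitoses_10hpf: int
    subtype: str
    time_years: float
    event: str  # bc_death | other_death | censored


EVENT_TYPES = ("bc_death", "other_death", "censored")


def simulate_cohort(config: CohortConfig) -> list[CohortRecord]:
    """Draw a cohort of :class:`CohortRecord` (deterministic per seed)."""
    rng = np.random.default_rng(config.seed)
    n = config.n_patients
    grades = rng.choice([1, 2, 3], size=n, p=np.asarray(config.grade_probs))
    ki67 = np.empty(n)
    for g in (1, 2, 3):
        m = grades == g
        a, b = config.ki67_beta_by_grade[g]
        ki67[m] = rng.beta(a, b, size=int(m.sum()))
    mu = config.mitoses_intercept + config.mitoses_slope * ki67
    disp = config.mitoses_dispersion
    mitoses = rng.negative_binomial(disp, disp / (disp + mu))
    subtypes = rng.choice(list(config.subtype_probs), size=n,
                          p=np.asarray(list(config.subtype_probs.values())))
    age = np.clip(rng.normal(69.9, 10.9, size=n), 42.0, 95.0)

    z = ki67 - config.ki67_center
    lam_bc = config.hazard_bc_base * np.exp(config.hazard_bc_coef * z)
    lam_ot = config.hazard_other_base * np.exp(config.hazard_other_coef * z)
    t_bc = rng.exponential(1.0 / lam_bc)
    t_ot = rng.exponential(1.0 / lam_ot)
    t_cens = config.admin_censor_years

    records = []
    for i in range(n):
        t = min(t_bc[i], t_ot[i], t_cens)
        if t_cens <= min(t_bc[i], t_ot[i]):
            event = "censored"
        elif t_bc[i] <= t_ot[i]:
            event = "bc_death"
        else:
            event = "other_death"
        records.append(CohortRecord(
            patient_id=i, true_ki67=float(ki67[i]),
            age_at_diagnosis=float(age[i]), grade=int(grades[i]),
            mitoses_10hpf=int(mitoses[i]), subtype=str(subtypes[i]),
            time_years=float(t), event=event))
    return records
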