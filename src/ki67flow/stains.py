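"""Optical-density transform and H-DAB colour deconvolution.

Brightfield IHC images obey the Beer-Lambert law: the transmitted
intensity in channel c is ``I_c = I0 * 10**(-sum_s conc_s * v_{s,c})``
where each stain s has a unit optical-density vector ``v_s`` and a
per-pixel concentration ``conc_s``.  Converting the image to optical
density (OD) therefore makes pixel values linear in stain amounts, and
stain separation reduces to inverting a 3x3 matrix whose columns are the
stain vectors.

The default H-DAB basis is the widely used published one (hematoxylin
~(0.65, 0.70, 0.29), DAB ~(0.27, 0.57, 0.78)); per-image refinement is
available through :func:`estimate_stain_vectors`.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "StainProfile",
    "ODImage",
    "rgb_to_od",
    "deconvolve",
    "estimate_stain_vectors",
]

# Standard published H-DAB optical-density basis.
_DEFAULT_HEMATOXYLIN = (0.65, 0.70, 0.29)
_DEFAULT_DAB = (0.27, 0.57, 0.78)


def _unit(v) -> np.ndarray:
    v = np.asarray(v, dtype=float)
    n = np.linalg.norm(v)
    if n == 0:
        raise ValueError("stain vector must be nonzero")
    return v / n


@dataclass(frozen=True)
class StainProfile:
    """Unit OD vectors for hematoxylin, DAB and the residual stain.

    The residual is the (normalized, nonnegative) cross product of the
    two dye vectors; it completes the deconvolution basis so the 3x3
    stain matrix is invertible.
    """

    vec_hematoxylin: np.ndarray
    vec_dab: np.ndarray
    vec_residual: np.ndarray = None  # type: ignore[assignment]
    i0: float = 255.0

    def __post_init__(self):
        h = _unit(self.vec_hematoxylin)
        d = _unit(self.vec_dab)
        if np.any(h < 0) or np.any(d < 0):
            raise ValueError("stain vectors must be nonnegative")
        if self.vec_residual is None:
            # True cross product: orthogonal complement of the two dyes.
            # Unlike dye vectors it may carry negative components.
            r = _unit(np.cross(h, d))
        else:
            r = _unit(self.vec_residual)
        object.__setattr__(self, "vec_hematoxylin", h)
        object.__setattr__(self, "vec_dab", d)
        object.__setattr__(self, "vec_residual", r)
        if self.i0 <= 0:
            raise ValueError("white point i0 must be positive")

    @classmethod
    def default_hdab(cls, i0: float = 255.0) -> "StainProfile":
        """The community-standard H-DAB basis."""
        return cls(_DEFAULT_HEMATOXYLIN, _DEFAULT_DAB, i0=i0)

    @property
    def matrix(self) -> np.ndarray:
        """3x3 matrix whose columns are (hematoxylin, DAB, residual)."""
        return np.stack(
            [self.vec_hematoxylin, self.vec_dab, self.vec_residual], axis=1
        )

    @property
    def condition_number(self) -> float:
        return float(np.linalg.cond(self.matrix))

    @property
    def stain_names(self) -> tuple[str, str, str]:
        return ("hematoxylin", "dab", "residual")

    def angular_distance_deg(self, other: "StainProfile") -> dict[str, float]:
        """Per-stain angle (degrees) between this profile and another."""
        out = {}
        for name, a, b in (
            ("hematoxylin", self.vec_hematoxylin, other.vec_hematoxylin),
            ("dab", self.vec_dab, other.vec_dab),
            ("residual", self.vec_residual, other.vec_residual),
        ):
            c = float(np.clip(np.dot(a, b), -1.0, 1.0))
            out[name] = float(np.degrees(np.arccos(c)))
        return out


@dataclass
class ODImage:
    """Per-channel optical-density raster with its physical pixel size."""

    od: np.ndarray  # (H, W, 3), nonnegative
    pixel_size_um: float = 0.23
    i0: float = 255.0

    def __post_init__(self):
        self.od = np.asarray(self.od, dtype=float)
        if self.od.ndim != 3 or self.od.shape[-1] != 3:
            raise ValueError("OD raster must have shape (H, W, 3)")
        if self.pixel_size_um <= 0:
            raise ValueError("pixel_size_um must be positive")

    @property
    def od_sum(self) -> np.ndarray:
        """Channel-summed OD, the watershed detection channel."""
        return self.od.sum(axis=-1)

    @property
    def shape(self) -> tuple[int, int]:
        return self.od.shape[:2]


def rgb_to_od(rgb_image: np.ndarray, i0: float = 255.0, epsilon: float = 1.0,
              pixel_size_um: float = 0.23) -> ODImage:
    """Convert a brightfield RGB image to optical density.

    ``OD_c = -log10(clip(I_c, epsilon, i0) / i0)`` — the exact inverse
    of Beer-Lambert transmission; ``epsilon`` (one 8-bit intensity unit
    by default) only guards against log(0) at fully absorbed pixels.
    """
    img = np.asarray(rgb_image, dtype=float)
    if img.ndim != 3 or img.shape[-1] != 3:
        raise ValueError("expected an RGB image of shape (H, W, 3)")
    od = -np.log10(np.clip(img, epsilon, i0) / i0)
    od = np.clip(od, 0.0, None)
    return ODImage(od=od, pixel_size_um=pixel_size_um, i0=i0)


def deconvolve(od: ODImage, profile: StainProfile,
               clip_negative: bool = True) -> dict[str, np.ndarray]:
    """Unmix an OD image into per-stain concentration rasters.

    Solves ``M @ conc = od`` per pixel, M being the stain matrix.
    Negative concentrations (noise outside the stain simplex) are
    clipped to zero and the clipped fraction is logged.
    """
    m = profile.matrix
    cond = np.linalg.cond(m)
    if not np.isfinite(cond) or cond > 1e8:
        angles = profile.angular_distance_deg(profile)  # placeholder for naming
        pairs = []
        names = profile.stain_names
        vecs = [profile.vec_hematoxylin, profile.vec_dab, profile.vec_residual]
        for i in range(3):
            for j in range(i + 1, 3):
                if abs(np.dot(vecs[i], vecs[j])) > 1 - 1e-9:
                    pairs.append(f"{names[i]}~{names[j]}")
        raise ValueError(
            "singular stain profile; collinear vectors: "
            + (", ".join(pairs) if pairs else "ill-conditioned matrix")
        )
    inv = np.linalg.inv(m)
    flat = od.od.reshape(-1, 3)
    conc = flat @ inv.T
    if clip_negative:
        neg = conc < 0
        frac = float(neg.mean())
        if frac > 0:
            logger.info("deconvolve: clipped %.3f%% negative concentrations",
                        100 * frac)
        conc = np.where(neg, 0.0, conc)
    conc = conc.reshape(od.od.shape)
    names = profile.stain_names
    return {names[k]: conc[..., k] for k in range(3)}


def estimate_stain_vectors(od: ODImage, default: StainProfile | None = None,
                           min_od_sum: float = 0.15,
                           percentile: float = 5.0,
                           min_pixels_per_stain: int = 50) -> StainProfile:
    """Re-estimate the H and DAB vectors from the image itself.

    Foreground pixels (``od_sum > min_od_sum``) are assigned to their
    dominant stain under the default profile; each dye vector is then
    the unit-normalized trimmed mean direction of its pixel group
    (the ``percentile``% of pixels most deviant in angle from the
    provisional mean are discarded).  Falls back to the default profile
    with a warning when a stain group is too small.
    """
    if default is None:
        default = StainProfile.default_hdab(i0=od.i0)
    flat = od.od.reshape(-1, 3)
    fg = flat[flat.sum(axis=1) > min_od_sum]
    if fg.shape[0] < 2 * min_pixels_per_stain:
        logger.warning("estimate_stain_vectors: too few foreground pixels "
                       "(%d); returning default profile", fg.shape[0])
        return default

    conc = fg @ np.linalg.inv(default.matrix).T
    pos = np.clip(conc[:, :2], 0.0, None)
    dominant = np.argmax(pos, axis=1)  # 0 = hematoxylin, 1 = DAB
    purity = pos.max(axis=1) / np.maximum(pos.sum(axis=1), 1e-12)

    new_vecs = []
    for k, name in enumerate(("hematoxylin", "dab")):
        sel = dominant == k
        if sel.sum() < min_pixels_per_stain:
            logger.warning("estimate_stain_vectors: only %d %s-dominant "
                           "pixels; returning default profile",
                           int(sel.sum()), name)
            return default
        # favour the purest quartile of each group: mixture pixels pull
        # the mean direction toward the other stain
        cut = np.percentile(purity[sel], 75)
        group = fg[sel & (purity >= cut)]
        dirs = group / np.linalg.norm(group, axis=1, keepdims=True)
        mean_dir = _unit(dirs.mean(axis=0))
        if percentile > 0:
            cos = dirs @ mean_dir
            keep = cos >= np.percentile(cos, percentile)
            mean_dir = _unit(dirs[keep].mean(axis=0))
        new_vecs.append(np.clip(mean_dir, 0.0, None))
    return StainProfile(new_vecs[0], new_vecs[1], i0=default.i0)
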