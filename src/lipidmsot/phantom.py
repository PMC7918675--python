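"""Layered forearm cross-section phantom with ground-truth labels.

The imaged geometry is a hand-held probe view of the forearm: a coupling
medium above the skin line, then skin, subcutaneous fat, and skeletal
muscle with increasing depth; a superficial vein (cephalic) embedded in the
fat layer and a deeper artery (radial) embedded in the muscle. Default
field of view is 4 x 4 cm at 0.1 mm/pixel (400 x 400), comfortably above
the < 300 um resolution of the clinical system being emulated.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["Compartment", "PhantomConfig", "TissueGeometry", "GeometryError",
           "build_forearm_phantom"]


class GeometryError(ValueError):
    """A structure was placed outside its host tissue."""


class Compartment:
    """Integer labels of the phantom compartments."""

    BACKGROUND = 0  # acoustic coupling medium above the skin
    SKIN = 1
    FAT = 2
    MUSCLE = 3
    ARTERY = 4
    VEIN = 5

    NAMES = {
        BACKGROUND: "background",
        SKIN: "skin",
        FAT: "fat",
        MUSCLE: "muscle",
        ARTERY: "artery",
        VEIN: "vein",
    }
    BY_NAME = {v: k for k, v in NAMES.items()}


@dataclass(frozen=True)
class PhantomConfig:
    """Geometry parameters; ranges are sampled per seed.

    All physical lengths in mm. Vessels are axis-aligned ellipses fully
    contained in their host layer (vein in fat, artery in muscle). Explicit
    vessel placements override the seeded draw and are validated.
    """

    height: int = 400
    width: int = 400
    pixel_pitch: float = 0.1          # mm / pixel
    skin_row: int = 60                # first tissue row (skin line)
    skin_thickness: float = 1.5
    fat_thickness_range: tuple[float, float] = (5.0, 9.0)
    vein_radius_range: tuple[float, float] = (1.2, 1.8)   # cephalic vein ~2.4-3.6 mm across
    artery_radius_range: tuple[float, float] = (1.1, 1.4)  # radial artery ~2.2-2.8 mm across
    vein_center: tuple[float, float] | None = None    # (row, col) in px, optional
    artery_center: tuple[float, float] | None = None
    vein_radii: tuple[float, float] | None = None     # (vertical, horizontal) mm
    artery_radii: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        if self.height < 128 or self.width < 128:
            raise ValueError("image must be at least 128 x 128 pixels")
        if not (0.05 < self.pixel_pitch <= 0.2):
            raise ValueError("pixel_pitch must lie in (0.05, 0.2] mm")
        if not (0 < self.skin_row < self.height // 2):
            raise ValueError("skin_row must lie in the upper half of the image")


@dataclass(frozen=True)
class TissueGeometry:
    """Label map plus the physical scale needed to interpret it."""

    label_map: np.ndarray             # (H, W) uint8, Compartment labels
    pixel_pitch: float                # mm / pixel
    skin_row: int

    @property
    def shape(self) -> tuple[int, int]:
        return self.label_map.shape  # type: ignore[return-value]

    def mask(self, compartment: str) -> np.ndarray:
        """Boolean ground-truth mask for a named compartment."""
        label = Compartment.BY_NAME[compartment]
        return self.label_map == label

    def depth_mm(self) -> np.ndarray:
        """Per-pixel depth below the skin line in mm (0 above the skin)."""
        rows = np.arange(self.label_map.shape[0])
        depth = np.maximum(rows - self.skin_row, 0) * self.pixel_pitch
        return np.broadcast_to(depth[:, None], self.label_map.shape)


def _ellipse_mask(shape, center_rc, radii_px):
    rr = np.arange(shape[0])[:, None]
    cc = np.arange(shape[1])[None, :]
    r0, c0 = center_rc
    ar, ac = radii_px
    return ((rr - r0) / ar) ** 2 + ((cc - c0) / ac) ** 2 <= 1.0


def build_forearm_phantom(
    config: PhantomConfig | None = None, seed: int = 0
) -> TissueGeometry:
    """Build a seeded layered phantom; deterministic for fixed (config, seed)."""
    cfg = config or PhantomConfig()
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0x9E0]))
    h, w, pitch = cfg.height, cfg.width, cfg.pixel_pitch

    labels = np.full((h, w), Compartment.BACKGROUND, dtype=np.uint8)
    skin_px = max(1, round(cfg.skin_thickness / pitch))
    fat_mm = rng.uniform(*cfg.fat_thickness_range)
    fat_px = max(1, round(fat_mm / pitch))
    fat_top = cfg.skin_row + skin_px
    muscle_top = fat_top + fat_px
    if muscle_top >= h:
        raise GeometryError("fat layer extends past the bottom of the image")

    labels[cfg.skin_row:fat_top, :] = Compartment.SKIN
    labels[fat_top:muscle_top, :] = Compartment.FAT
    labels[muscle_top:, :] = Compartment.MUSCLE

    # vein: superficial, in the fat layer
    if cfg.vein_radii is not None:
        v_ar, v_ac = (r / pitch for r in cfg.vein_radii)
    else:
        v_ar = rng.uniform(*cfg.vein_radius_range) / pitch
        v_ac = v_ar * rng.uniform(1.0, 1.3)
    if cfg.vein_center is not None:
        v_rc = cfg.vein_center
    else:
        margin = 2
        lo, hi = fat_top + v_ar + margin, muscle_top - v_ar - margin
        if lo >= hi:
            raise GeometryError("fat layer too thin to host the vein")
        v_rc = (rng.uniform(lo, hi), rng.uniform(0.2 * w, 0.45 * w))
    _check_vessel(v_rc, (v_ar, v_ac), fat_top, muscle_top, cfg, "vein")
    labels[_ellipse_mask((h, w), v_rc, (v_ar, v_ac))] = Compartment.VEIN

    # artery: deeper, in the muscle
    if cfg.artery_radii is not None:
        a_ar, a_ac = (r / pitch for r in cfg.artery_radii)
    else:
        a_ar = rng.uniform(*cfg.artery_radius_range) / pitch
        a_ac = a_ar * rng.uniform(1.0, 1.3)
    if cfg.artery_center is not None:
        a_rc = cfg.artery_center
    else:
        lo = muscle_top + a_ar + 2
        hi = min(muscle_top + (6.0 / pitch), h - a_ar - 2)
        if lo >= hi:
            raise GeometryError("muscle layer too thin to host the artery")
        a_rc = (rng.uniform(lo, hi), rng.uniform(0.55 * w, 0.8 * w))
    _check_vessel(a_rc, (a_ar, a_ac), muscle_top, h, cfg, "artery")
    labels[_ellipse_mask((h, w), a_rc, (a_ar, a_ac))] = Compartment.ARTERY

    return TissueGeometry(label_map=labels, pixel_pitch=pitch, skin_row=cfg.skin_row)


def _check_vessel(center_rc, radii_px, top, bottom, cfg, name):
    r0, c0 = center_rc
    ar, ac = radii_px
    if r0 < cfg.skin_row:
        raise GeometryError(f"{name} center lies above the skin line")
    if r0 - ar < top or r0 + ar > bottom:
        raise GeometryError(f"{name} does not fit inside its host layer")
    if c0 - ac < 0 or c0 + ac > cfg.width:
        raise GeometryError(f"{name} extends past the lateral image bounds")
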