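"""Synthetic drying-leaf phantom.

Generates the ground-truth scene that both imaging pipelines observe: a
leaf-shaped region on a perfectly reflecting metal platform, with a
procedural venation pattern (midrib plus parallel, bamboo-style
secondaries, or branching, celtis-style secondaries), per-pixel water and
dry-matter volume fractions, a thickness map, and a piecewise-exponential
three-stage drying law.  Veins carry more water than the lamina and are
thicker (the midrib core tapers up to roughly twice the lamina thickness),
and they dehydrate more slowly.

Everything is a pure function of (preset, shape, pixel pitch, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy import ndimage

__all__ = [
    "LeafPhantom",
    "DryingCurve",
    "generate_phantom",
    "drying_multiplier",
    "phantom_at",
]

PRESETS = ("parallel_venation", "pinnate_venation")


class ValidationError(ValueError):
    pass


@dataclass(frozen=True)
class LeafPhantom:
    """Pixel grids describing the leaf-on-metal scene at one instant."""

    pixel_pitch_um: float
    water_fraction: np.ndarray
    dry_fraction: np.ndarray
    thickness_um: np.ndarray
    vein_mask: np.ndarray
    leaf_mask: np.ndarray
    seed: int

    def __post_init__(self) -> None:
        shape = self.water_fraction.shape
        for name in ("dry_fraction", "thickness_um", "vein_mask", "leaf_mask"):
            if getattr(self, name).shape != shape:
                raise ValidationError(f"{name} shape mismatch")
        if np.any(self.water_fraction + self.dry_fraction > 1.0 + 1e-9):
            raise ValidationError("water + dry fraction exceeds 1 somewhere")
        if np.any(self.thickness_um[~self.leaf_mask] != 0.0):
            raise ValidationError("off-leaf pixels must have zero thickness")

    @property
    def shape(self) -> tuple[int, int]:
        return self.water_fraction.shape

    def total_water(self) -> float:
        """Column-integrated water, sum of water_fraction * thickness (um)."""
        return float(np.sum(self.water_fraction * self.thickness_um))

    def to_npz(self, path) -> None:
        np.savez_compressed(
            path, pixel_pitch_um=self.pixel_pitch_um, seed=self.seed,
            water_fraction=self.water_fraction, dry_fraction=self.dry_fraction,
            thickness_um=self.thickness_um, vein_mask=self.vein_mask,
            leaf_mask=self.leaf_mask)

    @classmethod
    def from_npz(cls, path) -> "LeafPhantom":
        z = np.load(path)
        return cls(float(z["pixel_pitch_um"]), z["water_fraction"],
                   z["dry_fraction"], z["thickness_um"],
                   z["vein_mask"].astype(bool), z["leaf_mask"].astype(bool),
                   int(z["seed"]))

    def water_to_tiff(self, path) -> None:
        """Export the water-fraction map as a 16-bit TIFF (0..1 -> 0..65535)."""
        import tifffile

        img = np.clip(self.water_fraction, 0.0, 1.0)
        tifffile.imwrite(path, (img * 65535).astype(np.uint16))


@dataclass(frozen=True)
class DryingCurve:
    """Three-stage piecewise-exponential water-loss law.

    Stage boundaries default to 20 min (end of the rapid, stomata-open
    phase) and 120 min (end of the stabilised plateau, after which a slow
    continuous decay resumes).  Rates are per-minute decay constants; vein
    pixels use rates divided by ``vein_retention``.  The multiplier never
    falls below ``floor``.
    """

    t_fast_end: float = 20.0
    t_plateau_end: float = 120.0
    rate_fast: float = 0.06
    rate_plateau: float = 0.0015
    rate_slow: float = 0.01
    floor: float = 0.05
    vein_retention: float = 3.0

    def __post_init__(self) -> None:
        if not (0.0 < self.t_fast_end < self.t_plateau_end):
            raise ValidationError("require 0 < t_fast_end < t_plateau_end")
        if not (self.rate_fast > self.rate_slow > self.rate_plateau >= 0.0):
            raise ValidationError("require rate_fast > rate_slow > rate_plateau >= 0")
        if not (0.0 <= self.floor < 1.0):
            raise ValidationError("require 0 <= floor < 1")
        if not self.vein_retention >= 1.0:
            raise ValidationError("vein_retention must be >= 1")


# ---------------------------------------------------------------------------
# generation helpers
# ---------------------------------------------------------------------------

def _smooth_noise(rng: np.random.Generator, shape, sigma_frac: float = 1 / 16):
    """Unit-std spatially smooth noise field."""
    raw = rng.standard_normal(shape)
    sigma = max(1.0, sigma_frac * min(shape))
    sm = ndimage.gaussian_filter(raw, sigma=sigma, mode="reflect")
    sd = sm.std()
    return sm / sd if sd > 0 else sm


def _leaf_mask(rng: np.random.Generator, shape) -> np.ndarray:
    """Elliptical blade with a wobbly margin, long axis along rows."""
    nr, nc = shape
    r = (np.arange(nr) - (nr - 1) / 2) / (0.44 * nr)
    c = (np.arange(nc) - (nc - 1) / 2) / (0.33 * nc)
    rad = np.sqrt(r[:, None] ** 2 + c[None, :] ** 2)
    wobble = 0.05 * _smooth_noise(rng, shape, sigma_frac=1 / 8)
    return rad + wobble <= 1.0


def _vein_skeleton(rng: np.random.Generator, shape, leaf: np.ndarray,
                   preset: str) -> np.ndarray:
    """Boolean skeleton of midrib + secondary veins (1-px-wide strokes)."""
    nr, nc = shape
    skel = np.zeros(shape, dtype=bool)
    rows = np.arange(nr)
    mid = (nc - 1) / 2 + 0.02 * nc * np.sin(
        2 * np.pi * rows / nr + rng.uniform(0, 2 * np.pi))
    mid_idx = np.clip(np.round(mid).astype(int), 0, nc - 1)
    skel[rows, mid_idx] = True

    if preset == "parallel_venation":
        spacing = max(4, int(round(0.11 * nc)))
        n_side = max(1, (nc // 2) // spacing)
        for side in (-1, 1):
            for j in range(1, n_side + 1):
                off = side * j * spacing + rng.integers(-1, 2)
                wig = 0.01 * nc * np.sin(
                    2 * np.pi * rows / nr + rng.uniform(0, 2 * np.pi))
                col = np.clip(np.round(mid + off + wig).astype(int), 0, nc - 1)
                skel[rows, col] = True
    elif preset == "pinnate_venation":
        step = max(5, int(round(0.12 * nr)))
        slope = 0.9  # columns advanced per row
        for i, r0 in enumerate(range(step // 2, nr - 2, step)):
            side = -1 if i % 2 else 1
            length = int(0.5 * nc)
            rr = r0 + np.arange(length)  # branch slants down-and-out
            cc = mid[min(r0, nr - 1)] + side * slope * np.arange(length) \
                + rng.normal(0, 0.3)
            ok = (rr < nr) & (cc >= 0) & (cc <= nc - 1)
            skel[rr[ok], np.round(cc[ok]).astype(int)] = True
    else:
        raise ValidationError(f"unknown preset {preset!r}; use one of {PRESETS}")
    skel &= leaf
    return skel


def generate_phantom(preset: str = "parallel_venation",
                     shape: tuple[int, int] = (128, 128),
                     pixel_pitch_um: float = 200.0,
                     seed: int = 0,
                     *,
                     water_vein: float = 0.8,
                     water_lamina: float = 0.4,
                     dry_fraction: float = 0.15,
                     thickness_um: float = 200.0,
                     thickness_jitter: float = 0.10,
                     vein_thickness_boost: float = 1.0,
                     water_noise: float = 0.04,
                     crease_ridge: bool = False) -> LeafPhantom:
    """Generate a seeded leaf phantom.

    The venation profile tapers smoothly from the skeleton: water fraction
    rises from ``water_lamina`` to ``water_vein`` at the vein core and the
    thickness is boosted by up to ``1 + vein_thickness_boost`` at the
    midrib.  ``crease_ridge`` optionally adds a Gaussian ridge to the
    thickness map, emulating a crease/curl in the blade.
    """
    if preset not in PRESETS:
        raise ValidationError(f"unknown preset {preset!r}; use one of {PRESETS}")
    shape = tuple(int(s) for s in shape)
    if shape[0] < 16 or shape[1] < 16:
        raise ValidationError("shape must be at least 16x16")
    rng = np.random.default_rng(seed)

    leaf = _leaf_mask(rng, shape)
    skel = _vein_skeleton(rng, shape, leaf, preset)
    dist = ndimage.distance_transform_edt(~skel)
    width = max(1.2, 0.012 * shape[1])
    profile = np.exp(-((dist / width) ** 2))
    vein_mask = (dist <= width) & leaf

    water = water_lamina + (water_vein - water_lamina) * profile
    water = water + water_noise * _smooth_noise(rng, shape)
    water = np.clip(water, 0.02, 1.0 - dry_fraction - 0.02)
    water[~leaf] = 0.0

    dry = np.where(leaf, dry_fraction, 0.0)

    thick = thickness_um * (1.0 + thickness_jitter * _smooth_noise(rng, shape))
    thick = thick * (1.0 + vein_thickness_boost * profile)
    if crease_ridge:
        nr, nc = shape
        r0 = rng.uniform(0.3, 0.7) * nr
        rr = np.arange(nr)[:, None]
        thick = thick * (1.0 + 0.3 * np.exp(-((rr - r0) / (0.05 * nr)) ** 2))
    thick = np.clip(thick, 0.3 * thickness_um, None)
    thick[~leaf] = 0.0

    return LeafPhantom(float(pixel_pitch_um), water, dry, thick,
                       vein_mask, leaf, int(seed))


# ---------------------------------------------------------------------------
# drying dynamics
# ---------------------------------------------------------------------------

def drying_multiplier(t_min, curve: DryingCurve, on_vein=False):
    """Fraction of initial water retained at time ``t_min`` (continuous).

    Piecewise-exponential: decay constant ``rate_fast`` before
    ``t_fast_end``, ``rate_plateau`` until ``t_plateau_end``, ``rate_slow``
    afterwards; vein pixels divide every rate by ``vein_retention``.  The
    result is clamped from below at ``curve.floor``.
    """
    t = np.asarray(t_min, dtype=float)
    if np.any(t < 0):
        raise ValidationError("time must be >= 0")
    retention = np.where(np.asarray(on_vein, bool), curve.vein_retention, 1.0)
    expo = (
        curve.rate_fast * np.minimum(t, curve.t_fast_end)
        + curve.rate_plateau * np.clip(t - curve.t_fast_end, 0.0,
                                       curve.t_plateau_end - curve.t_fast_end)
        + curve.rate_slow * np.maximum(t - curve.t_plateau_end, 0.0)
    ) / retention
    out = np.maximum(np.exp(-expo), curve.floor)
    return out if out.ndim else float(out)


def phantom_at(phantom: LeafPhantom, curve: DryingCurve, t_min: float) -> LeafPhantom:
    """Phantom state after ``t_min`` minutes of drying (non-mutating).

    Only ``water_fraction`` changes; masks, dry matter and thickness are
    invariant.
    """
    mult = drying_multiplier(float(t_min), curve, on_vein=phantom.vein_mask)
    return replace(phantom, water_fraction=phantom.water_fraction * mult)
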