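"""Frequency-domain optics of a hydrated leaf on a metal backing.

A leaf is treated as a three-component effective medium (liquid water,
dry plant matter, air) forming a thin absorbing film on an ideally
reflecting metal platform.  This module provides

* a double-Debye model for the complex permittivity of liquid water in
  the terahertz band, with a scalar extinction calibration so that the
  power absorption coefficient can be anchored to published values
  (e.g. 500 cm^-1 at 2.71 THz),
* a constant-index model for dry plant matter (cellulose-like, weakly
  absorbing),
* a linear volume-fraction mixing rule for the effective complex
  refractive index of the composite,
* power absorption coefficient and 1/e penetration depth, and
* the complex reflection coefficient of an arbitrary layer stack over a
  perfect-conductor (or free-space) backing via the recursive
  Rouard/transfer-matrix method, at oblique incidence, s or p
  polarization.

Conventions: time dependence exp(-i omega t), so passive media have
``eps_imag >= 0`` and refractive index ``m = n + i k`` with ``k >= 0``.
Frequencies are in THz, thicknesses in micrometres, absorption
coefficients in cm^-1, penetration depths in micrometres.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.constants import c as C_LIGHT  # m/s

__all__ = [
    "DielectricSpectrum",
    "DebyeParams",
    "LayerStack",
    "water_permittivity",
    "dry_matter_spectrum",
    "calibrate_absorption",
    "effective_leaf_index",
    "absorption_coefficient",
    "penetration_depth",
    "stack_reflectivity",
    "front_surface_reflection",
    "leaf_on_metal_reflectivity",
    "mix_index",
]

THZ = 1e12
#: Display cap for the penetration depth of near-lossless media (um).
DEFAULT_DEPTH_CAP_UM = 5000.0


class ValidationError(ValueError):
    """Raised when a physical parameter set violates its invariants."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DielectricSpectrum:
    """Complex optical response of a material sampled on a frequency grid.

    Both the relative permittivity (``eps_real + i eps_imag``) and the
    refractive index (``n + i k``) views are stored; they satisfy
    ``(n + i k)^2 = eps_real + i eps_imag``.
    """

    freq_thz: np.ndarray
    eps_real: np.ndarray
    eps_imag: np.ndarray
    n: np.ndarray
    k: np.ndarray

    def __post_init__(self) -> None:
        f = np.asarray(self.freq_thz, dtype=float)
        if f.ndim != 1 or f.size == 0:
            raise ValidationError("freq grid must be a non-empty 1-D array")
        if f.size > 1 and not np.all(np.diff(f) > 0):
            raise ValidationError("freq grid must be strictly increasing")
        for name in ("eps_real", "eps_imag", "n", "k"):
            a = np.asarray(getattr(self, name), dtype=float)
            if a.shape != f.shape:
                raise ValidationError(f"{name} shape {a.shape} != grid {f.shape}")
            object.__setattr__(self, name, a)
        object.__setattr__(self, "freq_thz", f)
        if np.any(self.eps_imag < -1e-12):
            raise ValidationError("eps_imag must be >= 0 for a passive medium")
        if np.any(self.n < 1e-6):
            raise ValidationError("n must be >= 1e-6")
        if np.any(self.k < -1e-12):
            raise ValidationError("k must be >= 0")

    # -- constructors -------------------------------------------------------
    @classmethod
    def from_eps(cls, freq_thz, eps: np.ndarray) -> "DielectricSpectrum":
        """Build from complex relative permittivity (principal square root)."""
        eps = np.asarray(eps, dtype=complex)
        m = np.sqrt(eps)
        return cls(np.asarray(freq_thz, float), eps.real, eps.imag, m.real, m.imag)

    @classmethod
    def from_nk(cls, freq_thz, n, k) -> "DielectricSpectrum":
        n = np.asarray(n, float)
        k = np.asarray(k, float)
        return cls(np.asarray(freq_thz, float), n * n - k * k, 2 * n * k, n, k)

    # -- views ---------------------------------------------------------------
    @property
    def m(self) -> np.ndarray:
        """Complex refractive index n + i k."""
        return self.n + 1j * self.k

    def interp_m(self, freq_thz) -> np.ndarray:
        """Complex index linearly interpolated onto another grid."""
        f = np.asarray(freq_thz, float)
        if f.shape == self.freq_thz.shape and np.allclose(f, self.freq_thz):
            return self.m
        n = np.interp(f, self.freq_thz, self.n)
        k = np.interp(f, self.freq_thz, self.k)
        return n + 1j * k

    # -- serialization -------------------------------------------------------
    def to_csv(self, path) -> None:
        pd.DataFrame(
            {"freq_THz": self.freq_thz, "eps_real": self.eps_real,
             "eps_imag": self.eps_imag}
        ).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "DielectricSpectrum":
        df = pd.read_csv(path)
        return cls.from_eps(
            df["freq_THz"].to_numpy(),
            df["eps_real"].to_numpy() + 1j * df["eps_imag"].to_numpy(),
        )


@dataclass(frozen=True)
class DebyeParams:
    """Double-Debye relaxation parameters for liquid water.

    ``calib_scale`` is a unitless multiplier applied to the extinction
    coefficient k after the permittivity evaluation; it is set by
    :func:`calibrate_absorption` so the model's power absorption passes
    through published anchor values.
    """

    eps_static: float = 78.36
    eps_intermediate: float = 4.93
    eps_inf: float = 3.48
    tau1_ps: float = 8.24
    tau2_ps: float = 0.18
    calib_scale: float = 1.0

    def __post_init__(self) -> None:
        if not (self.eps_static > self.eps_intermediate > self.eps_inf > 1.0):
            raise ValidationError(
                "require eps_static > eps_intermediate > eps_inf > 1")
        if not (self.tau1_ps > self.tau2_ps > 0.0):
            raise ValidationError("require tau1 > tau2 > 0")
        if not self.calib_scale > 0.0:
            raise ValidationError("calib_scale must be > 0")


@dataclass(frozen=True)
class LayerStack:
    """Ordered stack of homogeneous layers over a backing half-space.

    ``layers`` lists (thickness_um, DielectricSpectrum) from the side the
    beam enters (air) down to the backing.
    """

    layers: Sequence[tuple[float, DielectricSpectrum]]
    backing: str = "perfect_conductor"
    incidence_angle_deg: float = 0.0
    polarization: str = "s"

    def __post_init__(self) -> None:
        for d, _spec in self.layers:
            if not d > 0:
                raise ValidationError("layer thicknesses must be > 0")
        if not (0.0 <= self.incidence_angle_deg < 90.0):
            raise ValidationError("incidence angle must be in [0, 90) deg")
        if self.backing not in ("perfect_conductor", "free_space"):
            raise ValidationError(f"unknown backing {self.backing!r}")
        if self.polarization not in ("s", "p"):
            raise ValidationError("polarization must be 's' or 'p'")


# ---------------------------------------------------------------------------
# Material models
# ---------------------------------------------------------------------------

def water_permittivity(freq_thz, params: DebyeParams | None = None) -> DielectricSpectrum:
    """Double-Debye permittivity of liquid water.

    eps(omega) = eps_inf + (eps_s - eps_i)/(1 - i omega tau1)
                         + (eps_i - eps_inf)/(1 - i omega tau2)

    in the exp(-i omega t) convention (positive-definite loss).  ``n`` and
    ``k`` come from the principal square root; ``params.calib_scale``
    multiplies ``k``.  Nominal validity: 0.05-6 THz (the relaxational form
    is evaluated, without error, on any non-negative grid so that static
    and high-frequency limits can be inspected).
    """
    p = params if params is not None else DebyeParams()
    f = np.atleast_1d(np.asarray(freq_thz, dtype=float))
    wt1 = 2.0 * np.pi * f * p.tau1_ps  # omega*tau, unitless (THz * ps)
    wt2 = 2.0 * np.pi * f * p.tau2_ps
    eps = (
        p.eps_inf
        + (p.eps_static - p.eps_intermediate) / (1.0 - 1j * wt1)
        + (p.eps_intermediate - p.eps_inf) / (1.0 - 1j * wt2)
    )
    m = np.sqrt(eps)
    n = m.real
    k = m.imag * p.calib_scale
    return DielectricSpectrum.from_nk(f, n, k)


def dry_matter_spectrum(freq_thz, n: float = 1.5,
                        alpha_1thz_cm: float = 10.0) -> DielectricSpectrum:
    """Dry plant matter (cellulose-like): constant n, absorption linear in f.

    alpha(f) = alpha_1thz_cm * f[THz]; since alpha = 4 pi f k / c this
    corresponds to a frequency-independent extinction coefficient.
    """
    f = np.atleast_1d(np.asarray(freq_thz, dtype=float))
    k_const = alpha_1thz_cm * 100.0 * C_LIGHT / (4.0 * np.pi * THZ)
    return DielectricSpectrum.from_nk(f, np.full_like(f, n), np.full_like(f, k_const))


def calibrate_absorption(params: DebyeParams,
                         anchors: Iterable[tuple[float, float]]) -> DebyeParams:
    """Set ``calib_scale`` by least squares through absorption anchors.

    ``anchors`` are (freq_THz, alpha_cm) pairs.  Because alpha is linear in
    k (hence in calib_scale), the least-squares problem has the closed-form
    solution ``scale = sum(alpha0*a) / sum(alpha0**2)`` where alpha0 is the
    uncalibrated model absorption.  A single anchor is matched exactly.
    Calibration is idempotent: the scale is always computed against the
    ``calib_scale = 1`` base model.
    """
    anchors = list(anchors)
    if not anchors:
        raise ValidationError("at least one anchor is required")
    freqs = np.array([a[0] for a in anchors], dtype=float)
    targets = np.array([a[1] for a in anchors], dtype=float)
    base = replace(params, calib_scale=1.0)
    alpha0 = absorption_coefficient(water_permittivity(freqs, base))
    if np.any(alpha0 <= 0.0):
        raise ValidationError("anchor at a frequency where the model has k = 0")
    scale = float(np.dot(alpha0, targets) / np.dot(alpha0, alpha0))
    return replace(params, calib_scale=scale)


def mix_index(f_water, f_dry, m_water, m_dry):
    """Volume-fraction-weighted complex index; air fills the remainder.

    Fractions may be scalars or arrays; a trailing frequency axis on the
    component indices is broadcast against leading pixel axes.
    """
    fw = np.asarray(f_water, dtype=float)[..., np.newaxis]
    fd = np.asarray(f_dry, dtype=float)[..., np.newaxis]
    fa = 1.0 - fw - fd
    return fw * m_water + fd * m_dry + fa * (1.0 + 0.0j)


def effective_leaf_index(f_water: float, f_dry: float, f_air: float,
                         water: DielectricSpectrum,
                         dry: DielectricSpectrum) -> DielectricSpectrum:
    """Effective index of the air/water/dry-matter composite.

    Linear-in-m mixing rule: m_eff = fw*m_w + fd*m_d + fa*1.
    """
    fracs = np.array([f_water, f_dry, f_air], dtype=float)
    if np.any(fracs < -1e-12):
        raise ValidationError("volume fractions must be >= 0")
    if abs(fracs.sum() - 1.0) > 1e-9:
        raise ValidationError(f"volume fractions sum to {fracs.sum()}, not 1")
    m_d = dry.interp_m(water.freq_thz)
    m_eff = f_water * water.m + f_dry * m_d + f_air * (1.0 + 0.0j)
    return DielectricSpectrum.from_nk(water.freq_thz, m_eff.real, m_eff.imag)


# ---------------------------------------------------------------------------
# Absorption and penetration depth
# ---------------------------------------------------------------------------

def absorption_coefficient(spec: DielectricSpectrum) -> np.ndarray:
    """Power absorption coefficient alpha = 4 pi f k / c, in cm^-1."""
    return 4.0 * np.pi * spec.freq_thz * THZ * spec.k / C_LIGHT / 100.0


def penetration_depth(alpha_cm, cap_um: float = DEFAULT_DEPTH_CAP_UM) -> np.ndarray:
    """Power 1/e penetration depth delta = 1/alpha, in um, clipped at cap."""
    alpha = np.asarray(alpha_cm, dtype=float)
    if np.any(alpha < 0):
        raise ValidationError("alpha must be >= 0")
    with np.errstate(divide="ignore"):
        delta = np.where(alpha > 0, 1e4 / np.maximum(alpha, 1e-300), cap_um)
    return np.minimum(delta, cap_um)


# ---------------------------------------------------------------------------
# Layered reflectivity (recursive transfer-matrix / Rouard method)
# ---------------------------------------------------------------------------

def _mcos(m, sin0):
    """m*cos(theta) inside a medium from Snell's law, decaying branch."""
    mc = np.sqrt(m * m - sin0 * sin0)
    # choose the branch with non-negative imaginary part (field decays into
    # the medium); for lossless media pick Re >= 0.
    flip = (mc.imag < 0) | ((mc.imag == 0) & (mc.real < 0))
    return np.where(flip, -mc, mc)


def _eta(m, mc, pol):
    """Effective admittance entering the Fresnel coefficients."""
    return mc if pol == "s" else mc / (m * m)


def layered_reflectivity(ms, ds_um, freq_thz, angle_deg: float = 0.0,
                         pol: str = "s",
                         backing: str = "perfect_conductor") -> np.ndarray:
    """Complex reflection coefficient of a layered stack, broadcastable.

    Parameters
    ----------
    ms
        Sequence of complex-index arrays, one per layer, each broadcastable
        to (..., nf) with the frequency axis last.
    ds_um
        Matching sequence of thicknesses (scalars or arrays broadcastable
        to the leading axes of ``ms``), in micrometres.
    freq_thz
        1-D frequency grid, THz.
    """
    f = np.atleast_1d(np.asarray(freq_thz, dtype=float))
    k0 = 2.0 * np.pi * f * THZ / C_LIGHT  # rad/m
    sin0 = np.sin(np.radians(angle_deg))
    cos0 = np.cos(np.radians(angle_deg))
    m_air = np.asarray(1.0 + 0.0j)
    eta_air = _eta(m_air, cos0, pol)

    ms = [np.asarray(m, dtype=complex) for m in ms]
    mcs = [_mcos(m, sin0) for m in ms]
    etas = [_eta(m, mc, pol) for m, mc in zip(ms, mcs)]

    if backing == "perfect_conductor":
        r_eff = np.asarray(-1.0 + 0.0j)
    elif backing == "free_space":
        eta_below = etas[-1] if ms else eta_air
        r_eff = (eta_below - eta_air) / (eta_below + eta_air)
    else:
        raise ValidationError(f"unknown backing {backing!r}")

    # walk interfaces from the backing toward the entry surface
    for j in range(len(ms) - 1, -1, -1):
        d_m = np.asarray(ds_um[j], dtype=float) * 1e-6
        if np.ndim(d_m) > 0:
            d_m = d_m[..., np.newaxis]
        x = np.exp(2j * k0 * mcs[j] * d_m)
        eta_above = etas[j - 1] if j > 0 else eta_air
        r_top = (eta_above - etas[j]) / (eta_above + etas[j])
        r_eff = (r_top + r_eff * x) / (1.0 + r_top * r_eff * x)
    return r_eff


def stack_reflectivity(stack: LayerStack, freq_thz) -> np.ndarray:
    """Complex reflection coefficient r(f) for a :class:`LayerStack`.

    A perfect-conductor backing contributes reflection -1 at the final
    interface; |r| <= 1 for passive layers.
    """
    f = np.atleast_1d(np.asarray(freq_thz, dtype=float))
    ms = [spec.interp_m(f) for _d, spec in stack.layers]
    ds = [d for d, _spec in stack.layers]
    return layered_reflectivity(
        ms, ds, f, angle_deg=stack.incidence_angle_deg,
        pol=stack.polarization, backing=stack.backing,
    )


def front_surface_reflection(m, angle_deg: float = 0.0, pol: str = "s") -> np.ndarray:
    """Fresnel reflection coefficient of the air/medium entry interface."""
    m = np.asarray(m, dtype=complex)
    sin0 = np.sin(np.radians(angle_deg))
    cos0 = np.cos(np.radians(angle_deg))
    mc = _mcos(m, sin0)
    eta_air = _eta(np.asarray(1.0 + 0.0j), cos0, pol)
    eta = _eta(m, mc, pol)
    return (eta_air - eta) / (eta_air + eta)


def leaf_on_metal_reflectivity(f_water, f_dry, thickness_um, freq_thz,
                               water: DielectricSpectrum,
                               dry: DielectricSpectrum,
                               angle_deg: float = 0.0, pol: str = "s",
                               ) -> np.ndarray:
    """Reflectivity of per-pixel leaf layers on a perfect conductor.

    ``f_water``, ``f_dry`` and ``thickness_um`` may be pixel arrays of any
    common shape; the result gains a trailing frequency axis.  Pixels with
    zero thickness reduce to the bare-metal response r = -1 (their mixed
    index is irrelevant as the layer phase vanishes only when the fractions
    are also zero, i.e. off-leaf pixels carry f_water = f_dry = 0).
    """
    f = np.atleast_1d(np.asarray(freq_thz, dtype=float))
    m_eff = mix_index(f_water, f_dry, water.interp_m(f), dry.interp_m(f))
    return layered_reflectivity([m_eff], [np.asarray(thickness_um, float)], f,
                                angle_deg=angle_deg, pol=pol,
                                backing="perfect_conductor")
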