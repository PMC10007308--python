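"""Fast terahertz QCL laser-feedback-interferometry (LFI) imaging.

A quantum cascade laser acts simultaneously as source and detector: light
reflected by the target re-enters the cavity and perturbs the laser's
terminal voltage (self-mixing).  A small current ramp on each 500 ns drive
pulse sweeps the emission frequency (~600 MHz), so the ~1.2 m external
cavity produces a handful of interferometric fringes per pixel; the target
amplitude is recovered from the dominant FFT peak of that interferogram.

The module forward-simulates per-pixel interferograms with the steady-state
excess-phase self-mixing model, recovers amplitude images, maps them to dB
relative to the frame peak (the bare-metal region), counts the "blue"
pixels more than 60 dB below the peak — the hydrated-area proxy — and
fits a continuous piecewise-linear staging model to the blue-fraction
time series to locate the dehydration-stage breakpoints.

By default the field re-coupled into the laser is the metal-backed
double-pass component only: the leaf's front-surface specular term is
excluded (``LFIConfig.include_front_reflection``), modelling the cuticle's
non-specular scatter.  This is what makes wet tissue fall tens of dB below
the bare-metal peak.  A quadratic field-curvature phase across the scan
field (the post-objective scanning artefact) can be applied; it scrambles
phase but leaves the recovered amplitudes essentially untouched, which is
why this scheme is a predominantly amplitude-detecting one.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd
from scipy.constants import c as C_LIGHT

from .leaf_phantom import DryingCurve, LeafPhantom, phantom_at
from .water_optics import (DielectricSpectrum, front_surface_reflection,
                           leaf_on_metal_reflectivity, mix_index)

__all__ = [
    "LFIConfig",
    "Interferogram",
    "LFIFrame",
    "HydrationSeries",
    "BreakpointFit",
    "sweep_frequency",
    "excess_phase",
    "simulate_interferogram",
    "recover_amplitude",
    "scan_frame",
    "run_lfi_sequence",
    "blue_fraction",
    "hydration_series",
    "synthesize_hydration_series",
    "fit_breakpoints",
]

#: Feedback level above which the excess-phase equation has >= 5 solutions
#: and even branch tracking becomes ambiguous.
C_STRONG_MULTISTABLE = 4.6


class ValidationError(ValueError):
    pass


@dataclass(frozen=True)
class LFIConfig:
    """Acquisition and self-mixing parameters of the QCL-LFI imager."""

    carrier_thz: float = 2.71
    sweep_span_mhz: float = 600.0
    pulse_duration_ns: float = 500.0
    samples_per_pulse: int = 512
    cavity_length_m: float = 1.2
    feedback_c: float = 0.3
    henry_alpha: float = 3.0
    pixel_dwell_ms: float = 0.1
    grid: tuple[int, int] = (500, 500)
    extent_mm: tuple[float, float] = (25.0, 25.0)
    #: peak quadratic phase (radians) at the field corner; 0 disables
    field_curvature_rad: float = 20.0
    blue_threshold_db: float = -60.0
    include_front_reflection: bool = False
    dc_offset: float = 0.1
    noise_rms: float = 1e-3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sweep_span_mhz <= 0:
            raise ValidationError("sweep_span must be > 0")
        if self.feedback_c < 0:
            raise ValidationError("feedback C must be >= 0")
        if self.samples_per_pulse < 16:
            raise ValidationError("need at least 16 samples per pulse")

    @property
    def frame_seconds(self) -> float:
        """Frame acquisition time = pixels x dwell."""
        return self.grid[0] * self.grid[1] * self.pixel_dwell_ms / 1e3

    def to_json(self) -> str:
        return json.dumps(asdict(self), sort_keys=True)


@dataclass(frozen=True)
class Interferogram:
    """Self-mixing voltage trace across one laser pulse."""

    sample_axis_ns: np.ndarray
    voltage: np.ndarray

    def __post_init__(self) -> None:
        if self.voltage.shape != self.sample_axis_ns.shape:
            raise ValidationError("axis/voltage shape mismatch")
        if not np.all(np.isfinite(self.voltage)):
            raise ValidationError("voltage must be finite")


@dataclass(frozen=True)
class LFIFrame:
    """One recovered amplitude image with its acquisition timestamp."""

    amplitude: np.ndarray
    db_map: np.ndarray
    frame_time_min: float
    leaf_mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        if not np.all(np.isfinite(self.amplitude)) or np.any(self.amplitude < 0):
            raise ValidationError("amplitude must be finite and >= 0")
        if self.db_map.max() > 1e-9:
            raise ValidationError("db_map must be <= 0 (peak-referenced)")


@dataclass(frozen=True)
class HydrationSeries:
    """Blue-pixel fraction vs frame time, plus fitted stage breakpoints."""

    times_min: np.ndarray
    blue_fraction: np.ndarray
    breakpoints_min: tuple[float, ...] = ()

    def __post_init__(self) -> None:
        if len(self.times_min) != len(self.blue_fraction):
            raise ValidationError("times and fractions must have equal length")
        if np.any(np.diff(self.times_min) <= 0):
            raise ValidationError("times must be strictly increasing")
        bps = tuple(float(b) for b in self.breakpoints_min)
        if list(bps) != sorted(bps):
            raise ValidationError("breakpoints must be sorted")
        for b in bps:
            if not (self.times_min[0] <= b <= self.times_min[-1]):
                raise ValidationError("breakpoints must lie inside the time range")

    def to_csv(self, path) -> None:
        pd.DataFrame({"time_min": self.times_min,
                      "blue_fraction": self.blue_fraction}).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "HydrationSeries":
        df = pd.read_csv(path)
        return cls(df["time_min"].to_numpy(), df["blue_fraction"].to_numpy())


@dataclass(frozen=True)
class BreakpointFit:
    """Continuous piecewise-linear staging fit of a hydration series."""

    breakpoints_min: tuple[float, ...]
    coef: np.ndarray            # [intercept, slope, hinge1, hinge2, ...]
    sse: float
    sse_line: float             # single-line (no-break) residual SS
    total_ss: float             # SS around the mean
    significant: bool           # improvement over the line >= 1% of total SS

    @property
    def improvement_fraction(self) -> float:
        if self.total_ss == 0:
            return 0.0
        return (self.sse_line - self.sse) / self.total_ss


# ---------------------------------------------------------------------------
# self-mixing signal model
# ---------------------------------------------------------------------------

def sweep_frequency(t_ns, cfg: LFIConfig):
    """Instantaneous optical frequency (THz) during the intra-pulse ramp.

    Linear sweep from the carrier to carrier + sweep span over the pulse.
    """
    t = np.asarray(t_ns, dtype=float)
    if np.any(t < 0) or np.any(t > cfg.pulse_duration_ns):
        raise ValidationError("t outside the drive pulse")
    f = cfg.carrier_thz + (cfg.sweep_span_mhz * 1e-6) * t / cfg.pulse_duration_ns
    return f if f.ndim else float(f)


def excess_phase(phi_s, c_fb: float, henry_alpha: float,
                 return_multistable: bool = False):
    """Solve the steady-state excess-phase equation of self-mixing.

    Finds phi_fb with  phi_s = phi_fb + C sin(phi_fb + arctan(alpha_H)),
    the solution continuous in phi_s.  For C < 1 the equation is monotone
    and the solution unique (damped Newton, residual < 1e-10).  For C >= 1
    the branch is tracked by continuation along the last axis of ``phi_s``
    (the intra-pulse sweep axis); with ``return_multistable=True`` a flag
    marking the strongly multistable regime (C >= 4.6) is also returned.
    """
    if c_fb < 0:
        raise ValidationError("feedback C must be >= 0")
    phi_s_arr = np.asarray(phi_s, dtype=float)
    theta = np.arctan(henry_alpha)

    if c_fb == 0.0:
        out = phi_s_arr.copy()
    elif c_fb < 1.0:
        # the relation is 2pi-periodic: solve for the wrapped stimulus and
        # restore the winding number afterwards (keeps Newton well scaled
        # even for the ~1e5 rad external-cavity phases)
        winding = np.round(phi_s_arr / (2.0 * np.pi))
        wrapped = phi_s_arr - 2.0 * np.pi * winding
        out = wrapped.copy()
        for _ in range(100):
            g = out + c_fb * np.sin(out + theta) - wrapped
            step = np.clip(g / (1.0 + c_fb * np.cos(out + theta)), -2.0, 2.0)
            out = out - step
            if np.max(np.abs(step)) < 1e-12:
                break
        out = out + 2.0 * np.pi * winding
    else:
        # C >= 1: the equation has multiple solutions; track the branch by
        # continuation along the last axis (the intra-pulse sweep).  At each
        # step every real root inside [phi_s - C, phi_s + C] is located by a
        # bracketed bisection and the one nearest the previous solution is
        # kept, which reproduces the hysteresis jumps at branch folds.
        flat = (phi_s_arr.reshape(-1, phi_s_arr.shape[-1])
                if phi_s_arr.ndim else phi_s_arr.reshape(1, 1))
        sol = np.empty_like(flat)

        def roots_near(target: float, guess: float) -> float:
            xs = np.linspace(target - c_fb - 0.5, target + c_fb + 0.5, 600)
            gs = xs + c_fb * np.sin(xs + theta) - target
            sign_change = np.flatnonzero(np.diff(np.sign(gs)) != 0)
            best, best_d = None, np.inf
            for i in sign_change:
                lo, hi = xs[i], xs[i + 1]
                for _ in range(60):
                    mid = 0.5 * (lo + hi)
                    gm = mid + c_fb * np.sin(mid + theta) - target
                    gl = lo + c_fb * np.sin(lo + theta) - target
                    if gl * gm <= 0:
                        hi = mid
                    else:
                        lo = mid
                root = 0.5 * (lo + hi)
                if abs(root - guess) < best_d:
                    best, best_d = root, abs(root - guess)
            return best if best is not None else guess

        for row in range(flat.shape[0]):
            prev = flat[row, 0]
            for j in range(flat.shape[1]):
                prev = roots_near(float(flat[row, j]), prev)
                sol[row, j] = prev
        out = sol.reshape(phi_s_arr.shape)

    out = out if out.ndim else float(out)
    if return_multistable:
        return out, bool(c_fb >= C_STRONG_MULTISTABLE)
    return out


def _interferogram_batch(r_amp: np.ndarray, r_phase: np.ndarray,
                         cfg: LFIConfig,
                         rng: np.random.Generator | None = None) -> np.ndarray:
    """Self-mixing voltage traces for many pixels at once, (npix, nsamp)."""
    t = np.linspace(0.0, cfg.pulse_duration_ns, cfg.samples_per_pulse)
    f_hz = sweep_frequency(t, cfg) * 1e12
    phi_ext = 4.0 * np.pi * cfg.cavity_length_m * f_hz / C_LIGHT  # (nsamp,)
    r_amp = np.atleast_1d(np.asarray(r_amp, float))
    r_phase = np.atleast_1d(np.asarray(r_phase, float))
    phi_s = phi_ext[np.newaxis, :] + r_phase[:, np.newaxis]

    # feedback level varies per pixel through r_amp; for C < 1 the equation
    # is monotone, so one damped-Newton sweep handles every pixel at once
    c_eff = (cfg.feedback_c * r_amp)[:, np.newaxis]
    theta = np.arctan(cfg.henry_alpha)
    if np.all(c_eff < 1.0):
        winding = np.round(phi_s / (2.0 * np.pi))
        wrapped = phi_s - 2.0 * np.pi * winding
        phi_fb = wrapped.copy()
        for _ in range(100):
            g = phi_fb + c_eff * np.sin(phi_fb + theta) - wrapped
            step = np.clip(g / (1.0 + c_eff * np.cos(phi_fb + theta)), -2.0, 2.0)
            phi_fb -= step
            if np.max(np.abs(step)) < 1e-12:
                break
        phi_fb = phi_fb + 2.0 * np.pi * winding
    else:
        phi_fb = np.empty_like(phi_s)
        for i in range(r_amp.size):
            phi_fb[i] = excess_phase(phi_s[i], float(c_eff[i, 0]),
                                     cfg.henry_alpha)
    v = r_amp[:, np.newaxis] * np.cos(phi_fb) + cfg.dc_offset
    if rng is not None and cfg.noise_rms > 0:
        v = v + cfg.noise_rms * rng.standard_normal(v.shape)
    return v


def simulate_interferogram(r_amp: float, r_phase: float, cfg: LFIConfig,
                           rng: np.random.Generator | None = None) -> Interferogram:
    """Interferogram of a single pixel with target amplitude/phase.

    phi_s(t) = 4 pi L f(t) / c + r_phase; the effective feedback level is
    C * r_amp; the voltage is proportional to r_amp cos(phi_fb) plus a DC
    offset and optional seeded noise (pass an ``rng``).
    """
    if not (0.0 <= r_amp <= 1.0):
        raise ValidationError("r_amp must be in [0, 1]")
    t = np.linspace(0.0, cfg.pulse_duration_ns, cfg.samples_per_pulse)
    v = _interferogram_batch(np.array([r_amp]), np.array([r_phase]), cfg, rng)[0]
    return Interferogram(t, v)


# ---------------------------------------------------------------------------
# amplitude recovery
# ---------------------------------------------------------------------------

def _hann_mainlobe(delta: np.ndarray) -> np.ndarray:
    """Normalised Hann main-lobe magnitude W(delta)/W(0) at bin offset delta."""
    out = np.ones_like(delta)
    nz = delta != 0.0
    d = delta[nz]
    out[nz] = np.sin(np.pi * d) / (np.pi * d) / (1.0 - d * d)
    return out


def _recover_batch(voltage: np.ndarray) -> np.ndarray:
    """Dominant non-DC FFT peak magnitude, Hann-windowed, peak-interpolated.

    The mean is removed and a Hann window applied.  The fractional bin
    offset of the dominant tone is estimated from the ratio of the peak bin
    to its larger neighbour using the Hann main lobe's closed form
    (delta = (2 rho - 1)/(1 + rho)), and the peak magnitude is corrected by
    the main-lobe shape and the window's coherent gain.  A pure cosine of
    amplitude a at an integer bin returns a exactly (the Hann spectrum of
    such a tone occupies exactly three bins, so the neighbour ratio is
    exactly 1/2 and the offset exactly 0); off-bin tones are recovered to
    well under 2% (residual error is the finite-length approximation of the
    main lobe plus negative-frequency image leakage).
    """
    v = np.atleast_2d(np.asarray(voltage, float))
    n = v.shape[-1]
    if n < 16:
        raise ValidationError("trace too short (need >= 16 samples)")
    # periodic (DFT-even) Hann: its spectrum of an integer-bin tone occupies
    # exactly three bins, which the interpolation below relies on
    w = 0.5 - 0.5 * np.cos(2.0 * np.pi * np.arange(n) / n)
    gain = w.sum() / 2.0
    x = (v - v.mean(axis=-1, keepdims=True)) * w
    mag = np.abs(np.fft.rfft(x, axis=-1))
    nb = mag.shape[-1]
    pk = np.argmax(mag[..., 1:], axis=-1) + 1  # largest non-DC bin
    pk = np.clip(pk, 1, nb - 2)
    rows = np.arange(v.shape[0])
    a0 = mag[rows, pk]
    am = mag[rows, pk - 1]
    ap = mag[rows, pk + 1]
    out = np.zeros(v.shape[0])
    ok = a0 > 0
    # interpolate toward the larger neighbour
    towards_up = ap >= am
    neigh = np.where(towards_up, ap, am)
    rho = np.where(ok, neigh / np.where(ok, a0, 1.0), 0.0)
    delta = (2.0 * rho - 1.0) / (1.0 + rho)
    delta = np.clip(delta, 0.0, 0.5) * np.where(towards_up, 1.0, -1.0)
    out[ok] = (a0[ok] / _hann_mainlobe(delta[ok])) / gain
    return out


def recover_amplitude(ig: Interferogram | np.ndarray) -> float:
    """Target amplitude from the dominant FFT peak of one interferogram.

    Invariant to any DC offset (the mean is removed first) and, because
    only the peak magnitude is used, essentially invariant to the target
    phase — including the post-objective field-curvature phase.  An
    all-zero trace returns 0.
    """
    v = ig.voltage if isinstance(ig, Interferogram) else np.asarray(ig, float)
    return float(_recover_batch(v[np.newaxis, :])[0])


# ---------------------------------------------------------------------------
# frame scanning
# ---------------------------------------------------------------------------

def scan_frame(phantom: LeafPhantom, curve: DryingCurve, frame_start_min: float,
               cfg: LFIConfig, water: DielectricSpectrum,
               dry: DielectricSpectrum,
               rng: np.random.Generator | None = None) -> LFIFrame:
    """Acquire one LFI frame of the drying phantom.

    Within-frame drying is neglected (a frame takes seconds, drying takes
    minutes): the whole frame sees the phantom advanced to
    ``frame_start_min``.  Per pixel, the carrier-frequency reflectivity of
    the leaf-on-metal stack (normal incidence) drives a simulated
    interferogram whose amplitude is then recovered; ``db_map`` is
    20 log10(amplitude / frame max).
    """
    state = phantom_at(phantom, curve, frame_start_min)
    rows, cols = state.shape
    fc = np.array([cfg.carrier_thz])
    r = leaf_on_metal_reflectivity(
        state.water_fraction.ravel(), state.dry_fraction.ravel(),
        state.thickness_um.ravel(), fc, water, dry, angle_deg=0.0)[:, 0]
    if not cfg.include_front_reflection:
        m_eff = mix_index(state.water_fraction.ravel(),
                          state.dry_fraction.ravel(),
                          water.interp_m(fc), dry.interp_m(fc))[:, 0]
        r01 = front_surface_reflection(m_eff)
        on_leaf = state.leaf_mask.ravel()
        r = np.where(on_leaf, r - r01, r)
    r_amp = np.clip(np.abs(r), 0.0, 1.0)
    r_phase = np.angle(r)
    if cfg.field_curvature_rad != 0.0:
        rr, cc = np.meshgrid(np.linspace(-1, 1, rows), np.linspace(-1, 1, cols),
                             indexing="ij")
        r_phase = r_phase + cfg.field_curvature_rad * (rr ** 2 + cc ** 2).ravel()

    v = _interferogram_batch(r_amp, r_phase, cfg, rng)
    amp = _recover_batch(v).reshape(rows, cols)
    peak = amp.max()
    with np.errstate(divide="ignore"):
        db = 20.0 * np.log10(np.maximum(amp, 1e-300) / peak) if peak > 0 \
            else np.zeros_like(amp)
    db = np.maximum(db, -300.0)
    return LFIFrame(amp, db, float(frame_start_min), state.leaf_mask)


def run_lfi_sequence(phantom: LeafPhantom, curve: DryingCurve, cfg: LFIConfig,
                     times_min, water: DielectricSpectrum,
                     dry: DielectricSpectrum,
                     rng: np.random.Generator | None = None) -> list[LFIFrame]:
    """Repeated frame acquisition at the given start times (minutes)."""
    return [scan_frame(phantom, curve, float(t), cfg, water, dry, rng)
            for t in np.asarray(times_min, float)]


# ---------------------------------------------------------------------------
# hydration statistics
# ---------------------------------------------------------------------------

def blue_fraction(frame: LFIFrame, threshold_db: float | None = None,
                  leaf_mask: np.ndarray | None = None) -> float:
    """Fraction of leaf pixels at or below the dB threshold (default -60).

    "Blue" pixels are those whose recovered reflectivity amplitude lies
    ``|threshold|`` dB or more below the frame peak — the proxy for highly
    hydrated (strongly absorbing) area.
    """
    mask = leaf_mask if leaf_mask is not None else frame.leaf_mask
    if mask is None or not np.any(mask):
        raise ValidationError("empty leaf mask")
    thr = threshold_db if threshold_db is not None else -60.0
    return float(np.mean(frame.db_map[mask] <= thr))


def hydration_series(frames: list[LFIFrame], threshold_db: float = -60.0
                     ) -> HydrationSeries:
    """Assemble the blue-fraction time series from a frame sequence."""
    if len(frames) < 3:
        raise ValidationError("need at least 3 frames")
    times = np.array([f.frame_time_min for f in frames], dtype=float)
    if np.any(np.diff(times) <= 0):
        raise ValidationError("frames must have strictly increasing times")
    fracs = np.array([blue_fraction(f, threshold_db) for f in frames])
    return HydrationSeries(times, fracs)


def synthesize_hydration_series(times_min,
                                breakpoints_min: tuple[float, float] = (20.0, 120.0),
                                levels: tuple[float, ...] = (0.35, 0.15, 0.13, 0.02),
                                ) -> HydrationSeries:
    """Noise-free three-stage piecewise-linear blue-fraction series.

    ``levels`` are the fractions at scan start, the two breakpoints and the
    final frame; the series interpolates linearly between them (continuous,
    non-increasing for the default levels).
    """
    t = np.asarray(times_min, dtype=float)
    knots = np.array([t[0], *breakpoints_min, t[-1]])
    vals = np.asarray(levels, dtype=float)
    return HydrationSeries(t, np.interp(t, knots, vals))


# ---------------------------------------------------------------------------
# staging (changepoint) fit
# ---------------------------------------------------------------------------

def _hinge_gram(t: np.ndarray, y: np.ndarray):
    """Suffix sums enabling O(1) inner products with hinge bases relu(t-b)."""
    s0 = np.cumsum(np.ones_like(t)[::-1])[::-1]
    s1 = np.cumsum(t[::-1])[::-1]
    s2 = np.cumsum((t * t)[::-1])[::-1]
    sy = np.cumsum(y[::-1])[::-1]
    sty = np.cumsum((t * y)[::-1])[::-1]
    return s0, s1, s2, sy, sty


def fit_breakpoints(series: HydrationSeries, n_breaks: int = 2,
                    min_seg: int = 3) -> BreakpointFit:
    """Exhaustive continuous piecewise-linear least-squares staging fit.

    Candidate breakpoints are the frame times themselves; every admissible
    pair (or single breakpoint) is scored by the residual SS of the
    continuous piecewise-linear model  y ~ 1 + t + relu(t-b1) [+ relu(t-b2)]
    and the global minimiser is returned, ties broken toward earlier
    breakpoints.  ``n_breaks`` may be 0, 1 or 2.
    """
    if n_breaks not in (0, 1, 2):
        raise ValidationError("n_breaks must be 0, 1 or 2")
    t = np.asarray(series.times_min, float)
    y = np.asarray(series.blue_fraction, float)
    n = t.size
    if n < 5 * (n_breaks + 1):
        raise ValidationError(
            f"need at least {5 * (n_breaks + 1)} points for {n_breaks} breaks")

    ones = np.ones_like(t)
    yty = float(y @ y)
    total_ss = float(np.sum((y - y.mean()) ** 2))

    def solve(cols):
        X = np.column_stack(cols)
        beta, *_ = np.linalg.lstsq(X, y, rcond=None)
        sse = float(yty - beta @ (X.T @ y))
        return beta, max(sse, 0.0)

    beta_line, sse_line = solve([ones, t])
    if n_breaks == 0:
        return BreakpointFit((), beta_line, sse_line, sse_line, total_ss, False)

    s0, s1, s2, sy, sty = _hinge_gram(t, y)

    def hinge_stats(i):
        """Inner products of relu(t - t_i) with {1, t, y} and itself."""
        b = t[i]
        j = i + 1  # suffix starting past the knot
        h1 = s1[j] - b * s0[j]
        ht = s2[j] - b * s1[j]
        hy = sty[j] - b * sy[j]
        hh = s2[j] - 2 * b * s1[j] + b * b * s0[j]
        return h1, ht, hy, hh

    def cross(i, k):
        """<relu(t - t_i), relu(t - t_k)> for i <= k."""
        bi, bk = t[i], t[k]
        j = k + 1
        return s2[j] - (bi + bk) * s1[j] + bi * bk * s0[j]

    n1 = float(n)
    st = float(t.sum())
    stt = float(t @ t)
    syv = float(y.sum())
    sty_full = float(t @ y)

    best = None
    if n_breaks == 1:
        cand = range(min_seg - 1, n - min_seg)
        for i in cand:
            h1, ht, hy, hh = hinge_stats(i)
            A = np.array([[n1, st, h1], [st, stt, ht], [h1, ht, hh]])
            bvec = np.array([syv, sty_full, hy])
            try:
                beta = np.linalg.solve(A, bvec)
            except np.linalg.LinAlgError:
                continue
            sse = max(yty - beta @ bvec, 0.0)
            if best is None or sse < best[0] - 1e-15:
                best = (sse, (i,), beta)
        sse, idx, beta = best
        return BreakpointFit((float(t[idx[0]]),), beta, float(sse), sse_line,
                             total_ss, bool((sse_line - sse) >= 0.01 * total_ss))

    # n_breaks == 2: vectorise the inner loop over the second breakpoint
    i_cand = np.arange(min_seg - 1, n - 2 * min_seg)
    for i in i_cand:
        h1_i, ht_i, hy_i, hh_i = hinge_stats(i)
        ks = np.arange(i + min_seg, n - min_seg)
        if ks.size == 0:
            continue
        bk = t[ks]
        j = ks + 1
        h1_k = s1[j] - bk * s0[j]
        ht_k = s2[j] - bk * s1[j]
        hy_k = sty[j] - bk * sy[j]
        hh_k = s2[j] - 2 * bk * s1[j] + bk * bk * s0[j]
        hik = s2[j] - (t[i] + bk) * s1[j] + t[i] * bk * s0[j]

        m = ks.size
        A = np.empty((m, 4, 4))
        A[:, 0, 0] = n1;      A[:, 0, 1] = st;    A[:, 0, 2] = h1_i; A[:, 0, 3] = h1_k
        A[:, 1, 0] = st;      A[:, 1, 1] = stt;   A[:, 1, 2] = ht_i; A[:, 1, 3] = ht_k
        A[:, 2, 0] = h1_i;    A[:, 2, 1] = ht_i;  A[:, 2, 2] = hh_i; A[:, 2, 3] = hik
        A[:, 3, 0] = h1_k;    A[:, 3, 1] = ht_k;  A[:, 3, 2] = hik;  A[:, 3, 3] = hh_k
        bvec = np.stack([np.full(m, syv), np.full(m, sty_full),
                         np.full(m, hy_i), hy_k], axis=1)
        try:
            beta = np.linalg.solve(A, bvec[..., np.newaxis])[..., 0]
        except np.linalg.LinAlgError:
            continue
        sse = yty - np.einsum("ij,ij->i", beta, bvec)
        sse = np.maximum(sse, 0.0)
        kbest = int(np.argmin(sse))
        if best is None or sse[kbest] < best[0] - 1e-15:
            best = (float(sse[kbest]), (i, int(ks[kbest])), beta[kbest])
    if best is None:
        raise ValidationError("no admissible breakpoint pair")
    sse, idx, beta = best
    bps = tuple(float(t[j]) for j in idx)
    return BreakpointFit(bps, beta, float(sse), sse_line, total_ss,
                         bool((sse_line - sse) >= 0.01 * total_ss))
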