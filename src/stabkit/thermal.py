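"""Melting-temperature and isothermal-decay analysis.

Melting curves (DSF fluorescence ratio, CD ellipticity, DSC apparent heat
capacity) are analyzed under a two-state unfolding model with linear pre-
and post-transition baselines; Tm is estimated three ways — midpoint of the
normalized transition, full nonlinear two-state fit, and DSC peak maximum —
mirroring the instrument triangulation commonly used to validate a
stabilized variant. Isothermal ellipticity decays are fit to a single
exponential with plateau; the secondary-structure half-life is
``t_half = tau * ln 2 = ln 2 / lambda``.
"""

from __future__ import annotations

import dataclasses
import math

import numpy as np
from scipy import optimize

__all__ = [
    "MeltingCurve",
    "DecayCurve",
    "NormalizedTransition",
    "TwoStateFit",
    "DscPeak",
    "DecayFit",
    "NoTransitionError",
    "normalize_transition",
    "tm_midpoint",
    "fit_two_state",
    "tm_dsc_peak",
    "fit_decay",
    "fit_decay_series",
    "delta_tm",
]

_R = 1.987204259e-3  # kcal/(mol*K)
_LN2 = math.log(2.0)

SIGMOIDAL_MODALITIES = ("fluorescence", "ellipticity")


class NoTransitionError(ValueError):
    """Raised when a curve shows no resolvable unfolding transition."""


@dataclasses.dataclass
class MeltingCurve:
    """A temperature scan: ascending temperatures (degC) and the monitored
    signal (330/350 fluorescence ratio, ellipticity, or apparent heat
    capacity depending on ``modality``)."""

    temperature_c: np.ndarray
    signal: np.ndarray
    modality: str = "fluorescence"

    def __post_init__(self):
        self.temperature_c = np.asarray(self.temperature_c, dtype=float)
        self.signal = np.asarray(self.signal, dtype=float)
        if self.temperature_c.shape != self.signal.shape:
            raise ValueError("temperature and signal must have the same length")
        if self.temperature_c.size < 10:
            raise ValueError("a melting curve needs at least 10 points")
        if np.any(np.diff(self.temperature_c) <= 0):
            raise ValueError("temperatures must be strictly increasing")


@dataclasses.dataclass
class DecayCurve:
    """Isothermal time course: time in hours, ellipticity-like signal."""

    time_h: np.ndarray
    signal: np.ndarray

    def __post_init__(self):
        self.time_h = np.asarray(self.time_h, dtype=float)
        self.signal = np.asarray(self.signal, dtype=float)
        if self.time_h.shape != self.signal.shape:
            raise ValueError("time and signal must have the same length")
        if self.time_h.size < 6:
            raise ValueError("a decay curve needs at least 6 points")


@dataclasses.dataclass
class NormalizedTransition:
    """Fraction-unfolded curve derived from a sigmoidal melt."""

    temperature_c: np.ndarray
    fraction_unfolded: np.ndarray
    pre_baseline: tuple[float, float]  # (slope, intercept)
    post_baseline: tuple[float, float]


@dataclasses.dataclass
class TwoStateFit:
    """Parameters of the two-state fit.

    ``tm`` degC; ``dh_vh`` van't Hoff enthalpy, kcal/mol; baselines as
    (slope, intercept); ``residual_rms`` in signal units.
    """

    tm: float
    dh_vh: float
    pre_baseline: tuple[float, float]
    post_baseline: tuple[float, float]
    residual_rms: float
    success: bool
    message: str = ""

    def fraction_unfolded(self, t_celsius):
        t_k = np.asarray(t_celsius, dtype=float) + 273.15
        lnk = -(self.dh_vh / _R) * (1.0 / t_k - 1.0 / (self.tm + 273.15))
        k = np.exp(np.clip(lnk, -500, 500))
        return k / (1.0 + k)


@dataclasses.dataclass
class DscPeak:
    """DSC peak-location result: the reported Tm (tallest peak), all peak
    candidates ``(temperature, height)`` for diagnostics, and a boundary
    flag set when the maximum sits on the scan edge."""

    tm: float
    peaks: list[tuple[float, float]]
    on_boundary: bool


@dataclasses.dataclass
class DecayFit:
    """Single-exponential decay fit ``y = plateau + amplitude*exp(-lambda*t)``.

    ``t_half = tau * ln 2`` holds exactly by construction. ``stable`` is set
    when the curve does not decay measurably within the observation window
    (fitted half-life beyond 3x the window, or no amplitude)."""

    lambda_per_h: float
    tau_h: float
    t_half_h: float
    amplitude: float
    plateau: float
    residual_rms: float
    stable: bool


def _flank_slices(n: int, fraction: float) -> tuple[slice, slice]:
    k = max(3, int(round(n * fraction)))
    return slice(0, k), slice(n - k, n)


def _linfit(x: np.ndarray, y: np.ndarray) -> tuple[float, float, float]:
    """Least-squares baseline; returns (slope, intercept, residual std).

    Windows under 8 points get a constant baseline: a slope estimated from
    a handful of noisy points extrapolates far worse than ignoring the
    (small) true baseline slope.
    """
    if x.size < 8:
        intercept = float(np.mean(y))
        return 0.0, intercept, float(np.std(y - intercept))
    slope, intercept = np.polyfit(x, y, 1)
    resid = y - (slope * x + intercept)
    return float(slope), float(intercept), float(np.std(resid))


def _transition_window(t: np.ndarray, y: np.ndarray) -> tuple[int, int] | None:
    """Locate the transition region from the smoothed signal gradient.

    Returns index bounds (inclusive) of the contiguous region around the
    steepest point where the gradient magnitude stays above 25% of its
    maximum, or None when no clear transition stands out of the noise.
    """
    ys = _moving_average(y, 7)
    g = np.gradient(ys, t)
    ag = np.abs(g)
    imax = int(np.argmax(ag))
    # compare peak gradient against the gradient noise floor (median level)
    floor = float(np.median(ag))
    if ag[imax] <= 3.0 * floor or ag[imax] == 0:
        return None
    thr = 0.25 * ag[imax]
    left = imax
    while left > 0 and ag[left - 1] > thr:
        left -= 1
    right = imax
    while right < t.size - 1 and ag[right + 1] > thr:
        right += 1
    # margin so baseline windows clear the transition tails
    margin = max(1, (right - left) // 2)
    return max(left - margin, 0), min(right + margin, t.size - 1)


def normalize_transition(curve: MeltingCurve) -> NormalizedTransition:
    """Map a sigmoidal melt to fraction unfolded.

    Linear pre- and post-transition baselines are fit outside the detected
    transition region (located from the signal gradient, so melts with the
    midpoint near a scan edge keep usable baselines) and the signal is
    normalized as ``f = (y - pre(T)) / (post(T) - pre(T))``, clipped to
    [0, 1]. Raises :class:`NoTransitionError` when no transition stands out
    of the noise or the baselines are indistinguishable (flat or
    featureless curves).
    """
    if curve.modality not in SIGMOIDAL_MODALITIES:
        raise ValueError(
            f"normalize_transition expects a sigmoidal modality, got {curve.modality!r}"
        )
    t, y = curve.temperature_c, curve.signal
    window = _transition_window(t, y)
    if window is None:
        raise NoTransitionError(
            "no resolvable transition: the signal gradient never stands out of the noise"
        )
    wl, wr = window
    # keep at least 3 points per baseline even when the transition
    # crowds a scan edge
    lo = slice(0, max(wl, 3))
    hi = slice(min(wr + 1, t.size - 3), t.size)
    s1, i1, r1 = _linfit(t[lo], y[lo])
    s2, i2, r2 = _linfit(t[hi], y[hi])
    pre = s1 * t + i1
    post = s2 * t + i2
    span = np.abs(post - pre)
    scatter = max(r1, r2)
    floor = 1e-12 * max(1.0, float(np.max(np.abs(y))))
    if float(np.median(span)) <= max(5.0 * scatter, floor):
        raise NoTransitionError("no resolvable transition: baselines are indistinguishable")
    f = (y - pre) / (post - pre)
    return NormalizedTransition(
        temperature_c=t,
        fraction_unfolded=np.clip(f, 0.0, 1.0),
        pre_baseline=(s1, i1),
        post_baseline=(s2, i2),
    )


def _moving_average(y: np.ndarray, window: int) -> np.ndarray:
    if window <= 1:
        return y
    kernel = np.ones(window) / window
    pad = window // 2
    ypad = np.pad(y, pad, mode="edge")
    out = np.convolve(ypad, kernel, mode="valid")
    return out[: y.size]


def tm_midpoint(normalized: NormalizedTransition, smooth_window: int = 3) -> float:
    """Tm as the 0.5-crossing of the normalized transition.

    A short moving average (window 3 by default) is applied before
    interpolation so that noise-induced multiple crossings resolve
    deterministically to the first crossing of the smoothed curve; the
    crossing temperature is linearly interpolated.
    """
    t = normalized.temperature_c
    f = _moving_average(normalized.fraction_unfolded, smooth_window)
    above = f >= 0.5
    if not above.any() or above.all():
        raise NoTransitionError("fraction unfolded does not cross 0.5")
    idx = int(np.argmax(above))
    if idx == 0:
        return float(t[0])
    f0, f1 = f[idx - 1], f[idx]
    t0, t1 = t[idx - 1], t[idx]
    if f1 == f0:
        return float(t0)
    return float(t0 + (0.5 - f0) * (t1 - t0) / (f1 - f0))


def _two_state_model(t_c, tm, dh, s1, i1, s2, i2):
    t_k = t_c + 273.15
    lnk = -(dh / _R) * (1.0 / t_k - 1.0 / (tm + 273.15))
    k = np.exp(np.clip(lnk, -500, 500))
    f = k / (1.0 + k)
    return (1.0 - f) * (s1 * t_c + i1) + f * (s2 * t_c + i2)


def fit_two_state(curve: MeltingCurve) -> TwoStateFit:
    """Full nonlinear least-squares fit of the two-state model with linear
    baselines: ``y(T) = (1-f)*pre(T) + f*post(T)`` where
    ``f = K/(1+K)``, ``K = exp[-(dH/R)(1/T - 1/Tm)]`` (T in kelvin).

    Initialized from the flank baselines and the midpoint estimate; on clean
    data the fitted Tm agrees with :func:`tm_midpoint` to well within 0.5 degC.
    Non-convergence is reported through ``success``/``message`` rather than
    raising, so batch tables keep their bookkeeping.
    """
    norm = normalize_transition(curve)
    try:
        tm0 = tm_midpoint(norm)
    except NoTransitionError:
        tm0 = float(np.median(curve.temperature_c))
    p0 = [tm0, 80.0, *norm.pre_baseline, *norm.post_baseline]
    t, y = curve.temperature_c, curve.signal
    lo = [t[0], 1.0, -np.inf, -np.inf, -np.inf, -np.inf]
    hi = [t[-1], 5000.0, np.inf, np.inf, np.inf, np.inf]
    try:
        popt, _ = optimize.curve_fit(
            _two_state_model, t, y, p0=p0, bounds=(lo, hi), maxfev=20000
        )
        resid = y - _two_state_model(t, *popt)
        return TwoStateFit(
            tm=float(popt[0]),
            dh_vh=float(popt[1]),
            pre_baseline=(float(popt[2]), float(popt[3])),
            post_baseline=(float(popt[4]), float(popt[5])),
            residual_rms=float(np.sqrt(np.mean(resid**2))),
            success=True,
        )
    except RuntimeError as exc:
        return TwoStateFit(
            tm=float("nan"),
            dh_vh=float("nan"),
            pre_baseline=norm.pre_baseline,
            post_baseline=norm.post_baseline,
            residual_rms=float("nan"),
            success=False,
            message=str(exc),
        )


def tm_dsc_peak(
    curve: MeltingCurve,
    smoothing_window: int = 5,
    baseline_fraction: float = 0.15,
) -> DscPeak:
    """Tm as the maximum of the baseline-subtracted apparent heat capacity.

    A linear baseline through the flank means is removed, the trace is
    optionally smoothed (moving average), and the location of the tallest
    peak is refined by parabolic interpolation of the three points around
    the maximum. All local maxima above half the main peak are reported in
    ``peaks`` so that bimodal transitions are visible in diagnostics.
    """
    if curve.modality != "dsc":
        raise ValueError("tm_dsc_peak expects the heat-capacity modality")
    t, y = curve.temperature_c, curve.signal
    lo, hi = _flank_slices(t.size, baseline_fraction)
    x1, y1 = float(np.mean(t[lo])), float(np.mean(y[lo]))
    x2, y2 = float(np.mean(t[hi])), float(np.mean(y[hi]))
    slope = (y2 - y1) / (x2 - x1)
    baseline = y1 + slope * (t - x1)
    z = _moving_average(y - baseline, smoothing_window)

    imax = int(np.argmax(z))
    on_boundary = imax in (0, t.size - 1)
    if on_boundary:
        tm = float(t[imax])
    else:
        # parabola through the three samples around the maximum
        denom = z[imax - 1] - 2 * z[imax] + z[imax + 1]
        shift = 0.0 if denom == 0 else 0.5 * (z[imax - 1] - z[imax + 1]) / denom
        shift = float(np.clip(shift, -1.0, 1.0))
        tm = float(t[imax] + shift * (t[min(imax + 1, t.size - 1)] - t[imax]))

    from scipy.signal import find_peaks

    idx, props = find_peaks(z, height=0.25 * z[imax])
    peaks = [(float(t[i]), float(z[i])) for i in idx]
    if not peaks:
        peaks = [(float(t[imax]), float(z[imax]))]
    peaks.sort(key=lambda p: -p[1])
    return DscPeak(tm=tm, peaks=peaks, on_boundary=on_boundary)


def fit_decay(curve: DecayCurve, stable_factor: float = 3.0) -> DecayFit:
    """Fit ``y(t) = plateau + A * exp(-lambda * t)`` and derive
    ``tau = 1/lambda`` and ``t_half = tau * ln 2``.

    Curves that do not decay measurably — negligible amplitude, or a fitted
    half-life longer than ``stable_factor`` times the observation window —
    are flagged ``stable`` (the protein held its secondary structure within
    the window) and report an infinite half-life.
    """
    t, y = curve.time_h, curve.signal
    span = float(t[-1] - t[0])
    rng_y = float(np.ptp(y))
    scale = max(abs(float(np.mean(y))), rng_y, 1e-12)

    def _stable(plateau, rms):
        return DecayFit(
            lambda_per_h=0.0,
            tau_h=math.inf,
            t_half_h=math.inf,
            amplitude=0.0,
            plateau=plateau,
            residual_rms=rms,
            stable=True,
        )

    if rng_y <= 1e-9 * scale:
        return _stable(float(np.mean(y)), float(np.std(y)))

    a0 = float(y[0] - y[-1])
    lam0 = _LN2 / max(span / 4.0, 1e-6)
    p0 = [float(y[-1]), a0, lam0]

    def model(tt, plateau, a, lam):
        return plateau + a * np.exp(-lam * tt)

    try:
        popt, _ = optimize.curve_fit(
            model, t, y, p0=p0, bounds=([-np.inf, -np.inf, 0.0], [np.inf, np.inf, np.inf]),
            maxfev=20000,
        )
    except RuntimeError:
        resid = float(np.std(y - np.mean(y)))
        return _stable(float(np.mean(y)), resid)

    plateau, amp, lam = map(float, popt)
    resid = y - model(t, *popt)
    rms = float(np.sqrt(np.mean(resid**2)))
    if lam <= 0 or amp == 0:
        return _stable(plateau if amp == 0 else float(np.mean(y)), rms)
    # a decay amplitude within the noise is no decay at all
    if abs(amp) <= 3.0 * rms:
        return _stable(float(np.mean(y)), rms)
    tau = 1.0 / lam
    t_half = tau * _LN2
    stable = t_half > stable_factor * span
    return DecayFit(
        lambda_per_h=lam,
        tau_h=tau,
        t_half_h=t_half,
        amplitude=amp,
        plateau=plateau,
        residual_rms=rms,
        stable=stable,
    )


def fit_decay_series(
    curves: list[DecayCurve], share_plateau: bool = True, stable_factor: float = 3.0
) -> list[DecayFit]:
    """Fit several decays jointly with one shared plateau.

    Useful when curves were recorded under identical buffer conditions and
    the fully-unfolded ellipticity is common to all variants. With
    ``share_plateau=False`` this is just :func:`fit_decay` per curve.
    """
    if not curves:
        raise ValueError("no curves supplied")
    if not share_plateau:
        return [fit_decay(c, stable_factor) for c in curves]

    singles = [fit_decay(c, stable_factor) for c in curves]
    p0 = [float(np.mean([s.plateau for s in singles]))]
    for s, c in zip(singles, curves):
        amp = s.amplitude if s.amplitude else float(np.ptp(c.signal))
        lam = s.lambda_per_h if s.lambda_per_h > 0 else _LN2 / (c.time_h[-1] or 1.0)
        p0 += [amp, lam]

    def resid(p):
        plateau = p[0]
        out = []
        for i, c in enumerate(curves):
            a, lam = p[1 + 2 * i], p[2 + 2 * i]
            out.append(plateau + a * np.exp(-lam * c.time_h) - c.signal)
        return np.concatenate(out)

    lo = [-np.inf] + [-np.inf, 0.0] * len(curves)
    res = optimize.least_squares(resid, p0, bounds=(lo, np.inf))
    plateau = float(res.x[0])
    fits = []
    for i, c in enumerate(curves):
        amp, lam = float(res.x[1 + 2 * i]), float(res.x[2 + 2 * i])
        model = plateau + amp * np.exp(-lam * c.time_h)
        rms = float(np.sqrt(np.mean((c.signal - model) ** 2)))
        span = float(c.time_h[-1] - c.time_h[0])
        if lam <= 0 or abs(amp) <= 3.0 * rms:
            fits.append(
                DecayFit(0.0, math.inf, math.inf, 0.0, plateau, rms, stable=True)
            )
            continue
        tau = 1.0 / lam
        t_half = tau * _LN2
        fits.append(
            DecayFit(
                lambda_per_h=lam,
                tau_h=tau,
                t_half_h=t_half,
                amplitude=amp,
                plateau=plateau,
                residual_rms=rms,
                stable=t_half > stable_factor * span,
            )
        )
    return fits


def delta_tm(variant_fit, wildtype_fit) -> float:
    """Melting-temperature gain of a variant over wildtype (degC).

    Accepts anything with a ``tm`` attribute (TwoStateFit, DscPeak) or a
    plain float.
    """

    def _tm(x):
        return float(getattr(x, "tm", x))

    v, w = _tm(variant_fit), _tm(wildtype_fit)
    if math.isnan(v) or math.isnan(w):
        raise ValueError("delta_tm requires converged fits")
    return v - w
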