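"""Biolayer-interferometry (BLI) kinetics and equilibrium affinity.

Sensorgrams are analyzed under the 1:1 Langmuir interaction model:
association ``R(t) = Req (1 - exp(-(ka C + kd) t))`` with
``Req = Rmax C/(C + KD)``, dissociation ``R(t) = R0 exp(-kd t)``, and
``KD = kd/ka``. Two routes to the equilibrium constant are provided —
a kinetic estimate from a global shared-parameter fit across the
concentration series, and a saturation estimate from the per-concentration
plateau responses fit to the Langmuir isotherm — and their agreement is a
built-in model diagnostic.
"""

from __future__ import annotations

import dataclasses
import math
from typing import Sequence

import numpy as np
from scipy import optimize

__all__ = [
    "BLISensorgram",
    "DissociationFit",
    "AssociationFit",
    "SaturationFit",
    "BindingFit",
    "fit_dissociation",
    "fit_association",
    "fit_saturation",
    "fit_trace",
    "fit_series_req",
    "analyze_sensorgrams",
]


@dataclasses.dataclass
class BLISensorgram:
    """One association+dissociation trace at a single analyte concentration.

    ``time_s`` spans both phases; points with ``time_s <= t_assoc`` belong
    to the association phase.
    """

    time_s: np.ndarray
    response: np.ndarray
    conc_nM: float
    t_assoc: float = 300.0

    def __post_init__(self):
        self.time_s = np.asarray(self.time_s, dtype=float)
        self.response = np.asarray(self.response, dtype=float)
        if self.time_s.shape != self.response.shape:
            raise ValueError("time and response must have the same length")
        if self.conc_nM <= 0:
            raise ValueError("analyte concentration must be positive")

    @property
    def association(self) -> tuple[np.ndarray, np.ndarray]:
        m = self.time_s <= self.t_assoc
        return self.time_s[m], self.response[m]

    @property
    def dissociation(self) -> tuple[np.ndarray, np.ndarray]:
        """Dissociation phase with time rebased to zero at phase start."""
        m = self.time_s > self.t_assoc
        return self.time_s[m] - self.t_assoc, self.response[m]

    @property
    def phase_labels(self) -> np.ndarray:
        return np.where(self.time_s <= self.t_assoc, "assoc", "dissoc")


@dataclasses.dataclass
class DissociationFit:
    kd: float  # 1/s
    r0: float
    residual_rms: float


@dataclasses.dataclass
class AssociationFit:
    kobs: float  # 1/s
    req: float
    ka: float  # 1/(M s)
    residual_rms: float


@dataclasses.dataclass
class SaturationFit:
    kd_nM: float
    rmax: float
    kd_stderr_nM: float
    poorly_constrained: bool


@dataclasses.dataclass
class BindingFit:
    """Combined report of the 1:1 analysis.

    ``kd_kinetic_nM`` is exactly ``kd/ka`` (machine-precision identity);
    ``kd_saturation_nM`` comes from the Langmuir isotherm over the
    per-concentration equilibrium responses. A large relative divergence
    between the two flags departure from 1:1 behaviour.
    """

    ka: float
    kd: float
    rmax: float
    kd_kinetic_nM: float
    req_by_conc: dict[float, float]
    kd_saturation_nM: float
    saturation: SaturationFit
    residual_rms: float

    @property
    def kd_divergence(self) -> float:
        """Relative kinetic-vs-saturation KD disagreement (diagnostic)."""
        return abs(self.kd_saturation_nM - self.kd_kinetic_nM) / self.kd_kinetic_nM


def fit_dissociation(gram: BLISensorgram) -> DissociationFit:
    """Fit ``R(t) = R0 exp(-kd t)`` to the dissociation phase."""
    t, r = gram.dissociation
    if t.size < 5:
        raise ValueError("dissociation phase missing or too short")
    slope = np.polyfit(t, r, 1)[0]
    scale = max(float(np.max(np.abs(r))), 1e-12)
    if slope * (t[-1] - t[0]) >= -1e-9 * scale:
        raise ValueError("dissociation phase does not decay")
    r0_0 = float(r[0])
    kd0 = max(-slope / max(r0_0, 1e-12), 1e-6)
    popt, _ = optimize.curve_fit(
        lambda tt, r0, kd: r0 * np.exp(-kd * tt),
        t,
        r,
        p0=[r0_0, kd0],
        bounds=([0.0, 0.0], [np.inf, np.inf]),
        maxfev=20000,
    )
    resid = r - popt[0] * np.exp(-popt[1] * t)
    return DissociationFit(
        kd=float(popt[1]), r0=float(popt[0]), residual_rms=float(np.sqrt(np.mean(resid**2)))
    )


def _fit_exponential_approach(t: np.ndarray, r: np.ndarray) -> tuple[float, float, float]:
    """Fit ``R(t) = Req (1 - exp(-kobs t))``; returns (req, kobs, rms)."""
    if t.size < 5:
        raise ValueError("association phase missing or too short")
    req0 = float(np.max(r)) or 1e-6
    kobs0 = max(1.0 / max(t[-1] / 3.0, 1e-6), 1e-6)
    popt, _ = optimize.curve_fit(
        lambda tt, req, kobs: req * (1.0 - np.exp(-kobs * tt)),
        t,
        r,
        p0=[req0, kobs0],
        bounds=([0.0, 0.0], [np.inf, np.inf]),
        maxfev=20000,
    )
    req, kobs = float(popt[0]), float(popt[1])
    resid = r - req * (1.0 - np.exp(-kobs * t))
    return req, kobs, float(np.sqrt(np.mean(resid**2)))


def fit_association(gram: BLISensorgram, kd: float | None = None) -> AssociationFit:
    """Fit ``R(t) = Req (1 - exp(-kobs t))`` to the association phase and,
    given ``kd``, derive ``ka = (kobs - kd) / C``.

    With ``kd`` supplied, raises when the fitted ``kobs`` does not exceed it
    — non-physical under the 1:1 model (the observed rate is ``ka C + kd``).
    With ``kd=None`` only the observed rate and the equilibrium response are
    reported (``ka`` is NaN); this is the route used when only Req is needed
    for saturation analysis.
    """
    t, r = gram.association
    req, kobs, rms = _fit_exponential_approach(t, r)
    if kd is None:
        ka = math.nan
    else:
        if kobs <= kd:
            raise ValueError(
                f"non-physical kinetics: kobs={kobs:.3g}/s does not exceed kd={kd:.3g}/s"
            )
        c_M = gram.conc_nM * 1e-9
        ka = (kobs - kd) / c_M
    return AssociationFit(kobs=kobs, req=req, ka=ka, residual_rms=rms)


def fit_trace(gram: BLISensorgram) -> AssociationFit:
    """Fit one full trace — association and dissociation jointly — for its
    equilibrium response.

    Both phases share Req and kobs through the hand-off amplitude
    ``R(t_assoc) = Req (1 - exp(-kobs t_assoc))``, so the dissociation data
    tightens Req at low-signal concentrations where the association-only
    fit is noisy. Returns an :class:`AssociationFit` (``ka`` is NaN; derive
    it separately when kd is known).
    """
    t_a, r_a = gram.association
    t_d, r_d = gram.dissociation
    if t_a.size < 5:
        raise ValueError("association phase missing or too short")
    if t_d.size < 5:
        return fit_association(gram)

    def resid(p):
        req, kobs, kd = p
        m_a = req * (1.0 - np.exp(-kobs * t_a))
        r_end = req * (1.0 - np.exp(-kobs * gram.t_assoc))
        m_d = r_end * np.exp(-kd * t_d)
        return np.concatenate([m_a - r_a, m_d - r_d])

    k0 = 1.0 / max(gram.t_assoc / 3.0, 1e-6)
    p0 = [max(float(np.max(r_a)), 1e-6), k0, k0]
    res = optimize.least_squares(resid, p0, bounds=([0, 0, 0], [np.inf] * 3))
    req, kobs, _kd = map(float, res.x)
    return AssociationFit(
        kobs=kobs, req=req, ka=math.nan,
        residual_rms=float(np.sqrt(np.mean(res.fun**2))),
    )


def fit_series_req(grams: Sequence[BLISensorgram]) -> dict[float, float]:
    """Equilibrium responses for a concentration series with a shared
    dissociation rate.

    All traces are fit jointly — per-trace Req and kobs, one kd for the
    series (the off-rate does not depend on analyte concentration) — which
    stabilizes Req at the low-signal concentrations. Returns
    ``{conc_nM: Req}`` sorted by concentration.
    """
    grams = sorted(grams, key=lambda g: g.conc_nM)
    if not grams:
        raise ValueError("no sensorgrams supplied")
    data = [(g.association, g.dissociation, g.t_assoc) for g in grams]

    def resid(p):
        kd = p[0]
        out = []
        for i, ((t_a, r_a), (t_d, r_d), t_assoc) in enumerate(data):
            req, kobs = p[1 + 2 * i], p[2 + 2 * i]
            out.append(req * (1.0 - np.exp(-kobs * t_a)) - r_a)
            r_end = req * (1.0 - np.exp(-kobs * t_assoc))
            out.append(r_end * np.exp(-kd * t_d) - r_d)
        return np.concatenate(out)

    p0 = [1.0 / max(grams[0].t_assoc / 3.0, 1e-6)]
    for (t_a, r_a), _, _ in data:
        p0 += [max(float(np.max(r_a)), 1e-6), p0[0]]
    res = optimize.least_squares(resid, p0, bounds=(0.0, np.inf))
    return {g.conc_nM: float(res.x[1 + 2 * i]) for i, g in enumerate(grams)}


def fit_saturation(conc_nM: Sequence[float], req: Sequence[float]) -> SaturationFit:
    """Fit the Langmuir saturation isotherm ``Req(C) = Rmax C / (C + KD)``.

    Needs at least three concentrations. When the series never approaches
    KD the isotherm is nearly linear and KD is weakly identified; the fit is
    flagged ``poorly_constrained`` when the KD standard error exceeds the
    estimate or KD lands far beyond the measured range.
    """
    c = np.asarray(conc_nM, dtype=float)
    r = np.asarray(req, dtype=float)
    if c.size < 3:
        raise ValueError("saturation analysis needs at least 3 concentrations")
    kd0 = float(np.max(c))
    rmax0 = float(np.max(r)) * 2.0 or 1.0
    popt, pcov = optimize.curve_fit(
        lambda cc, rmax, kd: rmax * cc / (cc + kd),
        c,
        r,
        p0=[rmax0, kd0],
        bounds=([0.0, 0.0], [np.inf, np.inf]),
        maxfev=20000,
    )
    rmax, kd = float(popt[0]), float(popt[1])
    with np.errstate(invalid="ignore"):
        kd_se = float(np.sqrt(pcov[1, 1])) if np.isfinite(pcov[1, 1]) else math.inf
    poorly = (not math.isfinite(kd_se)) or kd_se > kd or kd > 50.0 * float(np.max(c))
    return SaturationFit(kd_nM=kd, rmax=rmax, kd_stderr_nM=kd_se, poorly_constrained=poorly)


def _global_model(params, grams):
    ka, kd, rmax = params
    out = []
    for g in grams:
        c_M = g.conc_nM * 1e-9
        kd_M = kd / ka
        req = rmax * c_M / (c_M + kd_M)
        kobs = ka * c_M + kd
        t_a, r_a = g.association
        model_a = req * (1.0 - np.exp(-kobs * t_a))
        r_end = req * (1.0 - np.exp(-kobs * g.t_assoc))
        t_d, r_d = g.dissociation
        model_d = r_end * np.exp(-kd * t_d)
        out.append(model_a - r_a)
        out.append(model_d - r_d)
    return np.concatenate(out)


def analyze_sensorgrams(
    grams: Sequence[BLISensorgram], mode: str = "global"
) -> BindingFit:
    """Full 1:1 analysis of a concentration series.

    ``mode="global"`` (default, standard BLI practice) fits shared ka, kd
    and Rmax across all traces by nonlinear least squares; ``mode="per_trace"``
    fits kd from each dissociation and ka from each association and averages.
    Either way, per-concentration equilibrium responses are extracted by
    per-trace association fits and passed to :func:`fit_saturation`, so both
    the kinetic and the equilibrium KD are reported.
    """
    if len(grams) == 0:
        raise ValueError("no sensorgrams supplied")
    if mode not in ("global", "per_trace"):
        raise ValueError(f"unknown mode {mode!r}")

    # seed estimates from the highest-concentration trace
    ref = max(grams, key=lambda g: g.conc_nM)
    d0 = fit_dissociation(ref)
    a0 = fit_association(ref, d0.kd)

    if mode == "global":
        rmax0 = max(a0.req * (1.0 + (d0.kd / a0.ka) / (ref.conc_nM * 1e-9)), a0.req)
        x0 = np.array([a0.ka, d0.kd, rmax0])
        res = optimize.least_squares(
            _global_model,
            x0,
            args=(grams,),
            bounds=([1e-3, 1e-9, 1e-12], [1e12, 1e3, 1e9]),
            x_scale=np.abs(x0),
        )
        ka, kd, rmax = map(float, res.x)
        rms = float(np.sqrt(np.mean(res.fun**2)))
    else:
        kds = [fit_dissociation(g).kd for g in grams]
        kd = float(np.mean(kds))
        kas = [fit_association(g, kd).ka for g in grams]
        ka = float(np.mean(kas))
        rmax = math.nan  # defined below from the saturation fit
        rms = math.nan

    req_by_conc = fit_series_req(grams)
    sat = fit_saturation(list(req_by_conc), list(req_by_conc.values()))
    if not math.isfinite(rmax):
        rmax = sat.rmax

    return BindingFit(
        ka=ka,
        kd=kd,
        rmax=rmax,
        kd_kinetic_nM=(kd / ka) * 1e9,
        req_by_conc=req_by_conc,
        kd_saturation_nM=sat.kd_nM,
        saturation=sat,
        residual_rms=rms,
    )
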