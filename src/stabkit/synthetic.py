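"""Seeded generators for every input the analysis pipeline consumes.

Each generator returns its dataset together with a :class:`GroundTruth`
record holding the planted parameters, so that downstream estimators can
be tested for parameter recovery. All randomness flows through a single
``numpy`` generator seeded from the ``seed`` argument; identical seeds
reproduce identical outputs.

Conventions
-----------
* Residue positions are 1-based in full-length protein numbering (an
  explicit ``numbering_offset`` shifts the first residue of a construct).
* Temperatures are degrees Celsius at the interface; the two-state model
  converts to kelvin internally.
* Noise is additive Gaussian on optical signals (melts, decays, BLI
  sensorgrams) and Poisson on photon counts (membrane images).
"""

from __future__ import annotations

import dataclasses
import json
import math
from typing import Mapping, Sequence

import numpy as np
from Bio.Align import MultipleSeqAlignment
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .thermal import DecayCurve, MeltingCurve
from .binding import BLISensorgram

__all__ = [
    "AMINO_ACIDS",
    "GAS_CONSTANT_KCAL",
    "GroundTruth",
    "gen_msa",
    "gen_ddg_table",
    "gen_melting_curve",
    "gen_decay_curve",
    "gen_bli_sensorgram",
    "gen_membrane_image",
    "expected_brightness",
    "two_state_fraction_unfolded",
]

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

#: Gas constant in kcal/(mol*K), the unit system of the ddG tables.
GAS_CONSTANT_KCAL = 1.987204259e-3


@dataclasses.dataclass(frozen=True)
class GroundTruth:
    """Planted parameters of a synthetic dataset.

    Attributes
    ----------
    generator : str
        Name of the generator that produced the dataset.
    parameters : dict
        Planted parameter values, keyed by name (units documented per
        generator).
    seed : int
        Seed the dataset was generated with.
    """

    generator: str
    parameters: dict
    seed: int

    def to_json(self, **kwargs) -> str:
        def _default(o):
            if isinstance(o, np.generic):
                return o.item()
            if isinstance(o, np.ndarray):
                return o.tolist()
            raise TypeError(f"not JSON serializable: {type(o)!r}")

        kwargs.setdefault("sort_keys", True)
        return json.dumps(dataclasses.asdict(self), default=_default, **kwargs)


def _as_profile(conservation_profile, length: int) -> np.ndarray:
    prof = np.broadcast_to(np.asarray(conservation_profile, dtype=float), (length,))
    if np.any(prof < 0) or np.any(prof > 1):
        raise ValueError("conservation frequencies must lie in [0, 1]")
    return prof.copy()


def gen_msa(
    target_sequence: str,
    n_homologs: int = 20,
    conservation_profile=0.8,
    planted_deviations: Sequence[tuple[int, str]] = (),
    seed: int = 0,
    gap_rate: float = 0.0,
    target_id: str = "target",
) -> tuple[MultipleSeqAlignment, GroundTruth]:
    """Generate an alignment of the target with homologs of controlled
    column conservation and planted back-to-consensus deviations.

    At a planted position ``(p, res)`` (1-based, ``res`` differing from
    the target residue there), at least ``ceil(0.5 * n_homologs)`` homologs
    carry ``res`` — the per-column count is ``ceil(freq * n_homologs)`` with
    ``freq`` the conservation-profile value, floored at 0.5 — while the
    target keeps its own residue, so a 50%-cutoff consensus caller must
    recover exactly the planted set. Elsewhere the *target* residue is the
    dominant residue at the stated frequency. Counts are deterministic
    (``ceil(freq * n)`` rows carry the dominant residue); only the row
    placement and the filler residues are random.

    Gaps, when ``gap_rate > 0``, replace non-dominant cells only and never
    occur in planted columns.
    """
    target_sequence = str(target_sequence).upper()
    length = len(target_sequence)
    if n_homologs < 2:
        raise ValueError("n_homologs must be >= 2")
    prof = _as_profile(conservation_profile, length)
    planted: dict[int, str] = {}
    for pos, res in planted_deviations:
        if not 1 <= pos <= length:
            raise ValueError(f"planted position {pos} outside 1..{length}")
        res = res.upper()
        if res not in AMINO_ACIDS:
            raise ValueError(f"invalid planted residue {res!r}")
        if res == target_sequence[pos - 1]:
            raise ValueError(
                f"planted consensus residue at position {pos} equals the target residue"
            )
        planted[pos] = res

    rng = np.random.default_rng(seed)
    columns = np.empty((n_homologs, length), dtype="U1")
    for j in range(length):
        pos = j + 1
        if pos in planted:
            dominant = planted[pos]
            freq = max(float(prof[j]), 0.5)
            # the consensus denominator counts the target row too, so floor
            # the planted count at a majority of all n+1 analyzed sequences
            n_dom = max(math.ceil(freq * n_homologs), math.ceil(0.5 * (n_homologs + 1)))
        else:
            dominant = target_sequence[j]
            freq = float(prof[j])
            n_dom = math.ceil(freq * n_homologs)
        n_dom = min(n_homologs, n_dom)
        rows = rng.permutation(n_homologs)
        others = [aa for aa in AMINO_ACIDS if aa != dominant]
        col = np.empty(n_homologs, dtype="U1")
        col[rows[:n_dom]] = dominant
        n_fill = n_homologs - n_dom
        if n_fill:
            col[rows[n_dom:]] = rng.choice(list(others), size=n_fill)
            if pos not in planted and gap_rate > 0:
                gap = rng.random(n_fill) < gap_rate
                col[rows[n_dom:][gap]] = "-"
        columns[:, j] = col

    records = [SeqRecord(Seq(target_sequence), id=target_id, description="")]
    for i in range(n_homologs):
        records.append(
            SeqRecord(Seq("".join(columns[i])), id=f"homolog_{i + 1:03d}", description="")
        )
    msa = MultipleSeqAlignment(records)
    truth = GroundTruth(
        generator="gen_msa",
        parameters={
            "target_id": target_id,
            "n_homologs": n_homologs,
            "conservation_profile": prof.tolist(),
            "planted_deviations": {str(p): r for p, r in sorted(planted.items())},
            "gap_rate": gap_rate,
        },
        seed=seed,
    )
    return msa, truth


def gen_ddg_table(
    sequence: str | None = None,
    sequence_length: int | None = None,
    stabilizer_positions: Sequence[int] = (),
    stabilizer_ddg: float = -1.8,
    background_ddg_mean: float = 1.0,
    background_ddg_sd: float = 0.5,
    numbering_offset: int = 1,
    seed: int = 0,
):
    """Generate a per-mutation ddG table with planted stabilizers.

    Emulates the output of force-field point-mutation scans: two predictor
    columns (``ddg_pred1``, ``ddg_pred2``, kcal/mol) over all 19 non-wildtype
    substitutions at every position. At each planted stabilizer position one
    substitution gets both predictors strictly below ``stabilizer_ddg``
    (which must be negative); all other entries are drawn from
    ``Normal(background_ddg_mean, background_ddg_sd)``.

    Returns a tidy ``pandas.DataFrame`` with columns
    ``position, wt, mut, ddg_pred1, ddg_pred2`` and the GroundTruth whose
    ``planted_stabilizers`` maps position to the planted mutant residue.
    """
    import pandas as pd

    if stabilizer_ddg >= 0:
        raise ValueError("stabilizer_ddg must be negative (stabilizing)")
    rng = np.random.default_rng(seed)
    if sequence is None:
        if sequence_length is None:
            raise ValueError("provide sequence or sequence_length")
        sequence = "".join(rng.choice(list(AMINO_ACIDS), size=sequence_length))
    sequence = sequence.upper()
    length = len(sequence)
    last = numbering_offset + length - 1
    for pos in stabilizer_positions:
        if not numbering_offset <= pos <= last:
            raise ValueError(f"stabilizer position {pos} outside {numbering_offset}..{last}")

    planted: dict[int, str] = {}
    rows = []
    for i, wt in enumerate(sequence):
        pos = numbering_offset + i
        muts = [aa for aa in AMINO_ACIDS if aa != wt]
        if pos in set(stabilizer_positions):
            planted[pos] = rng.choice(muts)
        for mut in muts:
            if planted.get(pos) == mut:
                d1 = stabilizer_ddg - rng.uniform(0.05, 0.5)
                d2 = stabilizer_ddg - rng.uniform(0.05, 0.5)
            else:
                d1 = rng.normal(background_ddg_mean, background_ddg_sd)
                d2 = rng.normal(background_ddg_mean, background_ddg_sd)
            rows.append((pos, wt, mut, d1, d2))
    table = pd.DataFrame(rows, columns=["position", "wt", "mut", "ddg_pred1", "ddg_pred2"])
    truth = GroundTruth(
        generator="gen_ddg_table",
        parameters={
            "sequence": sequence,
            "numbering_offset": numbering_offset,
            "stabilizer_ddg": stabilizer_ddg,
            "background_ddg_mean": background_ddg_mean,
            "background_ddg_sd": background_ddg_sd,
            "planted_stabilizers": {str(p): m for p, m in sorted(planted.items())},
        },
        seed=seed,
    )
    return table, truth


def two_state_fraction_unfolded(t_celsius, tm: float, dh_vh: float):
    """Fraction unfolded f(T) of a two-state unfolding equilibrium.

    ``K = exp[-(dH/R)(1/T - 1/Tm)]`` with temperatures in kelvin and the
    van't Hoff enthalpy ``dh_vh`` in kcal/mol; ``f = K / (1 + K)``.
    """
    t_k = np.asarray(t_celsius, dtype=float) + 273.15
    tm_k = tm + 273.15
    lnk = -(dh_vh / GAS_CONSTANT_KCAL) * (1.0 / t_k - 1.0 / tm_k)
    # guard exp overflow far from the transition
    lnk = np.clip(lnk, -500.0, 500.0)
    k = np.exp(lnk)
    return k / (1.0 + k)


def gen_melting_curve(
    tm: float,
    dh_vh: float = 80.0,
    baselines: tuple[tuple[float, float], tuple[float, float]] = ((-0.002, 1.0), (0.001, 2.0)),
    t_range: tuple[float, float] = (25.0, 90.0),
    step: float = 0.5,
    noise_sd: float = 0.0,
    modality: str = "fluorescence",
    seed: int = 0,
) -> tuple[MeltingCurve, GroundTruth]:
    """Generate a thermal-unfolding curve under the two-state model.

    Sigmoidal modalities (``fluorescence`` 330/350 ratio, ``ellipticity``)
    emit ``(1-f)*pre(T) + f*post(T) + noise`` with linear baselines given
    as ``(slope, intercept)`` pairs in the signal units per degC. The
    ``dsc`` modality emits the excess heat capacity ``dH * df/dT`` on top
    of the pre-transition baseline.
    """
    lo, hi = t_range
    if step <= 0:
        raise ValueError("step must be positive")
    if not lo < tm < hi:
        raise ValueError(f"tm={tm} outside the scanned range {t_range}")
    if dh_vh <= 0:
        raise ValueError("van't Hoff enthalpy must be positive")
    if modality not in ("fluorescence", "ellipticity", "dsc"):
        raise ValueError(f"unknown modality {modality!r}")

    rng = np.random.default_rng(seed)
    n = int(round((hi - lo) / step)) + 1
    t_c = lo + step * np.arange(n)
    f = two_state_fraction_unfolded(t_c, tm, dh_vh)
    (s1, i1), (s2, i2) = baselines
    if modality == "dsc":
        t_k = t_c + 273.15
        dfdt = f * (1.0 - f) * dh_vh / (GAS_CONSTANT_KCAL * t_k**2)
        signal = dh_vh * dfdt + (s1 * t_c + i1)
    else:
        signal = (1.0 - f) * (s1 * t_c + i1) + f * (s2 * t_c + i2)
    if noise_sd > 0:
        signal = signal + rng.normal(0.0, noise_sd, size=n)
    curve = MeltingCurve(temperature_c=t_c, signal=signal, modality=modality)
    truth = GroundTruth(
        generator="gen_melting_curve",
        parameters={
            "tm_C": tm,
            "dh_vh_kcal_mol": dh_vh,
            "baselines": [list(baselines[0]), list(baselines[1])],
            "t_range_C": list(t_range),
            "step_C": step,
            "noise_sd": noise_sd,
            "modality": modality,
        },
        seed=seed,
    )
    return curve, truth


def gen_decay_curve(
    t_half: float = 8.0,
    amplitude: float = 1.0,
    plateau: float = 0.0,
    duration_h: float = 24.0,
    interval_min: float = 5.0,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> tuple[DecayCurve, GroundTruth]:
    """Generate an isothermal ellipticity decay ``plateau + A*exp(-t*ln2/t_half)``.

    ``t_half`` is in hours; sampling every ``interval_min`` minutes over
    ``duration_h`` hours (the instrument protocol records every 5 min).
    ``t_half = math.inf`` yields a constant curve (a fully stable variant).
    """
    if not t_half > 0:
        raise ValueError("t_half must be positive (use math.inf for a stable protein)")
    if duration_h <= 0:
        raise ValueError("duration must be positive")
    rng = np.random.default_rng(seed)
    n = int(math.floor(duration_h * 60.0 / interval_min)) + 1
    t_h = (interval_min / 60.0) * np.arange(n)
    if math.isinf(t_half):
        y = np.full(n, plateau + amplitude, dtype=float)
    else:
        y = plateau + amplitude * np.exp(-t_h * math.log(2.0) / t_half)
    if noise_sd > 0:
        y = y + rng.normal(0.0, noise_sd, size=n)
    curve = DecayCurve(time_h=t_h, signal=y)
    truth = GroundTruth(
        generator="gen_decay_curve",
        parameters={
            "t_half_h": t_half,
            "amplitude": amplitude,
            "plateau": plateau,
            "duration_h": duration_h,
            "interval_min": interval_min,
            "noise_sd": noise_sd,
        },
        seed=seed,
    )
    return curve, truth


def gen_bli_sensorgram(
    ka: float = 1.0e4,
    kd: float = 7.64e-3,
    rmax: float = 1.0,
    concentrations_nM: Sequence[float] = (31.25, 62.5, 125.0, 250.0),
    t_assoc: float = 300.0,
    t_dissoc: float = 300.0,
    dt: float = 1.0,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> tuple[list[BLISensorgram], GroundTruth]:
    """Generate 1:1 Langmuir sensorgrams, one per analyte concentration.

    Association: ``R(t) = Req * (1 - exp(-(ka*C + kd) * t))`` with
    ``Req = rmax * C / (C + KD)`` and ``KD = kd/ka``; dissociation decays
    exponentially at ``kd`` from the end-of-association response. ``ka`` in
    1/(M*s), ``kd`` in 1/s, concentrations in nM (twofold dilution series
    31.25–250 nM by default, 300 s per phase).
    """
    if ka <= 0 or kd <= 0:
        raise ValueError("rate constants must be positive")
    if len(concentrations_nM) == 0:
        raise ValueError("at least one analyte concentration is required")
    if any(c <= 0 for c in concentrations_nM):
        raise ValueError("concentrations must be positive")
    rng = np.random.default_rng(seed)
    kd_M = kd / ka
    grams = []
    for conc in concentrations_nM:
        c_M = conc * 1e-9
        n_a = int(round(t_assoc / dt)) + 1
        n_d = int(round(t_dissoc / dt))
        t_a = dt * np.arange(n_a)
        kobs = ka * c_M + kd
        req = rmax * c_M / (c_M + kd_M)
        r_a = req * (1.0 - np.exp(-kobs * t_a))
        r_end = r_a[-1]
        t_d = t_assoc + dt * np.arange(1, n_d + 1)
        r_d = r_end * np.exp(-kd * (t_d - t_assoc))
        time = np.concatenate([t_a, t_d])
        resp = np.concatenate([r_a, r_d])
        if noise_sd > 0:
            resp = resp + rng.normal(0.0, noise_sd, size=resp.size)
        grams.append(
            BLISensorgram(time_s=time, response=resp, conc_nM=float(conc), t_assoc=t_assoc)
        )
    truth = GroundTruth(
        generator="gen_bli_sensorgram",
        parameters={
            "ka_per_M_s": ka,
            "kd_per_s": kd,
            "kd_eq_nM": kd_M * 1e9,
            "rmax": rmax,
            "concentrations_nM": list(map(float, concentrations_nM)),
            "t_assoc_s": t_assoc,
            "t_dissoc_s": t_dissoc,
            "noise_sd": noise_sd,
        },
        seed=seed,
    )
    return grams, truth


def _validate_mix(oligomer_mix: Mapping[int, float]) -> dict[int, float]:
    mix = {int(k): float(v) for k, v in oligomer_mix.items()}
    if not mix:
        raise ValueError("oligomer mix is empty")
    if any(k < 1 for k in mix):
        raise ValueError("oligomer sizes must be >= 1")
    if any(v < 0 for v in mix.values()):
        raise ValueError("mix fractions must be non-negative")
    total = sum(mix.values())
    if not math.isclose(total, 1.0, rel_tol=0, abs_tol=1e-9):
        raise ValueError(f"mix fractions must sum to 1 (got {total})")
    return mix


def expected_brightness(
    oligomer_mix: Mapping[int, float],
    photons_per_fluorophore: float = 10.0,
    gamma: float = 0.5,
) -> float:
    """Closed-form expected molecular brightness for a compound-Poisson
    membrane: ``epsilon = q * E[k^2] / (gamma * E[k])`` with oligomer size k
    drawn from the mix and q photons per fluorophore.

    This is the independent oracle for the FIF pipeline: per pixel the
    fluorophore count is ``S = sum_k k * Poisson(mu * p_k)``, photons are
    ``Poisson(q * S)``, hence ``Var/Mean - 1 = q * E[k^2]/E[k]``.
    """
    mix = _validate_mix(oligomer_mix)
    ek = sum(k * p for k, p in mix.items())
    ek2 = sum(k * k * p for k, p in mix.items())
    return photons_per_fluorophore * ek2 / (gamma * ek)


def gen_membrane_image(
    shape: tuple[int, int] = (150, 150),
    roi_mask: np.ndarray | None = None,
    oligomer_mix: Mapping[int, float] = {1: 1.0},
    mean_oligomers_per_pixel: float = 5.0,
    photons_per_fluorophore: float = 10.0,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray, GroundTruth]:
    """Generate a photon-counting membrane image for a monomer/dimer/mixture
    population.

    Per pixel, the number of k-mers is ``Poisson(mu * p_k)`` independently
    per size k (equivalent by Poisson thinning to drawing ``Poisson(mu)``
    oligomers with sizes from the mix), and the detected photon count is
    ``Poisson(q * total fluorophores)``. Pixels outside the ROI are zero.
    Returns ``(image uint16, mask bool, GroundTruth)``.
    """
    mix = _validate_mix(oligomer_mix)
    mu = float(mean_oligomers_per_pixel)
    q = float(photons_per_fluorophore)
    if mu <= 0:
        raise ValueError("mean oligomers per pixel must be positive")
    if q <= 0:
        raise ValueError("photons per fluorophore must be positive")
    if roi_mask is None:
        roi_mask = np.ones(shape, dtype=bool)
    else:
        roi_mask = np.asarray(roi_mask, dtype=bool)
        if roi_mask.shape != tuple(shape):
            raise ValueError("roi_mask shape must match image shape")
    if not roi_mask.any():
        raise ValueError("ROI mask is empty")

    rng = np.random.default_rng(seed)
    fluorophores = np.zeros(shape, dtype=float)
    for k in sorted(mix):
        fluorophores += k * rng.poisson(mu * mix[k], size=shape)
    photons = rng.poisson(q * fluorophores)
    photons[~roi_mask] = 0
    image = np.clip(photons, 0, np.iinfo(np.uint16).max).astype(np.uint16)
    truth = GroundTruth(
        generator="gen_membrane_image",
        parameters={
            "shape": list(shape),
            "oligomer_mix": {str(k): v for k, v in sorted(mix.items())},
            "mean_oligomers_per_pixel": mu,
            "photons_per_fluorophore": q,
            "expected_brightness_gamma_0.5": expected_brightness(mix, q, 0.5),
        },
        seed=seed,
    )
    return image, roi_mask, truth
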