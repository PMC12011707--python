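"""File formats: aligned FASTA, tidy CSV curve/table layouts, TIFF images,
and ground-truth JSON sidecars.

CSV layouts (all plain, comma-separated, header row):

* ddG table:     position, wt, mut, ddg_pred1, ddg_pred2
* annotations:   position, conservation, is_fgfr_site, is_heparin_site
* measured dTm:  position, wt, mut, dtm_C
* melting curve: temperature_C, signal
* decay curve:   time_min, signal
* sensorgrams:   time_s, response, conc_nM, phase
* segments:      segment, row0, col0, mean, variance, brightness
* distribution:  bin_center, normalized_frequency
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import AlignIO, SeqIO

from .binding import BLISensorgram
from .design import MutationCandidate, TargetProtein, candidates_to_frame
from .fif import BrightnessDistribution, SegmentStats
from .thermal import DecayCurve, MeltingCurve

_FLOAT_FMT = "%.10g"


def write_msa(msa, path) -> None:
    AlignIO.write(msa, str(path), "fasta")


def read_msa(path):
    return AlignIO.read(str(path), "fasta")


def read_fasta_sequence(path) -> tuple[str, str]:
    """First record of a FASTA file as ``(id, sequence)``."""
    rec = next(SeqIO.parse(str(path), "fasta"))
    return rec.id, str(rec.seq)


def write_ground_truth(truth, path) -> None:
    Path(path).write_text(truth.to_json(indent=2) + "\n")


def _write_frame(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False, float_format=_FLOAT_FMT)


def write_ddg_table(table: pd.DataFrame, path) -> None:
    _write_frame(table[["position", "wt", "mut", "ddg_pred1", "ddg_pred2"]], path)


def read_ddg_table(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    required = {"position", "wt", "mut", "ddg_pred1", "ddg_pred2"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"ddG table missing columns: {sorted(missing)}")
    return df


def read_annotations(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    required = {"position", "conservation", "is_fgfr_site", "is_heparin_site"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"annotation table missing columns: {sorted(missing)}")
    return df


def annotations_to_sites(df: pd.DataFrame) -> frozenset:
    """Binding-site position set (receptor or heparin) from an annotation table."""
    site = df["is_fgfr_site"].astype(bool) | df["is_heparin_site"].astype(bool)
    return frozenset(int(p) for p in df.loc[site, "position"])


def annotations_to_conservation(df: pd.DataFrame) -> dict[int, int]:
    return {int(r.position): int(r.conservation) for r in df.itertuples(index=False)}


def write_candidates(candidates, path) -> None:
    _write_frame(candidates_to_frame(candidates), path)


def read_measured_dtm(path) -> dict[str, float]:
    """Measured single-mutant dTm values keyed by mutation name (e.g. V123I)."""
    df = pd.read_csv(path)
    required = {"position", "wt", "mut", "dtm_C"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"dTm table missing columns: {sorted(missing)}")
    return {
        f"{r.wt}{int(r.position)}{r.mut}": float(r.dtm_C) for r in df.itertuples(index=False)
    }


def attach_measured_dtm(candidates, dtm_by_name) -> list[MutationCandidate]:
    for c in candidates:
        if c.name in dtm_by_name:
            c.measured_dtm = dtm_by_name[c.name]
    return list(candidates)


def plans_to_json(plans, path=None) -> str:
    payload = []
    for p in plans:
        payload.append(
            {
                "rank": p.rank,
                "name": p.name,
                "mutations": [m.name for m in p.members],
                "predicted_ddg": p.predicted_ddg,
                "predicted_dtm": p.predicted_dtm,
            }
        )
    text = json.dumps(payload, indent=2, sort_keys=True) + "\n"
    if path is not None:
        Path(path).write_text(text)
    return text


def write_melting_curve(curve: MeltingCurve, path) -> None:
    _write_frame(
        pd.DataFrame({"temperature_C": curve.temperature_c, "signal": curve.signal}), path
    )


def read_melting_curve(path, modality: str = "fluorescence") -> MeltingCurve:
    df = pd.read_csv(path)
    return MeltingCurve(
        temperature_c=df["temperature_C"].to_numpy(),
        signal=df["signal"].to_numpy(),
        modality=modality,
    )


def write_decay_curve(curve: DecayCurve, path) -> None:
    _write_frame(pd.DataFrame({"time_min": curve.time_h * 60.0, "signal": curve.signal}), path)


def read_decay_curve(path) -> DecayCurve:
    df = pd.read_csv(path)
    return DecayCurve(time_h=df["time_min"].to_numpy() / 60.0, signal=df["signal"].to_numpy())


def write_sensorgrams(grams, path) -> None:
    frames = []
    for g in sorted(grams, key=lambda g: g.conc_nM):
        frames.append(
            pd.DataFrame(
                {
                    "time_s": g.time_s,
                    "response": g.response,
                    "conc_nM": g.conc_nM,
                    "phase": g.phase_labels,
                }
            )
        )
    _write_frame(pd.concat(frames, ignore_index=True), path)


def read_sensorgrams(path) -> list[BLISensorgram]:
    df = pd.read_csv(path)
    grams = []
    for conc, sub in df.groupby("conc_nM", sort=True):
        assoc = sub[sub["phase"] == "assoc"]
        t_assoc = float(assoc["time_s"].max()) if len(assoc) else 300.0
        grams.append(
            BLISensorgram(
                time_s=sub["time_s"].to_numpy(),
                response=sub["response"].to_numpy(),
                conc_nM=float(conc),
                t_assoc=t_assoc,
            )
        )
    return grams


def write_image(image: np.ndarray, path) -> None:
    import tifffile

    tifffile.imwrite(str(path), np.asarray(image, dtype=np.uint16))


def read_image(path) -> np.ndarray:
    import tifffile

    return tifffile.imread(str(path))


def write_mask(mask: np.ndarray, path) -> None:
    import tifffile

    tifffile.imwrite(str(path), np.asarray(mask, dtype=np.uint8))


def read_mask(path) -> np.ndarray:
    import tifffile

    return tifffile.imread(str(path)).astype(bool)


def write_segments(stats: list[SegmentStats], path) -> None:
    _write_frame(
        pd.DataFrame(
            {
                "segment": [s.index for s in stats],
                "row0": [s.row0 for s in stats],
                "col0": [s.col0 for s in stats],
                "mean": [s.mean for s in stats],
                "variance": [s.variance for s in stats],
                "brightness": [s.brightness for s in stats],
            }
        ),
        path,
    )


def read_segment_brightness(path) -> np.ndarray:
    df = pd.read_csv(path)
    return df["brightness"].to_numpy(dtype=float)


def write_distribution(dist: BrightnessDistribution, path) -> None:
    _write_frame(
        pd.DataFrame(
            {"bin_center": dist.bin_centers, "normalized_frequency": dist.frequency}
        ),
        path,
    )
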