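"""Fluorescence-intensity-fluctuation (FIF) molecular-brightness analysis.

Membrane ROIs are tiled into fixed 15x15-pixel segments; per segment the
molecular brightness is ``epsilon = (1/gamma) * (sigma^2 / I - 1)`` with
shape factor gamma = 0.5, mean intensity I and variance sigma^2 of the
pixel photon counts. Brightness values pooled over the segments of many
cells (the protocol calls for at least 100) are histogrammed and compared
against monomer (LAT-like) and dimer controls: brightness scales with
oligomer size, so a pure dimer population doubles the monomer brightness
and ligand-stabilized mixtures land strictly in between.

Under-dispersed segments yield negative epsilon; they are retained —
discarding them would bias the distributions.
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np

__all__ = [
    "DEFAULT_GAMMA",
    "DEFAULT_SEGMENT_SIDE",
    "SegmentStats",
    "BrightnessDistribution",
    "ControlComparison",
    "tile_roi",
    "segment_brightness",
    "aggregate_distribution",
    "compare_to_control",
]

DEFAULT_GAMMA = 0.5
DEFAULT_SEGMENT_SIDE = 15
MIN_CELLS_DEFAULT = 100


@dataclasses.dataclass
class SegmentStats:
    """Statistics of one 225-pixel membrane segment."""

    index: int
    row0: int
    col0: int
    n_pixels: int
    mean: float
    variance: float
    brightness: float | None = None


@dataclasses.dataclass
class BrightnessDistribution:
    """Pooled, normalized brightness histogram over many cells.

    ``frequency`` sums to 1; ``values`` keeps the raw pooled brightness
    values so distributions with different bin specs can be re-binned for
    comparison.
    """

    bin_edges: np.ndarray
    frequency: np.ndarray
    n_segments: int
    n_cells: int
    gamma: float
    values: np.ndarray | None = None

    @property
    def bin_centers(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])

    @property
    def mean(self) -> float:
        if self.values is not None:
            return float(np.mean(self.values))
        return float(np.sum(self.bin_centers * self.frequency))

    @property
    def median(self) -> float:
        if self.values is not None:
            return float(np.median(self.values))
        cum = np.cumsum(self.frequency)
        return float(self.bin_centers[int(np.searchsorted(cum, 0.5))])


@dataclasses.dataclass
class ControlComparison:
    """Summary of a sample distribution against a monomer control (and
    optionally a dimer control).

    ``position`` locates the sample mean on the monomer-to-dimer axis
    (0 = monomer mean, 1 = dimer mean); the classification thresholds are
    0.25 and 0.75.
    """

    mean_ratio: float
    median_ratio: float
    median_shift: float
    overlap: float
    position: float | None = None
    classification: str | None = None


def tile_roi(
    image: np.ndarray,
    mask: np.ndarray,
    segment_side: int = DEFAULT_SEGMENT_SIDE,
    anchor: tuple[int, int] = (0, 0),
) -> list[SegmentStats]:
    """Tile the ROI into non-overlapping ``segment_side``-square segments
    and compute per-segment mean and variance of the pixel intensities.

    The grid is anchored at the mask bounding-box origin plus ``anchor``;
    only tiles fully inside the mask are kept (partial tiles are discarded,
    per the fixed-segment protocol). Variance uses the unbiased (ddof=1)
    estimator. Raises when the mask is empty or admits no full tile.
    """
    image = np.asarray(image, dtype=float)
    mask = np.asarray(mask, dtype=bool)
    if image.shape != mask.shape:
        raise ValueError("image and mask shapes differ")
    if np.any(image < 0):
        raise ValueError("intensities must be non-negative photon counts")
    if not mask.any():
        raise ValueError("empty ROI mask")
    rows, cols = np.nonzero(mask)
    r0, r1 = rows.min() + anchor[0], rows.max() + 1
    c0, c1 = cols.min() + anchor[1], cols.max() + 1
    stats: list[SegmentStats] = []
    idx = 0
    for rr in range(r0, r1 - segment_side + 1, segment_side):
        for cc in range(c0, c1 - segment_side + 1, segment_side):
            tile_mask = mask[rr : rr + segment_side, cc : cc + segment_side]
            if not tile_mask.all():
                continue
            tile = image[rr : rr + segment_side, cc : cc + segment_side]
            stats.append(
                SegmentStats(
                    index=idx,
                    row0=rr,
                    col0=cc,
                    n_pixels=segment_side * segment_side,
                    mean=float(tile.mean()),
                    variance=float(tile.var(ddof=1)),
                )
            )
            idx += 1
    if not stats:
        raise ValueError("ROI smaller than one full segment")
    return stats


def segment_brightness(
    stats: Sequence[SegmentStats], gamma: float = DEFAULT_GAMMA
) -> np.ndarray:
    """Molecular brightness ``epsilon = (1/gamma)(variance/mean - 1)`` per
    segment; fills the ``brightness`` field in place and returns the array.
    A zero-mean segment is an error (no signal to normalize by)."""
    if gamma <= 0:
        raise ValueError("gamma must be positive")
    eps = np.empty(len(stats), dtype=float)
    for i, s in enumerate(stats):
        if s.mean <= 0:
            raise ValueError(f"segment {s.index} has zero mean intensity")
        e = (s.variance / s.mean - 1.0) / gamma
        s.brightness = float(e)
        eps[i] = e
    return eps


def aggregate_distribution(
    per_cell_brightness: Sequence[np.ndarray],
    bins: int | np.ndarray = 50,
    min_cells: int = MIN_CELLS_DEFAULT,
    allow_fewer: bool = False,
    gamma: float = DEFAULT_GAMMA,
    percentile_range: tuple[float, float] = (1.0, 99.0),
) -> BrightnessDistribution:
    """Pool per-cell brightness values into a normalized histogram.

    ``bins`` is either explicit edges or a bin count; with a count, linear
    bins span the pooled 1st–99th percentile (the protocol does not fix a
    binning, so the default is data-driven and recorded in the result).
    The protocol pools at least ``min_cells`` cells; pass
    ``allow_fewer=True`` to relax explicitly (e.g. for simulations).
    """
    cells = [np.asarray(c, dtype=float) for c in per_cell_brightness if len(c)]
    if len(cells) < min_cells and not allow_fewer:
        raise ValueError(
            f"{len(cells)} cells < required minimum {min_cells}; "
            "pass allow_fewer=True to override"
        )
    if not cells:
        raise ValueError("no brightness values to aggregate")
    pooled = np.concatenate(cells)
    if np.isscalar(bins):
        lo, hi = np.percentile(pooled, percentile_range)
        if lo == hi:
            lo, hi = lo - 0.5, hi + 0.5
        edges = np.linspace(lo, hi, int(bins) + 1)
    else:
        edges = np.asarray(bins, dtype=float)
    counts, edges = np.histogram(pooled, bins=edges)
    total = counts.sum()
    freq = counts / total if total else counts.astype(float)
    return BrightnessDistribution(
        bin_edges=edges,
        frequency=freq,
        n_segments=int(pooled.size),
        n_cells=len(cells),
        gamma=gamma,
        values=pooled,
    )


def _rebin(dist: BrightnessDistribution, edges: np.ndarray) -> np.ndarray:
    if np.array_equal(dist.bin_edges, edges):
        return dist.frequency
    if dist.values is None:
        raise ValueError(
            "distributions have incompatible bins and no raw values to re-bin from"
        )
    counts, _ = np.histogram(dist.values, bins=edges)
    total = counts.sum()
    return counts / total if total else counts.astype(float)


def compare_to_control(
    sample: BrightnessDistribution,
    monomer_control: BrightnessDistribution,
    dimer_control: BrightnessDistribution | None = None,
) -> ControlComparison:
    """Compare a brightness distribution to the monomer control.

    Reports the mean and median brightness ratios, the median shift, and
    the histogram overlap coefficient (sum of bin-wise minima on a shared
    binning). With a dimer control, the sample is classified monomer-like /
    intermediate / dimer-like by where its mean falls on the
    monomer-to-dimer brightness axis (below 0.25 / between / above 0.75).
    """
    edges = monomer_control.bin_edges
    f_s = _rebin(sample, edges)
    f_m = _rebin(monomer_control, edges)
    overlap = float(np.minimum(f_s, f_m).sum())
    mean_ratio = sample.mean / monomer_control.mean
    median_ratio = sample.median / monomer_control.median
    median_shift = sample.median - monomer_control.median
    position = None
    classification = None
    if dimer_control is not None:
        span = dimer_control.mean - monomer_control.mean
        if span == 0:
            raise ValueError("dimer and monomer controls have identical means")
        position = float((sample.mean - monomer_control.mean) / span)
        if position < 0.25:
            classification = "monomer-like"
        elif position > 0.75:
            classification = "dimer-like"
        else:
            classification = "intermediate"
    return ControlComparison(
        mean_ratio=float(mean_ratio),
        median_ratio=float(median_ratio),
        median_shift=float(median_shift),
        overlap=overlap,
        position=position,
        classification=classification,
    )
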