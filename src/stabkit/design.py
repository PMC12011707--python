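"""Selection and combination of stabilizing point mutations.

Two selection routes are implemented, mirroring hybrid stability-design
practice:

* **energy route** — keep substitutions whose predicted folding free-energy
  change is below −1.0 kcal/mol in *both* predictor columns (FoldX-like and
  Rosetta-like scans are combined conservatively with an AND rule), at
  positions of evolutionary conservation grade ≤ 7 (1–9 ConSurf-style
  scale, 9 most conserved) and outside receptor/heparin binding sites;
* **back-to-consensus route** — propose reverting the target residue to the
  alignment consensus wherever a consensus residue exists at ≥ 50% of all
  analyzed sequences (gaps counted in the denominator), the target deviates
  from it, and the substitution is not destabilizing (both predictors
  < +0.5 kcal/mol), again excluding binding-site positions.

Survivors with a measured melting-temperature gain ΔTm ≥ 2 °C can be
combined into multi-point designs ranked by the additive ΔΔG sum; the
combined ΔTm prediction is the exact sum of member ΔTm values (the
additivity assumption that multi-point stabilization rests on).

Every examined mutation is retained in the output with its verdict flags,
so the audit trail ``selected ∪ rejected = input`` always holds.
"""

from __future__ import annotations

import dataclasses
import itertools
import logging
import math
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "TargetProtein",
    "ConsensusProfile",
    "MutationCandidate",
    "CombinationPlan",
    "ENERGY_DDG_CUTOFF",
    "CONSENSUS_DDG_CUTOFF",
    "CONSENSUS_CUTOFF",
    "CONSERVATION_CUTOFF",
    "DTM_THRESHOLD",
    "build_consensus_profile",
    "propose_consensus_mutations",
    "filter_energy_candidates",
    "combine_candidates",
    "select_singles_by_dtm",
    "predict_combined_dtm",
    "candidates_to_frame",
]

# Default gate values of the design protocol.
ENERGY_DDG_CUTOFF = -1.0  # kcal/mol, strict <
CONSENSUS_DDG_CUTOFF = 0.5  # kcal/mol, strict <
CONSENSUS_CUTOFF = 0.5  # fraction of all analyzed sequences, inclusive >=
CONSERVATION_CUTOFF = 7  # grade on the 1-9 scale, inclusive <=
DTM_THRESHOLD = 2.0  # degC, inclusive >=


@dataclasses.dataclass(frozen=True)
class TargetProtein:
    """The engineering target: sequence, numbering and functional sites.

    ``numbering_offset`` is the full-length position of the first residue
    (a 40–208 construct has offset 40), so reported mutation names match
    the printed full-length numbering. ``binding_site_positions`` holds the
    receptor- and heparin-binding positions to exclude from design.
    """

    sequence: str
    numbering_offset: int = 1
    binding_site_positions: frozenset = frozenset()

    def __post_init__(self):
        object.__setattr__(self, "sequence", self.sequence.upper())
        object.__setattr__(
            self, "binding_site_positions", frozenset(self.binding_site_positions)
        )
        last = self.numbering_offset + len(self.sequence) - 1
        bad = [p for p in self.binding_site_positions if not self.numbering_offset <= p <= last]
        if bad:
            raise ValueError(
                f"binding-site positions {sorted(bad)} outside {self.numbering_offset}..{last}"
            )

    def residue_at(self, position: int) -> str:
        i = position - self.numbering_offset
        if not 0 <= i < len(self.sequence):
            raise IndexError(f"position {position} outside the construct")
        return self.sequence[i]

    @property
    def positions(self) -> range:
        return range(self.numbering_offset, self.numbering_offset + len(self.sequence))


@dataclasses.dataclass
class ConsensusProfile:
    """Per-column residue frequencies of an alignment, mapped onto target
    numbering.

    Frequencies are computed over *all* analyzed sequences with gaps counted
    in the denominator (gap frequency is stored under ``"-"`` but a gap is
    never a consensus residue). ``column_to_position`` maps alignment
    columns (0-based) to target positions; columns where the target is
    gapped carry no mapping.
    """

    frequencies: list[dict[str, float]]
    n_sequences: int
    column_to_position: dict[int, int]
    target_id: str

    def consensus(self, column: int, cutoff: float = CONSENSUS_CUTOFF):
        """Return ``(residue, frequency)`` for the column, or ``(None, freq_max)``
        when no residue reaches the cutoff. A tied maximum — possible only
        at exactly the 0.5 cutoff, or below it — calls no consensus."""
        freqs = {r: f for r, f in self.frequencies[column].items() if r != "-"}
        if not freqs:
            return None, 0.0
        best = max(freqs.values())
        winners = sorted(r for r, f in freqs.items() if f == best)
        if best >= cutoff and len(winners) == 1:
            return winners[0], best
        return None, best

    def position_of(self, column: int):
        return self.column_to_position.get(column)


@dataclasses.dataclass
class MutationCandidate:
    """A single-point substitution with its provenance and filter verdicts.

    ``selected`` is true iff every verdict flag passed. ``ddg`` is the
    conservative scalar summary (mean of the two predictors when both are
    present) used for ranking combinations.
    """

    position: int
    wt: str
    mut: str
    source: str  # "energy" | "consensus"
    ddg_pred1: float | None = None
    ddg_pred2: float | None = None
    conservation: int | None = None
    consensus_frequency: float | None = None
    passed_ddg: bool = False
    passed_conservation: bool = False
    passed_site_exclusion: bool = False
    measured_dtm: float | None = None
    note: str = ""

    @property
    def name(self) -> str:
        return f"{self.wt}{self.position}{self.mut}"

    @property
    def ddg(self) -> float:
        vals = [v for v in (self.ddg_pred1, self.ddg_pred2) if v is not None]
        if not vals:
            return math.nan
        return float(np.mean(vals))

    @property
    def selected(self) -> bool:
        return self.passed_ddg and self.passed_conservation and self.passed_site_exclusion


@dataclasses.dataclass
class CombinationPlan:
    """A multi-point design: position-disjoint candidates with additive
    predictions. ``predicted_ddg`` and ``predicted_dtm`` are exact sums of
    member values."""

    members: tuple[MutationCandidate, ...]
    rank: int | None = None

    def __post_init__(self):
        positions = [m.position for m in self.members]
        if len(set(positions)) != len(positions):
            raise ValueError("combination members must occupy distinct positions")
        self.members = tuple(sorted(self.members, key=lambda m: m.position))

    @property
    def predicted_ddg(self) -> float:
        return float(sum(m.ddg for m in self.members))

    @property
    def predicted_dtm(self) -> float | None:
        if any(m.measured_dtm is None for m in self.members):
            return None
        return float(sum(m.measured_dtm for m in self.members))

    @property
    def name(self) -> str:
        return "+".join(m.name for m in self.members)


def build_consensus_profile(msa, target_id: str) -> ConsensusProfile:
    """Column-frequency profile of an alignment, anchored on the target row.

    ``msa`` is a Biopython ``MultipleSeqAlignment`` (or any iterable of
    records with ``id`` and ``seq``). All rows must have equal length and
    the target must be present. Frequencies use all sequences (target
    included) in the denominator, gaps included.
    """
    records = list(msa)
    if not records:
        raise ValueError("empty alignment")
    lengths = {len(r.seq) for r in records}
    if len(lengths) != 1:
        raise ValueError("ragged alignment: rows differ in length")
    try:
        target = next(r for r in records if r.id == target_id)
    except StopIteration:
        raise ValueError(f"target {target_id!r} not found in the alignment") from None

    n = len(records)
    length = lengths.pop()
    freqs: list[dict[str, float]] = []
    for j in range(length):
        counts: dict[str, int] = {}
        for r in records:
            c = str(r.seq[j]).upper()
            counts[c] = counts.get(c, 0) + 1
        freqs.append({c: k / n for c, k in sorted(counts.items())})

    col_to_pos: dict[int, int] = {}
    pos = 0
    tseq = str(target.seq).upper()
    for j, c in enumerate(tseq):
        if c != "-":
            pos += 1
            col_to_pos[j] = pos
    return ConsensusProfile(
        frequencies=freqs, n_sequences=n, column_to_position=col_to_pos, target_id=target_id
    )


def _both_below(v1, v2, cutoff: float) -> bool:
    """Conservative AND combination of the two ddG predictors."""
    return v1 is not None and v2 is not None and v1 < cutoff and v2 < cutoff


def _ddg_lookup(ddg_table: pd.DataFrame) -> dict[tuple[int, str], tuple[float, float]]:
    lut = {}
    for row in ddg_table.itertuples(index=False):
        lut[(int(row.position), str(row.mut))] = (float(row.ddg_pred1), float(row.ddg_pred2))
    return lut


def propose_consensus_mutations(
    profile: ConsensusProfile,
    target: TargetProtein,
    ddg_table: pd.DataFrame,
    consensus_cutoff: float = CONSENSUS_CUTOFF,
    ddg_cutoff: float = CONSENSUS_DDG_CUTOFF,
) -> list[MutationCandidate]:
    """Back-to-consensus proposals with the non-destabilizing ΔΔG gate.

    One candidate per position where the consensus residue (frequency
    ≥ ``consensus_cutoff``, inclusive) differs from the target residue.
    The candidate passes the energy gate when both predictors are strictly
    below ``ddg_cutoff`` (+0.5 kcal/mol default) and the site gate when the
    position lies outside the binding sites. Positions whose substitution
    lacks a ΔΔG record are kept in the audit list, flagged and logged, but
    can never be selected.
    """
    lut = _ddg_lookup(ddg_table)
    out: list[MutationCandidate] = []
    offset = target.numbering_offset - 1
    for col, seq_pos in sorted(profile.column_to_position.items()):
        position = seq_pos + offset
        wt = target.residue_at(position)
        consensus, freq = profile.consensus(col, consensus_cutoff)
        if consensus is None or consensus == wt:
            continue
        cand = MutationCandidate(
            position=position,
            wt=wt,
            mut=consensus,
            source="consensus",
            consensus_frequency=freq,
            passed_conservation=True,  # no conservation gate on this route
            passed_site_exclusion=position not in target.binding_site_positions,
        )
        key = (position, consensus)
        if key in lut:
            cand.ddg_pred1, cand.ddg_pred2 = lut[key]
            cand.passed_ddg = _both_below(cand.ddg_pred1, cand.ddg_pred2, ddg_cutoff)
        else:
            cand.passed_ddg = False
            cand.note = "missing ddG record; dropped from selection"
            logger.warning("consensus candidate %s has no ddG record; dropped", cand.name)
        if not cand.passed_site_exclusion and not cand.note:
            cand.note = "binding-site position"
        out.append(cand)
    return out


def filter_energy_candidates(
    ddg_table: pd.DataFrame,
    conservation: Mapping[int, int],
    target: TargetProtein,
    ddg_cutoff: float = ENERGY_DDG_CUTOFF,
    conservation_cutoff: int = CONSERVATION_CUTOFF,
) -> list[MutationCandidate]:
    """Energy-route filter over a full point-mutation scan.

    A substitution is selected iff both predictors are strictly below
    ``ddg_cutoff`` (−1.0 kcal/mol default), the position's conservation
    grade is ≤ ``conservation_cutoff`` (grades 1–9, 9 most conserved), and
    the position is not a binding-site residue. All records come back with
    verdict flags for audit. A candidate position missing from the
    conservation table is an error.
    """
    grades = {int(k): int(v) for k, v in dict(conservation).items()}
    bad = [g for g in grades.values() if not 1 <= g <= 9]
    if bad:
        raise ValueError(f"conservation grades must be 1..9, got {sorted(set(bad))}")
    out: list[MutationCandidate] = []
    for row in ddg_table.itertuples(index=False):
        position = int(row.position)
        if position not in grades:
            raise KeyError(f"no conservation grade for position {position}")
        cand = MutationCandidate(
            position=position,
            wt=str(row.wt),
            mut=str(row.mut),
            source="energy",
            ddg_pred1=float(row.ddg_pred1),
            ddg_pred2=float(row.ddg_pred2),
            conservation=grades[position],
        )
        cand.passed_ddg = _both_below(cand.ddg_pred1, cand.ddg_pred2, ddg_cutoff)
        cand.passed_conservation = cand.conservation <= conservation_cutoff
        cand.passed_site_exclusion = position not in target.binding_site_positions
        out.append(cand)
    return out


def _n_combinations(n: int, max_order: int) -> int:
    return sum(math.comb(n, k) for k in range(2, max_order + 1))


def combine_candidates(
    selected: Sequence[MutationCandidate],
    max_order: int = 4,
    top_k: int | None = None,
    max_enumeration: int = 200_000,
) -> list[CombinationPlan]:
    """Enumerate all position-disjoint 2..max_order-point combinations and
    rank them by predicted ΔΔG (most stabilizing first).

    Ties on predicted ΔΔG break deterministically by fewer mutations, then
    lexicographic position order. Enumeration is refused above
    ``max_enumeration`` plans; pass a larger limit explicitly for big sets.
    """
    if not selected:
        raise ValueError("no candidates to combine")
    if max_order < 2:
        raise ValueError("max_order must be >= 2")
    n = len(selected)
    total = _n_combinations(n, min(max_order, n))
    if total > max_enumeration:
        raise ValueError(
            f"enumeration of {total} combinations exceeds the guard of "
            f"{max_enumeration}; pass max_enumeration={total} (or higher) to proceed"
        )
    plans: list[CombinationPlan] = []
    for order in range(2, min(max_order, n) + 1):
        for combo in itertools.combinations(selected, order):
            positions = [m.position for m in combo]
            if len(set(positions)) != len(positions):
                continue
            plans.append(CombinationPlan(members=combo))
    plans.sort(
        key=lambda p: (
            p.predicted_ddg,
            len(p.members),
            tuple(m.position for m in p.members),
            tuple(m.mut for m in p.members),
        )
    )
    if top_k is not None:
        plans = plans[:top_k]
    for i, p in enumerate(plans, start=1):
        p.rank = i
    return plans


def select_singles_by_dtm(
    candidates: Iterable[MutationCandidate], dtm_threshold: float = DTM_THRESHOLD
) -> list[MutationCandidate]:
    """Keep candidates whose measured melting-temperature gain over
    wildtype is at least ``dtm_threshold`` (≥ 2 °C by default, inclusive).
    Candidates must carry a measured ΔTm."""
    out = []
    for c in candidates:
        if c.measured_dtm is None:
            raise ValueError(f"candidate {c.name} has no measured dTm")
        if c.measured_dtm >= dtm_threshold:
            out.append(c)
    return out


def predict_combined_dtm(plan: CombinationPlan) -> float:
    """Additive ΔTm prediction for a multi-point design: the exact sum of
    the members' measured single-mutant ΔTm values."""
    if not plan.members:
        raise ValueError("empty combination plan")
    dtm = plan.predicted_dtm
    if dtm is None:
        missing = [m.name for m in plan.members if m.measured_dtm is None]
        raise ValueError(f"members without measured dTm: {missing}")
    return dtm


def candidates_to_frame(candidates: Sequence[MutationCandidate]) -> pd.DataFrame:
    """Tidy audit table of candidates with verdict columns."""
    rows = []
    for c in candidates:
        rows.append(
            {
                "mutation": c.name,
                "position": c.position,
                "wt": c.wt,
                "mut": c.mut,
                "source": c.source,
                "ddg_pred1": c.ddg_pred1,
                "ddg_pred2": c.ddg_pred2,
                "conservation": c.conservation,
                "consensus_frequency": c.consensus_frequency,
                "passed_ddg": c.passed_ddg,
                "passed_conservation": c.passed_conservation,
                "passed_site_exclusion": c.passed_site_exclusion,
                "selected": c.selected,
                "measured_dtm": c.measured_dtm,
                "note": c.note,
            }
        )
    return pd.DataFrame(rows)
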