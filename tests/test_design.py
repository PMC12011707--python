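"""Selection-filter correctness (against brute-force oracles), consensus
calling, and combination enumeration/ranking."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from stabkit import design, synthetic
from stabkit.design import (
    CombinationPlan,
    TargetProtein,
    build_consensus_profile,
    combine_candidates,
    filter_energy_candidates,
    predict_combined_dtm,
    propose_consensus_mutations,
    select_singles_by_dtm,
)

from conftest import make_candidate


def _msa_from_strings(rows):
    from Bio.Align import MultipleSeqAlignment
    from Bio.Seq import Seq
    from Bio.SeqRecord import SeqRecord

    return MultipleSeqAlignment(
        [SeqRecord(Seq(s), id=name, description="") for name, s in rows]
    )


class TestConsensusProfile:
    def test_majority_column_called(self):
        rows = [("target", "A")] + [(f"h{i}", "D") for i in range(6)] + [
            (f"g{i}", "E") for i in range(3)
        ]
        profile = build_consensus_profile(_msa_from_strings(rows), "target")
        res, freq = profile.consensus(0)
        assert res == "D" and freq == pytest.approx(0.6)

    def test_below_cutoff_no_consensus(self):
        rows = (
            [("target", "A")]
            + [(f"h{i}", "D") for i in range(4)]
            + [(f"g{i}", "E") for i in range(3)]
            + [(f"f{i}", "K") for i in range(2)]
        )
        profile = build_consensus_profile(_msa_from_strings(rows), "target")
        res, freq = profile.consensus(0)
        assert res is None and freq == pytest.approx(0.4)

    def test_gaps_count_in_denominator(self):
        rows = [("target", "A"), ("h1", "D"), ("h2", "D"), ("h3", "-")]
        profile = build_consensus_profile(_msa_from_strings(rows), "target")
        res, freq = profile.consensus(0)
        assert res == "D" and freq == pytest.approx(0.5)

    def test_target_gap_column_unmapped(self):
        rows = [("target", "A-C"), ("h1", "ADC"), ("h2", "ADC")]
        profile = build_consensus_profile(_msa_from_strings(rows), "target")
        assert profile.column_to_position == {0: 1, 2: 2}

    def test_ragged_alignment_rejected(self):
        from Bio.Seq import Seq
        from Bio.SeqRecord import SeqRecord

        rows = [SeqRecord(Seq("AC"), id="target"), SeqRecord(Seq("A"), id="h1")]
        with pytest.raises(ValueError, match="ragged"):
            build_consensus_profile(rows, "target")

    def test_missing_target_rejected(self):
        with pytest.raises(ValueError, match="not found"):
            build_consensus_profile(_msa_from_strings([("h1", "AC")]), "target")


def _ddg_frame(entries):
    return pd.DataFrame(entries, columns=["position", "wt", "mut", "ddg_pred1", "ddg_pred2"])


class TestProposeConsensusMutations:
    def _profile_single_column(self, target_res, consensus_res, freq, n=10):
        # filler residue distinct from both so the consensus maximum is unique
        n_cons = round(freq * n)
        rows = [("target", target_res)]
        rows += [(f"h{i}", consensus_res) for i in range(n_cons)]
        rows += [(f"g{i}", "G") for i in range(n - n_cons - 1)]
        return build_consensus_profile(_msa_from_strings(rows), "target")

    def test_back_to_consensus_candidate_selected(self):
        # an N->D reversion at position 181 of a full-length-numbered construct
        profile = self._profile_single_column("N", "D", 0.7)
        target = TargetProtein(sequence="N", numbering_offset=181)
        ddg = _ddg_frame([(181, "N", "D", -0.3, -0.3)])
        cands = propose_consensus_mutations(profile, target, ddg)
        assert [c.name for c in cands] == ["N181D"]
        assert cands[0].selected and cands[0].consensus_frequency == pytest.approx(0.7)

    def test_boundary_frequency_half_accepted(self):
        profile = self._profile_single_column("N", "D", 0.5)
        target = TargetProtein(sequence="N")
        ddg = _ddg_frame([(1, "N", "D", -0.3, -0.3)])
        cands = propose_consensus_mutations(profile, target, ddg)
        assert len(cands) == 1 and cands[0].selected

    def test_boundary_ddg_half_rejected(self):
        profile = self._profile_single_column("N", "D", 0.7)
        target = TargetProtein(sequence="N")
        ddg = _ddg_frame([(1, "N", "D", 0.5, -0.3)])
        cands = propose_consensus_mutations(profile, target, ddg)
        assert len(cands) == 1 and not cands[0].passed_ddg and not cands[0].selected

    def test_binding_site_position_excluded(self):
        profile = self._profile_single_column("N", "D", 0.7)
        target = TargetProtein(sequence="N", binding_site_positions={1})
        ddg = _ddg_frame([(1, "N", "D", -0.3, -0.3)])
        cands = propose_consensus_mutations(profile, target, ddg)
        assert not cands[0].passed_site_exclusion and not cands[0].selected

    def test_missing_ddg_record_dropped_with_note(self):
        profile = self._profile_single_column("N", "D", 0.7)
        target = TargetProtein(sequence="N")
        cands = propose_consensus_mutations(profile, target, _ddg_frame([]))
        assert len(cands) == 1
        assert not cands[0].selected and "missing ddG" in cands[0].note


def _brute_force_energy(ddg, grades, sites, ddg_cutoff=-1.0, cons_cutoff=7):
    out = set()
    for r in ddg.itertuples(index=False):
        if (
            r.ddg_pred1 < ddg_cutoff
            and r.ddg_pred2 < ddg_cutoff
            and grades[int(r.position)] <= cons_cutoff
            and int(r.position) not in sites
        ):
            out.add((int(r.position), r.mut))
    return out


class TestFilterEnergyCandidates:
    def _setup(self, rng, n_positions=15):
        seq = "".join(rng.choice(list(synthetic.AMINO_ACIDS), size=n_positions))
        rows = []
        for i, wt in enumerate(seq):
            pos = i + 1
            for mut in synthetic.AMINO_ACIDS:
                if mut == wt:
                    continue
                rows.append((pos, wt, mut, rng.normal(-0.5, 1.0), rng.normal(-0.5, 1.0)))
        ddg = _ddg_frame(rows)
        grades = {i + 1: int(rng.integers(1, 10)) for i in range(n_positions)}
        sites = set(rng.choice(n_positions, size=3, replace=False) + 1)
        target = TargetProtein(sequence=seq, binding_site_positions=sites)
        return ddg, grades, sites, target

    def test_all_gates_pass(self):
        target = TargetProtein(sequence="A")
        cands = filter_energy_candidates(
            _ddg_frame([(1, "A", "V", -1.5, -1.5)]), {1: 5}, target
        )
        assert cands[0].selected

    def test_conservation_gate_fails(self):
        target = TargetProtein(sequence="A")
        cands = filter_energy_candidates(
            _ddg_frame([(1, "A", "V", -2.0, -2.0)]), {1: 8}, target
        )
        assert not cands[0].passed_conservation and not cands[0].selected

    def test_missing_conservation_grade_errors(self):
        target = TargetProtein(sequence="AC")
        with pytest.raises(KeyError):
            filter_energy_candidates(_ddg_frame([(2, "C", "V", -2.0, -2.0)]), {1: 5}, target)

    def test_matches_brute_force_oracle(self, rng):
        for _ in range(10):
            ddg, grades, sites, target = self._setup(rng)
            cands = filter_energy_candidates(ddg, grades, target)
            selected = {(c.position, c.mut) for c in cands if c.selected}
            assert selected == _brute_force_energy(ddg, grades, sites)

    def test_audit_completeness(self, rng):
        ddg, grades, _, target = self._setup(rng, n_positions=5)
        cands = filter_energy_candidates(ddg, grades, target)
        assert len(cands) == len(ddg)
        examined = {(c.position, c.mut) for c in cands}
        assert examined == {(int(r.position), r.mut) for r in ddg.itertuples(index=False)}

    def test_planted_stabilizers_recovered_exactly(self):
        """Round trip: generator-planted stabilizers are exactly the filter
        survivors when conservation and sites permit."""
        table, truth = synthetic.gen_ddg_table(
            sequence_length=10, stabilizer_positions=[4, 7], stabilizer_ddg=-1.8, seed=21
        )
        seq = truth.parameters["sequence"]
        target = TargetProtein(sequence=seq)
        grades = {p: 5 for p in range(1, 11)}
        cands = filter_energy_candidates(table, grades, target, ddg_cutoff=-1.0)
        selected = {(c.position, c.mut) for c in cands if c.selected}
        planted = {
            (int(p), m) for p, m in truth.parameters["planted_stabilizers"].items()
        }
        assert selected == planted


class TestCombineCandidates:
    def test_enumeration_count_matches_combinatorics(self):
        singles = [make_candidate(p) for p in (1, 2, 3, 4)]
        plans = combine_candidates(singles, max_order=4)
        assert len(plans) == math.comb(4, 2) + math.comb(4, 3) + math.comb(4, 4) == 11

    def test_best_quadruple_is_additive_sum(self):
        ddgs = [-2.0, -1.5, -1.2, -1.1]
        singles = [make_candidate(p + 1, ddg=d) for p, d in enumerate(ddgs)]
        plans = combine_candidates(singles, max_order=4)
        assert plans[0].predicted_ddg == pytest.approx(-5.8)
        assert len(plans[0].members) == 4

    def test_same_position_candidates_never_cooccur(self):
        singles = [
            make_candidate(1, mut="V"),
            make_candidate(1, mut="I"),
            make_candidate(2, mut="F"),
        ]
        plans = combine_candidates(singles, max_order=3)
        for p in plans:
            positions = [m.position for m in p.members]
            assert len(set(positions)) == len(positions)

    def test_enumeration_guard(self):
        singles = [make_candidate(p) for p in range(1, 30)]
        with pytest.raises(ValueError, match="max_enumeration"):
            combine_candidates(singles, max_order=6, max_enumeration=100)

    def test_ranking_is_deterministic_total_order(self):
        singles = [make_candidate(p, ddg=-1.0) for p in (3, 1, 2)]
        a = combine_candidates(singles, max_order=3)
        b = combine_candidates(list(reversed(singles)), max_order=3)
        assert [p.name for p in a] == [p.name for p in b]
        assert [p.rank for p in a] == list(range(1, len(a) + 1))


class TestDtmSelectionAndPrediction:
    def test_threshold_boundary(self):
        kept = select_singles_by_dtm(
            [make_candidate(1, dtm=2.0), make_candidate(2, dtm=1.9)]
        )
        assert [c.position for c in kept] == [1]

    def test_matches_threshold_scan(self, rng):
        dtms = rng.normal(2.0, 2.0, size=30)
        cands = [make_candidate(i + 1, dtm=float(d)) for i, d in enumerate(dtms)]
        kept = select_singles_by_dtm(cands)
        assert {c.position for c in kept} == {
            i + 1 for i, d in enumerate(dtms) if d >= 2.0
        }

    def test_missing_dtm_errors(self):
        with pytest.raises(ValueError, match="no measured dTm"):
            select_singles_by_dtm([make_candidate(1)])

    def test_additive_dtm_prediction(self):
        plan = CombinationPlan(
            members=tuple(
                make_candidate(p, dtm=d) for p, d in [(1, 5.0), (2, 5.0), (3, 5.0), (4, 4.0)]
            )
        )
        assert predict_combined_dtm(plan) == pytest.approx(19.0)

    def test_single_member_identity(self):
        plan = CombinationPlan(members=(make_candidate(1, dtm=3.3),))
        assert predict_combined_dtm(plan) == pytest.approx(3.3)

    def test_empty_plan_errors(self):
        with pytest.raises(ValueError):
            predict_combined_dtm(CombinationPlan(members=()))


@settings(max_examples=30, deadline=None, derandomize=True)
@given(
    ddgs=st.lists(
        st.tuples(
            st.integers(1, 8),
            st.floats(-3, 3, allow_nan=False),
            st.floats(-3, 3, allow_nan=False),
        ),
        min_size=1,
        max_size=40,
    ),
    cutoff=st.floats(-2, 0, allow_nan=False),
)
def test_energy_filter_equals_brute_force_property(ddgs, cutoff):
    """The vectorized verdicts equal an independent brute-force scan for any
    table and cutoff."""
    seq = "ACDEFGHK"
    rows, seen = [], set()
    muts = "VLIMFWY"
    for pos, d1, d2 in ddgs:
        mut = muts[len(seen) % len(muts)]
        if (pos, mut) in seen:
            continue
        seen.add((pos, mut))
        rows.append((pos, seq[pos - 1], mut, d1, d2))
    ddg = _ddg_frame(rows)
    grades = {p: ((p * 3) % 9) + 1 for p in range(1, 9)}
    target = TargetProtein(sequence=seq, binding_site_positions={2})
    cands = filter_energy_candidates(ddg, grades, target, ddg_cutoff=cutoff)
    selected = {(c.position, c.mut) for c in cands if c.selected}
    assert selected == _brute_force_energy(ddg, grades, {2}, ddg_cutoff=cutoff)
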