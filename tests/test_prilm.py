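"""Q/N composition quantitation and the sliding-window motif scanner."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from kogbody import simulate as sim
from kogbody.prilm import (
    MotifInterval,
    ProteinSequence,
    composition_table,
    interval_length_from_report,
    mutate_interval_to_alanine,
    qn_composition,
    scan_qn_windows,
)


class TestQNComposition:
    def test_all_glutamine(self):
        c = qn_composition(ProteinSequence("s", "QQQQQ"), MotifInterval("s", 0, 5))
        assert (c.qn_count, c.qn_percent) == (5, 100.0)

    def test_no_qn(self):
        c = qn_composition(ProteinSequence("s", "ACDEF"), MotifInterval("s", 0, 5))
        assert (c.qn_count, c.qn_percent) == (0, 0.0)

    def test_x_counts_toward_length_not_qn(self):
        c = qn_composition(ProteinSequence("s", "QXNX"), MotifInterval("s", 0, 4))
        assert c.qn_count == 2
        assert c.qn_percent == pytest.approx(50.0)

    def test_out_of_range_interval(self):
        with pytest.raises(IndexError):
            qn_composition(ProteinSequence("s", "QQQ"), MotifInterval("s", 0, 9))

    @given(st.text(alphabet="QNACDEFG", min_size=5, max_size=40), st.integers(0, 10**6))
    @settings(max_examples=60, deadline=None)
    def test_permutation_invariance(self, residues, seed):
        rng = np.random.default_rng(seed)
        shuffled = "".join(rng.permutation(list(residues)))
        iv = MotifInterval("s", 0, len(residues))
        a = qn_composition(ProteinSequence("s", residues), iv)
        b = qn_composition(ProteinSequence("s", shuffled), iv)
        assert (a.qn_count, a.length) == (b.qn_count, b.length)

    def test_reported_pair_28_of_35_90_percent_forces_length_78(self):
        # brute-force: the (count, rounded-percent) pair determines the length
        lengths = interval_length_from_report(28, 35.90, max_length=500)
        assert lengths == [78]
        c = qn_composition(
            ProteinSequence("kog1", "Q" * 28 + "A" * 50), MotifInterval("kog1", 0, 78)
        )
        assert round(c.qn_percent, 2) == 35.90


class TestScanQNWindows:
    def test_all_q_sequence_single_full_interval(self):
        seq = ProteinSequence("s", "Q" * 60)
        out = scan_qn_windows(seq, window_length=20, qn_threshold=1.0)
        assert len(out) == 1
        assert (out[0].start, out[0].end) == (0, 60)

    def test_no_qn_returns_empty(self):
        assert scan_qn_windows(ProteinSequence("s", "ACDEFGH" * 10), 20, 0.4) == []

    def test_window_longer_than_sequence_returns_empty(self):
        assert scan_qn_windows(ProteinSequence("s", "QQQ"), 20, 0.4) == []

    def test_intervals_disjoint_sorted_and_qn_terminated(self):
        seq = ProteinSequence("s", "A" * 30 + "QNQNQNQNQNQN" + "A" * 40 + "NQQN" * 6 + "A" * 30)
        out = scan_qn_windows(seq, window_length=10, qn_threshold=0.5, merge_gap=5)
        assert out == sorted(out, key=lambda iv: iv.start)
        for iv1, iv2 in zip(out, out[1:]):
            assert iv1.end <= iv2.start
        for iv in out:
            assert seq.residues[iv.start] in "QN"
            assert seq.residues[iv.end - 1] in "QN"

    @pytest.mark.parametrize("seed", range(25))
    def test_planted_motif_recovery(self, seed):
        spec = sim.SequenceSimSpec(
            length=300, motif_insertions=((120, 40, 0.6),), seed=seed
        )
        planted = sim.simulate_sequence(spec)
        out = scan_qn_windows(planted.sequence, window_length=20, qn_threshold=0.4)
        assert len(out) == 1
        truth = planted.motifs[0]
        inter = max(0, min(out[0].end, truth.end) - max(out[0].start, truth.start))
        union = max(out[0].end, truth.end) - min(out[0].start, truth.start)
        assert inter / union >= 0.8

    @pytest.mark.parametrize("seed", range(10))
    def test_mutated_motif_no_longer_detected(self, seed):
        spec = sim.SequenceSimSpec(
            length=300, motif_insertions=((120, 40, 0.6),), seed=seed
        )
        planted = sim.simulate_sequence(spec)
        mutated = mutate_interval_to_alanine(planted.sequence, planted.motifs[0])
        assert scan_qn_windows(mutated, window_length=20, qn_threshold=0.4) == []


class TestMutateToAlanine:
    def test_q_stretch_to_alanine(self):
        out = mutate_interval_to_alanine(
            ProteinSequence("s", "AQQA"), MotifInterval("s", 1, 3)
        )
        assert out.residues == "AAAA"

    def test_interval_without_targets_unchanged(self):
        seq = ProteinSequence("s", "ACDEF")
        assert mutate_interval_to_alanine(seq, MotifInterval("s", 0, 5)).residues == "ACDEF"

    def test_only_requested_residue_types_replaced(self):
        out = mutate_interval_to_alanine(
            ProteinSequence("s", "QNQN"), MotifInterval("s", 0, 4), frozenset("Q")
        )
        assert out.residues == "ANAN"

    def test_drives_interval_qn_percent_to_zero(self):
        seq = ProteinSequence("s", "QNQNQNQN")
        iv = MotifInterval("s", 0, 8)
        mutated = mutate_interval_to_alanine(seq, iv)
        assert qn_composition(mutated, iv).qn_percent == 0.0


class TestCompositionTable:
    def test_empty_manifest(self):
        assert composition_table([ProteinSequence("a", "QQ")], []).empty

    def test_two_intervals_two_rows(self):
        seqs = [ProteinSequence("a", "QQQAAANNN")]
        ivs = [MotifInterval("a", 0, 3, "m1"), MotifInterval("a", 6, 9, "m2")]
        table = composition_table(seqs, ivs)
        assert len(table) == 2
        assert table.qn_count.tolist() == [3, 3]
        assert table.qn_percent.tolist() == [100.0, 100.0]

    def test_dangling_reference_lists_offenders(self):
        with pytest.raises(KeyError, match="ghost"):
            composition_table(
                [ProteinSequence("a", "QQ")], [MotifInterval("ghost", 0, 2)]
            )

    def test_synthetic_panel_matches_planted_composition(self):
        seqs, intervals, expected = [], [], []
        for i, qn_fraction in enumerate(np.linspace(0.1, 1.0, 17)):
            spec = sim.SequenceSimSpec(
                length=120, motif_insertions=((40, 34, float(qn_fraction)),), seed=i
            )
            planted = sim.simulate_sequence(spec, seq_id=f"seq{i}")
            seqs.append(planted.sequence)
            intervals.append(planted.motifs[0])
            expected.append(round(qn_fraction * 34))
        table = composition_table(seqs, intervals)
        assert table.qn_count.tolist() == expected
        assert table.qn_percent.tolist() == [round(100 * e / 34, 2) for e in expected]

    def test_annotations_passed_through(self):
        ann = pd.DataFrame({"tsc1": ["+"]}, index=pd.Index(["a"], name="seq_id"))
        table = composition_table(
            [ProteinSequence("a", "QQ")], [MotifInterval("a", 0, 2)], annotations=ann
        )
        assert table.tsc1.tolist() == ["+"]
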