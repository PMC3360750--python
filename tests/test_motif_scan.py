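"""Unit tests for FASTA input, EF-hand and IQ scanning, length filtering."""

import logging

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from efscan.motif_scan import (
    InputError,
    PatternConfig,
    ProteinRecord,
    filter_by_length,
    read_fasta,
    scan_ef_hands,
    scan_iq_motifs,
    write_fasta,
)
from conftest import CANONICAL_LOOP, brute_force_ef_windows, brute_force_iq_starts

EMBEDDED = "AAELAAAFKEA" + CANONICAL_LOOP + "FAAELRHAM"


class TestReadFasta:
    def test_parses_records_in_order(self, make_fasta):
        path = make_fasta(">p1\nDKDGDGTITTKE\n>p2 some desc\nACDEF\nGHIKL\n")
        recs = read_fasta(path)
        assert [(r.id, r.sequence) for r in recs] == [
            ("p1", "DKDGDGTITTKE"),
            ("p2", "ACDEFGHIKL"),
        ]
        assert recs[1].description == "some desc"

    def test_uppercases_sequences(self, make_fasta):
        recs = read_fasta(make_fasta(">p1 desc\nacdef\n"))
        assert recs[0].sequence == "ACDEF"

    def test_rejects_bad_alphabet_with_warning(self, make_fasta, caplog):
        path = make_fasta(">p1\nDKD1GD\n>p2\nACDEF\n")
        with caplog.at_level(logging.WARNING, logger="efscan.motif_scan"):
            recs = read_fasta(path)
        assert [r.id for r in recs] == ["p2"]
        assert any("p1" in rec.message for rec in caplog.records)

    def test_all_records_invalid_is_empty_input(self, make_fasta):
        with pytest.raises(InputError):
            read_fasta(make_fasta(">p1\nDKD1GD\n"))

    def test_missing_file(self, tmp_path):
        with pytest.raises(InputError):
            read_fasta(tmp_path / "nope.fa")

    def test_duplicate_ids_rejected(self, make_fasta):
        with pytest.raises(InputError):
            read_fasta(make_fasta(">p1\nACDEF\n>p1\nGHIKL\n"))

    def test_roundtrip_with_write_fasta(self, tmp_path):
        recs = [ProteinRecord(id="a", sequence="ACDEF" * 30, description="x")]
        p = tmp_path / "out.fa"
        write_fasta(recs, p)
        assert [r.sequence for r in read_fasta(p)] == [recs[0].sequence]


class TestProteinRecord:
    @pytest.mark.parametrize("seq", ["", "ACB!", "acdf"])
    def test_invalid_sequences_rejected(self, seq):
        with pytest.raises(ValueError):
            ProteinRecord(id="p", sequence=seq)


class TestScanEFHands:
    def test_embedded_canonical_loop_single_hit(self):
        rec = ProteinRecord(id="p", sequence=EMBEDDED)
        hits = scan_ef_hands(rec)
        assert len(hits) == 1
        (h,) = hits
        assert h.loop_seq == CANONICAL_LOOP
        assert h.loop_start == 11 and h.motif_start == 2
        assert h.loop_start == h.motif_start + 9
        assert all(h.constraint_flags[k] for k in ("req1", "req12"))
        assert h.score == 4  # D at 3, D at 5, G at 6, T at 9

    def test_poly_alanine_has_no_hits(self):
        assert scan_ef_hands(ProteinRecord(id="p", sequence="A" * 40)) == []

    def test_sequence_shorter_than_motif_has_no_admissible_window(self):
        # 28 residues cannot host a full 29-residue motif window
        assert scan_ef_hands(ProteinRecord(id="p", sequence=CANONICAL_LOOP + "A" * 16)) == []

    def test_full_motif_window_requirement_can_be_relaxed(self):
        rec = ProteinRecord(id="p", sequence=CANONICAL_LOOP)
        assert scan_ef_hands(rec) == []
        relaxed = PatternConfig(require_full_motif_window=False)
        hits = scan_ef_hands(rec, relaxed)
        assert [h.loop_start for h in hits] == [0]

    def test_x_fails_checked_position(self):
        loop = "X" + CANONICAL_LOOP[1:]
        rec = ProteinRecord(id="p", sequence="A" * 9 + loop + "A" * 8)
        assert scan_ef_hands(rec) == []

    def test_greedy_overlap_resolution_drops_overlapping_loop(self):
        # passing windows at loop starts 9 and 20 overlap by one residue:
        # greedy left-to-right keeps only the left one
        seq = "A" * 9 + "DKDGDGTITTK" + CANONICAL_LOOP + "A" * 9
        rec = ProteinRecord(id="p", sequence=seq)
        raw = [h.loop_start for h in scan_ef_hands(rec, all_candidates=True)]
        resolved = [h.loop_start for h in scan_ef_hands(rec)]
        assert 9 in raw and 20 in raw
        assert resolved == [9]
        for a, b in zip(resolved, resolved[1:]):
            assert b - a >= 12

    def test_hit_invariants_recheckable_from_sequence(self):
        rec = ProteinRecord(id="p", sequence=EMBEDDED * 3)
        for h in scan_ef_hands(rec):
            assert len(h.loop_seq) == 12
            assert rec.sequence[h.loop_start : h.loop_start + 12] == h.loop_seq
            assert h.loop_start == h.motif_start + 9
            assert h.score >= PatternConfig().min_scored_matches

    def test_determinism(self):
        rec = ProteinRecord(id="p", sequence=EMBEDDED * 2)
        assert scan_ef_hands(rec) == scan_ef_hands(rec)

    def test_monotonic_in_min_scored_matches(self):
        rng = np.random.default_rng(11)
        residues = list("ACDEFGHIKLMNPQRSTVWY")
        for _ in range(30):
            seq = "".join(rng.choice(residues, size=120))
            rec = ProteinRecord(id="p", sequence=seq)
            prev = None
            for m in range(0, 5):
                starts = {
                    h.loop_start
                    for h in scan_ef_hands(
                        rec, PatternConfig(min_scored_matches=m), all_candidates=True
                    )
                }
                if prev is not None:
                    assert starts <= prev
                prev = starts

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(st.text(alphabet="ACDEFGHIKLMNPQRSTVWY", min_size=20, max_size=150))
    def test_raw_candidates_match_brute_force(self, seq):
        rec = ProteinRecord(id="p", sequence=seq)
        got = [h.loop_start for h in scan_ef_hands(rec, all_candidates=True)]
        assert got == brute_force_ef_windows(seq)


class TestScanIQ:
    def test_iq1_peptide_single_match(self):
        hits = scan_iq_motifs(ProteinRecord(id="iq", sequence="AILLQTNIRALWKREYYRAA"))
        assert len(hits) == 1
        assert hits[0].start == 3
        assert hits[0].matched_seq == "LQTNIRALWKR"

    def test_minimal_consensus_instance(self):
        hits = scan_iq_motifs(ProteinRecord(id="p", sequence="IQAAARAAAAK"))
        assert [(h.start, h.matched_seq) for h in hits] == [(0, "IQAAARAAAAK")]

    def test_position1_violation(self):
        assert scan_iq_motifs(ProteinRecord(id="p", sequence="AQAAARAAAAK")) == []

    def test_overlapping_matches_all_reported(self):
        seq = "IQIQARARAARRK"  # windows at 0 and 2 both satisfy the consensus
        starts = [h.start for h in scan_iq_motifs(ProteinRecord(id="p", sequence=seq))]
        assert starts == brute_force_iq_starts(seq)
        assert len(starts) >= 2

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(st.text(alphabet="ACDEFGHIKLMNPQRSTVWYX", min_size=11, max_size=120))
    def test_matches_regex_oracle(self, seq):
        got = [h.start for h in scan_iq_motifs(ProteinRecord(id="p", sequence=seq))]
        assert got == brute_force_iq_starts(seq)


class TestFilterByLength:
    def test_boundaries_retained(self):
        recs = [
            ProteinRecord(id=f"p{n}", sequence="A" * n) for n in (99, 100, 150, 2200, 2201)
        ]
        retained, excluded = filter_by_length(recs)
        assert [len(r) for r in retained] == [100, 150, 2200]
        assert [len(r) for r in excluded] == [99, 2201]

    def test_empty_input(self):
        assert filter_by_length([]) == ([], [])

    def test_all_too_short(self):
        recs = [ProteinRecord(id=f"p{i}", sequence="A" * 50) for i in range(3)]
        retained, excluded = filter_by_length(recs)
        assert retained == [] and excluded == recs

    def test_bad_bounds(self):
        with pytest.raises(ValueError):
            filter_by_length([], min_len=10, max_len=5)
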