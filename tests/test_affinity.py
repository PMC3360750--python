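"""Unit tests for consensus profiling and affinity-tier classification."""

import math

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from efscan import affinity as aff
from efscan.motif_scan import EFHandHit
from conftest import CANONICAL_LOOP


def refs_of(*loops):
    return aff.ReferenceLoopSet(
        loops=tuple(loops), source_labels=tuple(f"l{i}" for i in range(len(loops)))
    )


class TestReferenceLoopSet:
    def test_requires_at_least_two_loops(self):
        with pytest.raises(ValueError):
            refs_of(CANONICAL_LOOP)

    def test_rejects_wrong_length_loop_by_name(self):
        with pytest.raises(ValueError, match="DKDGDGTITTK"):
            refs_of(CANONICAL_LOOP, "DKDGDGTITTK")

    def test_load_tsv_and_fasta(self, tmp_path):
        tsv = tmp_path / "refs.tsv"
        tsv.write_text("label\tloop\na\tDKDGDGTITTKE\nb\tDADGNGTIDFPE\n")
        fa = tmp_path / "refs.fa"
        fa.write_text(">a\nDKDGDGTITTKE\n>b\nDADGNGTIDFPE\n")
        assert aff.load_reference_loops(tsv).loops == aff.load_reference_loops(fa).loops

    def test_packaged_default_set(self):
        refs = aff.default_reference_loops()
        assert len(refs.loops) == 40
        assert all(len(l) == 12 for l in refs.loops)


class TestBuildConsensus:
    def test_identical_inputs(self):
        prof = aff.build_consensus(refs_of(CANONICAL_LOOP, CANONICAL_LOOP))
        assert prof.consensus == CANONICAL_LOOP
        for col in prof.frequencies:
            assert col == {c: 1.0 for c in col}

    def test_tie_broken_by_fixed_residue_order(self):
        prof = aff.build_consensus(refs_of("DKDGDGTITTKE", "DKDGDGYISAAE"))
        assert prof.frequencies[0] == {"D": 1.0}
        assert prof.frequencies[6] == {"T": 0.5, "Y": 0.5}
        assert prof.consensus[6] == "T"  # T precedes Y in the tie order

    def test_columns_sum_to_one(self, default_profile):
        for col in default_profile.frequencies:
            assert math.isclose(sum(col.values()), 1.0, abs_tol=1e-9)

    def test_consensus_is_columnwise_majority(self, default_profile):
        for k, col in enumerate(default_profile.frequencies):
            assert col[default_profile.consensus[k]] == max(col.values())

    def test_bad_critical_positions(self, default_refs):
        with pytest.raises(ValueError):
            aff.build_consensus(default_refs, critical_positions={0, 13})


class TestCriticalIdentity:
    def test_consensus_itself_scores_one(self, canonical_profile):
        frac, matched = aff.critical_identity(canonical_profile.consensus, canonical_profile)
        assert frac == 1.0
        assert matched == frozenset({1, 3, 5, 7, 9})

    def test_three_mutations(self, canonical_profile):
        frac, matched = aff.critical_identity("AKAGAGTITTKE", canonical_profile)
        assert frac == pytest.approx(0.4)
        assert matched == frozenset({7, 9})

    def test_single_mutation(self, canonical_profile):
        frac, matched = aff.critical_identity("DKAGDGTITTKE", canonical_profile)
        assert frac == pytest.approx(0.8)
        assert matched == frozenset({1, 5, 7, 9})

    def test_wrong_length_rejected(self, canonical_profile):
        with pytest.raises(ValueError):
            aff.critical_identity("DKDG", canonical_profile)


class TestClassifyAffinity:
    @pytest.mark.parametrize(
        "fraction,tier,ka",
        [
            (1.0, "strong", "1e4-1e7"),
            (0.8, "medium", "<1e4"),
            (0.6, "medium", "<1e4"),
            (0.4, "low", "<1e2"),
            (0.2, "low", "<1e2"),
            (0.0, "low", "<1e2"),
        ],
    )
    def test_tier_table(self, fraction, tier, ka):
        call = aff.classify_affinity(fraction)
        assert (call.tier, call.ka_range) == (tier, ka)

    def test_out_of_range_rejected(self):
        for bad in (-0.1, 1.1):
            with pytest.raises(ValueError):
                aff.classify_affinity(bad)

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(st.floats(min_value=0.0, max_value=1.0, allow_nan=False))
    def test_total_single_tier_partition(self, fraction):
        call = aff.classify_affinity(fraction)
        assert call.tier in ("strong", "medium", "low")
        assert (call.tier == "strong") == (fraction == 1.0)
        assert (call.tier == "low") == (fraction < 0.5)

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(
        st.floats(min_value=0.0, max_value=1.0, allow_nan=False),
        st.floats(min_value=0.0, max_value=1.0, allow_nan=False),
    )
    def test_tier_rank_monotone_in_identity(self, f1, f2):
        if f1 > f2:
            f1, f2 = f2, f1
        assert aff.tier_rank(aff.classify_affinity(f1).tier) <= aff.tier_rank(
            aff.classify_affinity(f2).tier
        )


class TestRecovery:
    @pytest.mark.parametrize(
        "k,expected_tier", [(0, "strong"), (1, "medium"), (2, "medium"),
                            (3, "low"), (4, "low"), (5, "low")]
    )
    def test_k_mutations_at_critical_positions(self, canonical_profile, k, expected_tier):
        """Mutating exactly k critical positions yields fraction (5-k)/5 and
        the corresponding tier, for every choice of positions."""
        import itertools

        consensus = canonical_profile.consensus
        for positions in itertools.combinations(sorted({1, 3, 5, 7, 9}), k):
            loop = list(consensus)
            for p in positions:
                loop[p - 1] = "W" if consensus[p - 1] != "W" else "C"
            frac, _ = aff.critical_identity("".join(loop), canonical_profile)
            assert frac == pytest.approx((5 - k) / 5)
            assert aff.classify_affinity(frac).tier == expected_tier


class TestAffinityOfProtein:
    def _hit(self, loop, start=9):
        return EFHandHit(
            protein_id="p", motif_start=start - 9, loop_start=start,
            loop_seq=loop, constraint_flags={}, score=4,
        )

    def test_empty(self, canonical_profile):
        assert aff.affinity_of_protein([], canonical_profile) == []

    def test_consensus_loop_is_strong(self, canonical_profile):
        calls = aff.affinity_of_protein(
            [self._hit(canonical_profile.consensus)], canonical_profile
        )
        assert [c.tier for c in calls] == ["strong"]

    def test_order_preserved(self, canonical_profile):
        hits = [self._hit(canonical_profile.consensus), self._hit("AKAGAGTITTKE", 30)]
        calls = aff.affinity_of_protein(hits, canonical_profile)
        assert [c.tier for c in calls] == ["strong", "low"]
        assert [c.identity_fraction for c in calls] == [1.0, pytest.approx(0.4)]
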