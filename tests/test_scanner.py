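"""Core-motif anchoring, PSSM construction and anchor scoring."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from _util import brute_force_core_scan, random_sequence
from ureidoscan.records import STANDARD_AA, ProteinRecord
from ureidoscan.scanner import (
    DomainHit,
    build_profile,
    extract_cdomain,
    find_core_motifs,
    scan_protein,
    score_anchor,
)


class TestFindCoreMotifs:
    def test_snaa_like_window(self):
        rec = ProteinRecord("a", "MKTEHHLVHDGSAA")
        matches = find_core_motifs(rec)
        assert [(m.start, m.relaxed) for m in matches] == [(3, False)]
        assert rec.sequence[3:11] == "EHHLVHDG"

    def test_no_fixed_positions_satisfied(self):
        assert find_core_motifs(ProteinRecord("a", "AAAAAAAAAA")) == []

    def test_short_sequence_yields_empty_list(self):
        assert find_core_motifs(ProteinRecord("a", "MKTEHH")) == []

    def test_x_never_satisfies_a_fixed_position(self):
        # XHHXXX-X-G window: D replaced by X leaves only 3 of 4 positions
        rec = ProteinRecord("a", "AHHAAAXG")
        assert find_core_motifs(rec) == []
        assert [(m.start, m.relaxed) for m in find_core_motifs(rec, relaxed=True)] == [
            (0, True)
        ]

    def test_relaxed_flags_three_of_four_windows(self):
        rec = ProteinRecord("a", "AHHAAADGAAA")  # strict at 0
        strict = find_core_motifs(rec)
        assert [(m.start, m.relaxed) for m in strict] == [(0, False)]

    @settings(max_examples=100, derandomize=True)
    @given(seq=st.text(alphabet=STANDARD_AA + "X", min_size=0, max_size=120))
    def test_scan_equals_brute_force_oracle(self, seq):
        for relaxed in (False, True):
            got = [(m.start, m.relaxed) for m in find_core_motifs(seq, relaxed=relaxed)]
            assert got == brute_force_core_scan(seq, relaxed=relaxed)

    def test_long_fixed_seed_sequence_matches_oracle(self):
        seq = random_sequence(np.random.default_rng(42), 2000)
        got = [(m.start, m.relaxed) for m in find_core_motifs(seq)]
        assert got == brute_force_core_scan(seq)
        assert got == sorted(got)


class TestBuildProfile:
    def test_single_sequence_pseudocount_frequency(self):
        prof = build_profile(["EH"], pseudocount=0.5, window_offsets=(0, 2))
        e_idx = STANDARD_AA.index("E")
        assert prof.frequencies[0, e_idx] == pytest.approx(1.5 / 11.0)

    def test_uniform_column_has_near_zero_logodds(self):
        rows = [aa * 2 for aa in STANDARD_AA]  # 20 rows, each a distinct residue
        prof = build_profile(rows, pseudocount=1e-9, window_offsets=(0, 2))
        assert np.allclose(prof.logodds, 0.0, atol=1e-6)

    def test_columns_sum_to_one(self):
        rng = np.random.default_rng(7)
        rows = [random_sequence(rng, 15) for _ in range(8)]
        prof = build_profile(rows, window_offsets=(5, 10))
        assert np.allclose(prof.frequencies.sum(axis=1), 1.0, atol=1e-9)

    def test_ragged_alignment_rejected(self):
        with pytest.raises(ValueError, match="ragged"):
            build_profile(["EH", "EHH"], window_offsets=(0, 2))

    def test_all_gap_column_falls_back_to_background(self, caplog):
        import logging

        with caplog.at_level(logging.WARNING):
            prof = build_profile(["E-", "E-"], window_offsets=(0, 2))
        assert np.allclose(prof.frequencies[1], 1.0 / 20.0)
        assert "background" in caplog.text


class TestScoreAnchor:
    def test_hand_summed_toy_profile(self):
        prof = build_profile(["EHH", "EHH"], pseudocount=0.5, window_offsets=(0, 3))
        # freq of the consensus residue per column: (2 + 0.5) / (2 + 10)
        per_col = math.log2((2.5 / 12.0) * 20.0)
        got = score_anchor(prof, ProteinRecord("a", "EHHAAADG"), 0)
        assert got == pytest.approx(3 * per_col)

    def test_true_anchor_maximal_on_training_sequence(self):
        rng = np.random.default_rng(5)
        seq = random_sequence(rng, 60)
        window = (20, 40)
        prof = build_profile([seq[:60]] * 10, window_offsets=window)
        scores = {
            start: score_anchor(prof, seq, start) for start in range(0, 52)
        }
        assert max(scores, key=scores.get) == window[0]

    def test_zero_expected_score_on_balanced_profile(self):
        # each training column holds every residue exactly once, so the
        # pseudocounted frequencies equal the uniform background exactly
        rng = np.random.default_rng(11)
        cols = [rng.permutation(list(STANDARD_AA)) for _ in range(10)]
        rows = ["".join(col[r] for col in cols) for r in range(20)]
        prof = build_profile(rows, window_offsets=(0, 10))
        draws = [
            score_anchor(prof, random_sequence(rng, 10), 0) for _ in range(1000)
        ]
        assert abs(float(np.mean(draws))) < 1e-9

    def test_x_contributes_zero(self):
        prof = build_profile(["EHH"] * 4, window_offsets=(0, 3))
        full = score_anchor(prof, ProteinRecord("a", "EHHAAAAG"), 0)
        masked = score_anchor(prof, ProteinRecord("a", "EXHAAAAG"), 0)
        h_idx = STANDARD_AA.index("H")
        assert full - masked == pytest.approx(float(prof.logodds[1, h_idx]))

    def test_out_of_range_anchor_rejected(self):
        prof = build_profile(["EHH"], window_offsets=(0, 3))
        with pytest.raises(ValueError, match="out of range"):
            score_anchor(prof, ProteinRecord("a", "EHHAAADG"), 5)

    def test_invariant_under_appending_outside_window(self):
        rng = np.random.default_rng(3)
        rows = [random_sequence(rng, 40) for _ in range(6)]
        prof = build_profile(rows)  # default offsets (30, 10)
        seq = random_sequence(rng, 80)
        base = score_anchor(prof, seq, 40)
        extended = score_anchor(prof, seq + random_sequence(rng, 30), 40)
        assert base == pytest.approx(extended)


class TestExtractCdomain:
    def test_clipping_to_short_protein(self):
        rec = ProteinRecord("a", "MKTEHHLVHDGSAA")
        hit = extract_cdomain(rec, 3)
        assert (hit.domain_start, hit.domain_end) == (0, 14)
        assert hit.octamer == "EHHLVHDG"

    def test_interior_window_arithmetic(self):
        seq = random_sequence(np.random.default_rng(1), 2000)
        hit = extract_cdomain(ProteinRecord("a", seq), 500)
        assert (hit.domain_start, hit.domain_end) == (350, 800)

    def test_octamer_always_equals_sequence_slice(self):
        rng = np.random.default_rng(9)
        seq = random_sequence(rng, 300)
        rec = ProteinRecord("a", seq)
        for start in (0, 10, 142, 292):
            hit = extract_cdomain(rec, start)
            assert hit.octamer == seq[start : start + 8]

    def test_inconsistent_hit_rejected(self):
        with pytest.raises(ValueError):
            DomainHit("a", 10, 20, 5, "EHHLVHDG")


class TestScanProtein:
    def test_ties_broken_by_leftmost_anchor(self):
        # two identical strict windows, no profile: scores tie at 0
        seq = "AHHAAADG" + "KKKK" + "AHHAAADG"
        hits = scan_protein(ProteinRecord("a", seq))
        assert [h.motif_start for h in hits] == [0, 12]

    def test_min_score_filters_with_profile(self):
        rng = np.random.default_rng(2)
        seq = "AHHAAADG" + random_sequence(rng, 40)
        prof = build_profile(["AHHAAADG"] * 5, window_offsets=(0, 8))
        kept = scan_protein(ProteinRecord("a", seq), profile=prof, min_score=1.0)
        assert all(h.score >= 1.0 for h in kept)
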