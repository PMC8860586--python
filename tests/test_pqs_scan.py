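"""Scanner unit, example and property tests.

The brute-force oracle in ``_oracle.py`` re-derives island and chain
existence from the definitions; scanner results must agree with it
exactly on every sequence tested.
"""

import numpy as np
import pytest

from g4repeats import (
    ScanParams,
    classify_sequence,
    count_tandem_units,
    find_g_islands,
    find_repeats,
    gc_content,
    has_repeat,
    reverse_complement,
)
from g4repeats.synthetic_data import _plant_repeat

from _oracle import naive_has_chain, naive_islands, naive_max_units


# ---------------------------------------------------------------------------
# islands
# ---------------------------------------------------------------------------


class TestIslands:
    def test_perfect_subruns_of_a_4g_run(self, double_params):
        islands = find_g_islands("GGGG", double_params)
        coords = {(g.start, g.end, g.n_g) for g in islands}
        assert coords == {(0, 3, 3), (1, 4, 3), (0, 4, 4)}
        assert all(g.is_perfect for g in islands)

    def test_single_1nt_bulge_is_an_island(self, double_params):
        islands = find_g_islands("GGAGG", double_params)
        bulged = [g for g in islands if not g.is_perfect]
        assert (0, 5, 4, 2) in {(g.start, g.end, g.n_g, g.gap_pos) for g in bulged}

    def test_2nt_gap_is_not_a_bulge(self, double_params):
        assert find_g_islands("GGAAGG", double_params) == []

    def test_telomeric_islands_match_exhaustive_enumeration(self, double_params):
        seq = "TTAGGG" * 4
        got = {(g.start, g.end, g.n_g, g.is_perfect) for g in find_g_islands(seq, double_params)}
        expected = {(s, e, ng, perf) for s, e, ng, perf in naive_islands(seq, 3, 4)}
        assert got == expected
        assert len(got) == 4  # one perfect 3-G island per GGG run

    def test_n_is_neither_guanine_nor_bulge_gap(self, double_params):
        assert find_g_islands("GGNGG", double_params) == []
        assert find_g_islands("GGGNGGG", double_params) == [
            g for g in find_g_islands("GGGNGGG", double_params)
        ]
        assert {(g.start, g.end) for g in find_g_islands("GGGNGGG", double_params)} == {
            (0, 3),
            (4, 7),
        }

    def test_invalid_character_names_position(self, double_params):
        with pytest.raises(ValueError, match="position 3"):
            find_g_islands("GGGXGG", double_params)

    def test_empty_sequence_gives_empty_lattice(self, double_params):
        assert find_g_islands("", double_params) == []

    @pytest.mark.parametrize("seed", range(5))
    def test_island_lattice_equals_oracle_on_random_sequences(self, seed, double_params):
        rng = np.random.default_rng(seed)
        seq = "".join(rng.choice(list("GCAT"), size=50, p=[0.5, 0.2, 0.15, 0.15]))
        got = {(g.start, g.end, g.n_g, g.is_perfect) for g in find_g_islands(seq, double_params)}
        assert got == set(naive_islands(seq, 3, 4))


# ---------------------------------------------------------------------------
# repeats: examples from the studied oligonucleotides
# ---------------------------------------------------------------------------


class TestRepeats:
    def test_2tel_double_repeat_all_loops_3nt(self, table1, double_params):
        matches = find_repeats(table1["2TEL"], double_params)
        assert matches
        best = max(matches, key=lambda m: m.n_perfect)
        assert best.n_perfect == 8
        # a fully perfect chain with all loops 3 nt exists among all matches
        all_m = find_repeats(table1["2TEL"], ScanParams.double(strands="forward"), mode="all")
        assert any(m.n_perfect == 8 and set(m.loops) == {3} for m in all_m)

    def test_2tel6_central_6nt_linker_blocks_double(self, table1, double_params):
        assert find_repeats(table1["2TEL(6)"], double_params) == []
        assert not naive_has_chain(table1["2TEL(6)"], 8, 5)

    def test_2tel9_central_9nt_linker_blocks_double(self, table1, double_params):
        assert find_repeats(table1["2TEL(9)"], double_params) == []

    def test_ilpr_has_fully_perfect_4g_double_chain(self, table1):
        all_m = find_repeats(table1["ILPR"], ScanParams.double(strands="forward"), mode="all")
        assert any(
            m.n_perfect == 8
            and all(g.n_g == 4 for g in m.islands)
            and set(m.loops) == {3}
            for m in all_m
        )

    def test_htert_triple_repeat_exists(self, table1, triple_params):
        matches = find_repeats(table1["hTERT"], triple_params)
        assert matches
        assert max(m.n_perfect for m in matches) >= 8
        assert naive_has_chain(table1["hTERT"], 12, 8)

    def test_grich_nog4_has_no_double_or_triple(self, table1, double_params, triple_params):
        seq = table1["G-rich noG4"]
        assert not has_repeat(seq, double_params)
        assert not has_repeat(seq, triple_params)
        assert not naive_has_chain(seq, 8, 5)
        assert not naive_has_chain(seq, 12, 8)

    def test_sequence_shorter_than_pattern_yields_empty(self, double_params):
        assert find_repeats("GGG", double_params) == []

    def test_kit2kit_needs_zero_length_loops_to_chain(self, table1):
        """The printed 44-mer chains 8 islands only if 0-nt loops are allowed."""
        seq = table1["KIT2KIT*"]
        assert not has_repeat(seq, ScanParams.double(min_loop_len=1))
        assert has_repeat(seq, ScanParams.double(min_loop_len=0))
        assert not naive_has_chain(seq, 8, 5, min_loop=1)
        assert naive_has_chain(seq, 8, 5, min_loop=0)


# ---------------------------------------------------------------------------
# tandem-unit counting
# ---------------------------------------------------------------------------


class TestTandemUnits:
    @pytest.mark.parametrize("k", range(1, 7))
    def test_telomere_ladder(self, k):
        seq = "TTAGGG" * (4 * k)
        params = ScanParams.single()
        assert count_tandem_units(seq, params) == k
        report = classify_sequence(seq)
        assert report.has_double == (k >= 2)
        assert report.has_triple == (k >= 3)

    def test_no_g4_gives_zero(self):
        assert count_tandem_units("ATATATAT", ScanParams.single()) == 0


# ---------------------------------------------------------------------------
# classification
# ---------------------------------------------------------------------------


class TestClassification:
    def test_tel_is_single_not_double(self, table1):
        r = classify_sequence(table1["TEL"], seq_id="TEL")
        assert r.has_single and not r.has_double

    def test_3tel_is_triple(self, table1):
        assert classify_sequence(table1["3TEL"]).has_triple

    def test_reverse_complement_detected_via_reverse_strand(self, table1):
        r = classify_sequence(reverse_complement(table1["2TEL"]))
        assert r.has_double
        assert r.strands["double"] == "-"

    def test_flag_hierarchy_is_cumulative(self, table1):
        r = classify_sequence(table1["4TEL"])
        assert r.has_triple and r.has_double and r.has_single

    def test_all_n_sequence_is_all_negative(self):
        r = classify_sequence("N" * 100, seq_id="allN")
        assert not (r.has_single or r.has_double or r.has_triple)
        assert r.max_tandem_units == 0


# ---------------------------------------------------------------------------
# properties
# ---------------------------------------------------------------------------


def _random_gc_rich(rng, n):
    return "".join(rng.choice(list("GCAT"), size=n, p=[0.55, 0.2, 0.15, 0.1]))


class TestProperties:
    def test_scanner_matches_oracle_on_random_and_planted(self, rng, double_params, triple_params):
        """Existence flags equal brute-force enumeration on 200 mixed sequences."""
        for i in range(200):
            if i % 2 == 0:
                seq = _random_gc_rich(rng, int(rng.integers(30, 61)))
            else:
                units = int(rng.integers(2, 4))
                s = list(_plant_repeat(rng, units, 60))
                for _ in range(int(rng.integers(0, 4))):
                    s[int(rng.integers(0, len(s)))] = str(rng.choice(list("GCAT")))
                seq = "".join(s)
            assert has_repeat(seq, double_params) == naive_has_chain(seq, 8, 5), seq
            assert has_repeat(seq, triple_params) == naive_has_chain(seq, 12, 8), seq

    def test_every_emitted_match_satisfies_all_invariants(self, rng, double_params):
        checked = 0
        for _ in range(60):
            seq = "".join(
                list(_plant_repeat(rng, 2, 60)) + list(_random_gc_rich(rng, 20))
            )
            for m in find_repeats(seq, double_params, mode="all"):
                m.validate(double_params)
                checked += 1
        assert checked > 0

    def test_strand_symmetry(self, rng, double_params):
        """Reports for seq equal mirrored reports for its reverse complement."""
        for _ in range(50):
            seq = _random_gc_rich(rng, int(rng.integers(30, 61)))
            fwd = find_repeats(seq, ScanParams.double(strands="forward"), mode="all")
            rev = find_repeats(
                reverse_complement(seq), ScanParams.double(strands="reverse"), mode="all"
            )
            n = len(seq)
            mirrored = {(n - m.end, n - m.start, m.n_perfect) for m in rev}
            assert {(m.start, m.end, m.n_perfect) for m in fwd} == mirrored

    def test_relaxing_constraints_never_loses_positives(self, rng):
        base = ScanParams.double()
        looser_L = ScanParams.double(max_loop_len=7)
        lower_p = ScanParams.double(min_perfect_islands=4)
        for _ in range(80):
            s = list(_plant_repeat(rng, 2, 55))
            for _ in range(int(rng.integers(0, 3))):
                s[int(rng.integers(0, len(s)))] = str(rng.choice(list("GCAT")))
            seq = "".join(s)
            if has_repeat(seq, base):
                assert has_repeat(seq, looser_L)
                assert has_repeat(seq, lower_p)

    def test_tandem_count_matches_oracle(self, rng):
        params = ScanParams.single()
        for _ in range(60):
            seq = _random_gc_rich(rng, int(rng.integers(20, 55)))
            assert count_tandem_units(seq, params) == naive_max_units(seq)


# ---------------------------------------------------------------------------
# sequence helpers
# ---------------------------------------------------------------------------


class TestGC:
    @pytest.mark.parametrize(
        "seq,expected", [("GCGC", 1.0), ("ATAT", 0.0), ("GCAT", 0.5)]
    )
    def test_examples(self, seq, expected):
        assert gc_content(seq) == expected

    def test_empty_is_error(self):
        with pytest.raises(ValueError):
            gc_content("")

    def test_all_n_is_nan(self):
        assert np.isnan(gc_content("NNN"))

    def test_gc_invariant_under_reverse_complement(self, rng):
        for _ in range(20):
            seq = "".join(rng.choice(list("GCATN"), size=30))
            a, b = gc_content(seq), gc_content(reverse_complement(seq))
            assert (np.isnan(a) and np.isnan(b)) or a == pytest.approx(b)
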