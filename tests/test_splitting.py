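"""Palindrome detection, read splitting, and recursive correction."""

import numpy as np
import pytest

from palsplit.align import reverse_complement
from palsplit.simulate import ErrorModel, random_template, simulate_readset
from palsplit.splitting import (
    CorrectionParams,
    Read,
    correct_read,
    correct_set,
    detect_split,
    read_records,
    split_read,
    write_records,
)


def rand(seed, n):
    return random_template(n, 0.5, np.random.default_rng(seed))


class TestRead:
    def test_default_origin_spans_whole_read(self):
        r = Read("a", "ACGT")
        assert r.origin == ("a", 0, 4)

    def test_quality_length_mismatch_rejected(self):
        with pytest.raises(ValueError, match="quality length"):
            Read("a", "ACGT", qual="III")

    def test_origin_interval_must_match_length(self):
        with pytest.raises(ValueError, match="origin interval"):
            Read("a", "ACGT", origin=("a", 0, 3))


class TestDetectSplit:
    def test_perfect_palindrome_splits_at_center(self):
        x = rand(1, 100)
        assert detect_split(Read("r", x + reverse_complement(x))) == 100

    def test_plain_random_read_not_flagged(self):
        assert detect_split(Read("r", rand(7, 200))) is None

    def test_embedded_palindrome_splits_at_exact_junction(self):
        # A/A flanks cannot extend the palindromic alignment (they face T
        # runs in the reverse complement), so the union midpoint is exactly
        # the junction between the two 75 b arms: 50 + 75.
        x = rand(3, 75)
        read = Read("r", "A" * 50 + x + reverse_complement(x) + "A" * 50)
        assert detect_split(read) == 125

    def test_embedded_palindrome_with_random_flanks_splits_near_junction(self):
        # chance matches in random flanks may extend the local alignment a
        # few bases past the arm boundaries, moving the midpoint slightly
        rng = np.random.default_rng(3)
        b = random_template(50, 0.5, rng)
        x = random_template(75, 0.5, rng)
        c = random_template(50, 0.5, rng)
        read = Read("r", b + x + reverse_complement(x) + c)
        pos = detect_split(read)
        assert pos is not None and abs(pos - 125) <= 15

    def test_tiny_reads_never_split(self):
        assert detect_split(Read("r", "A")) is None

    def test_overlong_read_passed_through_with_warning(self, caplog):
        x = rand(2, 100)
        params = CorrectionParams(max_align_length=150)
        with caplog.at_level("WARNING", logger="palsplit"):
            assert detect_split(Read("r", x + reverse_complement(x)), params) is None
        assert "uncorrected" in caplog.text

    def test_strand_symmetry(self):
        # a read is flagged palindromic iff its reverse complement is
        for seed in range(5):
            x = rand(seed, 80)
            for seq in (x + reverse_complement(x), rand(seed + 100, 160)):
                flagged = detect_split(Read("f", seq)) is not None
                flagged_rc = detect_split(Read("r", reverse_complement(seq))) is not None
                assert flagged == flagged_rc


class TestSplitRead:
    def test_partition(self):
        r = Read("r", rand(5, 200))
        left, right = split_read(r, 100)
        assert left.seq + right.seq == r.seq
        assert (left.id, right.id) == ("r:0-100", "r:100-200")

    def test_quality_split_in_parallel(self):
        r = Read("r", rand(5, 200), qual="I" * 200)
        left, right = split_read(r, 100)
        assert len(left.qual) == len(right.qual) == 100

    @pytest.mark.parametrize("pos", [0, 200, -1])
    def test_boundary_positions_rejected(self, pos):
        with pytest.raises(ValueError):
            split_read(Read("r", rand(5, 200)), pos)

    def test_nested_split_ids_stay_in_original_frame(self):
        r = Read("r", rand(6, 200))
        _, right = split_read(r, 100)
        a, b = split_read(right, 50)
        assert (a.id, b.id) == ("r:100-150", "r:150-200")


class TestCorrectRead:
    def test_single_fold_splits_once(self):
        x = rand(11, 100)
        res = correct_read(Read("r", x + reverse_complement(x)))
        assert [len(f) for f in res.fragments] == [100, 100]
        assert res.iterations == 1
        assert "".join(f.seq for f in res.fragments) == x + reverse_complement(x)

    def test_double_fold_yields_four_fragments(self):
        t = rand(12, 150)
        r1 = t + reverse_complement(t)
        r2 = r1 + reverse_complement(r1)
        res = correct_read(Read("r", r2))
        assert len(res.fragments) == 4
        assert res.iterations == 3
        assert "".join(f.seq for f in res.fragments) == r2

    def test_short_fragments_are_discarded(self):
        x = rand(13, 40)
        res = correct_read(Read("r", x + reverse_complement(x)))
        assert res.fragments == []
        assert [len(d) for d in res.discarded] == [40, 40]
        assert res.iterations == 1

    def test_short_intact_read_is_discarded(self):
        res = correct_read(Read("r", rand(14, 30)))
        assert res.fragments == [] and len(res.discarded) == 1
        assert res.iterations == 0

    def test_empty_read_gives_empty_result(self):
        res = correct_read(Read("r", ""))
        assert res.fragments == [] and res.discarded == []

    def test_iteration_count_matches_leaf_count(self):
        t = rand(15, 80)
        r1 = t + reverse_complement(t)
        r2 = r1 + reverse_complement(r1)
        res = correct_read(Read("r", r2))
        assert res.iterations == len(res.fragments) + len(res.discarded) - 1

    def test_max_iterations_caps_splitting(self, caplog):
        t = rand(16, 100)
        r1 = t + reverse_complement(t)
        r2 = r1 + reverse_complement(r1)
        params = CorrectionParams(max_iterations=1)
        with caplog.at_level("WARNING", logger="palsplit"):
            res = correct_read(Read("r", r2), params)
        assert res.iterations == 1
        assert len(res.fragments) == 2
        assert "".join(f.seq for f in res.fragments) == r2
        assert "max_iterations" in caplog.text

    def test_split_positions_recorded_in_original_frame(self):
        t = rand(17, 100)
        r1 = t + reverse_complement(t)
        r2 = r1 + reverse_complement(r1)
        res = correct_read(Read("r", r2))
        assert sorted(pos for _iv, pos in res.split_positions) == [100, 200, 300]


class TestCorrectSet:
    def test_one_palindrome_among_three_reads(self):
        x = rand(21, 100)
        reads = [Read("a", rand(22, 150)), Read("b", x + reverse_complement(x)),
                 Read("c", rand(23, 150))]
        out = list(correct_set(reads))
        frags = [f for fr, _res in out for f in fr]
        assert len(frags) == 4
        assert sum(res.is_palindromic for _fr, res in out) == 1

    def test_empty_stream(self):
        assert list(correct_set([])) == []

    def test_idempotence_on_error_free_simulation(self):
        model = ErrorModel(sub_rate=0, ins_rate=0, del_rate=0, seed=9)
        reads, _truths = simulate_readset(20, 0.5, 150, 1, model)
        first = list(correct_set(reads))
        frags = [f for fr, _res in first for f in fr]
        assert any(res.is_palindromic for _fr, res in first)
        second = list(correct_set(frags))
        assert sum(res.iterations for _fr, res in second) == 0

    def test_conservation_on_noisy_simulation(self):
        model = ErrorModel(seed=4)  # 12% total error
        reads, _truths = simulate_readset(30, 0.5, 200, 1, model)
        for frags, res in correct_set(reads):
            read = next(r for r in reads if r.id == res.input_id)
            pieces = sorted(frags + res.discarded, key=lambda r: r.origin[1])
            assert "".join(p.seq for p in pieces) == read.seq
            assert all(len(f) >= 50 for f in frags)
            assert all(len(d) < 50 for d in res.discarded)

    def test_lenient_alphabet_maps_to_n(self):
        x = rand(40, 120)
        seq = x[:60] + "ry" + x[62:]
        ((frags, res),) = list(correct_set([Read("a", seq)],
                                           strict_alphabet=False))
        assert frags[0].seq == x[:60].upper() + "NN" + x[62:].upper()

    def test_strict_alphabet_aborts(self):
        with pytest.raises(ValueError):
            list(correct_set([Read("a", "ACGTRY" * 20)]))

    def test_skip_mode_drops_malformed_records(self, caplog):
        reads = [Read("a", "ACGTRY" * 20), Read("b", rand(25, 120))]
        with caplog.at_level("WARNING", logger="palsplit"):
            out = list(correct_set(reads, on_error="skip"))
        assert [res.input_id for _fr, res in out] == ["b"]
        assert "skipping" in caplog.text


class TestRecordRoundTrip:
    def test_records_tsv_round_trip(self, tmp_path):
        x = rand(31, 100)
        reads = [Read("a", x + reverse_complement(x)), Read("b", rand(32, 150))]
        results = [res for _fr, res in correct_set(reads)]
        path = tmp_path / "records.tsv"
        write_records(results, path)
        back = read_records(path)
        assert [r.input_id for r in back] == ["a", "b"]
        assert back[0].iterations == 1
        assert back[0].fragment_lengths == [100, 100]
        assert back[0].split_points == [100]
        assert back[1].fragment_lengths == [150]
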