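"""Contact parsing, dedup, binning, downsampling, complexity estimation."""

import numpy as np
import pytest
from scipy.stats import chisquare

from archscreen.contacts import (
    deduplicate,
    downsample,
    estimate_complexity,
    read_pairs,
    write_pairs,
)
from archscreen.genome import load_cpg_track
from archscreen.matrix import bin_contacts

from conftest import make_contacts


def write_lines(tmp_path, lines, name="test.pairs"):
    path = tmp_path / name
    path.write_text("\n".join(lines) + "\n")
    return path


class TestReadPairs:
    def test_parses_valid_lines_and_skips_headers(self, tmp_path, toy_bins):
        path = write_lines(tmp_path, [
            "## pairs format v1.0",
            "#columns: readID chrom1 pos1 chrom2 pos2",
            "r1\tchr1\t100\tchr1\t2000000",
            "r2\tchr1\t5\tchr2\t10",
            "r3\tchr2\t1\tchr2\t2500000",
        ])
        cs = read_pairs(path, toy_bins)
        assert len(cs) == 3
        assert cs.n_total == 3

    def test_canonicalizes_mate_order(self, tmp_path, toy_bins):
        path = write_lines(tmp_path, ["r1 chr2 100 chr1 50"])
        cs = read_pairs(path, toy_bins)
        assert (cs.c1[0], cs.p1[0], cs.c2[0], cs.p2[0]) == (0, 50, 1, 100)

    def test_unknown_chromosome_names_offender(self, tmp_path, toy_bins):
        path = write_lines(tmp_path, ["r1 chr1 10 chr_unknown 20"])
        with pytest.raises(ValueError, match="chr_unknown"):
            read_pairs(path, toy_bins)

    def test_position_beyond_chromosome_rejected(self, tmp_path, toy_bins):
        path = write_lines(tmp_path, ["r1 chr2 10 chr2 9999999"])
        with pytest.raises(ValueError, match="out of range"):
            read_pairs(path, toy_bins)

    def test_empty_file_gives_empty_set(self, tmp_path, toy_bins):
        path = tmp_path / "empty.pairs"
        path.write_text("")
        assert len(read_pairs(path, toy_bins)) == 0

    def test_write_read_round_trip(self, tmp_path, toy_bins):
        rng = np.random.default_rng(0)
        c = rng.integers(0, 2, size=(50, 2))
        p = rng.integers(1, 2_500_000, size=(50, 2))
        cs = make_contacts(
            toy_bins, np.column_stack([c[:, 0], p[:, 0], c[:, 1], p[:, 1]])
        )
        path = tmp_path / "rt.pairs"
        write_pairs(cs, path)
        back = read_pairs(path, toy_bins)
        for a, b in zip((cs.c1, cs.p1, cs.c2, cs.p2), (back.c1, back.p1, back.c2, back.p2)):
            assert np.array_equal(a, b)


class TestDeduplicate:
    def test_distinct_contacts_untouched(self, toy_bins):
        rows = [(0, i + 1, 0, i + 100) for i in range(10)]
        out = deduplicate(make_contacts(toy_bins, rows))
        assert len(out) == 10 and out.n_duplicates == 0

    def test_repeated_tuple_collapsed(self, toy_bins):
        out = deduplicate(make_contacts(toy_bins, [(0, 5, 1, 9)] * 5))
        assert len(out) == 1
        assert out.n_total == 5 and out.n_duplicates == 4

    def test_empty_set(self, toy_bins):
        out = deduplicate(make_contacts(toy_bins, np.empty((0, 4))))
        assert len(out) == 0 and out.n_total == 0 and out.n_duplicates == 0


class TestComplexity:
    def test_no_duplicates_is_unbounded(self):
        assert estimate_complexity(100, 100) == float("inf")

    @pytest.mark.parametrize("n_total,n_unique", [(2, 1), (1000, 500)])
    def test_matches_bisection_oracle(self, n_total, n_unique):
        from archscreen.validation import bisection_complexity_oracle

        est = estimate_complexity(n_total, n_unique)
        ref = bisection_complexity_oracle(n_total, n_unique)
        assert est == pytest.approx(ref, rel=1e-6)
        # saturation-curve round trip
        assert est * (1 - np.exp(-n_total / est)) == pytest.approx(n_unique, abs=1e-6)

    def test_oracle_agreement_on_grid(self):
        from archscreen.validation import bisection_complexity_oracle

        for n_total in (10, 200, 5000, 200_000):
            for frac in (0.3, 0.6, 0.9, 0.99):
                u = max(1, int(n_total * frac))
                est = estimate_complexity(n_total, u)
                assert est == pytest.approx(
                    bisection_complexity_oracle(n_total, u), rel=1e-6
                )

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            estimate_complexity(10, 11)
        with pytest.raises(ValueError):
            estimate_complexity(10, 0)


class TestBinContacts:
    def test_both_ends_in_first_bin(self, toy_bins):
        m = bin_contacts(make_contacts(toy_bins, [(0, 1, 0, 999_999)]), toy_bins)
        assert m.b1[0] == 0 and m.b2[0] == 0

    def test_off_diagonal_pair(self, toy_bins):
        m = bin_contacts(make_contacts(toy_bins, [(0, 1, 0, 2_500_000)]), toy_bins)
        assert (m.b1[0], m.b2[0]) == (0, 2)

    def test_total_conserved_for_random_sets(self, toy_bins):
        rng = np.random.default_rng(1)
        for binsize in (250_000, 1_000_000):
            bins = toy_bins.with_binsize(binsize)
            n = int(rng.integers(10, 300))
            c = rng.integers(0, 2, size=(n, 2))
            p = np.column_stack([
                rng.integers(1, 1 + toy_bins.lengths[c[:, 0]]),
                rng.integers(1, 1 + toy_bins.lengths[c[:, 1]]),
            ])
            cs = make_contacts(
                toy_bins, np.column_stack([c[:, 0], p[:, 0], c[:, 1], p[:, 1]])
            )
            m = bin_contacts(cs, bins)
            assert m.total == n
            # brute-force tally of one random bin pair
            i, j = int(m.b1[0]), int(m.b2[0])
            tally = int(np.sum((m.b1 == i) & (m.b2 == j)))
            assert m.dense()[i, j] in (tally, 2 * tally)  # diag counts once


class TestTripletIO:
    def test_binned_matrix_round_trips(self, tmp_path, toy_bins):
        from archscreen.matrix import BinnedMatrix

        rng = np.random.default_rng(6)
        c = rng.integers(0, 2, size=(80, 2))
        rows = np.column_stack([
            c[:, 0], rng.integers(1, 2_400_000, 80),
            c[:, 1], rng.integers(1, 2_400_000, 80),
        ])
        m = bin_contacts(make_contacts(toy_bins, rows), toy_bins)
        path = tmp_path / "m.tsv"
        m.to_triplets(path)
        back = BinnedMatrix.from_triplets(path, toy_bins)
        assert back.total == m.total
        assert np.array_equal(back.dense(), m.dense())


class TestDownsample:
    def test_full_size_identity(self, toy_bins):
        cs = make_contacts(toy_bins, [(0, i + 1, 1, i + 2) for i in range(20)])
        out = downsample(cs, 20, seed=3)
        assert np.array_equal(out.p1, cs.p1)

    def test_zero_gives_empty(self, toy_bins):
        cs = make_contacts(toy_bins, [(0, 1, 0, 2)])
        assert len(downsample(cs, 0, seed=0)) == 0

    def test_same_seed_same_subset(self, toy_bins):
        cs = make_contacts(toy_bins, [(0, i + 1, 1, i + 2) for i in range(50)])
        a, b = downsample(cs, 10, seed=7), downsample(cs, 10, seed=7)
        assert np.array_equal(a.p1, b.p1) and np.array_equal(a.p2, b.p2)

    def test_too_many_raises(self, toy_bins):
        cs = make_contacts(toy_bins, [(0, 1, 0, 2)])
        with pytest.raises(ValueError):
            downsample(cs, 2, seed=0)

    def test_uniform_inclusion_probability(self, toy_bins):
        """Chi-square goodness of fit on per-contact inclusion counts."""
        n_items, k, trials = 20, 5, 10_000
        cs = make_contacts(toy_bins, [(0, i + 1, 1, i + 2) for i in range(n_items)])
        counts = np.zeros(n_items)
        for t in range(trials):
            sub = downsample(cs, k, seed=t)
            counts[sub.p1 - 1] += 1
        stat, p = chisquare(counts)  # expected uniform k*trials/n per item
        assert p > 0.01


class TestCpGTrack:
    def test_exact_bin_cover(self, tmp_path, toy_bins):
        path = tmp_path / "a.bedgraph"
        path.write_text("chr1\t0\t1000000\t0.02\n")
        track = load_cpg_track(path, toy_bins)
        assert track.values[0] == pytest.approx(0.02)

    def test_length_weighted_mean(self, tmp_path, toy_bins):
        path = tmp_path / "b.bedgraph"
        path.write_text(
            "chr1\t0\t500000\t0.01\nchr1\t500000\t1000000\t0.03\n"
        )
        track = load_cpg_track(path, toy_bins)
        assert track.values[0] == pytest.approx(0.02)

    def test_uncovered_bin_masked(self, tmp_path, toy_bins):
        path = tmp_path / "c.bedgraph"
        path.write_text("chr1\t0\t1000000\t0.02\n")
        track = load_cpg_track(path, toy_bins)
        assert np.isnan(track.values[5])

    def test_malformed_line_reports_number(self, tmp_path, toy_bins):
        path = tmp_path / "d.bedgraph"
        path.write_text("chr1\t0\t1000000\t0.02\nchr1\tnope\n")
        with pytest.raises(ValueError, match="line 2"):
            load_cpg_track(path, toy_bins)
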