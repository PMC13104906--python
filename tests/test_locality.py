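"""Distance profiles, insulation/boundaries, APA loop strength."""

import numpy as np
import pytest
from scipy.integrate import quad

from archscreen.genome import GenomeBins
from archscreen.locality import (
    apa_p2ll,
    boundary_strength,
    distance_profile,
    insulation_profile,
    intermingling,
    read_bedpe,
    InsulationTrack,
)
from archscreen.matrix import BinnedMatrix
from archscreen.simulate import default_spec, simulate_contacts

from conftest import make_contacts


def single_chrom_bins(n, binsize):
    return GenomeBins(("chr1",), np.array([n * binsize]), binsize)


def matrix_from_dense(bins, dense, chrom=0):
    off = bins.offsets[chrom]
    i, j = np.nonzero(np.triu(dense))
    counts = dense[i, j].astype(int)
    return BinnedMatrix(bins, np.repeat(off + i, counts), np.repeat(off + j, counts))


class TestDistanceProfile:
    def test_trans_fraction(self, toy_bins):
        rows = [(0, 1, 0, 1_000_001)] * 8 + [(0, 1, 1, 1)] * 2
        prof = distance_profile(make_contacts(toy_bins, rows))
        assert prof.trans_fraction == pytest.approx(0.2)
        assert prof.fractions.sum() + prof.trans_fraction == pytest.approx(1.0, abs=1e-12)

    def test_single_distance_occupies_one_band(self, toy_bins):
        rows = [(0, 1, 0, 500_001)] * 5 + [(0, 1, 1, 1)] * 5
        prof = distance_profile(make_contacts(toy_bins, rows))
        assert prof.fractions.max() == pytest.approx(0.5)
        assert np.sum(prof.fractions > 0) == 1

    def test_band_fractions_match_numeric_integration(self):
        """Summary bands vs numeric integration of the truncated power-law
        contact-count density s**-alpha."""
        spec = default_spec(c=1.0, d=1.0, f_trans=0.0)
        depth = 200_000
        cs = simulate_contacts(spec, depth, seed=21)
        prof = distance_profile(cs)
        L, lo = 60e6, 1e4
        dens = lambda s: s**-1.0
        total, _ = quad(dens, lo, L, limit=200)
        for frac, a, b in (
            (prof.frac_short, lo, 2e6),
            (prof.frac_long, 2e6, 10e6),
            (prof.frac_very_long, 10e6, L),
        ):
            expect = quad(dens, a, b, limit=200)[0] / total
            se = np.sqrt(expect * (1 - expect) / depth)
            assert abs(frac - expect) < 4 * se

    def test_empty_set_rejected(self, toy_bins):
        with pytest.raises(ValueError):
            distance_profile(make_contacts(toy_bins, np.empty((0, 4))))


class TestIntermingling:
    def test_extremes(self, toy_bins):
        cis = make_contacts(toy_bins, [(0, 1, 0, 2)] * 100)
        trans = make_contacts(toy_bins, [(0, 1, 1, 2)] * 7)
        assert intermingling(cis) == 0.0
        assert intermingling(trans) == 1.0

    def test_recovers_simulated_trans_fraction(self):
        spec = default_spec(f_trans=0.1)
        cs = simulate_contacts(spec, 100_000, seed=22)
        se = np.sqrt(0.1 * 0.9 / 100_000)
        assert abs(intermingling(cs) - 0.1) < 3 * se


class TestInsulation:
    def test_uniform_matrix_is_flat_zero(self):
        bins = single_chrom_bins(80, 25_000)
        m = matrix_from_dense(bins, np.ones((80, 80), dtype=int))
        track = insulation_profile(m, 250_000)
        ok = np.isfinite(track.values)
        assert ok.sum() == 80 - 2 * 10
        assert np.allclose(track.values[ok], 0.0)

    def test_contact_free_seam_is_global_minimum(self):
        bins = single_chrom_bins(100, 25_000)
        dense = np.zeros((100, 100), dtype=int)
        dense[:50, :50] = 4
        dense[50:, 50:] = 4
        m = matrix_from_dense(bins, dense)
        track = insulation_profile(m, 250_000)
        assert np.nanargmin(track.values) in (49, 50)
        assert 49 in track.boundaries or 50 in track.boundaries

    def test_depth_scaling_invariance(self):
        bins = single_chrom_bins(60, 25_000)
        rng = np.random.default_rng(3)
        dense = rng.integers(1, 6, size=(60, 60))
        dense = np.triu(dense) + np.triu(dense, 1).T
        t1 = insulation_profile(matrix_from_dense(bins, dense), 250_000)
        t2 = insulation_profile(matrix_from_dense(bins, 2 * dense), 250_000)
        ok = np.isfinite(t1.values)
        assert np.allclose(t1.values[ok], t2.values[ok])

    def test_matches_brute_force_exactly(self):
        """Both the sparse range-add path and the dense integral-image path
        agree exactly with the naive O(n*w^2) loop oracle."""
        from archscreen.locality import _diamond_sums, diamond_sums
        from archscreen.validation import brute_force_insulation

        rng = np.random.default_rng(4)
        bins = single_chrom_bins(120, 25_000)
        dense = rng.integers(0, 5, size=(120, 120))
        dense = np.triu(dense) + np.triu(dense, 1).T
        m = matrix_from_dense(bins, dense)
        ref = brute_force_insulation(dense.astype(float), 10)
        ok = np.isfinite(ref)
        got_sparse = diamond_sums(m, 0, 10)
        got_dense = _diamond_sums(dense.astype(float), 10)
        assert np.array_equal(got_sparse[ok], ref[ok])
        assert np.array_equal(got_dense[ok], ref[ok])

    def test_window_larger_than_chromosome_masks(self):
        bins = single_chrom_bins(5, 25_000)
        m = matrix_from_dense(bins, np.ones((5, 5), dtype=int))
        with pytest.warns(UserWarning, match="smaller than"):
            track = insulation_profile(m, 250_000)
        assert np.all(~np.isfinite(track.values))


class TestBoundaryStrength:
    def build_track(self, values):
        bins = single_chrom_bins(len(values), 25_000)
        return InsulationTrack(bins, 250_000, np.asarray(values, float),
                               np.empty(0, dtype=int))

    def test_flat_track_zero(self):
        track = self.build_track(np.zeros(40))
        assert boundary_strength(track, [20]) == pytest.approx(0.0)

    def test_single_dip_prominence(self):
        vals = np.zeros(40)
        vals[20] = -1.0
        track = self.build_track(vals)
        assert boundary_strength(track, [20]) == pytest.approx(1.0)

    def test_no_reference_rejected(self):
        track = self.build_track(np.zeros(40))
        with pytest.raises(ValueError):
            boundary_strength(track, [])


class TestApa:
    def inject(self, n, loops, enrichment, half_window=5, binsize=50_000):
        bins = single_chrom_bins(n, binsize)
        m = BinnedMatrix(bins, np.array([0]), np.array([0]))
        oe = np.ones((n, n))
        for b1, b2 in loops:
            oe[b1, b2] = oe[b2, b1] = enrichment
        m.oe = {0: oe}
        loop_rows = np.array(
            [(0, b1 * binsize + binsize // 2, b2 * binsize + binsize // 2)
             for b1, b2 in loops]
        )
        return m, loop_rows

    def test_planted_enrichment_recovered(self):
        loops = [(20, 50), (60, 90), (100, 140)]
        m, rows = self.inject(200, loops, enrichment=5.0)
        res = apa_p2ll(m, rows, half_window=5)
        assert res.p2ll == pytest.approx(5.0, rel=0.10)
        assert res.n_used == 3

    def test_homogeneous_background_is_neutral(self):
        m, rows = self.inject(200, [(20, 50)], enrichment=1.0)
        res = apa_p2ll(m, rows, half_window=5)
        assert res.p2ll == pytest.approx(1.0)

    def test_singleton_stack_equals_own_submatrix(self):
        m, rows = self.inject(200, [(30, 70)], enrichment=3.0)
        res = apa_p2ll(m, rows, half_window=4)
        assert np.allclose(res.stack, m.oe[0][26:35, 66:75])

    def test_near_diagonal_loop_skipped(self):
        m, rows = self.inject(200, [(20, 24), (60, 90)], enrichment=2.0)
        with pytest.warns(UserWarning, match="skipped"):
            res = apa_p2ll(m, rows, half_window=5)
        assert res.n_used == 1 and res.n_skipped == 1

    def test_all_skipped_rejected(self):
        m, rows = self.inject(200, [(20, 24)], enrichment=2.0)
        with pytest.raises(ValueError):
            apa_p2ll(m, rows, half_window=5)

    def test_simulated_loops_enrich_p2ll(self):
        """Planted 3x loops on the toy genome raise P2LL well above the
        loop-free baseline."""
        from archscreen.matrix import bin_contacts

        vals = {}
        for mult in (1.0, 3.0):
            spec = default_spec(loop_mult=mult)
            cs = simulate_contacts(spec, 300_000, seed=23)
            m = bin_contacts(cs, spec.genome_bins(50_000))
            loops = np.asarray(spec.loop_anchors, dtype=np.int64)
            vals[mult] = apa_p2ll(m, loops, half_window=5).p2ll
        assert vals[1.0] == pytest.approx(1.0, abs=0.35)
        assert vals[3.0] > vals[1.0] + 1.0

    def test_bedpe_round_trip(self, tmp_path):
        spec = default_spec()
        path = tmp_path / "loops.bedpe"
        spec.loop_bedpe().to_csv(path, sep="\t", header=False, index=False)
        bins = spec.genome_bins(50_000)
        rows = read_bedpe(path, bins)
        ref = np.asarray(spec.loop_anchors, dtype=np.int64)
        assert rows.shape == ref.shape
        assert np.array_equal(rows[:, 0], ref[:, 0])
        assert np.all(np.abs(rows[:, 1] - ref[:, 1]) <= 1)
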