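import numpy as np
import pandas as pd
import pytest

from mesoprofiler.cnv import (
    PSI_GRID,
    RHO_GRID,
    BinTrack,
    SegmentProfile,
    Segment,
    _max_arc_stat,
    assign_copies,
    bintrack_from_log_ratio,
    count_bins,
    exon_copy_ratio,
    expected_ratio,
    fit_purity_ploidy,
    grid_distance_surface,
    mask_targets,
    segment_cbs,
)
from conftest import write_test_sam


# ---------------------------------------------------------------------------
# mask_targets
# ---------------------------------------------------------------------------

class TestMaskTargets:
    def test_padding_clipped_at_origin(self):
        targets = pd.DataFrame({"chrom": ["c"], "start": [100], "end": [200]})
        out = mask_targets(targets, padding=1000, chrom_sizes={"c": 10_000})
        assert out["c"].tolist() == [[0, 1200]]

    def test_interval_beyond_chromosome_end_clips_with_warning(self):
        targets = pd.DataFrame({"chrom": ["c"], "start": [9500], "end": [9900]})
        with pytest.warns(UserWarning, match="clipped"):
            out = mask_targets(targets, padding=1000, chrom_sizes={"c": 10_000})
        assert out["c"].tolist() == [[8500, 10_000]]

    def test_close_targets_merge_after_padding(self):
        # brute-force interval-union oracle on a base-resolution bitmap
        targets = pd.DataFrame(
            {"chrom": ["c", "c"], "start": [3000, 4500], "end": [3500, 5000]}
        )
        out = mask_targets(targets, padding=1000)
        bitmap = np.zeros(10_000, dtype=bool)
        for s, e in [(3000, 3500), (4500, 5000)]:
            bitmap[max(0, s - 1000):e + 1000] = True
        expected = []
        in_run = False
        for i, v in enumerate(bitmap):
            if v and not in_run:
                expected.append([i, None]); in_run = True
            if not v and in_run:
                expected[-1][1] = i; in_run = False
        if in_run:
            expected[-1][1] = len(bitmap)
        assert out["c"].tolist() == expected
        assert len(out["c"]) == 1  # 500-bp gap closed by 1000-bp padding

    def test_empty_bed_gives_pure_wgs_mode(self):
        out = mask_targets(pd.DataFrame(columns=["chrom", "start", "end"]))
        assert out == {}


# ---------------------------------------------------------------------------
# count_bins
# ---------------------------------------------------------------------------

class TestCountBins:
    def test_mapq_threshold_is_strict(self, tmp_path):
        reads = [
            {"chrom": "c", "start": 10, "mapq": 60},
            {"chrom": "c", "start": 20, "mapq": 60},
            {"chrom": "c", "start": 30, "mapq": 31},
            {"chrom": "c", "start": 40, "mapq": 30},  # fails strict > 30
            {"chrom": "c", "start": 50, "mapq": 10},
            {"chrom": "c", "start": 1500, "mapq": 60},
        ]
        sam = write_test_sam(tmp_path / "t.sam", reads, {"c": 5000})
        track = count_bins(sam, bin_size=1000, mapq_min=30)
        assert track.bins["count"].tolist()[:2] == [3, 1]

    def test_read_in_padded_target_not_counted(self, tmp_path):
        reads = [
            {"chrom": "c", "start": 100, "mapq": 60},
            {"chrom": "c", "start": 700, "mapq": 60},  # inside excluded
            {"chrom": "c", "start": 1100, "mapq": 60},
        ]
        sam = write_test_sam(tmp_path / "t.sam", reads, {"c": 5000})
        excluded = {"c": np.array([[600, 900]])}
        track = count_bins(sam, excluded, bin_size=1000, mapq_min=30)
        assert track.bins["count"].tolist()[:2] == [1, 1]

    def test_wholly_excluded_bin_is_masked(self, tmp_path):
        reads = [{"chrom": "c", "start": s, "mapq": 60}
                 for s in (100, 2100, 3100)]
        sam = write_test_sam(tmp_path / "t.sam", reads, {"c": 5000})
        excluded = {"c": np.array([[1000, 2000]])}
        track = count_bins(sam, excluded, bin_size=1000, mapq_min=30)
        assert not track.bins["mask"].iloc[1]

    def test_secondary_and_duplicate_reads_dropped(self, tmp_path):
        reads = [
            {"chrom": "c", "start": 10, "mapq": 60},
            {"chrom": "c", "start": 20, "mapq": 60, "flag": 256},   # secondary
            {"chrom": "c", "start": 30, "mapq": 60, "flag": 1024},  # duplicate
            {"chrom": "c", "start": 40, "mapq": 60, "flag": 2048},  # supplementary
        ]
        sam = write_test_sam(tmp_path / "t.sam", reads, {"c": 5000})
        track = count_bins(sam, bin_size=1000, mapq_min=30)
        assert track.bins["count"].iloc[0] == 1

    def test_ratio_mean_is_one_over_retained_bins(self, tmp_path):
        rng = np.random.default_rng(0)
        reads = [
            {"chrom": "c", "start": int(p), "mapq": 60}
            for p in rng.integers(0, 20_000, size=400)
        ]
        sam = write_test_sam(tmp_path / "t.sam", reads, {"c": 20_000})
        track = count_bins(sam, bin_size=1000, mapq_min=30)
        assert track.retained["ratio"].mean() == pytest.approx(1.0, rel=1e-9)
        assert np.isfinite(track.retained["log2_ratio"]).all()


# ---------------------------------------------------------------------------
# circular binary segmentation
# ---------------------------------------------------------------------------

class TestSegmentCBS:
    def test_max_stat_matches_exhaustive_search(self):
        # oracle: direct O(n^2) scan over every arc
        rng = np.random.default_rng(3)
        x = rng.normal(0, 1, 40)
        n = x.size
        sd = x.std()
        best, bi, bj = 0.0, 0, 0
        for i in range(n):
            for j in range(i + 1, n + 1):
                if j - i == n:
                    continue
                k = j - i
                za = x[i:j].mean() - np.delete(x, slice(i, j)).mean()
                z = abs(za) / (sd * np.sqrt(1 / k + 1 / (n - k)))
                if z > best:
                    best, bi, bj = z, i, j
        stat, i, j = _max_arc_stat(x)
        assert stat == pytest.approx(best, rel=1e-12)
        assert (i, j) == (bi, bj)

    def test_noiseless_step_locates_single_changepoint(self):
        # the arc statistic itself places the cut between bins 3 and 4
        stat, i, j = _max_arc_stat(np.array([0.0, 0, 0, 1, 1, 1]))
        assert {i, j} == {3, 6} or {i, j} == {0, 3}

    def test_constant_track_single_segment(self):
        track = bintrack_from_log_ratio(np.zeros(50))
        profile = segment_cbs(track, seed=0)
        assert len(profile.segments) == 1
        assert profile.segments[0].n_bins == 50

    def test_noiseless_multistep_exact_changepoints(self):
        levels = [0.0, 0.6, -0.4, 0.8, 0.2, 1.0]
        signal = np.repeat(levels, 50)
        track = bintrack_from_log_ratio(signal)
        profile = segment_cbs(track, seed=1)
        bounds = np.cumsum([s.n_bins for s in profile.segments])[:-1]
        assert bounds.tolist() == [50, 100, 150, 200, 250]

    def test_noisy_jump_breakpoint_within_two_bins(self):
        hits = 0
        n_runs = 30
        for seed in range(n_runs):
            rng = np.random.default_rng(seed)
            x = np.concatenate(
                [rng.normal(0, 0.1, 100), rng.normal(0.58, 0.1, 100)]
            )
            profile = segment_cbs(bintrack_from_log_ratio(x), seed=seed)
            bounds = np.cumsum([s.n_bins for s in profile.segments])[:-1]
            if len(bounds) and np.min(np.abs(bounds - 100)) <= 2:
                hits += 1
        assert hits >= int(0.9 * n_runs)

    def test_requires_two_unmasked_bins(self):
        track = bintrack_from_log_ratio(np.array([0.0, np.nan]))
        with pytest.raises(ValueError):
            segment_cbs(track)


# ---------------------------------------------------------------------------
# purity/ploidy grid fit
# ---------------------------------------------------------------------------

def _profile_from_ratios(ratios, n_bins=None):
    n_bins = n_bins or [10] * len(ratios)
    segs = [
        Segment(chrom="c", start=i * 10, end=i * 10 + 10, n_bins=nb,
                mean_ratio=r)
        for i, (r, nb) in enumerate(zip(ratios, n_bins))
    ]
    return SegmentProfile(segments=segs)


class TestGridFit:
    def test_exact_integer_solution_found(self):
        # truth rho=1, psi=2: ratios 0.5/1.0/1.5 imply copies 1/2/3
        profile = _profile_from_ratios([0.5, 1.0, 1.5])
        rho, psi, surface, fitted = fit_purity_ploidy(profile)
        assert (rho, psi) == (1.0, 2.0)
        assert fitted.distance == pytest.approx(0.0, abs=1e-12)
        assert [s.call for s in fitted.segments] == [1, 2, 3]

    def test_surface_equals_naive_triple_loop_bitwise(self):
        rng = np.random.default_rng(12)
        for _ in range(10):
            k = int(rng.integers(2, 8))
            ratios = rng.uniform(0.3, 2.0, size=k)
            weights = rng.integers(1, 50, size=k).astype(float)
            surface = grid_distance_surface(ratios, weights)
            naive = np.zeros((PSI_GRID.size, RHO_GRID.size))
            for i, psi in enumerate(PSI_GRID):
                for j, rho in enumerate(RHO_GRID):
                    d = 0.0
                    for r, w in zip(ratios, weights):
                        n_t = (psi * r - 2.0 * (1.0 - rho)) / rho
                        nearest = float(round(n_t))
                        if nearest < 0:
                            nearest = 0.0
                        d += w * abs(n_t - nearest)
                    naive[i, j] = d
            assert np.array_equal(surface, naive)

    def test_fit_invariant_to_segment_order(self):
        ratios = [0.55, 1.0, 1.42, 0.81]
        a = fit_purity_ploidy(_profile_from_ratios(ratios))
        b = fit_purity_ploidy(_profile_from_ratios(ratios[::-1]))
        assert (a[0], a[1]) == (b[0], b[1])

    def test_surface_nonnegative(self):
        rng = np.random.default_rng(5)
        surface = grid_distance_surface(rng.uniform(0.2, 2, 5), np.ones(5))
        assert (surface >= 0).all()
        assert surface.shape == (351, 81)

    def test_single_ratio_flags_degenerate(self):
        profile = _profile_from_ratios([1.0])
        rho, psi, surface, fitted = fit_purity_ploidy(profile)
        assert fitted.degenerate
        assert fitted.distance == pytest.approx(0.0, abs=1e-12)
        # tie-break: lowest psi on the zero ridge, then highest rho there
        assert (psi, rho) == (1.5, 0.5)

    def test_forward_inverse_consistency_noiseless(self):
        # any grid-representable (rho, psi) with integer copies round-trips
        rng = np.random.default_rng(8)
        for _ in range(20):
            rho = float(rng.choice(RHO_GRID))
            copies = rng.integers(0, 7, size=5)
            psi_s = float(np.mean(copies) * rho + 2 * (1 - rho))
            if psi_s < 1.5 or psi_s > 5:
                continue
            ratios = expected_ratio(copies, rho, psi_s)
            fitted = assign_copies(_profile_from_ratios(ratios), rho, psi_s)
            assert [s.call for s in fitted.segments] == copies.tolist()
            assert all(s.residual < 1e-9 for s in fitted.segments)

    def test_negative_nt_floors_at_zero(self):
        fitted = assign_copies(_profile_from_ratios([0.05]), 0.9, 2.0)
        assert fitted.segments[0].call == 0
        assert fitted.segments[0].n_t < 0
        assert fitted.segments[0].residual > 0


# ---------------------------------------------------------------------------
# exon-level on-target copy ratio
# ---------------------------------------------------------------------------

class TestExonCopyRatio:
    def _targets(self):
        return pd.DataFrame(
            {"chrom": ["c", "c"], "start": [1000, 3000], "end": [1200, 3200]}
        )

    def _sam(self, tmp_path, depth_by_exon):
        reads = []
        for (centre, depth) in depth_by_exon:
            for i in range(depth):
                reads.append(
                    {"chrom": "c", "start": centre - 50 + i, "mapq": 60,
                     "length": 100}
                )
        return write_test_sam(tmp_path / "e.sam", reads, {"c": 10_000})

    def test_ratio_against_reference(self, tmp_path):
        sam = self._sam(tmp_path, [(1100, 40), (3100, 20)])
        ref = pd.DataFrame(
            {"chrom": ["c", "c"], "start": [1000, 3000],
             "end": [1200, 3200], "count": [20, 20]}
        )
        out = exon_copy_ratio(sam, self._targets(), ref)
        assert out["ratio"].tolist() == [2.0, 1.0]

    def test_zero_reference_masks_ratio(self, tmp_path):
        sam = self._sam(tmp_path, [(1100, 10), (3100, 10)])
        ref = pd.DataFrame(
            {"chrom": ["c", "c"], "start": [1000, 3000],
             "end": [1200, 3200], "count": [10, 0]}
        )
        with pytest.warns(UserWarning):
            out = exon_copy_ratio(sam, self._targets(), ref)
        assert np.isnan(out["ratio"].iloc[1])

    def test_missing_reference_exon_rejected(self, tmp_path):
        sam = self._sam(tmp_path, [(1100, 5)])
        ref = pd.DataFrame(
            {"chrom": ["c"], "start": [1000], "end": [1200], "count": [5]}
        )
        with pytest.raises(ValueError, match="missing"):
            exon_copy_ratio(sam, self._targets(), ref)
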