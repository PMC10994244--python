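"""Genome-wide copy number from off-target reads of a targeted capture panel.

Off-target reads of a hybrid-capture panel form a uniform shallow
whole-genome sequencing experiment.  The pipeline masks the baited
(on-target) regions with padding, bins the rest of the genome, counts
MAPQ-filtered read starts per bin, normalizes to a ratio track

    r = count / mean(count)

segments log2(r) with circular binary segmentation, and fits tumour
purity (rho) and average ploidy (psi) on a grid by inverting the mixture
model

    r = (n_T * rho + 2 * (1 - rho)) / psi

where n_T is the local tumour copy number and the 2 comes from the
diploid admixed normal cells.  The (rho, psi) pair minimizing the summed
distance of the implied per-segment n_T from the nearest integers is
selected, and integer copies are assigned per segment.  Exon-level
on-target ratios against a diploid reference sample complete the module.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import pysam

# Grid of the purity/ploidy fit: ploidy 1.5..5 and purity 0.2..1, both in
# steps of 0.01 (351 x 81 grid points).
PSI_GRID = np.round(np.arange(150, 501) * 0.01, 2)
RHO_GRID = np.round(np.arange(20, 101) * 0.01, 2)

DEFAULT_BIN_SIZE = 30_000
DEFAULT_PADDING = 1_000
DEFAULT_MAPQ_MIN = 30  # strict: kept iff MAPQ > 30
DEFAULT_CBS_ALPHA = 0.01
DEFAULT_CBS_NPERM = 1000
MIN_SEGMENT_BINS = 2

# Two grid minima are "the same optimum" if their distances differ by less
# than this; a ridge of such minima spread in psi flags the fit degenerate.
DEGENERACY_TOL = 1e-12
DEGENERACY_PSI_SPAN = 0.1


# ---------------------------------------------------------------------------
# Target masking
# ---------------------------------------------------------------------------

def mask_targets(
    targets: pd.DataFrame,
    padding: int = DEFAULT_PADDING,
    chrom_sizes: dict[str, int] | None = None,
) -> dict[str, np.ndarray]:
    """Merge padded target intervals into an excluded-region set.

    Parameters
    ----------
    targets
        BED-style frame with columns ``chrom``, ``start``, ``end``
        (0-based half-open).
    padding
        Bases added on both sides of every interval before merging.
    chrom_sizes
        Optional chromosome lengths used to clip padded intervals.

    Returns
    -------
    dict mapping chromosome to an ``(n, 2)`` int array of merged,
    non-overlapping, sorted [start, end) intervals.
    """
    if padding < 0:
        raise ValueError("padding must be >= 0")
    excluded: dict[str, np.ndarray] = {}
    if len(targets) == 0:
        return excluded
    for chrom, sub in targets.groupby("chrom", sort=False):
        starts = sub["start"].to_numpy(dtype=np.int64) - padding
        ends = sub["end"].to_numpy(dtype=np.int64) + padding
        starts = np.maximum(starts, 0)
        if chrom_sizes is not None and chrom in chrom_sizes:
            size = chrom_sizes[chrom]
            if (ends > size).any():
                warnings.warn(
                    f"target interval(s) on {chrom} extend beyond the "
                    f"chromosome end ({size}); clipped",
                    stacklevel=2,
                )
            ends = np.minimum(ends, size)
        order = np.argsort(starts, kind="stable")
        starts, ends = starts[order], ends[order]
        merged: list[list[int]] = []
        for s, e in zip(starts, ends):
            if merged and s <= merged[-1][1]:
                merged[-1][1] = max(merged[-1][1], e)
            else:
                merged.append([int(s), int(e)])
        excluded[str(chrom)] = np.asarray(merged, dtype=np.int64)
    return excluded


def _in_excluded(pos: int, intervals: np.ndarray) -> bool:
    """True iff 0-based position lies in one of the sorted intervals."""
    if intervals is None or len(intervals) == 0:
        return False
    i = np.searchsorted(intervals[:, 0], pos, side="right") - 1
    return i >= 0 and pos < intervals[i, 1]


# ---------------------------------------------------------------------------
# Binned read-count track
# ---------------------------------------------------------------------------

@dataclass
class BinTrack:
    """Fixed-width genome bins with read counts and the normalized ratio.

    ``mask`` is True for retained bins; bins wholly inside excluded
    regions or with zero reads are masked out.  Over retained bins the
    ratio averages exactly 1 and ``log_ratio`` is finite.
    """

    bins: pd.DataFrame  # chrom, start, end, count, masked-aware ratio, log2

    @property
    def retained(self) -> pd.DataFrame:
        return self.bins[self.bins["mask"]]

    def to_tsv(self, path) -> None:
        self.bins.to_csv(path, sep="\t", index=False, float_format="%.6g")

    @classmethod
    def from_counts(
        cls,
        chrom: np.ndarray,
        start: np.ndarray,
        end: np.ndarray,
        count: np.ndarray,
        excluded_mask: np.ndarray | None = None,
    ) -> "BinTrack":
        """Build a normalized track from raw per-bin counts."""
        count = np.asarray(count, dtype=np.int64)
        if excluded_mask is None:
            excluded_mask = np.zeros(count.shape, dtype=bool)
        mask = (~excluded_mask) & (count > 0)
        if mask.sum() == 0:
            raise ValueError("no retained bins: all excluded or zero-count")
        mean_count = count[mask].mean()
        ratio = np.full(count.shape, np.nan)
        ratio[mask] = count[mask] / mean_count
        log_ratio = np.full(count.shape, np.nan)
        log_ratio[mask] = np.log2(ratio[mask])
        bins = pd.DataFrame(
            {
                "chrom": chrom,
                "start": start,
                "end": end,
                "count": count,
                "ratio": ratio,
                "log2_ratio": log_ratio,
                "mask": mask,
            }
        )
        return cls(bins)


def bintrack_from_log_ratio(
    log_ratio: np.ndarray,
    chrom: str = "chr1",
    bin_size: int = DEFAULT_BIN_SIZE,
) -> BinTrack:
    """Build a single-chromosome track directly from a log2-ratio signal.

    Convenience constructor for simulation studies that work on the
    ratio scale rather than on raw counts.
    """
    log_ratio = np.asarray(log_ratio, dtype=float)
    n = log_ratio.size
    starts = np.arange(n, dtype=np.int64) * bin_size
    bins = pd.DataFrame(
        {
            "chrom": np.repeat(chrom, n),
            "start": starts,
            "end": starts + bin_size,
            "count": np.zeros(n, dtype=np.int64),
            "ratio": 2.0**log_ratio,
            "log2_ratio": log_ratio,
            "mask": np.isfinite(log_ratio),
        }
    )
    return BinTrack(bins)


def count_bins(
    alignments: str,
    excluded: dict[str, np.ndarray] | None = None,
    bin_size: int = DEFAULT_BIN_SIZE,
    mapq_min: int = DEFAULT_MAPQ_MIN,
    chromosomes: list[str] | None = None,
) -> BinTrack:
    """Bin the genome and count MAPQ-filtered off-target read starts.

    A read is assigned to the bin containing its leftmost aligned
    position.  Unmapped, duplicate, secondary and supplementary reads are
    dropped, as are reads with MAPQ <= ``mapq_min`` (the filter is the
    strict "MAPQ > 30" of the pipeline) and reads starting inside an
    excluded (padded on-target) region.  Bins lying wholly inside
    excluded regions are masked.
    """
    if bin_size <= 0:
        raise ValueError("bin_size must be > 0")
    excluded = excluded or {}
    mode = "rb" if str(alignments).endswith(".bam") else "r"
    with pysam.AlignmentFile(str(alignments), mode) as af:
        if af.header.nreferences == 0:
            raise ValueError("alignment file has no sequence (@SQ) headers")
        refs = list(af.references)
        lengths = dict(zip(refs, af.lengths))
        if chromosomes is None:
            chromosomes = refs
        for c in chromosomes:
            if c not in lengths:
                raise ValueError(f"chromosome {c!r} absent from alignment headers")
        counts: dict[str, np.ndarray] = {
            c: np.zeros(-(-lengths[c] // bin_size), dtype=np.int64)
            for c in chromosomes
        }
        for read in af.fetch(until_eof=True):
            if read.is_unmapped or read.is_duplicate:
                continue
            if read.is_secondary or read.is_supplementary:
                continue
            if read.mapping_quality <= mapq_min:
                continue
            chrom = read.reference_name
            if chrom not in counts:
                continue
            pos = read.reference_start
            if _in_excluded(pos, excluded.get(chrom)):
                continue
            counts[chrom][pos // bin_size] += 1

    chrom_col, start_col, end_col, count_col, excl_col = [], [], [], [], []
    for c in chromosomes:
        n = len(counts[c])
        starts = np.arange(n, dtype=np.int64) * bin_size
        ends = np.minimum(starts + bin_size, lengths[c])
        iv = excluded.get(c)
        for b in range(n):
            wholly = False
            if iv is not None and len(iv):
                i = np.searchsorted(iv[:, 0], starts[b], side="right") - 1
                wholly = i >= 0 and iv[i, 0] <= starts[b] and ends[b] <= iv[i, 1]
            excl_col.append(wholly)
        chrom_col.extend([c] * n)
        start_col.extend(starts.tolist())
        end_col.extend(ends.tolist())
        count_col.extend(counts[c].tolist())
    return BinTrack.from_counts(
        np.asarray(chrom_col),
        np.asarray(start_col, dtype=np.int64),
        np.asarray(end_col, dtype=np.int64),
        np.asarray(count_col, dtype=np.int64),
        np.asarray(excl_col, dtype=bool),
    )


# ---------------------------------------------------------------------------
# Circular binary segmentation
# ---------------------------------------------------------------------------

def _max_arc_stat(x: np.ndarray) -> tuple[float, int, int]:
    """Maximal circular-arc t-like statistic over one batch of values.

    For every contiguous arc (i, j] the statistic compares the arc mean
    with the complement mean, standardized by the pooled per-bin variance.
    Wrap-around arcs equal the complement of contiguous arcs and give the
    same |Z|, so contiguous windows suffice.  Returns (max |Z|, i, j).
    """
    n = x.size
    sd = x.std()
    if sd == 0:
        return 0.0, 0, 0
    c = np.concatenate(([0.0], np.cumsum(x)))
    total = c[-1]
    best, best_i, best_j = 0.0, 0, 0
    for k in range(1, n):
        w = c[k:] - c[:-k]  # all window sums of length k
        z = (w / k - (total - w) / (n - k)) / (sd * np.sqrt(1.0 / k + 1.0 / (n - k)))
        a = np.abs(z)
        m = int(np.argmax(a))
        if a[m] > best:
            best, best_i, best_j = float(a[m]), m, m + k
    return best, best_i, best_j


def _perm_max_stats(x: np.ndarray, n_perm: int, rng: np.random.Generator,
                    stop_after: int | None = None,
                    observed: float | None = None) -> tuple[int, int]:
    """Count permutation max-statistics >= observed, with early rejection.

    Permutations run in chunks; once the exceedance count rules out
    significance at any level of interest the scan stops.  Returns
    (exceedances, permutations done).
    """
    n = x.size
    sd = x.std()
    exceed = 0
    done = 0
    chunk = 256
    while done < n_perm:
        b = min(chunk, n_perm - done)
        perm = rng.permuted(np.tile(x, (b, 1)), axis=1)
        c = np.concatenate(
            (np.zeros((b, 1)), np.cumsum(perm, axis=1)), axis=1
        )
        total = c[:, -1]
        best = np.zeros(b)
        for k in range(1, n):
            w = c[:, k:] - c[:, :-k]
            z = np.abs(
                (w / k - (total[:, None] - w) / (n - k))
                / (sd * np.sqrt(1.0 / k + 1.0 / (n - k)))
            )
            np.maximum(best, z.max(axis=1), out=best)
        exceed += int((best >= observed).sum())
        done += b
        if stop_after is not None and exceed > stop_after:
            break
    return exceed, done


def _best_binary_cut(x: np.ndarray, lo: int, hi: int) -> int:
    """Position in (lo, hi) best splitting x[lo:hi] into two segments.

    Maximizes the two-sample t-like statistic over cuts keeping both
    sides >= MIN_SEGMENT_BINS wide; returns the cut index (absolute).
    """
    seg = x[lo:hi]
    n = seg.size
    c = np.concatenate(([0.0], np.cumsum(seg)))
    total = c[-1]
    ks = np.arange(MIN_SEGMENT_BINS, n - MIN_SEGMENT_BINS + 1)
    left = c[ks] / ks
    right = (total - c[ks]) / (n - ks)
    z = np.abs(left - right) / np.sqrt(1.0 / ks + 1.0 / (n - ks))
    return lo + int(ks[np.argmax(z)])


def _refine_breakpoints(
    x: np.ndarray, breakpoints: list[int], max_passes: int = 20
) -> list[int]:
    """Iteratively re-locate breakpoints to locally optimal cuts.

    The recursive search can freeze a slightly misplaced boundary (the
    maximal arc's edge need not coincide with a true changepoint); each
    pass re-optimizes every breakpoint between its neighbours until the
    set is stable.
    """
    bps = sorted(breakpoints)
    n = x.size
    for _ in range(max_passes):
        moved = False
        for i, b in enumerate(bps):
            lo = bps[i - 1] if i > 0 else 0
            hi = bps[i + 1] if i + 1 < len(bps) else n
            if hi - lo < 2 * MIN_SEGMENT_BINS:
                continue
            new = _best_binary_cut(x, lo, hi)
            if new != b:
                bps[i] = new
                moved = True
        bps = sorted(set(bps))
        if not moved:
            break
    return bps


@dataclass
class Segment:
    chrom: str
    start: int
    end: int
    n_bins: int
    mean_ratio: float
    n_t: float = np.nan
    call: int = -1
    residual: float = np.nan


@dataclass
class SegmentProfile:
    """CBS segments with (after fitting) purity/ploidy and integer calls."""

    segments: list[Segment]
    rho: float = np.nan
    psi: float = np.nan
    distance: float = np.nan
    degenerate: bool = False

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "chrom": [s.chrom for s in self.segments],
                "start": [s.start for s in self.segments],
                "end": [s.end for s in self.segments],
                "n_bins": [s.n_bins for s in self.segments],
                "mean_ratio": [s.mean_ratio for s in self.segments],
                "n_T": [s.n_t for s in self.segments],
                "call": [s.call for s in self.segments],
                "residual": [s.residual for s in self.segments],
            }
        )

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False, float_format="%.6g")


def _cbs_recurse(
    log_ratio: np.ndarray,
    offset: int,
    alpha: float,
    n_perm: int,
    rng: np.random.Generator,
    breakpoints: list[int],
) -> None:
    n = log_ratio.size
    if n < 2 * MIN_SEGMENT_BINS:
        return
    stat, i, j = _max_arc_stat(log_ratio)
    if stat == 0.0:
        return
    # significance threshold on the exceedance count: p = (e+1)/(n_perm+1)
    max_exceed = int(np.floor(alpha * (n_perm + 1))) - 1
    exceed, done = _perm_max_stats(
        log_ratio, n_perm, rng, stop_after=max_exceed, observed=stat
    )
    if exceed > max_exceed:
        return  # split not significant
    # accept arc (i, j]: up to two changepoints inside this stretch
    cuts = sorted({c for c in (i, j) if MIN_SEGMENT_BINS <= c <= n - MIN_SEGMENT_BINS})
    if not cuts:
        return
    bounds = [0] + cuts + [n]
    for c in cuts:
        breakpoints.append(offset + c)
    for a, b in zip(bounds[:-1], bounds[1:]):
        _cbs_recurse(log_ratio[a:b], offset + a, alpha, n_perm, rng, breakpoints)


def segment_cbs(
    track: BinTrack,
    alpha: float = DEFAULT_CBS_ALPHA,
    n_perm: int = DEFAULT_CBS_NPERM,
    seed: int = 0,
) -> SegmentProfile:
    """Segment the log2 ratio track with circular binary segmentation.

    Recursively finds the arc maximizing the two-sample t-like statistic
    against its complement, accepts the split if the permutation p-value
    is below ``alpha``, and recurses.  Segments are reported per
    chromosome with their mean ratio computed on the linear scale (the
    purity/ploidy model is written in r, not log r).
    """
    retained = track.retained
    if len(retained) < 2:
        raise ValueError("need at least 2 unmasked bins to segment")
    rng = np.random.default_rng(seed)
    segments: list[Segment] = []
    for chrom, sub in retained.groupby("chrom", sort=False):
        lr = sub["log2_ratio"].to_numpy()
        r = sub["ratio"].to_numpy()
        starts = sub["start"].to_numpy()
        ends = sub["end"].to_numpy()
        breakpoints: list[int] = []
        if lr.size >= 2 * MIN_SEGMENT_BINS and not np.allclose(lr, lr[0]):
            _cbs_recurse(lr, 0, alpha, n_perm, rng, breakpoints)
            breakpoints = _refine_breakpoints(lr, breakpoints)
        bounds = [0] + sorted(breakpoints) + [lr.size]
        for a, b in zip(bounds[:-1], bounds[1:]):
            segments.append(
                Segment(
                    chrom=str(chrom),
                    start=int(starts[a]),
                    end=int(ends[b - 1]),
                    n_bins=b - a,
                    mean_ratio=float(r[a:b].mean()),
                )
            )
    return SegmentProfile(segments=segments)


# ---------------------------------------------------------------------------
# Purity / ploidy grid fit
# ---------------------------------------------------------------------------

@dataclass
class GridFitSurface:
    """Distance surface of the purity/ploidy fit over the (psi, rho) grid."""

    psi_values: np.ndarray = field(default_factory=lambda: PSI_GRID.copy())
    rho_values: np.ndarray = field(default_factory=lambda: RHO_GRID.copy())
    distance: np.ndarray | None = None  # shape (len(psi), len(rho))

    def to_tsv(self, path) -> None:
        df = pd.DataFrame(
            self.distance, index=self.psi_values, columns=self.rho_values
        )
        df.index.name = "psi"
        df.to_csv(path, sep="\t", float_format="%.10g")


def grid_distance_surface(
    mean_ratios: np.ndarray,
    weights: np.ndarray,
    psi_values: np.ndarray = PSI_GRID,
    rho_values: np.ndarray = RHO_GRID,
) -> np.ndarray:
    """Distance surface D(psi, rho) = sum_s w_s |n_T(s) - round(n_T(s))|.

    The nearest integer is floored at 0 (copy numbers are non-negative),
    which discards spurious exact fits whose implied copies are negative.
    Accumulates segment by segment with plain element-wise arithmetic so
    the result is bit-identical to a scalar triple loop in the same
    segment order.
    """
    psi = psi_values[:, None]
    rho = rho_values[None, :]
    dist = np.zeros((psi_values.size, rho_values.size))
    for r, w in zip(mean_ratios, weights):
        n_t = (psi * r - 2.0 * (1.0 - rho)) / rho
        dist += w * np.abs(n_t - np.maximum(np.round(n_t), 0.0))
    return dist


def fit_purity_ploidy(
    profile: SegmentProfile,
    weight_by_length: bool = False,
    psi_values: np.ndarray = PSI_GRID,
    rho_values: np.ndarray = RHO_GRID,
) -> tuple[float, float, GridFitSurface, SegmentProfile]:
    """Fit purity and ploidy by minimizing the integer-distance surface.

    For every grid point the per-segment tumour copy number is
    n_T = (psi * r - 2(1 - rho)) / rho; the distance is the (optionally
    bin-count-weighted) sum of |n_T - round(n_T)| over segments.  Ties
    break deterministically to the lowest psi, then the highest rho
    (the most parsimonious genome).  A ridge of near-equal minima spread
    in psi (> 0.1 apart within 1e-12 of the minimum) flags the fit as
    degenerate/unidentifiable.
    """
    ratios = np.asarray([s.mean_ratio for s in profile.segments], dtype=float)
    if ratios.size == 0 or not np.isfinite(ratios).any():
        raise ValueError("need at least one segment with finite mean ratio")
    keep = np.isfinite(ratios)
    ratios = ratios[keep]
    if weight_by_length:
        weights = np.asarray(
            [s.n_bins for s, k in zip(profile.segments, keep) if k], dtype=float
        )
    else:
        weights = np.ones(ratios.size)

    dist = grid_distance_surface(ratios, weights, psi_values, rho_values)
    dmin = dist.min()
    at_min = np.argwhere(dist <= dmin + DEGENERACY_TOL)
    # tie-break: lowest psi, then highest rho
    psi_idx = at_min[:, 0].min()
    rho_idx = at_min[at_min[:, 0] == psi_idx][:, 1].max()
    rho_star = float(rho_values[rho_idx])
    psi_star = float(psi_values[psi_idx])
    psi_spread = psi_values[at_min[:, 0].max()] - psi_values[at_min[:, 0].min()]
    degenerate = bool(psi_spread > DEGENERACY_PSI_SPAN)

    surface = GridFitSurface(
        psi_values=np.asarray(psi_values), rho_values=np.asarray(rho_values),
        distance=dist,
    )
    fitted = assign_copies(profile, rho_star, psi_star)
    fitted.distance = float(dist[psi_idx, rho_idx])
    fitted.degenerate = degenerate
    return rho_star, psi_star, surface, fitted


def assign_copies(
    profile: SegmentProfile, rho: float, psi: float
) -> SegmentProfile:
    """Assign real-valued n_T and integer copy calls at a (rho, psi) fit.

    n_T = (psi * r - 2(1 - rho)) / rho per segment; the integer call is
    max(0, round(n_T)); the residual |n_T - call| is reported.
    """
    out = []
    for s in profile.segments:
        n_t = (psi * s.mean_ratio - 2.0 * (1.0 - rho)) / rho
        call = max(0, int(np.round(n_t)))
        out.append(
            Segment(
                chrom=s.chrom, start=s.start, end=s.end, n_bins=s.n_bins,
                mean_ratio=s.mean_ratio, n_t=float(n_t), call=call,
                residual=float(abs(n_t - call)),
            )
        )
    return SegmentProfile(segments=out, rho=rho, psi=psi)


def expected_ratio(n_t: np.ndarray | float, rho: float, psi: float):
    """Forward mixture model: r = (n_T rho + 2(1 - rho)) / psi."""
    return (np.asarray(n_t, dtype=float) * rho + 2.0 * (1.0 - rho)) / psi


# ---------------------------------------------------------------------------
# On-target exon-level copy ratio
# ---------------------------------------------------------------------------

def exon_copy_ratio(
    alignments: str,
    exon_targets: pd.DataFrame,
    reference_counts: pd.DataFrame,
    mapq_min: int = DEFAULT_MAPQ_MIN,
    rescale_diploid: bool = False,
) -> pd.DataFrame:
    """Per-exon copy ratio against a diploid reference sample.

    Counts MAPQ-filtered reads overlapping the centre base of each exon
    target and divides by the reference sample's count at the same
    centre (normalizing for target-capture efficiency).  Exons whose
    reference count is zero get an undefined (NaN) ratio with a warning.
    ``rescale_diploid`` multiplies ratios by 2 to put them on the copy
    scale of the diploid reference.
    """
    ref = reference_counts.set_index(["chrom", "start", "end"])["count"]
    missing = [
        t for t in exon_targets.itertuples(index=False)
        if (t.chrom, t.start, t.end) not in ref.index
    ]
    if missing:
        raise ValueError(
            f"reference_counts missing {len(missing)} exon target(s), "
            f"first: {missing[0]}"
        )
    centres = [
        (t.chrom, (int(t.start) + int(t.end)) // 2)
        for t in exon_targets.itertuples(index=False)
    ]
    depths = np.zeros(len(centres), dtype=np.int64)
    by_chrom: dict[str, list[tuple[int, int]]] = {}
    for i, (chrom, centre) in enumerate(centres):
        by_chrom.setdefault(chrom, []).append((centre, i))
    for chrom in by_chrom:
        by_chrom[chrom].sort()
    mode = "rb" if str(alignments).endswith(".bam") else "r"
    with pysam.AlignmentFile(str(alignments), mode) as af:
        for read in af.fetch(until_eof=True):
            if read.is_unmapped or read.is_duplicate:
                continue
            if read.is_secondary or read.is_supplementary:
                continue
            if read.mapping_quality <= mapq_min:
                continue
            chrom_centres = by_chrom.get(read.reference_name)
            if not chrom_centres:
                continue
            start, end = read.reference_start, read.reference_end
            for centre, i in chrom_centres:
                if start <= centre < end:
                    depths[i] += 1
                elif centre >= end:
                    break
    rows = []
    for i, t in enumerate(exon_targets.itertuples(index=False)):
        centre = centres[i][1]
        depth = int(depths[i])
        ref_count = ref.loc[(t.chrom, t.start, t.end)]
        if ref_count <= 0:
            warnings.warn(
                f"reference count 0 at {t.chrom}:{t.start}-{t.end}; "
                "ratio undefined",
                stacklevel=2,
            )
            ratio = np.nan
        else:
            ratio = depth / ref_count
            if rescale_diploid:
                ratio *= 2.0
        rows.append(
            {
                "chrom": t.chrom, "start": t.start, "end": t.end,
                "centre": centre, "count": depth,
                "reference_count": int(ref_count), "ratio": ratio,
            }
        )
    return pd.DataFrame(rows)


def read_bed(path) -> pd.DataFrame:
    """Read a 3+ column BED file (0-based half-open) into a frame."""
    df = pd.read_csv(
        path, sep="\t", header=None, comment="#",
        usecols=[0, 1, 2], names=["chrom", "start", "end"],
        dtype={"chrom": str, "start": np.int64, "end": np.int64},
    )
    return df
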