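"""Synthetic inputs with known ground truth for every pipeline stage.

Each generator emulates the statistical structure the corresponding
analysis assumes, so the whole pipeline is verifiable without patient
data:

* binned off-target read counts under a clonal integer copy-number
  profile diluted with diploid normal cells (negative-binomial noise,
  Poisson in the zero-dispersion limit);
* spliced RNA-seq reads over a multi-exon gene with controllable
  aberrant (exon-skipping or otherwise non-canonical) isoforms, with an
  exhaustive-placement enumeration of the per-exon ground truth;
* 2D-gel spot-volume tables spanning the three CDK4 profile classes;
* expression + survival cohorts with group-dependent exponential
  hazards and independent exponential censoring.

All generators are pure functions of their inputs and seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import pysam

from .cnv import BinTrack, expected_ratio
from .splice import (
    ExonModel,
    ExpectedUpstreamSets,
    _five_prime_start,
    expected_upstream,
)

# ---------------------------------------------------------------------------
# Off-target copy-number counts
# ---------------------------------------------------------------------------


@dataclass
class TruthCNProfile:
    """Ground-truth clonal copy-number profile of a simulated tumour.

    ``segments`` are (chrom, start, end, n_T) with integer tumour copy
    numbers, contiguous within each chromosome.  ``purity`` is the
    tumour cell fraction rho; the average ploidy psi is derived as the
    length-weighted mean of n_T.  ``mean_depth`` is the expected reads
    per bin at ratio 1; ``dispersion`` is the relative extra-Poisson
    variance of the negative-binomial counts (variance = (1 +
    dispersion) * mean, realized with NB size = mean / dispersion;
    0 degrades to Poisson).
    """

    segments: list[tuple[str, int, int, int]]
    purity: float
    mean_depth: float = 200.0
    dispersion: float = 0.05

    def __post_init__(self) -> None:
        if not 0 < self.purity <= 1:
            raise ValueError("purity must be in (0, 1]")
        if self.mean_depth <= 0:
            raise ValueError("mean_depth must be > 0")
        if self.dispersion < 0:
            raise ValueError("dispersion must be >= 0")
        by_chrom: dict[str, list[tuple[int, int, int]]] = {}
        for chrom, start, end, n_t in self.segments:
            if end <= start:
                raise ValueError("segment end must exceed start")
            if n_t < 0 or int(n_t) != n_t:
                raise ValueError("n_T must be a non-negative integer")
            by_chrom.setdefault(chrom, []).append((start, end, n_t))
        for chrom, segs in by_chrom.items():
            segs.sort()
            for (s1, e1, _), (s2, e2, _) in zip(segs[:-1], segs[1:]):
                if s2 < e1:
                    raise ValueError(f"overlapping segments on {chrom}")

    @property
    def ploidy(self) -> float:
        """Tumour ploidy: length-weighted mean copy number of tumour cells."""
        lengths = np.asarray([e - s for _, s, e, _ in self.segments], dtype=float)
        copies = np.asarray([n for _, _, _, n in self.segments], dtype=float)
        return float((lengths * copies).sum() / lengths.sum())

    @property
    def sample_ploidy(self) -> float:
        """Average copy number of the sequenced cell mixture.

        psi_s = rho * psi_tumour + 2 (1 - rho).  Because the ratio track
        is normalized to mean 1 (r = count / mean count), this mixture
        average is the ploidy scale on which the grid fit operates and
        the quantity it recovers.
        """
        return self.purity * self.ploidy + 2.0 * (1.0 - self.purity)


def simulate_offtarget_counts(
    profile: TruthCNProfile,
    bin_size: int = 30_000,
    seed: int = 0,
) -> tuple[BinTrack, pd.DataFrame]:
    """Draw binned off-target read counts under a copy-number profile.

    Bins tile each chromosome's segmented span; each bin's expected
    count is mean_depth * r with r = (n_T rho + 2(1 - rho)) / psi for
    the segment containing the bin start.  A gap between segments that
    leaves a bin uncovered rejects the input.  Returns the normalized
    track and a truth table carrying (rho, psi, per-bin n_T, r).
    """
    if bin_size <= 0:
        raise ValueError("bin_size must be > 0")
    rng = np.random.default_rng(seed)
    psi = profile.ploidy
    rho = profile.purity

    by_chrom: dict[str, list[tuple[int, int, int]]] = {}
    for chrom, start, end, n_t in profile.segments:
        by_chrom.setdefault(chrom, []).append((start, end, n_t))
    rows = []
    for chrom, segs in by_chrom.items():
        segs.sort()
        for (s1, e1, _), (s2, _, _) in zip(segs[:-1], segs[1:]):
            if s2 != e1:
                raise ValueError(
                    f"segment gap on {chrom} at {e1}..{s2} leaves bins uncovered"
                )
        lo, hi = segs[0][0], segs[-1][1]
        starts = np.arange(lo, hi, bin_size, dtype=np.int64)
        ends = np.minimum(starts + bin_size, hi)
        seg_starts = np.asarray([s for s, _, _ in segs])
        seg_idx = np.searchsorted(seg_starts, starts, side="right") - 1
        for b, (bs, be) in enumerate(zip(starts, ends)):
            n_t = segs[seg_idx[b]][2]
            rows.append((chrom, int(bs), int(be), n_t))
    truth = pd.DataFrame(rows, columns=["chrom", "start", "end", "n_T"])
    truth["r"] = expected_ratio(truth["n_T"].to_numpy(), rho, psi)
    mean = profile.mean_depth * truth["r"].to_numpy()
    if profile.dispersion == 0:
        counts = rng.poisson(mean)
    else:
        # NB as gamma-Poisson with size = m/d: variance = m * (1 + d)
        size = mean / profile.dispersion
        lam = rng.gamma(shape=size, scale=mean / size)
        counts = rng.poisson(lam)
    truth["expected_count"] = mean
    truth["rho"] = rho
    truth["psi_tumour"] = psi
    truth["psi_sample"] = profile.sample_ploidy
    track = BinTrack.from_counts(
        truth["chrom"].to_numpy(),
        truth["start"].to_numpy(),
        truth["end"].to_numpy(),
        counts,
    )
    return track, truth


# ---------------------------------------------------------------------------
# Spliced RNA-seq reads
# ---------------------------------------------------------------------------


@dataclass
class TruthTranscriptMix:
    """Isoform mixture for the spliced-read simulator.

    ``isoforms`` holds (exon-rank tuple, mixing fraction) pairs; ranks
    are 0-based in transcription order and strictly increasing within
    each isoform; fractions are >= 0 and sum to 1.
    """

    isoforms: list[tuple[tuple[int, ...], float]]
    read_length: int = 97
    n_reads: int = 2000
    seed: int = 0

    def __post_init__(self) -> None:
        fracs = np.asarray([f for _, f in self.isoforms], dtype=float)
        if (fracs < 0).any() or not np.isclose(fracs.sum(), 1.0):
            raise ValueError("mixing fractions must be >= 0 and sum to 1")
        for ranks, _ in self.isoforms:
            if list(ranks) != sorted(set(ranks)):
                raise ValueError("exon ranks must be strictly increasing")


def _isoform_blocks(model: ExonModel, ranks: tuple[int, ...]) -> list[tuple[int, int]]:
    """Genomic exon blocks of an isoform, sorted left to right."""
    for r in ranks:
        if not 0 <= r < len(model.exons):
            raise ValueError(f"exon rank {r} not in the model")
    return sorted(model.exons[r] for r in ranks)


def _placement_blocks(
    blocks: list[tuple[int, int]],
    spliced_start: int,
    read_length: int,
    strand: str,
) -> list[tuple[int, int]]:
    """Genomic blocks covered by a read at a spliced-coordinate offset.

    Spliced coordinates run 5'->3' along the isoform; on the minus
    strand that is right to left in genomic space, so the interval is
    mirrored before mapping through the cumulative block lengths.
    """
    lengths = [e - s for s, e in blocks]
    total = sum(lengths)
    a = spliced_start
    b = spliced_start + read_length
    if strand == "-":
        a, b = total - b, total - a
    out = []
    offset = 0
    for (s, e), ln in zip(blocks, lengths):
        lo = max(a, offset)
        hi = min(b, offset + ln)
        if lo < hi:
            out.append((s + (lo - offset), s + (hi - offset)))
        offset += ln
    return out


def _blocks_to_cigar(blocks: list[tuple[int, int]]) -> list[tuple[int, int]]:
    cigar = []
    for i, (s, e) in enumerate(blocks):
        if i > 0:
            gap = s - blocks[i - 1][1]
            cigar.append((3, gap))  # N
        cigar.append((0, e - s))  # M
    return cigar


def simulate_spliced_reads(
    model: ExonModel,
    mix: TruthTranscriptMix,
    sam_path: str | None = None,
) -> tuple[list[dict], pd.DataFrame]:
    """Place reads uniformly along each sampled isoform's spliced sequence.

    Reads are converted to genomic start + CIGAR (N operations span the
    skipped introns/exons) and optionally written as SAM with @SQ
    headers.  An isoform shorter than the read length is rejected.  The
    per-exon ground truth (expected/informative weights under exhaustive
    enumeration of every placement) accompanies the reads.
    """
    rng = np.random.default_rng(mix.seed)
    iso_blocks = []
    for ranks, frac in mix.isoforms:
        blocks = _isoform_blocks(model, ranks)
        total = sum(e - s for s, e in blocks)
        if mix.read_length > total:
            raise ValueError(
                f"read_length {mix.read_length} exceeds spliced length "
                f"{total} of isoform {ranks}"
            )
        iso_blocks.append(blocks)
    fracs = np.asarray([f for _, f in mix.isoforms], dtype=float)
    choice = rng.choice(len(mix.isoforms), size=mix.n_reads, p=fracs)
    reads = []
    for i, iso in enumerate(choice):
        blocks = iso_blocks[iso]
        total = sum(e - s for s, e in blocks)
        o = int(rng.integers(0, total - mix.read_length + 1))
        rblocks = _placement_blocks(blocks, o, mix.read_length, model.strand)
        reads.append(
            {
                "name": f"read_{i}",
                "chrom": model.chrom,
                "start": rblocks[0][0],
                "cigar": _blocks_to_cigar(rblocks),
                "blocks": rblocks,
            }
        )
    truth = enumerate_placement_truth(model, mix)
    if sam_path is not None:
        write_sam(reads, model, sam_path)
    return reads, truth


def enumerate_placement_truth(
    model: ExonModel,
    mix: TruthTranscriptMix,
    sets: ExpectedUpstreamSets | None = None,
) -> pd.DataFrame:
    """Exhaustive-placement expectation of the splicing-ratio statistic.

    Enumerates every read placement of every isoform, weights it by the
    isoform fraction over its number of placements, and tallies
    informative and expected weight per exon exactly as the ratio
    reader counts reads.  Also reports the expected fraction of
    noncanonical splice gaps.
    """
    if sets is None:
        sets = expected_upstream(model)
    anchor = model.upstream_anchor
    introns = set(model.introns)
    n_exons = len(model.exons)
    informative = np.zeros(n_exons)
    expected = np.zeros(n_exons)
    gap_total = 0.0
    gap_noncanonical = 0.0
    for ranks, frac in mix.isoforms:
        if frac == 0:
            continue
        blocks = _isoform_blocks(model, ranks)
        total = sum(e - s for s, e in blocks)
        n_place = total - mix.read_length + 1
        w = frac / n_place
        for o in range(n_place):
            rblocks = _placement_blocks(blocks, o, mix.read_length, model.strand)
            start5 = _five_prime_start(
                rblocks[0][0], rblocks[-1][1], model.strand
            )
            for k, (es, ee) in enumerate(model.exons):
                if not any(s < ee and es < e for s, e in rblocks):
                    continue
                informative[k] += w
                for j in sets.sets[k]:
                    js, je = anchor if j == -1 else model.exons[j]
                    if js <= start5 < je:
                        expected[k] += w
                        break
            for (s1, e1), (s2, e2) in zip(rblocks[:-1], rblocks[1:]):
                gap_total += w
                if (e1, s2) not in introns:
                    gap_noncanonical += w
    with np.errstate(invalid="ignore", divide="ignore"):
        ratio = np.where(informative > 0, expected / informative, np.nan)
    df = pd.DataFrame(
        {
            "exon_rank": np.arange(1, n_exons + 1),
            "informative_weight": informative,
            "expected_weight": expected,
            "true_ratio": ratio,
        }
    )
    df.attrs["noncanonical_gap_fraction"] = (
        gap_noncanonical / gap_total if gap_total > 0 else float("nan")
    )
    return df


def write_sam(reads: list[dict], model: ExonModel, path: str) -> None:
    """Write simulated reads as SAM with an @SQ header for the contig."""
    ref_len = model.span[1] + 10_000
    header = {
        "HD": {"VN": "1.6", "SO": "coordinate"},
        "SQ": [{"SN": model.chrom, "LN": int(ref_len)}],
    }
    reads = sorted(reads, key=lambda r: r["start"])
    with pysam.AlignmentFile(str(path), "w", header=header) as out:
        for r in reads:
            a = pysam.AlignedSegment(out.header)
            a.query_name = r["name"]
            a.reference_name = r["chrom"]
            a.reference_start = r["start"]
            a.cigartuples = r["cigar"]
            a.mapping_quality = 60
            a.flag = 0
            length = sum(ln for op, ln in r["cigar"] if op == 0)
            a.query_sequence = "A" * length
            out.write(a)


# ---------------------------------------------------------------------------
# 2D-gel spot tables
# ---------------------------------------------------------------------------

# sampling intervals strictly inside each profile class
_CLASS_RATIO_RANGES = {"A": (0.002, 0.023), "L": (0.05, 0.45), "H": (0.6, 3.0)}


def simulate_spot_table(
    n_per_class: tuple[int, int, int] = (5, 5, 5),
    seed: int = 0,
) -> pd.DataFrame:
    """Spot-volume table with true spot3/spot2 ratios inside each class.

    ``n_per_class`` gives the number of samples for profiles (A, L, H)
    in that order.  Spot 2 volumes are log-uniform over a plausible
    densitometry range; spot 3 = ratio * spot 2.
    """
    rng = np.random.default_rng(seed)
    rows = []
    for cls, n in zip("ALH", n_per_class):
        if n < 0:
            raise ValueError("n_per_class entries must be >= 0")
        lo, hi = _CLASS_RATIO_RANGES[cls]
        for i in range(n):
            ratio = float(rng.uniform(lo, hi))
            spot2 = float(10 ** rng.uniform(4.5, 5.8))
            rows.append(
                {
                    "sample_id": f"{cls}{i + 1}",
                    "spot2_volume": spot2,
                    "spot3_volume": ratio * spot2,
                    "true_ratio": ratio,
                    "true_profile": cls,
                }
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Expression + survival cohorts
# ---------------------------------------------------------------------------


@dataclass
class TruthCohort:
    """Cohort generator settings: group hazards and expression means.

    ``hazard_by_group`` and ``censor_rate`` are exponential rates per
    month; ``expression_means`` maps gene -> group -> CP20M-scale mean.
    """

    n_patients: int
    group_assignments: list[str]
    hazard_by_group: dict[str, float]
    censor_rate: float = 0.02
    expression_means: dict[str, dict[str, float]] = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.group_assignments) != self.n_patients:
            raise ValueError("one group label per patient required")
        groups = set(self.group_assignments)
        if not groups:
            raise ValueError("at least one group required")
        for g in groups:
            if self.hazard_by_group.get(g, 0) <= 0:
                raise ValueError(f"hazard for group {g!r} must be > 0")
        if self.censor_rate <= 0:
            raise ValueError("censor_rate must be > 0")


_COHORT_LIBRARY = int(2e7)  # fixed library size: CP20M equals raw counts


def simulate_cohort(truth: TruthCohort) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate a genes x samples count matrix and a survival table.

    Survival times are exponential with the patient's group hazard,
    censored by an independent exponential clock; expression counts are
    Poisson around the group's CP20M mean at a fixed 2e7 library (a
    filler gene absorbs the remaining library mass so column sums equal
    the library size exactly).
    """
    rng = np.random.default_rng(truth.seed)
    samples = [f"P{i + 1:03d}" for i in range(truth.n_patients)]
    groups = np.asarray(truth.group_assignments)
    hazards = np.asarray([truth.hazard_by_group[g] for g in groups])
    t_event = rng.exponential(1.0 / hazards)
    t_censor = rng.exponential(1.0 / truth.censor_rate, size=truth.n_patients)
    time = np.minimum(t_event, t_censor)
    event = (t_event <= t_censor).astype(int)
    surv = pd.DataFrame(
        {
            "sample_id": samples,
            "time_months": time,
            "event": event,
            "group": groups,
        }
    )
    genes = sorted(truth.expression_means)
    data = {}
    for s, g in zip(samples, groups):
        col = np.asarray(
            [rng.poisson(truth.expression_means[gene][g]) for gene in genes],
            dtype=np.int64,
        )
        filler = _COHORT_LIBRARY - col.sum()
        if filler < 0:
            raise ValueError("expression means exceed the library size")
        data[s] = np.concatenate((col, [filler]))
    counts = pd.DataFrame(data, index=genes + ["FILLER"], dtype=np.int64)
    return counts, surv
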