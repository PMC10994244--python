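"""Per-exon expected splicing ratio of a gene from RNA-seq alignments.

For each exon of a gene, a read overlapping the exon is "expected" if
its transcription-wise start lies inside one of the upstream exons whose
sequence a canonically spliced read of the library read length could
contain while still reaching the considered exon.  The fraction of
expected reads among informative (overlapping) reads is the expected
splicing ratio; values below 1 flag aberrant splicing or partial
deletions, and exons covered by fewer than ``min_reads`` reads are
masked as not informative.  A companion screen counts the fraction of
spliced (CIGAR N) gaps that do not match annotated introns.
"""

from __future__ import annotations

import os
from dataclasses import dataclass

import gffutils
import numpy as np
import pandas as pd
import pysam

DEFAULT_READ_LENGTH = 97
DEFAULT_MIN_READS = 10
UPSTREAM_ANCHOR_LENGTH = 200  # promoter pseudo-exon 5' of the TSS


# ---------------------------------------------------------------------------
# Exon model
# ---------------------------------------------------------------------------

@dataclass
class ExonModel:
    """Merged exon intervals of one gene, ordered in transcription direction.

    Coordinates are 0-based half-open internally.  ``exons`` is ordered
    5'->3' (reversed genomic order on the minus strand).  The upstream
    anchor is a 200-nt pseudo-exon immediately 5' of the transcription
    start site, where promoter-proximal read starts still count as
    expected.
    """

    gene_id: str
    chrom: str
    strand: str
    exons: list[tuple[int, int]]  # 5'->3' order, 0-based half-open
    read_length: int = DEFAULT_READ_LENGTH

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError("strand must be '+' or '-'")
        for s, e in self.exons:
            if e <= s:
                raise ValueError(f"zero-length exon [{s}, {e})")
        genomic = sorted(self.exons)
        for (s1, e1), (s2, e2) in zip(genomic[:-1], genomic[1:]):
            if s2 < e1:
                raise ValueError("exons overlap; merge before building the model")

    @property
    def exon_lengths(self) -> np.ndarray:
        return np.asarray([e - s for s, e in self.exons], dtype=np.int64)

    @property
    def introns(self) -> list[tuple[int, int]]:
        """Inter-exon gaps in genomic coordinates (0-based half-open)."""
        genomic = sorted(self.exons)
        return [
            (e1, s2) for (s1, e1), (s2, e2) in zip(genomic[:-1], genomic[1:])
        ]

    @property
    def tss(self) -> int:
        """Transcription start: leftmost base (+) or rightmost-1 base (-)."""
        if self.strand == "+":
            return min(s for s, _ in self.exons)
        return max(e for _, e in self.exons) - 1

    @property
    def upstream_anchor(self) -> tuple[int, int]:
        """Genomic interval of the 200-nt promoter pseudo-exon."""
        if self.strand == "+":
            start = max(0, self.tss - UPSTREAM_ANCHOR_LENGTH)
            return (start, self.tss)
        return (self.tss + 1, self.tss + 1 + UPSTREAM_ANCHOR_LENGTH)

    @property
    def span(self) -> tuple[int, int]:
        genomic = sorted(self.exons)
        return (genomic[0][0], genomic[-1][1])


def build_exon_model(
    annotation: str,
    gene_id: str,
    read_length: int = DEFAULT_READ_LENGTH,
) -> ExonModel:
    """Extract and merge a gene's exons from a GTF annotation.

    Overlapping exon records (e.g. from multiple transcripts) are merged
    into one interval per cluster; the list is then ordered 5'->3' by
    strand.  GTF coordinates are 1-based inclusive and converted to
    0-based half-open internally.
    """
    db = gffutils.create_db(
        str(annotation),
        dbfn=":memory:",
        force=True,
        keep_order=True,
        merge_strategy="merge",
        disable_infer_genes=True,
        disable_infer_transcripts=True,
    )
    exon_rows = []
    strand = None
    chrom = None
    for feat in db.all_features(featuretype="exon"):
        gid = feat.attributes.get("gene_id", [None])[0]
        if gid != gene_id:
            continue
        start0 = feat.start - 1  # GTF 1-based inclusive -> 0-based half-open
        end0 = feat.end
        if end0 <= start0:
            raise ValueError(f"zero-length exon in annotation at {feat.start}")
        exon_rows.append((start0, end0))
        strand = feat.strand
        chrom = feat.seqid
    if not exon_rows:
        raise ValueError(f"gene {gene_id!r} not found in annotation (no exons)")
    exon_rows.sort()
    merged: list[list[int]] = []
    for s, e in exon_rows:
        if merged and s <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    exons = [(s, e) for s, e in merged]
    if strand == "-":
        exons = exons[::-1]
    return ExonModel(
        gene_id=gene_id, chrom=str(chrom), strand=str(strand),
        exons=exons, read_length=read_length,
    )


# ---------------------------------------------------------------------------
# Expected-upstream sets
# ---------------------------------------------------------------------------

@dataclass
class ExpectedUpstreamSets:
    """Per exon k (0-based rank), the upstream exon ranks a canonical read
    ending in k may start in.  Rank -1 denotes the promoter anchor."""

    sets: list[set[int]]


def _reachable(lengths: np.ndarray, j: int, k: int, read_length: int) -> bool:
    """Can a read of ``read_length`` nt ending in exon k start in exon j?

    The limiting read ends on exon k's first base and extends
    read_length - 1 nt upstream in spliced coordinates, so exon j (< k)
    is reachable iff the exonic length strictly between j and k is
    < read_length - 1.  This boundary convention is isolated here.
    """
    between = int(lengths[j + 1:k].sum())
    return between < read_length - 1


def expected_upstream(model: ExonModel) -> ExpectedUpstreamSets:
    """Compute each exon's set of expected upstream start exons.

    Exon k always contains itself; upstream exons are included while the
    spliced distance allows a canonical read to bridge them (the sets
    are therefore suffix-contiguous).  The promoter anchor (rank -1,
    treated as a 200-nt pseudo-exon before exon 0) joins the set when
    reachable the same way.
    """
    lengths = model.exon_lengths
    # prepend the anchor as pseudo-exon at rank -1
    ext = np.concatenate(([UPSTREAM_ANCHOR_LENGTH], lengths))
    sets: list[set[int]] = []
    for k in range(lengths.size):
        members = {k}
        for j in range(k - 1, -2, -1):
            # ranks shift by +1 in the extended length vector
            if _reachable(ext, j + 1, k + 1, model.read_length):
                members.add(j)
            else:
                break
        sets.append(members)
    return ExpectedUpstreamSets(sets=sets)


# ---------------------------------------------------------------------------
# Ratio computation from alignments
# ---------------------------------------------------------------------------

@dataclass
class SpliceRatioColumn:
    """One sample's per-exon ratios with informative-read counts."""

    sample: str
    ratio: np.ndarray  # NaN where not informative
    informative_reads: np.ndarray
    expected_reads: np.ndarray


def _read_blocks(read: "pysam.AlignedSegment") -> list[tuple[int, int]]:
    """Aligned reference blocks (M/=/X), merging abutting blocks."""
    blocks = read.get_blocks()
    merged: list[list[int]] = []
    for s, e in blocks:
        if merged and s == merged[-1][1]:
            merged[-1][1] = e
        else:
            merged.append([s, e])
    return [(s, e) for s, e in merged]


def _five_prime_start(read_start: int, read_end: int, strand: str) -> int:
    """Transcription-wise start base of the read on the gene's strand."""
    return read_start if strand == "+" else read_end - 1


def compute_ratio(
    alignments: str,
    model: ExonModel,
    sets: ExpectedUpstreamSets | None = None,
    min_reads: int = DEFAULT_MIN_READS,
    sample: str | None = None,
) -> SpliceRatioColumn:
    """Expected splicing ratio per exon for one sample.

    A read is informative for exon k when one of its aligned blocks
    overlaps the exon by at least one base; it is expected when its
    transcription-wise start base lies inside an exon of k's expected
    set or inside the promoter anchor (when the anchor is in the set).
    Exons with fewer than ``min_reads`` informative reads are reported
    as NaN (not informative).
    """
    if sets is None:
        sets = expected_upstream(model)
    n_exons = len(model.exons)
    informative = np.zeros(n_exons, dtype=np.int64)
    expected = np.zeros(n_exons, dtype=np.int64)
    span = model.span
    anchor = model.upstream_anchor
    mode = "rb" if str(alignments).endswith(".bam") else "r"
    with pysam.AlignmentFile(str(alignments), mode) as af:
        try:
            reads = af.fetch(model.chrom, max(0, span[0] - 10000), span[1] + 10000)
        except ValueError:
            reads = (
                r for r in af.fetch(until_eof=True)
                if r.reference_name == model.chrom
            )
        for read in reads:
            if read.is_unmapped or read.is_secondary or read.is_supplementary:
                continue
            blocks = _read_blocks(read)
            if not blocks:
                continue
            start5 = _five_prime_start(blocks[0][0], blocks[-1][1], model.strand)
            for k, (es, ee) in enumerate(model.exons):
                overlaps = any(s < ee and es < e for s, e in blocks)
                if not overlaps:
                    continue
                informative[k] += 1
                ok = False
                for j in sets.sets[k]:
                    if j == -1:
                        js, je = anchor
                    else:
                        js, je = model.exons[j]
                    if js <= start5 < je:
                        ok = True
                        break
                if ok:
                    expected[k] += 1
    ratio = np.full(n_exons, np.nan)
    has = informative >= min_reads
    ratio[has] = expected[has] / informative[has]
    name = sample or os.path.basename(str(alignments))
    return SpliceRatioColumn(
        sample=name, ratio=ratio,
        informative_reads=informative, expected_reads=expected,
    )


def noncanonical_junction_fraction(
    alignments: str,
    model: ExonModel,
) -> float:
    """Fraction of spliced-read gaps that match no annotated intron.

    Every N operation in a read's CIGAR defines a gap with genomic
    boundaries; the gap is canonical iff it coincides exactly with one
    of the gene's annotated introns.  Returns noncanonical / total gaps
    over the gene span (NaN if no gapped read is seen).
    """
    introns = set(model.introns)
    span = model.span
    total = 0
    noncanonical = 0
    mode = "rb" if str(alignments).endswith(".bam") else "r"
    with pysam.AlignmentFile(str(alignments), mode) as af:
        try:
            reads = af.fetch(model.chrom, max(0, span[0] - 10000), span[1] + 10000)
        except ValueError:
            reads = (
                r for r in af.fetch(until_eof=True)
                if r.reference_name == model.chrom
            )
        for read in reads:
            if read.is_unmapped or read.is_secondary or read.is_supplementary:
                continue
            if read.cigartuples is None:
                continue
            pos = read.reference_start
            for op, length in read.cigartuples:
                if op in (0, 7, 8, 2):  # M, =, X, D consume reference
                    pos += length
                elif op == 3:  # N: spliced gap
                    gap = (pos, pos + length)
                    total += 1
                    if gap not in introns:
                        noncanonical += 1
                    pos += length
    if total == 0:
        return float("nan")
    return noncanonical / total


# ---------------------------------------------------------------------------
# Matrix assembly
# ---------------------------------------------------------------------------

@dataclass
class SpliceRatioMatrix:
    """Exon x sample matrix of expected splicing ratios (NaN = masked)."""

    exon_labels: list[str]
    samples: list[str]
    values: np.ndarray
    informative_reads: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values, index=self.exon_labels, columns=self.samples
        )

    def to_tsv(self, path) -> None:
        df = self.to_frame()
        df.index.name = "exon"
        df.to_csv(path, sep="\t", na_rep="NA", float_format="%.6g")


def assemble_matrix(
    columns: list[SpliceRatioColumn],
    model: ExonModel,
    heatmap_path: str | None = None,
) -> SpliceRatioMatrix | None:
    """Assemble per-sample columns into the exon x sample ratio matrix.

    Exon rows are labelled by rank and genomic coordinates (1-based, to
    match annotation conventions).  Optionally renders a heatmap in
    which not-informative cells are black.
    """
    if not columns:
        return None
    names = [c.sample for c in columns]
    if len(set(names)) != len(names):
        raise ValueError("duplicate sample labels")
    n_exons = len(model.exons)
    for c in columns:
        if c.ratio.size != n_exons:
            raise ValueError("column does not match the exon model")
    labels = [
        f"exon_{k + 1}:{model.chrom}:{s + 1}-{e}"
        for k, (s, e) in enumerate(model.exons)
    ]
    values = np.column_stack([c.ratio for c in columns])
    informative = np.column_stack([c.informative_reads for c in columns])
    matrix = SpliceRatioMatrix(
        exon_labels=labels, samples=names,
        values=values, informative_reads=informative,
    )
    if heatmap_path is not None:
        _render_heatmap(matrix, heatmap_path)
    return matrix


def _render_heatmap(matrix: SpliceRatioMatrix, path: str) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    data = np.ma.masked_invalid(matrix.values)
    cmap = plt.get_cmap("viridis").copy()
    cmap.set_bad("black")
    fig, ax = plt.subplots(
        figsize=(max(4, 0.5 * len(matrix.samples)),
                 max(3, 0.3 * len(matrix.exon_labels))),
    )
    im = ax.imshow(data, aspect="auto", cmap=cmap, vmin=0.0, vmax=1.0)
    ax.set_xticks(range(len(matrix.samples)))
    ax.set_xticklabels(matrix.samples, rotation=90, fontsize=7)
    ax.set_yticks(range(len(matrix.exon_labels)))
    ax.set_yticklabels(matrix.exon_labels, fontsize=6)
    fig.colorbar(im, ax=ax, label="expected splicing ratio")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
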