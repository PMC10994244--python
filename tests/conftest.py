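import numpy as np
import pandas as pd
import pysam
import pytest

from mesoprofiler.splice import ExonModel


@pytest.fixture
def toy_exon_model() -> ExonModel:
    """Five-exon plus-strand gene; exon 3 (150 nt) blocks read-through,
    so skipping it is visible to the splicing-ratio detector."""
    return ExonModel(
        gene_id="TOY",
        chrom="chrT",
        strand="+",
        exons=[(1000, 1200), (2000, 2150), (3000, 3150),
               (4000, 4120), (5000, 5300)],
        read_length=97,
    )


@pytest.fixture
def toy_gtf(tmp_path):
    """GTF annotation of the toy gene, with one duplicated/overlapping
    exon record to exercise interval merging (1-based inclusive)."""
    lines = []
    exons = [(1001, 1200), (2001, 2150), (3001, 3150), (4001, 4120),
             (5001, 5300)]
    attrs = 'gene_id "TOY"; transcript_id "TOY.1";'
    for s, e in exons:
        lines.append(
            f"chrT\ttest\texon\t{s}\t{e}\t.\t+\t.\t{attrs}"
        )
    # overlapping variant of exon 2 from a second transcript
    lines.append(
        f'chrT\ttest\texon\t1951\t2100\t.\t+\t.\tgene_id "TOY"; '
        f'transcript_id "TOY.2";'
    )
    path = tmp_path / "toy.gtf"
    path.write_text("\n".join(lines) + "\n")
    return str(path)


def write_test_sam(path, reads, chrom_lengths):
    """Write simple single-end alignments to SAM.

    ``reads`` are dicts with chrom, start (0-based), cigar (pysam
    tuples) or length, and optional mapq/flag.
    """
    header = {
        "HD": {"VN": "1.6", "SO": "coordinate"},
        "SQ": [{"SN": c, "LN": int(ln)} for c, ln in chrom_lengths.items()],
    }
    reads = sorted(reads, key=lambda r: (r["chrom"], r["start"]))
    with pysam.AlignmentFile(str(path), "w", header=header) as out:
        for i, r in enumerate(reads):
            a = pysam.AlignedSegment(out.header)
            a.query_name = r.get("name", f"q{i}")
            a.reference_name = r["chrom"]
            a.reference_start = r["start"]
            cigar = r.get("cigar") or [(0, r.get("length", 100))]
            a.cigartuples = cigar
            a.mapping_quality = r.get("mapq", 60)
            a.flag = r.get("flag", 0)
            a.query_sequence = "A" * sum(ln for op, ln in cigar if op in (0, 1))
            out.write(a)
    return str(path)


@pytest.fixture
def sam_writer():
    return write_test_sam


def four_state_profile(purity=0.7, mean_depth=200.0, dispersion=0.05,
                       bins=500, bin_size=30_000):
    """Four-copy-state single-chromosome truth profile (n_T = 1..4)."""
    from mesoprofiler.synthetic import TruthCNProfile

    span = bins * bin_size
    q = [0, span // 4, span // 2, 3 * span // 4, span]
    return TruthCNProfile(
        segments=[("chr1", q[i], q[i + 1], i + 1) for i in range(4)],
        purity=purity, mean_depth=mean_depth, dispersion=dispersion,
    )
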