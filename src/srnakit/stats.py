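"""Per-read feature extraction and per-region/per-sample aggregation.

From each mapped primary alignment this module extracts the small-RNA
features of interest — full read length (soft clips included, since clipped
bases are the candidate non-templated 3' additions), strand, 5'/3'
soft-clipped sequences in read orientation, the 5'-most nucleotide and the
base composition — and aggregates them per region into count histograms and
strand-specific coverage, plus the per-sample totals T (all counted records)
and K (records over knockdown/background regions) that drive
knockdown-corrected normalization.

Orientation: a read's biological 5'/3' ends do not depend on which genome
strand it aligned to, so for reverse-strand alignments the stored sequence is
reverse-complemented before any read feature is derived, and the CIGAR's
leading soft clip becomes the 3' clip (and the trailing one the 5' clip).
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import pysam

from .regions import KNOCKDOWN_ROLES, Region

logger = logging.getLogger(__name__)

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")

#: CIGAR op codes (SAM spec): M=0 I=1 D=2 N=3 S=4 H=5 P=6 ==7 X=8
_REF_ALIGNED_OPS = frozenset({0, 7, 8})
_REF_SKIP_OPS = frozenset({2, 3})
_NUCLEOTIDES = ("A", "C", "G", "T", "N")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class ReadFeatures:
    """Read-orientation features of one aligned record."""

    read_id: str
    chrom: str
    aln_start: int  # 0-based
    aln_end: int  # 0-based exclusive
    read_strand: str  # '+' or '-'
    read_length: int  # full query length incl. soft clips
    clip5: str  # soft-clipped bases at the read 5' end, read orientation
    clip3: str  # soft-clipped bases at the read 3' end, read orientation
    first_nt: str  # 5'-most base of the read
    base_counts: tuple[tuple[str, int], ...]  # whole-read composition
    blocks: tuple[tuple[int, int], ...]  # reference-aligned (M/=/X) blocks


class AlignmentError(ValueError):
    """Record violates the extraction preconditions."""


def extract_read_features(aln: pysam.AlignedSegment) -> ReadFeatures:
    """Extract :class:`ReadFeatures` from a mapped primary SAM record.

    Requires CIGAR and sequence to be present.  Hard clips contribute no
    bases.  For reverse-strand alignments everything is reported after
    reverse-complementing into read orientation.
    """
    seq = aln.query_sequence
    if seq is None:
        raise AlignmentError(f"record {aln.query_name!r} has no sequence")
    cig = aln.cigartuples
    if not cig:
        raise AlignmentError(f"record {aln.query_name!r} has no CIGAR")

    # soft clips sit immediately inside any hard clips
    i = 1 if cig[0][0] == 5 else 0
    lead = cig[i][1] if i < len(cig) and cig[i][0] == 4 else 0
    j = len(cig) - (2 if cig[-1][0] == 5 else 1)
    trail = cig[j][1] if j >= 0 and cig[j][0] == 4 else 0

    if aln.is_reverse:
        rseq = reverse_complement(seq)
        strand = "-"
        clip5 = rseq[:trail] if trail else ""
        clip3 = rseq[len(rseq) - lead:] if lead else ""
    else:
        rseq = seq.upper()
        strand = "+"
        clip5 = rseq[:lead] if lead else ""
        clip3 = rseq[len(rseq) - trail:] if trail else ""

    # reference-aligned blocks from the CIGAR (M/=/X advance both, D/N only ref)
    blocks: list[tuple[int, int]] = []
    pos = aln.reference_start
    for op, n in cig:
        if op in _REF_ALIGNED_OPS:
            blocks.append((pos, pos + n))
            pos += n
        elif op in _REF_SKIP_OPS:
            pos += n

    base_counts = tuple((nt, rseq.count(nt)) for nt in _NUCLEOTIDES)
    return ReadFeatures(
        read_id=aln.query_name,
        chrom=aln.reference_name,
        aln_start=aln.reference_start,
        aln_end=pos,
        read_strand=strand,
        read_length=len(seq),
        clip5=clip5,
        clip3=clip3,
        first_nt=rseq[0],
        base_counts=base_counts,
        blocks=tuple(blocks),
    )


def assign_to_regions(
    feature: ReadFeatures, regions: list[Region]
) -> list[str]:
    """Names of all regions overlapping the alignment by >= 1 reference base."""
    return [
        r.name
        for r in regions
        if r.overlaps(feature.chrom, feature.aln_start, feature.aln_end)
    ]


def is_antisense(feature: ReadFeatures, region: Region) -> bool:
    """True iff the read strand differs from the region strand.

    For unstranded regions antisense is defined relative to the reference
    plus strand: a minus-strand read is antisense.
    """
    if region.strand == ".":
        return feature.read_strand == "-"
    return feature.read_strand != region.strand


@dataclass
class RegionStats:
    """Aggregated read statistics for one region."""

    region_name: str
    length: int  # region length in nt (for the coverage vectors)
    R: int = 0  # total assigned reads
    AS: int = 0  # antisense reads
    length_hist: Counter = field(default_factory=Counter)
    strand_by_length: Counter = field(default_factory=Counter)  # (len, sense|antisense)
    clip_profile: Counter = field(default_factory=Counter)  # (5p|3p, nt)
    first_nt_counts: Counter = field(default_factory=Counter)
    base_composition: Counter = field(default_factory=Counter)
    coverage_plus: np.ndarray = None
    coverage_minus: np.ndarray = None

    def __post_init__(self) -> None:
        if self.coverage_plus is None:
            self.coverage_plus = np.zeros(self.length, dtype=np.int64)
        if self.coverage_minus is None:
            self.coverage_minus = np.zeros(self.length, dtype=np.int64)


@dataclass
class SampleStats:
    """Per-sample totals and per-region aggregates.

    ``T`` counts every mapped, primary, non-supplementary record with a
    sequence; ``K`` the subset overlapping >= 1 region with role knockdown or
    background, each record at most once.
    """

    sample_name: str
    T: int = 0
    K: int = 0
    skipped: int = 0  # records without sequence, tallied not dropped silently
    filtered: int = 0  # records removed by the optional length filter
    region_stats: dict[str, RegionStats] = field(default_factory=dict)


def _update_region(stats: RegionStats, feat: ReadFeatures, region: Region) -> None:
    stats.R += 1
    anti = is_antisense(feat, region)
    orient = "antisense" if anti else "sense"
    if anti:
        stats.AS += 1
    stats.length_hist[feat.read_length] += 1
    stats.strand_by_length[(feat.read_length, orient)] += 1
    for nt in feat.clip5:
        stats.clip_profile[("5p", nt)] += 1
    for nt in feat.clip3:
        stats.clip_profile[("3p", nt)] += 1
    stats.first_nt_counts[feat.first_nt] += 1
    for nt, n in feat.base_counts:
        if n:
            stats.base_composition[nt] += n
    cov = stats.coverage_plus if feat.read_strand == "+" else stats.coverage_minus
    for bstart, bend in feat.blocks:
        lo = max(bstart, region.start) - region.start
        hi = min(bend, region.end) - region.start
        if lo < hi:
            cov[lo:hi] += 1


def collect_sample_stats(
    alignment_path: str | Path,
    regions: list[Region],
    sample_name: str | None = None,
    min_len: int | None = None,
    max_len: int | None = None,
) -> SampleStats:
    """Stream a SAM/BAM file and aggregate per-region and per-sample statistics.

    Counted records are mapped, primary and non-supplementary; secondary and
    supplementary alignments and unmapped records are excluded from T, K and
    all region statistics.  Records lacking a stored sequence are skipped with
    a warning and tallied in ``skipped``.  When ``min_len``/``max_len`` are
    given, reads whose full length (soft clips included) falls outside the
    bounds are excluded from R, T and K and tallied in ``filtered``.
    """
    alignment_path = Path(alignment_path)
    if sample_name is None:
        sample_name = alignment_path.stem
    result = SampleStats(sample_name=sample_name)
    for r in regions:
        result.region_stats[r.name] = RegionStats(r.name, r.length)
    by_chrom: dict[str, list[Region]] = {}
    for r in regions:
        by_chrom.setdefault(r.chrom, []).append(r)

    with pysam.AlignmentFile(str(alignment_path), check_sq=False) as af:
        refs = set(af.references or ())
        for chrom in by_chrom:
            if refs and chrom not in refs:
                logger.warning(
                    "region chromosome %r absent from %s header; its regions "
                    "will report zero reads",
                    chrom,
                    alignment_path.name,
                )
        for aln in af:
            if aln.is_unmapped or aln.is_secondary or aln.is_supplementary:
                continue
            if aln.query_sequence is None:
                result.skipped += 1
                logger.warning(
                    "skipping record %r: no stored sequence", aln.query_name
                )
                continue
            feat = extract_read_features(aln)
            if (min_len is not None and feat.read_length < min_len) or (
                max_len is not None and feat.read_length > max_len
            ):
                result.filtered += 1
                continue
            result.T += 1
            candidates = by_chrom.get(feat.chrom)
            if not candidates:
                continue
            hit_kd = False
            for region in candidates:
                if region.overlaps(feat.chrom, feat.aln_start, feat.aln_end):
                    _update_region(result.region_stats[region.name], feat, region)
                    if region.role in KNOCKDOWN_ROLES:
                        hit_kd = True
            if hit_kd:
                result.K += 1
    return result


# ---------------------------------------------------------------------------
# stats bundle serialization (TSV, one file per table)
# ---------------------------------------------------------------------------

BUNDLE_FILES = (
    "region_summary.tsv",
    "length_hist.tsv",
    "strand_by_length.tsv",
    "clip_profile.tsv",
    "first_nt.tsv",
    "base_composition.tsv",
    "coverage.tsv",
)


def _header(sample: SampleStats) -> str:
    from . import __version__

    return (
        f"# srnakit={__version__} sample={sample.sample_name} "
        f"T={sample.T} K={sample.K} skipped={sample.skipped} "
        f"filtered={sample.filtered}\n"
    )


def write_stats_bundle(sample: SampleStats, out_dir: str | Path) -> Path:
    """Write the per-sample TSV bundle; returns the bundle directory."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    head = _header(sample)

    with open(out_dir / "region_summary.tsv", "w") as fh:
        fh.write(head)
        fh.write("region\tR\tAS\n")
        for name, rs in sample.region_stats.items():
            fh.write(f"{name}\t{rs.R}\t{rs.AS}\n")

    with open(out_dir / "length_hist.tsv", "w") as fh:
        fh.write(head)
        fh.write("region\tlength\tcount\n")
        for name, rs in sample.region_stats.items():
            for length in sorted(rs.length_hist):
                fh.write(f"{name}\t{length}\t{rs.length_hist[length]}\n")

    with open(out_dir / "strand_by_length.tsv", "w") as fh:
        fh.write(head)
        fh.write("region\tlength\torientation\tcount\n")
        for name, rs in sample.region_stats.items():
            for length, orient in sorted(rs.strand_by_length):
                fh.write(
                    f"{name}\t{length}\t{orient}\t"
                    f"{rs.strand_by_length[(length, orient)]}\n"
                )

    with open(out_dir / "clip_profile.tsv", "w") as fh:
        fh.write(head)
        fh.write("region\tend\tnucleotide\tcount\n")
        for name, rs in sample.region_stats.items():
            for end, nt in sorted(rs.clip_profile):
                fh.write(f"{name}\t{end}\t{nt}\t{rs.clip_profile[(end, nt)]}\n")

    with open(out_dir / "first_nt.tsv", "w") as fh:
        fh.write(head)
        fh.write("region\tnucleotide\tcount\n")
        for name, rs in sample.region_stats.items():
            for nt in sorted(rs.first_nt_counts):
                fh.write(f"{name}\t{nt}\t{rs.first_nt_counts[nt]}\n")

    with open(out_dir / "base_composition.tsv", "w") as fh:
        fh.write(head)
        fh.write("region\tnucleotide\tcount\n")
        for name, rs in sample.region_stats.items():
            for nt in sorted(rs.base_composition):
                fh.write(f"{name}\t{nt}\t{rs.base_composition[nt]}\n")

    with open(out_dir / "coverage.tsv", "w") as fh:
        fh.write(head)
        fh.write("region\toffset\tstrand\tdepth\n")
        for name, rs in sample.region_stats.items():
            for strand, cov in (("+", rs.coverage_plus), ("-", rs.coverage_minus)):
                for offset in np.nonzero(cov)[0]:
                    fh.write(f"{name}\t{offset}\t{strand}\t{cov[offset]}\n")
    return out_dir


def read_region_summary(path: str | Path) -> tuple[str, int, int, pd.DataFrame]:
    """Read a region_summary.tsv; returns (sample_name, T, K, table).

    The table has columns region, R, AS.  T and K come from the bundle's
    ``#`` header line.
    """
    path = Path(path)
    meta: dict[str, str] = {}
    with open(path) as fh:
        first = fh.readline()
        if not first.startswith("#"):
            raise ValueError(f"{path}: missing '#' metadata header line")
        for tok in first[1:].split():
            if "=" in tok:
                key, val = tok.split("=", 1)
                meta[key] = val
    df = pd.read_csv(path, sep="\t", comment="#")
    expected = {"region", "R", "AS"}
    if not expected.issubset(df.columns):
        raise ValueError(f"{path}: expected columns {sorted(expected)}")
    return meta.get("sample", path.stem), int(meta["T"]), int(meta["K"]), df
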