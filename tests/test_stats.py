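import numpy as np
import pysam
import pytest

from srnakit import (
    Region,
    assign_to_regions,
    collect_sample_stats,
    extract_read_features,
    is_antisense,
)
from srnakit.stats import reverse_complement

from ._oracle import oracle_sample_stats
from .conftest import make_sam, random_regions, random_sam, sam_record


def features_of(write_sam, record):
    path = write_sam([record])
    with pysam.AlignmentFile(str(path)) as af:
        (aln,) = list(af)
    return extract_read_features(aln)


class TestExtractReadFeatures:
    def test_forward_unclipped(self, write_sam):
        seq = "ACGTACGTACGTACGTACGTACG"  # 23 nt
        feat = features_of(write_sam, sam_record("r1", 0, 110, "23M", seq))
        assert feat.read_strand == "+"
        assert feat.read_length == 23
        assert (feat.clip5, feat.clip3) == ("", "")
        assert feat.first_nt == seq[0]
        assert (feat.aln_start, feat.aln_end) == (110, 133)

    def test_forward_trailing_soft_clip_is_clip3(self, write_sam):
        seq = "G" * 22 + "T"
        feat = features_of(write_sam, sam_record("r1", 0, 110, "22M1S", seq))
        assert feat.clip3 == "T"
        assert feat.clip5 == ""
        assert feat.read_length == 23
        assert feat.aln_end == 132  # the clipped base consumes no reference

    def test_reverse_leading_clip_becomes_clip3_in_read_orientation(self, write_sam):
        # stored: leading 1S then 22M; read 3' end is the stored start
        stored = "A" + "C" * 22
        feat = features_of(write_sam, sam_record("r1", 16, 110, "1S22M", stored))
        assert feat.read_strand == "-"
        assert feat.clip3 == reverse_complement("A")  # == "T"
        assert feat.clip5 == ""
        assert feat.first_nt == reverse_complement(stored[-1])  # complement of last stored base
        assert feat.read_length == 23

    def test_hard_clips_contribute_no_bases(self, write_sam):
        seq = "A" * 20
        feat = features_of(write_sam, sam_record("r1", 0, 110, "2H18M2S", seq))
        assert feat.read_length == 20
        assert feat.clip3 == "AA"

    def test_read_and_its_reverse_alignment_give_identical_features(self, write_sam):
        """Biological 5'/3' identity is strand-independent."""
        read = "TGCAGGTACGATCGTAGCTAGC" + "AAG"  # 22 aligned + 3 nt tail
        fwd = sam_record("f", 0, 300, "22M3S", read)
        rev = sam_record("f", 16, 300, "3S22M", reverse_complement(read))
        ffeat = features_of(write_sam, fwd)
        rfeat = features_of(write_sam, rev)
        for attr in ("read_length", "clip5", "clip3", "first_nt", "base_counts"):
            assert getattr(ffeat, attr) == getattr(rfeat, attr)


class TestRegionAssignment:
    region = Region("ND169", "chr1", 100, 200, "+", "target")

    def make_feat(self, write_sam, pos, cigar, seq):
        return features_of(write_sam, sam_record("r", 0, pos, cigar, seq))

    def test_contained_read_assigned(self, write_sam):
        feat = self.make_feat(write_sam, 110, "23M", "A" * 23)
        assert assign_to_regions(feat, [self.region]) == ["ND169"]

    def test_partial_overlap_assigned(self, write_sam):
        feat = self.make_feat(write_sam, 95, "10M", "A" * 10)  # overlap = 5 bases
        assert assign_to_regions(feat, [self.region]) == ["ND169"]

    def test_half_open_boundary_not_assigned(self, write_sam):
        feat = self.make_feat(write_sam, 200, "23M", "A" * 23)
        assert assign_to_regions(feat, [self.region]) == []

    def test_read_spanning_two_regions_counted_in_each(self, write_sam):
        other = Region("next", "chr1", 190, 300, "+", "target")
        feat = self.make_feat(write_sam, 185, "23M", "A" * 23)
        assert assign_to_regions(feat, [self.region, other]) == ["ND169", "next"]


@pytest.mark.parametrize(
    "read_strand,region_strand,expected",
    [
        ("-", "+", True),
        ("+", "+", False),
        ("+", "-", True),
        ("-", "-", False),
        ("-", ".", True),  # unstranded: antisense relative to plus strand
        ("+", ".", False),
    ],
)
def test_is_antisense(write_sam, read_strand, region_strand, expected):
    flag = 16 if read_strand == "-" else 0
    feat = features_of(write_sam, sam_record("r", flag, 110, "20M", "A" * 20))
    region = Region("x", "chr1", 100, 200, region_strand)
    assert is_antisense(feat, region) is expected


class TestCollectSampleStats:
    def test_empty_sam(self, write_sam, nd169_region):
        path = write_sam([])
        stats = collect_sample_stats(path, [nd169_region])
        assert (stats.T, stats.K) == (0, 0)
        assert stats.region_stats["ND169"].R == 0

    def test_two_sense_one_antisense(self, write_sam, nd169_region):
        records = [
            sam_record("a", 0, 110, "23M", "A" * 23),
            sam_record("b", 0, 130, "22M", "C" * 22),
            sam_record("c", 16, 150, "23M", "G" * 23),
        ]
        stats = collect_sample_stats(write_sam(records), [nd169_region])
        rs = stats.region_stats["ND169"]
        assert (stats.T, rs.R, rs.AS) == (3, 3, 1)
        assert rs.length_hist == {23: 2, 22: 1}
        assert rs.strand_by_length[(23, "sense")] == 1
        assert rs.strand_by_length[(23, "antisense")] == 1

    def test_k_deduplicated_across_overlapping_knockdown_regions(self, write_sam):
        regions = [
            Region("kdA", "chr1", 100, 200, "+", "knockdown"),
            Region("kdB", "chr1", 150, 250, "+", "background"),
        ]
        # one read overlapping both knockdown regions, one overlapping neither
        records = [
            sam_record("a", 0, 160, "23M", "A" * 23),
            sam_record("b", 0, 400, "23M", "A" * 23),
        ]
        stats = collect_sample_stats(write_sam(records), regions)
        assert stats.T == 2
        assert stats.K == 1  # counted once despite two overlaps
        assert stats.region_stats["kdA"].R == 1
        assert stats.region_stats["kdB"].R == 1

    def test_secondary_and_unmapped_excluded_star_seq_tallied(self, write_sam, nd169_region):
        records = [
            sam_record("a", 0, 110, "23M", "A" * 23),
            sam_record("a", 256, 150, "23M", "A" * 23),  # secondary
            sam_record("b", 4, 110, "23M", "A" * 23),  # unmapped
            sam_record("c", 0, 110, "23M", "*"),  # no sequence
        ]
        stats = collect_sample_stats(write_sam(records), [nd169_region])
        assert stats.T == 1
        assert stats.skipped == 1
        assert stats.region_stats["ND169"].R == 1

    def test_length_filter_removes_read_from_r_and_t(self, write_sam, nd169_region):
        records = [
            sam_record("short", 0, 110, "23M", "A" * 23),
            sam_record("long", 0, 120, "30M", "A" * 30),
        ]
        stats = collect_sample_stats(
            write_sam(records), [nd169_region], min_len=21, max_len=25
        )
        assert stats.T == 1
        assert stats.filtered == 1
        assert stats.region_stats["ND169"].R == 1

    def test_coverage_equals_sum_of_aligned_overlaps(self, write_sam, nd169_region):
        records = [
            sam_record("a", 0, 95, "10M", "A" * 10),  # 5 bases inside
            sam_record("b", 16, 150, "10M2D10M", "A" * 20),  # 22 ref bases, 20 covered
            sam_record("c", 0, 195, "23M", "A" * 23),  # 5 bases inside
        ]
        stats = collect_sample_stats(write_sam(records), [nd169_region])
        rs = stats.region_stats["ND169"]
        assert len(rs.coverage_plus) == nd169_region.length
        assert int(rs.coverage_plus.sum() + rs.coverage_minus.sum()) == 5 + 20 + 5
        assert int(rs.coverage_minus.sum()) == 20

    def test_missing_chrom_warns_and_reports_zero(self, write_sam, caplog):
        region = Region("ghost", "chrZ", 0, 100, "+")
        path = write_sam([sam_record("a", 0, 110, "23M", "A" * 23)])
        with caplog.at_level("WARNING"):
            stats = collect_sample_stats(path, [region])
        assert stats.region_stats["ghost"].R == 0
        assert any("chrZ" in message for message in caplog.messages)


def test_disjoint_regions_never_exceed_total(tmp_path):
    """Conservation: over non-overlapping regions, sum of R is at most T."""
    rng = np.random.default_rng(99)
    chroms = {"chr1": 3000}
    path = tmp_path / "c.sam"
    path.write_text(random_sam(rng, n_records=300, chroms=chroms))
    regions = [
        Region(f"g{i}", "chr1", i * 300, i * 300 + 250, "+", "target")
        for i in range(10)
    ]
    stats = collect_sample_stats(path, regions)
    assert sum(rs.R for rs in stats.region_stats.values()) <= stats.T


@pytest.mark.parametrize("seed", range(8))
def test_matches_brute_force_oracle_on_random_sams(tmp_path, seed):
    """Record-for-record equivalence against an independent implementation."""
    rng = np.random.default_rng(seed)
    chroms = {"chr1": 3000, "chr2": 1500}
    sam = random_sam(rng, n_records=250, chroms=chroms)
    regions = random_regions(rng, chroms)
    path = tmp_path / "r.sam"
    path.write_text(sam)
    stats = collect_sample_stats(path, regions)
    expected = oracle_sample_stats(sam, regions)
    assert stats.T == expected["T"]
    assert stats.K == expected["K"]
    assert stats.skipped == expected["skipped"]
    for region in regions:
        rs = stats.region_stats[region.name]
        exp = expected["regions"][region.name]
        assert rs.R == exp["R"]
        assert rs.AS == exp["AS"]
        assert dict(rs.length_hist) == dict(exp["length_hist"])
        assert dict(rs.strand_by_length) == dict(exp["strand_by_length"])
        assert dict(rs.clip_profile) == dict(exp["clip_profile"])
        assert dict(rs.first_nt_counts) == dict(exp["first_nt"])
        assert int(rs.coverage_plus.sum() + rs.coverage_minus.sum()) == exp[
            "coverage_total"
        ]
        assert sum(rs.length_hist.values()) == rs.R
        assert 0 <= rs.AS <= rs.R
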