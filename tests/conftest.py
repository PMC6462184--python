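from __future__ import annotations

from pathlib import Path

import numpy as np
import pytest

from srnakit import Region

FIXTURES = Path(__file__).parent / "fixtures"

SAM_HEADER = "@HD\tVN:1.6\tSO:coordinate\n@SQ\tSN:chr1\tLN:10000\n"


def sam_record(
    name: str,
    flag: int,
    pos0: int,
    cigar: str,
    seq: str,
    chrom: str = "chr1",
    mapq: int = 42,
) -> str:
    """One SAM line; pos0 is 0-based (converted to SAM's 1-based here)."""
    return f"{name}\t{flag}\t{chrom}\t{pos0 + 1}\t{mapq}\t{cigar}\t*\t0\t0\t{seq}\t*"


def make_sam(records: list[str], header: str = SAM_HEADER) -> str:
    return header + "\n".join(records) + ("\n" if records else "")


@pytest.fixture
def write_sam(tmp_path):
    def _write(records: list[str], header: str = SAM_HEADER, name="reads.sam") -> Path:
        path = tmp_path / name
        path.write_text(make_sam(records, header))
        return path

    return _write


@pytest.fixture
def nd169_region() -> Region:
    return Region("ND169", "chr1", 100, 200, "+", "target")


def random_sam(
    rng: np.random.Generator,
    n_records: int,
    chroms: dict[str, int],
) -> str:
    """Random SAM text exercising clips, indels, strands and skip paths."""
    names = list(chroms)
    header = "@HD\tVN:1.6\tSO:unsorted\n" + "".join(
        f"@SQ\tSN:{c}\tLN:{l}\n" for c, l in chroms.items()
    )
    alphabet = np.array(list("ACGT"))
    lines = []
    for i in range(n_records):
        chrom = names[rng.integers(len(names))]
        flag = 0
        if rng.random() < 0.5:
            flag |= 0x10
        roll = rng.random()
        if roll < 0.04:
            flag |= 0x4  # unmapped
        elif roll < 0.08:
            flag |= 0x100  # secondary
        elif roll < 0.10:
            flag |= 0x800  # supplementary
        core = int(rng.integers(15, 31))
        lead = int(rng.integers(1, 4)) if rng.random() < 0.3 else 0
        trail = int(rng.integers(1, 4)) if rng.random() < 0.3 else 0
        cigar = ""
        qlen = lead + trail
        if lead:
            cigar += f"{lead}S"
        if rng.random() < 0.2:  # split the match with a deletion or insertion
            a = core // 2
            if rng.random() < 0.5:
                cigar += f"{a}M{int(rng.integers(1, 3))}D{core - a}M"
            else:
                ins = int(rng.integers(1, 3))
                cigar += f"{a}M{ins}I{core - a}M"
                qlen += ins
        else:
            cigar += f"{core}M"
        qlen += core
        if trail:
            cigar += f"{trail}S"
        pos = int(rng.integers(0, chroms[chrom] - core - 10))
        if rng.random() < 0.03:
            seq = "*"
            cigar = f"{qlen}M"  # length must not matter for a skipped record
        else:
            seq = "".join(rng.choice(alphabet, size=qlen))
        lines.append(
            f"r{i}\t{flag}\t{chrom}\t{pos + 1}\t42\t{cigar}\t*\t0\t0\t{seq}\t*"
        )
    return header + "\n".join(lines) + "\n"


def random_regions(rng: np.random.Generator, chroms: dict[str, int]) -> list[Region]:
    regions = []
    roles = ["target", "target", "target", "knockdown", "background"]
    names = list(chroms)
    for i, role in enumerate(roles):
        chrom = names[rng.integers(len(names))]
        start = int(rng.integers(0, chroms[chrom] - 200))
        end = start + int(rng.integers(50, 200))
        strand = ["+", "-", "."][rng.integers(3)]
        regions.append(Region(f"reg{i}", chrom, start, end, strand, role))
    return regions
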