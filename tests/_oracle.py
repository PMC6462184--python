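"""Independent brute-force reference implementation for alignment statistics.

Parses SAM text directly (no pysam, no srnakit.stats) and aggregates the
same quantities with the most literal code possible.  Used only as the
oracle side of equivalence tests.
"""

from __future__ import annotations

import re
from collections import Counter

_CIGAR_RE = re.compile(r"(\d+)([MIDNSHP=X])")
_COMP = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}


def _revcomp(seq: str) -> str:
    return "".join(_COMP[b] for b in reversed(seq))


def oracle_sample_stats(sam_text: str, regions) -> dict:
    """Brute-force statistics over SAM text.

    ``regions`` is a list of objects with name/chrom/start/end/strand/role.
    Returns a dict with T, K, skipped and a per-region dict of
    R / AS / length_hist / strand_by_length / clip_profile / first_nt /
    coverage_total (sum of aligned overlap lengths).
    """
    per_region = {
        r.name: {
            "R": 0,
            "AS": 0,
            "length_hist": Counter(),
            "strand_by_length": Counter(),
            "clip_profile": Counter(),
            "first_nt": Counter(),
            "coverage_total": 0,
        }
        for r in regions
    }
    T = K = skipped = 0
    for line in sam_text.splitlines():
        if not line or line.startswith("@"):
            continue
        f = line.split("\t")
        flag = int(f[1])
        if flag & 0x4 or flag & 0x100 or flag & 0x800:
            continue
        if f[9] == "*":
            skipped += 1
            continue
        chrom, pos, cigar, seq = f[2], int(f[3]) - 1, f[5], f[9].upper()
        ops = [(int(n), op) for n, op in _CIGAR_RE.findall(cigar)]

        read_length = sum(n for n, op in ops if op in "MIS=X")
        # reference-aligned blocks (M/=/X only)
        blocks = []
        ref = pos
        for n, op in ops:
            if op in "M=X":
                blocks.append((ref, ref + n))
                ref += n
            elif op in "DN":
                ref += n
        aln_start, aln_end = pos, ref

        # soft clips in stored orientation, skipping hard clips
        core = [t for t in ops if t[1] != "H"]
        lead = core[0][0] if core and core[0][1] == "S" else 0
        trail = core[-1][0] if len(core) > 1 and core[-1][1] == "S" else 0
        if flag & 0x10:
            strand = "-"
            clip5 = _revcomp(seq[len(seq) - trail:]) if trail else ""
            clip3 = _revcomp(seq[:lead]) if lead else ""
            first_nt = _COMP[seq[-1]]
        else:
            strand = "+"
            clip5 = seq[:lead]
            clip3 = seq[len(seq) - trail:] if trail else ""
            first_nt = seq[0]

        T += 1
        hit_kd = False
        for region in regions:
            if region.chrom != chrom:
                continue
            if not (aln_start < region.end and region.start < aln_end):
                continue
            if region.role in ("knockdown", "background"):
                hit_kd = True
            entry = per_region[region.name]
            entry["R"] += 1
            if region.strand == ".":
                anti = strand == "-"
            else:
                anti = strand != region.strand
            if anti:
                entry["AS"] += 1
            entry["length_hist"][read_length] += 1
            entry["strand_by_length"][
                (read_length, "antisense" if anti else "sense")
            ] += 1
            for nt in clip5:
                entry["clip_profile"][("5p", nt)] += 1
            for nt in clip3:
                entry["clip_profile"][("3p", nt)] += 1
            entry["first_nt"][first_nt] += 1
            for bs, be in blocks:
                entry["coverage_total"] += max(
                    0, min(be, region.end) - max(bs, region.start)
                )
        if hit_kd:
            K += 1
    return {"T": T, "K": K, "skipped": skipped, "regions": per_region}
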