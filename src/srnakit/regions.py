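"""Region and sample-configuration parsing.

Regions are the unit of quantification: named genomic intervals carrying a
strand and a *role*.  Role ``target`` marks loci whose small-RNA accumulation
is being compared; ``knockdown`` marks loci that receive the silencing trigger
(primary siRNAs) and accumulate secondary siRNAs; ``background`` marks any
other locus whose reads should be excluded from the effective library size
(e.g. non-insert vector positions).  Reads over knockdown/background regions
define the per-sample correction term K used by knockdown-corrected scaling.

Coordinate convention
---------------------
Region files use the BED dialect throughout: 0-based, half-open,
tab-separated.  Column 7 (after chrom, start, end, name, score, strand) is a
non-standard extension carrying the role.  SAM's 1-based positions are
converted once, at the alignment-parser boundary; everything in this package
is 0-based half-open.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

STRANDS = ("+", "-", ".")
ROLES = ("target", "knockdown", "background")

#: roles whose reads are subtracted from the library size (the K term)
KNOCKDOWN_ROLES = frozenset({"knockdown", "background"})


class RegionFileError(ValueError):
    """Malformed region file (bad coordinates, duplicate names, ...)."""


class SampleConfigError(ValueError):
    """Malformed sample configuration (unknown regions, duplicate samples)."""


@dataclass(frozen=True)
class Region:
    """A named genomic interval with strand and role.

    ``start``/``end`` are 0-based half-open; ``strand`` is ``+``, ``-`` or
    ``.`` (unstranded); ``role`` is one of ``target``, ``knockdown``,
    ``background``.
    """

    name: str
    chrom: str
    start: int
    end: int
    strand: str = "."
    role: str = "target"

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise RegionFileError(
                f"region {self.name!r}: need 0 <= start < end, "
                f"got [{self.start}, {self.end})"
            )
        if self.strand not in STRANDS:
            raise RegionFileError(
                f"region {self.name!r}: strand must be one of {STRANDS}, "
                f"got {self.strand!r}"
            )
        if self.role not in ROLES:
            raise RegionFileError(
                f"region {self.name!r}: role must be one of {ROLES}, "
                f"got {self.role!r}"
            )

    @property
    def length(self) -> int:
        return self.end - self.start

    def overlaps(self, chrom: str, start: int, end: int) -> bool:
        """≥1-base overlap with the half-open interval [start, end)."""
        return chrom == self.chrom and start < self.end and self.start < end


@dataclass(frozen=True)
class SampleConfig:
    """One sample of a multi-sample run.

    ``stats_path`` points at the sample's per-region summary table (the
    ``region_summary.tsv`` of its stats bundle).  ``knockdown_region_names``
    lists the regions whose reads define this sample's K; an empty list means
    K = 0 (plain total-count scaling for that sample).
    """

    sample_name: str
    stats_path: str
    knockdown_region_names: tuple[str, ...] = field(default_factory=tuple)


def parse_regions(path: str | Path) -> list[Region]:
    """Parse a BED6(+1) region file into validated :class:`Region` objects.

    Each line needs at least chrom, start, end, name; optional columns are
    score (ignored), strand (default unstranded) and role (default target).
    Lines starting with ``#``, ``track`` or ``browser`` are skipped.
    """
    path = Path(path)
    regions: list[Region] = []
    seen: set[str] = set()
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 4:
                raise RegionFileError(
                    f"{path}:{lineno}: expected >= 4 tab-separated fields, "
                    f"got {len(fields)}"
                )
            chrom, start_s, end_s, name = fields[:4]
            try:
                start, end = int(start_s), int(end_s)
            except ValueError as exc:
                raise RegionFileError(
                    f"{path}:{lineno}: non-integer coordinates "
                    f"{start_s!r}/{end_s!r}"
                ) from exc
            strand = fields[5] if len(fields) > 5 and fields[5] else "."
            role = fields[6] if len(fields) > 6 and fields[6] else "target"
            if name in seen:
                raise RegionFileError(
                    f"{path}:{lineno}: duplicate region name {name!r}"
                )
            seen.add(name)
            try:
                regions.append(Region(name, chrom, start, end, strand, role))
            except RegionFileError as exc:
                raise RegionFileError(f"{path}:{lineno}: {exc}") from exc
    return regions


def write_regions(regions: Iterable[Region], path: str | Path) -> None:
    """Write regions back to the BED6(+1) dialect read by :func:`parse_regions`."""
    with open(path, "w") as fh:
        for r in regions:
            fh.write(
                f"{r.chrom}\t{r.start}\t{r.end}\t{r.name}\t0\t{r.strand}\t{r.role}\n"
            )


def parse_sample_config(
    path: str | Path, regions: list[Region]
) -> list[SampleConfig]:
    """Parse the 3-column sample configuration TSV.

    Columns: sample_name, stats_path, comma-separated knockdown region names
    (the third column may be empty).  Every named region must exist and carry
    role ``knockdown`` or ``background``.
    """
    path = Path(path)
    by_name = {r.name: r for r in regions}
    configs: list[SampleConfig] = []
    seen: set[str] = set()
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 2:
                raise SampleConfigError(
                    f"{path}:{lineno}: expected >= 2 tab-separated fields"
                )
            sample = fields[0]
            stats_path = fields[1]
            kd_field = fields[2] if len(fields) > 2 else ""
            kd_names = tuple(n for n in kd_field.split(",") if n.strip())
            if sample in seen:
                raise SampleConfigError(
                    f"{path}:{lineno}: duplicate sample name {sample!r}"
                )
            seen.add(sample)
            for n in kd_names:
                if n not in by_name:
                    raise SampleConfigError(
                        f"{path}:{lineno}: unknown knockdown region {n!r}"
                    )
                if by_name[n].role not in KNOCKDOWN_ROLES:
                    raise SampleConfigError(
                        f"{path}:{lineno}: region {n!r} has role "
                        f"{by_name[n].role!r}; knockdown regions must have "
                        f"role in {sorted(KNOCKDOWN_ROLES)}"
                    )
            configs.append(SampleConfig(sample, stats_path, kd_names))
    return configs


def write_sample_config(
    configs: Iterable[SampleConfig], path: str | Path
) -> None:
    with open(path, "w") as fh:
        for c in configs:
            fh.write(
                f"{c.sample_name}\t{c.stats_path}\t"
                f"{','.join(c.knockdown_region_names)}\n"
            )
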