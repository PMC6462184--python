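"""Seeded simulator of toy references and small-RNA alignment files.

The generator emulates the statistical structure of knockdown small-RNA
sequencing libraries so that the whole pipeline is testable offline:
21-25 nt reads with a modal length, per-region antisense fractions,
non-templated 3' additions appearing as soft clips, and — for knockdown
designs — spike-in reads over the knockdown locus that can dominate the
library the way introduced primary siRNAs and amplified secondary siRNAs do.

Reads are simulated error-free apart from the non-templated tail: the point
is to exercise statistics extraction and normalization, not aligner
robustness.  Every draw flows from a single integer seed through
``numpy.random.SeedSequence``, so a fixed seed reproduces output
byte-identically.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import yaml

from .regions import KNOCKDOWN_ROLES, Region, SampleConfig, write_regions, write_sample_config
from .stats import reverse_complement

_ALPHABET = np.array(["A", "C", "G", "T"])

DEFAULT_LENGTH_DISTRIBUTION = {21: 0.10, 22: 0.20, 23: 0.40, 24: 0.20, 25: 0.10}
DEFAULT_CLIP3_BIAS = {"A": 0.4, "C": 0.1, "G": 0.1, "T": 0.4}

#: default toy layout: four target loci and one knockdown locus on one contig
DEFAULT_REGIONS = (
    ("tgt1", 200, 600, "+", "target"),
    ("tgt2", 800, 1200, "+", "target"),
    ("tgt3", 1400, 1800, "-", "target"),
    ("tgt4", 2000, 2400, "+", "target"),
    ("kd1", 3000, 3400, "+", "knockdown"),
)


class SimulationError(ValueError):
    pass


@dataclass
class SimulationConfig:
    """Generative parameters of one simulated library.

    ``expected_reads`` and ``antisense_fraction`` may be a single value or a
    per-region-name mapping.  ``knockdown_spike`` is a count of extra reads
    distributed over role=knockdown regions (modelling the siRNA excess of a
    knockdown library); ``depth_scale`` multiplies every region's expected
    read count (library depth variation between replicates).
    """

    seed: int = 0
    chrom: str = "chrSim"
    genome_length: int = 5000
    regions: tuple = DEFAULT_REGIONS
    expected_reads: float | dict = 1000.0
    length_distribution: dict = field(
        default_factory=lambda: dict(DEFAULT_LENGTH_DISTRIBUTION)
    )
    antisense_fraction: float | dict = 0.2
    clip3_prob: float = 0.15
    clip3_max_len: int = 3
    clip3_alphabet_bias: dict = field(
        default_factory=lambda: dict(DEFAULT_CLIP3_BIAS)
    )
    knockdown_spike: int = 0
    depth_scale: float = 1.0

    def region_objects(self) -> list[Region]:
        return [
            Region(name, self.chrom, start, end, strand, role)
            for name, start, end, strand, role in self.regions
        ]

    def validate(self) -> None:
        probs = np.array(list(self.length_distribution.values()), float)
        if probs.size == 0 or abs(probs.sum() - 1.0) > 1e-9 or (probs < 0).any():
            raise SimulationError("length_distribution must sum to 1")
        for p in (self.clip3_prob,):
            if not 0 <= p <= 1:
                raise SimulationError("clip3_prob must be in [0, 1]")
        max_len = max(self.length_distribution) + self.clip3_max_len
        for r in self.region_objects():
            if r.end > self.genome_length:
                raise SimulationError(
                    f"region {r.name!r} ends at {r.end} beyond genome "
                    f"length {self.genome_length}"
                )
            if r.length < max_len:
                raise SimulationError(
                    f"region {r.name!r} shorter than the longest simulated "
                    f"read ({max_len} nt)"
                )
            af = self._per_region(self.antisense_fraction, r.name)
            if not 0 <= af <= 1:
                raise SimulationError(
                    f"antisense_fraction for {r.name!r} must be in [0, 1]"
                )

    @staticmethod
    def _per_region(value, name: str) -> float:
        if isinstance(value, dict):
            return float(value[name])
        return float(value)

    # -- plain-text round trip -------------------------------------------
    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimulationConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = set(cls.__dataclass_fields__)
        unknown = set(data) - known
        if unknown:
            raise SimulationError(f"unknown simulation config keys: {sorted(unknown)}")
        if "regions" in data:
            data["regions"] = tuple(tuple(r) for r in data["regions"])
        if "length_distribution" in data:
            data["length_distribution"] = {
                int(k): float(v) for k, v in data["length_distribution"].items()
            }
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        data = {
            "seed": self.seed,
            "chrom": self.chrom,
            "genome_length": self.genome_length,
            "regions": [list(r) for r in self.regions],
            "expected_reads": self.expected_reads,
            "length_distribution": self.length_distribution,
            "antisense_fraction": self.antisense_fraction,
            "clip3_prob": self.clip3_prob,
            "clip3_max_len": self.clip3_max_len,
            "clip3_alphabet_bias": self.clip3_alphabet_bias,
            "knockdown_spike": self.knockdown_spike,
            "depth_scale": self.depth_scale,
        }
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=False)


def simulate_reference(config: SimulationConfig) -> tuple[str, list[Region]]:
    """Uniform-random reference sequence plus its region definitions.

    Returns (FASTA text, regions).  Deterministic under ``config.seed``.
    """
    config.validate()
    rng = np.random.default_rng(np.random.SeedSequence(config.seed, spawn_key=(0,)))
    seq = "".join(rng.choice(_ALPHABET, size=config.genome_length))
    lines = [f">{config.chrom}"]
    for i in range(0, len(seq), 70):
        lines.append(seq[i : i + 70])
    return "\n".join(lines) + "\n", config.region_objects()


def fasta_sequence(fasta_text: str) -> str:
    """The (single) sequence of a FASTA string."""
    return "".join(
        line.strip() for line in fasta_text.splitlines() if not line.startswith(">")
    )


def simulate_sample(
    config: SimulationConfig,
    genome: str,
    *,
    rng: np.random.Generator | None = None,
    depth_scale: float | None = None,
    knockdown_spike: int | None = None,
    read_group: str = "sim",
) -> str:
    """Simulate one library as coordinate-sorted SAM text.

    Per region the read count is Poisson(expected_reads * depth_scale);
    knockdown regions receive ``knockdown_spike`` extra reads on top.  Each
    read copies the reference (reverse-complemented when antisense to the
    region), and with probability ``clip3_prob`` gains a 1..clip3_max_len nt
    non-templated 3' tail encoded as a soft clip — trailing in the CIGAR for
    forward reads, leading for reverse reads.
    """
    config.validate()
    if len(genome) < config.genome_length:
        raise SimulationError("reference shorter than configured genome_length")
    if rng is None:
        rng = np.random.default_rng(
            np.random.SeedSequence(config.seed, spawn_key=(1,))
        )
    depth = config.depth_scale if depth_scale is None else depth_scale
    spike = config.knockdown_spike if knockdown_spike is None else knockdown_spike

    lengths = np.array(sorted(config.length_distribution), dtype=int)
    length_p = np.array(
        [config.length_distribution[l] for l in lengths], dtype=float
    )
    length_p = length_p / length_p.sum()
    clip_nts = np.array(sorted(config.clip3_alphabet_bias))
    clip_p = np.array(
        [config.clip3_alphabet_bias[n] for n in clip_nts], dtype=float
    )
    clip_p = clip_p / clip_p.sum()

    regions = config.region_objects()
    kd_regions = [r for r in regions if r.role in KNOCKDOWN_ROLES]
    spike_share = {
        r.name: spike // len(kd_regions) + (1 if i < spike % len(kd_regions) else 0)
        for i, r in enumerate(kd_regions)
    } if kd_regions else {}

    records: list[tuple[int, str]] = []
    idx = 0
    for region in regions:
        mean = config._per_region(config.expected_reads, region.name) * depth
        n = int(rng.poisson(mean)) + spike_share.get(region.name, 0)
        if n == 0:
            continue
        af = config._per_region(config.antisense_fraction, region.name)
        read_lens = rng.choice(lengths, size=n, p=length_p)
        anti = rng.random(n) < af
        u_start = rng.random(n)
        has_clip = rng.random(n) < config.clip3_prob
        clip_lens = rng.integers(1, config.clip3_max_len + 1, size=n)
        sense_strand = "-" if region.strand == "-" else "+"
        for k in range(n):
            L = int(read_lens[k])
            start = region.start + int(u_start[k] * (region.length - L + 1))
            segment = genome[start : start + L]
            strand = sense_strand
            if anti[k]:
                strand = "-" if sense_strand == "+" else "+"
            tail = ""
            if has_clip[k]:
                tail = "".join(rng.choice(clip_nts, size=int(clip_lens[k]), p=clip_p))
            if strand == "+":
                flag = 0
                seq = segment + tail
                cigar = f"{L}M{len(tail)}S" if tail else f"{L}M"
            else:
                flag = 16
                seq = (reverse_complement(tail) if tail else "") + segment
                cigar = f"{len(tail)}S{L}M" if tail else f"{L}M"
            name = f"{read_group}.{idx:06d}"
            idx += 1
            records.append(
                (
                    start,
                    f"{name}\t{flag}\t{config.chrom}\t{start + 1}\t42\t"
                    f"{cigar}\t*\t0\t0\t{seq}\t*",
                )
            )
    records.sort(key=lambda t: t[0])
    header = (
        "@HD\tVN:1.6\tSO:coordinate\n"
        f"@SQ\tSN:{config.chrom}\tLN:{config.genome_length}\n"
    )
    return header + "\n".join(r[1] for r in records) + ("\n" if records else "")


@dataclass
class ExperimentBundle:
    """File layout of a simulated multi-sample knockdown experiment."""

    out_dir: Path
    fasta_path: Path
    regions_path: Path
    sam_paths: dict[str, Path]
    sample_config_path: Path
    sample_configs: list[SampleConfig]
    depth_scales: dict[str, float]
    spikes: dict[str, int]


def simulate_knockdown_experiment(
    config: SimulationConfig,
    n_samples: int,
    out_dir: str | Path,
    *,
    depth_range: tuple[float, float] = (0.5, 2.0),
    spike_fraction_range: tuple[float, float] = (0.3, 0.7),
) -> ExperimentBundle:
    """Simulate n biological replicates of a knockdown experiment.

    The replicates share per-region expectations but differ in library depth
    (drawn uniformly from ``depth_range``) and in the knockdown spike: each
    sample gains, over its knockdown regions, extra reads amounting to a
    uniform fraction (``spike_fraction_range``) of its baseline library size.  Writes reference.fa, regions.bed, one SAM per sample
    and a ready-to-run sample configuration; returns the file layout.
    """
    if n_samples < 2:
        raise SimulationError("a replicate experiment needs n_samples >= 2")
    config.validate()
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    fasta, regions = simulate_reference(config)
    genome = fasta_sequence(fasta)
    fasta_path = out_dir / "reference.fa"
    fasta_path.write_text(fasta)
    regions_path = out_dir / "regions.bed"
    write_regions(regions, regions_path)

    kd_names = tuple(r.name for r in regions if r.role in KNOCKDOWN_ROLES)
    if not kd_names:
        raise SimulationError("experiment config defines no knockdown region")
    master = np.random.default_rng(np.random.SeedSequence(config.seed, spawn_key=(2,)))
    baseline = sum(
        config._per_region(config.expected_reads, r.name) for r in regions
    )
    sam_paths: dict[str, Path] = {}
    depth_scales: dict[str, float] = {}
    spikes: dict[str, int] = {}
    for i in range(n_samples):
        name = f"rep{i + 1}"
        depth = float(master.uniform(*depth_range))
        frac = float(master.uniform(*spike_fraction_range))
        spike = int(round(baseline * depth * frac))
        rng = np.random.default_rng(
            np.random.SeedSequence(config.seed, spawn_key=(3, i))
        )
        sam = simulate_sample(
            config,
            genome,
            rng=rng,
            depth_scale=depth,
            knockdown_spike=spike,
            read_group=name,
        )
        path = out_dir / f"{name}.sam"
        path.write_text(sam)
        sam_paths[name] = path
        depth_scales[name] = depth
        spikes[name] = spike
    # a design without any spike needs no knockdown correction: emit an
    # empty knockdown set so downstream KDCS degenerates to TCS exactly
    effective_kd = kd_names if any(spikes.values()) else ()
    sample_configs = [
        SampleConfig(name, f"{name}_stats/region_summary.tsv", effective_kd)
        for name in sam_paths
    ]
    sample_config_path = out_dir / "samples.tsv"
    write_sample_config(sample_configs, sample_config_path)
    return ExperimentBundle(
        out_dir=out_dir,
        fasta_path=fasta_path,
        regions_path=regions_path,
        sam_paths=sam_paths,
        sample_config_path=sample_config_path,
        sample_configs=sample_configs,
        depth_scales=depth_scales,
        spikes=spikes,
    )


def normalization_cov_study(
    base_seed: int,
    *,
    n_seeds: int = 100,
    n_samples: int = 4,
    config: SimulationConfig | None = None,
    workdir: str | Path | None = None,
):
    """Replicate-simulation benchmark of the normalization methods.

    For each of ``n_seeds`` simulated experiments (``n_samples`` replicates
    sharing expectations, random depths and knockdown spikes), runs the full
    pipeline — SAM, per-sample statistics, normalization — and records the
    mean per-region CoV of the raw, TCS-, KDCS- and size-factor-normalized
    target counts.  Returns a per-seed DataFrame of those means.
    """
    import pandas as pd

    from .metrics import coefficient_of_variation
    from .normalize import (
        count_table_from_stats,
        kdcs_normalize,
        size_factor_normalize,
        tcs_normalize,
    )
    from .stats import collect_sample_stats

    if config is None:
        config = SimulationConfig()
    rows = []
    import tempfile

    with tempfile.TemporaryDirectory(dir=workdir) as tmp:
        for k in range(n_seeds):
            seed = int(
                np.random.SeedSequence(base_seed, spawn_key=(k,)).generate_state(1)[0]
                % (2**31)
            )
            cfg = replace(config, seed=seed)
            exp_dir = Path(tmp) / f"seed{k}"
            bundle = simulate_knockdown_experiment(cfg, n_samples, exp_dir)
            regions = cfg.region_objects()
            stats = [
                collect_sample_stats(path, regions, sample_name=name)
                for name, path in bundle.sam_paths.items()
            ]
            targets = [r.name for r in regions if r.role == "target"]
            table = count_table_from_stats(stats, target_regions=targets)

            def mean_cov(matrix) -> float:
                vals = [coefficient_of_variation(row) for row in np.asarray(matrix, float)]
                return float(np.nanmean(vals))

            rows.append(
                {
                    "seed": seed,
                    "cov_raw": mean_cov(table.counts),
                    "cov_tcs": mean_cov(tcs_normalize(table).normalized),
                    "cov_kdcs": mean_cov(kdcs_normalize(table).normalized),
                    "cov_sizefactor": mean_cov(
                        size_factor_normalize(table).normalized
                    ),
                }
            )
            for p in bundle.sam_paths.values():
                p.unlink()
    return pd.DataFrame(rows)
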