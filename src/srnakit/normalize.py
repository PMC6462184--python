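"""Multi-sample count normalization for knockdown small-RNA experiments.

In a knockdown experiment the introduced primary siRNAs and the amplified
secondary siRNAs all map to the knockdown locus and can dominate the library,
so scaling by total mapped reads (TCS) mis-normalizes every other region.
Knockdown-corrected scaling (KDCS) removes those reads from the effective
library size first:

    R_hat = R * M / (T - K)

where, per sample, T is the total number of mapped reads, K the number of
reads mapping to knockdown/background regions, and M = max over samples of
(T - K).  With K = 0 everywhere KDCS reduces to TCS.  As an alternative for
knockdown-free designs a median-of-ratios size-factor normalization (the
DESeq2 scheme) is provided: per sample the size factor is the median, over
regions with no zero count, of the count divided by the region's geometric
mean across samples.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .regions import KNOCKDOWN_ROLES, Region, SampleConfig
from .stats import SampleStats, read_region_summary


class NormalizationError(ValueError):
    pass


@dataclass
class CountTable:
    """Raw per-region read counts across samples, with per-sample T and K."""

    regions: list[str]
    samples: list[str]
    counts: np.ndarray  # (n_regions, n_samples), non-negative integers
    totals: np.ndarray  # per-sample T
    knockdown: np.ndarray  # per-sample K

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        self.totals = np.asarray(self.totals)
        self.knockdown = np.asarray(self.knockdown)
        nr, ns = len(self.regions), len(self.samples)
        if self.counts.shape != (nr, ns):
            raise NormalizationError(
                f"counts shape {self.counts.shape} inconsistent with "
                f"{nr} regions x {ns} samples"
            )
        if self.totals.shape != (ns,) or self.knockdown.shape != (ns,):
            raise NormalizationError("totals/knockdown must be per-sample vectors")
        if (self.counts < 0).any():
            raise NormalizationError("negative counts")
        if (self.knockdown < 0).any() or (self.totals < self.knockdown).any():
            raise NormalizationError("need totals >= knockdown >= 0 per sample")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.regions, columns=self.samples)


@dataclass
class NormalizedTable:
    regions: list[str]
    samples: list[str]
    normalized: np.ndarray
    method: str  # KDCS | TCS | size_factor
    M: float | None = None
    size_factors: np.ndarray | None = field(default=None)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.normalized, index=self.regions, columns=self.samples
        )


def count_table_from_stats(
    samples: list[SampleStats], target_regions: list[str] | None = None
) -> CountTable:
    """Build a CountTable from in-memory :class:`SampleStats`.

    K is each sample's deduplicated knockdown count (a read overlapping
    several knockdown regions counted once).  ``target_regions`` selects and
    orders the rows (default: all regions in configured order).
    """
    if not samples:
        raise NormalizationError("no samples")
    region_names = list(samples[0].region_stats)
    for s in samples[1:]:
        if list(s.region_stats) != region_names:
            raise NormalizationError(
                f"sample {s.sample_name!r} has a different region set"
            )
    rows = target_regions if target_regions is not None else region_names
    counts = np.array(
        [[s.region_stats[r].R for s in samples] for r in rows], dtype=np.int64
    )
    return CountTable(
        regions=list(rows),
        samples=[s.sample_name for s in samples],
        counts=counts,
        totals=np.array([s.T for s in samples], dtype=np.int64),
        knockdown=np.array([s.K for s in samples], dtype=np.int64),
    )


def count_table_from_bundles(
    configs: list[SampleConfig],
    regions: list[Region],
    base_dir: str | Path | None = None,
) -> CountTable:
    """Build a CountTable from per-sample region_summary.tsv files.

    Per-sample K follows the sample's configured knockdown set: the bundle's
    deduplicated K when the set covers every knockdown/background region,
    zero when the set is empty, otherwise the sum of R over the named regions
    (exact for non-overlapping knockdown regions).
    """
    if not configs:
        raise NormalizationError("no samples configured")
    base = Path(base_dir) if base_dir is not None else None
    all_kd = {r.name for r in regions if r.role in KNOCKDOWN_ROLES}
    target_names = [r.name for r in regions if r.role == "target"]
    names, totals, ks, columns = [], [], [], []
    for cfg in configs:
        path = Path(cfg.stats_path)
        if base is not None and not path.is_absolute():
            path = base / path
        if not path.exists():
            raise NormalizationError(
                f"sample {cfg.sample_name!r}: stats file {path} not found"
            )
        _, T, K_dedup, df = read_region_summary(path)
        r_by_name = dict(zip(df["region"], df["R"]))
        kd_set = set(cfg.knockdown_region_names)
        if not kd_set:
            K = 0
        elif kd_set == all_kd:
            K = K_dedup
        else:
            K = int(sum(r_by_name[n] for n in kd_set))
        names.append(cfg.sample_name)
        totals.append(T)
        ks.append(K)
        columns.append([int(r_by_name[r]) for r in target_names])
    return CountTable(
        regions=target_names,
        samples=names,
        counts=np.array(columns, dtype=np.int64).T,
        totals=np.array(totals, dtype=np.int64),
        knockdown=np.array(ks, dtype=np.int64),
    )


def kdcs_normalize(table: CountTable) -> NormalizedTable:
    """Knockdown-corrected scaling: R_hat = R * M / (T - K), M = max(T - K)."""
    denom = table.totals - table.knockdown
    bad = np.flatnonzero(denom <= 0)
    if bad.size:
        names = ", ".join(table.samples[i] for i in bad)
        raise NormalizationError(
            f"knockdown reads exhaust the library for sample(s) {names}: "
            "T - K <= 0"
        )
    M = float(denom.max())
    normalized = table.counts * (M / denom)
    return NormalizedTable(
        regions=list(table.regions),
        samples=list(table.samples),
        normalized=normalized,
        method="KDCS",
        M=M,
    )


def tcs_normalize(table: CountTable) -> NormalizedTable:
    """Total-count scaling: KDCS with K forced to zero."""
    zeroed = CountTable(
        regions=list(table.regions),
        samples=list(table.samples),
        counts=table.counts,
        totals=table.totals,
        knockdown=np.zeros_like(table.knockdown),
    )
    out = kdcs_normalize(zeroed)
    out.method = "TCS"
    return out


def size_factor_normalize(table: CountTable) -> NormalizedTable:
    """Median-of-ratios size factors (the DESeq2 scheme).

    Regions containing any zero count are excluded from size-factor
    estimation; the factors then divide every raw count.
    """
    counts = table.counts.astype(float)
    positive = (counts > 0).all(axis=1)
    if not positive.any():
        raise NormalizationError(
            "no region has strictly positive counts in every sample; "
            "size factors are undefined — use KDCS or TCS instead"
        )
    sub = counts[positive]
    log_geo_mean = np.log(sub).mean(axis=1)
    ratios = np.log(sub) - log_geo_mean[:, None]
    size_factors = np.exp(np.median(ratios, axis=0))
    return NormalizedTable(
        regions=list(table.regions),
        samples=list(table.samples),
        normalized=counts / size_factors,
        method="size_factor",
        size_factors=size_factors,
    )


NORMALIZERS = {
    "kdcs": kdcs_normalize,
    "tcs": tcs_normalize,
    "sizefactor": size_factor_normalize,
}


def write_normalized(table: NormalizedTable, path: str | Path) -> None:
    """Write normalized_counts.tsv: '#' metadata line, then region x sample."""
    from . import __version__

    meta = [f"srnakit={__version__}", f"method={table.method}"]
    if table.M is not None:
        meta.append(f"M={table.M:g}")
    if table.size_factors is not None:
        meta.append(
            "size_factors=" + ",".join(f"{f:.10g}" for f in table.size_factors)
        )
    with open(path, "w") as fh:
        fh.write("# " + " ".join(meta) + "\n")
        fh.write("region\t" + "\t".join(table.samples) + "\n")
        for i, region in enumerate(table.regions):
            row = "\t".join(f"{v:.10g}" for v in table.normalized[i])
            fh.write(f"{region}\t{row}\n")


def read_normalized(path: str | Path) -> NormalizedTable:
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
    df = pd.read_csv(path, sep="\t", comment="#", index_col=0)
    sf = meta.get("size_factors")
    return NormalizedTable(
        regions=list(df.index),
        samples=list(df.columns),
        normalized=df.to_numpy(dtype=float),
        method=meta.get("method", "unknown"),
        M=float(meta["M"]) if "M" in meta else None,
        size_factors=(
            np.array([float(x) for x in sf.split(",")]) if sf else None
        ),
    )
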