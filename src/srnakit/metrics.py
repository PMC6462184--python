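"""Comparison statistics across samples: coefficient of variation and
antisense ratio.

CoV_i = sigma_i / mu_i scores, per region i, how variable the (normalized)
counts are across samples — replicates of one system should agree, so a
lower CoV means a better normalization.  The sample (n-1) standard deviation
is used, appropriate for the small replicate numbers typical of knockdown
studies.

ASR_i = AS_i / R_i is the fraction of a region's reads aligned opposite to
its annotated strand.  It is a within-sample ratio of raw counts: any
per-sample scaling cancels, so normalization never enters.

Undefined values (CoV with n < 2 or zero mean; ASR with R = 0) are returned
as NaN and serialized as "NA", never silently as 0.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .normalize import NormalizedTable
from .stats import RegionStats, SampleStats


class MetricError(ValueError):
    pass


def coefficient_of_variation(values: Sequence[float]) -> float:
    """Sample standard deviation over mean; NaN when undefined.

    Undefined for fewer than two values or a non-positive mean.
    """
    arr = np.asarray(values, dtype=float)
    if arr.size < 2:
        return math.nan
    mu = arr.mean()
    if mu <= 0:
        return math.nan
    return float(arr.std(ddof=1) / mu)


def antisense_ratio(stats: RegionStats) -> float:
    """AS / R for one region in one sample; NaN when the region has no reads."""
    if stats.R == 0:
        return math.nan
    return stats.AS / stats.R


@dataclass
class MetricTable:
    """Per-region CoV (over samples) and per-region-per-sample ASR."""

    cov: pd.Series  # index: region; NaN where undefined
    asr: pd.DataFrame  # regions x samples; NaN where R = 0
    n: int  # number of samples
    method: str = ""  # normalization method behind the CoV column


def build_comparison_table(
    samples: list[SampleStats], normalized: NormalizedTable
) -> MetricTable:
    """Assemble the comparison metrics for one normalization.

    CoV is computed per region on the normalized counts across samples;
    ASR per region per sample from the raw AS and R counts.
    """
    norm_samples = list(normalized.samples)
    stat_names = [s.sample_name for s in samples]
    if set(stat_names) != set(norm_samples):
        raise MetricError(
            f"sample sets differ: stats {sorted(stat_names)} vs "
            f"normalized {sorted(norm_samples)}"
        )
    by_name = {s.sample_name: s for s in samples}
    ordered = [by_name[name] for name in norm_samples]

    frame = normalized.to_frame()
    cov = pd.Series(
        [coefficient_of_variation(frame.loc[r]) for r in normalized.regions],
        index=normalized.regions,
        name="CoV",
    )
    asr = pd.DataFrame(
        {
            s.sample_name: [
                antisense_ratio(s.region_stats[r])
                if r in s.region_stats
                else math.nan
                for r in normalized.regions
            ]
            for s in ordered
        },
        index=normalized.regions,
    )
    return MetricTable(cov=cov, asr=asr, n=len(ordered), method=normalized.method)


def cov_of_counts(counts: np.ndarray, regions: Sequence[str]) -> pd.Series:
    """Per-region CoV of a raw regions x samples count matrix."""
    return pd.Series(
        [coefficient_of_variation(row) for row in np.asarray(counts, float)],
        index=list(regions),
        name="CoV_raw",
    )


def write_cov_table(cov_columns: dict[str, pd.Series], path: str | Path) -> None:
    """Write comparison_cov.tsv with one CoV column per method run."""
    from . import __version__

    df = pd.DataFrame({f"CoV_{m}": s for m, s in cov_columns.items()})
    with open(path, "w") as fh:
        fh.write(f"# srnakit={__version__} table=comparison_cov\n")
        df.to_csv(fh, sep="\t", index_label="region", na_rep="NA", float_format="%.10g")


def write_asr_table(asr: pd.DataFrame, path: str | Path) -> None:
    """Write comparison_asr.tsv (region x sample, NA for regions without reads)."""
    from . import __version__

    with open(path, "w") as fh:
        fh.write(f"# srnakit={__version__} table=comparison_asr\n")
        asr.to_csv(fh, sep="\t", index_label="region", na_rep="NA", float_format="%.10g")


def read_metric_table(path: str | Path) -> pd.DataFrame:
    """Re-read a comparison TSV written by this module (NA -> NaN)."""
    return pd.read_csv(path, sep="\t", comment="#", index_col=0, na_values="NA")
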