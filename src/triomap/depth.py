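"""Read-depth screening for aneuploidies and large structural variants.

Whole-chromosome copy-number changes (e.g. a trisomy) and large deletions
or duplications shift binned read depth away from the diploid baseline.
The screen normalizes each sample's binned depth by its autosomal median —
so the nominal coverage level drops out — and flags chromosomes and
queried regions whose normalized ratio leaves the configured diploid band.

Expected ratios are 1.0 for two copies, 1.5 for three and 0.5 for one;
the default thresholds (0.75 / 1.25) sit midway between those states.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from enum import Enum
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "DepthProfile",
    "DepthFlag",
    "RegionDepth",
    "DepthSummary",
    "normalize_depth",
    "flag_regions",
    "read_depth_tsv",
    "write_depth_summary",
]

DEFAULT_LOSS_THRESHOLD = 0.75
DEFAULT_GAIN_THRESHOLD = 1.25


class DepthFlag(Enum):
    NORMAL = "NORMAL"
    LOSS = "LOSS"
    GAIN = "GAIN"
    NO_DATA = "NO_DATA"


@dataclass
class DepthProfile:
    """Binned mean read depth of one sample (fixed bin width, bp ≥ 0)."""

    sample_id: str
    bins: pd.DataFrame  # columns: chrom, start, end, mean_depth
    normalized: bool = False

    def __post_init__(self) -> None:
        required = {"chrom", "start", "end", "mean_depth"}
        if not required.issubset(self.bins.columns):
            raise ValueError(f"depth bins need columns {sorted(required)}")
        if (self.bins["mean_depth"] < 0).any():
            raise ValueError("depths must be non-negative")
        widths = (self.bins["end"] - self.bins["start"]).to_numpy()
        if len(widths) and not (widths == widths[0]).all():
            raise ValueError("bin width must be constant within a profile")


@dataclass(frozen=True)
class RegionDepth:
    chrom: str
    start: int
    end: int
    mean_ratio: float | None
    flag: DepthFlag


@dataclass
class DepthSummary:
    sample_id: str
    chrom_median_ratio: dict[str, float] = field(default_factory=dict)
    chrom_flags: dict[str, DepthFlag] = field(default_factory=dict)
    region_depths: list[RegionDepth] = field(default_factory=list)


def normalize_depth(
    profile: DepthProfile,
    exclude_chroms: Sequence[str] = (),
) -> DepthProfile:
    """Divide every bin's depth by the sample's autosomal median bin depth.

    ``exclude_chroms`` lists non-autosomal chromosomes (sex chromosomes,
    mitochondrion) excluded from the baseline; their bins are still
    normalized.  The autosomal median of the output is 1.0 by construction.
    Raises when the baseline depth is zero (e.g. all-zero input).
    """
    depths = profile.bins["mean_depth"].to_numpy(dtype=float)
    autosomal = ~profile.bins["chrom"].isin(list(exclude_chroms)).to_numpy()
    if not autosomal.any():
        raise ValueError("no autosomal bins to normalize against")
    baseline = float(np.median(depths[autosomal]))
    if baseline <= 0:
        raise ValueError("autosomal median depth is zero; cannot normalize")
    bins = profile.bins.copy()
    bins["mean_depth"] = depths / baseline
    return replace(profile, bins=bins, normalized=True)


def flag_regions(
    profile: DepthProfile,
    regions: Sequence[tuple[str, int, int]] = (),
    loss_threshold: float = DEFAULT_LOSS_THRESHOLD,
    gain_threshold: float = DEFAULT_GAIN_THRESHOLD,
) -> DepthSummary:
    """Flag chromosomes (median ratio) and regions (mean ratio) vs the diploid band.

    ``profile`` must be normalized.  Regions are 1-based inclusive
    intervals; a bin belongs to a region when it overlaps it.  A region
    covered by no bins is flagged NO_DATA rather than erroring.
    """
    if not profile.normalized:
        raise ValueError("profile must be normalized first (see normalize_depth)")

    def classify(ratio: float) -> DepthFlag:
        if ratio < loss_threshold:
            return DepthFlag.LOSS
        if ratio > gain_threshold:
            return DepthFlag.GAIN
        return DepthFlag.NORMAL

    summary = DepthSummary(sample_id=profile.sample_id)
    for chrom, grp in profile.bins.groupby("chrom", sort=False):
        med = float(grp["mean_depth"].median())
        summary.chrom_median_ratio[str(chrom)] = med
        summary.chrom_flags[str(chrom)] = classify(med)

    chroms = profile.bins["chrom"].to_numpy()
    starts = profile.bins["start"].to_numpy()
    ends = profile.bins["end"].to_numpy()
    ratios = profile.bins["mean_depth"].to_numpy(dtype=float)
    for chrom, start, end in regions:
        mask = (chroms == chrom) & (ends >= start) & (starts <= end)
        if not mask.any():
            summary.region_depths.append(RegionDepth(chrom, start, end, None, DepthFlag.NO_DATA))
            continue
        mean_ratio = float(ratios[mask].mean())
        summary.region_depths.append(
            RegionDepth(chrom, start, end, mean_ratio, classify(mean_ratio))
        )
    return summary


def read_depth_tsv(path: str | Path, sample_id: str | None = None) -> DepthProfile:
    """Read a per-sample binned depth TSV (chrom, start, end, mean_depth)."""
    bins = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    return DepthProfile(sample_id=sample_id or Path(path).stem, bins=bins)


def write_depth_summary(summary: DepthSummary, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("sample\tscope\tchrom\tstart\tend\tratio\tflag\n")
        for chrom, med in summary.chrom_median_ratio.items():
            fh.write(
                f"{summary.sample_id}\tchromosome\t{chrom}\t.\t.\t"
                f"{med:.4f}\t{summary.chrom_flags[chrom].value}\n"
            )
        for r in summary.region_depths:
            ratio = "NA" if r.mean_ratio is None else f"{r.mean_ratio:.4f}"
            fh.write(
                f"{summary.sample_id}\tregion\t{r.chrom}\t{r.start}\t{r.end}\t"
                f"{ratio}\t{r.flag.value}\n"
            )
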