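"""Runs of homozygosity and shared identity-by-descent regions.

In a consanguineous pedigree a recessive causal allele sits on a haplotype
inherited identical-by-descent (IBD) from a common ancestor through both
parental lines, so each affected animal is homozygous over a long stretch
around it.  This module detects per-sample runs of homozygosity (ROH) with
a deterministic consecutive-runs scanner, certifies that two cases' runs
carry the *same* haplotype by allelic matching of their overlap, and
annotates each shared region with whether the parents are compatible with
obligate-carrier status.

Detection model (consecutive-runs): a run is a maximal window of
consecutive markers whose endpoints are homozygous calls, containing at
most ``max_het_in_run`` heterozygous and ``max_missing_in_run`` missing
calls and no adjacent-marker gap above ``max_gap_kb``; runs shorter than
``min_length_kb`` or with fewer than ``min_snps`` markers are discarded.
Two maximal runs may overlap (a limited het budget can be spent on either
side); both are reported.

All coordinates are 1-based inclusive base pairs; lengths are
``end - start + 1``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from .variant_io import GenotypeCall, VariantRecord

__all__ = [
    "RohParams",
    "RohSegment",
    "ParentState",
    "SharedIbdRegion",
    "RegionSummary",
    "detect_roh",
    "match_segments",
    "shared_regions",
    "summarize_regions",
    "genotype_track",
    "write_segments_tsv",
    "write_regions_bed",
]

Track = Sequence[tuple[int, GenotypeCall]]


@dataclass(frozen=True)
class RohParams:
    """Tuning knobs of the ROH scanner and the cross-case matcher.

    ``min_length_kb`` (1000) and ``match_threshold`` (0.95) mirror standard
    homozygosity-mapping practice for WGS trio studies; the remaining knobs
    have no canonical published value and follow common ROH defaults.
    ``min_joint_snps`` guards allelic matching: a match fraction computed on
    a handful of jointly called markers certifies nothing.
    """

    min_length_kb: float = 1000.0
    min_snps: int = 50
    max_het_in_run: int = 1
    max_missing_in_run: int = 5
    max_gap_kb: float = 1000.0
    match_threshold: float = 0.95
    min_joint_snps: int = 20

    def __post_init__(self) -> None:
        if self.min_length_kb <= 0:
            raise ValueError("min_length_kb must be > 0")
        if not (0 < self.match_threshold <= 1):
            raise ValueError("match_threshold must be in (0, 1]")


@dataclass(frozen=True)
class RohSegment:
    sample_id: str
    chrom: str
    start: int  # 1-based inclusive bp
    end: int
    n_snps: int
    n_het: int
    n_missing: int

    @property
    def length_bp(self) -> int:
        return self.end - self.start + 1


class ParentState(Enum):
    HETEROZYGOUS_COMPATIBLE = "het_compatible"
    NOT_COMPATIBLE = "not_compatible"


@dataclass(frozen=True)
class SharedIbdRegion:
    """Intersection of two cases' allelically matched ROH segments."""

    chrom: str
    start: int
    end: int
    match_fraction: float
    parent_state: Mapping[str, ParentState]

    @property
    def length_bp(self) -> int:
        return self.end - self.start + 1

    def contains(self, chrom: str, pos: int) -> bool:
        return self.chrom == chrom and self.start <= pos <= self.end


@dataclass(frozen=True)
class RegionSummary:
    n_regions: int
    max_length_bp: int
    n_chroms: int


def genotype_track(
    records: Iterable[VariantRecord], sample_id: str, chrom: str
) -> list[tuple[int, GenotypeCall]]:
    """Ordered (pos, call) track of one sample along one chromosome."""
    return sorted(
        (rec.pos, rec.genotypes[sample_id]) for rec in records if rec.chrom == chrom
    )


# ---------------------------------------------------------------------------
# ROH detection
# ---------------------------------------------------------------------------

def _is_hom(call: GenotypeCall) -> bool:
    return not call.missing and call.allele_count_alt in (0, 2)


def detect_roh(
    track: Track,
    params: RohParams,
    *,
    sample_id: str = "",
    chrom: str = "",
) -> list[RohSegment]:
    """Detect maximal homozygous runs along one chromosome.

    ``track`` is an ordered (pos, GenotypeCall) sequence with strictly
    increasing positions (hard error otherwise).  Deterministic; see the
    module docstring for the run definition.
    """
    positions = [p for p, _ in track]
    for a, b in zip(positions, positions[1:]):
        if b <= a:
            raise ValueError(f"track positions not strictly increasing at {a} -> {b}")

    calls = [c for _, c in track]
    n = len(track)
    max_gap_bp = params.max_gap_kb * 1000.0

    # split into chunks no window may cross (gap too large)
    chunks: list[tuple[int, int]] = []
    start = 0
    for k in range(n - 1):
        if positions[k + 1] - positions[k] > max_gap_bp:
            chunks.append((start, k))
            start = k + 1
    if n:
        chunks.append((start, n - 1))

    segments: list[RohSegment] = []
    for lo, hi in chunks:
        segments.extend(
            _scan_chunk(positions, calls, lo, hi, params, sample_id, chrom)
        )
    return segments


def _scan_chunk(
    positions: Sequence[int],
    calls: Sequence[GenotypeCall],
    lo: int,
    hi: int,
    params: RohParams,
    sample_id: str,
    chrom: str,
) -> list[RohSegment]:
    """Two-pointer scan for maximal admissible windows in a gap-free chunk.

    For homozygous starts i in increasing order, the furthest admissible end
    j_max(i) is non-decreasing (constraints are hereditary under shrinking),
    so maximal windows are exactly the earliest start achieving each new
    j_max.
    """
    hom = [_is_hom(c) for c in calls]
    out: list[RohSegment] = []
    n_het = n_miss = 0
    r = lo  # window is [i, r); counts cover it
    last_j = -1
    for i in range(lo, hi + 1):
        if r < i:
            r = i
            n_het = n_miss = 0
        if not hom[i]:
            # drop i from window before moving on
            if r > i:
                if calls[i].missing:
                    n_miss -= 1
                elif calls[i].is_het:
                    n_het -= 1
            continue
        # extend r as far as budgets allow
        while r <= hi:
            c = calls[r]
            add_het = 1 if (not c.missing and c.is_het) else 0
            add_miss = 1 if c.missing else 0
            if n_het + add_het > params.max_het_in_run:
                break
            if n_miss + add_miss > params.max_missing_in_run:
                break
            n_het += add_het
            n_miss += add_miss
            r += 1
        # trim end to last homozygous call in [i, r)
        j = r - 1
        while j >= i and not hom[j]:
            j -= 1
        if j >= i and j > last_j:
            w_het = sum(1 for k in range(i, j + 1) if calls[k].is_het)
            w_miss = sum(1 for k in range(i, j + 1) if calls[k].missing)
            seg = RohSegment(
                sample_id=sample_id,
                chrom=chrom,
                start=positions[i],
                end=positions[j],
                n_snps=j - i + 1,
                n_het=w_het,
                n_missing=w_miss,
            )
            if seg.length_bp >= params.min_length_kb * 1000 and seg.n_snps >= params.min_snps:
                out.append(seg)
            last_j = j
        # remove i from the window counts (it is homozygous: no-op for budgets)
    return out


# ---------------------------------------------------------------------------
# Cross-case allelic matching
# ---------------------------------------------------------------------------

def match_segments(
    seg_a: RohSegment,
    seg_b: RohSegment,
    track_a: Track,
    track_b: Track,
    params: RohParams,
) -> tuple[tuple[int, int], float] | None:
    """Allelic match of two samples' ROH segments on the same chromosome.

    Returns the positional overlap interval and the fraction of identical
    genotypes over jointly non-missing markers inside it, or ``None`` when
    there is no overlap, fewer than ``min_joint_snps`` jointly called
    markers (matching cannot be certified), or the fraction falls below
    ``match_threshold``.
    """
    if seg_a.chrom != seg_b.chrom:
        return None
    start = max(seg_a.start, seg_b.start)
    end = min(seg_a.end, seg_b.end)
    if start > end:
        return None

    dos_a = {p: c.allele_count_alt for p, c in track_a
             if start <= p <= end and not c.missing}
    n_joint = n_same = 0
    for p, c in track_b:
        if p < start or p > end or c.missing:
            continue
        da = dos_a.get(p)
        if da is None:
            continue
        n_joint += 1
        if da == c.allele_count_alt:
            n_same += 1
    if n_joint < params.min_joint_snps:
        return None
    fraction = n_same / n_joint
    if fraction < params.match_threshold:
        return None
    return (start, end), fraction


def _parent_state(
    region: tuple[str, int, int],
    case_tracks: Sequence[Track],
    parent_track: Track,
) -> ParentState:
    """Obligate-carrier compatibility of one parent over a shared region.

    Candidate-compatible sites are the markers inside the region where both
    cases are homozygous for the alternate allele — the only places a shared
    recessive candidate can sit.  The parent is compatible iff it is
    heterozygous at one or more of those sites: the region can then harbor
    a recessive candidate for which this parent is an obligate carrier.
    (A parent homozygous-alt at *some* shared site does not refute carrier
    status — that site simply cannot be the candidate, since an unaffected
    parent cannot be homozygous for the causal allele; common alleles
    riding the shared haplotype routinely produce such sites.)  A region
    with no compatible het site yields NOT_COMPATIBLE.
    """
    chrom, start, end = region
    hom_alt_sites: set[int] | None = None
    for track in case_tracks:
        sites = {p for p, c in track
                 if start <= p <= end and not c.missing and c.allele_count_alt == 2}
        hom_alt_sites = sites if hom_alt_sites is None else hom_alt_sites & sites
    if not hom_alt_sites:
        return ParentState.NOT_COMPATIBLE
    for p, c in parent_track:
        if p in hom_alt_sites and c.is_het:
            return ParentState.HETEROZYGOUS_COMPATIBLE
    return ParentState.NOT_COMPATIBLE


def shared_regions(
    case_segments: Mapping[str, Sequence[RohSegment]],
    tracks: Mapping[str, Track],
    parent_ids: Sequence[str],
    params: RohParams,
    *,
    merge: bool = True,
) -> list[SharedIbdRegion]:
    """Shared IBD regions from two cases' ROH segments.

    Every pair of overlapping segments (one per case, same chromosome) that
    passes allelic matching contributes its intersection.  Each listed
    parent is annotated for obligate-carrier compatibility over the region.
    Overlapping regions with identical parent annotation are merged when
    ``merge`` is true (the reported match_fraction is the minimum of the
    merged parts); the raw pairwise view is available with ``merge=False``.
    Output is symmetric in the two cases and sorted by (chrom, start).
    """
    if len(case_segments) != 2:
        raise ValueError("shared_regions expects segments for exactly two cases")
    (case_a, segs_a), (case_b, segs_b) = sorted(case_segments.items())
    regions: list[SharedIbdRegion] = []
    for sa in segs_a:
        for sb in segs_b:
            matched = match_segments(sa, sb, tracks[case_a], tracks[case_b], params)
            if matched is None:
                continue
            (start, end), fraction = matched
            pstate = {
                pid: _parent_state(
                    (sa.chrom, start, end),
                    [tracks[case_a], tracks[case_b]],
                    tracks[pid],
                )
                for pid in parent_ids
            }
            regions.append(
                SharedIbdRegion(
                    chrom=sa.chrom, start=start, end=end,
                    match_fraction=fraction, parent_state=pstate,
                )
            )
    regions.sort(key=lambda r: (r.chrom, r.start, r.end))
    if not merge:
        return regions

    merged: list[SharedIbdRegion] = []
    for reg in regions:
        if (
            merged
            and merged[-1].chrom == reg.chrom
            and reg.start <= merged[-1].end + 1
            and dict(merged[-1].parent_state) == dict(reg.parent_state)
        ):
            prev = merged[-1]
            merged[-1] = SharedIbdRegion(
                chrom=prev.chrom,
                start=prev.start,
                end=max(prev.end, reg.end),
                match_fraction=min(prev.match_fraction, reg.match_fraction),
                parent_state=prev.parent_state,
            )
        else:
            merged.append(reg)
    return merged


def summarize_regions(regions: Sequence[SharedIbdRegion]) -> RegionSummary:
    """Count, maximum length (bp) and number of distinct chromosomes."""
    if not regions:
        return RegionSummary(0, 0, 0)
    return RegionSummary(
        n_regions=len(regions),
        max_length_bp=max(r.length_bp for r in regions),
        n_chroms=len({r.chrom for r in regions}),
    )


# ---------------------------------------------------------------------------
# Writers
# ---------------------------------------------------------------------------

def write_segments_tsv(segments: Sequence[RohSegment], path: str | Path) -> None:
    """PLINK-.hom-style table (1-based inclusive coordinates)."""
    with open(path, "w") as fh:
        fh.write("sample\tchrom\tstart\tend\tn_snps\tn_het\tn_missing\tlength_kb\n")
        for s in segments:
            fh.write(
                f"{s.sample_id}\t{s.chrom}\t{s.start}\t{s.end}\t"
                f"{s.n_snps}\t{s.n_het}\t{s.n_missing}\t{s.length_bp / 1000:.3f}\n"
            )


def write_regions_bed(regions: Sequence[SharedIbdRegion], path: str | Path) -> None:
    """Shared regions as BED (0-based half-open, converted on write)."""
    with open(path, "w") as fh:
        for r in regions:
            states = ",".join(f"{p}={s.value}" for p, s in sorted(r.parent_state.items()))
            fh.write(f"{r.chrom}\t{r.start - 1}\t{r.end}\t"
                     f"match={r.match_fraction:.4f};{states}\n")
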