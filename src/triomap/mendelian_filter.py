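"""Trio genotype-pattern filtering under competing inheritance scenarios.

Two scenarios are screened for a pair of affected paternal half-sibs with
sequenced parents:

* ``RECESSIVE_HOMOZYGOUS`` — the defect is a rare autosomal recessive: both
  cases are homozygous for the variant allele and all parents are obligate
  (heterozygous) carriers.  Control cohorts may carry the allele, but never
  homozygous.
* ``PATERNAL_GERMLINE_DENOVO`` — a dominant allele that arose in the sire's
  germline: heterozygous in the sire's (semen-derived) sample and in both
  cases, absent from the dams and from every control.

The cascade applies, in order: genotype pattern -> functional impact
(protein-changing: MODERATE/HIGH) -> local control-cohort exclusion ->
global control-catalog exclusion, and reports surviving counts per step.
"Private" is operationalized purely as absence (under the scenario's
policy) from the control cohorts; no allele-frequency threshold is used.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from .variant_io import Impact, Role, SampleSet, VariantRecord

__all__ = [
    "Scenario",
    "ControlPolicy",
    "ScenarioSpec",
    "RECESSIVE_HOMOZYGOUS",
    "PATERNAL_GERMLINE_DENOVO",
    "SCENARIOS",
    "CohortCounts",
    "CohortSummary",
    "FilterStep",
    "FilterReport",
    "summarize_cohort",
    "genotype_pattern_filter",
    "impact_filter",
    "cohort_exclusion_filter",
    "run_cascade",
    "candidate_region_check",
    "PROTEIN_CHANGING",
]

PROTEIN_CHANGING = frozenset({Impact.MODERATE, Impact.HIGH})


class Scenario(Enum):
    RECESSIVE_HOMOZYGOUS = "recessive"
    PATERNAL_GERMLINE_DENOVO = "denovo"


class ControlPolicy(Enum):
    """How control-cohort genotypes exclude a candidate variant."""

    EXCLUDE_IF_HOM_ALT = "hom_alt"
    EXCLUDE_IF_ANY_ALT = "any_alt"


@dataclass(frozen=True)
class ScenarioSpec:
    """Required genotype set per role plus the control-exclusion policy."""

    name: Scenario
    pattern: Mapping[Role, frozenset[int]]
    control_policy: ControlPolicy


RECESSIVE_HOMOZYGOUS = ScenarioSpec(
    name=Scenario.RECESSIVE_HOMOZYGOUS,
    pattern={
        Role.CASE: frozenset({2}),
        Role.DAM: frozenset({1}),
        Role.SIRE: frozenset({1}),
    },
    control_policy=ControlPolicy.EXCLUDE_IF_HOM_ALT,
)

PATERNAL_GERMLINE_DENOVO = ScenarioSpec(
    name=Scenario.PATERNAL_GERMLINE_DENOVO,
    pattern={
        Role.CASE: frozenset({1}),
        Role.DAM: frozenset({0}),
        Role.SIRE: frozenset({1}),
    },
    control_policy=ControlPolicy.EXCLUDE_IF_ANY_ALT,
)

SCENARIOS: dict[Scenario, ScenarioSpec] = {
    s.name: s for s in (RECESSIVE_HOMOZYGOUS, PATERNAL_GERMLINE_DENOVO)
}


@dataclass(frozen=True)
class CohortCounts:
    """Genotype-class counts for one variant in one control cohort."""

    n_hom_ref: int = 0
    n_het: int = 0
    n_hom_alt: int = 0
    n_missing: int = 0

    def __post_init__(self) -> None:
        if min(self.n_hom_ref, self.n_het, self.n_hom_alt, self.n_missing) < 0:
            raise ValueError("cohort counts must be non-negative")

    def as_tuple(self) -> tuple[int, int, int]:
        return (self.n_hom_ref, self.n_het, self.n_hom_alt)


@dataclass
class CohortSummary:
    """Occurrence catalog: per-variant genotype counts for a control cohort.

    Variants absent from the catalog are treated as unobserved in the cohort
    (absence of evidence = private).
    """

    name: str
    counts: dict[tuple[str, int, str, str], CohortCounts] = field(default_factory=dict)

    def get(self, key: tuple[str, int, str, str]) -> CohortCounts | None:
        return self.counts.get(key)

    def excludes(self, key: tuple[str, int, str, str], policy: ControlPolicy) -> bool:
        c = self.counts.get(key)
        if c is None:
            return False
        if policy is ControlPolicy.EXCLUDE_IF_HOM_ALT:
            return c.n_hom_alt > 0
        return c.n_het + c.n_hom_alt > 0

    def write_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("chrom\tpos\tref\talt\tn_hom_ref\tn_het\tn_hom_alt\tn_missing\n")
            for (chrom, pos, ref, alt), c in sorted(self.counts.items()):
                fh.write(
                    f"{chrom}\t{pos}\t{ref}\t{alt}\t"
                    f"{c.n_hom_ref}\t{c.n_het}\t{c.n_hom_alt}\t{c.n_missing}\n"
                )

    @classmethod
    def read_tsv(cls, path: str | Path, name: str | None = None) -> "CohortSummary":
        summary = cls(name=name or Path(path).stem)
        with open(path) as fh:
            header = fh.readline().rstrip("\n").split("\t")
            idx = {col: i for i, col in enumerate(header)}
            for line in fh:
                parts = line.rstrip("\n").split("\t")
                key = (parts[idx["chrom"]], int(parts[idx["pos"]]),
                       parts[idx["ref"]], parts[idx["alt"]])
                summary.counts[key] = CohortCounts(
                    n_hom_ref=int(parts[idx["n_hom_ref"]]),
                    n_het=int(parts[idx["n_het"]]),
                    n_hom_alt=int(parts[idx["n_hom_alt"]]),
                    n_missing=int(parts[idx.get("n_missing", -1)]) if "n_missing" in idx else 0,
                )
        return summary


@dataclass
class FilterStep:
    name: str
    scenario: Scenario
    variants_in: int
    variants_out: int

    def __post_init__(self) -> None:
        if self.variants_out > self.variants_in:
            raise ValueError("a filter step cannot add variants")


@dataclass
class FilterReport:
    """Ordered cascade steps with surviving counts plus the final candidates."""

    scenario: Scenario
    steps: list[FilterStep] = field(default_factory=list)
    candidates: list[VariantRecord] = field(default_factory=list)
    manual_review: str = "not performed"

    def add_step(self, name: str, n_in: int, n_out: int) -> None:
        self.steps.append(FilterStep(name, self.scenario, n_in, n_out))

    def to_rows(self) -> list[dict]:
        return [
            {"step": s.name, "scenario": s.scenario.value,
             "variants_in": s.variants_in, "variants_out": s.variants_out}
            for s in self.steps
        ]

    def write_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("step\tscenario\tvariants_in\tvariants_out\n")
            for s in self.steps:
                fh.write(f"{s.name}\t{s.scenario.value}\t{s.variants_in}\t{s.variants_out}\n")


def summarize_cohort(
    records: Iterable[VariantRecord],
    sample_ids: Sequence[str],
    name: str = "cohort",
) -> CohortSummary:
    """Collapse per-sample genotypes of a control cohort into a count catalog."""
    summary = CohortSummary(name=name)
    for rec in records:
        n_rr = n_rv = n_vv = n_miss = 0
        for s in sample_ids:
            call = rec.genotypes.get(s)
            if call is None or call.missing:
                n_miss += 1
            elif call.allele_count_alt == 0:
                n_rr += 1
            elif call.allele_count_alt == 1:
                n_rv += 1
            else:
                n_vv += 1
        summary.counts[rec.key] = CohortCounts(n_rr, n_rv, n_vv, n_miss)
    return summary


# ---------------------------------------------------------------------------
# Filters
# ---------------------------------------------------------------------------

def genotype_pattern_filter(
    records: Iterable[VariantRecord],
    sample_set: SampleSet,
    scenario: ScenarioSpec,
) -> list[VariantRecord]:
    """Keep records whose trio genotypes match the scenario pattern exactly.

    Every CASE/DAM/SIRE sample must be non-missing and carry a dosage in the
    scenario's required set for its role; a missing trio genotype fails the
    pattern (strict — the trio genotypes are treated as confirmed calls).
    """
    role_samples = [
        (samples, scenario.pattern[role])
        for role in (Role.CASE, Role.DAM, Role.SIRE)
        if (samples := sample_set.with_role(role))
    ]
    for role in scenario.pattern:
        if not sample_set.with_role(role):
            raise ValueError(f"scenario {scenario.name.value} needs a {role.value} sample")

    out = []
    for rec in records:
        ok = True
        for samples, allowed in role_samples:
            for s in samples:
                call = rec.genotypes.get(s)
                if call is None or call.missing or call.allele_count_alt not in allowed:
                    ok = False
                    break
            if not ok:
                break
        if ok:
            out.append(rec)
    return out


def impact_filter(
    records: Iterable[VariantRecord],
    allowed: frozenset[Impact] | set[Impact] = PROTEIN_CHANGING,
) -> list[VariantRecord]:
    """Keep protein-changing records (impact in ``allowed``); unset impact fails."""
    return [rec for rec in records if rec.impact is not None and rec.impact in allowed]


def cohort_exclusion_filter(
    records: Iterable[VariantRecord],
    cohort: CohortSummary,
    policy: ControlPolicy,
) -> list[VariantRecord]:
    """Drop records observed in the control cohort under the given policy.

    ``EXCLUDE_IF_HOM_ALT`` tolerates heterozygous carriers (recessive
    scenario); ``EXCLUDE_IF_ANY_ALT`` tolerates none (de novo scenario).
    Records absent from the catalog survive.
    """
    return [rec for rec in records if not cohort.excludes(rec.key, policy)]


def run_cascade(
    records: Sequence[VariantRecord],
    sample_set: SampleSet,
    local_cohort: CohortSummary,
    global_cohort: CohortSummary,
    scenario: ScenarioSpec,
) -> FilterReport:
    """Run the full filtering cascade for one scenario and report per-step counts."""
    report = FilterReport(scenario=scenario.name)
    surviving = list(records)

    n_in = len(surviving)
    surviving = genotype_pattern_filter(surviving, sample_set, scenario)
    report.add_step("genotype_pattern", n_in, len(surviving))

    n_in = len(surviving)
    surviving = impact_filter(surviving)
    report.add_step("protein_changing_impact", n_in, len(surviving))

    n_in = len(surviving)
    surviving = cohort_exclusion_filter(surviving, local_cohort, scenario.control_policy)
    report.add_step(f"absent_in_{local_cohort.name}", n_in, len(surviving))

    n_in = len(surviving)
    surviving = cohort_exclusion_filter(surviving, global_cohort, scenario.control_policy)
    report.add_step(f"absent_in_{global_cohort.name}", n_in, len(surviving))

    report.candidates = surviving
    return report


def candidate_region_check(
    candidates: Iterable[VariantRecord],
    shared_regions: Sequence,
) -> list[tuple[VariantRecord, int | None]]:
    """Flag each candidate with the index of the containing shared IBD region.

    A candidate is contained when its position lies within ``[start, end]``
    (1-based inclusive) of a region on the same chromosome; ``None`` when no
    region contains it.
    """
    out: list[tuple[VariantRecord, int | None]] = []
    for rec in candidates:
        hit = None
        for i, region in enumerate(shared_regions):
            if region.chrom == rec.chrom and region.start <= rec.pos <= region.end:
                hit = i
                break
        out.append((rec, hit))
    return out
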