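"""Population segregation analysis of candidate variants.

Once a candidate recessive variant is identified from the trio, targeted
genotyping of the breeding population measures how widespread the allele
is: genotype-class counts per cohort (affected, obligate carriers,
screened bulls, external controls), the allele frequency with a Wilson
score interval, carrier prevalence by group (e.g. birth year), and — for
two candidate loci — a digenic co-segregation table asking whether disease
requires homozygosity at both loci simultaneously.

Genotypes are alt-allele dosages (0 = ref/ref, 1 = ref/var, 2 = var/var);
``None`` marks a failed/missing genotype, which is counted separately and
excluded from every denominator.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Hashable, Iterable, Mapping, Sequence

import numpy as np
from statsmodels.stats.proportion import proportion_confint

__all__ = [
    "GenotypeCounts",
    "GenotypeCountTable",
    "AlleleFrequencyEstimate",
    "DigenicTable",
    "GroupPrevalence",
    "count_genotypes",
    "allele_frequency",
    "digenic_cosegregation",
    "carrier_prevalence_by_group",
]


@dataclass(frozen=True)
class GenotypeCounts:
    n_ref_ref: int = 0
    n_ref_var: int = 0
    n_var_var: int = 0
    n_missing: int = 0

    def __post_init__(self) -> None:
        if min(self.n_ref_ref, self.n_ref_var, self.n_var_var, self.n_missing) < 0:
            raise ValueError("genotype counts must be non-negative")

    @property
    def n(self) -> int:
        """Successfully genotyped individuals (missing excluded)."""
        return self.n_ref_ref + self.n_ref_var + self.n_var_var

    def as_tuple(self) -> tuple[int, int, int]:
        return (self.n_ref_ref, self.n_ref_var, self.n_var_var)


@dataclass
class GenotypeCountTable:
    """Per-cohort genotype-class counts for one locus."""

    locus: str
    cohorts: dict[str, GenotypeCounts] = field(default_factory=dict)

    def cohort(self, name: str) -> GenotypeCounts:
        return self.cohorts.get(name, GenotypeCounts())


@dataclass(frozen=True)
class AlleleFrequencyEstimate:
    """Variant-allele frequency with a Wilson 95% interval on 2N allele trials.

    The source studies of this kind report only a rounded percentage; the
    interval is an addition of this package, labelled as such in output.
    """

    q_hat: float
    n_alleles: int
    ci95: tuple[float, float]

    @property
    def percent_rounded(self) -> int:
        return int(round(100.0 * self.q_hat))


@dataclass
class DigenicTable:
    """3x3 joint genotype table at two loci, split by affection status."""

    locus_a: str
    locus_b: str
    affected: np.ndarray  # shape (3, 3); [dosage_a, dosage_b]
    unaffected: np.ndarray
    verdicts: list[str]
    n_individuals: int

    def marginal(self, locus: str) -> GenotypeCounts:
        joint = self.affected + self.unaffected
        if locus == self.locus_a:
            totals = joint.sum(axis=1)
        elif locus == self.locus_b:
            totals = joint.sum(axis=0)
        else:
            raise KeyError(locus)
        return GenotypeCounts(int(totals[0]), int(totals[1]), int(totals[2]))


@dataclass(frozen=True)
class GroupPrevalence:
    group: Hashable
    n: int
    n_carriers: int
    fraction: float | None  # None when the group has no genotyped individuals


# ---------------------------------------------------------------------------


def count_genotypes(
    genotypes: Mapping[str, int | None],
    cohort_of: Mapping[str, str],
    locus: str = "locus",
) -> GenotypeCountTable:
    """Exact genotype-class counts per cohort at one locus.

    ``genotypes`` maps sample id -> dosage (``None`` = missing);
    ``cohort_of`` maps sample id -> cohort label.  Samples without a cohort
    label are ignored.
    """
    acc: dict[str, list[int]] = {}
    for sample, dosage in genotypes.items():
        cohort = cohort_of.get(sample)
        if cohort is None:
            continue
        counts = acc.setdefault(cohort, [0, 0, 0, 0])
        counts[3 if dosage is None else dosage] += 1
    return GenotypeCountTable(
        locus=locus,
        cohorts={
            name: GenotypeCounts(c[0], c[1], c[2], c[3]) for name, c in acc.items()
        },
    )


def allele_frequency(counts: GenotypeCounts | tuple[int, int, int]) -> AlleleFrequencyEstimate:
    """Variant-allele frequency q = (n_het + 2 n_hom_var) / 2N with Wilson CI."""
    if isinstance(counts, tuple):
        counts = GenotypeCounts(*counts)
    n = counts.n
    if n < 1:
        raise ValueError("allele_frequency needs at least one genotyped individual")
    n_alleles = 2 * n
    n_var = counts.n_ref_var + 2 * counts.n_var_var
    q_hat = n_var / n_alleles
    lower, upper = proportion_confint(n_var, n_alleles, alpha=0.05, method="wilson")
    return AlleleFrequencyEstimate(q_hat=q_hat, n_alleles=n_alleles, ci95=(float(lower), float(upper)))


def digenic_cosegregation(
    genotypes_a: Mapping[str, int | None],
    genotypes_b: Mapping[str, int | None],
    affected: Mapping[str, bool],
    locus_a: str = "A",
    locus_b: str = "B",
) -> DigenicTable:
    """Joint two-locus genotype table with co-segregation verdicts.

    Only individuals genotyped at both loci enter the table.  Verdicts:

    * ``digenic-consistent`` — every affected individual is var/var at both
      loci and no unaffected individual is; the digenic-recessive model
      survives.
    * ``digenic-inconsistent`` — some unaffected individual is var/var at
      both loci, or an affected one is not.
    * ``monogenic-<locus>-inconsistent`` — some unaffected individual is
      var/var at that locus alone, refuting a single-locus fully penetrant
      recessive model there.
    * ``uninformative`` — no individual carries a var/var genotype at
      either locus, so consistency holds vacuously.
    """
    aff = np.zeros((3, 3), dtype=int)
    unaff = np.zeros((3, 3), dtype=int)
    n = 0
    affected_ok = True
    unaffected_dd = False
    mono_a_bad = mono_b_bad = False
    any_var_var = False
    for sample, da in genotypes_a.items():
        db = genotypes_b.get(sample)
        if da is None or db is None:
            continue
        n += 1
        is_aff = bool(affected.get(sample, False))
        (aff if is_aff else unaff)[da, db] += 1
        if da == 2 or db == 2:
            any_var_var = True
        if is_aff and not (da == 2 and db == 2):
            affected_ok = False
        if not is_aff:
            if da == 2 and db == 2:
                unaffected_dd = True
            if da == 2:
                mono_a_bad = True
            if db == 2:
                mono_b_bad = True

    verdicts: list[str] = []
    if not any_var_var:
        verdicts.append("uninformative")
    if affected_ok and not unaffected_dd:
        verdicts.append("digenic-consistent")
    else:
        verdicts.append("digenic-inconsistent")
    if mono_a_bad:
        verdicts.append(f"monogenic-{locus_a}-inconsistent")
    if mono_b_bad:
        verdicts.append(f"monogenic-{locus_b}-inconsistent")
    return DigenicTable(
        locus_a=locus_a, locus_b=locus_b,
        affected=aff, unaffected=unaff,
        verdicts=verdicts, n_individuals=n,
    )


def carrier_prevalence_by_group(
    genotypes: Mapping[str, int | None],
    group_of: Mapping[str, Hashable],
    groups: Sequence[Hashable] | None = None,
) -> list[GroupPrevalence]:
    """Carrier (het + hom-var) fraction per group, e.g. per birth year.

    Missing genotypes are excluded from the denominator; a group with no
    genotyped individuals reports ``n=0`` and an undefined fraction.
    """
    order: list[Hashable] = list(groups) if groups is not None else sorted(
        set(group_of.values()), key=str
    )
    acc: dict[Hashable, list[int]] = {g: [0, 0] for g in order}
    for sample, dosage in genotypes.items():
        g = group_of.get(sample)
        if g not in acc or dosage is None:
            continue
        acc[g][0] += 1
        if dosage >= 1:
            acc[g][1] += 1
    return [
        GroupPrevalence(
            group=g, n=acc[g][0], n_carriers=acc[g][1],
            fraction=(acc[g][1] / acc[g][0]) if acc[g][0] else None,
        )
        for g in order
    ]
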