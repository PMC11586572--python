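"""Synthetic pedigree-cohort generator for the trio prioritization pipeline.

Emulates the data the analysis assumes, without any external download:

* a consanguineous pedigree — two affected paternal half-sibs, their two
  dams and the common sire, with an inbreeding loop through a common
  ancestor;
* an ancestral haplotype carrying an injected recessive variant,
  transmitted through *both* parental lines to both cases, so the cases
  are homozygous over a long run around the variant and the parents are
  obligate heterozygous carriers;
* an injected paternal-germline (de novo) variant: heterozygous in the
  sire's sample and both cases, absent from dams and every control;
* a digenic pair: two recessive injections on different chromosomes plus
  one screened bull homozygous at exactly one of them;
* biallelic SNV background drawn under Hardy-Weinberg from a Beta
  allele-frequency spectrum, gene-dropped through the pedigree;
* a local control cohort emitted per sample and a larger global cohort
  emitted as a genotype-count catalog;
* binned read-depth profiles with optional trisomy/deletion events.

Model notes.  Founder haplotypes are independent Bernoulli(q) draws per
marker; offspring gametes recombine parental haplotypes with Poisson
crossovers.  Around each injected recessive locus the ancestral haplotype
spans a fixed core interval (``ancestral_haplotype_length_kb``); gametes
are conditioned to transmit it at the locus, and linkage outside the core
is broken (fresh crossover phase per flank), so the planted identical
segment never silently extends beyond the core and background markers
outside cores follow the unconditional transmission model exactly.  That
makes the cascade-survival probability of a background marker with allele
frequency q closed-form; see :func:`expected_background_survivors`.

Everything is deterministic given the seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from enum import Enum
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .depth import DepthProfile
from .mendelian_filter import CohortCounts, CohortSummary
from .variant_io import Impact, Role, SampleSet, VariantRecord, call_of

__all__ = [
    "InjectionKind",
    "Injection",
    "DepthEvent",
    "DepthConfig",
    "SimConfig",
    "InjectionTruth",
    "TruthTable",
    "SyntheticCohort",
    "simulate_cohort",
    "expected_background_survivors",
    "Table2Fixture",
    "emit_table2_fixture",
]

TRIO_IDS = ("case1", "case2", "dam1", "dam2", "sire")
TRIO_ROLES: dict[str, Role] = {
    "case1": Role.CASE,
    "case2": Role.CASE,
    "dam1": Role.DAM,
    "dam2": Role.DAM,
    "sire": Role.SIRE,
}


class InjectionKind(Enum):
    RECESSIVE_IBD = "recessive_ibd"
    PATERNAL_DENOVO = "paternal_denovo"
    DIGENIC_PAIR = "digenic_pair"


@dataclass(frozen=True)
class Injection:
    """One planted variant (or pair, for DIGENIC_PAIR via chrom2/pos2).

    ``carrier_freq_controls`` is the heterozygous-carrier rate in the
    control cohorts (controls are never made homozygous for an injected
    allele); ``bull_carrier_freq`` is the het rate in the screened-bull
    genotyping cohort.
    """

    kind: InjectionKind
    chrom: str
    pos: int
    carrier_freq_controls: float = 0.0
    bull_carrier_freq: float = 0.0
    chrom2: str | None = None
    pos2: int | None = None
    bull_carrier_freq2: float = 0.0
    impact: Impact = Impact.MODERATE


@dataclass(frozen=True)
class DepthEvent:
    """A planted copy-number event: whole-chromosome trisomy or a deletion."""

    kind: str  # "trisomy" | "deletion"
    chrom: str
    start: int | None = None  # deletion only, 1-based inclusive
    end: int | None = None
    sample_id: str = "case1"

    def __post_init__(self) -> None:
        if self.kind not in ("trisomy", "deletion"):
            raise ValueError(f"unknown depth event kind {self.kind!r}")
        if self.kind == "deletion" and (self.start is None or self.end is None):
            raise ValueError("deletion events need start and end")


@dataclass(frozen=True)
class DepthConfig:
    mean_depth: float = 18.2  # nominal WGS coverage of the emulated study
    noise_cv: float = 0.15
    bin_width: int = 10_000
    events: tuple[DepthEvent, ...] = ()


def _default_injections() -> tuple[Injection, ...]:
    return (
        Injection(
            kind=InjectionKind.DIGENIC_PAIR,
            chrom="2", pos=10_000_000, bull_carrier_freq=0.10,
            chrom2="4", pos2=10_000_000, bull_carrier_freq2=0.03,
        ),
        Injection(kind=InjectionKind.PATERNAL_DENOVO, chrom="1", pos=10_000_000),
    )


@dataclass(frozen=True)
class SimConfig:
    """Study conditions of the emulated cohort; the seed fully determines output."""

    seed: int = 0
    n_chroms: int = 5
    chrom_length_bp: int = 20_000_000
    markers_per_mb: float = 100.0
    af_beta: tuple[float, float] = (0.2, 2.0)
    n_local_controls: int = 942
    n_global_controls: int = 5279
    n_screened_bulls: int = 332
    bull_years: tuple[int, ...] = (2017, 2018, 2019, 2020)
    injections: tuple[Injection, ...] = field(default_factory=_default_injections)
    ancestral_haplotype_length_kb: float = 2000.0
    recombination_rate_per_mb: float = 0.01  # 1 crossover / 100 Mb / meiosis
    # background impact spectrum: most variants are non-coding
    impact_probs: Mapping[str, float] = field(
        default_factory=lambda: {"MODIFIER": 0.93, "LOW": 0.03, "MODERATE": 0.03, "HIGH": 0.01}
    )
    depth: DepthConfig = field(default_factory=DepthConfig)

    def chrom_names(self) -> list[str]:
        return [str(i + 1) for i in range(self.n_chroms)]

    def validate(self) -> None:
        names = set(self.chrom_names())
        seen: set[tuple[str, int]] = set()
        for inj in self.injections:
            loci = [(inj.chrom, inj.pos)]
            if inj.kind is InjectionKind.DIGENIC_PAIR:
                if inj.chrom2 is None or inj.pos2 is None:
                    raise ValueError("DIGENIC_PAIR needs chrom2/pos2")
                loci.append((inj.chrom2, inj.pos2))
            for chrom, pos in loci:
                if chrom not in names:
                    raise ValueError(f"injection chromosome {chrom!r} not simulated")
                if not (1 <= pos <= self.chrom_length_bp):
                    raise ValueError(f"injection position {chrom}:{pos} out of bounds")
                if (chrom, pos) in loci[: loci.index((chrom, pos))] or (chrom, pos) in seen:
                    raise ValueError(f"duplicate injection at {chrom}:{pos}")
                seen.add((chrom, pos))
            if not (0 <= inj.carrier_freq_controls <= 1):
                raise ValueError("carrier_freq_controls must be in [0, 1]")


@dataclass(frozen=True)
class InjectionTruth:
    key: tuple[str, int, str, str]
    kind: InjectionKind
    scenario: str  # "recessive" | "denovo" — expected final cascade membership
    core_interval: tuple[str, int, int] | None  # planted IBD interval


@dataclass
class TruthTable:
    injections: list[InjectionTruth]
    depth_events: list[DepthEvent]

    def keys_for_scenario(self, scenario: str) -> set[tuple[str, int, str, str]]:
        return {t.key for t in self.injections if t.scenario == scenario}

    def planted_intervals(self) -> list[tuple[str, int, int]]:
        return [t.core_interval for t in self.injections if t.core_interval]

    def to_json(self, path: str | Path) -> None:
        payload = {
            "injections": [
                {
                    "chrom": t.key[0], "pos": t.key[1], "ref": t.key[2], "alt": t.key[3],
                    "kind": t.kind.value, "scenario": t.scenario,
                    "core_interval": list(t.core_interval) if t.core_interval else None,
                }
                for t in self.injections
            ],
            "depth_events": [
                {"kind": e.kind, "chrom": e.chrom, "start": e.start,
                 "end": e.end, "sample_id": e.sample_id}
                for e in self.depth_events
            ],
        }
        Path(path).write_text(json.dumps(payload, indent=2) + "\n")


# ---------------------------------------------------------------------------
# internal marker bookkeeping
# ---------------------------------------------------------------------------

_BASES = np.array(list("ACGT"))
_GT_STR = {0: "0/0", 1: "0/1", 2: "1/1"}


@dataclass
class _ChromSim:
    """Per-chromosome marker grid plus the planted loci on it."""

    name: str
    positions: np.ndarray  # strictly increasing, int
    q: np.ndarray  # population allele frequency per marker
    cond_index: int | None = None  # marker index gametes are conditioned on
    core: tuple[int, int] | None = None  # bp interval of the ancestral segment
    denovo_index: int | None = None


class SyntheticCohort:
    """In-memory result of :func:`simulate_cohort`, with file emitters."""

    def __init__(
        self,
        config: SimConfig,
        sample_set: SampleSet,
        records: list[VariantRecord],
        local_catalog: CohortSummary,
        global_catalog: CohortSummary,
        local_matrix: np.ndarray,
        allele_freqs: np.ndarray,
        depth_profiles: dict[str, DepthProfile],
        bull_genotypes: dict[str, dict[str, int | None]],
        bull_year: dict[str, int],
        affection: dict[str, bool],
        truth: TruthTable,
    ) -> None:
        self.config = config
        self.sample_set = sample_set
        self.records = records
        self.local_catalog = local_catalog
        self.global_catalog = global_catalog
        self.local_matrix = local_matrix
        self.allele_freqs = allele_freqs
        self.depth_profiles = depth_profiles
        self.bull_genotypes = bull_genotypes
        self.bull_year = bull_year
        self.affection = affection
        self.truth = truth

    # -- file emission ------------------------------------------------------

    def write_vcf(self, path: str | Path, include_local_controls: bool = True) -> None:
        """Emit a VCF 4.2 with trio (and optionally local-control) columns."""
        n_local = self.local_matrix.shape[0] if include_local_controls else 0
        control_ids = [f"ctrl{i + 1:04d}" for i in range(n_local)]
        with open(path, "w") as fh:
            fh.write("##fileformat=VCFv4.2\n")
            for chrom in self.config.chrom_names():
                fh.write(f"##contig=<ID={chrom},length={self.config.chrom_length_bp}>\n")
            fh.write('##INFO=<ID=ANN,Number=.,Type=String,Description="Functional annotations: '
                     "'Allele|Annotation|Annotation_Impact|Gene_Name'\">\n")
            fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
            fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                     + "\t".join(list(TRIO_IDS) + control_ids) + "\n")
            for idx, rec in enumerate(self.records):
                ann = f"ANN={rec.alt}|variant|{rec.impact.name}|{rec.gene}" if rec.impact else "."
                gts = [_GT_STR.get(rec.dosage(s), "./.") if rec.dosage(s) is not None
                       else "./." for s in TRIO_IDS]
                if n_local:
                    gts.extend(_GT_STR[int(d)] for d in self.local_matrix[:, idx])
                fh.write(f"{rec.chrom}\t{rec.pos}\t.\t{rec.ref}\t{rec.alt}\t.\t.\t{ann}\tGT\t"
                         + "\t".join(gts) + "\n")

    def write_pedigree(self, path: str | Path, include_local_controls: bool = True) -> None:
        rows = [
            ("case1", "sire", "dam1", "F", "affected", "case"),
            ("case2", "sire", "dam2", "M", "affected", "case"),
            ("dam1", "0", "0", "F", "unaffected", "dam"),
            ("dam2", "0", "0", "F", "unaffected", "dam"),
            ("sire", "0", "0", "M", "unaffected", "sire"),
        ]
        if include_local_controls:
            rows += [
                (f"ctrl{i + 1:04d}", "0", "0", "U", "unaffected", "local_control")
                for i in range(self.local_matrix.shape[0])
            ]
        with open(path, "w") as fh:
            fh.write("id\tsire\tdam\tsex\tstatus\trole\n")
            for row in rows:
                fh.write("\t".join(row) + "\n")

    def write_bull_genotypes(self, path: str | Path) -> None:
        loci = sorted(self.bull_genotypes)
        with open(path, "w") as fh:
            fh.write("sample\tyear\t" + "\t".join(loci) + "\n")
            for bull in sorted(self.bull_year):
                row = [bull, str(self.bull_year[bull])]
                for locus in loci:
                    d = self.bull_genotypes[locus].get(bull)
                    row.append("NA" if d is None else str(d))
                fh.write("\t".join(row) + "\n")

    def write_depth_tsvs(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        for sample, profile in self.depth_profiles.items():
            profile.bins.to_csv(outdir / f"depth_{sample}.tsv", sep="\t", index=False)

    def write_all(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.write_vcf(outdir / "cohort.vcf")
        self.write_pedigree(outdir / "pedigree.tsv")
        self.local_catalog.write_tsv(outdir / "local_catalog.tsv")
        self.global_catalog.write_tsv(outdir / "global_catalog.tsv")
        self.write_bull_genotypes(outdir / "bull_genotypes.tsv")
        self.write_depth_tsvs(outdir)
        self.truth.to_json(outdir / "truth.json")


# ---------------------------------------------------------------------------
# simulation
# ---------------------------------------------------------------------------

def _marker_grid(config: SimConfig) -> list[_ChromSim]:
    """Evenly spaced markers per chromosome, with injected loci inserted."""
    spacing = 1_000_000.0 / config.markers_per_mb
    half_core = config.ancestral_haplotype_length_kb * 500.0  # kb -> bp, halved
    injected: dict[str, list[tuple[int, InjectionKind]]] = {}
    for inj in config.injections:
        if inj.kind is InjectionKind.DIGENIC_PAIR:
            injected.setdefault(inj.chrom, []).append((inj.pos, InjectionKind.RECESSIVE_IBD))
            injected.setdefault(inj.chrom2, []).append((inj.pos2, InjectionKind.RECESSIVE_IBD))
        else:
            injected.setdefault(inj.chrom, []).append((inj.pos, inj.kind))

    chroms: list[_ChromSim] = []
    for name in config.chrom_names():
        n = int(round(config.markers_per_mb * config.chrom_length_bp / 1e6))
        base = np.round((np.arange(n) + 0.5) * spacing).astype(int)
        extra = [pos for pos, _ in injected.get(name, [])]
        positions = np.unique(np.concatenate([base, np.array(extra, dtype=int)])) if extra else base
        chrom = _ChromSim(name=name, positions=positions, q=np.empty(0))
        for pos, kind in injected.get(name, []):
            idx = int(np.searchsorted(positions, pos))
            if kind is InjectionKind.RECESSIVE_IBD:
                if chrom.cond_index is not None:
                    raise ValueError(f"two conditioned loci on chromosome {name}")
                chrom.cond_index = idx
                chrom.core = (
                    max(1, int(pos - half_core)),
                    min(config.chrom_length_bp, int(pos + half_core)),
                )
            else:
                if chrom.denovo_index is not None or chrom.cond_index is not None:
                    raise ValueError(f"two conditioned loci on chromosome {name}")
                chrom.denovo_index = idx
        chroms.append(chrom)
    return chroms


def _gamete_mask(
    rng: np.random.Generator,
    positions: np.ndarray,
    chrom_len: int,
    rate_per_mb: float,
    cond_index: int | None,
    core: tuple[int, int] | None,
) -> np.ndarray:
    """Boolean mask per marker: False = transmit haplotype 0, True = haplotype 1.

    Unconditioned: a single Poisson-crossover process with random phase.
    Conditioned: the mask is forced to haplotype 0 at ``cond_index``; the
    flanks outside ``core`` get independent crossover phase (linkage to the
    planted segment is broken at the core boundary by construction).
    """

    def process(pos: np.ndarray, span_bp: float) -> np.ndarray:
        n_x = rng.poisson(rate_per_mb * span_bp / 1e6)
        xpos = np.sort(rng.uniform(0, span_bp, size=n_x))
        start = rng.integers(0, 2)
        if len(pos) == 0:
            return np.zeros(0, dtype=bool)
        origin = pos[0]
        cum = np.searchsorted(xpos, pos - origin)
        return ((start + cum) % 2).astype(bool)

    if cond_index is None:
        return process(positions, chrom_len)

    assert core is not None
    a, b = core
    in_core = (positions >= a) & (positions <= b)
    left = positions[positions < a]
    right = positions[positions > b]
    core_pos = positions[in_core]
    core_mask = process(core_pos, float(b - a + 1))
    j = int(np.searchsorted(core_pos, positions[cond_index]))
    if core_mask[j]:
        core_mask = ~core_mask
    mask = np.empty(len(positions), dtype=bool)
    mask[positions < a] = process(left, float(max(a - 1, 1)))
    mask[in_core] = core_mask
    mask[positions > b] = process(right, float(max(chrom_len - b, 1)))
    return mask


def simulate_cohort(config: SimConfig) -> SyntheticCohort:
    """Generate the full synthetic cohort (see module docstring for the model)."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    chroms = _marker_grid(config)

    impact_names = list(config.impact_probs)
    impact_p = np.array([config.impact_probs[k] for k in impact_names], dtype=float)
    impact_p = impact_p / impact_p.sum()

    records: list[VariantRecord] = []
    local_cols: list[np.ndarray] = []
    q_all: list[np.ndarray] = []
    truth_inj: list[InjectionTruth] = []
    key_of_locus: dict[tuple[str, int], tuple[str, int, str, str]] = {}

    inj_controls_freq: dict[tuple[str, int], float] = {}
    for inj in config.injections:
        inj_controls_freq[(inj.chrom, inj.pos)] = inj.carrier_freq_controls
        if inj.kind is InjectionKind.DIGENIC_PAIR:
            inj_controls_freq[(inj.chrom2, inj.pos2)] = inj.carrier_freq_controls

    global_counts: dict[tuple[str, int, str, str], CohortCounts] = {}
    local_counts: dict[tuple[str, int, str, str], CohortCounts] = {}

    for chrom in chroms:
        n = len(chrom.positions)
        q = rng.beta(*config.af_beta, size=n)
        q = np.clip(q, 1e-4, 0.5)
        injected_idx = [i for i in (chrom.cond_index, chrom.denovo_index) if i is not None]
        for i in injected_idx:
            q[i] = 0.0  # injected alleles are absent from the background population
        chrom.q = q

        # founder haplotypes: [hap0, hap1] per founder
        founders = {
            fid: rng.random((2, n)) < q for fid in ("sire", "dam1", "dam2")
        }
        if chrom.cond_index is not None:
            a, b = chrom.core
            in_core = (chrom.positions >= a) & (chrom.positions <= b)
            ancestral = rng.random(np.count_nonzero(in_core)) < q[in_core]
            j = int(np.searchsorted(chrom.positions[in_core], chrom.positions[chrom.cond_index]))
            ancestral[j] = True  # the recessive allele rides the ancestral segment
            for fid in ("sire", "dam1", "dam2"):
                founders[fid][0, in_core] = ancestral
                founders[fid][1, chrom.cond_index] = False  # parents are het, not hom
        if chrom.denovo_index is not None:
            founders["sire"][0, chrom.denovo_index] = True  # germline mutation in the sire

        cond = chrom.cond_index if chrom.cond_index is not None else chrom.denovo_index
        core = chrom.core if chrom.cond_index is not None else None
        if chrom.denovo_index is not None and chrom.cond_index is None:
            # de novo transmission is conditioned at the locus only; no
            # ancestral segment, so "core" collapses to the marker itself
            pos = int(chrom.positions[chrom.denovo_index])
            core = (pos, pos)

        def gamete(parent: str, conditioned: bool) -> np.ndarray:
            mask = _gamete_mask(
                rng, chrom.positions, config.chrom_length_bp,
                config.recombination_rate_per_mb,
                cond if conditioned else None, core,
            )
            haps = founders[parent]
            return np.where(mask, haps[1], haps[0])

        sire_conditioned = cond is not None
        dam_conditioned = chrom.cond_index is not None
        case_gt = {
            "case1": gamete("sire", sire_conditioned).astype(np.int8)
            + gamete("dam1", dam_conditioned).astype(np.int8),
            "case2": gamete("sire", sire_conditioned).astype(np.int8)
            + gamete("dam2", dam_conditioned).astype(np.int8),
        }
        founder_gt = {fid: founders[fid].sum(axis=0).astype(np.int8) for fid in founders}

        # local control cohort: HWE draws; injected loci het at the carrier rate
        local = rng.binomial(2, q[None, :], size=(config.n_local_controls, n)).astype(np.int8)
        for i in injected_idx:
            c = inj_controls_freq[(chrom.name, int(chrom.positions[i]))]
            local[:, i] = (rng.random(config.n_local_controls) < c).astype(np.int8)
        local_cols.append(local)

        # global cohort: counts only
        n_glob = config.n_global_controls
        p_hom = q ** 2
        n_vv = rng.binomial(n_glob, p_hom)
        with np.errstate(divide="ignore", invalid="ignore"):
            p_het_given = np.where(p_hom < 1, 2 * q * (1 - q) / (1 - p_hom), 0.0)
        n_rv = rng.binomial(n_glob - n_vv, p_het_given)
        for i in injected_idx:
            c = inj_controls_freq[(chrom.name, int(chrom.positions[i]))]
            n_vv[i] = 0
            n_rv[i] = rng.binomial(n_glob, c)

        # alleles, annotation, record assembly
        ref_idx = rng.integers(0, 4, size=n)
        alt_idx = (ref_idx + rng.integers(1, 4, size=n)) % 4
        impacts = rng.choice(len(impact_names), size=n, p=impact_p)
        for i in range(n):
            pos = int(chrom.positions[i])
            ref, alt = str(_BASES[ref_idx[i]]), str(_BASES[alt_idx[i]])
            if i in injected_idx:
                impact = Impact.MODERATE
                gene = f"INJ_{chrom.name}_{pos}"
            else:
                impact = Impact[impact_names[impacts[i]]]
                gene = f"G{chrom.name}_{i:05d}"
            key = (chrom.name, pos, ref, alt)
            genotypes = {
                "case1": call_of(int(case_gt["case1"][i])),
                "case2": call_of(int(case_gt["case2"][i])),
                "dam1": call_of(int(founder_gt["dam1"][i])),
                "dam2": call_of(int(founder_gt["dam2"][i])),
                "sire": call_of(int(founder_gt["sire"][i])),
            }
            records.append(
                VariantRecord(chrom=chrom.name, pos=pos, ref=ref, alt=alt,
                              genotypes=genotypes, gene=gene, impact=impact)
            )
            n_het_local = int((local[:, i] == 1).sum())
            n_hom_local = int((local[:, i] == 2).sum())
            local_counts[key] = CohortCounts(
                n_hom_ref=config.n_local_controls - n_het_local - n_hom_local,
                n_het=n_het_local, n_hom_alt=n_hom_local,
            )
            global_counts[key] = CohortCounts(
                n_hom_ref=int(n_glob - n_rv[i] - n_vv[i]),
                n_het=int(n_rv[i]), n_hom_alt=int(n_vv[i]),
            )
            if i in injected_idx:
                key_of_locus[(chrom.name, pos)] = key
        q_all.append(q)

        if chrom.cond_index is not None:
            pos = int(chrom.positions[chrom.cond_index])
            truth_inj.append(
                InjectionTruth(
                    key=key_of_locus[(chrom.name, pos)],
                    kind=InjectionKind.RECESSIVE_IBD,
                    scenario="recessive",
                    core_interval=(chrom.name, chrom.core[0], chrom.core[1]),
                )
            )
        if chrom.denovo_index is not None:
            pos = int(chrom.positions[chrom.denovo_index])
            truth_inj.append(
                InjectionTruth(
                    key=key_of_locus[(chrom.name, pos)],
                    kind=InjectionKind.PATERNAL_DENOVO,
                    scenario="denovo",
                    core_interval=None,
                )
            )

    local_matrix = np.hstack(local_cols)
    allele_freqs = np.concatenate(q_all)

    sample_set = SampleSet(sample_ids=TRIO_IDS, roles=dict(TRIO_ROLES))
    local_catalog = CohortSummary(name="local_controls", counts=local_counts)
    global_catalog = CohortSummary(name="global_catalog", counts=global_counts)

    bull_genotypes, bull_year = _simulate_bulls(config, rng, key_of_locus)
    depth_profiles = _simulate_depth(config, rng)

    affection = {"case1": True, "case2": True, "dam1": False, "dam2": False, "sire": False}
    for bull in bull_year:
        affection[bull] = False

    truth = TruthTable(injections=truth_inj, depth_events=list(config.depth.events))
    return SyntheticCohort(
        config=config,
        sample_set=sample_set,
        records=records,
        local_catalog=local_catalog,
        global_catalog=global_catalog,
        local_matrix=local_matrix,
        allele_freqs=allele_freqs,
        depth_profiles=depth_profiles,
        bull_genotypes=bull_genotypes,
        bull_year=bull_year,
        affection=affection,
        truth=truth,
    )


def _simulate_bulls(
    config: SimConfig,
    rng: np.random.Generator,
    key_of_locus: dict[tuple[str, int], tuple[str, int, str, str]],
) -> tuple[dict[str, dict[str, int | None]], dict[str, int]]:
    """Targeted genotyping of the screened-bull cohort at the injected loci.

    For a DIGENIC_PAIR, one bull is made homozygous for the first locus and
    homozygous reference at the second — the sentinel unaffected animal
    that refutes a monogenic model at the first locus.
    """
    bulls = [f"bull{i + 1:04d}" for i in range(config.n_screened_bulls)]
    years = rng.choice(np.array(config.bull_years), size=len(bulls))
    bull_year = {b: int(y) for b, y in zip(bulls, years)}
    genotypes: dict[str, dict[str, int | None]] = {}

    def locus_name(chrom: str, pos: int) -> str:
        key = key_of_locus[(chrom, pos)]
        return f"{key[0]}:{key[1]}{key[2]}>{key[3]}"

    for inj in config.injections:
        if inj.kind is InjectionKind.PATERNAL_DENOVO:
            continue  # targeted genotyping covers the recessive candidates only
        loci = [(inj.chrom, inj.pos, inj.bull_carrier_freq)]
        if inj.kind is InjectionKind.DIGENIC_PAIR:
            loci.append((inj.chrom2, inj.pos2, inj.bull_carrier_freq2))
        sentinel = bulls[0] if inj.kind is InjectionKind.DIGENIC_PAIR else None
        for k, (chrom, pos, freq) in enumerate(loci):
            name = locus_name(chrom, pos)
            draws = (rng.random(len(bulls)) < freq).astype(int)
            gt = {b: int(d) for b, d in zip(bulls, draws)}
            if sentinel is not None:
                gt[sentinel] = 2 if k == 0 else 0
            genotypes[name] = gt
    return genotypes, bull_year


def _simulate_depth(config: SimConfig, rng: np.random.Generator) -> dict[str, DepthProfile]:
    """Binned read depth per trio sample with Gaussian bin noise and planted events."""
    width = config.depth.bin_width
    starts = np.arange(1, config.chrom_length_bp, width)
    ends = np.minimum(starts + width - 1, config.chrom_length_bp)
    profiles: dict[str, DepthProfile] = {}
    for sample in TRIO_IDS:
        frames = []
        for chrom in config.chrom_names():
            mean = np.full(len(starts), config.depth.mean_depth)
            for ev in config.depth.events:
                if ev.sample_id != sample or ev.chrom != chrom:
                    continue
                if ev.kind == "trisomy":
                    mean = mean * 1.5
                else:  # heterozygous deletion: one copy lost
                    hit = (ends >= ev.start) & (starts <= ev.end)
                    mean = np.where(hit, mean * 0.5, mean)
            noise = rng.normal(0.0, config.depth.noise_cv * config.depth.mean_depth, len(starts))
            depth = np.maximum(mean + noise, 0.0)
            frames.append(pd.DataFrame({
                "chrom": chrom, "start": starts, "end": ends, "mean_depth": depth,
            }))
        profiles[sample] = DepthProfile(sample_id=sample, bins=pd.concat(frames, ignore_index=True))
    return profiles


# ---------------------------------------------------------------------------
# closed-form cascade survival of background markers
# ---------------------------------------------------------------------------

def expected_background_survivors(
    cohort: SyntheticCohort,
    scenario: str = "recessive",
    protein_changing: Sequence[Impact] = (Impact.MODERATE, Impact.HIGH),
) -> tuple[float, float]:
    """Expected count (and variance) of background variants surviving the cascade.

    Under the simulator's transmission model a background marker with
    allele frequency q survives the recessive cascade with probability

        P = [2q(1-q)]^3 / 16 * 1{protein-changing} * (1 - q^2)^(N_local + N_global)

    (three founders heterozygous; all four conditioning-free gametes
    transmit the variant allele; no homozygote among the controls).  For
    the de novo scenario the pattern term is 2q(1-q) * (1-q)^4 / 4 and the
    exclusion term is (1-q)^(2(N_local + N_global)) (no variant allele at
    all among controls).  Markers inside planted ancestral core intervals
    are excluded — their transmission is conditioned, not background.

    Returns (sum of per-marker probabilities, sum of p(1-p)) — the mean and
    variance of a Poisson-binomial count.
    """
    n_controls = cohort.config.n_local_controls + cohort.config.n_global_controls
    pc = set(protein_changing)
    cores = cohort.truth.planted_intervals()
    injected = {t.key for t in cohort.truth.injections}

    mean = var = 0.0
    for rec, q in zip(cohort.records, cohort.allele_freqs):
        if rec.key in injected or rec.impact not in pc:
            continue
        if any(c == rec.chrom and s <= rec.pos <= e for c, s, e in cores):
            continue
        if scenario == "recessive":
            p_pattern = (2 * q * (1 - q)) ** 3 / 16.0
            p_excl = (1 - q ** 2) ** n_controls
        elif scenario == "denovo":
            p_pattern = 2 * q * (1 - q) * (1 - q) ** 4 / 4.0
            p_excl = (1 - q) ** (2 * n_controls)
        else:
            raise ValueError(f"unknown scenario {scenario!r}")
        p = p_pattern * p_excl
        mean += p
        var += p * (1 - p)
    return mean, var


# ---------------------------------------------------------------------------
# deterministic two-locus genotyping fixture
# ---------------------------------------------------------------------------

@dataclass
class Table2Fixture:
    """Deterministic two-locus genotyping cohort for segregation analyses.

    Synthetic by construction: genotype-class totals per cohort follow the
    published association-table layout of a carrier screen (affected
    calves, obligate-carrier parents, screened bulls, external controls),
    including one unaffected bull homozygous at the first locus only and a
    small number of genotyping failures at the first locus.
    """

    locus_a: str
    locus_b: str
    genotypes_a: dict[str, int | None]
    genotypes_b: dict[str, int | None]
    cohort_of: dict[str, str]
    year_of: dict[str, int]
    affected: dict[str, bool]
    external_counts: dict[str, "tuple[int, int, int]"]

    def write_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write(f"sample\tcohort\tyear\taffected\t{self.locus_a}\t{self.locus_b}\n")
            for s in self.genotypes_a:
                ga, gb = self.genotypes_a[s], self.genotypes_b[s]
                fh.write(
                    f"{s}\t{self.cohort_of[s]}\t{self.year_of.get(s, 0)}\t"
                    f"{int(self.affected[s])}\t"
                    f"{'NA' if ga is None else ga}\t{'NA' if gb is None else gb}\n"
                )


def emit_table2_fixture(
    locus_a: str = "TGDS_like",
    locus_b: str = "LAMA4_like",
    bulls_a: tuple[int, int, int] = (296, 32, 1),
    bulls_b: tuple[int, int, int] = (321, 11, 0),
    n_bulls: int = 332,
    external_a: tuple[int, int, int] = (5279, 0, 0),
    external_b: tuple[int, int, int] = (5278, 1, 0),
) -> Table2Fixture:
    """Build the per-individual cohort whose genotype counts equal the given totals.

    Defaults reproduce the carrier-screen association table of the emulated
    study: the trio (cases var/var at both loci, parents het at both), a
    screened-bull cohort with the stated genotype-class counts per locus
    (individuals failing genotyping at a locus get a missing call), and
    external-control cohorts kept as counts.  The bull homozygous at the
    first locus is homozygous reference at the second.
    """
    if sum(bulls_a) > n_bulls or sum(bulls_b) > n_bulls:
        raise ValueError("cohort counts exceed the number of bulls")
    genotypes_a: dict[str, int | None] = {}
    genotypes_b: dict[str, int | None] = {}
    cohort_of: dict[str, str] = {}
    year_of: dict[str, int] = {}
    affected: dict[str, bool] = {}

    for s in ("case1", "case2"):
        genotypes_a[s] = genotypes_b[s] = 2
        cohort_of[s] = "affected"
        affected[s] = True
    for s in ("dam1", "dam2", "sire"):
        genotypes_a[s] = genotypes_b[s] = 1
        cohort_of[s] = "obligate_carriers"
        affected[s] = False

    n_rr_a, n_rv_a, n_vv_a = bulls_a
    n_rr_b, n_rv_b, n_vv_b = bulls_b
    years = (2017, 2018, 2019, 2020)
    for i in range(n_bulls):
        s = f"bull{i + 1:04d}"
        cohort_of[s] = "screened_bulls"
        affected[s] = False
        year_of[s] = years[i % len(years)]
        # locus A blocks: hom-var first (the sentinel bull), then het, ref/ref, missing
        if i < n_vv_a:
            genotypes_a[s] = 2
        elif i < n_vv_a + n_rv_a:
            genotypes_a[s] = 1
        elif i < n_vv_a + n_rv_a + n_rr_a:
            genotypes_a[s] = 0
        else:
            genotypes_a[s] = None
        # locus B: the locus-A hom-var bull is ref/ref here; hets follow
        if i < n_vv_a:
            genotypes_b[s] = 0
        elif i < n_vv_a + n_vv_b:
            genotypes_b[s] = 2
        elif i < n_vv_a + n_vv_b + n_rv_b:
            genotypes_b[s] = 1
        elif i < n_vv_a + n_vv_b + n_rv_b + (n_rr_b - n_vv_a):
            genotypes_b[s] = 0
        else:
            genotypes_b[s] = None

    return Table2Fixture(
        locus_a=locus_a, locus_b=locus_b,
        genotypes_a=genotypes_a, genotypes_b=genotypes_b,
        cohort_of=cohort_of, year_of=year_of, affected=affected,
        external_counts={locus_a: external_a, locus_b: external_b},
    )
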