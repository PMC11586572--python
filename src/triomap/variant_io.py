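"""Reading, annotating and writing biallelic variant genotype data.

The internal variant model is deliberately minimal: every record is one
biallelic substitution or indel (multi-allelic sites are split on read), and
every genotype collapses to an alternate-allele dosage in {0, 1, 2} or
"missing".  Phase is discarded — downstream filtering only ever asks which
genotype *class* (ref/ref, ref/var, var/var) a sample carries.

Coordinates are 1-based and inclusive throughout the package, matching VCF
and PLINK ``.hom`` conventions.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from enum import Enum
from pathlib import Path
from typing import Iterable, Mapping, Sequence

log = logging.getLogger(__name__)

__all__ = [
    "Impact",
    "Role",
    "GenotypeCall",
    "MISSING_CALL",
    "VariantRecord",
    "SampleSet",
    "VariantIOError",
    "read_pedigree",
    "read_vcf",
    "parse_annotation",
    "annotate_records",
    "read_annotation_sidecar",
    "write_variant_table",
    "read_variant_table",
]


class VariantIOError(ValueError):
    """Raised for malformed or inconsistent variant input."""


class Impact(Enum):
    """snpEff-style functional-impact class; HIGH is most severe."""

    HIGH = 4
    MODERATE = 3
    LOW = 2
    MODIFIER = 1

    @classmethod
    def parse(cls, token: str) -> "Impact":
        try:
            return cls[token.strip().upper()]
        except KeyError:
            raise VariantIOError(f"unknown impact token: {token!r}") from None

    @property
    def severity(self) -> int:
        return self.value


class Role(Enum):
    """Pedigree/cohort role of a sample in the trio design."""

    CASE = "case"
    DAM = "dam"
    SIRE = "sire"
    LOCAL_CONTROL = "local_control"


@dataclass(frozen=True)
class GenotypeCall:
    """Alt-allele dosage of one sample at one biallelic site.

    ``allele_count_alt`` must not be read when ``missing`` is true; doing so
    raises instead of returning a bogus number.
    """

    missing: bool
    _dosage: int = -1

    @classmethod
    def of(cls, dosage: int) -> "GenotypeCall":
        if dosage not in (0, 1, 2):
            raise ValueError(f"dosage must be 0, 1 or 2, got {dosage}")
        return cls(missing=False, _dosage=dosage)

    @property
    def allele_count_alt(self) -> int:
        if self.missing:
            raise ValueError("allele_count_alt is undefined for a missing call")
        return self._dosage

    @property
    def is_het(self) -> bool:
        return not self.missing and self._dosage == 1

    @property
    def is_hom(self) -> bool:
        return not self.missing and self._dosage in (0, 2)

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return "GenotypeCall(missing)" if self.missing else f"GenotypeCall({self._dosage})"


MISSING_CALL = GenotypeCall(missing=True)
_CALLS = {0: GenotypeCall.of(0), 1: GenotypeCall.of(1), 2: GenotypeCall.of(2)}


def call_of(dosage: int | None) -> GenotypeCall:
    """Interned genotype call for a dosage, or the missing call for ``None``."""
    return MISSING_CALL if dosage is None else _CALLS[dosage]


@dataclass
class VariantRecord:
    """One biallelic variant with per-sample dosage genotypes."""

    chrom: str
    pos: int  # 1-based
    ref: str
    alt: str
    genotypes: dict[str, GenotypeCall] = field(default_factory=dict)
    gene: str | None = None
    impact: Impact | None = None

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"pos must be >= 1, got {self.pos}")
        if "," in self.alt:
            raise ValueError(f"record must be biallelic, got alt {self.alt!r}")

    @property
    def key(self) -> tuple[str, int, str, str]:
        return (self.chrom, self.pos, self.ref, self.alt)

    def dosage(self, sample_id: str) -> int | None:
        """Alt dosage for a sample, or ``None`` when missing."""
        call = self.genotypes[sample_id]
        return None if call.missing else call.allele_count_alt


@dataclass(frozen=True)
class SampleSet:
    """Ordered cohort samples with their trio/cohort roles."""

    sample_ids: tuple[str, ...]
    roles: Mapping[str, Role]

    def __post_init__(self) -> None:
        unknown = set(self.roles) - set(self.sample_ids)
        if unknown:
            raise ValueError(f"role assigned to unknown samples: {sorted(unknown)}")
        if not self.with_role(Role.CASE):
            raise ValueError("a SampleSet needs at least one CASE sample")

    def with_role(self, role: Role) -> tuple[str, ...]:
        return tuple(s for s in self.sample_ids if self.roles.get(s) is role)

    @property
    def cases(self) -> tuple[str, ...]:
        return self.with_role(Role.CASE)

    @property
    def dams(self) -> tuple[str, ...]:
        return self.with_role(Role.DAM)

    @property
    def sires(self) -> tuple[str, ...]:
        return self.with_role(Role.SIRE)


def read_pedigree(path: str | Path) -> tuple[dict[str, Role], dict[str, bool], "object"]:
    """Read a pedigree TSV (id, sire, dam, sex, status, role).

    Returns (sample -> Role, sample -> affected?, DataFrame of the file).
    Role tokens are matched case-insensitively against {case, dam, sire,
    local_control}; unknown tokens are a hard error.
    """
    import pandas as pd

    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"id", "role", "status"}
    if not required.issubset(df.columns):
        raise VariantIOError(f"{path}: pedigree needs columns {sorted(required)}")
    roles: dict[str, Role] = {}
    affected: dict[str, bool] = {}
    for row in df.itertuples():
        token = str(row.role).strip().lower()
        try:
            roles[str(row.id)] = Role(token)
        except ValueError:
            raise VariantIOError(f"{path}: unknown role {row.role!r} for {row.id}") from None
        affected[str(row.id)] = str(row.status).strip().lower() == "affected"
    return roles, affected, df


# ---------------------------------------------------------------------------
# VCF reading
# ---------------------------------------------------------------------------

def _recode_gt(alleles: Sequence[int], alt_index: int) -> GenotypeCall:
    """Project one GT onto the biallelic view of a single alt allele.

    ``alleles`` are the integer allele indices of the call (negative =
    missing).  In the biallelic view of alt ``alt_index``, any allele other
    than {ref, this alt} is foreign, and any half-missing call is treated as
    missing (conservative: a half call never certifies a genotype class).
    """
    if any(a < 0 for a in alleles):
        return MISSING_CALL
    if any(a not in (0, alt_index) for a in alleles):
        return MISSING_CALL
    return _CALLS[sum(1 for a in alleles if a == alt_index)]


def read_vcf(
    path: str | Path,
    sample_roles: Mapping[str, Role],
    *,
    pass_only: bool = False,
) -> tuple[SampleSet, list[VariantRecord]]:
    """Read a multi-sample VCF into biallelic :class:`VariantRecord` objects.

    Multi-allelic sites are split into one record per alt allele, with
    genotypes recoded per alt (alleles foreign to the biallelic view become
    missing).  Records are returned sorted by (header chromosome order, pos).

    Parameters
    ----------
    path
        VCF 4.x file, plain or bgzipped; a GT FORMAT field is required.
    sample_roles
        Maps sample id -> :class:`Role`; every mapped sample must appear in
        the VCF header.  Unmapped header samples are carried along without a
        role.
    pass_only
        If true, skip records whose FILTER column is set to anything other
        than PASS/missing.  Off by default; no claim is made that the source
        study applied it.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path), gts012=False)
    samples: tuple[str, ...] = tuple(vcf.samples)
    if not samples:
        raise VariantIOError(f"{path}: VCF has no sample columns (no GT data)")
    absent = [s for s in sample_roles if s not in samples]
    if absent:
        raise VariantIOError(f"{path}: role-mapped samples absent from header: {absent}")
    if "##FORMAT=<ID=GT" not in vcf.raw_header:
        raise VariantIOError(f"{path}: VCF header does not define a GT FORMAT field")

    chrom_order = {c: i for i, c in enumerate(vcf.seqnames)}
    records: list[VariantRecord] = []
    for var in vcf:
        if pass_only and var.FILTER is not None:
            continue
        gts = var.genotypes  # [[a, b, phased], ...] aligned with samples
        if len(gts) != len(samples):
            raise VariantIOError(
                f"{var.CHROM}:{var.POS}: GT missing or malformed for this site"
            )
        ann = var.INFO.get("ANN")
        for alt_index, alt in enumerate(var.ALT, start=1):
            rec = VariantRecord(
                chrom=var.CHROM,
                pos=var.POS,
                ref=var.REF,
                alt=alt,
                genotypes={
                    s: _recode_gt(gt[:-1], alt_index) for s, gt in zip(samples, gts)
                },
            )
            if ann:
                rec = parse_annotation(rec, ann)
            records.append(rec)
    vcf.close()

    records.sort(key=lambda r: (chrom_order.get(r.chrom, len(chrom_order)), r.pos, r.ref, r.alt))
    seen: set[tuple[str, int, str, str]] = set()
    for rec in records:
        if rec.key in seen:
            raise VariantIOError(f"duplicate variant {rec.chrom}:{rec.pos}{rec.ref}>{rec.alt}")
        seen.add(rec.key)

    roles = dict(sample_roles)
    sample_set = SampleSet(sample_ids=samples, roles=roles)
    return sample_set, records


# ---------------------------------------------------------------------------
# Functional annotation
# ---------------------------------------------------------------------------

def parse_annotation(
    record: VariantRecord,
    ann_source: str | Mapping[str, str],
) -> VariantRecord:
    """Populate ``gene`` and ``impact`` on a record from an annotation source.

    ``ann_source`` is either a snpEff pipe-delimited ANN string (possibly
    comma-separated over several transcript entries) or a sidecar mapping
    with ``gene`` and ``impact`` keys.  Among ANN entries matching the
    record's alt allele, the most severe impact (HIGH > MODERATE > LOW >
    MODIFIER) wins, together with its gene.  If no entry matches the alt,
    the impact is left unset and a warning is logged.
    """
    if isinstance(ann_source, str):
        best: tuple[Impact, str | None] | None = None
        for entry in ann_source.split(","):
            parts = entry.split("|")
            if len(parts) < 3:
                raise VariantIOError(f"malformed ANN entry: {entry!r}")
            allele, _effect, impact_token = parts[0], parts[1], parts[2]
            if allele != record.alt:
                continue
            impact = Impact.parse(impact_token)
            gene = parts[3] if len(parts) > 3 and parts[3] else None
            if best is None or impact.severity > best[0].severity:
                best = (impact, gene)
        if best is None:
            log.warning(
                "no ANN entry matches alt %s at %s:%d; impact left unset",
                record.alt, record.chrom, record.pos,
            )
            return record
        return replace(record, impact=best[0], gene=best[1])

    impact = Impact.parse(str(ann_source["impact"]))
    gene = ann_source.get("gene") or None
    return replace(record, impact=impact, gene=gene)


def read_annotation_sidecar(path: str | Path) -> dict[tuple[str, int, str, str], dict[str, str]]:
    """Read a sidecar TSV (chrom, pos, ref, alt, gene, impact) keyed by variant."""
    import pandas as pd

    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    required = {"chrom", "pos", "ref", "alt", "gene", "impact"}
    if not required.issubset(df.columns):
        raise VariantIOError(f"{path}: sidecar needs columns {sorted(required)}")
    return {
        (str(r.chrom), int(r.pos), str(r.ref), str(r.alt)): {
            "gene": "" if pd.isna(r.gene) else str(r.gene),
            "impact": str(r.impact),
        }
        for r in df.itertuples()
    }


def annotate_records(
    records: Iterable[VariantRecord],
    sidecar: Mapping[tuple[str, int, str, str], Mapping[str, str]],
) -> list[VariantRecord]:
    """Apply a sidecar annotation table to matching records; others pass through."""
    out = []
    for rec in records:
        row = sidecar.get(rec.key)
        out.append(parse_annotation(rec, row) if row is not None else rec)
    return out


# ---------------------------------------------------------------------------
# Internal variant table (TSV)
# ---------------------------------------------------------------------------

_TABLE_FIXED_COLS = ["chrom", "pos", "ref", "alt", "gene", "impact"]


def write_variant_table(
    records: Sequence[VariantRecord],
    path: str | Path,
    sample_ids: Sequence[str] | None = None,
) -> None:
    """Write records to a TSV with one 0/1/2/NA genotype column per sample.

    The format is lossless for the internal model and round-trips through
    :func:`read_variant_table`.
    """
    if sample_ids is None:
        sample_ids = list(records[0].genotypes) if records else []
    with open(path, "w") as fh:
        fh.write("\t".join(_TABLE_FIXED_COLS + list(sample_ids)) + "\n")
        for rec in records:
            row = [
                rec.chrom,
                str(rec.pos),
                rec.ref,
                rec.alt,
                rec.gene or "NA",
                rec.impact.name if rec.impact else "NA",
            ]
            for s in sample_ids:
                d = rec.dosage(s)
                row.append("NA" if d is None else str(d))
            fh.write("\t".join(row) + "\n")


def read_variant_table(path: str | Path) -> list[VariantRecord]:
    """Read back a variant table written by :func:`write_variant_table`."""
    records = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header[: len(_TABLE_FIXED_COLS)] != _TABLE_FIXED_COLS:
            raise VariantIOError(f"{path}: not a triomap variant table")
        sample_ids = header[len(_TABLE_FIXED_COLS):]
        for lineno, line in enumerate(fh, start=2):
            parts = line.rstrip("\n").split("\t")
            if len(parts) != len(header):
                raise VariantIOError(f"{path}:{lineno}: expected {len(header)} columns")
            chrom, pos, ref, alt, gene, impact = parts[:6]
            genotypes = {
                s: (MISSING_CALL if v == "NA" else _CALLS[int(v)])
                for s, v in zip(sample_ids, parts[6:])
            }
            records.append(
                VariantRecord(
                    chrom=chrom,
                    pos=int(pos),
                    ref=ref,
                    alt=alt,
                    gene=None if gene == "NA" else gene,
                    impact=None if impact == "NA" else Impact.parse(impact),
                    genotypes=genotypes,
                )
            )
    return records
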