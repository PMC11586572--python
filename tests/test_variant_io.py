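"""VCF reading, multi-allelic splitting, annotation and table round trips."""

import itertools

import pytest
from hypothesis import given
from hypothesis import strategies as st

from triomap.variant_io import (
    MISSING_CALL,
    GenotypeCall,
    Impact,
    Role,
    SampleSet,
    VariantIOError,
    VariantRecord,
    call_of,
    parse_annotation,
    read_pedigree,
    read_variant_table,
    read_vcf,
    write_variant_table,
)

TRIO_ROLES = {"case1": Role.CASE, "dam1": Role.DAM, "sire": Role.SIRE}


class TestReadVcf:
    def test_basic_trio_line(self, make_vcf):
        path = make_vcf(["1 100 . A T . . . GT 1/1 0/1 0/1"])
        sample_set, records = read_vcf(path, TRIO_ROLES)
        assert sample_set.cases == ("case1",)
        (rec,) = records
        assert rec.key == ("1", 100, "A", "T")
        assert rec.dosage("case1") == 2
        assert rec.dosage("dam1") == 1
        assert rec.dosage("sire") == 1

    def test_missing_and_half_missing_calls(self, make_vcf):
        path = make_vcf(["1 100 . A T . . . GT ./. ./1 1/."])
        _, (rec,) = read_vcf(path, TRIO_ROLES)
        assert all(rec.dosage(s) is None for s in ("case1", "dam1", "sire"))

    def test_records_sorted_by_header_chrom_order(self, make_vcf):
        path = make_vcf([
            "12 50 . A T . . . GT 0/1 0/1 0/1",
            "2 500 . G C . . . GT 0/1 0/1 0/1",
            "1 900 . T A . . . GT 0/1 0/1 0/1",
        ])
        _, records = read_vcf(path, TRIO_ROLES)
        assert [r.chrom for r in records] == ["1", "2", "12"]

    def test_duplicate_site_detected(self, make_vcf):
        path = make_vcf([
            "1 100 . A T . . . GT 0/1 0/1 0/1",
            "1 100 . A T . . . GT 0/0 0/1 0/1",
        ])
        with pytest.raises(VariantIOError, match="duplicate"):
            read_vcf(path, TRIO_ROLES)

    def test_role_mapped_sample_absent_is_hard_error(self, make_vcf):
        path = make_vcf(["1 100 . A T . . . GT 0/1 0/1 0/1"])
        with pytest.raises(VariantIOError, match="absent"):
            read_vcf(path, {**TRIO_ROLES, "ghost": Role.CASE})

    def test_vcf_without_gt_format_is_hard_error(self, tmp_path):
        path = tmp_path / "nogt.vcf"
        path.write_text(
            "##fileformat=VCFv4.2\n##contig=<ID=1,length=1000>\n"
            '##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Depth">\n'
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\ts1\n"
            "1\t100\t.\tA\tT\t.\t.\t.\tDP\t10\n"
        )
        with pytest.raises(VariantIOError, match="GT"):
            read_vcf(path, {"s1": Role.CASE})

    def test_ann_info_field_parsed_on_read(self, make_vcf):
        path = make_vcf(["12 69092831 . A T . . ANN=T|missense_variant|MODERATE|TGDS GT 1/1 0/1 0/1"])
        _, (rec,) = read_vcf(path, TRIO_ROLES)
        assert rec.impact is Impact.MODERATE
        assert rec.gene == "TGDS"


def _recode_oracle(a: int, b: int, alt: int):
    """Independent hand enumeration of the biallelic recoding of GT (a, b)."""
    if a < 0 or b < 0:
        return None
    if {a, b} - {0, alt}:
        return None  # a foreign allele makes this biallelic view undefined
    return (a == alt) + (b == alt)


class TestMultiallelicSplit:
    GT_STRINGS = ["%d/%d" % pair for pair in itertools.product(range(3), range(3))]
    GT_STRINGS += ["./.", "./1", "2/."]

    def _read_split(self, make_vcf):
        samples = tuple(f"s{i}" for i in range(len(self.GT_STRINGS)))
        line = "1 100 . A T,G . . . GT " + " ".join(self.GT_STRINGS)
        path = make_vcf([line], samples=samples)
        roles = {samples[0]: Role.CASE}
        _, records = read_vcf(path, roles)
        return samples, records

    def test_split_matches_enumerated_recoding_table(self, make_vcf):
        samples, records = self._read_split(make_vcf)
        assert [r.alt for r in records] == ["G", "T"]  # sorted within position
        by_alt = {r.alt: r for r in records}
        for alt, alt_index in (("T", 1), ("G", 2)):
            rec = by_alt[alt]
            for s, gt in zip(samples, self.GT_STRINGS):
                a, b = [(-1 if x == "." else int(x)) for x in gt.split("/")]
                assert rec.dosage(s) == _recode_oracle(a, b, alt_index), (gt, alt)

    def test_split_conserves_alt_dosage_for_fully_known_genotypes(self, make_vcf):
        samples, records = self._read_split(make_vcf)
        for s, gt in zip(samples, self.GT_STRINGS):
            dosages = [r.dosage(s) for r in records]
            if any(d is None for d in dosages):
                continue
            alleles = [int(x) for x in gt.split("/")]
            assert sum(dosages) == sum(1 for a in alleles if a != 0)


class TestAnnotation:
    def test_highest_severity_entry_wins(self):
        rec = VariantRecord("1", 100, "A", "T", {"s": call_of(1)})
        ann = "T|intron_variant|MODIFIER|GENEA|x,T|stop_gained|HIGH|GENEA|y"
        out = parse_annotation(rec, ann)
        assert out.impact is Impact.HIGH

    def test_non_matching_alt_leaves_impact_unset(self, caplog):
        rec = VariantRecord("1", 100, "A", "T", {"s": call_of(1)})
        out = parse_annotation(rec, "G|missense_variant|MODERATE|GENEA")
        assert out.impact is None

    def test_unknown_impact_token_is_error(self):
        rec = VariantRecord("1", 100, "A", "T", {"s": call_of(1)})
        with pytest.raises(VariantIOError, match="SEVERE"):
            parse_annotation(rec, "T|x|SEVERE|GENEA")

    @pytest.mark.parametrize("token", ["HIGH", "MODERATE", "LOW", "MODIFIER"])
    @pytest.mark.parametrize("case", [str.lower, str.upper, str.title])
    def test_sidecar_impact_tokens_case_insensitive(self, token, case):
        rec = VariantRecord("1", 100, "A", "T", {"s": call_of(1)})
        out = parse_annotation(rec, {"gene": "G1", "impact": case(token)})
        assert out.impact is Impact[token]
        assert out.gene == "G1"


genotype_st = st.one_of(st.none(), st.integers(0, 2))
impact_st = st.one_of(st.none(), st.sampled_from(list(Impact)))


@st.composite
def records_st(draw):
    samples = ["case1", "case2", "dam1", "dam2", "sire"]
    n = draw(st.integers(0, 12))
    used = set()
    records = []
    for _ in range(n):
        key = draw(
            st.tuples(
                st.sampled_from(["1", "2", "X"]),
                st.integers(1, 10_000_000),
                st.sampled_from(["A", "C", "G", "TTA"]),
                st.sampled_from(["T", "G", "C"]),
            ).filter(lambda k: k[2] != k[3] and k not in used)
        )
        used.add(key)
        records.append(
            VariantRecord(
                chrom=key[0], pos=key[1], ref=key[2], alt=key[3],
                genotypes={s: call_of(draw(genotype_st)) for s in samples},
                gene=draw(st.one_of(st.none(), st.sampled_from(["TGDS", "LAMA4"]))),
                impact=draw(impact_st),
            )
        )
    return records


class TestVariantTable:
    def test_empty_record_list_gives_header_only(self, tmp_path):
        path = tmp_path / "t.tsv"
        write_variant_table([], path, sample_ids=["a", "b"])
        assert path.read_text().count("\n") == 1
        assert read_variant_table(path) == []

    def test_column_count(self, tmp_path):
        rec = VariantRecord("1", 5, "A", "T", {f"s{i}": call_of(1) for i in range(5)})
        path = tmp_path / "t.tsv"
        write_variant_table([rec], path)
        lines = path.read_text().splitlines()
        assert len(lines) == 2
        assert len(lines[1].split("\t")) == 11

    @given(records=records_st())
    def test_write_read_round_trip_is_identity(self, records, tmp_path_factory):
        path = tmp_path_factory.mktemp("vt") / "t.tsv"
        write_variant_table(records, path, sample_ids=["case1", "case2", "dam1", "dam2", "sire"])
        assert read_variant_table(path) == records


class TestGenotypeCall:
    def test_missing_dosage_must_not_be_read(self):
        assert MISSING_CALL.missing
        with pytest.raises(ValueError):
            _ = MISSING_CALL.allele_count_alt

    def test_invalid_dosage_rejected(self):
        with pytest.raises(ValueError):
            GenotypeCall.of(3)


class TestSampleSetAndPedigree:
    def test_sample_set_requires_a_case(self):
        with pytest.raises(ValueError, match="CASE"):
            SampleSet(("a",), {"a": Role.DAM})

    def test_read_pedigree_roles_and_status(self, tmp_path):
        path = tmp_path / "ped.tsv"
        path.write_text(
            "id\tsire\tdam\tsex\tstatus\trole\n"
            "case1\tsire\tdam1\tF\taffected\tcase\n"
            "dam1\t0\t0\tF\tunaffected\tDam\n"
            "ctrl1\t0\t0\tU\tunaffected\tlocal_control\n"
        )
        roles, affected, _ = read_pedigree(path)
        assert roles == {"case1": Role.CASE, "dam1": Role.DAM, "ctrl1": Role.LOCAL_CONTROL}
        assert affected == {"case1": True, "dam1": False, "ctrl1": False}

    def test_read_pedigree_unknown_role_is_error(self, tmp_path):
        path = tmp_path / "ped.tsv"
        path.write_text("id\tsire\tdam\tsex\tstatus\trole\nx\t0\t0\tU\tunaffected\tcousin\n")
        with pytest.raises(VariantIOError, match="cousin"):
            read_pedigree(path)
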