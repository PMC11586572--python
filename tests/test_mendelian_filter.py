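"""Genotype-pattern filtering, cohort exclusion and the full cascade."""

import itertools

import numpy as np
import pytest

from triomap.mendelian_filter import (
    CohortCounts,
    CohortSummary,
    ControlPolicy,
    PATERNAL_GERMLINE_DENOVO,
    RECESSIVE_HOMOZYGOUS,
    candidate_region_check,
    cohort_exclusion_filter,
    genotype_pattern_filter,
    impact_filter,
    run_cascade,
    summarize_cohort,
)
from triomap.roh import ParentState, SharedIbdRegion
from triomap.variant_io import Impact, Role, SampleSet, VariantRecord, call_of

SAMPLES = ["case1", "case2", "dam1", "dam2", "sire"]
SAMPLE_SET = SampleSet(
    tuple(SAMPLES),
    {
        "case1": Role.CASE, "case2": Role.CASE,
        "dam1": Role.DAM, "dam2": Role.DAM, "sire": Role.SIRE,
    },
)


def make_record(pos, dosages, impact=Impact.MODERATE, chrom="1"):
    return VariantRecord(
        chrom=chrom, pos=pos, ref="A", alt="T",
        genotypes={s: call_of(d) for s, d in zip(SAMPLES, dosages)},
        gene="G", impact=impact,
    )


def pattern_oracle(dosages, scenario):
    """Plain per-record re-statement of the scenario genotype patterns."""
    case1, case2, dam1, dam2, sire = dosages
    if any(d is None for d in dosages):
        return False
    if scenario == "recessive":
        return case1 == 2 and case2 == 2 and dam1 == 1 and dam2 == 1 and sire == 1
    return case1 == 1 and case2 == 1 and dam1 == 0 and dam2 == 0 and sire == 1


class TestGenotypePatternFilter:
    def test_obligate_carrier_configuration_survives_recessive(self):
        rec = make_record(1, [2, 2, 1, 1, 1])
        assert genotype_pattern_filter([rec], SAMPLE_SET, RECESSIVE_HOMOZYGOUS) == [rec]

    def test_one_het_case_violates_recessive_pattern(self):
        rec = make_record(1, [2, 1, 1, 1, 1])
        assert genotype_pattern_filter([rec], SAMPLE_SET, RECESSIVE_HOMOZYGOUS) == []

    def test_missing_trio_genotype_fails_pattern(self):
        rec = make_record(1, [2, 2, None, 1, 1])
        assert genotype_pattern_filter([rec], SAMPLE_SET, RECESSIVE_HOMOZYGOUS) == []

    @pytest.mark.parametrize("scenario_name,scenario", [
        ("recessive", RECESSIVE_HOMOZYGOUS),
        ("denovo", PATERNAL_GERMLINE_DENOVO),
    ])
    def test_random_records_match_brute_force_predicate(self, scenario_name, scenario):
        rng = np.random.default_rng(42)
        choices = [0, 1, 2, None]
        records = [
            make_record(i + 1, [choices[k] for k in rng.integers(0, 4, size=5)])
            for i in range(1000)
        ]
        got = genotype_pattern_filter(records, SAMPLE_SET, scenario)
        expected = [
            r for r in records
            if pattern_oracle([r.dosage(s) for s in SAMPLES], scenario_name)
        ]
        assert got == expected

    def test_missing_required_role_is_error(self):
        no_sire = SampleSet(("c", "d"), {"c": Role.CASE, "d": Role.DAM})
        with pytest.raises(ValueError, match="sire"):
            genotype_pattern_filter([], no_sire, RECESSIVE_HOMOZYGOUS)

    def test_scenario_patterns_are_disjoint_on_observed_genotypes(self):
        # a case cannot be both hom-alt and het: no fully observed record
        # can satisfy both scenarios
        for dosages in itertools.product([0, 1, 2], repeat=5):
            rec = make_record(1, list(dosages))
            both = (
                genotype_pattern_filter([rec], SAMPLE_SET, RECESSIVE_HOMOZYGOUS)
                and genotype_pattern_filter([rec], SAMPLE_SET, PATERNAL_GERMLINE_DENOVO)
            )
            assert not both


class TestCohortExclusion:
    KEY = ("1", 1, "A", "T")

    def make_cohort(self, counts):
        return CohortSummary("c", {self.KEY: CohortCounts(*counts)})

    def test_het_carriers_tolerated_under_hom_alt_policy(self):
        rec = make_record(1, [2, 2, 1, 1, 1])
        cohort = self.make_cohort((940, 2, 0))
        assert cohort_exclusion_filter([rec], cohort, ControlPolicy.EXCLUDE_IF_HOM_ALT) == [rec]

    def test_single_het_excludes_under_any_alt_policy(self):
        rec = make_record(1, [1, 1, 0, 0, 1])
        cohort = self.make_cohort((941, 1, 0))
        assert cohort_exclusion_filter([rec], cohort, ControlPolicy.EXCLUDE_IF_ANY_ALT) == []

    def test_hom_alt_carrier_excludes_under_hom_alt_policy(self):
        rec = make_record(1, [2, 2, 1, 1, 1])
        cohort = self.make_cohort((940, 1, 1))
        assert cohort_exclusion_filter([rec], cohort, ControlPolicy.EXCLUDE_IF_HOM_ALT) == []

    @pytest.mark.parametrize("policy", list(ControlPolicy))
    def test_record_absent_from_catalog_survives(self, policy):
        rec = make_record(99, [2, 2, 1, 1, 1])
        cohort = self.make_cohort((900, 40, 2))  # catalogued at pos 1, not 99
        assert cohort_exclusion_filter([rec], cohort, policy) == [rec]

    def test_catalog_tsv_round_trip(self, tmp_path):
        cohort = self.make_cohort((940, 2, 0))
        path = tmp_path / "cat.tsv"
        cohort.write_tsv(path)
        back = CohortSummary.read_tsv(path, name="c")
        assert back.counts == cohort.counts


class TestImpactFilter:
    def test_kept_set_is_exactly_moderate_plus_high(self):
        records = [make_record(i + 1, [2, 2, 1, 1, 1], impact=imp)
                   for i, imp in enumerate(Impact)]
        records.append(make_record(99, [2, 2, 1, 1, 1], impact=None))
        kept = impact_filter(records)
        assert {r.impact for r in kept} == {Impact.MODERATE, Impact.HIGH}


class TestCascade:
    def _cohorts(self):
        return CohortSummary("local_controls"), CohortSummary("global_catalog")

    def test_empty_input_reports_zero_counts(self):
        local, global_ = self._cohorts()
        report = run_cascade([], SAMPLE_SET, local, global_, RECESSIVE_HOMOZYGOUS)
        assert len(report.steps) == 4
        assert all(s.variants_in == 0 and s.variants_out == 0 for s in report.steps)
        assert report.candidates == []

    def test_counts_shrink_monotonically(self, default_cohort):
        c = default_cohort
        for scenario in (RECESSIVE_HOMOZYGOUS, PATERNAL_GERMLINE_DENOVO):
            report = run_cascade(
                c.records, c.sample_set, c.local_catalog, c.global_catalog, scenario
            )
            for step in report.steps:
                assert step.variants_out <= step.variants_in
            ins = [s.variants_in for s in report.steps]
            outs = [s.variants_out for s in report.steps]
            assert ins[1:] == outs[:-1]
            assert set(r.key for r in report.candidates) <= set(r.key for r in c.records)

    def test_step_order_invariance_of_final_candidates(self, default_cohort):
        c = default_cohort
        scenario = RECESSIVE_HOMOZYGOUS
        base = genotype_pattern_filter(c.records, c.sample_set, scenario)
        steps = {
            "impact": lambda rs: impact_filter(rs),
            "local": lambda rs: cohort_exclusion_filter(rs, c.local_catalog, scenario.control_policy),
            "global": lambda rs: cohort_exclusion_filter(rs, c.global_catalog, scenario.control_policy),
        }
        results = []
        for order in itertools.permutations(steps):
            surviving = base
            for name in order:
                surviving = steps[name](surviving)
            results.append({r.key for r in surviving})
        assert all(r == results[0] for r in results)


class TestCandidateRegionCheck:
    def _region(self, chrom, start, end):
        return SharedIbdRegion(chrom, start, end, 1.0, {"sire": ParentState.HETEROZYGOUS_COMPATIBLE})

    def test_contained_candidate_flagged(self):
        # mirrors a candidate inside a ~2 Mb shared segment
        cand = make_record(69092831, [2, 2, 1, 1, 1], chrom="12")
        regions = [self._region("12", 68_500_000, 70_600_000)]
        assert candidate_region_check([cand], regions) == [(cand, 0)]

    def test_candidate_on_chrom_without_regions_unflagged(self):
        cand = make_record(100, [2, 2, 1, 1, 1], chrom="3")
        regions = [self._region("12", 1, 10)]
        assert candidate_region_check([cand], regions) == [(cand, None)]

    def test_random_candidates_match_brute_force_membership(self):
        rng = np.random.default_rng(7)
        regions = []
        for _ in range(20):
            chrom = str(rng.integers(1, 4))
            start = int(rng.integers(1, 1000))
            regions.append(self._region(chrom, start, start + int(rng.integers(1, 500))))
        candidates = [
            make_record(int(rng.integers(1, 1600)), [2, 2, 1, 1, 1], chrom=str(rng.integers(1, 4)))
            for _ in range(100)
        ]
        got = candidate_region_check(candidates, regions)
        for rec, idx in got:
            hits = [i for i, r in enumerate(regions)
                    if r.chrom == rec.chrom and r.start <= rec.pos <= r.end]
            assert idx == (hits[0] if hits else None)


class TestSummarizeCohort:
    def test_counts_match_direct_tally(self):
        rng = np.random.default_rng(3)
        ids = [f"ctrl{i}" for i in range(50)]
        records = []
        for pos in range(1, 21):
            dosages = [[0, 1, 2, None][k] for k in rng.integers(0, 4, size=50)]
            records.append(
                VariantRecord("1", pos, "A", "T", {s: call_of(d) for s, d in zip(ids, dosages)})
            )
        summary = summarize_cohort(records, ids)
        for rec in records:
            c = summary.counts[rec.key]
            dosages = [rec.dosage(s) for s in ids]
            assert c.as_tuple() == (dosages.count(0), dosages.count(1), dosages.count(2))
            assert c.n_missing == dosages.count(None)
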