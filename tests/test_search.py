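import numpy as np
import pytest

from marrowmatch.alleles import Locus, parse_allele
from marrowmatch.frequencies import ProbabilityCategory
from marrowmatch.matching import match_grade
from marrowmatch.registry import DonorRecord
from marrowmatch.search import (
    BestGrade,
    RegistryIndex,
    SearchCase,
    SearchPolicy,
    TerminationReason,
    run_cohort,
    run_search,
    select_mismatched_donor,
)

from .conftest import HAP1, HAP2, HAP3, make_genotype

PATIENT = make_genotype("pt", HAP1, HAP2, dpb1=("DPB1*04:01", "DPB1*02:01"))

HAP2_DQ_MM = ("A*02:01", "B*07:02", "C*07:02", "DRB1*15:01", "DQB1*06:03")


def donor(gid, hap_a, hap_b, dpb1=None):
    g = make_genotype(gid, hap_a, hap_b, dpb1=dpb1)
    return DonorRecord(
        id=gid, true_genotype=g, reported_genotype=g,
        resolution_profile="high", available=True,
    )


def _policy(**kw):
    defaults = dict(unavailability_rate=0.0, max_rounds=3)
    defaults.update(kw)
    return SearchPolicy(**defaults)


def _case(category):
    return SearchCase(patient=PATIENT, category=category)


class TestPlantedScenarios:
    @pytest.mark.parametrize("category", list(ProbabilityCategory))
    def test_planted_full_match_is_found(self, category):
        registry = [
            donor("D1", HAP1, HAP3),
            donor("D2", HAP1, HAP2, dpb1=("DPB1*04:01", "DPB1*02:01")),
            donor("D3", HAP3, HAP3),
        ]
        case = _case(category)
        out = run_search(case, registry, _policy(urgent=True),
                         np.random.default_rng(0))
        assert out.best_grade is BestGrade.m10
        assert out.terminated_reason is TerminationReason.matched_found
        assert out.best_donor_id == "D2"

    @pytest.mark.parametrize("category", list(ProbabilityCategory))
    def test_planted_dqb1_mismatch_yields_9_of_10(self, category):
        registry = [donor("D1", HAP1, HAP2_DQ_MM)]
        case = _case(category)
        out = run_search(case, registry, _policy(urgent=True),
                         np.random.default_rng(0))
        assert out.best_grade is BestGrade.m9
        assert out.terminated_reason is TerminationReason.mismatch_accepted

    @pytest.mark.parametrize("category", list(ProbabilityCategory))
    def test_empty_registry_terminates_without_donor(self, category):
        case = _case(category)
        out = run_search(case, [], _policy(), np.random.default_rng(0))
        assert out.best_grade is BestGrade.none
        expected = (
            TerminationReason.alternative_source
            if category is ProbabilityCategory.low
            else TerminationReason.exhausted
        )
        assert out.terminated_reason is expected

    def test_incompatible_registry_low_category_alternative_source(self):
        registry = [donor("D1", HAP3, HAP3)]
        out = run_search(_case(ProbabilityCategory.low), registry, _policy(),
                         np.random.default_rng(0))
        assert out.best_grade is BestGrade.none
        assert out.terminated_reason is TerminationReason.alternative_source
        assert out.donors_tested == 0


class TestDpb1Branch:
    def test_nonurgent_high_search_prefers_dpb1_matched_donor(self):
        registry = [
            donor("D1", HAP1, HAP2, dpb1=("DPB1*03:01", "DPB1*05:01")),
            donor("D2", HAP1, HAP2, dpb1=("DPB1*04:01", "DPB1*02:01")),
        ]
        out = run_search(
            _case(ProbabilityCategory.high), registry,
            _policy(urgent=False, batch_size_high=(2, 2)),
            np.random.default_rng(0),
        )
        assert out.best_donor_id == "D2"
        assert out.dpb1_status.value == "matched"
        assert out.best_grade is BestGrade.m10

    def test_tce3_fallback_selects_permissive_mismatch(self, tce_table):
        registry = [
            # nonpermissive: donor min TCE group 1 vs patient group 3
            donor("D1", HAP1, HAP2, dpb1=("DPB1*09:01", "DPB1*04:01")),
            # permissive: both minimum group 3
            donor("D2", HAP1, HAP2, dpb1=("DPB1*04:02", "DPB1*01:01")),
        ]
        out = run_search(
            _case(ProbabilityCategory.high), registry,
            _policy(urgent=False, batch_size_high=(2, 2), max_rounds=1),
            np.random.default_rng(0), tce_table=tce_table,
        )
        assert out.terminated_reason is TerminationReason.matched_found
        assert out.best_donor_id == "D2"

    def test_urgent_search_skips_dpb1_branch(self):
        registry = [donor("D1", HAP1, HAP2, dpb1=("DPB1*03:01", "DPB1*05:01"))]
        out = run_search(
            _case(ProbabilityCategory.high), registry, _policy(urgent=True),
            np.random.default_rng(0),
        )
        assert out.best_grade is BestGrade.m10
        assert out.terminated_reason is TerminationReason.matched_found


class TestSelectMismatchedDonor:
    def _graded(self, *donors):
        return [(d, match_grade(PATIENT, d.true_genotype)) for d in donors]

    def test_dqb1_mismatch_ranked_before_c_mismatch(self):
        c_mm = donor("A-Cmm", HAP1, ("A*02:01", "B*07:02", "C*07:04", "DRB1*15:01", "DQB1*06:02"))
        dq_mm = donor("B-DQmm", HAP1, HAP2_DQ_MM)
        ranked = select_mismatched_donor(PATIENT, self._graded(c_mm, dq_mm))
        assert [d.id for d, _ in ranked] == ["B-DQmm", "A-Cmm"]

    def test_b_mismatch_preserving_c_before_a_mismatch(self):
        b_mm = donor("b", HAP1, ("A*02:01", "B*07:04", "C*07:02", "DRB1*15:01", "DQB1*06:02"))
        a_mm = donor("a", HAP1, ("A*02:05", "B*07:02", "C*07:02", "DRB1*15:01", "DQB1*06:02"))
        ranked = select_mismatched_donor(PATIENT, self._graded(b_mm, a_mm))
        assert [d.id for d, _ in ranked] == ["b", "a"]

    def test_rare_allele_locus_outranks_b(self):
        b_mm = donor("b", HAP1, ("A*02:01", "B*07:04", "C*07:02", "DRB1*15:01", "DQB1*06:02"))
        a_mm = donor("a", HAP1, ("A*02:05", "B*07:02", "C*07:02", "DRB1*15:01", "DQB1*06:02"))
        ranked = select_mismatched_donor(
            PATIENT, self._graded(b_mm, a_mm), rare_loci=frozenset({Locus.A})
        )
        assert [d.id for d, _ in ranked] == ["a", "b"]

    def test_single_candidate_returned_as_is(self):
        only = donor("solo", HAP1, HAP2_DQ_MM)
        ranked = select_mismatched_donor(PATIENT, self._graded(only))
        assert [d.id for d, _ in ranked] == ["solo"]

    def test_empty_candidates_empty_ranking(self):
        assert select_mismatched_donor(PATIENT, []) == []


class TestWorkflowInvariants:
    def test_day_stamps_nondecreasing_and_counters_consistent(self):
        registry = [donor(f"D{i}", HAP1, HAP3) for i in range(12)]
        case = _case(ProbabilityCategory.intermediate)
        out = run_search(case, registry, _policy(), np.random.default_rng(1))
        days = [e.day for e in case.log]
        assert days == sorted(days)
        assert case.donors_tested == out.donors_tested
        assert out.donors_tested <= 3 * 6  # max_rounds x max batch

    def test_unavailable_donors_are_skipped_not_tested(self):
        registry = [donor("D1", HAP1, HAP2)]
        case = _case(ProbabilityCategory.high)
        out = run_search(case, registry,
                         _policy(unavailability_rate=1.0, urgent=True),
                         np.random.default_rng(0))
        assert out.donors_tested == 0
        assert out.best_grade is BestGrade.none

    def test_same_seed_same_outcome(self):
        registry = [donor(f"D{i}", HAP1, HAP2 if i == 5 else HAP3) for i in range(9)]
        policy = _policy(unavailability_rate=0.3, urgent=True)
        outs = [
            run_search(_case(ProbabilityCategory.low), registry, policy,
                       np.random.default_rng(77))
            for _ in range(2)
        ]
        assert outs[0] == outs[1]

    def test_degraded_reported_typing_resolved_by_confirmatory_typing(
        self, serotype_map
    ):
        from marrowmatch.registry import degrade_typing

        true = make_genotype("D1", HAP1, HAP2)
        reported, _ = degrade_typing(true, "serologic", serotype_map)
        rec = DonorRecord(id="D1", true_genotype=true, reported_genotype=reported,
                          resolution_profile="serologic", available=True)
        out = run_search(
            _case(ProbabilityCategory.high), [rec], _policy(urgent=True),
            np.random.default_rng(0), serotype_map=serotype_map,
        )
        assert out.best_grade is BestGrade.m10

    def test_backup_donor_recorded(self):
        registry = [
            donor("D1", HAP1, HAP2),
            donor("D2", HAP1, HAP2),
            donor("D3", HAP3, HAP3),
        ]
        out = run_search(_case(ProbabilityCategory.high), registry,
                         _policy(urgent=True, batch_size_high=(3, 3)),
                         np.random.default_rng(0))
        assert out.best_donor_id == "D1"
        assert out.backup_donor_id == "D2"

    def test_run_cohort_empty(self):
        assert run_cohort([], [], _policy()) == []

    def test_run_cohort_matches_individual_runs_in_length(self, serotype_map):
        registry = [donor(f"D{i}", HAP1, HAP2) for i in range(4)]
        cases = [_case(ProbabilityCategory.high) for _ in range(5)]
        outs = run_cohort(cases, registry, _policy(urgent=True), seed=3,
                          serotype_map=serotype_map)
        assert len(outs) == 5
        assert all(o.best_grade is BestGrade.m10 for o in outs)
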