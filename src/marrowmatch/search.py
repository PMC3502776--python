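"""Discrete simulation of the unrelated-donor search workflow.

The search proceeds in rounds: a batch of candidate donors is requested
from the registry (high-probability searches request 2-4 donors
including a back-up, others 4-6, anticipating >20% donor
unavailability), available donors undergo confirmatory typing, and the
resulting match grades drive the next step.  High-probability,
non-urgent searches additionally evaluate DPB1 aiming at a 12/12 donor,
falling back to the TCE3 permissiveness rule when no DPB1-matched donor
emerges.  Low-probability searches consider a single mismatch early and,
when nothing acceptable is found, terminate toward another stem-cell
source (cord blood, haplo-identical donor) or a non-transplant protocol.

Candidate preselection uses the donors' *reported* (possibly
low-resolution) typings with ambiguity treated as potentially
compatible, mirroring real searches where low-resolution registry donors
need confirmatory typing before they can be graded.

The time model is a stub clock with fixed configurable per-action
durations; it provides reproducible, ordered day stamps but is not a
model of real-world search durations.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import StrEnum
from typing import Mapping, Sequence

import numpy as np

from .alleles import CORE_LOCI, Allele, Locus, Resolution, SerotypeMap
from .frequencies import ProbabilityCategory
from .genotypes import Genotype
from .matching import Dpb1Status, MatchGrade, TceCall, match_grade, tce3_classify
from .registry import DonorRecord, sample_availability

__all__ = [
    "BestGrade",
    "TerminationReason",
    "SearchPolicy",
    "SearchCase",
    "SearchOutcome",
    "RegistryIndex",
    "run_search",
    "run_cohort",
    "select_mismatched_donor",
]


class BestGrade(StrEnum):
    m10 = "m10"
    m9 = "m9"
    m8_or_less = "m8_or_less"
    none = "none"


class TerminationReason(StrEnum):
    matched_found = "matched_found"
    mismatch_accepted = "mismatch_accepted"
    exhausted = "exhausted"
    alternative_source = "alternative_source"


def _default_durations() -> dict[str, int]:
    return {"request": 7, "typing": 14, "report": 3}


@dataclass(frozen=True)
class SearchPolicy:
    """Knobs of the search workflow."""

    batch_size_high: tuple[int, int] = (2, 4)
    batch_size_other: tuple[int, int] = (4, 6)
    urgent: bool = False
    dpb1_branch_enabled: bool = True
    max_rounds: int = 3
    step_durations: Mapping[str, int] = field(default_factory=_default_durations)
    unavailability_rate: float = 0.25

    def __post_init__(self) -> None:
        for lo, hi in (self.batch_size_high, self.batch_size_other):
            if not 1 <= lo <= hi <= 10:
                raise ValueError("batch ranges must lie within 1-10")
        if self.max_rounds < 1:
            raise ValueError("max_rounds must be >= 1")


@dataclass
class Event:
    day: int
    action: str
    detail: str = ""


@dataclass
class SearchCase:
    patient: Genotype
    category: ProbabilityCategory
    state: str = "start"
    log: list[Event] = field(default_factory=list)
    donors_requested: int = 0
    donors_tested: int = 0


@dataclass(frozen=True)
class SearchOutcome:
    best_grade: BestGrade
    dpb1_status: Dpb1Status
    donors_tested: int
    days_to_identification: int
    terminated_reason: TerminationReason
    best_donor_id: str | None = None
    backup_donor_id: str | None = None


# -- fast candidate preselection -----------------------------------------

def _allele_tokens(
    allele: Allele, serotype_map: SerotypeMap | None
) -> tuple[str, str, int | None]:
    """(two-field key, group key, serotype value) for fast comparison."""
    if allele.resolution is Resolution.serologic:
        return ("", "", allele.serotype_value)
    sero = serotype_map.serotype_of(allele) if serotype_map else None
    return (
        allele.match_key,
        allele.group_key,
        sero.serotype_value if sero else None,
    )


def _donor_locus_rep(
    alleles: tuple[Allele, ...], serotype_map: SerotypeMap | None
) -> tuple[tuple[str, object], ...]:
    rep = []
    pair = (alleles[0], alleles[0]) if len(alleles) == 1 else alleles
    for a in pair:
        if a.resolution is Resolution.high:
            rep.append(("H", a.match_key))
        elif a.resolution is Resolution.allele_group:
            rep.append(("G", a.group_key))
        else:
            rep.append(("S", a.serotype_value))
    return tuple(rep)


def _slot_ok(patient_tok: tuple[str, str, int | None], donor_tok: tuple[str, object]) -> bool:
    kind, val = donor_tok
    if kind == "H":
        return patient_tok[0] == val
    if kind == "G":
        return patient_tok[1] == val
    # serologic donor typing: unmapped patient allele stays ambiguous
    return patient_tok[2] is None or patient_tok[2] == val


class RegistryIndex:
    """Registry with precomputed reported-typing tokens for fast
    compatibility scans."""

    def __init__(
        self, donors: Sequence[DonorRecord], serotype_map: SerotypeMap | None = None
    ):
        self.donors = list(donors)
        self.serotype_map = serotype_map
        self._reps: list[dict[Locus, tuple]] = []
        self._exact_keys: list[tuple[str, ...] | None] = []
        for d in self.donors:
            rep: dict[Locus, tuple] = {}
            g = d.reported_genotype
            for locus in CORE_LOCI:
                if locus in g.typings:
                    rep[locus] = _donor_locus_rep(g.typings[locus], serotype_map)
            self._reps.append(rep)
            if g.is_high_resolution() and all(l in g.typings for l in CORE_LOCI):
                self._exact_keys.append(g.allele_multiset())
            else:
                self._exact_keys.append(None)

    def candidates_for(self, patient: Genotype) -> list[DonorRecord]:
        """Potentially compatible donors, ordered for requesting.

        Donors whose reported typing could still be a full match come
        first (reported-exact matches before ambiguous ones needing
        confirmatory typing), followed by donors with a single
        definitely-mismatched locus — potential 9/10 donors, which the
        low-probability path considers early.  Ties break on donor id.
        """
        patient.require(CORE_LOCI)
        p_toks = {
            locus: tuple(
                _allele_tokens(a, self.serotype_map) for a in patient.pair(locus)
            )
            for locus in CORE_LOCI
        }
        p_exact = patient.allele_multiset()
        hits: list[tuple[int, str, DonorRecord]] = []
        for d, rep, exact in zip(self.donors, self._reps, self._exact_keys):
            mismatched_loci = 0
            for locus, (p1, p2) in p_toks.items():
                toks = rep.get(locus)
                if toks is None:
                    continue  # untyped locus: resolved by confirmatory typing
                d1, d2 = toks
                if not (
                    (_slot_ok(p1, d1) and _slot_ok(p2, d2))
                    or (_slot_ok(p1, d2) and _slot_ok(p2, d1))
                ):
                    mismatched_loci += 1
                    if mismatched_loci > 1:
                        break
            if mismatched_loci > 1:
                continue
            if mismatched_loci == 1:
                tier = 2
            else:
                tier = 0 if exact == p_exact else 1
            hits.append((tier, d.id, d))
        hits.sort(key=lambda t: t[:2])
        return [d for _, _, d in hits]


def select_mismatched_donor(
    patient: Genotype,
    candidates: Sequence[tuple[DonorRecord, MatchGrade]],
    rare_loci: frozenset[Locus] = frozenset(),
) -> list[tuple[DonorRecord, MatchGrade]]:
    """Rank 9/10 donors by mismatch acceptability.

    Order: DQB1 mismatches first (the most readily accepted), then a
    mismatch at the locus carrying the patient's rare allele, then B
    mismatches preserving HLA-C, then DRB1 mismatches preserving DQB1,
    then everything else (A or C mismatches, DRB3 disparities).  Ties
    break on donor id for determinism.
    """

    def rank(item: tuple[DonorRecord, MatchGrade]) -> tuple[int, str]:
        donor, grade = item
        core_mm = [m for m in grade.mismatched_loci if m[0] is not Locus.DPB1]
        if not core_mm:  # DRB3 disparity only
            return (5, donor.id)
        locus = core_mm[0][0]
        if locus is Locus.DQB1:
            return (0, donor.id)
        if locus in rare_loci:
            return (1, donor.id)
        if locus is Locus.B:
            return (2, donor.id)
        if locus is Locus.DRB1:
            return (3, donor.id)
        return (4, donor.id)

    return sorted(candidates, key=rank)


_GRADE_ORDER = {"10/10": 0, "9/10": 1, "<=8/10 or nonevaluable": 2}


def _grade_rank(grade: MatchGrade) -> int:
    return _GRADE_ORDER[grade.label]


def _to_best_grade(grade: MatchGrade | None) -> BestGrade:
    if grade is None:
        return BestGrade.none
    return {
        "10/10": BestGrade.m10,
        "9/10": BestGrade.m9,
        "<=8/10 or nonevaluable": BestGrade.m8_or_less,
    }[grade.label]


def run_search(
    case: SearchCase,
    registry: Sequence[DonorRecord] | RegistryIndex,
    policy: SearchPolicy,
    rng: np.random.Generator,
    serotype_map: SerotypeMap | None = None,
    tce_table: Mapping[str, int] | None = None,
    rare_loci: frozenset[Locus] = frozenset(),
) -> SearchOutcome:
    """Run one search to termination and return its outcome."""
    index = (
        registry
        if isinstance(registry, RegistryIndex)
        else RegistryIndex(registry, serotype_map)
    )
    patient = case.patient
    dpb1_mode = (
        case.category is ProbabilityCategory.high
        and not policy.urgent
        and policy.dpb1_branch_enabled
        and Locus.DPB1 in patient.typings
    )
    candidates = index.candidates_for(patient)
    case.state = "candidates_preselected"
    case.log.append(Event(0, "preselect", f"{len(candidates)} potential donors"))

    day = 0
    ptr = 0
    graded: list[tuple[DonorRecord, MatchGrade]] = []
    ten_of_ten: list[tuple[DonorRecord, MatchGrade]] = []
    decisive_day: int | None = None
    lo, hi = (
        policy.batch_size_high
        if case.category is ProbabilityCategory.high
        else policy.batch_size_other
    )

    def finish(
        best: tuple[DonorRecord, MatchGrade] | None,
        reason: TerminationReason,
    ) -> SearchOutcome:
        donor, grade = best if best else (None, None)
        ranked = sorted(graded, key=lambda t: (_grade_rank(t[1]), t[0].id))
        backup = next(
            (d.id for d, _ in ranked if donor is None or d.id != donor.id), None
        )
        case.state = "terminated"
        return SearchOutcome(
            best_grade=_to_best_grade(grade),
            dpb1_status=grade.dpb1_status if grade else Dpb1Status.untyped,
            donors_tested=case.donors_tested,
            days_to_identification=decisive_day if decisive_day is not None else day,
            terminated_reason=reason,
            best_donor_id=donor.id if donor else None,
            backup_donor_id=backup,
        )

    for _ in range(policy.max_rounds):
        if ptr >= len(candidates):
            break
        size = int(rng.integers(lo, hi + 1))
        batch = candidates[ptr : ptr + size]
        ptr += size
        day += policy.step_durations["request"]
        case.donors_requested += len(batch)
        case.log.append(Event(day, "request", f"{len(batch)} donors"))

        tested: list[DonorRecord] = []
        for donor in batch:
            # availability is resampled per request: a donor may have
            # become unavailable since registration
            if sample_availability(policy.unavailability_rate, rng):
                tested.append(donor)
            else:
                case.log.append(Event(day, "unavailable", donor.id))
        if not tested:
            continue

        day += policy.step_durations["typing"]
        batch_graded: list[tuple[DonorRecord, MatchGrade]] = []
        for donor in tested:
            grade = match_grade(
                patient, donor.true_genotype, include_dpb1=dpb1_mode,
                serotype_map=serotype_map,
            )
            case.donors_tested += 1
            batch_graded.append((donor, grade))
            case.log.append(
                Event(day, "typed", f"{donor.id}: {grade.label}")
            )
        day += policy.step_durations["report"]
        case.log.append(Event(day, "report", f"round result for {len(tested)} donors"))
        graded.extend(batch_graded)

        new_ten = [
            (d, g) for d, g in batch_graded if g.label == "10/10"
        ]
        ten_of_ten.extend(new_ten)
        if new_ten:
            decisive_day = day
            if not dpb1_mode:
                best = min(new_ten, key=lambda t: t[0].id)
                case.log.append(Event(day, "matched", best[0].id))
                return finish(best, TerminationReason.matched_found)
            dpb1_ok = [
                (d, g) for d, g in ten_of_ten if g.dpb1_status is Dpb1Status.matched
            ]
            if dpb1_ok:
                best = min(dpb1_ok, key=lambda t: t[0].id)
                case.log.append(Event(day, "matched", f"{best[0].id} (DPB1 matched)"))
                return finish(best, TerminationReason.matched_found)
            # keep searching for a DPB1-matched donor while rounds remain

    # rounds or candidates exhausted
    if ten_of_ten:
        # DPB1 branch fallback: prefer a TCE3-permissive DPB1 mismatch
        pool = ten_of_ten
        if tce_table is not None and Locus.DPB1 in patient.typings:
            permissive = [
                (d, g)
                for d, g in ten_of_ten
                if Locus.DPB1 in d.true_genotype.typings
                and tce3_classify(
                    patient.pair(Locus.DPB1),
                    d.true_genotype.pair(Locus.DPB1),
                    tce_table,
                )
                is TceCall.permissive
            ]
            if permissive:
                pool = permissive
        best = min(pool, key=lambda t: t[0].id)
        case.log.append(Event(day, "matched", f"{best[0].id} (TCE3 fallback)"))
        return finish(best, TerminationReason.matched_found)

    nine = [(d, g) for d, g in graded if g.label == "9/10"]
    if nine:
        decisive_day = day
        if case.category is ProbabilityCategory.low or policy.urgent:
            ranked = select_mismatched_donor(patient, nine, rare_loci)
            best = ranked[0]
            case.log.append(Event(day, "mismatch_accepted", best[0].id))
            return finish(best, TerminationReason.mismatch_accepted)
        best = min(nine, key=lambda t: t[0].id)
        return finish(best, TerminationReason.exhausted)

    lesser = sorted(graded, key=lambda t: (_grade_rank(t[1]), t[0].id))
    best = lesser[0] if lesser else None
    if case.category is ProbabilityCategory.low:
        # no acceptable donor: move to another HSC source or a
        # non-transplant protocol
        case.log.append(Event(day, "alternative_source", ""))
        return finish(best, TerminationReason.alternative_source)
    return finish(best, TerminationReason.exhausted)


def run_cohort(
    cases: Sequence[SearchCase],
    registry: Sequence[DonorRecord] | RegistryIndex,
    policy: SearchPolicy,
    seed: int = 0,
    serotype_map: SerotypeMap | None = None,
    tce_table: Mapping[str, int] | None = None,
) -> list[SearchOutcome]:
    """Independent seeded searches for a cohort of cases."""
    index = (
        registry
        if isinstance(registry, RegistryIndex)
        else RegistryIndex(registry, serotype_map)
    )
    seeds = np.random.SeedSequence(seed).spawn(len(cases))
    return [
        run_search(
            case, index, policy, np.random.default_rng(s),
            serotype_map=serotype_map, tce_table=tce_table,
        )
        for case, s in zip(cases, seeds)
    ]
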