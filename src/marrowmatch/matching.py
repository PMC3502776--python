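"""Match grading between patient and donor HLA typings.

The clinical currency of unrelated-donor searches is the matched-allele
count over HLA-A, B, C, DRB1 and DQB1 — the 10/10 grade — optionally
extended to 12/12 by HLA-DPB1.  A disparity at the secondary DRB loci
(DRB3/4/5) demotes a 10/10 to 9/10.  DPB1 mismatches additionally carry a
direction: graft-versus-host when the patient has an allele the donor
lacks, rejection (host-versus-graft) when the donor has one the patient
lacks.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import StrEnum
from typing import Mapping

from .alleles import (
    CORE_LOCI,
    Allele,
    Compat,
    Locus,
    SerotypeMap,
    alleles_compatible,
)
from .genotypes import Genotype

__all__ = [
    "Dpb1Status",
    "TceCall",
    "MatchGrade",
    "match_grade",
    "dpb1_direction",
    "tce3_classify",
    "locus_mismatch_count",
]


class Dpb1Status(StrEnum):
    matched = "matched"
    GvH_only = "GvH_only"
    HvG_only = "HvG_only"
    bidirectional = "bidirectional"
    untyped = "untyped"


class TceCall(StrEnum):
    permissive = "permissive"
    nonpermissive_GvH = "nonpermissive_GvH"
    nonpermissive_HvG = "nonpermissive_HvG"
    unknown = "unknown"


@dataclass(frozen=True)
class MatchGrade:
    """Matched-allele count with per-locus mismatch annotations."""

    matched: int
    denominator: int
    mismatched_loci: tuple[tuple[Locus, Allele, Allele], ...]
    drb3_disparity: bool
    dpb1_status: Dpb1Status
    not_evaluable_loci: tuple[Locus, ...] = ()
    core_matched: int = -1  # matched count over the 10 core alleles

    def __post_init__(self) -> None:
        if not 0 <= self.matched <= self.denominator:
            raise ValueError("matched count outside [0, denominator]")
        if self.core_matched < 0:
            object.__setattr__(
                self, "core_matched", min(self.matched, 10)
            )

    @property
    def is_full_match(self) -> bool:
        return self.matched == self.denominator

    @property
    def label(self) -> str:
        """Grade label over the 10 core alleles, as used in cohort reports."""
        if any(l is not Locus.DPB1 for l in self.not_evaluable_loci):
            return "<=8/10 or nonevaluable"
        if self.core_matched >= 10:
            return "10/10"
        if self.core_matched == 9:
            return "9/10"
        return "<=8/10 or nonevaluable"


def _pairings(
    patient: tuple[Allele, Allele], donor: tuple[Allele, Allele]
) -> tuple[tuple[tuple[Allele, Allele], ...], ...]:
    p1, p2 = patient
    d1, d2 = donor
    return (((p1, d1), (p2, d2)), ((p1, d2), (p2, d1)))


def _grade_locus(
    patient: tuple[Allele, Allele],
    donor: tuple[Allele, Allele],
    serotype_map: SerotypeMap | None,
) -> tuple[int, int, list[tuple[Allele, Allele]]]:
    """Mismatch/ambiguity counts at one locus under the optimal pairing.

    Within a locus the two patient alleles are paired with the two donor
    alleles so as to minimise mismatches (standard practice; 0, 1 or 2
    mismatches per locus).
    """
    best: tuple[int, int, list[tuple[Allele, Allele]]] | None = None
    for pairing in _pairings(patient, donor):
        mm = 0
        amb = 0
        mm_pairs: list[tuple[Allele, Allele]] = []
        for pa, da in pairing:
            status = alleles_compatible(pa, da, serotype_map)
            if status is Compat.mismatch:
                mm += 1
                mm_pairs.append((pa, da))
            elif status is Compat.ambiguous:
                amb += 1
        cand = (mm, amb, mm_pairs)
        if best is None or (mm + amb, mm) < (best[0] + best[1], best[0]):
            best = cand
    assert best is not None
    return best


def locus_mismatch_count(
    patient: tuple[Allele, Allele],
    donor: tuple[Allele, Allele],
    serotype_map: SerotypeMap | None = None,
) -> int:
    """Mismatches at one locus under the minimising allele pairing."""
    return _grade_locus(patient, donor, serotype_map)[0]


def _drb345_disparity(patient: Genotype, donor: Genotype) -> bool:
    """Secondary-DRB disparity: both sides typed and allele supports differ.

    A single recorded allele counts as homozygous; an untyped side is
    treated as not evaluable (no disparity flagged).  However many
    alleles differ, the disparity deducts at most one point.
    """
    if not (patient.has_drb345_typing() and donor.has_drb345_typing()):
        return False
    p = {a.match_key for a in patient.drb345_alleles()}
    d = {a.match_key for a in donor.drb345_alleles()}
    return p != d


def dpb1_direction(
    patient_pair: tuple[Allele, Allele], donor_pair: tuple[Allele, Allele]
) -> Dpb1Status:
    """Directionality of a DPB1 disparity.

    GvH component: the patient carries an allele absent from the donor.
    HvG (rejection) component: the donor carries an allele absent from
    the patient.  Matched when the allele supports coincide.
    """
    p = {a.match_key for a in patient_pair}
    d = {a.match_key for a in donor_pair}
    gvh = bool(p - d)
    hvg = bool(d - p)
    if gvh and hvg:
        return Dpb1Status.bidirectional
    if gvh:
        return Dpb1Status.GvH_only
    if hvg:
        return Dpb1Status.HvG_only
    return Dpb1Status.matched


def tce3_classify(
    patient_pair: tuple[Allele, Allele],
    donor_pair: tuple[Allele, Allele],
    tce_table: Mapping[str, int],
) -> TceCall:
    """Permissiveness of a DPB1 disparity under the three-group T-cell
    epitope (TCE3) model.

    Each individual is assigned the minimum (most immunogenic) group of
    its two DPB1 alleles; equal group indices are permissive, a lower
    patient index is nonpermissive in GvH direction, a lower donor index
    nonpermissive in HvG direction.  Any allele absent from the table
    yields ``unknown`` (a value, not an error).  The exact published rule
    lives outside this package's sources; this minimum-group comparison
    is an interpretation isolated behind this one function.
    """
    groups: list[int] = []
    for pair in (patient_pair, donor_pair):
        gs = [tce_table.get(a.match_key) for a in pair]
        if any(g is None for g in gs):
            return TceCall.unknown
        groups.append(min(g for g in gs if g is not None))
    pg, dg = groups
    if pg == dg:
        return TceCall.permissive
    return TceCall.nonpermissive_GvH if pg < dg else TceCall.nonpermissive_HvG


def match_grade(
    patient: Genotype,
    donor: Genotype,
    include_dpb1: bool = False,
    serotype_map: SerotypeMap | None = None,
) -> MatchGrade:
    """Grade a donor against a patient over the five core loci.

    ``matched`` is 10 minus the per-allele mismatches over HLA-A, B, C,
    DRB1 and DQB1 (optimal pairing within each locus), minus one point
    for a DRB3/4/5 disparity, floored at 0.  With ``include_dpb1`` the
    denominator is 12, DPB1 contributes per-allele counts and the
    direction of any DPB1 disparity is annotated.  Ambiguous comparisons
    (low-resolution typings) are never silently matched: the locus is
    reported as not evaluable and its ambiguous alleles excluded from the
    matched count.
    """
    patient.require(CORE_LOCI)
    donor.require(CORE_LOCI)

    mismatches: list[tuple[Locus, Allele, Allele]] = []
    not_evaluable: list[Locus] = []
    total_mm = 0
    total_amb = 0
    for locus in CORE_LOCI:
        mm, amb, mm_pairs = _grade_locus(
            patient.pair(locus), donor.pair(locus), serotype_map
        )
        total_mm += mm
        total_amb += amb
        if amb:
            not_evaluable.append(locus)
        mismatches.extend((locus, pa, da) for pa, da in mm_pairs)

    drb3 = _drb345_disparity(patient, donor)
    core_matched = max(0, 10 - total_mm - total_amb - (1 if drb3 else 0))
    matched = core_matched
    denominator = 10
    dpb1_status = Dpb1Status.untyped

    if include_dpb1:
        denominator = 12
        if Locus.DPB1 in patient.typings and Locus.DPB1 in donor.typings:
            p_pair = patient.pair(Locus.DPB1)
            d_pair = donor.pair(Locus.DPB1)
            mm, amb, mm_pairs = _grade_locus(p_pair, d_pair, serotype_map)
            if amb:
                not_evaluable.append(Locus.DPB1)
            else:
                dpb1_status = dpb1_direction(p_pair, d_pair)
            matched += 2 - mm - amb
            mismatches.extend((Locus.DPB1, pa, da) for pa, da in mm_pairs)
        # untyped DPB1 contributes nothing: a 12/12 needs typed, matched DPB1

    return MatchGrade(
        matched=matched,
        denominator=denominator,
        mismatched_loci=tuple(mismatches),
        drb3_disparity=drb3,
        dpb1_status=dpb1_status,
        not_evaluable_loci=tuple(not_evaluable),
        core_matched=core_matched,
    )
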