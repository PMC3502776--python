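"""Heuristic criteria that push a search toward a low probability estimate.

Besides the numeric haplotype-frequency estimate, searches are screened
against a closed set of warning criteria: very few donors in the
worldwide registry (BMDW), non-European ancestry, a rare allele (fewer
than 5% of the alleles carrying the patient's serotype), unusual B-C or
DRB1-DQB1 associations, and B-locus alleles whose haplotypes carry an
elevated risk of C or B*35 mismatches.  A rare allele residing on a
known conserved haplotype is exempt: such alleles travel with a fixed
extended haplotype, so the search may still succeed.

How these criteria combine with the numeric estimate is a design choice
of this package: each distinct firing rule family demotes the
frequency-derived category one step (high -> intermediate -> low), and a
registry donor count at or below the configured minimum forces low
outright.  Both the pre- and post-demotion categories are reported for
auditability.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from enum import StrEnum
from pathlib import Path
from typing import Sequence

import yaml

from .alleles import Allele, Locus, SerotypeMap, parse_allele
from .frequencies import (
    DEFAULT_AVAILABILITY,
    HaplotypeFrequencyTable,
    MatchProbabilityResult,
    ProbabilityCategory,
    estimate_match_probability,
)
from .genotypes import Genotype

__all__ = [
    "RuleId",
    "RuleHit",
    "ClassifierConfig",
    "ClassificationResult",
    "rare_allele_rule",
    "rare_association_rule",
    "risk_haplotype_rule",
    "classify_search",
]


class RuleId(StrEnum):
    few_bmdw_donors = "few_bmdw_donors"
    non_european = "non_european"
    rare_allele = "rare_allele"
    rare_BC_association = "rare_BC_association"
    rare_DRB1DQB1_association = "rare_DRB1DQB1_association"
    C_mm_risk_haplotype = "C_mm_risk_haplotype"
    B35_allele_mm_risk = "B35_allele_mm_risk"


@dataclass(frozen=True)
class RuleHit:
    rule_id: RuleId
    evidence: str
    severity: bool = True  # pushes the estimate toward low


def _default_c_risk() -> tuple[str, ...]:
    return ("B*15:01", "B*18:01", "B*27:05", "B*51:01")


def _default_b35_risk() -> tuple[str, ...]:
    return ("B*35:02", "B*35:03", "B*35:08")


@dataclass(frozen=True)
class ClassifierConfig:
    """Thresholds and allele lists behind the warning criteria.

    ``rare_allele_threshold``: an allele is rare when it accounts for
    less than this fraction of the alleles carrying its serotype (0.05).
    ``rare_association_threshold``: a B-C or DRB1-DQB1 pairing is rare
    when the conditional frequency of the partner allele falls below
    this fraction.  ``bmdw_min_donors``: at or below this many registry
    donors the search is low outright.
    """

    rare_allele_threshold: float = 0.05
    rare_association_threshold: float = 0.05
    bmdw_min_donors: int = 3
    c_mm_risk_b_alleles: tuple[str, ...] = field(default_factory=_default_c_risk)
    b35_risk_alleles: tuple[str, ...] = field(default_factory=_default_b35_risk)
    conserved_haplotype_whitelist: tuple[tuple[str, ...], ...] = ()

    def __post_init__(self) -> None:
        for t in (self.rare_allele_threshold, self.rare_association_threshold):
            if not 0 < t < 1:
                raise ValueError("thresholds must lie in (0, 1)")
        for text in (*self.c_mm_risk_b_alleles, *self.b35_risk_alleles):
            parse_allele(text)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ClassifierConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        lists = {
            k: tuple(v)
            for k, v in raw.items()
            if k in ("c_mm_risk_b_alleles", "b35_risk_alleles")
        }
        wl = raw.get("conserved_haplotype_whitelist")
        if wl is not None:
            lists["conserved_haplotype_whitelist"] = tuple(tuple(h) for h in wl)
        scalars = {
            k: v
            for k, v in raw.items()
            if k in ("rare_allele_threshold", "rare_association_threshold", "bmdw_min_donors")
        }
        return cls(**scalars, **lists)


@dataclass(frozen=True)
class ClassificationResult:
    category: ProbabilityCategory | None
    pre_demotion: ProbabilityCategory | None
    hits: tuple[RuleHit, ...]
    probability: MatchProbabilityResult | None
    note: str = ""


def rare_allele_rule(
    allele: Allele, within_serotype_share: float, config: ClassifierConfig
) -> RuleHit | None:
    """Rare-allele criterion: fewer than the threshold fraction of the
    alleles carrying the patient's serotype are this allele."""
    if not 0 <= within_serotype_share <= 1:
        raise ValueError("share outside [0, 1]")
    if within_serotype_share < config.rare_allele_threshold:
        return RuleHit(
            RuleId.rare_allele,
            f"{allele.render()} accounts for {within_serotype_share:.1%} of its serotype",
        )
    return None


def rare_association_rule(
    pair_kind: str,
    observed_pair: tuple[Allele, Allele],
    conditional_freq: float,
    config: ClassifierConfig,
) -> RuleHit | None:
    """Rare two-locus association (B-C or DRB1-DQB1): the second allele is
    an unusual haplotype partner of the first."""
    rule = {
        "B_C": RuleId.rare_BC_association,
        "DRB1_DQB1": RuleId.rare_DRB1DQB1_association,
    }[pair_kind]
    if conditional_freq < config.rare_association_threshold:
        first, second = observed_pair
        return RuleHit(
            rule,
            f"{first.render()}-{second.render()} conditional frequency "
            f"{conditional_freq:.2%}",
        )
    return None


def risk_haplotype_rule(
    genotype: Genotype, config: ClassifierConfig
) -> tuple[RuleHit, ...]:
    """B-locus alleles on haplotypes with elevated C-mismatch or B*35
    allele-mismatch risk."""
    if Locus.B not in genotype.typings:
        raise ValueError("B locus must be typed for risk-haplotype screening")
    hits: list[RuleHit] = []
    b_keys = {a.match_key: a for a in genotype.pair(Locus.B)}
    c_risk = {parse_allele(t).match_key for t in config.c_mm_risk_b_alleles}
    b35_risk = {parse_allele(t).match_key for t in config.b35_risk_alleles}
    for key, allele in sorted(b_keys.items()):
        if key in c_risk:
            hits.append(
                RuleHit(RuleId.C_mm_risk_haplotype,
                        f"{allele.render()}-positive haplotype: higher risk of C mismatch")
            )
        if key in b35_risk:
            hits.append(
                RuleHit(RuleId.B35_allele_mm_risk,
                        f"{allele.render()}-positive haplotype: higher risk of B*35 allele mismatch")
            )
    return tuple(hits)


def within_serotype_share(
    allele: Allele, table: HaplotypeFrequencyTable, serotype_map: SerotypeMap
) -> float | None:
    """Share of the allele among same-serotype alleles in the table.

    Returns None when the allele's serotype is unmapped (the rule is then
    not assessable).  An allele absent from the table has share 0.
    """
    sero = serotype_map.serotype_of(allele)
    if sero is None:
        return None
    marginal = table.allele_marginal(allele.locus)
    sero_total = 0.0
    for key, f in marginal.items():
        mapped = serotype_map.serotype_of(parse_allele(key.split("#")[0]))
        if mapped is not None and mapped.match_key == sero.match_key:
            sero_total += f
    if sero_total == 0:
        return 0.0
    return marginal.get(allele.match_key, 0.0) / sero_total


def _whitelist_suppresses(
    allele: Allele, patient: Genotype, whitelist: tuple[tuple[str, ...], ...]
) -> bool:
    """True when the rare allele sits on a whitelisted conserved haplotype
    whose remaining alleles are all present in the patient."""
    allele_key = allele.match_key
    patient_keys = {
        a.match_key for locus in patient.typings for a in patient.pair(locus)
    }
    for hap in whitelist:
        keys = [parse_allele(t).match_key for t in hap]
        if allele_key in keys and all(k in patient_keys for k in keys):
            return True
    return False


def _demote(cat: ProbabilityCategory, steps: int) -> ProbabilityCategory:
    ladder = [ProbabilityCategory.high, ProbabilityCategory.intermediate,
              ProbabilityCategory.low]
    return ladder[min(len(ladder) - 1, ladder.index(cat) + steps)]


def evaluate_rules(
    patient: Genotype,
    table: HaplotypeFrequencyTable | None,
    serotype_map: SerotypeMap | None,
    config: ClassifierConfig,
    ancestry_flag: bool = False,
) -> tuple[RuleHit, ...]:
    """All warning-rule hits for a patient phenotype.

    Association rules are phase-agnostic: for each B (resp. DRB1) allele
    the best-supported partner among the patient's C (resp. DQB1) alleles
    is used, so a hit means even the most favourable phase assignment is
    a rare pairing.
    """
    hits: list[RuleHit] = []
    if ancestry_flag:
        hits.append(RuleHit(RuleId.non_european, "non-European ancestry reported"))
    hits.extend(risk_haplotype_rule(patient, config))
    if table is None:
        return tuple(hits)

    if serotype_map is not None:
        seen: set[str] = set()
        for locus in patient.typings:
            for allele in patient.pair(locus):
                if allele.match_key in seen:
                    continue
                seen.add(allele.match_key)
                share = within_serotype_share(allele, table, serotype_map)
                if share is None:
                    continue
                hit = rare_allele_rule(allele, share, config)
                if hit is not None and not _whitelist_suppresses(
                    allele, patient, config.conserved_haplotype_whitelist
                ):
                    hits.append(hit)

    for kind, (la, lb) in (
        ("B_C", (Locus.B, Locus.C)),
        ("DRB1_DQB1", (Locus.DRB1, Locus.DQB1)),
    ):
        if la not in patient.typings or lb not in patient.typings:
            continue
        for first in dict.fromkeys(patient.pair(la)):
            best = max(
                table.conditional_frequency(la, first, lb, second)
                for second in patient.pair(lb)
            )
            partner = max(
                patient.pair(lb),
                key=lambda s: table.conditional_frequency(la, first, lb, s),
            )
            hit = rare_association_rule(kind, (first, partner), best, config)
            if hit is not None:
                hits.append(hit)
    return tuple(hits)


def classify_search(
    patient: Genotype,
    table: HaplotypeFrequencyTable | None,
    bmdw_count: int | None,
    ancestry_flag: bool = False,
    config: ClassifierConfig | None = None,
    serotype_map: SerotypeMap | None = None,
    n_donors: int = 1000,
    availability: float = DEFAULT_AVAILABILITY,
) -> ClassificationResult:
    """Assign the search probability category for a patient.

    The numeric haplotype-frequency estimate provides the starting
    category; each distinct firing rule family demotes it one step, and
    ``bmdw_count <= config.bmdw_min_donors`` forces low regardless.
    Without a frequency table the classifier runs in rules-only mode and
    reports that the numeric estimate is unavailable.
    """
    config = config or ClassifierConfig()
    hits = evaluate_rules(patient, table, serotype_map, config, ancestry_flag)

    if bmdw_count is not None and bmdw_count <= config.bmdw_min_donors:
        hits = (
            RuleHit(RuleId.few_bmdw_donors, f"only {bmdw_count} donors in BMDW"),
            *hits,
        )
        prob = (
            estimate_match_probability(patient, [table], n_donors, availability)
            if table is not None
            else None
        )
        pre = prob.category if prob is not None else None
        return ClassificationResult(
            ProbabilityCategory.low, pre, hits, prob,
            note="forced low by BMDW donor count",
        )

    if table is None:
        category = ProbabilityCategory.low if any(h.severity for h in hits) else None
        return ClassificationResult(
            category, None, hits, None,
            note="numeric estimate unavailable (no frequency table); rules-only mode",
        )

    prob = estimate_match_probability(patient, [table], n_donors, availability)
    families = {h.rule_id for h in hits if h.severity}
    category = _demote(prob.category, len(families))
    return ClassificationResult(category, prob.category, hits, prob)
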