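"""Haplotype-frequency-based donor match probability.

The chance that a random registry donor is genotype-identical to the
patient at HLA-A, B, C, DRB1, DQB1 follows from population five-locus
haplotype frequencies under Hardy-Weinberg equilibrium: an individual is
an independent draw of two haplotypes, so a multilocus genotype built
from haplotypes ``i`` and ``j`` has probability ``2 f_i f_j`` (``i != j``)
or ``f_i**2``.  Matching is evaluated at the genotype level, not the
haplotype-phase level: a donor carrying the same ten alleles in a
different phase counts as matched, because clinical grading is
allele-based.

Frequency tables rarely sum to one; the residual mass is an implicit
"other" pseudo-haplotype that is conservatively assumed never to match
any patient.

Search probabilities are classified into the three categories used at
search start: high (>95% chance of a fully matched donor), intermediate,
and low (<5%).
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import StrEnum
from typing import Iterable, Sequence

import numpy as np

from .alleles import CORE_LOCI, Allele, Locus, parse_allele
from .genotypes import Genotype

__all__ = [
    "ProbabilityCategory",
    "HaplotypeFrequencyTable",
    "MatchProbabilityResult",
    "genotype_probability",
    "donor_match_probability",
    "mixture_match_probability",
    "registry_match_probability",
    "categorize",
    "estimate_match_probability",
]

_SUM_TOL = 1e-9

#: Default donor availability: unavailability rates above 20% are the norm
#: when donors are actually requested, so a 25% attrition is assumed.
DEFAULT_AVAILABILITY = 0.75


class ProbabilityCategory(StrEnum):
    high = "high"
    intermediate = "intermediate"
    low = "low"


@dataclass(frozen=True)
class HaplotypeFrequencyTable:
    """Five-locus (A-B-C-DRB1-DQB1) haplotypes with population frequencies.

    ``haplotypes[k]`` is a tuple of five alleles in core-locus order;
    ``frequencies[k]`` its population frequency.  The implicit residual
    mass ``1 - sum(frequencies)`` never matches any patient.
    """

    haplotypes: tuple[tuple[Allele, ...], ...]
    frequencies: tuple[float, ...]
    population: str = "unlabeled"

    def __post_init__(self) -> None:
        if len(self.haplotypes) != len(self.frequencies):
            raise ValueError("haplotypes and frequencies differ in length")
        for hap in self.haplotypes:
            if len(hap) != len(CORE_LOCI) or any(
                a.locus is not l for a, l in zip(hap, CORE_LOCI)
            ):
                raise ValueError(
                    f"haplotype {'-'.join(a.raw for a in hap)} is not A-B-C-DRB1-DQB1"
                )
        if any(f < 0 for f in self.frequencies):
            raise ValueError("negative haplotype frequency")
        if sum(self.frequencies) > 1 + _SUM_TOL:
            raise ValueError("haplotype frequencies sum to more than 1")
        keys = self.haplotype_keys()
        if len(set(keys)) != len(keys):
            raise ValueError("duplicate haplotypes in table")

    @classmethod
    def from_strings(
        cls,
        rows: Iterable[tuple[Sequence[str], float]],
        population: str = "unlabeled",
    ) -> "HaplotypeFrequencyTable":
        haps = []
        freqs = []
        for alleles, f in rows:
            haps.append(tuple(parse_allele(a) for a in alleles))
            freqs.append(float(f))
        return cls(tuple(haps), tuple(freqs), population)

    @property
    def residual(self) -> float:
        return max(0.0, 1.0 - sum(self.frequencies))

    def haplotype_keys(self) -> tuple[tuple[str, ...], ...]:
        """Per-haplotype tuples of allele match-keys, core-locus order."""
        return tuple(
            tuple(a.match_key for a in hap) for hap in self.haplotypes
        )

    def allele_marginal(self, locus: Locus) -> dict[str, float]:
        """Marginal frequency of each allele at one locus."""
        idx = CORE_LOCI.index(locus)
        out: dict[str, float] = {}
        for hap, f in zip(self.haplotypes, self.frequencies):
            key = hap[idx].match_key
            out[key] = out.get(key, 0.0) + f
        return out

    def conditional_frequency(
        self, given_locus: Locus, given: Allele, target_locus: Locus, target: Allele
    ) -> float:
        """P(target allele | given allele) from the haplotype table."""
        gi = CORE_LOCI.index(given_locus)
        ti = CORE_LOCI.index(target_locus)
        joint = 0.0
        marg = 0.0
        for hap, f in zip(self.haplotypes, self.frequencies):
            if hap[gi].match_key == given.match_key:
                marg += f
                if hap[ti].match_key == target.match_key:
                    joint += f
        return joint / marg if marg > 0 else 0.0

    def __len__(self) -> int:
        return len(self.haplotypes)


@dataclass(frozen=True)
class MatchProbabilityResult:
    """Probability of finding a genotype-identical donor in a registry."""

    p_single: float
    p_registry: float
    category: ProbabilityCategory
    n_donors: int
    availability: float


def _genotype_locus_multisets(genotype: Genotype) -> tuple[frozenset[tuple[str, int]], ...]:
    out = []
    for locus in CORE_LOCI:
        a, b = genotype.pair(locus)
        pair = tuple(sorted((a.match_key, b.match_key)))
        out.append(pair)
    return tuple(out)


def matching_haplotype_pairs(
    genotype: Genotype, table: HaplotypeFrequencyTable
) -> list[tuple[int, int]]:
    """Unordered haplotype index pairs whose allele union reproduces the
    genotype's per-locus allele pairs."""
    genotype.require(CORE_LOCI)
    target = _genotype_locus_multisets(genotype)
    keys = table.haplotype_keys()
    n = len(keys)
    # prefilter: haplotypes whose allele at each locus occurs in the genotype
    candidates = [
        i
        for i in range(n)
        if all(keys[i][l] in target[l] for l in range(len(CORE_LOCI)))
    ]
    pairs = []
    for ii, i in enumerate(candidates):
        for j in candidates[ii:]:
            if all(
                tuple(sorted((keys[i][l], keys[j][l]))) == target[l]
                for l in range(len(CORE_LOCI))
            ):
                pairs.append((i, j))
    return pairs


def genotype_probability(
    genotype: Genotype, table: HaplotypeFrequencyTable
) -> float:
    """HWE probability of the five-locus genotype under the table.

    Sums ``2 f_i f_j`` (``i != j``) or ``f_i**2`` over all unordered
    haplotype pairs reproducing the genotype.  Alleles absent from the
    table, including residual-mass pseudo-haplotypes, contribute zero.
    """
    total = 0.0
    for i, j in matching_haplotype_pairs(genotype, table):
        fi, fj = table.frequencies[i], table.frequencies[j]
        total += fi * fi if i == j else 2.0 * fi * fj
    return total


def donor_match_probability(
    patient: Genotype, table: HaplotypeFrequencyTable
) -> float:
    """Probability a random HWE donor is genotype-identical to the patient
    at the five core loci."""
    return genotype_probability(patient, table)


def mixture_match_probability(
    patient: Genotype,
    tables: Sequence[HaplotypeFrequencyTable],
    weights: Sequence[float],
) -> float:
    """p_single in a mixed-population registry.

    A donor belongs to population ``k`` with probability ``weights[k]``
    and is then an HWE draw from that population's table, so the
    single-donor match probability is the weighted mixture of per-table
    probabilities.
    """
    w = np.asarray(weights, dtype=float)
    if len(w) != len(tables):
        raise ValueError("one weight per table required")
    if np.any(w < 0) or not np.isclose(w.sum(), 1.0):
        raise ValueError("weights must be non-negative and sum to 1")
    return float(
        sum(wk * donor_match_probability(patient, t) for wk, t in zip(w, tables))
    )


def registry_match_probability(
    p_single: float, n_donors: int, availability: float = DEFAULT_AVAILABILITY
) -> float:
    """Probability that at least one of ``n_donors`` independent registry
    donors matches and is available: ``1 - (1 - p_single*availability)**N``."""
    if not 0 <= p_single <= 1 or not 0 <= availability <= 1:
        raise ValueError("probabilities must lie in [0, 1]")
    if n_donors < 0:
        raise ValueError("n_donors must be >= 0")
    return 1.0 - (1.0 - p_single * availability) ** n_donors


def categorize(
    p_registry: float, high_threshold: float = 0.95, low_threshold: float = 0.05
) -> ProbabilityCategory:
    """Classify a registry match probability into the search categories:
    high (>95% chance), intermediate, low (<5%)."""
    if not 0 <= p_registry <= 1:
        raise ValueError("probability outside [0, 1]")
    if p_registry > high_threshold:
        return ProbabilityCategory.high
    if p_registry < low_threshold:
        return ProbabilityCategory.low
    return ProbabilityCategory.intermediate


def estimate_match_probability(
    patient: Genotype,
    tables: Sequence[HaplotypeFrequencyTable],
    n_donors: int,
    availability: float = DEFAULT_AVAILABILITY,
    weights: Sequence[float] | None = None,
    high_threshold: float = 0.95,
    low_threshold: float = 0.05,
) -> MatchProbabilityResult:
    """Full pipeline: p_single (possibly over a population mixture),
    registry-level probability, and category."""
    if weights is None:
        weights = [1.0 / len(tables)] * len(tables)
    p_single = mixture_match_probability(patient, tables, weights)
    p_reg = registry_match_probability(p_single, n_donors, availability)
    return MatchProbabilityResult(
        p_single=p_single,
        p_registry=p_reg,
        category=categorize(p_reg, high_threshold, low_threshold),
        n_donors=n_donors,
        availability=availability,
    )
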