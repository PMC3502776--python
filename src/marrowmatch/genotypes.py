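"""Per-locus HLA typings for patients and donors.

A :class:`Genotype` stores an unordered pair of alleles per typed locus.
A single recorded allele is treated as homozygous for grading but kept
flagged, because registries often omit the second allele when it is
either identical or unresolved.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

from .alleles import (
    CORE_LOCI,
    DRB345_LOCI,
    Allele,
    Locus,
    Resolution,
    parse_allele,
)

__all__ = ["Genotype", "MissingLocusError"]


class MissingLocusError(ValueError):
    """A required locus is absent from a genotype."""


@dataclass(eq=False)
class Genotype:
    """Unordered per-locus allele pairs for one individual.

    ``typings`` maps each typed locus to a tuple of 1 or 2 alleles of
    that locus.  HLA-A, B, C, DRB1 and DQB1 are required for a 10/10
    evaluation; DPB1 and DRB3/4/5 are optional.
    """

    id: str
    typings: Mapping[Locus, tuple[Allele, ...]]

    def __post_init__(self) -> None:
        for locus, alleles in self.typings.items():
            if not 1 <= len(alleles) <= 2:
                raise ValueError(f"{self.id}: locus {locus} holds {len(alleles)} alleles")
            for allele in alleles:
                if allele.locus is not locus:
                    raise ValueError(
                        f"{self.id}: allele {allele.raw} filed under locus {locus}"
                    )

    @classmethod
    def from_strings(
        cls, id: str, typings: Mapping[str, Iterable[str]]
    ) -> "Genotype":
        parsed: dict[Locus, tuple[Allele, ...]] = {}
        for locus_name, texts in typings.items():
            alleles = tuple(parse_allele(t) for t in texts if t)
            if alleles:
                parsed[Locus(locus_name)] = alleles
        return cls(id, parsed)

    # -- accessors --------------------------------------------------------
    @property
    def typed_loci(self) -> frozenset[Locus]:
        return frozenset(self.typings)

    def pair(self, locus: Locus) -> tuple[Allele, Allele]:
        """The allele pair at a locus, duplicating a single recorded allele."""
        alleles = self.typings[locus]
        return (alleles[0], alleles[0]) if len(alleles) == 1 else (alleles[0], alleles[1])

    def is_homozygous_or_unresolved(self, locus: Locus) -> bool:
        alleles = self.typings[locus]
        return len(alleles) == 1 or alleles[0].match_key == alleles[1].match_key

    def require(self, loci: Iterable[Locus]) -> None:
        missing = [l for l in loci if l not in self.typings]
        if missing:
            raise MissingLocusError(
                f"{self.id}: missing required loci {[l.value for l in missing]}"
            )

    def drb345_alleles(self) -> tuple[Allele, ...]:
        """All recorded secondary-DRB (DRB3/4/5) alleles."""
        out: list[Allele] = []
        for locus in DRB345_LOCI:
            out.extend(self.typings.get(locus, ()))
        return tuple(out)

    def has_drb345_typing(self) -> bool:
        return any(l in self.typings for l in DRB345_LOCI)

    def allele_multiset(self, loci: Iterable[Locus] = CORE_LOCI) -> tuple[str, ...]:
        """Sorted match-keys over the given loci (two per locus).

        This is the phase-free representation used for genotype identity:
        a donor with the same alleles in a different haplotype phase is
        the same multilocus genotype.
        """
        keys: list[str] = []
        for locus in loci:
            a, b = self.pair(locus)
            keys.extend(sorted((a.match_key, b.match_key)))
        return tuple(keys)

    def is_high_resolution(self, loci: Iterable[Locus] = CORE_LOCI) -> bool:
        return all(
            all(a.resolution is Resolution.high for a in self.typings[l])
            for l in loci
            if l in self.typings
        )

    def __repr__(self) -> str:  # pragma: no cover
        parts = ", ".join(
            f"{l.value}:{'/'.join(a.render() for a in als)}"
            for l, als in self.typings.items()
        )
        return f"Genotype({self.id}: {parts})"
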