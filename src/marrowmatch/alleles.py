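"""HLA allele nomenclature: parsing, resolution levels, serotype mapping.

HLA typings arrive at three resolution levels that must interoperate:

* **high resolution** — two (or more) colon-delimited numeric fields,
  e.g. ``A*02:151``, resolving the protein-level variant.  Fields beyond
  the second (synonymous / non-coding variation) do not affect matching.
* **allele group** — a single field, e.g. ``DRB1*15``, the set of alleles
  sharing the first field.
* **serologic** — an antibody-defined antigen label, e.g. ``B35``, which
  may span several allele groups and is related to molecular names only
  through a lookup table (:class:`SerotypeMap`).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from enum import Enum, StrEnum
from pathlib import Path
from typing import Iterable, Mapping

__all__ = [
    "Locus",
    "Resolution",
    "Compat",
    "Allele",
    "SerotypeMap",
    "AlleleParseError",
    "parse_allele",
    "alleles_compatible",
]


class Locus(StrEnum):
    A = "A"
    B = "B"
    C = "C"
    DRB1 = "DRB1"
    DRB3 = "DRB3"
    DRB4 = "DRB4"
    DRB5 = "DRB5"
    DQB1 = "DQB1"
    DPB1 = "DPB1"


#: Loci required for a 10/10 evaluation, in canonical order.
CORE_LOCI: tuple[Locus, ...] = (Locus.A, Locus.B, Locus.C, Locus.DRB1, Locus.DQB1)

#: Secondary DRB loci; a disparity here demotes a 10/10 to 9/10.
DRB345_LOCI: tuple[Locus, ...] = (Locus.DRB3, Locus.DRB4, Locus.DRB5)

CLASS_I_LOCI: frozenset[Locus] = frozenset({Locus.A, Locus.B, Locus.C})


class Resolution(Enum):
    serologic = "serologic"
    allele_group = "allele_group"
    high = "high"


class Compat(StrEnum):
    """Outcome of a resolution-aware allele comparison."""

    match = "match"
    mismatch = "mismatch"
    ambiguous = "ambiguous"


class AlleleParseError(ValueError):
    """Raised when an HLA allele or serotype string cannot be parsed."""


# serologic prefixes and the molecular locus they belong to
_SERO_PREFIX = {"A": Locus.A, "B": Locus.B, "CW": Locus.C,
                "DR": Locus.DRB1, "DQ": Locus.DQB1, "DP": Locus.DPB1}
_SERO_CANON = {Locus.A: "A", Locus.B: "B", Locus.C: "Cw",
               Locus.DRB1: "DR", Locus.DQB1: "DQ", Locus.DPB1: "DP"}

_MOLECULAR_RE = re.compile(
    r"^(?P<locus>[A-Z0-9]+)\*(?P<fields>\d{1,4}(?::\d{1,4}){0,3})(?P<suffix>[NLSCAQ])?$"
)
_SEROLOGIC_RE = re.compile(r"^(?P<prefix>A|B|CW|DR|DQ|DP)(?P<num>\d{1,3})$")


@dataclass(frozen=True, slots=True)
class Allele:
    """One HLA allele or serotype.

    ``fields`` is empty for serologic typings, which instead carry the
    numeric serotype in ``serotype_value``.
    """

    locus: Locus
    fields: tuple[int, ...]
    resolution: Resolution
    raw: str
    serotype_value: int | None = None
    suffix: str | None = None

    def __post_init__(self) -> None:
        if self.resolution is Resolution.high and len(self.fields) < 2:
            raise ValueError("high resolution requires >=2 fields")
        if self.resolution is Resolution.allele_group and len(self.fields) != 1:
            raise ValueError("allele group has exactly 1 field")
        if self.resolution is Resolution.serologic and (
            self.fields or self.serotype_value is None
        ):
            raise ValueError("serologic allele carries a serotype token, no fields")

    # -- identity helpers -------------------------------------------------
    @property
    def match_key(self) -> str:
        """Key used for allele identity: locus plus first two fields.

        Fields beyond the second (silent / non-coding variants) are
        deliberately ignored for grading.
        """
        if self.resolution is Resolution.serologic:
            return f"{self.locus.value}#{self.serotype_value}"
        if self.resolution is Resolution.allele_group:
            return f"{self.locus.value}*{self.fields[0]:02d}"
        return f"{self.locus.value}*{self.fields[0]:02d}:{self.fields[1]:02d}"

    @property
    def group_key(self) -> str:
        """Locus plus first field only (allele-group key)."""
        if self.resolution is Resolution.serologic:
            return self.match_key
        return f"{self.locus.value}*{self.fields[0]:02d}"

    def render(self) -> str:
        """Canonical text form; reproduces the input up to case."""
        if self.resolution is Resolution.serologic:
            return f"{_SERO_CANON[self.locus]}{self.serotype_value}"
        body = ":".join(
            f"{f:0{max(2, len(str(f)))}d}" if i < 2 else str(f)
            for i, f in enumerate(self.fields)
        )
        return f"{self.locus.value}*{body}{self.suffix or ''}"

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.render()

    def __lt__(self, other: "Allele") -> bool:
        return (self.locus.value, self.match_key) < (other.locus.value, other.match_key)


def parse_allele(text: str) -> Allele:
    """Parse a WHO-nomenclature allele string or a serotype label.

    Accepts e.g. ``"A*02:151"`` (high resolution), ``"DRB1*15"`` (allele
    group), ``"B35"``/``"Cw7"`` (serologic) and an optional ``HLA-``
    prefix.  Raises :class:`AlleleParseError` naming the offending token.
    """
    if not text or not text.strip():
        raise AlleleParseError("empty allele string")
    cleaned = text.strip().upper()
    if cleaned.startswith("HLA-"):
        cleaned = cleaned[4:]

    if "*" in cleaned:
        m = _MOLECULAR_RE.match(cleaned)
        if not m:
            raise AlleleParseError(f"malformed allele string: {text!r}")
        locus_token = m.group("locus")
        try:
            locus = Locus(locus_token)
        except ValueError:
            raise AlleleParseError(
                f"unknown HLA locus {locus_token!r} in {text!r}"
            ) from None
        fields = tuple(int(f) for f in m.group("fields").split(":"))
        resolution = Resolution.high if len(fields) >= 2 else Resolution.allele_group
        return Allele(locus, fields, resolution, text.strip(), suffix=m.group("suffix"))

    m = _SEROLOGIC_RE.match(cleaned)
    if not m:
        raise AlleleParseError(f"unrecognized serotype or allele: {text!r}")
    locus = _SERO_PREFIX[m.group("prefix")]
    return Allele(
        locus, (), Resolution.serologic, text.strip(),
        serotype_value=int(m.group("num")),
    )


class SerotypeMap:
    """Mapping from molecular alleles / allele groups to serotype labels.

    Entries are keyed by two-field allele (``B*35:02``) or allele group
    (``B*35``); lookup falls back from the two-field key to the group key,
    mirroring how serologic equivalents are tabulated.
    """

    def __init__(self, entries: Mapping[str, str]):
        self._entries: dict[str, Allele] = {}
        for key, label in entries.items():
            key_allele = parse_allele(key)
            sero = parse_allele(label)
            if sero.resolution is not Resolution.serologic:
                raise ValueError(f"serotype label {label!r} is not serologic")
            if sero.locus is not key_allele.locus:
                raise ValueError(
                    f"serotype {label!r} maps allele of different locus {key!r}"
                )
            self._entries[key_allele.match_key] = sero

    @classmethod
    def from_tsv(cls, path: str | Path) -> "SerotypeMap":
        entries: dict[str, str] = {}
        for line in Path(path).read_text().splitlines():
            line = line.strip()
            if not line or line.startswith("#") or line.lower().startswith("allele\t"):
                continue
            allele, label = line.split("\t")[:2]
            entries[allele] = label
        return cls(entries)

    def serotype_of(self, allele: Allele) -> Allele | None:
        """Serotype of a molecular allele, or None if unmapped."""
        if allele.resolution is Resolution.serologic:
            return allele
        hit = self._entries.get(allele.match_key)
        if hit is None and allele.resolution is Resolution.high:
            hit = self._entries.get(allele.group_key)
        return hit

    def alleles_under(self, serotype: Allele) -> list[str]:
        """Match-keys of all mapped alleles carrying the given serotype."""
        return sorted(
            k for k, v in self._entries.items() if v.match_key == serotype.match_key
        )

    def __len__(self) -> int:
        return len(self._entries)

    def __contains__(self, allele: Allele) -> bool:
        return self.serotype_of(allele) is not None


def alleles_compatible(
    a: Allele, b: Allele, serotype_map: SerotypeMap | None = None
) -> Compat:
    """Resolution-aware comparison of two same-locus alleles.

    Two high-resolution alleles match iff their first two fields agree.
    Across resolution levels the result is :attr:`Compat.ambiguous` when
    the lower-resolution value could contain the higher-resolution one
    (e.g. serotype A2 versus A*02:05 under a map sending A*02:05 to A2)
    and :attr:`Compat.mismatch` when it cannot.  Registry typings are
    heterogeneous, so ambiguity is a first-class outcome: it marks donors
    that need confirmatory typing, never a silent match.
    """
    if a.locus is not b.locus:
        raise ValueError(f"locus disagreement: {a.locus} vs {b.locus}")

    ra, rb = a.resolution, b.resolution
    if Resolution.serologic in (ra, rb):
        if ra is Resolution.serologic and rb is Resolution.serologic:
            return (
                Compat.ambiguous
                if a.serotype_value == b.serotype_value
                else Compat.mismatch
            )
        sero, mol = (a, b) if ra is Resolution.serologic else (b, a)
        mapped = serotype_map.serotype_of(mol) if serotype_map else None
        if mapped is None:
            # no mapping available: containment can be neither proven nor
            # excluded, so the donor stays a candidate for confirmatory typing
            return Compat.ambiguous
        return (
            Compat.ambiguous
            if mapped.serotype_value == sero.serotype_value
            else Compat.mismatch
        )

    if a.fields[0] != b.fields[0]:
        return Compat.mismatch
    if ra is Resolution.high and rb is Resolution.high:
        return Compat.match if a.fields[1] == b.fields[1] else Compat.mismatch
    # at least one side is an allele group with the same first field: the
    # underlying alleles may or may not coincide
    return Compat.ambiguous


def parse_alleles(texts: Iterable[str]) -> list[Allele]:
    return [parse_allele(t) for t in texts]
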