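"""Synthetic donor-registry generation.

Donors are Hardy-Weinberg draws from a (possibly mixed-population)
five-locus haplotype frequency table.  Real registries are heterogeneous
in typing resolution, so each donor's internally high-resolution
genotype is degraded to a *reported* genotype according to a resolution
profile (full high resolution, class-I low resolution, or
serologic-only), and donors are unavailable with a configurable rate.

Residual table mass (haplotypes outside the catalogue) is realised as
per-draw sentinel haplotypes with private ``*00:<id>`` alleles, so a
residual donor can never grade as matched against any patient while
generation stays bit-reproducible from the seed.

Secondary-DRB loci are not part of the five-locus haplotypes; they are
assigned from the DRB1 allele group through the well-known DRB3/4/5
linkage (DR3/11/12/13/14 carry DRB3, DR4/7/9 carry DRB4, DR15/16 carry
DRB5).  DPB1 recombines freely enough from the class II block that it is
sampled independently from a separate allele-frequency list.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .alleles import (
    CLASS_I_LOCI,
    CORE_LOCI,
    Allele,
    Locus,
    Resolution,
    SerotypeMap,
    parse_allele,
)
from .frequencies import HaplotypeFrequencyTable
from .genotypes import Genotype

__all__ = [
    "RESOLUTION_PROFILES",
    "DonorRecord",
    "RegistryConfig",
    "generate_registry",
    "sample_patient_genotypes",
    "degrade_typing",
    "sample_availability",
]

RESOLUTION_PROFILES = ("high", "class1_low", "serologic")

#: Default registry composition over resolution profiles.  The real
#: worldwide-registry composition is not published; these fractions are
#: configuration placeholders.
DEFAULT_RESOLUTION_DISTRIBUTION: dict[str, float] = {
    "high": 0.5,
    "class1_low": 0.3,
    "serologic": 0.2,
}

#: DRB1 allele group -> (secondary DRB locus, alleles with sampling weights).
#: DR1/8/10 haplotypes carry no secondary DRB gene.  DRB1*13 haplotypes
#: split between DRB3*01:01 and DRB3*02:02, the constellation behind the
#: DRB3-mismatch risk that search algorithms type for explicitly.
DRB345_LINKAGE: dict[int, tuple[Locus, tuple[tuple[str, float], ...]]] = {
    3: (Locus.DRB3, (("DRB3*01:01", 1.0),)),
    11: (Locus.DRB3, (("DRB3*02:02", 1.0),)),
    12: (Locus.DRB3, (("DRB3*02:02", 1.0),)),
    13: (Locus.DRB3, (("DRB3*01:01", 0.8), ("DRB3*02:02", 0.2))),
    14: (Locus.DRB3, (("DRB3*02:02", 1.0),)),
    4: (Locus.DRB4, (("DRB4*01:03", 1.0),)),
    7: (Locus.DRB4, (("DRB4*01:01", 1.0),)),
    9: (Locus.DRB4, (("DRB4*01:03", 1.0),)),
    15: (Locus.DRB5, (("DRB5*01:01", 1.0),)),
    16: (Locus.DRB5, (("DRB5*02:02", 1.0),)),
}


@dataclass
class DonorRecord:
    """One registry donor: true genotype, reported (possibly degraded)
    genotype, per-locus resolution profile, availability flag."""

    id: str
    true_genotype: Genotype
    reported_genotype: Genotype
    resolution_profile: str
    available: bool
    registry_label: str = "SYNTH"
    unmappable: tuple[str, ...] = ()


@dataclass
class RegistryConfig:
    n_donors: int
    population_mix: Sequence[tuple[HaplotypeFrequencyTable, float]]
    resolution_distribution: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_RESOLUTION_DISTRIBUTION)
    )
    unavailability_rate: float = 0.25
    seed: int = 0
    dpb1_frequencies: Sequence[tuple[str, float]] | None = None
    registry_label: str = "SYNTH"

    def __post_init__(self) -> None:
        if self.n_donors < 0:
            raise ValueError("n_donors must be >= 0")
        weights = [w for _, w in self.population_mix]
        if weights and not np.isclose(sum(weights), 1.0):
            raise ValueError("population weights must sum to 1")
        res = dict(self.resolution_distribution)
        if set(res) - set(RESOLUTION_PROFILES):
            raise ValueError(f"unknown resolution profiles: {set(res) - set(RESOLUTION_PROFILES)}")
        if not np.isclose(sum(res.values()), 1.0):
            raise ValueError("resolution fractions must sum to 1")
        if not 0 <= self.unavailability_rate <= 1:
            raise ValueError("unavailability_rate must lie in [0, 1]")


def sample_availability(rate: float, rng: np.random.Generator) -> bool:
    """One availability draw: True with probability ``1 - rate``."""
    if not 0 <= rate <= 1:
        raise ValueError("rate must lie in [0, 1]")
    return bool(rng.random() >= rate)


# -- haplotype sampling ---------------------------------------------------

def _sentinel_haplotype(rng: np.random.Generator) -> tuple[Allele, ...]:
    """A residual-mass haplotype: private alleles that match nothing.

    The first field starts at 100, far above any real allele group, so a
    sentinel can never collide with catalogue alleles; the ~1e8 key space
    makes accidental sentinel-sentinel identity across patients and
    donors negligible while keeping draws seed-reproducible.
    """
    f1 = int(rng.integers(100, 10_000))
    f2 = int(rng.integers(0, 10_000))
    return tuple(
        Allele(locus, (f1, f2), Resolution.high, f"{locus.value}*{f1}:{f2:04d}")
        for locus in CORE_LOCI
    )


def _draw_haplotypes(
    tables: Sequence[HaplotypeFrequencyTable],
    weights: Sequence[float],
    n_draws: int,
    rng: np.random.Generator,
) -> list[tuple[Allele, ...]]:
    pop_idx = rng.choice(len(tables), size=n_draws, p=np.asarray(weights))
    # per-table categorical over explicit haplotypes + residual sentinel slot
    draws: list[tuple[Allele, ...]] = []
    probs = []
    for t in tables:
        p = np.array([*t.frequencies, t.residual], dtype=float)
        probs.append(p / p.sum())
    for k in pop_idx:
        t = tables[k]
        h = int(rng.choice(len(t.haplotypes) + 1, p=probs[k]))
        if h == len(t.haplotypes):
            draws.append(_sentinel_haplotype(rng))
        else:
            draws.append(t.haplotypes[h])
    return draws


def _drb345_for(drb1: Allele, rng: np.random.Generator) -> tuple[Locus, Allele] | None:
    entry = DRB345_LINKAGE.get(drb1.fields[0] if drb1.fields else -1)
    if entry is None:
        return None
    locus, choices = entry
    texts = [t for t, _ in choices]
    w = np.array([p for _, p in choices])
    pick = texts[int(rng.choice(len(texts), p=w / w.sum()))]
    return locus, parse_allele(pick)


def _assemble_genotype(
    gid: str,
    hap_a: tuple[Allele, ...],
    hap_b: tuple[Allele, ...],
    rng: np.random.Generator,
    dpb1_alleles: Sequence[Allele] | None,
    dpb1_probs: np.ndarray | None,
) -> Genotype:
    typings: dict[Locus, tuple[Allele, ...]] = {
        locus: (hap_a[i], hap_b[i]) for i, locus in enumerate(CORE_LOCI)
    }
    drb345: dict[Locus, list[Allele]] = {}
    for hap in (hap_a, hap_b):
        linked = _drb345_for(hap[CORE_LOCI.index(Locus.DRB1)], rng)
        if linked is not None:
            drb345.setdefault(linked[0], []).append(linked[1])
    for locus, alleles in drb345.items():
        typings[locus] = tuple(alleles)
    if dpb1_alleles is not None:
        i, j = rng.choice(len(dpb1_alleles), size=2, p=dpb1_probs)
        typings[Locus.DPB1] = (dpb1_alleles[int(i)], dpb1_alleles[int(j)])
    return Genotype(gid, typings)


def degrade_typing(
    genotype: Genotype, profile: str, serotype_map: SerotypeMap
) -> tuple[Genotype, tuple[str, ...]]:
    """Degrade a high-resolution genotype to a reported typing.

    ``high`` is the identity.  ``class1_low`` maps class I alleles
    through the serotype map and truncates class II to allele groups.
    ``serologic`` does the same but also drops DPB1 (serologic-era
    registrations rarely carry it).  Class I alleles missing from the
    serotype map are kept at allele-group resolution and returned in the
    unmappable list — never silently dropped.
    """
    if profile not in RESOLUTION_PROFILES:
        raise ValueError(f"unknown resolution profile {profile!r}")
    if profile == "high":
        return genotype, ()

    unmappable: list[str] = []
    typings: dict[Locus, tuple[Allele, ...]] = {}
    for locus, alleles in genotype.typings.items():
        if locus is Locus.DPB1 and profile == "serologic":
            continue
        degraded: list[Allele] = []
        for allele in alleles:
            if allele.resolution is not Resolution.high:
                degraded.append(allele)
                continue
            if locus in CLASS_I_LOCI:
                sero = serotype_map.serotype_of(allele)
                if sero is not None:
                    degraded.append(sero)
                    continue
                unmappable.append(allele.match_key)
            degraded.append(
                Allele(locus, allele.fields[:1], Resolution.allele_group,
                       allele.group_key)
            )
        typings[locus] = tuple(degraded)
    return Genotype(genotype.id, typings), tuple(unmappable)


def _load_dpb1(
    dpb1_frequencies: Sequence[tuple[str, float]] | None,
) -> tuple[list[Allele] | None, np.ndarray | None]:
    if dpb1_frequencies is None:
        return None, None
    alleles = [parse_allele(t) for t, _ in dpb1_frequencies]
    p = np.array([f for _, f in dpb1_frequencies], dtype=float)
    return alleles, p / p.sum()


def generate_registry(
    config: RegistryConfig, serotype_map: SerotypeMap
) -> list[DonorRecord]:
    """Generate a synthetic registry, fully reproducible from the seed."""
    rng = np.random.default_rng(config.seed)
    tables = [t for t, _ in config.population_mix]
    weights = [w for _, w in config.population_mix]
    dpb1_alleles, dpb1_probs = _load_dpb1(config.dpb1_frequencies)

    haps = _draw_haplotypes(tables, weights, 2 * config.n_donors, rng)
    res_names = sorted(config.resolution_distribution)
    res_p = np.array([config.resolution_distribution[k] for k in res_names])
    donors: list[DonorRecord] = []
    for i in range(config.n_donors):
        gid = f"D{i:06d}"
        true = _assemble_genotype(
            gid, haps[2 * i], haps[2 * i + 1], rng, dpb1_alleles, dpb1_probs
        )
        profile = res_names[int(rng.choice(len(res_names), p=res_p))]
        reported, unmappable = degrade_typing(true, profile, serotype_map)
        donors.append(
            DonorRecord(
                id=gid,
                true_genotype=true,
                reported_genotype=reported,
                resolution_profile=profile,
                available=sample_availability(config.unavailability_rate, rng),
                registry_label=config.registry_label,
                unmappable=unmappable,
            )
        )
    return donors


def sample_patient_genotypes(
    tables: Sequence[HaplotypeFrequencyTable],
    weights: Sequence[float],
    n: int,
    rng: np.random.Generator,
    dpb1_frequencies: Sequence[tuple[str, float]] | None = None,
    id_prefix: str = "P",
) -> list[Genotype]:
    """HWE patient draws from the same haplotype distribution as donors
    (residual draws yield unique phenotypes outside the catalogue)."""
    dpb1_alleles, dpb1_probs = _load_dpb1(dpb1_frequencies)
    haps = _draw_haplotypes(tables, weights, 2 * n, rng)
    return [
        _assemble_genotype(
            f"{id_prefix}{i:04d}", haps[2 * i], haps[2 * i + 1], rng,
            dpb1_alleles, dpb1_probs,
        )
        for i in range(n)
    ]
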