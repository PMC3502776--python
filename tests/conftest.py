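from __future__ import annotations

import numpy as np
import pytest

from marrowmatch import Genotype, HaplotypeFrequencyTable, parse_allele
from marrowmatch.alleles import CORE_LOCI, Locus
from marrowmatch import datasets


@pytest.fixture(scope="session")
def serotype_map():
    return datasets.load_serotype_map()


@pytest.fixture(scope="session")
def demo_table():
    return datasets.load_demo_frequency_table()


@pytest.fixture(scope="session")
def dpb1_frequencies():
    return datasets.load_dpb1_frequencies()


@pytest.fixture(scope="session")
def tce_table():
    return datasets.load_tce_groups()


def make_genotype(
    gid: str,
    hap_a: tuple[str, ...],
    hap_b: tuple[str, ...],
    dpb1: tuple[str, str] | None = None,
    drb345: tuple[str, ...] = (),
) -> Genotype:
    """Build a genotype from two five-allele (A,B,C,DRB1,DQB1) haplotypes."""
    typings: dict[Locus, tuple] = {}
    for locus, a, b in zip(CORE_LOCI, hap_a, hap_b):
        typings[locus] = (parse_allele(a), parse_allele(b))
    if dpb1 is not None:
        typings[Locus.DPB1] = tuple(parse_allele(t) for t in dpb1)
    for text in drb345:
        allele = parse_allele(text)
        typings.setdefault(allele.locus, ())
        typings[allele.locus] = typings[allele.locus] + (allele,)
    return Genotype(gid, typings)


#: Two equifrequent haplotypes: the smallest HWE playground.
@pytest.fixture()
def two_hap_table() -> HaplotypeFrequencyTable:
    return HaplotypeFrequencyTable.from_strings(
        [
            (("A*01:01", "B*08:01", "C*07:01", "DRB1*03:01", "DQB1*02:01"), 0.5),
            (("A*02:01", "B*07:02", "C*07:02", "DRB1*15:01", "DQB1*06:02"), 0.5),
        ],
        population="toy",
    )


HAP1 = ("A*01:01", "B*08:01", "C*07:01", "DRB1*03:01", "DQB1*02:01")
HAP2 = ("A*02:01", "B*07:02", "C*07:02", "DRB1*15:01", "DQB1*06:02")
HAP3 = ("A*03:01", "B*35:01", "C*04:01", "DRB1*01:01", "DQB1*05:01")


def bruteforce_genotype_probability(patient: Genotype, table) -> float:
    """Independent oracle: enumerate all ordered haplotype pairs, build the
    resulting phase-free genotype, and accumulate f_i * f_j on equality."""
    target = patient.allele_multiset()
    keys = table.haplotype_keys()
    total = 0.0
    for hi, fi in zip(keys, table.frequencies):
        for hj, fj in zip(keys, table.frequencies):
            flat: list[str] = []
            for l in range(len(CORE_LOCI)):
                flat.extend(sorted((hi[l], hj[l])))
            if tuple(flat) == target:
                total += fi * fj
    return total


def random_table_and_patient(rng: np.random.Generator):
    """A random frequency table of <=6 haplotypes over a small allele pool
    plus a patient drawn from it (used for oracle-equivalence checks)."""
    pool = {
        "A": ["A*01:01", "A*02:01", "A*03:01"],
        "B": ["B*07:02", "B*08:01"],
        "C": ["C*07:01", "C*07:02"],
        "DRB1": ["DRB1*03:01", "DRB1*15:01"],
        "DQB1": ["DQB1*02:01", "DQB1*06:02"],
    }
    n_hap = int(rng.integers(1, 7))
    haps: set[tuple[str, ...]] = set()
    while len(haps) < n_hap:
        haps.add(tuple(pool[l][rng.integers(len(pool[l]))] for l in pool))
    hap_list = sorted(haps)
    raw = rng.random(len(hap_list))
    freqs = raw / raw.sum() * rng.uniform(0.3, 1.0)
    table = HaplotypeFrequencyTable.from_strings(
        list(zip(hap_list, freqs)), population="rand"
    )
    i, j = rng.integers(len(hap_list), size=2)
    patient = make_genotype("pt", hap_list[i], hap_list[j])
    return table, patient
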