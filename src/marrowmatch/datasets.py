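"""Packaged reference and fixture data.

* ``serotype_map`` — editable class I/II allele -> serotype table covering
  the alleles used elsewhere in the package; users may extend it.
* ``conserved_haplotypes`` — catalogue of conserved extended haplotypes
  known to carry otherwise-rare class I alleles (whitelist for the
  rare-allele warning rule).
* ``tce_groups`` — demo DPB1 T-cell-epitope (TCE3) group table.
* ``dpb1_frequencies`` — European-like DPB1 allele frequencies for the
  registry generator.
* ``demo_haplotype_frequencies`` — synthetic but European-like five-locus
  haplotype frequency table (the probability-engine substrate).
* cohort margin fixtures — published aggregate outcomes of a consecutive
  unrelated-donor search cohort (matching grades and time frames per
  probability category) and of a prospective DPB1-typing series; margins
  only, per-patient rows were never published.
"""

from __future__ import annotations

from importlib import resources
from pathlib import Path

import pandas as pd

from .alleles import SerotypeMap
from .frequencies import HaplotypeFrequencyTable
from .io import read_frequency_tables

__all__ = [
    "data_path",
    "load_serotype_map",
    "load_conserved_haplotypes",
    "load_tce_groups",
    "load_dpb1_frequencies",
    "load_demo_frequency_table",
    "load_cohort_matching_margins",
    "load_cohort_time_margins",
    "load_dpb1_prospective_margins",
    "FIXTURE_FILES",
]

FIXTURE_FILES = (
    "serotype_map.tsv",
    "conserved_haplotypes.tsv",
    "tce_groups.tsv",
    "dpb1_frequencies.tsv",
    "demo_haplotype_frequencies.tsv",
    "cohort_matching_margins.tsv",
    "cohort_time_margins.tsv",
    "dpb1_prospective_margins.tsv",
)


def data_path(name: str) -> Path:
    return Path(str(resources.files("marrowmatch").joinpath("data", name)))


def load_serotype_map() -> SerotypeMap:
    return SerotypeMap.from_tsv(data_path("serotype_map.tsv"))


def load_conserved_haplotypes() -> tuple[tuple[str, ...], ...]:
    """Whitelisted conserved haplotypes as (A, B, C, DRB1) string tuples."""
    df = pd.read_csv(data_path("conserved_haplotypes.tsv"), sep="\t")
    return tuple(
        (r["A"], r["B"], r["C"], r["DRB1"]) for _, r in df.iterrows()
    )


def load_tce_groups() -> dict[str, int]:
    from .alleles import parse_allele

    df = pd.read_csv(data_path("tce_groups.tsv"), sep="\t")
    return {
        parse_allele(r["allele"]).match_key: int(r["group"])
        for _, r in df.iterrows()
    }


def load_dpb1_frequencies() -> tuple[tuple[str, float], ...]:
    df = pd.read_csv(data_path("dpb1_frequencies.tsv"), sep="\t")
    return tuple((r["allele"], float(r["frequency"])) for _, r in df.iterrows())


def load_demo_frequency_table() -> HaplotypeFrequencyTable:
    return read_frequency_tables(data_path("demo_haplotype_frequencies.tsv"))["EUR"]


def load_cohort_matching_margins() -> list[dict]:
    df = pd.read_csv(data_path("cohort_matching_margins.tsv"), sep="\t")
    return df.to_dict(orient="records")


def load_cohort_time_margins() -> list[dict]:
    df = pd.read_csv(data_path("cohort_time_margins.tsv"), sep="\t")
    return df.to_dict(orient="records")


def load_dpb1_prospective_margins() -> dict:
    df = pd.read_csv(data_path("dpb1_prospective_margins.tsv"), sep="\t")
    return df.iloc[0].to_dict()
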