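"""Readers and writers for the package's delimited-text formats.

All formats are plain TSV (or YAML/JSON for configuration and reports)
so that fixtures and results stay inspectable.  Every writer's output is
accepted by its reader.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Any, Iterable, Sequence

import pandas as pd
import yaml
from pydantic import BaseModel, Field

from .alleles import CORE_LOCI, Locus, parse_allele
from .frequencies import HaplotypeFrequencyTable
from .genotypes import Genotype
from .registry import DonorRecord
from .reporting import OutcomeRecord
from .search import SearchPolicy

__all__ = [
    "read_typings",
    "write_typings",
    "read_frequency_tables",
    "write_frequency_table",
    "read_registry",
    "write_registry",
    "read_policy",
    "write_policy",
    "read_outcome_records",
    "write_outcome_records",
    "SearchReport",
    "write_report",
    "read_report",
]

_TYPING_COLUMNS = [
    "id",
    "A_1", "A_2", "B_1", "B_2", "C_1", "C_2",
    "DRB1_1", "DRB1_2", "DRB345_1", "DRB345_2",
    "DQB1_1", "DQB1_2", "DPB1_1", "DPB1_2",
]


def _genotype_from_row(row: pd.Series) -> Genotype:
    typings: dict[Locus, list] = {}
    for col in _TYPING_COLUMNS[1:]:
        value = row.get(col)
        if value is None or (isinstance(value, float) and pd.isna(value)) or value == "":
            continue
        allele = parse_allele(str(value))
        typings.setdefault(allele.locus, []).append(allele)
    return Genotype(str(row["id"]), {l: tuple(a) for l, a in typings.items()})


def _genotype_to_row(genotype: Genotype) -> dict[str, str]:
    row = {c: "" for c in _TYPING_COLUMNS}
    row["id"] = genotype.id
    for locus, alleles in genotype.typings.items():
        if locus.value in ("DRB3", "DRB4", "DRB5"):
            prefix = "DRB345"
        else:
            prefix = locus.value
        for allele in alleles:
            for slot in (1, 2):
                col = f"{prefix}_{slot}"
                if row[col] == "":
                    row[col] = allele.render()
                    break
    return row


def read_typings(path: str | Path) -> list[Genotype]:
    """Read patient/donor typings from TSV; empty cells mean untyped."""
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    if "id" not in df.columns:
        raise ValueError(f"{path}: typing file lacks an 'id' column")
    return [_genotype_from_row(row) for _, row in df.iterrows()]


def write_typings(genotypes: Iterable[Genotype], path: str | Path) -> None:
    df = pd.DataFrame([_genotype_to_row(g) for g in genotypes], columns=_TYPING_COLUMNS)
    df.to_csv(path, sep="\t", index=False)


def read_frequency_tables(path: str | Path) -> dict[str, HaplotypeFrequencyTable]:
    """Read five-locus haplotype frequencies, one table per population.

    Columns: A, B, C, DRB1, DQB1, frequency, population.
    """
    df = pd.read_csv(path, sep="\t", dtype={"population": str})
    tables: dict[str, HaplotypeFrequencyTable] = {}
    for pop, sub in df.groupby("population", sort=True):
        rows = [
            (tuple(str(r[l.value]) for l in CORE_LOCI), float(r["frequency"]))
            for _, r in sub.iterrows()
        ]
        tables[str(pop)] = HaplotypeFrequencyTable.from_strings(rows, population=str(pop))
    return tables


def write_frequency_table(table: HaplotypeFrequencyTable, path: str | Path) -> None:
    records = [
        {
            **{l.value: a.render() for l, a in zip(CORE_LOCI, hap)},
            "frequency": f,
            "population": table.population,
        }
        for hap, f in zip(table.haplotypes, table.frequencies)
    ]
    pd.DataFrame(records).to_csv(path, sep="\t", index=False)


def write_registry(donors: Sequence[DonorRecord], path: str | Path) -> None:
    """Registry snapshot: reported typings plus resolution and label."""
    rows = []
    for d in donors:
        row = _genotype_to_row(d.reported_genotype)
        row["resolution"] = d.resolution_profile
        row["registry_label"] = d.registry_label
        row["available"] = str(int(d.available))
        rows.append(row)
    cols = _TYPING_COLUMNS + ["resolution", "registry_label", "available"]
    pd.DataFrame(rows, columns=cols).to_csv(path, sep="\t", index=False)


def read_registry(path: str | Path) -> list[DonorRecord]:
    """Read a registry snapshot.

    Only reported typings are stored in snapshots; the reported genotype
    also serves as the best available stand-in for the true genotype
    when a snapshot is used directly for simulation.
    """
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    donors = []
    for _, row in df.iterrows():
        genotype = _genotype_from_row(row)
        donors.append(
            DonorRecord(
                id=genotype.id,
                true_genotype=genotype,
                reported_genotype=genotype,
                resolution_profile=row.get("resolution", "high") or "high",
                available=bool(int(row.get("available", "1") or "1")),
                registry_label=row.get("registry_label", "") or "",
            )
        )
    return donors


def read_policy(path: str | Path) -> SearchPolicy:
    raw = yaml.safe_load(Path(path).read_text()) or {}
    for key in ("batch_size_high", "batch_size_other"):
        if key in raw:
            raw[key] = tuple(raw[key])
    return SearchPolicy(**raw)


def write_policy(policy: SearchPolicy, path: str | Path) -> None:
    data = {
        "batch_size_high": list(policy.batch_size_high),
        "batch_size_other": list(policy.batch_size_other),
        "urgent": policy.urgent,
        "dpb1_branch_enabled": policy.dpb1_branch_enabled,
        "max_rounds": policy.max_rounds,
        "step_durations": dict(policy.step_durations),
        "unavailability_rate": policy.unavailability_rate,
    }
    Path(path).write_text(yaml.safe_dump(data, sort_keys=False))


def read_outcome_records(path: str | Path) -> list[OutcomeRecord]:
    df = pd.read_csv(path, sep="\t")
    records = []
    for _, row in df.iterrows():
        days = row.get("days_to_identification")
        records.append(
            OutcomeRecord(
                category=str(row["category"]),
                grade=str(row["grade"]),
                donors_tested=int(row["donors_tested"]),
                days_to_identification=None if pd.isna(days) else int(days),
            )
        )
    return records


def write_outcome_records(records: Sequence[OutcomeRecord], path: str | Path) -> None:
    pd.DataFrame(
        [
            {
                "category": r.category,
                "grade": r.grade,
                "donors_tested": r.donors_tested,
                "days_to_identification": r.days_to_identification,
            }
            for r in records
        ]
    ).to_csv(path, sep="\t", index=False)


class OutcomeModel(BaseModel):
    case_id: str
    category: str
    best_grade: str
    dpb1_status: str
    donors_tested: int
    days_to_identification: int
    terminated_reason: str
    best_donor_id: str | None = None
    backup_donor_id: str | None = None


class SearchReport(BaseModel):
    """Schema-validated simulation report; all randomness parameters are
    echoed for reproducibility."""

    seed: int
    registry_size: int
    policy: dict[str, Any]
    config: dict[str, Any] = Field(default_factory=dict)
    outcomes: list[OutcomeModel]


def write_report(report: SearchReport, path: str | Path) -> None:
    Path(path).write_text(report.model_dump_json(indent=2))


def read_report(path: str | Path) -> SearchReport:
    return SearchReport.model_validate_json(Path(path).read_text())
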