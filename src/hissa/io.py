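"""File-format plumbing: FASTQ input, TSV serialization of tables."""

from __future__ import annotations

import gzip
from typing import Iterator

import pandas as pd
from Bio import SeqIO

from .dedup import CountTable, MoleculeTable, RemovalReport
from .design import ParseReport, ParsedRead


def read_fastq(path) -> Iterator[tuple[str, str]]:
    """Yield ``(read_id, sequence)`` from a plain or gzip FASTQ file."""
    path = str(path)
    handle = gzip.open(path, "rt") if path.endswith(".gz") else open(path)
    try:
        for record in SeqIO.parse(handle, "fastq"):
            yield record.id, str(record.seq)
    finally:
        handle.close()


def write_parsed_reads(parsed: list[ParsedRead], path) -> None:
    pd.DataFrame(
        {
            "read_id": [r.read_id for r in parsed],
            "umi": [r.umi for r in parsed],
            "linker_random": [r.linker_random for r in parsed],
            "variable_region": [r.variable_region for r in parsed],
            "insert": [r.insert for r in parsed],
        }
    ).to_csv(path, sep="\t", index=False)


def read_parsed_reads(path) -> list[ParsedRead]:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    return [
        ParsedRead(row.read_id, row.umi, row.linker_random,
                   row.variable_region, row.insert)
        for row in df.itertuples()
    ]


def write_parse_report(report: ParseReport, path) -> None:
    pd.DataFrame([report.as_dict()]).to_csv(path, sep="\t", index=False)


def write_molecule_table(table: MoleculeTable, path) -> None:
    rows = [
        {"umi": umi, "sequence": var, "count": count}
        for (umi, var), count in sorted(table.entries.items())
    ]
    pd.DataFrame(rows, columns=["umi", "sequence", "count"]).to_csv(
        path, sep="\t", index=False
    )


def read_molecule_table(path, design_id: str = "") -> MoleculeTable:
    df = pd.read_csv(path, sep="\t", dtype={"umi": str, "sequence": str},
                     keep_default_na=False)
    return MoleculeTable(
        {(row.umi, row.sequence): int(row.count) for row in df.itertuples()},
        design_id,
    )


def write_count_table(table: CountTable, path) -> None:
    rows = sorted(table.counts.items())
    pd.DataFrame(rows, columns=["sequence", "count"]).to_csv(
        path, sep="\t", index=False
    )


def read_count_table(path, library_label: str = "") -> CountTable:
    df = pd.read_csv(path, sep="\t", dtype={"sequence": str}, keep_default_na=False)
    return CountTable(
        {row.sequence: int(row.count) for row in df.itertuples()}, library_label
    )


def write_removal_report(report: RemovalReport, path) -> None:
    rows = [
        {"kind": kind, "sequence": seq, "count": count}
        for kind, removed in (("endogenous", report.endogenous),
                              ("cross_design", report.cross_design))
        for seq, count in sorted(removed.items())
    ]
    pd.DataFrame(rows, columns=["kind", "sequence", "count"]).to_csv(
        path, sep="\t", index=False
    )
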