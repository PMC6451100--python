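"""UMI-based PCR-duplicate collapsing and iterative error elimination.

Deduplication proceeds in three conceptual steps:

1. **Exact collapse** — reads sharing the same (UMI, variable-region)
   combination are counted as a single cDNA molecule; the pre-collapse read
   counts feed the duplication statistics.
2. **Iterative error elimination** — within each UMI group, sequences within
   a small Hamming radius of the most abundant sequence are treated as
   PCR/sequencing error derivatives of that sequence and absorbed into it;
   this repeats until every surviving pair in the group differs by more than
   the elimination radius.  The same procedure is then applied in the other
   dimension (UMI sequences grouped by identical variable region) to catch
   errors inside the UMI itself.
3. **Contamination removal** — molecules matching endogenous copies of the
   constant-region hairpin loop (within a small mismatch budget) or
   structurally matching a different library design are discarded.

The final :class:`CountTable` maps each variable-region sequence to the
number of distinct molecules observed and is the substrate of every
enrichment statistic downstream.
"""

from __future__ import annotations

from collections import Counter, defaultdict
from dataclasses import dataclass, field
from typing import Iterable, Literal, Mapping

from .design import ParsedRead, OligoDesign, normalize_sequence


class DedupError(ValueError):
    pass


def hamming(a: str, b: str) -> int:
    """Hamming distance between equal-length strings."""
    if len(a) != len(b):
        raise DedupError(
            f"Hamming distance undefined for unequal lengths ({len(a)} vs {len(b)})"
        )
    return sum(x != y for x, y in zip(a, b))


@dataclass
class MoleculeTable:
    """Molecule counts keyed by (UMI, variable region)."""

    entries: dict[tuple[str, str], int]
    design_id: str = ""

    @property
    def n_molecules(self) -> int:
        return len(self.entries)

    @property
    def total_reads(self) -> int:
        return sum(self.entries.values())


@dataclass
class DuplicationStats:
    """Read-duplication accounting from exact UMI+insert collapsing.

    ``fraction_amplified`` is the proportion of *reads* that belong to
    molecules observed more than once — the per-library quantity one stacks
    to see how much of a library is PCR amplification.
    """

    fraction_amplified: float
    amplification_distribution: Counter
    mean_amplification: float
    total_reads: int
    total_molecules: int


@dataclass
class CountTable:
    """Deduplicated variable-region counts for one library."""

    counts: dict[str, int]
    library_label: str = ""

    @property
    def total_molecules(self) -> int:
        return sum(self.counts.values())

    @property
    def variable_length(self) -> int:
        if not self.counts:
            raise DedupError("empty count table has no variable length")
        lengths = {len(s) for s in self.counts}
        if len(lengths) != 1:
            raise DedupError(f"heterogeneous sequence lengths: {sorted(lengths)}")
        return next(iter(lengths))

    @classmethod
    def from_sequences(cls, sequences: Iterable[str], library_label: str = "") -> "CountTable":
        return cls(dict(Counter(normalize_sequence(s) for s in sequences)), library_label)

    @classmethod
    def from_counts(cls, counts: Mapping[str, int], library_label: str = "") -> "CountTable":
        return cls({normalize_sequence(k): int(v) for k, v in counts.items()}, library_label)


def collapse_exact(
    parsed: Iterable[ParsedRead], design_id: str = ""
) -> tuple[MoleculeTable, DuplicationStats]:
    """Collapse reads with identical (UMI, variable-region) into molecules.

    Duplication statistics are computed from the pre-collapse read counts:
    every entry with more than one read is an amplified molecule.
    """
    entries: dict[tuple[str, str], int] = {}
    for read in parsed:
        key = (read.umi, read.variable_region)
        entries[key] = entries.get(key, 0) + 1
    total_reads = sum(entries.values())
    amplified = {k: c for k, c in entries.items() if c > 1}
    amp_reads = sum(amplified.values())
    stats = DuplicationStats(
        fraction_amplified=(amp_reads / total_reads) if total_reads else 0.0,
        amplification_distribution=Counter(amplified.values()),
        mean_amplification=(amp_reads / len(amplified)) if amplified else 0.0,
        total_reads=total_reads,
        total_molecules=len(entries),
    )
    return MoleculeTable(entries, design_id), stats


def _collapse_group(
    group: dict[str, int], elimination_radius: int, drop_absorbed: bool
) -> dict[str, int]:
    """Iterative error elimination within one group of equal-length sequences.

    Repeatedly select the highest-count sequence (ties: lexicographically
    smallest) as the group representative, absorb every other sequence within
    ``elimination_radius`` Hamming mismatches of it, set the representative
    aside, and continue on the remainder.  The output satisfies pairwise
    distinctness: every surviving pair differs by more than the radius.
    """
    remaining = dict(group)
    out: dict[str, int] = {}
    while remaining:
        rep = min(remaining, key=lambda s: (-remaining[s], s))
        rep_count = remaining.pop(rep)
        absorbed = [s for s in remaining if hamming(s, rep) <= elimination_radius]
        for s in absorbed:
            if not drop_absorbed:
                rep_count += remaining[s]
            del remaining[s]
        out[rep] = rep_count
    return out


def error_collapse(
    table: MoleculeTable,
    group_by: Literal["umi", "insert"],
    search_radius: int = 2,
    elimination_radius: int = 4,
    drop_absorbed: bool = False,
) -> MoleculeTable:
    """Eliminate PCR/sequencing-error derivative sequences within groups.

    Parameters
    ----------
    group_by
        ``"umi"`` collapses variable-region sequences within groups sharing a
        UMI; ``"insert"`` collapses UMI sequences within groups sharing a
        variable region.
    search_radius
        Radius used to pre-cluster similar sequences before elimination.
        Retained for interface parity; it cannot change the final result
        (any sequence within the elimination radius of a representative is
        absorbed regardless of pre-clustering), so the implementation
        guarantees the documented post-condition directly.
    elimination_radius
        Sequences within this many mismatches of the group representative
        are absorbed; iteration continues until all surviving sequences in a
        group differ pairwise by more than this radius.
    drop_absorbed
        When True, absorbed read counts are discarded (literal elimination);
        by default they are added to the representative so that total read
        counts are conserved.
    """
    if group_by not in ("umi", "insert"):
        raise DedupError(f"group_by must be 'umi' or 'insert', got {group_by!r}")
    del search_radius  # see docstring

    groups: dict[str, dict[str, int]] = defaultdict(dict)
    for (umi, var), count in table.entries.items():
        if group_by == "umi":
            groups[umi][var] = groups[umi].get(var, 0) + count
        else:
            groups[var][umi] = groups[var].get(umi, 0) + count

    entries: dict[tuple[str, str], int] = {}
    for key, group in groups.items():
        collapsed = _collapse_group(group, elimination_radius, drop_absorbed)
        for member, count in collapsed.items():
            entry = (key, member) if group_by == "umi" else (member, key)
            entries[entry] = count
    return MoleculeTable(entries, table.design_id)


def deduplicate(
    parsed: Iterable[ParsedRead],
    design: OligoDesign | None = None,
    error_correct: bool = True,
    elimination_radius: int = 4,
    drop_absorbed: bool = False,
) -> tuple[MoleculeTable, DuplicationStats]:
    """Full deduplication: exact collapse then both error-elimination passes.

    The UMI-grouped insert collapse runs first, then the insert-grouped UMI
    collapse.  Libraries without UMIs (``design.umi_length == 0``) skip both
    the exact collapse semantics and error elimination; every read stands
    for itself.
    """
    design_id = design.design_id if design else ""
    table, stats = collapse_exact(parsed, design_id)
    if design is not None and design.umi_length == 0:
        return table, stats
    if error_correct:
        table = error_collapse(
            table, "umi", elimination_radius=elimination_radius,
            drop_absorbed=drop_absorbed,
        )
        table = error_collapse(
            table, "insert", elimination_radius=elimination_radius,
            drop_absorbed=drop_absorbed,
        )
    return table, stats


@dataclass
class RemovalReport:
    """Sequences removed as contamination, with molecule counts."""

    endogenous: dict[str, int] = field(default_factory=dict)
    cross_design: dict[str, int] = field(default_factory=dict)

    @property
    def n_removed(self) -> int:
        return len(self.endogenous) + len(self.cross_design)


def remove_contaminants(
    table: CountTable,
    endogenous_refs: Iterable[str],
    max_mismatch: int = 2,
    other_design: OligoDesign | None = None,
    other_design_sequences: CountTable | None = None,
) -> tuple[CountTable, RemovalReport]:
    """Remove endogenous-loop and cross-design contaminant sequences.

    A sequence is endogenous contamination when it is within ``max_mismatch``
    Hamming mismatches of any reference at the variable-region register (the
    reference 5' end, where an endogenous loop read-through would sit).  A
    sequence is cross-design contamination when its layout matches
    ``other_design``: its first ``other_design.variable_length`` bases
    followed by that design's constant insert reproduce the sequence (and,
    when ``other_design_sequences`` is given, the variable part was actually
    observed in the other library).
    """
    refs = [normalize_sequence(r) for r in endogenous_refs]
    report = RemovalReport()
    kept: dict[str, int] = {}
    length = table.variable_length if table.counts else 0

    cross_len = other_design.variable_length if other_design is not None else None
    for seq, count in table.counts.items():
        endo = False
        for ref in refs:
            window = ref[:length]
            if len(window) == length and hamming(seq, window) <= max_mismatch:
                endo = True
                break
        if endo:
            report.endogenous[seq] = count
            continue
        if cross_len is not None and cross_len < length:
            tail = other_design.constant_insert[: length - cross_len]
            if len(tail) == length - cross_len and seq[cross_len:] == tail:
                head = seq[:cross_len]
                if (
                    other_design_sequences is None
                    or head in other_design_sequences.counts
                ):
                    report.cross_design[seq] = count
                    continue
        kept[seq] = count
    return CountTable(kept, table.library_label), report


def to_count_table(table: MoleculeTable, library_label: str = "") -> CountTable:
    """Count distinct molecules per variable-region sequence.

    Each molecule (table entry) contributes exactly one count regardless of
    how many reads supported it; deduplicated counts are what all enrichment
    statistics consume.
    """
    counts: dict[str, int] = {}
    for (_, var) in table.entries:
        counts[var] = counts.get(var, 0) + 1
    return CountTable(counts, library_label)
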