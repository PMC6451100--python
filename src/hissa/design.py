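"""Oligo-library architectures and structural read parsing.

A HISSA library is built from a partially randomized RNA oligo embedded in a
fixed scaffold.  Along the sequenced read (5'->3') the layout is::

    [UMI][anchor5][linker-random][variable region][constant insert][3' adapter]

where the variable region is the randomized block under study (5 or 8 nt in
the library designs shipped here) and the constant insert is the non-variable
portion of the mir-317 hairpin loop that serves as the splinted-ligation
bridge site.  Reads that do not show the constant insert at its expected
coordinate, or whose anchor-to-constant distance is wrong, are structural
failures (truncated ligation products, endogenous RNA carry-over) and are
rejected before any quantification.

All coordinates are 0-based, half-open.  All comparisons run in DNA space;
``U`` is mapped to ``T`` on ingestion.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Iterable, Iterator

import yaml

DNA_ALPHABET = frozenset("ACGT")
NUCLEOTIDES = "ACGT"

#: Illumina TruSeq small-RNA 3' adapter, the default sequencing adapter.
DEFAULT_ADAPTER3 = "TGGAATTCTCGGGTGCCAAGG"


class DesignError(ValueError):
    """Raised for an inconsistent or malformed library design."""


def normalize_sequence(seq: str) -> str:
    """Uppercase and map RNA ``U`` to DNA ``T``."""
    return seq.upper().replace("U", "T")


def _check_alphabet(name: str, seq: str) -> None:
    bad = set(seq) - DNA_ALPHABET
    if bad:
        raise DesignError(
            f"{name} contains non-ACGT characters {sorted(bad)!r}: {seq!r}"
        )


@dataclass(frozen=True)
class OligoDesign:
    """Declarative description of one randomized-oligo library architecture.

    Parameters
    ----------
    design_id
        Human-readable label, e.g. ``"5p-8N"``.
    umi_length
        Length of the unique molecular identifier at the read 5' end
        (0 when the library carries no UMI).
    anchor5
        5'-linker anchor sequence immediately downstream of the UMI
        (empty string when no anchor is declared).
    linker_random_length
        Number of randomized linker bases between the anchor and the insert.
    variable_length
        Length of the randomized region under study.
    constant_insert
        Non-variable insert portion used for structural validation.
    constant_insert_offset
        Expected 0-based position of ``constant_insert`` within the insert;
        equals ``variable_length`` (the randomized block immediately
        precedes the constant block).
    adapter3
        3' sequencing adapter to trim from the insert end.
    required_anchor_gap
        Enforced distance in nt between the end of ``anchor5`` and the start
        of ``constant_insert``; equals
        ``linker_random_length + variable_length``.
    max_constant_mismatches
        Mismatches tolerated when matching ``constant_insert`` at its
        expected coordinate (default 0: exact positional match).
    """

    design_id: str
    umi_length: int
    anchor5: str
    linker_random_length: int
    variable_length: int
    constant_insert: str
    constant_insert_offset: int
    adapter3: str = DEFAULT_ADAPTER3
    required_anchor_gap: int = -1  # -1: derive from the layout
    max_constant_mismatches: int = 0

    def __post_init__(self) -> None:
        for name in ("anchor5", "constant_insert", "adapter3"):
            object.__setattr__(self, name, normalize_sequence(getattr(self, name)))
            _check_alphabet(name, getattr(self, name))
        if self.variable_length < 1:
            raise DesignError("variable_length must be >= 1")
        if self.umi_length < 0 or self.linker_random_length < 0:
            raise DesignError("lengths must be non-negative")
        if not self.constant_insert:
            raise DesignError("constant_insert must be non-empty")
        derived_gap = self.linker_random_length + self.variable_length
        if self.required_anchor_gap == -1:
            object.__setattr__(self, "required_anchor_gap", derived_gap)
        elif self.anchor5 and self.required_anchor_gap != derived_gap:
            raise DesignError(
                f"required_anchor_gap={self.required_anchor_gap} inconsistent with "
                f"linker_random_length + variable_length = {derived_gap}"
            )
        if self.constant_insert_offset != self.variable_length:
            raise DesignError(
                "constant_insert_offset must equal variable_length "
                f"({self.constant_insert_offset} != {self.variable_length})"
            )

    # -- derived coordinates on the read ---------------------------------
    @property
    def insert_start(self) -> int:
        """Read coordinate where the insert (variable region) begins."""
        return self.umi_length + len(self.anchor5) + self.linker_random_length

    @property
    def constant_start(self) -> int:
        """Read coordinate where the constant insert is expected."""
        return self.insert_start + self.variable_length

    @property
    def min_read_length(self) -> int:
        return self.constant_start + len(self.constant_insert)

    def sequence_space_size(self) -> int:
        return 4 ** self.variable_length


def sequence_space(length: int) -> Iterator[str]:
    """Yield all ``4**length`` DNA sequences of the given length, sorted."""
    for combo in itertools.product(NUCLEOTIDES, repeat=length):
        yield "".join(combo)


def five_n_design(**overrides) -> OligoDesign:
    """The 5'-5N library: 5 randomized nt, no UMI, long constant insert."""
    kwargs = dict(
        design_id="5p-5N",
        umi_length=0,
        anchor5="",
        linker_random_length=0,
        variable_length=5,
        constant_insert="TGAAATGCAAGCAAG",
        constant_insert_offset=5,
    )
    kwargs.update(overrides)
    return OligoDesign(**kwargs)


def eight_n_design(**overrides) -> OligoDesign:
    """The 5'-8N library: 12-nt UMI, TGTAGC anchor, 2 linker-random nt,
    8 randomized nt, 10-nt enforced anchor gap."""
    kwargs = dict(
        design_id="5p-8N",
        umi_length=12,
        anchor5="TGTAGC",
        linker_random_length=2,
        variable_length=8,
        constant_insert="AATGCAAGCAAG",
        constant_insert_offset=8,
    )
    kwargs.update(overrides)
    return OligoDesign(**kwargs)


def load_design(config_source) -> OligoDesign:
    """Build a validated :class:`OligoDesign` from a config mapping or a
    YAML file path.

    Raises
    ------
    DesignError
        On malformed sequences or inconsistent layout parameters.
    """
    if isinstance(config_source, OligoDesign):
        return config_source
    if isinstance(config_source, dict):
        config = dict(config_source)
    else:
        with open(config_source) as handle:
            config = yaml.safe_load(handle)
        if not isinstance(config, dict):
            raise DesignError(f"design config {config_source!r} is not a mapping")
    known = {
        "design_id",
        "umi_length",
        "anchor5",
        "linker_random_length",
        "variable_length",
        "constant_insert",
        "constant_insert_offset",
        "adapter3",
        "required_anchor_gap",
        "max_constant_mismatches",
    }
    unknown = set(config) - known
    if unknown:
        raise DesignError(f"unknown design fields: {sorted(unknown)}")
    config.setdefault("design_id", "custom")
    config.setdefault("anchor5", "")
    config.setdefault("linker_random_length", 0)
    if "constant_insert_offset" not in config and "variable_length" in config:
        config["constant_insert_offset"] = config["variable_length"]
    try:
        return OligoDesign(**config)
    except TypeError as exc:  # missing required fields
        raise DesignError(str(exc)) from exc


@dataclass
class ParsedRead:
    """A read decomposed according to an :class:`OligoDesign`."""

    read_id: str
    umi: str
    linker_random: str
    variable_region: str
    insert: str


@dataclass
class ParseReport:
    """Exhaustive disposition tally of a parsing run.

    Reads in the accepted (correct-length) category are the only ones used
    for quantification.
    """

    accepted_correct_length: int = 0
    rejected_missing_constant: int = 0
    rejected_bad_anchor_gap: int = 0
    rejected_other: int = 0

    @property
    def total(self) -> int:
        return (
            self.accepted_correct_length
            + self.rejected_missing_constant
            + self.rejected_bad_anchor_gap
            + self.rejected_other
        )

    def as_dict(self) -> dict:
        return {
            "accepted_correct_length": self.accepted_correct_length,
            "rejected_missing_constant": self.rejected_missing_constant,
            "rejected_bad_anchor_gap": self.rejected_bad_anchor_gap,
            "rejected_other": self.rejected_other,
            "total": self.total,
        }


def _mismatches(a: str, b: str) -> int:
    return sum(x != y for x, y in zip(a, b))


def _matches_at(seq: str, pattern: str, pos: int, max_mismatch: int) -> bool:
    if pos < 0 or pos + len(pattern) > len(seq):
        return False
    return _mismatches(seq[pos : pos + len(pattern)], pattern) <= max_mismatch


def _trim_adapter(insert: str, adapter3: str, min_overlap: int = 6) -> str:
    """Remove the 3' adapter by longest-prefix match at the insert 3' end.

    A full internal adapter occurrence (with read-through beyond it) is
    trimmed at its first occurrence; otherwise the longest adapter prefix of
    at least ``min_overlap`` nt that is a suffix of the insert is trimmed.
    Inserts without a detectable adapter are returned unchanged.
    """
    if not adapter3:
        return insert
    idx = insert.find(adapter3)
    if idx != -1:
        return insert[:idx]
    max_k = min(len(adapter3) - 1, len(insert))
    for k in range(max_k, min_overlap - 1, -1):
        if insert.endswith(adapter3[:k]):
            return insert[: len(insert) - k]
    return insert


def parse_reads(
    reads: Iterable, design: OligoDesign
) -> tuple[list[ParsedRead], ParseReport]:
    """Decompose raw reads into (UMI, linker-random, variable region, insert).

    Parameters
    ----------
    reads
        Iterable of ``(read_id, sequence)`` pairs or Biopython ``SeqRecord``
        objects.
    design
        Validated library architecture.

    Returns
    -------
    (parsed, report)
        Accepted reads in input order and an exhaustive
        :class:`ParseReport`; dispositions partition the input.

    Notes
    -----
    Acceptance requires the constant insert at its expected coordinate
    (within ``design.max_constant_mismatches``) and, when a 5' anchor is
    declared, the anchor at its coordinate with the required anchor gap to
    the constant insert.  The 3' adapter is trimmed from the insert but
    adapter presence is not itself an acceptance requirement.
    """
    parsed: list[ParsedRead] = []
    report = ParseReport()
    anchor_end = design.umi_length + len(design.anchor5)
    for item in reads:
        if hasattr(item, "id") and hasattr(item, "seq"):
            read_id, seq = str(item.id), str(item.seq)
        else:
            read_id, seq = item
        seq = normalize_sequence(seq)

        if len(seq) < design.min_read_length:
            report.rejected_other += 1
            continue
        if design.anchor5 and not _matches_at(
            seq, design.anchor5, design.umi_length, 0
        ):
            report.rejected_other += 1
            continue
        at_expected = _matches_at(
            seq, design.constant_insert, design.constant_start,
            design.max_constant_mismatches,
        )
        if not at_expected:
            elsewhere = seq.find(design.constant_insert, anchor_end)
            if elsewhere == -1:
                report.rejected_missing_constant += 1
            elif design.anchor5:
                # constant present but at the wrong anchor distance
                report.rejected_bad_anchor_gap += 1
            else:
                report.rejected_missing_constant += 1
            continue

        umi = seq[: design.umi_length]
        linker_random = seq[anchor_end : anchor_end + design.linker_random_length]
        insert_raw = seq[design.insert_start :]
        insert = _trim_adapter(insert_raw, design.adapter3)
        variable_region = insert[: design.variable_length]
        report.accepted_correct_length += 1
        parsed.append(
            ParsedRead(
                read_id=read_id,
                umi=umi,
                linker_random=linker_random,
                variable_region=variable_region,
                insert=insert,
            )
        )
    return parsed, report
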