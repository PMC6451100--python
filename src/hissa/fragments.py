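"""mRNA-fragment pipeline: annotation filter cascade and 3-nt motif tests.

Endogenous small-RNA libraries mapped to the genome (BED) are stripped of
everything plausibly derived from duplex precursors — reads outside
annotated gene loci, reads overlapping miRNA/siRNA/piRNA or RepeatMasker
annotations, multi-mappers, staggered (opposite-strand overlapping) reads,
and 21-nt reads (the dominant siRNA length) — leaving candidate
single-stranded mRNA fragments.  The 3-mers at read positions 1-3, 2-4 and
3-5 are then tallied per frame, and each motif's IP/input fold enrichment
is tested with a two-sided Fisher exact test on the 2x2 read-count table.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from intervaltree import IntervalTree
from scipy import stats

from .design import normalize_sequence
from .enrichment import all_kmers

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


class FragmentError(ValueError):
    pass


@dataclass
class GenomicRead:
    """One mapped read; coordinates 0-based half-open; sequence 5'->3' of
    the read (already reverse-complemented for minus-strand reads)."""

    chrom: str
    start: int
    end: int
    strand: str
    read_id: str = ""
    sequence: str | None = None
    mapping_multiplicity: int = 1
    read_count: int = 1

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise FragmentError(f"invalid interval {self.start}-{self.end}")
        if self.strand not in "+-":
            raise FragmentError(f"invalid strand {self.strand!r}")
        if self.sequence is not None:
            self.sequence = normalize_sequence(self.sequence)

    @property
    def length(self) -> int:
        return self.end - self.start


def read_bed(
    source,
    sequence_orientation: str = "read",
) -> list[GenomicRead]:
    """Load reads from a BED6(+2) file.

    Columns: chrom, start, end, name, score, strand, then optionally
    sequence (column 7) and mapping multiplicity (column 8).  The score
    column carries the read count (0 or '.' means 1).  With
    ``sequence_orientation="reference"`` stored sequences are plus-strand
    genomic and are reverse-complemented for minus-strand reads so that
    ``GenomicRead.sequence`` is always read-5'->3'.
    """
    if sequence_orientation not in ("read", "reference"):
        raise FragmentError(f"bad sequence_orientation {sequence_orientation!r}")
    close = False
    if isinstance(source, (str, bytes)) or hasattr(source, "__fspath__"):
        handle = open(source)
        close = True
    else:
        handle = source
    reads = []
    try:
        for line in handle:
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 6:
                raise FragmentError(f"BED line has fewer than 6 fields: {line!r}")
            chrom, start, end, name, score, strand = fields[:6]
            seq = fields[6] if len(fields) > 6 and fields[6] not in (".", "") else None
            mult = int(fields[7]) if len(fields) > 7 and fields[7] not in (".", "") else 1
            count = 1
            if score not in (".", "", "0"):
                count = int(score)
            if seq is not None and sequence_orientation == "reference" and strand == "-":
                seq = reverse_complement(normalize_sequence(seq))
            reads.append(
                GenomicRead(
                    chrom=chrom,
                    start=int(start),
                    end=int(end),
                    strand=strand,
                    read_id=name,
                    sequence=seq,
                    mapping_multiplicity=mult,
                    read_count=count,
                )
            )
    finally:
        if close:
            handle.close()
    return reads


Interval = tuple[str, int, int, str]  # chrom, start, end, strand ('.' = unstranded)


def _build_trees(intervals: Iterable[Interval]) -> dict[str, IntervalTree]:
    trees: dict[str, IntervalTree] = {}
    for chrom, start, end, strand in intervals:
        trees.setdefault(chrom, IntervalTree()).addi(start, end, strand)
    return trees


def read_annotation_bed(source) -> list[Interval]:
    """Load an annotation interval set from a BED file (>=3 columns)."""
    close = False
    if isinstance(source, (str, bytes)) or hasattr(source, "__fspath__"):
        handle = open(source)
        close = True
    else:
        handle = source
    out = []
    try:
        for line in handle:
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            strand = fields[5] if len(fields) > 5 else "."
            out.append((fields[0], int(fields[1]), int(fields[2]), strand))
    finally:
        if close:
            handle.close()
    return out


@dataclass
class AnnotationBundle:
    """Interval sets driving the filter cascade.

    ``gene_loci`` is a keep-filter (reads must lie within a gene locus);
    the small-RNA sets and ``repeatmasker`` are removal filters.  A missing
    (None) removal set — e.g. piRNA outside ovary libraries — causes that
    stage to be skipped with a warning.
    """

    gene_loci: list[Interval]
    mirna: list[Interval] | None = None
    sirna: list[Interval] | None = None
    pirna: list[Interval] | None = None
    repeatmasker: list[Interval] | None = None

    def __post_init__(self) -> None:
        self._trees = {
            name: _build_trees(ivs) if ivs is not None else None
            for name, ivs in (
                ("gene_loci", self.gene_loci),
                ("mirna", self.mirna),
                ("sirna", self.sirna),
                ("pirna", self.pirna),
                ("repeatmasker", self.repeatmasker),
            )
        }

    def _hits(self, name: str, read: GenomicRead):
        trees = self._trees[name]
        if trees is None or read.chrom not in trees:
            return []
        return trees[read.chrom][read.start : read.end]

    def contains(self, name: str, read: GenomicRead, stranded: bool) -> bool:
        """Read fully contained in some interval of the set."""
        for iv in self._hits(name, read):
            if iv.begin <= read.start and read.end <= iv.end:
                if not stranded or iv.data in (".", read.strand):
                    return True
        return False

    def overlaps(self, name: str, read: GenomicRead, stranded: bool) -> bool:
        """Read overlaps (>=1 nt) some interval of the set."""
        for iv in self._hits(name, read):
            if not stranded or iv.data in (".", read.strand):
                return True
        return False


# (stage name, filter set, removal?, stranded?)
_ANNOTATION_STAGES = [
    ("mirna", True),
    ("sirna", True),
    ("pirna", True),
    ("repeatmasker", False),  # repeat annotations are not reliably stranded
]


def _staggered_index(reads: Sequence[GenomicRead]) -> set[int]:
    """Indices of reads overlapped by an opposite-strand read of the same
    library — the duplex (siRNA-like) signature."""
    trees: dict[tuple[str, str], IntervalTree] = {}
    for i, read in enumerate(reads):
        trees.setdefault((read.chrom, read.strand), IntervalTree()).addi(
            read.start, read.end, i
        )
    flagged: set[int] = set()
    for i, read in enumerate(reads):
        other = "-" if read.strand == "+" else "+"
        tree = trees.get((read.chrom, other))
        if tree is not None and tree.overlaps(read.start, read.end):
            flagged.add(i)
    return flagged


def filter_cascade(
    reads: Sequence[GenomicRead],
    annotations: AnnotationBundle,
    drop_length: int = 21,
    gene_containment: bool = True,
) -> tuple[list[GenomicRead], pd.DataFrame]:
    """Apply the duplex-exclusion filter cascade in its canonical order.

    Stages: (1) keep reads lying within gene loci (full containment,
    strand-aware); (2-5) remove reads overlapping miRNA / siRNA / piRNA /
    RepeatMasker annotations; (6) remove multi-mappers; (7) remove
    staggered reads (overlapped by an opposite-strand read anywhere in the
    input library); (8) remove reads of length exactly ``drop_length``.

    Returns the surviving reads and an attrition report DataFrame with one
    row per stage (``stage, kept, removed, skipped``).
    """
    reads = list(reads)
    staggered = _staggered_index(reads)
    flagged_ids = {id(reads[i]) for i in staggered}

    rows = [{"stage": "input", "kept": len(reads), "removed": 0, "skipped": False}]
    surviving = [
        r for r in reads
        if annotations.contains("gene_loci", r, stranded=gene_containment)
    ]
    rows.append(
        {"stage": "gene_loci", "kept": len(surviving),
         "removed": rows[-1]["kept"] - len(surviving), "skipped": False}
    )

    for name, stranded in _ANNOTATION_STAGES:
        if getattr(annotations, name) is None:
            warnings.warn(f"annotation set {name!r} missing; stage skipped",
                          stacklevel=2)
            rows.append({"stage": name, "kept": len(surviving), "removed": 0,
                         "skipped": True})
            continue
        before = len(surviving)
        surviving = [
            r for r in surviving if not annotations.overlaps(name, r, stranded)
        ]
        rows.append({"stage": name, "kept": len(surviving),
                     "removed": before - len(surviving), "skipped": False})

    before = len(surviving)
    surviving = [r for r in surviving if r.mapping_multiplicity <= 1]
    rows.append({"stage": "multimappers", "kept": len(surviving),
                 "removed": before - len(surviving), "skipped": False})

    before = len(surviving)
    surviving = [r for r in surviving if id(r) not in flagged_ids]
    rows.append({"stage": "staggered", "kept": len(surviving),
                 "removed": before - len(surviving), "skipped": False})

    before = len(surviving)
    surviving = [r for r in surviving if r.length != drop_length]
    rows.append({"stage": f"length_{drop_length}", "kept": len(surviving),
                 "removed": before - len(surviving), "skipped": False})

    return surviving, pd.DataFrame(rows)


def frame_motif_counts(
    reads: Iterable[GenomicRead],
    frames: Sequence[int] = (1, 2, 3),
    motif_length: int = 3,
) -> tuple[dict[int, pd.Series], int]:
    """Tally the 3-mer at read positions f..f+2 per frame, read-count
    weighted.

    Returns ``(tables, n_skipped)`` where each table is a zero-filled
    Series over all 4**motif_length motifs, and ``n_skipped`` counts
    (read, frame) combinations skipped because the read was too short or
    carried no sequence.
    """
    motifs = all_kmers(motif_length)
    tables = {f: pd.Series(0.0, index=motifs) for f in frames}
    skipped = 0
    for read in reads:
        seq = read.sequence
        for f in frames:
            if seq is None or len(seq) < f - 1 + motif_length:
                skipped += 1
                continue
            motif = seq[f - 1 : f - 1 + motif_length]
            if set(motif) <= set("ACGT"):
                tables[f][motif] += read.read_count
            else:
                skipped += 1
    return tables, skipped


def combine_frames(tables: dict[int, pd.Series]) -> pd.Series:
    """Sum the per-frame motif tables (the all-windows-combined view)."""
    return sum(tables.values())


def fisher_exact_pvalue(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher exact p for the 2x2 table [[a, b], [c, d]]
    (sum of same-margin table probabilities <= the observed one)."""
    _, p = stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")
    return float(p)


def motif_enrichment(
    ip_counts: pd.Series, input_counts: pd.Series, frame: int | str = "combined"
) -> pd.DataFrame:
    """Fold enrichment + Fisher exact test for every motif in one frame.

    For each motif the 2x2 table is ``[[count_ip, other_ip], [count_input,
    other_input]]``; fold enrichment is the ratio of within-library motif
    percentages; the p-value is the conventional two-sided Fisher exact
    test (sum of table probabilities <= the observed one).  A motif absent
    from both libraries has undefined (NaN) fold and p = 1.
    """
    total_ip = float(ip_counts.sum())
    total_in = float(input_counts.sum())
    if total_ip <= 0 or total_in <= 0:
        raise FragmentError("both libraries must have nonzero motif totals")
    rows = []
    for motif in ip_counts.index:
        a = float(ip_counts[motif])
        c = float(input_counts[motif])
        b = total_ip - a
        d = total_in - c
        if a == 0 and c == 0:
            fold, p = np.nan, 1.0
        else:
            fold = (a / total_ip) / (c / total_in) if c > 0 else np.nan
            p = fisher_exact_pvalue(
                int(round(a)), int(round(b)), int(round(c)), int(round(d))
            )
        rows.append(
            {
                "frame": frame,
                "motif": motif,
                "count_ip": a,
                "other_ip": b,
                "count_input": c,
                "other_input": d,
                "fold_enrichment": fold,
                "p_value": p,
            }
        )
    df = pd.DataFrame(rows)
    return df.sort_values(
        ["fold_enrichment", "motif"], ascending=[False, True], na_position="last"
    ).reset_index(drop=True)


def fragment_motif_analysis(
    ip_reads: Sequence[GenomicRead],
    input_reads: Sequence[GenomicRead],
    annotations: AnnotationBundle,
    drop_length: int = 21,
) -> dict:
    """Run the full fragment pipeline on an IP/input library pair.

    Returns a dict with per-library survivors and attrition reports plus
    per-frame and combined motif-enrichment tables.
    """
    ip_surv, ip_attrition = filter_cascade(ip_reads, annotations, drop_length)
    in_surv, in_attrition = filter_cascade(input_reads, annotations, drop_length)
    ip_tables, _ = frame_motif_counts(ip_surv)
    in_tables, _ = frame_motif_counts(in_surv)
    per_frame = {
        f: motif_enrichment(ip_tables[f], in_tables[f], frame=f)
        for f in ip_tables
    }
    combined = motif_enrichment(
        combine_frames(ip_tables), combine_frames(in_tables), frame="combined"
    )
    return {
        "ip_survivors": ip_surv,
        "input_survivors": in_surv,
        "ip_attrition": ip_attrition,
        "input_attrition": in_attrition,
        "per_frame": per_frame,
        "combined": combined,
    }
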