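"""Synthetic experiments with known ground truth.

The generator emulates the full randomized-oligo workflow: a uniform input
pool over the 4**L variable-region space, IP selection by a multiplicative
log-linear loading-weight model, UMI tagging, uneven PCR amplification, and
per-base substitution sequencing errors.  Its bookkeeping (which molecule
produced which reads) is independent of the analysis code, so every
pipeline stage can be tested for exact recovery or statistical calibration
against planted effects.

A companion generator emits toy genomic fixtures (BED reads plus annotation
sets) with controlled filter violations and planted per-frame motif biases
for the mRNA-fragment pipeline.
"""

from __future__ import annotations

import gzip
import itertools
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .design import NUCLEOTIDES, OligoDesign, sequence_space
from .dedup import CountTable
from .fragments import AnnotationBundle, GenomicRead, Interval


class SimulationError(ValueError):
    pass


@dataclass
class EffectModel:
    """Multiplicative loading-weight model over variable-region sequences.

    The weight of a sequence is the product of all matching effect weights
    over a baseline of 1:

    - ``single_effects[(position, nt)]`` applies when the (1-based)
      position carries that nucleotide;
    - ``motif_effects[(motif, start)]`` applies when the motif occurs at
      the given 1-based start, or anywhere (once) when start is ``"any"``;
    - ``pair_effects[(pos_i, nt_a, pos_j, nt_b)]`` applies when both
      positions carry the given nucleotides.

    IP molecules are drawn with probability proportional to weight; an
    empty model makes IP statistically identical to input.
    """

    single_effects: dict[tuple[int, str], float] = field(default_factory=dict)
    motif_effects: dict[tuple[str, int | str], float] = field(default_factory=dict)
    pair_effects: dict[tuple[int, str, int, str], float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for mapping in (self.single_effects, self.motif_effects, self.pair_effects):
            for key, w in mapping.items():
                if w <= 0:
                    raise SimulationError(f"effect weight must be > 0: {key} -> {w}")

    def weight(self, seq: str) -> float:
        w = 1.0
        for (pos, nt), eff in self.single_effects.items():
            if pos <= len(seq) and seq[pos - 1] == nt:
                w *= eff
        for (motif, start), eff in self.motif_effects.items():
            if start == "any":
                if motif in seq:
                    w *= eff
            elif seq[start - 1 : start - 1 + len(motif)] == motif:
                w *= eff
        for (pi, na, pj, nb), eff in self.pair_effects.items():
            if (
                pi <= len(seq) and pj <= len(seq)
                and seq[pi - 1] == na and seq[pj - 1] == nb
            ):
                w *= eff
        return w

    def weights_over_space(self, length: int) -> np.ndarray:
        """Weight of every sequence of the given length, in sorted order."""
        return np.fromiter(
            (self.weight(s) for s in sequence_space(length)),
            dtype=float,
            count=4 ** length,
        )


def gac_model(weight: float = 2.0) -> EffectModel:
    """Planted 5'-GAC motif effect (the AGO1-style preference)."""
    return EffectModel(motif_effects={("GAC", 1): weight})


def g_rich_model(weight: float = 1.3, length: int = 8) -> EffectModel:
    """Position-independent G preference (the AGO2-style preference)."""
    return EffectModel(
        single_effects={(pos, "G"): weight for pos in range(1, length + 1)}
    )


_SEQ_CACHE: dict[int, list[str]] = {}


def _space(length: int) -> list[str]:
    if length not in _SEQ_CACHE:
        _SEQ_CACHE[length] = list(sequence_space(length))
    return _SEQ_CACHE[length]


def simulate_count_tables(
    design: OligoDesign,
    model: EffectModel,
    n_input: int,
    n_ip: int,
    seed: int | np.random.Generator = 0,
) -> tuple[CountTable, CountTable]:
    """Sequencing-free simulation: molecule count tables only.

    Input counts are multinomial over the uniform sequence space; IP counts
    are multinomial with probabilities proportional to the model weights.
    This is the mode used for statistical calibration at large n, where the
    read-level machinery (UMIs, amplification, errors) is not under test.
    Returns ``(ip_table, input_table)``.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    length = design.variable_length
    space = _space(length)
    size = len(space)
    counts_in = rng.multinomial(n_input, np.full(size, 1.0 / size))
    weights = model.weights_over_space(length)
    counts_ip = rng.multinomial(n_ip, weights / weights.sum())
    table_in = CountTable(
        {s: int(c) for s, c in zip(space, counts_in) if c}, "input"
    )
    table_ip = CountTable({s: int(c) for s, c in zip(space, counts_ip) if c}, "ip")
    return table_ip, table_in


@dataclass
class MoleculeRecord:
    library: str
    molecule_id: int
    variable_region: str
    umi: str
    linker_random: str
    amplification: int
    read_ids: list[str]


@dataclass
class SimulationTruth:
    """Ground truth of one simulated experiment."""

    records: list[MoleculeRecord]
    seed: int
    design_id: str

    def multiplicities(self, library: str) -> dict[str, int]:
        """True molecule multiplicity per variable-region sequence."""
        out: dict[str, int] = {}
        for rec in self.records:
            if rec.library == library:
                out[rec.variable_region] = out.get(rec.variable_region, 0) + 1
        return out

    def n_molecules(self, library: str) -> int:
        return sum(1 for r in self.records if r.library == library)

    def total_reads(self, library: str | None = None) -> int:
        return sum(
            r.amplification
            for r in self.records
            if library is None or r.library == library
        )


@dataclass
class HissaSimulation:
    """Reads and ground truth of one simulated experiment."""

    input_reads: list[tuple[str, str]]
    ip_reads: list[tuple[str, str]]
    truth: SimulationTruth
    design: OligoDesign

    def write_fastq(self, prefix: str, compress: bool = True) -> tuple[str, str]:
        paths = []
        for label, reads in (("input", self.input_reads), ("ip", self.ip_reads)):
            path = f"{prefix}.{label}.fastq" + (".gz" if compress else "")
            opener = gzip.open if compress else open
            with opener(path, "wt") as handle:
                for read_id, seq in reads:
                    handle.write(f"@{read_id}\n{seq}\n+\n{'I' * len(seq)}\n")
            paths.append(path)
        return tuple(paths)


def _draw_amplification(rng: np.random.Generator, n: int, spec) -> np.ndarray:
    """Per-molecule read multiplicities (always >= 1).

    ``spec`` may be an int (constant), ``("geometric", mean)`` with the
    geometric truncated-at-1 distribution (long right tail, matching the
    hundreds-of-reads-per-molecule events seen in amplified libraries), or
    ``("lognormal", mu, sigma)`` (rounded up).
    """
    if isinstance(spec, int):
        if spec < 1:
            raise SimulationError("constant amplification must be >= 1")
        return np.full(n, spec, dtype=np.int64)
    kind = spec[0]
    if kind == "geometric":
        mean = float(spec[1])
        if mean < 1:
            raise SimulationError("geometric amplification mean must be >= 1")
        return rng.geometric(1.0 / mean, size=n)
    if kind == "lognormal":
        mu, sigma = float(spec[1]), float(spec[2])
        return np.maximum(1, np.ceil(rng.lognormal(mu, sigma, size=n))).astype(np.int64)
    raise SimulationError(f"unknown amplification spec {spec!r}")


def _random_bases(rng: np.random.Generator, n: int) -> str:
    return "".join(NUCLEOTIDES[i] for i in rng.integers(0, 4, size=n))


def _apply_errors(rng: np.random.Generator, seq: str, error_rate: float) -> str:
    if error_rate <= 0:
        return seq
    arr = list(seq)
    hits = np.nonzero(rng.random(len(arr)) < error_rate)[0]
    for i in hits:
        alternatives = [nt for nt in NUCLEOTIDES if nt != arr[i]]
        arr[i] = alternatives[rng.integers(0, 3)]
    return "".join(arr)


def simulate_experiment(
    design: OligoDesign,
    model: EffectModel,
    n_input: int,
    n_ip: int,
    amplification=("geometric", 1.25),
    error_rate: float = 0.0,
    seed: int = 0,
) -> HissaSimulation:
    """Simulate a full IP/input experiment at the read level.

    Input molecules are uniform over the sequence space; IP molecules are
    drawn proportionally to the model weights.  Each molecule receives an
    independent uniform-random UMI (collisions allowed) and linker-random
    bases, a read multiplicity from the amplification distribution, and
    each emitted read is assembled per the design layout
    (UMI + anchor + linker-random + variable + constant + adapter) with
    independent per-base substitution errors at ``error_rate``.
    """
    if n_input < 1 or n_ip < 1:
        raise SimulationError("n_input and n_ip must be >= 1")
    if not 0 <= error_rate < 0.25:
        raise SimulationError("error_rate must be in [0, 0.25)")
    rng = np.random.default_rng(seed)
    length = design.variable_length
    space = _space(length)
    weights = model.weights_over_space(length)
    probs_ip = weights / weights.sum()
    uniform = np.full(len(space), 1.0 / len(space))

    records: list[MoleculeRecord] = []
    libraries: dict[str, list[tuple[str, str]]] = {"input": [], "ip": []}
    mol_id = 0
    for library, n, probs in (("input", n_input, uniform), ("ip", n_ip, probs_ip)):
        seq_idx = rng.choice(len(space), size=n, p=probs)
        amps = _draw_amplification(rng, n, amplification)
        for i in range(n):
            var = space[seq_idx[i]]
            umi = _random_bases(rng, design.umi_length)
            linker = _random_bases(rng, design.linker_random_length)
            template = (
                umi + design.anchor5 + linker + var
                + design.constant_insert + design.adapter3
            )
            read_ids = []
            for rep in range(int(amps[i])):
                read_id = f"{library}:{mol_id}:{rep}"
                libraries[library].append(
                    (read_id, _apply_errors(rng, template, error_rate))
                )
                read_ids.append(read_id)
            records.append(
                MoleculeRecord(library, mol_id, var, umi, linker, int(amps[i]), read_ids)
            )
            mol_id += 1
    truth = SimulationTruth(records, seed, design.design_id)
    return HissaSimulation(libraries["input"], libraries["ip"], truth, design)


# ---------------------------------------------------------------------------
# Genomic fragment fixtures
# ---------------------------------------------------------------------------

#: Violations the fixture can plant, each defeating exactly one cascade stage.
FIXTURE_VIOLATIONS = (
    "outside_gene",
    "mirna",
    "sirna",
    "pirna",
    "repeatmasker",
    "multimapper",
    "staggered",
    "length21",
)


@dataclass
class FragmentFixture:
    """Toy genomic fixture with generator-side survivor bookkeeping."""

    ip_reads: list[GenomicRead]
    input_reads: list[GenomicRead]
    annotations: AnnotationBundle
    expected_ip_survivors: list[str]
    expected_input_survivors: list[str]
    gac_bias: float
    seed: int


def _fixture_annotations() -> AnnotationBundle:
    chrom = "chr2L"
    genes: list[Interval] = [(chrom, 1_000, 60_000, ".")]
    return AnnotationBundle(
        gene_loci=genes,
        mirna=[(chrom, 5_000, 5_100, "+")],
        sirna=[(chrom, 10_000, 10_100, "+")],
        pirna=[(chrom, 15_000, 15_100, "+")],
        repeatmasker=[(chrom, 20_000, 20_100, ".")],
    )


def _fixture_sequence(rng: np.random.Generator, length: int, gac_bias: float) -> str:
    """Random read sequence whose first 3-mer is GAC-weighted by the bias."""
    motifs = ["".join(p) for p in itertools.product(NUCLEOTIDES, repeat=3)]
    weights = np.ones(64)
    weights[motifs.index("GAC")] = gac_bias
    head = motifs[rng.choice(64, p=weights / weights.sum())]
    return head + _random_bases(rng, length - 3)


def simulate_fragment_fixture(
    seed: int = 0,
    n_survivors_ip: int = 6,
    n_survivors_input: int = 6,
    violations: Sequence[str] = ("outside_gene", "mirna", "multimapper", "length21"),
    gac_bias: float = 1.0,
    read_length: int = 23,
) -> FragmentFixture:
    """Emit a toy BED fixture with controlled cascade violations.

    Survivor reads sit inside the gene locus, clear of every removal
    annotation, uniquely mapped, same-strand (so never staggered) and not
    ``drop_length`` nt.  Each requested violation adds reads to the IP
    library that defeat exactly one stage (``staggered`` adds the
    opposite-strand pair, i.e. two reads).  The expected-survivor lists are
    the generator's own bookkeeping, independent of the filter cascade.

    With ``gac_bias > 1``, IP survivor sequences start with GAC
    ``gac_bias``-fold more often than uniform (a planted frame-1 motif
    bias); input survivors always draw their first 3-mer uniformly.
    """
    unknown = set(violations) - set(FIXTURE_VIOLATIONS)
    if unknown:
        raise SimulationError(f"unknown violations: {sorted(unknown)}")
    rng = np.random.default_rng(seed)
    chrom = "chr2L"
    annotations = _fixture_annotations()

    def survivor(library: str, i: int, bias: float) -> GenomicRead:
        # cycle within a clean same-strand region of the gene locus
        start = 30_000 + 50 * (i % 500)
        return GenomicRead(
            chrom, start, start + read_length, "+",
            read_id=f"{library}_ok_{i}",
            sequence=_fixture_sequence(rng, read_length, bias),
        )

    ip_reads = [survivor("ip", i, gac_bias) for i in range(n_survivors_ip)]
    input_reads = [survivor("input", i, 1.0) for i in range(n_survivors_input)]
    expected_ip = [r.read_id for r in ip_reads]
    expected_input = [r.read_id for r in input_reads]

    def violator(name: str) -> list[GenomicRead]:
        seq = lambda L=read_length: _fixture_sequence(rng, L, 1.0)
        if name == "outside_gene":
            return [GenomicRead(chrom, 70_000, 70_000 + read_length, "+",
                                read_id="ip_outside_gene", sequence=seq())]
        if name == "mirna":
            return [GenomicRead(chrom, 5_020, 5_020 + read_length, "+",
                                read_id="ip_mirna", sequence=seq())]
        if name == "sirna":
            return [GenomicRead(chrom, 10_020, 10_020 + read_length, "+",
                                read_id="ip_sirna", sequence=seq())]
        if name == "pirna":
            return [GenomicRead(chrom, 15_020, 15_020 + read_length, "+",
                                read_id="ip_pirna", sequence=seq())]
        if name == "repeatmasker":
            return [GenomicRead(chrom, 20_020, 20_020 + read_length, "+",
                                read_id="ip_repeat", sequence=seq())]
        if name == "multimapper":
            return [GenomicRead(chrom, 40_000, 40_000 + read_length, "+",
                                read_id="ip_multi", sequence=seq(),
                                mapping_multiplicity=3)]
        if name == "staggered":
            return [
                GenomicRead(chrom, 57_000, 57_000 + read_length, "+",
                            read_id="ip_stag_plus", sequence=seq()),
                GenomicRead(chrom, 57_010, 57_010 + read_length, "-",
                            read_id="ip_stag_minus", sequence=seq()),
            ]
        if name == "length21":
            return [GenomicRead(chrom, 50_000, 50_021, "+",
                                read_id="ip_len21", sequence=seq(21))]
        raise AssertionError(name)

    for name in violations:
        ip_reads.extend(violator(name))
    return FragmentFixture(
        ip_reads, input_reads, annotations,
        expected_ip, expected_input, gac_bias, seed,
    )


def write_bed(reads: Sequence[GenomicRead], path: str) -> None:
    """Write reads as BED6+2 (sequence and multiplicity in columns 7-8)."""
    with open(path, "w") as handle:
        for r in reads:
            handle.write(
                f"{r.chrom}\t{r.start}\t{r.end}\t{r.read_id}\t{r.read_count}\t"
                f"{r.strand}\t{r.sequence or '.'}\t{r.mapping_multiplicity}\n"
            )


def write_annotation_bed(intervals: Sequence[Interval], path: str) -> None:
    with open(path, "w") as handle:
        for chrom, start, end, strand in intervals:
            handle.write(f"{chrom}\t{start}\t{end}\t.\t0\t{strand}\n")
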