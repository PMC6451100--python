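"""Enrichment statistics over deduplicated variable-region counts.

All statistics compare an Argonaute-IP library against its matched input
(the randomized pool sequenced without selection).  Normalization is always
within-library (reads-per-million or fractions), so every statistic is
invariant to rescaling either library's counts by a constant.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .design import NUCLEOTIDES
from .dedup import CountTable


class EnrichmentError(ValueError):
    pass


def _require_nonempty(*tables: CountTable) -> None:
    for t in tables:
        if t.total_molecules == 0:
            raise EnrichmentError(
                f"library {t.library_label!r} is empty: no normalization basis"
            )


def per_sequence_enrichment(
    ip: CountTable, input_: CountTable, pseudocount: float = 0.0
) -> pd.DataFrame:
    """Per-sequence enrichment factors (IP RPM / input RPM), ranked.

    Returns a DataFrame with columns ``sequence, count_input, count_ip,
    rpm_input, rpm_ip, enrichment_factor, rank``, sorted by descending
    enrichment factor.  Sequences present in both libraries carry an
    enrichment factor and a 1-based rank; sequences absent from one library
    have NaN factor and rank unless a positive ``pseudocount`` is supplied
    (added to every count in both libraries before normalization).
    """
    _require_nonempty(ip, input_)
    seqs = sorted(set(ip.counts) | set(input_.counts))
    ci = np.array([input_.counts.get(s, 0) for s in seqs], dtype=float)
    cp = np.array([ip.counts.get(s, 0) for s in seqs], dtype=float)
    if pseudocount:
        ci = ci + pseudocount
        cp = cp + pseudocount
    rpm_in = ci * 1e6 / ci.sum()
    rpm_ip = cp * 1e6 / cp.sum()
    with np.errstate(divide="ignore", invalid="ignore"):
        factor = np.where((ci > 0) & (cp > 0), rpm_ip / rpm_in, np.nan)
    df = pd.DataFrame(
        {
            "sequence": seqs,
            "count_input": ci,
            "count_ip": cp,
            "rpm_input": rpm_in,
            "rpm_ip": rpm_ip,
            "enrichment_factor": factor,
        }
    )
    df = df.sort_values(
        ["enrichment_factor", "sequence"], ascending=[False, True], na_position="last"
    ).reset_index(drop=True)
    ranked = df["enrichment_factor"].notna()
    df["rank"] = np.nan
    df.loc[ranked, "rank"] = np.arange(1, ranked.sum() + 1)
    return df


@dataclass
class PositionNucleotideMatrix:
    """Per-position nucleotide percentages and their IP/input log2 ratios.

    ``percent_input`` / ``percent_ip`` are (position x nucleotide) grids in
    percent (rows sum to 100); ``log2_ratio`` is
    ``log2(percent_ip / percent_input)``, NaN wherever the input percentage
    is zero (never silently +/-inf).  ``se_log2`` is the delta-method
    standard error of each log2 ratio under multinomial sampling in both
    libraries, useful for null calibration.
    """

    percent_input: pd.DataFrame
    percent_ip: pd.DataFrame
    log2_ratio: pd.DataFrame
    se_log2: pd.DataFrame


def _position_percent(table: CountTable) -> tuple[pd.DataFrame, int]:
    length = table.variable_length
    counts = np.zeros((length, 4))
    nt_index = {nt: i for i, nt in enumerate(NUCLEOTIDES)}
    for seq, count in table.counts.items():
        for pos, base in enumerate(seq):
            counts[pos, nt_index[base]] += count
    total = table.total_molecules
    percent = pd.DataFrame(
        counts * 100.0 / total,
        index=pd.RangeIndex(1, length + 1, name="position"),
        columns=list(NUCLEOTIDES),
    )
    return percent, total


def per_position_enrichment(
    ip: CountTable, input_: CountTable
) -> PositionNucleotideMatrix:
    """Positional nucleotide composition of IP vs input, log2 transformed."""
    _require_nonempty(ip, input_)
    if ip.variable_length != input_.variable_length:
        raise EnrichmentError("libraries have different variable-region lengths")
    pct_in, n_in = _position_percent(input_)
    pct_ip, n_ip = _position_percent(ip)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(pct_in.values > 0, pct_ip.values / pct_in.values, np.nan)
        log2_ratio = np.log2(np.where(ratio > 0, ratio, np.nan))
        p_in = pct_in.values / 100.0
        p_ip = pct_ip.values / 100.0
        var = np.where(
            (p_in > 0) & (p_ip > 0),
            (1 - p_ip) / (n_ip * p_ip) + (1 - p_in) / (n_in * p_in),
            np.nan,
        )
        se = np.sqrt(var) / np.log(2)
    frame = lambda a: pd.DataFrame(a, index=pct_in.index, columns=pct_in.columns)
    return PositionNucleotideMatrix(pct_in, pct_ip, frame(log2_ratio), frame(se))


def all_kmers(k: int) -> list[str]:
    return ["".join(p) for p in itertools.product(NUCLEOTIDES, repeat=k)]


def _kmer_frequencies(table: CountTable, k: int) -> pd.Series:
    counts = {kmer: 0.0 for kmer in all_kmers(k)}
    for seq, count in table.counts.items():
        for i in range(len(seq) - k + 1):
            counts[seq[i : i + k]] += count
    series = pd.Series(counts, name=table.library_label)
    total = series.sum()
    if total == 0:
        raise EnrichmentError("no k-mer windows (empty library?)")
    return series / total


def kmer_enrichment(
    ip: CountTable, input_: CountTable, k: int = 3
) -> pd.DataFrame:
    """Position-independent k-mer enrichment (Bind-n-Seq-style).

    Every overlapping length-``k`` window of every sequence contributes its
    molecule count; per-library window frequencies are ratioed IP over
    input.  Returns a DataFrame ``kmer, freq_input, freq_ip, enrichment,
    rank`` sorted by descending enrichment (4**k rows).
    """
    _require_nonempty(ip, input_)
    if k > ip.variable_length or k > input_.variable_length:
        raise EnrichmentError(
            f"k={k} exceeds the variable-region length"
        )
    freq_in = _kmer_frequencies(input_, k)
    freq_ip = _kmer_frequencies(ip, k)
    with np.errstate(divide="ignore", invalid="ignore"):
        enr = np.where(freq_in.values > 0, freq_ip.values / freq_in.values, np.nan)
    df = pd.DataFrame(
        {
            "kmer": freq_in.index,
            "freq_input": freq_in.values,
            "freq_ip": freq_ip.values,
            "enrichment": enr,
        }
    )
    df = df.sort_values(
        ["enrichment", "kmer"], ascending=[False, True], na_position="last"
    ).reset_index(drop=True)
    df["rank"] = np.arange(1, len(df) + 1)
    return df


def five_prime_nucleotide_enrichment(
    ip: CountTable, input_: CountTable, exclude_nac: bool = False
) -> pd.Series:
    """log2 enrichment of each 5'-nucleotide in IP over input.

    For each nucleotide ``n`` the value is
    ``log2(fraction of IP molecules starting with n / same fraction in
    input)``.  With ``exclude_nac`` set, molecules whose positions 2-3 read
    ``AC`` are removed from both libraries first — the re-analysis that asks
    whether 5'-G preference survives outside the NAC context.  Undefined
    values (zero fraction in either library, or empty library after
    filtering) are NaN.
    """
    _require_nonempty(ip, input_)

    def fractions(table: CountTable) -> pd.Series:
        counts = dict.fromkeys(NUCLEOTIDES, 0)
        total = 0
        for seq, count in table.counts.items():
            if exclude_nac and seq[1:3] == "AC":
                continue
            counts[seq[0]] += count
            total += count
        if total == 0:
            return pd.Series({nt: np.nan for nt in NUCLEOTIDES})
        return pd.Series({nt: counts[nt] / total for nt in NUCLEOTIDES})

    f_in = fractions(input_)
    f_ip = fractions(ip)
    with np.errstate(divide="ignore", invalid="ignore"):
        values = np.where(
            (f_in.values > 0) & (f_ip.values > 0),
            np.log2(f_ip.values / f_in.values),
            np.nan,
        )
    return pd.Series(values, index=list(NUCLEOTIDES), name="log2_enrichment")


@dataclass
class EndogenousSummary:
    """Top-abundance extraction of an endogenous small-RNA library."""

    selected: pd.DataFrame  # sequence, count, fraction, cumulative_fraction
    motif: str
    motif_presence: int
    probability_matrix: pd.DataFrame  # position x nucleotide, rows sum to 1


def endogenous_summary(
    library: CountTable,
    top_fraction: float = 0.70,
    motif: str = "GTC",
    logo_length: int = 21,
    mode: str = "cumulative",
) -> EndogenousSummary:
    """Summarize an endogenous AGO-IP library: top sequences, motif, logo.

    Sequences are sorted by descending abundance; the selected set is the
    smallest prefix whose cumulative abundance fraction reaches
    ``top_fraction`` (``mode="cumulative"``, default) or the top
    ``top_fraction`` share of distinct sequences (``mode="distinct"``).
    ``motif_presence`` counts selected sequences containing ``motif`` as a
    substring.  The probability matrix covers positions 1..``logo_length``;
    sequences shorter than a position simply do not contribute there.
    """
    if library.total_molecules == 0:
        raise EnrichmentError("empty library")
    if not 0 < top_fraction <= 1:
        raise EnrichmentError("top_fraction must be in (0, 1]")
    items = sorted(library.counts.items(), key=lambda kv: (-kv[1], kv[0]))
    total = library.total_molecules
    df = pd.DataFrame(items, columns=["sequence", "count"])
    df["fraction"] = df["count"] / total
    df["cumulative_fraction"] = df["fraction"].cumsum()
    if mode == "cumulative":
        cutoff = int(np.searchsorted(df["cumulative_fraction"].values, top_fraction))
        selected = df.iloc[: cutoff + 1].reset_index(drop=True)
    elif mode == "distinct":
        n_sel = max(1, int(np.ceil(top_fraction * len(df))))
        selected = df.iloc[:n_sel].reset_index(drop=True)
    else:
        raise EnrichmentError(f"unknown mode {mode!r}")

    presence = int(selected["sequence"].str.contains(motif, regex=False).sum())

    counts = np.zeros((logo_length, 4))
    nt_index = {nt: i for i, nt in enumerate(NUCLEOTIDES)}
    for seq, count in zip(selected["sequence"], selected["count"]):
        for pos in range(min(len(seq), logo_length)):
            counts[pos, nt_index[seq[pos]]] += count
    totals = counts.sum(axis=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        probs = np.where(totals > 0, counts / totals, np.nan)
    matrix = pd.DataFrame(
        probs,
        index=pd.RangeIndex(1, logo_length + 1, name="position"),
        columns=list(NUCLEOTIDES),
    )
    return EndogenousSummary(selected, motif, presence, matrix)
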