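"""Pairwise positional-interaction analysis of the 8-nt randomized design.

With 65,536 possible 8-mers, per-sequence enrichment factors are too noisy
to compare individually, so interactions between nucleotides at pairs of
positions are estimated instead.  The full space is scanned in 4-position
windows (C(8,4) = 70 of them): molecules are projected onto each window's
positions, a log2 IP/input enrichment is computed per projected 4-mer, and
within the window every (position-pair, nucleotide-pair) indicator is
screened by univariate linear regression (P < alpha).  Screened terms enter
a bidirectional stepwise selection of a joint linear model driven by an
information criterion; coefficients of the terms the joint model retains
are finally averaged over all windows in which they were retained.

A planted interaction (say G at position 1 with A at position 2) surfaces
as a positive averaged coefficient for that (1,G)x(2,A) term.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
import statsmodels.api as sm

from .design import NUCLEOTIDES
from .dedup import CountTable


class PairwiseError(ValueError):
    pass


def enumerate_windows(length: int = 8, window_size: int = 4) -> list[tuple[int, ...]]:
    """All strictly increasing position subsets (1-based), lexicographic."""
    if window_size > length:
        raise PairwiseError(
            f"window_size={window_size} exceeds sequence length {length}"
        )
    return list(itertools.combinations(range(1, length + 1), window_size))


_NT_CODE = {nt: i for i, nt in enumerate(NUCLEOTIDES)}


def _encode(table: CountTable) -> tuple[np.ndarray, np.ndarray]:
    """Encode a count table as a (n_seq, L) base-code matrix + count vector."""
    seqs = list(table.counts)
    counts = np.fromiter((table.counts[s] for s in seqs), dtype=float, count=len(seqs))
    length = table.variable_length
    flat = np.frombuffer("".join(seqs).encode(), dtype=np.uint8).reshape(-1, length)
    codes = np.zeros_like(flat)
    for nt, code in _NT_CODE.items():
        codes[flat == ord(nt)] = code
    return codes, counts


def _project(codes: np.ndarray, counts: np.ndarray, window: tuple[int, ...]) -> np.ndarray:
    """Aggregate counts onto the window's positions -> length 4**w vector."""
    w = len(window)
    cols = codes[:, [p - 1 for p in window]].astype(np.int64)
    powers = 4 ** np.arange(w - 1, -1, -1)
    idx = cols @ powers
    return np.bincount(idx, weights=counts, minlength=4 ** w)


def _index_to_kmer(idx: int, w: int) -> str:
    out = []
    for shift in range(w - 1, -1, -1):
        out.append(NUCLEOTIDES[(idx >> (2 * shift)) & 3])
    return "".join(out)


@dataclass
class WindowDataset:
    """Per-window regression dataset.

    ``kmers`` are the projected 4-mers observed in both libraries;
    ``response`` is their log2(IP fraction / input fraction);
    ``weight`` is the input molecule count behind each 4-mer.
    """

    window: tuple[int, ...]
    kmers: list[str]
    response: np.ndarray
    weight: np.ndarray

    def __len__(self) -> int:
        return len(self.kmers)


def build_window_dataset(
    ip: CountTable, input_: CountTable, window: tuple[int, ...]
) -> WindowDataset:
    """Project both libraries onto a window and form the log2 responses.

    4-mers with a zero count in either library are omitted (their log ratio
    is undefined).
    """
    enc_ip = _encode(ip)
    enc_in = _encode(input_)
    return _build_window_dataset_encoded(enc_ip, enc_in, window)


def _build_window_dataset_encoded(enc_ip, enc_in, window) -> WindowDataset:
    v_ip = _project(*enc_ip, window)
    v_in = _project(*enc_in, window)
    valid = (v_ip > 0) & (v_in > 0)
    frac_ip = v_ip / v_ip.sum()
    frac_in = v_in / v_in.sum()
    idx = np.nonzero(valid)[0]
    response = np.log2(frac_ip[idx] / frac_in[idx])
    w = len(window)
    kmers = [_index_to_kmer(int(i), w) for i in idx]
    return WindowDataset(tuple(window), kmers, response, v_in[idx])


@dataclass(frozen=True)
class TermKey:
    """A (position, nucleotide) x (position, nucleotide) interaction term."""

    pos_i: int
    nt_a: str
    pos_j: int
    nt_b: str


@dataclass
class SelectedTerm:
    key: TermKey
    coefficient: float
    p_screen: float


def _term_indicators(dataset: WindowDataset) -> dict[TermKey, np.ndarray]:
    """Indicator vectors for the 6 slot-pairs x 16 nucleotide-pairs."""
    window = dataset.window
    m = len(dataset)
    codes = np.zeros((m, len(window)), dtype=np.uint8)
    for row, kmer in enumerate(dataset.kmers):
        for slot, base in enumerate(kmer):
            codes[row, slot] = _NT_CODE[base]
    indicators: dict[TermKey, np.ndarray] = {}
    for s1, s2 in itertools.combinations(range(len(window)), 2):
        for a, b in itertools.product(NUCLEOTIDES, repeat=2):
            key = TermKey(window[s1], a, window[s2], b)
            indicators[key] = (
                (codes[:, s1] == _NT_CODE[a]) & (codes[:, s2] == _NT_CODE[b])
            ).astype(float)
    return indicators


def screen_and_select(
    dataset: WindowDataset,
    alpha: float = 0.1,
    weighted: bool = False,
    criterion: str = "aic",
) -> list[SelectedTerm]:
    """Two-stage term selection within one window.

    Stage 1 screens every (position-pair, nucleotide-pair) indicator by a
    univariate linear regression of the responses on the indicator, keeping
    terms with a two-sided slope p-value below ``alpha`` (no multiplicity
    correction — the screen is intentionally permissive).  Stage 2 runs
    bidirectional stepwise selection over the screened terms, minimizing AIC
    (or BIC) of the joint linear model, and reports the retained terms with
    their joint-model coefficients.
    """
    if len(dataset) < 3:
        raise PairwiseError("window dataset has fewer than 3 responses")
    y = dataset.response
    indicators = _term_indicators(dataset)

    screened: list[tuple[TermKey, float]] = []
    for key, x in indicators.items():
        if x.min() == x.max():  # degenerate: indicator constant in this dataset
            warnings.warn(f"constant indicator skipped: {key}", stacklevel=2)
            continue
        res = stats.linregress(x, y)
        if res.pvalue < alpha:
            screened.append((key, res.pvalue))
    if not screened:
        return []

    keys = [k for k, _ in screened]
    pvals = dict(screened)
    X_all = np.column_stack([indicators[k] for k in keys])
    w = dataset.weight if weighted else None

    def fit(active: tuple[int, ...]):
        X = sm.add_constant(X_all[:, list(active)]) if active else np.ones((len(y), 1))
        model = sm.WLS(y, X, weights=w) if w is not None else sm.OLS(y, X)
        return model.fit()

    def score(result) -> float:
        return result.bic if criterion == "bic" else result.aic

    active = tuple(range(len(keys)))
    current = fit(active)
    current_score = score(current)
    while True:
        best_move = None
        best_score = current_score
        for i in active:  # backward: drop one term
            cand = tuple(j for j in active if j != i)
            s = score(fit(cand))
            if s < best_score - 1e-9:
                best_score, best_move = s, cand
        for i in range(len(keys)):  # forward: re-add a screened term
            if i not in active:
                cand = tuple(sorted(active + (i,)))
                s = score(fit(cand))
                if s < best_score - 1e-9:
                    best_score, best_move = s, cand
        if best_move is None:
            break
        active, current_score = best_move, best_score
        current = fit(active)

    coefs = current.params[1:] if active else []
    return [
        SelectedTerm(keys[i], float(c), pvals[keys[i]])
        for i, c in zip(active, coefs)
    ]


def average_coefficients(
    per_window_selections: list[list[SelectedTerm]],
) -> pd.DataFrame:
    """Average each retained term's coefficient over the windows retaining it.

    Windows where a term was not retained do not contribute (no
    zero-filling).  Returns a DataFrame with columns ``pos_i, nt_a, pos_j,
    nt_b, mean_coefficient, n_windows_retained`` sorted by positions.
    """
    acc: dict[TermKey, list[float]] = {}
    for selection in per_window_selections:
        for term in selection:
            acc.setdefault(term.key, []).append(term.coefficient)
    rows = [
        {
            "pos_i": key.pos_i,
            "nt_a": key.nt_a,
            "pos_j": key.pos_j,
            "nt_b": key.nt_b,
            "mean_coefficient": float(np.mean(coefs)),
            "n_windows_retained": len(coefs),
        }
        for key, coefs in acc.items()
    ]
    df = pd.DataFrame(
        rows,
        columns=["pos_i", "nt_a", "pos_j", "nt_b", "mean_coefficient", "n_windows_retained"],
    )
    if len(df):
        df = df.sort_values(["pos_i", "pos_j", "nt_a", "nt_b"]).reset_index(drop=True)
    return df


def pairwise_interaction_analysis(
    ip: CountTable,
    input_: CountTable,
    alpha: float = 0.1,
    window_size: int = 4,
    weighted: bool = False,
    criterion: str = "aic",
) -> pd.DataFrame:
    """Full windowed pairwise-interaction analysis of an IP/input pair."""
    length = ip.variable_length
    if input_.variable_length != length:
        raise PairwiseError("libraries have different variable-region lengths")
    enc_ip = _encode(ip)
    enc_in = _encode(input_)
    selections = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for window in enumerate_windows(length, window_size):
            dataset = _build_window_dataset_encoded(enc_ip, enc_in, window)
            if len(dataset) < 3:
                continue
            selections.append(
                screen_and_select(dataset, alpha=alpha, weighted=weighted,
                                  criterion=criterion)
            )
    return average_coefficients(selections)


def interaction_matrix(averaged: pd.DataFrame, length: int = 8) -> pd.DataFrame:
    """Pivot averaged coefficients into a (L*4) x (L*4) matrix for heatmaps."""
    labels = [f"{pos}{nt}" for pos in range(1, length + 1) for nt in NUCLEOTIDES]
    mat = pd.DataFrame(np.nan, index=labels, columns=labels)
    for row in averaged.itertuples():
        a = f"{row.pos_i}{row.nt_a}"
        b = f"{row.pos_j}{row.nt_b}"
        mat.loc[a, b] = row.mean_coefficient
        mat.loc[b, a] = row.mean_coefficient
    return mat
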