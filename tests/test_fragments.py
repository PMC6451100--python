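"""mRNA-fragment filter cascade and per-frame motif enrichment."""

import io
import math

import numpy as np
import pytest

from hissa import (
    AnnotationBundle,
    GenomicRead,
    filter_cascade,
    frame_motif_counts,
    motif_enrichment,
    simulate_fragment_fixture,
)
from hissa.fragments import (
    FragmentError,
    combine_frames,
    read_bed,
    reverse_complement,
)
from hissa.simulate import FIXTURE_VIOLATIONS


def series(counts):
    import pandas as pd
    from hissa.enrichment import all_kmers
    s = pd.Series(0.0, index=all_kmers(3))
    for k, v in counts.items():
        s[k] = v
    return s


class TestFrameMotifs:
    def test_frame_definition(self):
        read = GenomicRead("chr2L", 0, 8, "+", sequence="GACGATTG")
        tables, skipped = frame_motif_counts([read])
        assert skipped == 0
        assert tables[1]["GAC"] == 1
        assert tables[2]["ACG"] == 1
        assert tables[3]["CGA"] == 1

    def test_sixty_four_slots_per_frame(self):
        read = GenomicRead("chr2L", 0, 8, "+", sequence="GACGATTG")
        tables, _ = frame_motif_counts([read])
        for f in (1, 2, 3):
            assert len(tables[f]) == 64

    def test_read_count_weighting_and_conservation(self):
        reads = [
            GenomicRead("chr2L", 0, 8, "+", sequence="GACGATTG", read_count=5),
            GenomicRead("chr2L", 10, 18, "+", sequence="AAAAAAAA", read_count=2),
        ]
        tables, _ = frame_motif_counts(reads)
        for f in (1, 2, 3):
            assert tables[f].sum() == 7

    def test_combined_frames_additive(self):
        reads = [GenomicRead("chr2L", 0, 8, "+", sequence="GACGATTG")]
        tables, _ = frame_motif_counts(reads)
        combined = combine_frames(tables)
        assert combined.sum() == sum(t.sum() for t in tables.values())
        assert combined["GAC"] == 1

    def test_short_read_skipped_per_frame(self):
        read = GenomicRead("chr2L", 0, 4, "+", sequence="GACG")
        tables, skipped = frame_motif_counts([read])
        assert tables[1]["GAC"] == 1 and tables[2]["ACG"] == 1
        assert skipped == 1  # frame 3 needs 5 nt

    def test_minus_strand_reference_sequence_reoriented(self):
        # stored plus-strand genomic sequence of a minus-strand read must be
        # reverse-complemented on load; frame motifs are then identical to a
        # plus-strand read carrying the read-orientation sequence directly
        seq = "GACGATTG"
        bed_plus = f"chr2L\t0\t8\tr1\t1\t+\t{seq}\t1\n"
        bed_minus = f"chr2L\t0\t8\tr2\t1\t-\t{reverse_complement(seq)}\t1\n"
        plus = read_bed(io.StringIO(bed_plus), sequence_orientation="reference")
        minus = read_bed(io.StringIO(bed_minus), sequence_orientation="reference")
        t_plus, _ = frame_motif_counts(plus)
        t_minus, _ = frame_motif_counts(minus)
        for f in (1, 2, 3):
            assert (t_plus[f] == t_minus[f]).all()


class TestFilterCascade:
    def test_fixture_survivors_exact(self):
        fixture = simulate_fragment_fixture(
            seed=0, n_survivors_ip=6,
            violations=("outside_gene", "mirna", "multimapper", "length21"),
        )
        assert len(fixture.ip_reads) == 10
        survivors, attrition = filter_cascade(
            fixture.ip_reads, fixture.annotations
        )
        assert sorted(r.read_id for r in survivors) == sorted(
            fixture.expected_ip_survivors
        )

    def test_all_violation_types_removed(self):
        fixture = simulate_fragment_fixture(
            seed=3, n_survivors_ip=5, violations=FIXTURE_VIOLATIONS
        )
        survivors, attrition = filter_cascade(fixture.ip_reads, fixture.annotations)
        assert sorted(r.read_id for r in survivors) == sorted(
            fixture.expected_ip_survivors
        )
        removed = attrition.set_index("stage")["removed"]
        assert removed["gene_loci"] == 1
        assert removed["mirna"] == removed["sirna"] == removed["pirna"] == 1
        assert removed["repeatmasker"] == 1
        assert removed["multimappers"] == 1
        assert removed["staggered"] == 2  # both reads of the duplex pair
        assert removed["length_21"] == 1

    def test_attrition_monotone(self):
        fixture = simulate_fragment_fixture(seed=5, violations=FIXTURE_VIOLATIONS)
        _, attrition = filter_cascade(fixture.ip_reads, fixture.annotations)
        kept = attrition["kept"].tolist()
        assert all(a >= b for a, b in zip(kept, kept[1:]))
        assert (attrition["kept"] + attrition["removed"].cumsum()
                == attrition.loc[0, "kept"]).all()

    def test_missing_pirna_stage_skipped_with_warning(self):
        fixture = simulate_fragment_fixture(seed=1, violations=("pirna",))
        bundle = AnnotationBundle(
            gene_loci=fixture.annotations.gene_loci,
            mirna=fixture.annotations.mirna,
            sirna=fixture.annotations.sirna,
            pirna=None,
            repeatmasker=fixture.annotations.repeatmasker,
        )
        with pytest.warns(UserWarning, match="pirna"):
            survivors, attrition = filter_cascade(fixture.ip_reads, bundle)
        row = attrition.set_index("stage").loc["pirna"]
        assert bool(row["skipped"]) and row["removed"] == 0
        # without the piRNA annotation the violating read survives
        assert "ip_pirna" in {r.read_id for r in survivors}

    def test_21nt_read_removed_after_annotation_filters(self):
        fixture = simulate_fragment_fixture(seed=2, violations=("length21",))
        survivors, _ = filter_cascade(fixture.ip_reads, fixture.annotations)
        assert "ip_len21" not in {r.read_id for r in survivors}


def brute_force_fisher(a, b, c, d):
    """Two-sided Fisher p by explicit hypergeometric summation (exact
    integer arithmetic): sum the probabilities of all same-margin tables
    whose probability does not exceed the observed one."""
    r1, r2, n1 = a + b, c + d, a + c
    N = r1 + r2
    denom = math.comb(N, n1)
    probs = [
        math.comb(r1, x) * math.comb(r2, n1 - x)
        for x in range(max(0, n1 - r2), min(r1, n1) + 1)
    ]
    p_obs = math.comb(r1, a) * math.comb(r2, n1 - a)
    # integer comparison with a tiny relative tolerance as used by the
    # conventional two-sided rule
    return sum(p for p in probs if p <= p_obs + 1e-7 * p_obs) / denom


class TestMotifEnrichment:
    def test_hand_fold_and_exact_p(self):
        ip = series({"GAC": 10, "AAA": 90})
        inp = series({"GAC": 5, "AAA": 95})
        df = motif_enrichment(ip, inp).set_index("motif")
        assert df.loc["GAC", "fold_enrichment"] == pytest.approx(2.0)
        assert df.loc["GAC", "p_value"] == pytest.approx(
            brute_force_fisher(10, 90, 5, 95), abs=1e-12
        )

    def test_identical_tables_unit_fold(self):
        t = series({"GAC": 10, "AAA": 90})
        df = motif_enrichment(t, t)
        observed = df[df["count_ip"] > 0]
        assert np.allclose(observed["fold_enrichment"], 1.0)
        assert np.allclose(observed["p_value"], 1.0)

    def test_absent_motif_undefined_fold_unit_p(self):
        ip = series({"AAA": 10})
        inp = series({"AAA": 10})
        df = motif_enrichment(ip, inp).set_index("motif")
        assert np.isnan(df.loc["GGG", "fold_enrichment"])
        assert df.loc["GGG", "p_value"] == 1.0

    def test_planted_frame1_gac_bias_detected(self):
        hits = 0
        for seed in range(20):
            fixture = simulate_fragment_fixture(
                seed=400 + seed, n_survivors_ip=3000, n_survivors_input=3000,
                violations=(), gac_bias=2.0,
            )
            ip_surv, _ = filter_cascade(fixture.ip_reads, fixture.annotations)
            in_surv, _ = filter_cascade(fixture.input_reads, fixture.annotations)
            ip_tables, _ = frame_motif_counts(ip_surv)
            in_tables, _ = frame_motif_counts(in_surv)
            df = motif_enrichment(ip_tables[1], in_tables[1]).set_index("motif")
            hits += df.loc["GAC", "fold_enrichment"] > 1
        assert hits >= 19


def test_bed_round_trip(tmp_path):
    from hissa.simulate import write_bed
    fixture = simulate_fragment_fixture(seed=9, violations=("multimapper",))
    path = tmp_path / "reads.bed"
    write_bed(fixture.ip_reads, path)
    loaded = read_bed(path)
    assert len(loaded) == len(fixture.ip_reads)
    by_id = {r.read_id: r for r in loaded}
    assert by_id["ip_multi"].mapping_multiplicity == 3
    original = {r.read_id: r for r in fixture.ip_reads}
    for rid, r in by_id.items():
        assert (r.chrom, r.start, r.end, r.strand, r.sequence) == (
            original[rid].chrom, original[rid].start, original[rid].end,
            original[rid].strand, original[rid].sequence,
        )
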