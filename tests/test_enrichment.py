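"""Per-sequence, per-position, k-mer and 5'-nucleotide enrichment."""

import numpy as np
import pytest

from hissa import (
    CountTable,
    EffectModel,
    endogenous_summary,
    five_prime_nucleotide_enrichment,
    gac_model,
    kmer_enrichment,
    per_position_enrichment,
    per_sequence_enrichment,
    simulate_count_tables,
    five_n_design,
    eight_n_design,
)
from hissa.enrichment import EnrichmentError


def table(counts, label=""):
    return CountTable(dict(counts), label)


class TestPerSequence:
    def test_identity_gives_unit_factors(self):
        t = table({"AAAAA": 10, "GACGA": 30})
        df = per_sequence_enrichment(t, t)
        assert np.allclose(df["enrichment_factor"], 1.0)

    def test_hand_arithmetic(self):
        inp = table({"AAAAA": 900, "GGGGG": 100})
        ip = table({"AAAAA": 500, "GGGGG": 500})
        df = per_sequence_enrichment(ip, inp).set_index("sequence")
        assert df.loc["GGGGG", "enrichment_factor"] == pytest.approx(5.0)
        assert df.loc["AAAAA", "enrichment_factor"] == pytest.approx(0.5556, abs=5e-5)
        assert df.loc["GGGGG", "rank"] == 1

    def test_ranks_are_permutation(self):
        design = five_n_design()
        ip, inp = simulate_count_tables(design, gac_model(), 20000, 20000, seed=3)
        df = per_sequence_enrichment(ip, inp)
        ranked = df[df["rank"].notna()]
        assert sorted(ranked["rank"]) == list(range(1, len(ranked) + 1))
        assert len(df) <= 1024

    def test_absent_sequences_unranked(self):
        inp = table({"AAAAA": 5, "CCCCC": 5})
        ip = table({"AAAAA": 5})
        df = per_sequence_enrichment(ip, inp).set_index("sequence")
        assert np.isnan(df.loc["CCCCC", "enrichment_factor"])
        assert np.isnan(df.loc["CCCCC", "rank"])

    def test_empty_library_rejected(self):
        with pytest.raises(EnrichmentError):
            per_sequence_enrichment(table({}), table({"AAAAA": 1}))

    def test_scale_invariance(self):
        inp = table({"AAAAA": 900, "GGGGG": 100})
        ip = table({"AAAAA": 500, "GGGGG": 500})
        scaled = table({k: v * 17 for k, v in ip.counts.items()})
        a = per_sequence_enrichment(ip, inp)["enrichment_factor"]
        b = per_sequence_enrichment(scaled, inp)["enrichment_factor"]
        assert np.allclose(a, b)


class TestPerPosition:
    def test_identity_zero_log_ratio(self):
        t = table({"AAAAA": 1, "GACGA": 2, "TTTTT": 3})
        matrix = per_position_enrichment(t, t)
        defined = matrix.log2_ratio.values[~np.isnan(matrix.log2_ratio.values)]
        assert np.allclose(defined, 0.0)

    def test_hand_arithmetic(self):
        inp = table({"AAAAA": 50, "GAAAA": 50})
        ip = table({"AAAAA": 25, "GAAAA": 75})
        matrix = per_position_enrichment(ip, inp)
        assert matrix.log2_ratio.loc[1, "A"] == pytest.approx(-1.0)
        assert matrix.log2_ratio.loc[1, "G"] == pytest.approx(0.585, abs=5e-4)

    def test_percentages_sum_to_100(self):
        design = eight_n_design()
        ip, inp = simulate_count_tables(design, EffectModel(), 5000, 5000, seed=1)
        matrix = per_position_enrichment(ip, inp)
        assert np.allclose(matrix.percent_input.sum(axis=1), 100.0)
        assert np.allclose(matrix.percent_ip.sum(axis=1), 100.0)

    def test_zero_input_cell_flagged_nan(self):
        inp = table({"AAAAA": 10})  # no G anywhere in input
        ip = table({"AAAAA": 5, "GAAAA": 5})
        matrix = per_position_enrichment(ip, inp)
        assert np.isnan(matrix.log2_ratio.loc[1, "G"])

    def test_planted_positive_weight_recovered(self):
        # G at position 1 with weight x2 must surface as positive log2 ratio
        design = eight_n_design()
        model = EffectModel(single_effects={(1, "G"): 2.0})
        hits = 0
        for seed in range(20):
            ip, inp = simulate_count_tables(design, model, 100_000, 100_000,
                                            seed=seed)
            matrix = per_position_enrichment(ip, inp)
            hits += matrix.log2_ratio.loc[1, "G"] > 0
        assert hits >= 19


class TestKmer:
    def test_identity_unit_enrichment(self):
        t = table({"GACGATTG": 4, "AAAAAAAA": 1})
        df = kmer_enrichment(t, t, 3)
        defined = df["enrichment"].dropna()
        assert np.allclose(defined, 1.0)

    def test_window_combinatorics(self):
        t = table({"GACGA": 1})
        df = kmer_enrichment(t, t, 3)
        assert len(df) == 64
        # 3 windows per 5-mer: GAC, ACG, CGA
        observed = df[df["freq_input"] > 0]["kmer"].tolist()
        assert sorted(observed) == ["ACG", "CGA", "GAC"]

    def test_frequencies_sum_to_one(self):
        design = five_n_design()
        ip, inp = simulate_count_tables(design, gac_model(), 5000, 5000, seed=2)
        df = kmer_enrichment(ip, inp, 3)
        assert df["freq_input"].sum() == pytest.approx(1.0)
        assert df["freq_ip"].sum() == pytest.approx(1.0)

    def test_k_too_large_rejected(self):
        t = table({"GACGA": 1})
        with pytest.raises(EnrichmentError):
            kmer_enrichment(t, t, 6)

    def test_planted_ggg_ranks_first(self):
        # global G preference makes GGG the top 3-mer (G-richness readout)
        design = five_n_design()
        model = EffectModel(motif_effects={("GGG", "any"): 4.0})
        hits = 0
        for seed in range(20):
            ip, inp = simulate_count_tables(design, model, 100_000, 100_000,
                                            seed=100 + seed)
            df = kmer_enrichment(ip, inp, 3)
            hits += df.iloc[0]["kmer"] == "GGG"
        assert hits >= 19


class TestFivePrime:
    def test_identity_all_zero(self):
        t = table({"AACGA": 1, "GACGA": 2, "CACGA": 3, "TACGA": 4})
        series = five_prime_nucleotide_enrichment(t, t)
        assert np.allclose(series.dropna(), 0.0)

    def test_hand_arithmetic(self):
        inp = table({"AAAAA": 25, "CAAAA": 25, "GAAAA": 25, "TAAAA": 25})
        ip = table({"AAAAA": 20, "CAAAA": 20, "GAAAA": 40, "TAAAA": 20})
        series = five_prime_nucleotide_enrichment(ip, inp)
        assert series["G"] == pytest.approx(0.678, abs=5e-4)
        assert series["A"] == pytest.approx(np.log2(0.8), abs=1e-9)

    def test_exclude_nac_degenerate(self):
        # only NAC-context sequences: the filtered libraries are empty
        t = table({"GACAA": 1, "TACAA": 1})
        series = five_prime_nucleotide_enrichment(t, t, exclude_nac=True)
        assert series.isna().all()

    def test_exclude_nac_removes_gac_contribution(self):
        design = five_n_design()
        hits = 0
        for seed in range(10):
            ip, inp = simulate_count_tables(design, gac_model(3.0),
                                            100_000, 100_000, seed=seed)
            with_nac = five_prime_nucleotide_enrichment(ip, inp)
            without = five_prime_nucleotide_enrichment(ip, inp, exclude_nac=True)
            hits += without["G"] < with_nac["G"]
        assert hits >= 9


class TestEndogenousSummary:
    def test_cumulative_selection_rule(self):
        lib = table({"AAAAA": 70, "CCCCC": 20, "GGGGG": 10})
        summary = endogenous_summary(lib, top_fraction=0.70)
        assert summary.selected["sequence"].tolist() == ["AAAAA"]

    def test_motif_presence_count(self):
        lib = table({"TGTCA": 60, "AAAAA": 40})
        summary = endogenous_summary(lib, top_fraction=1.0, motif="GTC")
        assert summary.motif_presence == 1

    def test_identical_sequences_indicator_matrix(self):
        lib = table({"GACGA": 10})
        summary = endogenous_summary(lib, top_fraction=1.0, logo_length=5)
        for pos, base in enumerate("GACGA", start=1):
            assert summary.probability_matrix.loc[pos, base] == 1.0

    def test_heterogeneous_lengths_supported(self):
        lib = table({"GACGATTGACGATTGACGATTGACG": 50, "GTC": 50})
        summary = endogenous_summary(lib, top_fraction=1.0, logo_length=21)
        # short sequence contributes only to positions it covers
        assert summary.probability_matrix.loc[4].sum() == pytest.approx(1.0)
        assert summary.motif_presence == 1

    def test_empty_library_rejected(self):
        with pytest.raises(EnrichmentError):
            endogenous_summary(table({}))
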