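import numpy as np
import pytest

from thtargets import (
    DR4_PATTERN,
    ScanConfig,
    SimConfig,
    build_motif,
    reverse_complement,
    scan_promoter,
    scan_set,
    simulate,
)
from conftest import naive_scan


def random_seq(rng, n):
    return "".join(rng.choice(list("ACGT"), size=n))


class TestScanPromoter:
    def test_exact_match_forward(self):
        hits = scan_promoter(
            "AGGTCATTTTAGGTCA", ScanConfig(max_mismatch=0, strands="forward_only")
        )
        assert len(hits) == 1
        h = hits[0]
        assert (h.start, h.strand, h.mismatches) == (0, "+", 0)
        assert h.matched_seq == "AGGTCATTTTAGGTCA"

    def test_reverse_strand_hit_reports_forward_coordinate(self):
        seq = reverse_complement("AGGTCATTTTAGGTCA")  # TGACCTAAAATGACCT
        hits = scan_promoter(seq, ScanConfig(max_mismatch=0))
        assert len(hits) == 1
        assert (hits[0].start, hits[0].strand) == (0, "-")
        assert hits[0].matched_seq == "AGGTCATTTTAGGTCA"

    def test_spacer_positions_are_free(self):
        for spacer in ("AAAA", "GCGC", "TTTT"):
            seq = f"AGGTCA{spacer}AGGTCA"
            hits = scan_promoter(seq, ScanConfig(max_mismatch=0, strands="forward_only"))
            assert [h.mismatches for h in hits] == [0]

    def test_sequence_n_counts_as_mismatch(self):
        seq = "NGGTCATTTTAGGTCA"
        assert scan_promoter(seq, ScanConfig(max_mismatch=0, strands="forward_only")) == []
        hits = scan_promoter(seq, ScanConfig(max_mismatch=1, strands="forward_only"))
        assert [h.mismatches for h in hits] == [1]

    def test_short_sequence_yields_empty(self):
        assert scan_promoter("AGGTCA", ScanConfig()) == []

    def test_illegal_characters_rejected(self):
        with pytest.raises(ValueError, match="illegal"):
            scan_promoter("AGGTCAXTTTAGGTCA", ScanConfig())

    @pytest.mark.parametrize("budget", [0, 1, 2, 3, 4])
    @pytest.mark.parametrize("strands", ["forward_only", "both"])
    def test_matches_bruteforce_oracle_on_random_sequences(self, budget, strands):
        rng = np.random.default_rng(97)
        for _ in range(100):
            seq = random_seq(rng, 1000)
            cfg = ScanConfig(max_mismatch=budget, strands=strands)
            got = [
                (h.start, h.strand, h.matched_seq, h.mismatches)
                for h in scan_promoter(seq, cfg)
            ]
            assert got == naive_scan(seq, DR4_PATTERN, budget, strands == "both")

    def test_strand_involution(self):
        # scanning the reverse complement maps hits via start -> n-16-start
        # with strands flipped
        rng = np.random.default_rng(3)
        seq = random_seq(rng, 500)
        cfg = ScanConfig(max_mismatch=3)
        fwd = {(h.start, h.strand, h.mismatches) for h in scan_promoter(seq, cfg)}
        rc = {
            (len(seq) - 16 - h.start, {"+": "-", "-": "+"}[h.strand], h.mismatches)
            for h in scan_promoter(reverse_complement(seq), cfg)
        }
        assert fwd == rc

    def test_budget_monotonicity(self):
        rng = np.random.default_rng(12)
        seq = random_seq(rng, 2000)
        small = {
            (h.start, h.strand)
            for h in scan_promoter(seq, ScanConfig(max_mismatch=2))
        }
        large = {
            (h.start, h.strand)
            for h in scan_promoter(seq, ScanConfig(max_mismatch=4))
        }
        assert small <= large


class TestScanSet:
    def test_empty_promoter_set(self):
        table = scan_set({}, ScanConfig())
        assert len(table) == 0
        assert list(table.columns) == [
            "gene_id", "start", "end", "matched_seq", "mismatches", "strand",
        ]

    def test_planted_elements_recovered_best_per_gene(self):
        cfg = SimConfig(
            n_genes=100, planted_mismatches=0, promoter_length=1000, seed=31
        )
        _, truth, promoters = simulate(cfg)
        direct = truth.direct_genes
        hits = scan_set(
            {g: promoters[g] for g in direct},
            ScanConfig(max_mismatch=0, window_bp=1000),
            mode="best_per_gene",
        )
        assert set(hits["gene_id"]) == set(direct)
        for _, row in hits.iterrows():
            assert row["start"] == truth.table.at[row["gene_id"], "tre_pos"]
            assert row["strand"] == truth.table.at[row["gene_id"], "tre_strand"]

    def test_best_per_gene_prefers_fewest_mismatches_then_leftmost(self):
        # perfect element at 40, 1-mismatch element at 0
        rng = np.random.default_rng(8)
        perfect = "AGGTCAGGGGAGGTCA"
        off = "CGGTCAGGGGAGGTCA"
        seq = off + random_seq(rng, 24) + perfect + random_seq(rng, 20)
        hits = scan_set({"g": seq}, ScanConfig(max_mismatch=4), mode="best_per_gene")
        assert len(hits) == 1
        assert hits.at[0, "start"] == 40
        assert hits.at[0, "mismatches"] == 0

    def test_window_limits_scan_to_tss_proximal_bases(self):
        # element sits outside the trailing window -> not reported
        rng = np.random.default_rng(9)
        seq = "AGGTCAGGGGAGGTCA" + random_seq(rng, 200)
        cfg = ScanConfig(max_mismatch=0, window_bp=100)
        assert len(scan_set({"g": seq}, cfg)) == 0
        cfg_full = ScanConfig(max_mismatch=0, window_bp=len(seq))
        assert len(scan_set({"g": seq}, cfg_full)) == 1

    def test_budget_superset_property_on_a_set(self):
        _, truth, promoters = simulate(
            SimConfig(n_genes=40, planted_mismatches=2, promoter_length=500, seed=5)
        )
        t2 = scan_set(promoters, ScanConfig(max_mismatch=2, window_bp=500))
        t4 = scan_set(promoters, ScanConfig(max_mismatch=4, window_bp=500))
        keys2 = set(map(tuple, t2[["gene_id", "start", "strand"]].to_numpy()))
        keys4 = set(map(tuple, t4[["gene_id", "start", "strand"]].to_numpy()))
        assert keys2 <= keys4


class TestBuildMotif:
    def test_invariant_columns_give_two_bits_and_exact_consensus(self):
        motif = build_motif(["AGGTCATTTTAGGTCA"] * 23)
        assert np.allclose(motif.ic, 2.0)
        assert motif.consensus == "AGGTCATTTTAGGTCA"
        assert motif.n_sequences == 23

    def test_uniform_column_gives_zero_bits_and_n(self):
        seqs = [f"AGGTCA{b}TTTAGGTCA" for b in "ACGT"]
        motif = build_motif(seqs)
        assert motif.ic[6] == pytest.approx(0.0)
        assert motif.consensus[6] == "n"

    def test_half_half_column_gives_one_bit_and_lowercase_first_base(self):
        seqs = ["AGGTCAATTTAGGTCA", "AGGTCACTTTAGGTCA"]
        motif = build_motif(seqs)
        assert motif.ic[6] == pytest.approx(1.0)
        # tie at 0.5/0.5 -> first base in A<C<G<T order, lowercase
        assert motif.consensus[6] == "a"

    def test_counts_sum_to_n_sequences_at_every_position(self):
        rng = np.random.default_rng(44)
        seqs = ["".join(rng.choice(list("ACGT"), size=16)) for _ in range(17)]
        motif = build_motif(seqs)
        assert (motif.counts.sum(axis=1) == 17).all()
        assert np.allclose(motif.frequencies.sum(axis=1), 1.0)

    def test_threshold_semantics_upper_and_lower(self):
        # 3 of 4 = 0.75 -> uppercase; 2 of 4 = 0.5 -> lowercase
        seqs = [
            "AGGTCAGGTTAGGTCA",
            "AGGTCAGGTTAGGTCA",
            "AGGTCAGCTTAGGTCA",
            "AGGTCAACTTAGGTCA",
        ]
        motif = build_motif(seqs)
        assert motif.consensus[6] == "G"  # 0.75 exactly
        # position 7 ties G/C at 0.5 each: first base in A<C<G<T order, lowercase
        assert motif.consensus[7] == "c"

    @pytest.mark.parametrize("bad", [[], ["AGGTCA"], ["AGGTCATTTTAGGTCN"]])
    def test_invalid_inputs_rejected(self, bad):
        with pytest.raises(ValueError):
            build_motif(bad)
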