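import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import random_count_table
from oracles import enc_oracle, gc3s_oracle, positional_gc_oracle, rscu_oracle

from cubkit.codon_metrics import (
    CodonCountTable,
    codon_count_matrix,
    count_codons,
    enc_matrix,
    enc_wright,
    pool_counts,
    positional_gc,
    profile_gene,
    profile_table,
    rscu,
    rscu_matrix,
    synonymous_third_base,
)
from cubkit.genetic_code import (
    AA_TO_CODONS,
    CODON_INDEX,
    CODONS,
    DEGENERACY,
    DEGENERATE_AA,
    SYNONYMOUS_CODONS,
)
from cubkit.sequence_io import CodonSeq
from cubkit.synthetic_data import SimulationConfig, simulate_cds


def table_from(counts: dict[str, int], scope="t") -> CodonCountTable:
    arr = np.zeros(64, dtype=int)
    for c, n in counts.items():
        arr[CODON_INDEX[c]] = n
    return CodonCountTable(scope=scope, counts=arr)


class TestCounting:
    def test_direct_count(self):
        t = count_codons(CodonSeq("g", ("ATG", "GCT", "GCT", "TAA")))
        assert t.counts[CODON_INDEX["GCT"]] == 2
        assert t.counts[CODON_INDEX["ATG"]] == 1
        assert t.n_sense == 3  # stop codon excluded from sense total

    def test_empty_raises(self):
        with pytest.raises(ValueError):
            count_codons(CodonSeq("g", ()))

    def test_pooling_is_elementwise_sum(self):
        a = count_codons(CodonSeq("a", ("ATG", "GCT")))
        b = count_codons(CodonSeq("b", ("GCT", "TTT")))
        pooled = a + b
        assert (pooled.counts == a.counts + b.counts).all()
        mat = codon_count_matrix([CodonSeq("a", ("ATG", "GCT")), CodonSeq("b", ("GCT", "TTT"))])
        assert (pool_counts(mat).counts == pooled.counts).all()


class TestRSCU:
    def test_phenylalanine_example(self):
        """Phe counts 3:1 -> RSCU 1.5 and 0.5 (hand-evaluated formula)."""
        vec = rscu(table_from({"TTT": 3, "TTC": 1}))
        assert vec["TTT"] == pytest.approx(1.5)
        assert vec["TTC"] == pytest.approx(0.5)

    def test_single_codon_takes_full_degeneracy(self):
        """Ala used only as GCA -> RSCU(GCA) = 4, siblings 0."""
        vec = rscu(table_from({"GCA": 4}))
        assert vec["GCA"] == pytest.approx(4.0)
        assert vec["GCT"] == pytest.approx(0.0)

    def test_uniform_usage_gives_ones(self):
        counts = {c: 7 for c in AA_TO_CODONS["L"]}
        vec = rscu(table_from(counts))
        for c in AA_TO_CODONS["L"]:
            assert vec[c] == pytest.approx(1.0)

    def test_absent_amino_acid_is_masked(self):
        vec = rscu(table_from({"TTT": 3, "TTC": 1}))
        assert np.isnan(vec["GCA"])

    def test_normalization_sums_to_degeneracy(self):
        """Sum of RSCU over each amino acid equals its degeneracy (1000 tables)."""
        rng = np.random.default_rng(0)
        mat = np.stack([random_count_table(rng).to_numpy() for _ in range(1000)])
        r = rscu_matrix(mat)
        cols = np.array([CODON_INDEX[c] for c in SYNONYMOUS_CODONS])
        for aa in DEGENERATE_AA:
            idx = [list(SYNONYMOUS_CODONS).index(c) for c in AA_TO_CODONS[aa]]
            sums = r[:, idx].sum(axis=1)
            present = ~np.isnan(sums)
            assert np.allclose(sums[present], DEGENERACY[aa], atol=1e-9)

    def test_matches_bruteforce_oracle(self):
        rng = np.random.default_rng(7)
        for _ in range(50):
            counts = random_count_table(rng)
            expected = rscu_oracle(counts.to_dict())
            got = rscu(table_from(counts.to_dict()))
            for c in SYNONYMOUS_CODONS:
                if np.isnan(expected[c]):
                    assert np.isnan(got[c])
                else:
                    assert got[c] == pytest.approx(expected[c], abs=1e-9)

    def test_pooled_equals_summed_counts(self, small_dataset):
        tables = [
            table_from(dict(zip(CODONS, row)), scope=g)
            for g, row in small_dataset.counts.iterrows()
        ]
        via_sum = rscu(pool_counts(small_dataset.counts))
        via_add = rscu(sum(tables[1:], tables[0]))
        pd.testing.assert_series_equal(
            via_sum, via_add, check_names=False, atol=0, rtol=0
        )


class TestENC:
    def test_balanced_two_codon_usage_hand_value(self):
        """Counts (2,2) give F = (4*0.5-1)/3 = 1/3 in every class.

        One amino acid per class, each using two codons twice, makes all
        class means 1/3, so ENC = 2 + 27 + 3 + 15 + 9 = 56 exactly.
        """
        counts = {
            "TTT": 2, "TTC": 2,  # Phe (2-fold)
            "ATT": 2, "ATC": 2,  # Ile (3-fold)
            "GCA": 2, "GCT": 2,  # Ala (4-fold)
            "TTA": 2, "TTG": 2,  # Leu (6-fold)
        }
        assert enc_wright(table_from(counts)) == pytest.approx(56.0, abs=1e-12)

    def test_uniform_gene_caps_at_61(self, uniform_codon_seq):
        assert enc_wright(count_codons(uniform_codon_seq)) == 61.0

    def test_one_codon_per_aa_gives_20(self, one_codon_per_aa_seq):
        assert enc_wright(count_codons(one_codon_per_aa_seq)) == 20.0

    def test_missing_when_class_absent(self):
        """A gene with no 6-fold amino acids at all has undefined ENC."""
        counts = {"TTT": 5, "TTC": 5, "GCA": 5, "GCT": 5, "ATT": 5, "ATC": 5}
        assert np.isnan(enc_wright(table_from(counts)))

    def test_bounds_on_random_genes(self):
        cfg = SimulationConfig(n_genes=1000, seed=5, bias_strength=(0.0, 0.9))
        ds = simulate_cds(cfg)
        enc = enc_matrix(ds.counts)
        defined = enc[~np.isnan(enc)]
        assert len(defined) > 900
        assert (defined >= 20.0).all() and (defined <= 61.0).all()

    def test_matches_bruteforce_oracle(self):
        rng = np.random.default_rng(13)
        for _ in range(50):
            counts = random_count_table(rng)
            expected = enc_oracle(counts.to_dict())
            got = enc_wright(table_from(counts.to_dict()))
            if np.isnan(expected):
                assert np.isnan(got)
            else:
                assert got == pytest.approx(expected, abs=1e-9)


class TestPositionalComposition:
    def test_all_gc_saturates(self):
        pg = positional_gc(CodonSeq("g", ("GCC",) * 10))
        assert (pg.gc1, pg.gc2, pg.gc3, pg.gc) == (1.0, 1.0, 1.0, 1.0)

    def test_gat_positions(self):
        pg = positional_gc(CodonSeq("g", ("GAT",) * 4))
        assert (pg.gc1, pg.gc2, pg.gc3) == (1.0, 0.0, 0.0)
        assert pg.gc12 == pytest.approx(0.5)

    def test_gc_identities_hold(self, small_dataset):
        prof = profile_table(small_dataset.counts)
        assert np.allclose(prof["GC12"], (prof["GC1"] + prof["GC2"]) / 2)
        assert np.allclose(prof["GC"], (prof["GC1"] + prof["GC2"] + prof["GC3"]) / 3)

    def test_third_base_counts(self):
        tb = synonymous_third_base(CodonSeq("g", ("GCA", "GCT", "GCG", "GCC")))
        assert (tb.a3, tb.t3, tb.g3, tb.c3) == (1, 1, 1, 1)
        assert tb.gc3s == pytest.approx(0.5)

    def test_met_trp_excluded(self):
        tb = synonymous_third_base(CodonSeq("g", ("ATG", "TGG")))
        assert (tb.a3, tb.t3, tb.g3, tb.c3) == (0, 0, 0, 0)
        assert np.isnan(tb.gc3s)

    def test_lysine_gc3s(self):
        tb = synonymous_third_base(CodonSeq("g", ("AAA", "AAG")))
        assert tb.gc3s == pytest.approx(0.5)

    def test_matches_looping_oracles(self, small_dataset):
        from cubkit.sequence_io import tokenize

        for seq in small_dataset.sequences[:20]:
            cs = tokenize(seq)
            pg = positional_gc(cs)
            g1, g2, g3 = positional_gc_oracle(list(cs.codons))
            assert (pg.gc1, pg.gc2, pg.gc3) == pytest.approx((g1, g2, g3))
            tb = synonymous_third_base(cs)
            assert tb.gc3s == pytest.approx(gc3s_oracle(list(cs.codons)))


class TestProfiles:
    def test_profile_composes_all_fields(self, uniform_codon_seq):
        p = profile_gene(uniform_codon_seq)
        assert p.enc == 61.0
        assert not np.isnan(p.gc3s)
        assert p.a3 + p.t3 + p.g3 + p.c3 == len(uniform_codon_seq.codons)

    def test_bulk_profiles_have_no_missing_gc(self, small_dataset):
        prof = profile_table(small_dataset.counts)
        assert len(prof) == 120
        assert prof[["GC", "GC1", "GC2", "GC3", "GC12", "GC3s"]].notna().all().all()

    def test_bulk_matches_scalar_path(self, small_dataset):
        from cubkit.sequence_io import tokenize

        prof = profile_table(small_dataset.counts)
        for i in (0, 7, 42):
            p = profile_gene(tokenize(small_dataset.sequences[i]))
            row = prof.iloc[i]
            assert row["ENC"] == pytest.approx(p.enc, nan_ok=True)
            assert row["GC3s"] == pytest.approx(p.gc3s)
            assert row["length_codons"] == p.length_codons
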