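import numpy as np
import pandas as pd
import pytest
from scipy import stats

from oracles import welch_oracle

from cubkit.codon_metrics import profile_table
from cubkit.genetic_code import CODONS
from cubkit.expression_link import (
    amino_acid_level_groups,
    assign_tiers,
    codon_level_groups,
    dominant_third_base,
    sequence_level_test,
    welch_t,
)
from cubkit.synthetic_data import SimulationConfig, simulate_cds, simulate_expression


def _expr(rpkm: dict[str, float]) -> pd.DataFrame:
    df = pd.DataFrame({"root": rpkm, "leaf": rpkm})
    df.index.name = "gene_id"
    return df


def _profiles(genes, enc) -> pd.DataFrame:
    return pd.DataFrame({"gene": genes, "ENC": enc})


class TestWelch:
    def test_identical_samples(self):
        r = welch_t([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert r.t_statistic == 0.0 and r.p_value == 1.0

    def test_shifted_samples_sign_convention(self):
        r = welch_t([1.0, 2.0, 3.0], [11.0, 12.0, 13.0])
        assert r.t_statistic < 0 and r.p_value < 0.01

    def test_frozen_worked_example(self):
        """Classic unequal-variance example, frozen to 4 decimals."""
        x = [19.8, 20.4, 19.6, 17.8, 18.5, 18.9, 18.3, 18.9, 19.5, 22.0]
        y = [28.2, 26.6, 20.1, 23.3, 25.2, 22.1, 17.7, 27.6, 20.6, 13.7,
             23.2, 17.5, 20.6, 18.0, 23.9, 21.6, 24.3, 20.4, 24.0, 13.2]
        r = welch_t(x, y)
        assert r.t_statistic == pytest.approx(-2.2192, abs=1e-4)
        assert r.p_value == pytest.approx(0.0360, abs=1e-4)
        assert r.df == pytest.approx(24.4962, abs=1e-4)

    def test_matches_oracle_and_scipy_on_random_samples(self):
        rng = np.random.default_rng(8)
        for _ in range(25):
            x = rng.normal(0, 1, int(rng.integers(3, 40)))
            y = rng.normal(0.3, 2, int(rng.integers(3, 40)))
            r = welch_t(x, y)
            t_o, df_o = welch_oracle(list(x), list(y))
            assert r.t_statistic == pytest.approx(t_o, abs=1e-10)
            assert r.df == pytest.approx(df_o, abs=1e-10)
            t_s, p_s = stats.ttest_ind(x, y, equal_var=False)
            assert r.t_statistic == pytest.approx(t_s, abs=1e-10)
            assert r.p_value == pytest.approx(p_s, abs=1e-10)

    def test_antisymmetric_under_swap(self):
        rng = np.random.default_rng(9)
        x, y = rng.normal(0, 1, 10), rng.normal(1, 1, 12)
        a, b = welch_t(x, y), welch_t(y, x)
        assert a.t_statistic == pytest.approx(-b.t_statistic)
        assert a.p_value == pytest.approx(b.p_value)

    def test_degenerate_variances(self):
        r = welch_t([2.0, 2.0, 2.0], [2.0, 2.0, 2.0])
        assert (r.t_statistic, r.p_value) == (0.0, 1.0)
        r = welch_t([3.0, 3.0, 3.0], [2.0, 2.0, 2.0])
        assert np.isinf(r.t_statistic) and r.p_value == 0.0

    def test_small_sample_rejected(self):
        with pytest.raises(ValueError):
            welch_t([1.0, 2.0], [1.0, 2.0, 3.0])


class TestTiers:
    def test_boundaries(self):
        expr = _expr({"a": 11.0, "b": 10.0, "c": 1.0, "d": 0.5, "e": 0.0})
        prof = _profiles(list("abcde"), [40, 45, 50, 55, 60])
        asg = assign_tiers(expr, prof).set_index("gene")
        assert asg.loc["a", "tier"] == "high"
        assert asg.loc["b", "tier"] == "medium"  # 10 is medium (10 >= RPKM > 1)
        assert asg.loc["c", "tier"] == "low"  # 1 is low (0 < RPKM <= 1)
        assert asg.loc["d", "tier"] == "low"
        assert asg.loc["e", "tier"] == "excluded"

    def test_partition(self, small_dataset):
        cfg = small_dataset.config
        expr = simulate_expression(cfg, small_dataset)
        prof = profile_table(small_dataset.counts)
        asg = assign_tiers(expr, prof)
        assert len(asg) == len(prof)
        assert set(asg["tier"]) <= {"high", "medium", "low", "excluded"}
        assert asg["tier"].notna().all()

    def test_median_split_within_tier(self):
        expr = _expr({f"g{i}": 50.0 for i in range(10)})
        prof = _profiles([f"g{i}" for i in range(10)], np.arange(40, 50))
        asg = assign_tiers(expr, prof)
        counts = asg["enc_group"].value_counts()
        assert counts["strong_bias"] == 5 and counts["weak_bias"] == 5
        strong = asg.loc[asg["enc_group"] == "strong_bias", "enc"]
        assert strong.max() < asg.loc[asg["enc_group"] == "weak_bias", "enc"].min()

    def test_fixed_threshold_split(self):
        expr = _expr({f"g{i}": 50.0 for i in range(10)})
        prof = _profiles([f"g{i}" for i in range(10)], np.arange(40, 50))
        asg = assign_tiers(expr, prof, enc_split=42.0)
        assert (asg["enc_group"] == "strong_bias").sum() == 3

    def test_empty_join_raises(self):
        with pytest.raises(ValueError):
            assign_tiers(_expr({"x": 1.0}), _profiles(["y"], [50]))


class TestSequenceLevel:
    def test_null_identical_groups(self):
        rpkm = {f"g{i}": 20.0 + (i % 5) for i in range(40)}
        expr = _expr(rpkm)
        prof = _profiles(list(rpkm), np.tile([40, 41, 42, 43, 44, 45, 46, 47], 5))
        res = sequence_level_test(assign_tiers(expr, prof))
        row = res[res["tier"] == "high"].iloc[0]
        assert row["testable"]
        assert abs(row["t"]) < 3

    def test_coupled_generator_positive_significant(self):
        cfg = SimulationConfig(
            n_genes=1000, gc3_coupling=0.0, gc3_range=(0.5, 0.5),
            tier_probs=(1.0, 0.0, 0.0, 0.0), seed=21,
        )
        ds = simulate_cds(cfg)
        expr = simulate_expression(cfg, ds)
        res = sequence_level_test(assign_tiers(expr, profile_table(ds.counts)))
        row = res[res["tier"] == "high"].iloc[0]
        assert row["n_strong"] >= 450 and row["t"] > 0 and row["p"] < 0.05

    def test_small_group_untestable(self):
        expr = _expr({"a": 20.0, "b": 30.0, "c": 40.0})
        prof = _profiles(list("abc"), [40, 50, 60])
        res = sequence_level_test(assign_tiers(expr, prof))
        assert not res[res["tier"] == "high"]["testable"].iloc[0]


class TestCodonLevel:
    def test_dominant_base_argmax_and_tie(self):
        prof = pd.DataFrame(
            {"gene": ["a", "b"], "A3": [10, 5], "T3": [3, 5], "G3": [2, 1], "C3": [1, 1]}
        )
        dom = dominant_third_base(prof)
        assert dom["a"] == "A"
        assert dom["b"] == "T"  # tie broken by fixed order T > A > G > C

    def test_gc_dominant_genes_with_higher_rpkm_detected(self):
        """Planted construction: G/C-dominant genes get higher RPKM."""
        rng = np.random.default_rng(5)
        n = 400
        genes = [f"g{i}" for i in range(n)]
        gc_dom = rng.random(n) < 0.5
        prof = pd.DataFrame(
            {
                "gene": genes,
                "A3": np.where(gc_dom, 5, 20),
                "T3": np.where(gc_dom, 5, 15),
                "G3": np.where(gc_dom, 20, 5),
                "C3": np.where(gc_dom, 15, 5),
            }
        )
        rpkm = 10 ** (1.0 + 0.4 * gc_dom + rng.normal(0, 0.2, n))
        expr = _expr(dict(zip(genes, rpkm)))
        _, tests = codon_level_groups(prof, expr)
        row = tests[(tests["group1"] == "GC3") & (tests["group2"] == "AT3")].iloc[0]
        assert row["t"] > 0 and row["p"] < 0.01


class TestAminoAcidLevel:
    def test_family_partition_sizes(self, small_dataset):
        cfg = small_dataset.config
        expr = simulate_expression(cfg, small_dataset)
        out = amino_acid_level_groups(small_dataset.counts, expr)
        sizes = out.groupby("family")["amino_acid"].count().to_dict()
        assert sizes == {2: 9, 3: 1, 4: 5, 6: 3}

    def test_aag_preferring_genes_detected(self):
        """RPKM boosted for AAG-preferring genes -> Lys test significant."""
        rng = np.random.default_rng(6)
        n = 300
        genes = [f"g{i}" for i in range(n)]
        prefers_aag = rng.random(n) < 0.5
        counts = pd.DataFrame(0, index=genes, columns=list(CODONS))
        counts["AAA"] = np.where(prefers_aag, 2, 8)
        counts["AAG"] = np.where(prefers_aag, 8, 2)
        rpkm = 10 ** (1.0 + 0.5 * prefers_aag + rng.normal(0, 0.2, n))
        expr = _expr(dict(zip(genes, rpkm)))
        out = amino_acid_level_groups(counts, expr).set_index("amino_acid")
        row = out.loc["K"]
        assert row["t"] > 0 and row["p"] < 0.01  # AAG = G-ending group higher

    def test_ties_excluded(self):
        genes = ["a", "b", "c", "d", "e", "f"]
        counts = pd.DataFrame(0, index=genes, columns=list(CODONS))
        counts.loc[:, "AAA"] = 4
        counts.loc[:, "AAG"] = 4  # all tied for Lys
        expr = _expr({g: 5.0 for g in genes})
        out = amino_acid_level_groups(counts, expr).set_index("amino_acid")
        assert out.loc["K", "n_tied"] == 6
        assert not out.loc["K", "testable"]
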