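"""LFQ table operations: filter, exclusives, differential tests, ratios."""

import numpy as np
import pandas as pd
import pytest

from compartquant.proteomics import (LFQTable, abundance_ratio, compartment_de,
                                     exclusive_proteins, filter_detection,
                                     genotype_t_test)
from compartquant.sim.lfq import LFQSimConfig, generate_lfq_table


def small_table(values: np.ndarray, compartments, genotypes=None, proteins=None):
    n_prot, n_samp = values.shape
    proteins = proteins or [f"P{i}" for i in range(n_prot)]
    samples = [f"s{i}" for i in range(n_samp)]
    genotypes = genotypes or ["wt"] * n_samp
    # replicate numbering restarts within each compartment so (clone, replicate)
    # pairs match across compartments
    seen: dict[str, int] = {}
    replicates = []
    for comp in compartments:
        seen[comp] = seen.get(comp, 0) + 1
        replicates.append(seen[comp])
    meta = pd.DataFrame({"compartment": compartments, "genotype": genotypes,
                         "clone": ["c1"] * n_samp,
                         "replicate": replicates}, index=samples)
    return LFQTable(pd.DataFrame(values, index=proteins, columns=samples), meta)


class TestDetectionFilter:
    def test_seventy_percent_boundary(self):
        vals = np.full((2, 10), 20.0)
        vals[0, 7:] = np.nan   # detected in 7/10 -> kept
        vals[1, 6:] = np.nan   # detected in 6/10 -> removed
        table = small_table(vals, ["neurite"] * 5 + ["soma"] * 5)
        kept = filter_detection(table, 0.7)
        assert list(kept.values.index) == ["P0"]

    def test_fully_observed_kept(self):
        table = small_table(np.full((3, 6), 20.0), ["neurite"] * 3 + ["soma"] * 3)
        assert filter_detection(table).values.shape == (3, 6)

    def test_idempotent(self):
        tab, _ = generate_lfq_table(LFQSimConfig(n_proteins=200, rng_seed=3))
        once = filter_detection(tab)
        twice = filter_detection(once)
        pd.testing.assert_frame_equal(once.values, twice.values)

    def test_matches_brute_force_count_oracle(self, rng):
        vals = rng.normal(20, 2, (100, 12))
        vals[rng.random((100, 12)) < 0.4] = np.nan
        table = small_table(vals, ["neurite"] * 6 + ["soma"] * 6)
        kept = set(filter_detection(table, 0.7).values.index)
        expected = {f"P{i}" for i in range(100)
                    if np.sum(~np.isnan(vals[i])) >= 0.7 * 12}
        assert kept == expected

    def test_invalid_fraction_rejected(self):
        table = small_table(np.ones((1, 2)), ["neurite", "soma"])
        with pytest.raises(ValueError):
            filter_detection(table, 0.0)

    def test_sample_exclusion_applied_first(self):
        vals = np.full((1, 10), 20.0)
        vals[0, :4] = np.nan  # 6/10 detected; 6/9 after excluding one missing sample
        table = small_table(vals, ["neurite"] * 5 + ["soma"] * 5)
        assert len(filter_detection(table, 0.65).values) == 0
        assert list(filter_detection(table, 0.65, exclude_samples=["s0"]).values.index) == ["P0"]


class TestExclusives:
    def test_both_compartments_neither_set(self):
        table = small_table(np.full((1, 4), 20.0), ["neurite", "neurite", "soma", "soma"])
        ne, se = exclusive_proteins(table)
        assert not ne and not se

    def test_one_sided_detection(self):
        vals = np.full((2, 4), 20.0)
        vals[0, 2:] = np.nan  # neurite-only
        vals[1, :2] = np.nan  # soma-only
        table = small_table(vals, ["neurite", "neurite", "soma", "soma"])
        ne, se = exclusive_proteins(table)
        assert ne == {"P0"} and se == {"P1"}

    def test_planted_exclusives_recovered_exactly(self):
        cfg = LFQSimConfig(n_proteins=300, n_neurite_exclusive=12, n_soma_exclusive=5,
                           rng_seed=8)
        table, truth = generate_lfq_table(cfg)
        ne, se = exclusive_proteins(table)
        assert ne == set(truth["neurite_exclusive"])
        assert se == set(truth["soma_exclusive"])
        assert not (ne & se)


class TestCompartmentDE:
    def test_identical_groups_nothing_passes(self):
        table = small_table(np.tile([20.0, 21, 22, 20, 21, 22], (4, 1)),
                            ["neurite"] * 3 + ["soma"] * 3)
        de = compartment_de(table)
        assert not de["passes"].any()

    def test_planted_large_effects_all_pass(self):
        cfg = LFQSimConfig(n_proteins=400, n_differential=30, differential_log2fc=3.0,
                           within_sd=0.3, n_replicates=6, rng_seed=2)
        table, truth = generate_lfq_table(cfg)
        de = compartment_de(filter_detection(table))
        planted_tested = [p for p in truth["differential"] if p in de.index and de.loc[p, "tested"]]
        assert len(planted_tested) >= 0.85 * len(truth["differential"])
        assert de.loc[planted_tested, "passes"].all()

    def test_large_significance_small_fc_fails(self):
        rng = np.random.default_rng(0)
        base = rng.normal(0, 0.01, 12)
        vals = np.vstack([base + np.r_[np.zeros(6), np.full(6, 1.4)]])
        table = small_table(vals + 20.0, ["neurite"] * 6 + ["soma"] * 6)
        de = compartment_de(table)
        assert de["p_adjusted"].iloc[0] < 0.001
        assert abs(de["log2fc"].iloc[0]) < 1.5
        assert not de["passes"].iloc[0]

    def test_pass_flag_matches_invariant(self):
        tab, _ = generate_lfq_table(LFQSimConfig(n_proteins=200, rng_seed=4))
        de = compartment_de(filter_detection(tab))
        tested = de[de.tested]
        expected = (tested["p_adjusted"] < 0.05) & (tested["log2fc"].abs() > 1.5)
        assert (tested["passes"] == expected).all()
        assert (tested["p_adjusted"] >= tested["p"] - 1e-12).all()

    def test_sensitivity_monotone_in_effect_size(self):
        rates = []
        for effect in (0.5, 1.8, 3.0):
            cfg = LFQSimConfig(n_proteins=300, n_differential=40,
                               differential_log2fc=effect, rng_seed=6)
            table, truth = generate_lfq_table(cfg)
            de = compartment_de(filter_detection(table))
            planted = [p for p in truth["differential"] if p in de.index]
            rates.append(de.loc[planted, "passes"].mean())
        assert rates[0] <= rates[1] <= rates[2]


class TestGenotypeT:
    def test_identical_groups(self):
        vals = np.array([[1.0, 2, 3, 1, 2, 3]]) + 20
        table = small_table(vals, ["neurite"] * 6, genotypes=["wt"] * 3 + ["mut"] * 3)
        t, df, p = genotype_t_test(table, "P0", "neurite", "wt", "mut")
        assert t == pytest.approx(0.0) and p == pytest.approx(1.0)

    def test_hand_pooled_t(self):
        vals = np.array([[1.0, 2, 3, 2, 3, 4]])
        table = small_table(vals, ["neurite"] * 6, genotypes=["a"] * 3 + ["b"] * 3)
        t, df, p = genotype_t_test(table, "P0", "neurite", "a", "b")
        assert t == pytest.approx(-1.2247, abs=1e-4)
        assert df == 4

    def test_df_reflects_missing_drop(self):
        vals = np.array([[1.0, 2, np.nan, 2, 3, 4, 5]])
        table = small_table(vals, ["neurite"] * 7, genotypes=["a"] * 3 + ["b"] * 4)
        t, df, p = genotype_t_test(table, "P0", "neurite", "a", "b")
        assert df == 2 + 4 - 2

    def test_insufficient_n_untested(self):
        vals = np.array([[1.0, np.nan, np.nan, 2, 3, 4]])
        table = small_table(vals, ["neurite"] * 6, genotypes=["a"] * 3 + ["b"] * 3)
        assert genotype_t_test(table, "P0", "neurite", "a", "b") is None


class TestAbundanceRatio:
    def test_equal_values_ratio_one(self):
        vals = np.array([[20.0, 20.0]])
        table = small_table(vals, ["soma", "neurite"])
        rec = abundance_ratio(table, "P0")
        assert rec["ratio"].iloc[0] == pytest.approx(1.0)
        assert rec["log2_difference"].iloc[0] == pytest.approx(0.0)

    def test_ratio_of_logs_as_printed(self):
        vals = np.array([[30.0, 20.0]])
        table = small_table(vals, ["soma", "neurite"])
        assert abundance_ratio(table, "P0")["ratio"].iloc[0] == pytest.approx(1.5)

    def test_unmatched_replicate_skipped_with_warning(self):
        vals = np.array([[30.0, np.nan]])
        table = small_table(vals, ["soma", "neurite"])
        with pytest.warns(UserWarning, match="unmatched"):
            rec = abundance_ratio(table, "P0")
        assert rec.empty

    def test_full_table_hand_oracle(self):
        tab, _ = generate_lfq_table(LFQSimConfig(
            n_proteins=50, n_neurite_exclusive=4, n_soma_exclusive=2,
            n_differential=6, missing_midpoint=0.0, rng_seed=1))
        prot = tab.values.index[40]
        rec = abundance_ratio(tab, prot).set_index(["clone", "replicate"])
        meta = tab.meta
        for (clone, rep), row in rec.iterrows():
            cols_s = meta[(meta.clone == clone) & (meta.replicate == rep)
                          & (meta.compartment == "soma")].index
            cols_n = meta[(meta.clone == clone) & (meta.replicate == rep)
                          & (meta.compartment == "neurite")].index
            s = tab.values.loc[prot, cols_s].mean()
            n = tab.values.loc[prot, cols_n].mean()
            assert row["ratio"] == pytest.approx(s / n)


class TestSimTrivials:
    def test_no_missingness_complete_table(self):
        # midpoint far below every abundance -> detection probability ~ 1
        cfg = LFQSimConfig(n_proteins=100, n_neurite_exclusive=0, n_soma_exclusive=0,
                           missing_midpoint=-100.0, rng_seed=0)
        table, _ = generate_lfq_table(cfg)
        assert not table.values.isna().any().any()

    def test_deterministic_under_seed(self):
        t1, _ = generate_lfq_table(LFQSimConfig(n_proteins=150, n_neurite_exclusive=10,
                                                n_soma_exclusive=4, n_differential=10,
                                                rng_seed=9))
        t2, _ = generate_lfq_table(LFQSimConfig(n_proteins=150, n_neurite_exclusive=10,
                                                n_soma_exclusive=4, n_differential=10,
                                                rng_seed=9))
        pd.testing.assert_frame_equal(t1.values, t2.values)

    def test_overplanting_rejected(self):
        with pytest.raises(ValueError, match="exceed"):
            LFQSimConfig(n_proteins=10, n_neurite_exclusive=8, n_soma_exclusive=8).validate()
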