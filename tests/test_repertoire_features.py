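"""Feature panel statistics: Fisher/Welch/BH/Pearson behaviour and
group-comparison bookkeeping."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from statsmodels.stats.weightstats import ttest_ind as sm_ttest_ind

from oracles import fisher_two_sided_enumeration
from repgut.repertoire_features import (
    CATEGORICAL_FEATURES,
    FeaturePanel,
    benjamini_hochberg,
    cdr3_charge_class,
    compare_repertoires,
    correlation_matrix,
    fisher_exact_2x2,
    iga_igg_ratio,
    welch_t,
)
from repgut.repertoire_io import Rearrangement


class TestChargeClass:
    @pytest.mark.parametrize(
        "cdr3,expected",
        [("ARKKY", "positive"), ("ARDDY", "negative"), ("AKDGY", "neutral"),
         ("GHHHG", "neutral")],  # histidine excluded from the net charge
    )
    def test_classes(self, cdr3, expected):
        assert cdr3_charge_class(cdr3) == expected

    def test_invalid_character(self):
        with pytest.raises(ValueError, match="non-amino-acid"):
            cdr3_charge_class("ARD*Y")


class TestFisher:
    def test_published_polyreactive_sharing_table(self):
        # 12/99 vs 1/101 polyreactive gut-blood shared sequences
        p = fisher_exact_2x2(12, 87, 1, 100)
        assert f"{p:.2g}" == "0.0012"

    def test_symmetric_table_is_one(self):
        assert fisher_exact_2x2(5, 5, 5, 5) == pytest.approx(1.0)

    def test_all_zero_table(self):
        assert fisher_exact_2x2(0, 0, 0, 0) == 1.0

    def test_row_column_swap_invariance(self):
        p = fisher_exact_2x2(7, 2, 3, 9)
        assert fisher_exact_2x2(2, 7, 9, 3) == pytest.approx(p, rel=1e-12)
        assert fisher_exact_2x2(3, 9, 7, 2) == pytest.approx(p, rel=1e-12)

    def test_exhaustive_enumeration_oracle_small_margins(self):
        for r1 in range(0, 13):
            for a in range(0, r1 + 1):
                for r2 in range(0, 13):
                    for c in range(0, r2 + 1):
                        p = fisher_exact_2x2(a, r1 - a, c, r2 - c)
                        oracle = fisher_two_sided_enumeration(a, r1 - a, c, r2 - c)
                        assert p == pytest.approx(oracle, abs=1e-12), (a, r1, c, r2)


class TestWelch:
    def test_identical_samples(self):
        t, df, p = welch_t([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert t == 0.0 and p == 1.0

    def test_separated_means(self):
        rng = np.random.default_rng(0)
        x = np.zeros(4) + rng.normal(0, 1e-9, 4)
        y = np.ones(4) + rng.normal(0, 1e-9, 4)
        _, _, p = welch_t(x, y)
        assert p < 1e-6

    def test_zero_variance_equal_means(self):
        t, _, p = welch_t([2.0, 2.0], [2.0, 2.0])
        assert p == 1.0

    def test_cross_check_against_statsmodels(self):
        rng = np.random.default_rng(1)
        for _ in range(500):
            x = rng.normal(rng.uniform(-2, 2), rng.uniform(0.5, 3), rng.integers(3, 40))
            y = rng.normal(rng.uniform(-2, 2), rng.uniform(0.5, 3), rng.integers(3, 40))
            t, df, p = welch_t(x, y)
            t_ref, p_ref, df_ref = sm_ttest_ind(x, y, usevar="unequal")
            assert t == pytest.approx(t_ref, abs=1e-9)
            assert p == pytest.approx(p_ref, abs=1e-9)
            assert df == pytest.approx(df_ref, abs=1e-9)


class TestBenjaminiHochberg:
    def test_hand_computed_steps(self):
        adjusted, reject, threshold = benjamini_hochberg([0.001, 0.02, 0.03, 0.9], q=0.05)
        assert list(reject) == [True, True, True, False]
        assert threshold == 0.03

    @given(st.lists(st.floats(min_value=1e-12, max_value=1.0), min_size=1, max_size=40))
    @settings(max_examples=100, deadline=None, derandomize=True)
    def test_adjusted_monotone_in_raw_order(self, p_list):
        adjusted, _, _ = benjamini_hochberg(p_list)
        order = np.argsort(p_list)
        assert np.all(np.diff(adjusted[order]) >= -1e-12)


def _panel(group, v_families, n):
    rng = np.random.default_rng(hash(group) % 2**31)
    rows = []
    for i in range(n):
        fam = v_families[i % len(v_families)]
        rows.append(
            {
                "sequence_id": f"{group}{i}",
                "v_family": fam,
                "j_gene": "TVJ1",
                "d_family": np.nan,
                "vj_pairing": f"{fam}|TVJ1",
                "heavy_light_family": np.nan,
                "isotype": "IGA",
                "cdr3_charge_class": "neutral",
                "light_cdr3_charge_class": np.nan,
                "cdr3_length_class": "medium",
                "cdr3_length_aa": 12,
                "vh_mutation_count": float(rng.poisson(20)),
                "light_v_mutation_count": np.nan,
            }
        )
    return FeaturePanel(group=group, table=pd.DataFrame(rows))


class TestCompareRepertoires:
    def test_identical_panels_nothing_significant(self):
        panel = _panel("x", ["VH1", "VH2"], 100)
        table = compare_repertoires(panel, FeaturePanel(group="y", table=panel.table.copy()))
        categorical = table[table["test"] == "fisher_2x2"]
        assert (categorical["p_value"] == 1.0).all()
        assert not categorical["significant"].any()

    def test_parameter_count_matches_enumerated_levels(self):
        panel_a = _panel("a", ["VH1", "VH2", "VH3"], 60)
        panel_b = _panel("b", ["VH1", "VH2"], 60)
        table = compare_repertoires(panel_a, panel_b)
        categorical = table[table["test"] == "fisher_2x2"]
        expected = 0
        for feature in CATEGORICAL_FEATURES:
            levels = set(panel_a.categorical_levels(feature).index) | set(
                panel_b.categorical_levels(feature).index
            )
            expected += len(levels)
        assert len(categorical) == expected

    def test_planted_usage_shift_detected(self):
        # a 3-fold V-family usage shift at n=300/group should light up
        rng = np.random.default_rng(7)
        detected = 0
        n_seeds = 100
        for _ in range(n_seeds):
            rows_a = rng.choice(["VH1", "VH2", "VH3"], size=300, p=[0.30, 0.35, 0.35])
            rows_b = rng.choice(["VH1", "VH2", "VH3"], size=300, p=[0.10, 0.45, 0.45])
            pa, pb = (
                FeaturePanel(
                    group=g,
                    table=pd.DataFrame(
                        {
                            "sequence_id": [f"{g}{i}" for i in range(300)],
                            "v_family": rows,
                            **{
                                col: [np.nan] * 300
                                for col in CATEGORICAL_FEATURES
                                if col != "v_family"
                            },
                            "cdr3_length_aa": [np.nan] * 300,
                            "vh_mutation_count": [np.nan] * 300,
                            "light_v_mutation_count": [np.nan] * 300,
                        }
                    ),
                )
                for g, rows in (("a", rows_a), ("b", rows_b))
            )
            table = compare_repertoires(pa, pb)
            hit = table[(table["feature"] == "v_family") & (table["level"] == "VH1")]
            detected += bool(hit["significant"].iloc[0])
        assert detected / n_seeds >= 0.9

    def test_order_invariance(self):
        panel_a = _panel("a", ["VH1", "VH2"], 50)
        shuffled = FeaturePanel(
            group="a", table=panel_a.table.sample(frac=1.0, random_state=1)
        )
        panel_b = _panel("b", ["VH1", "VH3"], 50)
        t1 = compare_repertoires(panel_a, panel_b).reset_index(drop=True)
        t2 = compare_repertoires(shuffled, panel_b).reset_index(drop=True)
        pd.testing.assert_frame_equal(t1, t2)


class TestCorrelationMatrix:
    def test_perfect_linear_relation(self):
        x = np.arange(20, dtype=float)
        r_mat, p_mat, table, _ = correlation_matrix(pd.DataFrame({"x": x, "y": 2 * x + 1}))
        assert r_mat.loc["x", "y"] == pytest.approx(1.0)
        assert p_mat.loc["x", "y"] < 1e-20

    def test_constant_column_reported_missing(self):
        df = pd.DataFrame({"x": np.arange(10.0), "c": np.ones(10)})
        r_mat, p_mat, table, _ = correlation_matrix(df)
        assert np.isnan(r_mat.loc["x", "c"])

    def test_null_calibration(self):
        rng = np.random.default_rng(3)
        hits = total = 0
        for _ in range(100):
            df = pd.DataFrame(rng.standard_normal((78, 5)), columns=list("abcde"))
            _, _, table, _ = correlation_matrix(df)
            hits += int((table["p_value"] < 0.05).sum())
            total += len(table)
        rate = hits / total
        assert abs(rate - 0.05) < 3 * np.sqrt(0.05 * 0.95 / total)


class TestIgaIggRatio:
    def _records(self, n_iga, n_igg):
        out = []
        for i in range(n_iga):
            out.append(Rearrangement(sequence_id=f"a{i}", sequence="ACGT", isotype="IGA"))
        for i in range(n_igg):
            out.append(Rearrangement(sequence_id=f"g{i}", sequence="ACGT", isotype="IGG"))
        return out

    def test_simple_ratio(self):
        assert iga_igg_ratio(self._records(10, 5)) == 2.0

    def test_zero_iga(self):
        assert iga_igg_ratio(self._records(0, 5)) == 0.0

    def test_zero_igg_warns_infinite(self):
        with pytest.warns(UserWarning, match="infinite"):
            assert iga_igg_ratio(self._records(3, 0)) == np.inf

    def test_simulated_isotype_mix_recovered(self, reference):
        from repgut.synthetic_repertoire import SimulationConfig, simulate_repertoire

        config = SimulationConfig(
            seed=0, n_clones=1000, isotype_mix={"gut": 0.6, "blood": 0.6}
        )
        rep = simulate_repertoire(config, reference)
        records = [
            Rearrangement(sequence_id=row["sequence_id"], sequence="ACGT",
                          isotype=row["isotype"])
            for _, row in rep.truth.iterrows()
        ]
        assert iga_igg_ratio(records) == pytest.approx(1.5, rel=0.05)
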