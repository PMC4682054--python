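import numpy as np
import pandas as pd
import pytest

from catgut import calibration
from catgut.simulate import CohortSpec, default_effect_spec, generate_counts, generate_design
from catgut.tables import (FeatureTable, aggregate_to_level, read_feature_table,
                           round_percent, summarize_abundant_features,
                           to_relative_abundance, write_feature_table)


class TestFeatureTableIO:
    def test_round_trip_is_exact(self, small_counts, tmp_path):
        p = tmp_path / "t.tsv"
        write_feature_table(small_counts, p, header_comment="test")
        back = read_feature_table(p, "genus")
        pd.testing.assert_frame_equal(back.data, small_counts.data)
        assert back.value_kind == "counts"
        assert back.feature_ids == ["f1", "f2", "f3"]

    def test_empty_data_section_rejected(self, tmp_path):
        p = tmp_path / "e.tsv"
        p.write_text("feature_id\ts1\ts2\n")
        with pytest.raises(ValueError, match="no features"):
            read_feature_table(p, "genus")

    def test_duplicate_feature_id_named(self, tmp_path):
        p = tmp_path / "d.tsv"
        p.write_text("feature_id\ts1\nfA\t1\nfA\t2\n")
        with pytest.raises(ValueError, match="fA"):
            read_feature_table(p, "genus")

    def test_negative_cell_located(self, tmp_path):
        p = tmp_path / "n.tsv"
        p.write_text("feature_id\ts1\ts2\nfA\t1\t2\nfB\t-3\t4\n")
        with pytest.raises(ValueError, match="fB"):
            read_feature_table(p, "genus")

    def test_non_numeric_cell_located(self, tmp_path):
        p = tmp_path / "x.tsv"
        p.write_text("feature_id\ts1\nfA\toops\n")
        with pytest.raises(ValueError, match="fA"):
            read_feature_table(p, "genus")

    def test_proportions_column_sum_invariant(self):
        bad = pd.DataFrame({"s1": [0.7, 0.6]}, index=["a", "b"])
        with pytest.raises(ValueError, match="sum"):
            FeatureTable("genus", bad, "proportions")


class TestRelativeAbundance:
    def test_column_sum_normalisation(self, small_counts):
        p = to_relative_abundance(small_counts)
        np.testing.assert_allclose(p.data["s1"], [0.2, 0.3, 0.5])
        np.testing.assert_allclose(p.data.sum(axis=0), 1.0, atol=1e-12)

    def test_explicit_denominator(self, small_counts):
        p = to_relative_abundance(small_counts, {"s1": 20, "s2": 40})
        np.testing.assert_allclose(p.data["s1"], [0.10, 0.15, 0.25])

    def test_all_zero_column_with_explicit_denominator(self):
        t = FeatureTable("genus", pd.DataFrame({"s1": [0, 0]}, index=["a", "b"]))
        p = to_relative_abundance(t, {"s1": 10})
        assert (p.data["s1"] == 0).all()

    def test_zero_denominator_rejected(self):
        t = FeatureTable("genus", pd.DataFrame({"s1": [0, 0]}, index=["a", "b"]))
        with pytest.raises(ValueError, match="zero denominator"):
            to_relative_abundance(t)


class TestAggregation:
    def test_tree_mapping_is_additive_and_conserves_mass(self):
        t = FeatureTable("genus", pd.DataFrame(
            {"s1": [0.1, 0.2, 0.3]}, index=["g1", "g2", "g3"]), "proportions")
        agg = aggregate_to_level(t, {"g1": "P1", "g2": "P1", "g3": "P2"},
                                 level="phylum")
        assert agg.data.loc["P1", "s1"] == pytest.approx(0.3)
        assert agg.data["s1"].sum() == pytest.approx(t.data["s1"].sum(), abs=1e-12)

    def test_many_to_many_full_weight_duplicates_mass(self):
        t = FeatureTable("KO", pd.DataFrame({"s1": [0.05]}, index=["ko1"]),
                         "proportions")
        agg = aggregate_to_level(t, {"ko1": ["pwA", "pwB"]}, level="pathway")
        assert agg.data.loc["pwA", "s1"] == pytest.approx(0.05)
        assert agg.data.loc["pwB", "s1"] == pytest.approx(0.05)

    def test_split_mode_conserves_mass(self):
        t = FeatureTable("KO", pd.DataFrame({"s1": [0.06]}, index=["ko1"]),
                         "proportions")
        agg = aggregate_to_level(t, {"ko1": ["pwA", "pwB", "pwC"]},
                                 level="pathway", weight="split")
        np.testing.assert_allclose(agg.data["s1"], 0.02)

    def test_unmapped_children_routed_and_logged(self):
        t = FeatureTable("genus", pd.DataFrame({"s1": [1, 2]}, index=["a", "b"]))
        agg = aggregate_to_level(t, {"a": "P"})
        assert agg.data.loc["unmapped", "s1"] == 2
        assert agg.unmapped_features == ["b"]

    def test_displayed_genera_do_not_exceed_phylum_mean(self):
        # within any phylum the displayed genera are a subset, so their sum
        # stays at or below the phylum value at every age
        g = calibration.genus_means_percent()
        p = calibration.phylum_means_percent()
        g2p = calibration.genus_to_phylum()
        for phylum in p.index:
            shown = g.loc[[x for x in g.index if g2p[x] == phylum]].sum(axis=0)
            assert (shown <= p.loc[phylum] + 1e-9).all()
        week18 = g.loc[[x for x in g.index
                        if g2p[x] == "Bacteroidetes"], 18].sum()
        assert week18 == pytest.approx(8.9)
        assert week18 <= p.loc["Bacteroidetes", 18] == 10.2


class TestAbundanceSummary:
    @pytest.fixture(scope="class")
    def cohort(self):
        spec = CohortSpec(seed=11)
        design = generate_design(spec)
        eff = default_effect_spec(seed=11)
        genus, _, _ = generate_counts(design, eff, seed=11)
        return design, to_relative_abundance(genus), eff

    def test_impossible_threshold_keeps_nothing(self, cohort):
        design, prop, _ = cohort
        out = summarize_abundant_features(prop, design, threshold=1.0)
        assert (out["role"] == "feature").sum() == 0

    def test_single_dominant_feature_always_retained(self, default_design):
        n = default_design.n_samples
        t = FeatureTable("genus", pd.DataFrame(
            [np.ones(n)], index=["only"],
            columns=default_design.sample_ids), "proportions")
        out = summarize_abundant_features(t, default_design, threshold=1.0)
        assert "only" in out.index[out["role"] == "feature"]

    def test_parent_totals_sum_displayed_parents(self, cohort):
        design, prop, eff = cohort
        phylum = aggregate_to_level(prop, dict(eff.genus_phylum), level="phylum")
        out = summarize_abundant_features(
            prop, design, threshold=0.003,
            parent_map=dict(eff.genus_phylum), parent_table=phylum)
        parents = out[out["role"] == "parent"]
        totals = out.loc["Total (parents)"]
        for age in design.ages:
            assert totals[age] == pytest.approx(parents[age].sum(), abs=1e-12)


def test_round_percent_is_half_up():
    assert round_percent(0.96649, 1) == 96.6
    assert round_percent(0.00125, 1) == 0.1   # 0.125 % -> 0.1 at 1 dp
    assert round_percent(0.0015, 1) == 0.2    # ties away from zero
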