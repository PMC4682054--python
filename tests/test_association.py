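import numpy as np
import pandas as pd
import pytest

from catgut.association import (AssociationResult, analyze_table,
                                classify_direction, filter_features,
                                fit_feature_gee, sidak_threshold,
                                summarize_families)
from catgut.simulate import CohortSpec, generate_counts, generate_design, small_effect_spec
from catgut.tables import FeatureTable


class TestZeroFilter:
    def _table(self, zero_counts, n_samples=88):
        rows = {}
        for i, nz in enumerate(zero_counts):
            v = np.ones(n_samples, dtype=int)
            v[:nz] = 0
            rows[f"f{i}"] = v
        df = pd.DataFrame(rows, index=[f"s{j}" for j in range(n_samples)]).T
        return FeatureTable("genus", df, "counts")

    def test_rule_is_strictly_greater(self):
        t = self._table([67, 66, 0])  # 76.1 %, 75.0 %, 0 %
        kept, flog = filter_features(t, 0.75)
        assert kept.feature_ids == ["f1", "f2"]
        assert list(flog["feature_id"]) == ["f0"]
        assert flog["zero_proportion"].iloc[0] == pytest.approx(67 / 88)

    def test_all_nonzero_kept(self):
        t = self._table([0, 0])
        kept, flog = filter_features(t)
        assert kept.n_features == 2 and len(flog) == 0


class TestSidak:
    @pytest.mark.parametrize("m,rounded,places", [
        (605, 0.000085, 6),
        (238, 0.000215, 6),
        (6427, 0.000008, 6),
        (190, 0.00027, 5),
        (32, 0.0016, 4),
    ])
    def test_reproduces_printed_critical_values(self, m, rounded, places):
        assert round(sidak_threshold(0.05, m), places) == rounded

    def test_single_test_identity(self):
        assert sidak_threshold(0.05, 1) == pytest.approx(0.05)

    def test_invalid_m_rejected(self):
        with pytest.raises(ValueError):
            sidak_threshold(0.05, 0)


class TestGEE:
    def test_unit_clusters_reduce_to_logistic_regression(
            self, unit_cluster_design):
        import statsmodels.api as sm
        counts = pd.Series([10, 50] * 10,
                           index=unit_cluster_design.sample_ids, name="f")
        r = fit_feature_gee(counts, unit_cluster_design)
        # cross-product odds ratio (50/50)/(10/90) = 9
        assert r.contrasts["18-30"]["or"] == pytest.approx(9.0, abs=1e-6)
        X = np.column_stack([np.ones(20), np.tile([0, 1], 10)])
        y = np.column_stack([counts.values, 100 - counts.values])
        glm = sm.GLM(y, X, family=sm.families.Binomial()).fit()
        assert r.contrasts["18-30"]["log_or"] == pytest.approx(
            glm.params[1], abs=1e-6)

    def test_constant_proportion_is_null(self, default_design):
        denom = default_design.table.set_index("sample_id")["denominator"]
        counts = (denom * 0.05).astype(int)
        r = fit_feature_gee(counts, default_design)
        for c in ("18-30", "18-42", "30-42"):
            assert r.contrasts[c]["or"] == pytest.approx(1.0, abs=1e-6)
        assert not (np.isfinite(r.p_age) and r.p_age < 0.0001)

    def test_feature_absent_at_one_age_is_flagged_not_crashed(
            self, default_design):
        meta = default_design.indexed()
        counts = pd.Series(0, index=meta.index)
        counts[meta["age_week"] == 42] = 500
        r = fit_feature_gee(counts, default_design)
        assert "quasi_separated" in r.flags

    def test_all_zero_feature_handled(self, default_design):
        counts = pd.Series(0, index=default_design.sample_ids)
        r = fit_feature_gee(counts, default_design)
        assert "all_zero" in r.flags
        assert r.p_age == 1.0

    def test_injected_effect_recovered_on_one_cohort(self):
        eff = small_effect_spec(baseline={"Clostridium": 0.05},
                                age_log_or={"Clostridium": (1.0, 1.0)}, seed=42)
        design = generate_design(CohortSpec(seed=42))
        genus, _, _ = generate_counts(design, eff, seed=42)
        r = fit_feature_gee(genus.data.loc["Clostridium"], design)
        assert r.contrasts["18-30"]["log_or"] == pytest.approx(1.0, abs=0.5)
        assert r.contrasts["18-42"]["log_or"] == pytest.approx(1.0, abs=0.5)


def _result(or_pairs, sig=True, thr=0.01):
    """Build an AssociationResult with given (OR, p) per contrast."""
    r = AssociationResult("f", "genus")
    for name, (orv, p) in or_pairs.items():
        r.contrasts[name] = {"log_or": np.log(orv), "or": orv, "se": 0.1, "p": p}
    r.significant = sig
    return r


class TestDirection:
    def test_pairwise18_up(self):
        r = _result({"18-30": (1.5, 1e-4), "18-42": (2.0, 1e-4),
                     "30-42": (1.3, 0.2)})
        assert classify_direction(r, "pairwise-18", 0.01) == "up"

    def test_pairwise18_down(self):
        r = _result({"18-30": (0.5, 1e-4), "18-42": (0.3, 1e-4),
                     "30-42": (0.6, 0.2)})
        assert classify_direction(r, "pairwise-18", 0.01) == "down"

    def test_monotone_reversal_is_mixed(self):
        r = _result({"18-30": (1.5, 1e-4), "18-42": (1.2, 1e-4),
                     "30-42": (0.8, 1e-4)})
        assert classify_direction(r, "monotone") == "mixed"

    def test_monotone_up_ignores_contrast_p(self):
        r = _result({"18-30": (1.5, 0.3), "18-42": (2.0, 0.3),
                     "30-42": (1.3, 0.3)})
        assert classify_direction(r, "monotone") == "up"

    def test_not_significant_is_ns(self):
        r = _result({"18-30": (1.5, 1e-4), "18-42": (2.0, 1e-4),
                     "30-42": (1.3, 1e-4)}, sig=False)
        assert classify_direction(r, "pairwise-18", 0.01) == "ns"

    def test_missing_contrast_rejected(self):
        r = _result({"18-30": (1.5, 1e-4)})
        with pytest.raises(ValueError, match="missing contrast"):
            classify_direction(r, "monotone")


class TestFamilySummary:
    def test_counts_and_identity(self):
        results = []
        for d in ["up"] * 3 + ["down"] * 2 + ["mixed"] + ["ns"] * 4:
            r = AssociationResult(f"f{len(results)}", "genus")
            r.direction = d
            r.significant = d != "ns"
            results.append(r)
        out = summarize_families({"genus": results}, identified={"genus": 12})
        row = out.loc["genus"]
        assert row["identified"] == 12
        assert row["significant"] == 6
        assert (row["increasing"], row["decreasing"], row["mixed"]) == (3, 2, 1)

    def test_broken_identity_raises(self):
        r = AssociationResult("f", "genus")
        r.significant = True
        r.direction = "ns"  # inconsistent on purpose
        with pytest.raises(AssertionError, match="bookkeeping"):
            summarize_families({"genus": [r]})

    def test_empty_results_all_zero(self):
        out = summarize_families({"genus": []})
        assert (out.loc["genus", ["significant", "increasing",
                                  "decreasing", "mixed"]] == 0).all()


def test_analyze_table_end_to_end_small(default_design):
    eff = small_effect_spec(n_genera=6,
                            baseline={"Bacteroides": 0.08},
                            age_log_or={"Bacteroides": (1.2, 2.0)}, seed=9)
    genus, _, _ = generate_counts(default_design, eff, seed=9)
    results, flog, thr = analyze_table(genus, default_design, family="genus")
    assert thr == pytest.approx(sidak_threshold(0.05, len(results)))
    by_id = {r.feature_id: r for r in results}
    assert by_id["Bacteroides"].significant
    assert by_id["Bacteroides"].direction == "up"
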