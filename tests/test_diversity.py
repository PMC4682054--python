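import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.special import gammaln

from catgut.diversity import (fit_diversity_trend, gene_richness,
                              rarefaction_table, rarefy_richness,
                              scaled_depth_schedule, shannon_index,
                              shannon_per_sample)
from catgut.simulate import (CohortSpec, default_effect_spec, generate_counts,
                             generate_design)


class TestShannon:
    def test_uniform_is_log_richness(self):
        assert shannon_index(np.full(10, 0.1)) == pytest.approx(np.log(10))

    def test_single_species_is_zero(self):
        assert shannon_index([1.0]) == 0.0
        assert shannon_index([1.0, 0.0, 0.0]) == 0.0

    def test_closed_form_example(self):
        assert shannon_index([0.5, 0.25, 0.25]) == pytest.approx(
            1.5 * np.log(2), abs=1e-12)

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError):
            shannon_index([0.0, 0.0])

    @given(st.lists(st.floats(0.01, 1.0), min_size=2, max_size=8))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_permutation_invariant_and_split_increases(self, raw):
        p = np.array(raw) / np.sum(raw)
        h = shannon_index(p)
        rng = np.random.default_rng(0)
        assert shannon_index(rng.permutation(p)) == pytest.approx(h, abs=1e-12)
        # splitting one species into two equal halves strictly increases H'
        split = np.concatenate([p[:-1], [p[-1] / 2, p[-1] / 2]])
        assert shannon_index(split) > h


def expected_richness(counts, depth):
    """Closed form E[S_d] = sum_i 1 - C(N-N_i, d)/C(N, d)."""
    counts = np.asarray(counts)
    N = counts.sum()

    def log_comb(n, k):
        return gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1)

    total = 0.0
    for n_i in counts[counts > 0]:
        if N - n_i < depth:
            total += 1.0
        else:
            total += 1.0 - np.exp(log_comb(N - n_i, depth) - log_comb(N, depth))
    return total


class TestRarefaction:
    counts = np.array([50, 30, 20, 5, 1, 0])

    def test_exhaustive_depth_sees_every_taxon(self):
        out = rarefy_richness(self.counts, [int(self.counts.sum())],
                              replicates=4, seed=0)
        assert (out["richness"] == 5).all()

    def test_depth_one_sees_one_taxon(self):
        out = rarefy_richness(self.counts, [1], replicates=6, seed=0)
        assert (out["richness"] == 1).all()

    def test_non_integer_depth_rejected(self):
        with pytest.raises(ValueError, match="non-integer"):
            rarefy_richness(self.counts, [10.5], seed=0)

    def test_excessive_depth_skipped(self):
        out = rarefy_richness(self.counts, [10, 10_000], replicates=3, seed=0)
        assert set(out["depth"]) == {10}

    @pytest.mark.parametrize("depth", [5, 20, 60])
    def test_replicate_mean_matches_closed_form(self, depth):
        out = rarefy_richness(self.counts, [depth], replicates=1000, seed=3)
        exp = expected_richness(self.counts, depth)
        obs = out["richness"].to_numpy()
        se = obs.std(ddof=1) / np.sqrt(len(obs))
        assert abs(obs.mean() - exp) < 3 * max(se, 1e-3)

    def test_scaled_schedule_keeps_13_depths(self):
        sched = scaled_depth_schedule(50_000)
        assert len(sched) == 13
        assert sched[-1] == 50_000
        assert all(d >= 1 for d in sched)

    def test_table_is_deterministic(self, default_design, default_effects):
        genus, _, _ = generate_counts(default_design, default_effects, seed=7)
        sub = genus.select_samples(genus.sample_ids[:3])
        a = rarefaction_table(sub, replicates=2, seed=5)
        b = rarefaction_table(sub, replicates=2, seed=5)
        pd.testing.assert_frame_equal(a, b)


class TestGeneRichness:
    def test_union_over_age(self):
        import pandas as pd

        from catgut.tables import StudyDesign
        rows = [dict(sample_id="s1", kitten_id="k1", litter_id="L", sex="F",
                     neuter_group="EN", age_week=18, denominator=10),
                dict(sample_id="s2", kitten_id="k2", litter_id="L2", sex="M",
                     neuter_group="CN", age_week=18, denominator=10)]
        d = StudyDesign(pd.DataFrame(rows))
        per_sample, per_age = gene_richness(
            {"s1": frozenset("ab"), "s2": frozenset("bc")}, d)
        assert per_sample["s1"] == 2
        assert per_age[18] == 3

    def test_empty_sets_count_zero(self):
        per_sample, _ = gene_richness({"s1": frozenset()})
        assert per_sample["s1"] == 0

    def test_new_genus_at_later_age_increases_gene_richness(
            self, default_design):
        # a genus absent at week 18 but present later carries a private
        # gene pool, so the per-age union must grow
        from catgut.simulate import EffectSpec
        means = pd.DataFrame(
            {18: [0.5, 0.5, 0.0], 30: [0.4, 0.3, 0.3], 42: [0.4, 0.3, 0.3]},
            index=["A", "B", "C"])
        eff = EffectSpec(genus_means=means, theta=500.0, kitten_sd=0.0,
                         n_ko=4, seed=1)
        _, _, genes = generate_counts(default_design, eff, seed=1)
        _, per_age = gene_richness(genes, default_design)
        assert per_age[18] < per_age[30] == per_age[42]


class TestTrendModel:
    def test_constant_response_reports_nothing(self, default_design):
        vals = pd.Series(2.5, index=default_design.sample_ids)
        rep = fit_diversity_trend(vals, default_design)
        assert rep["final_terms"] == []
        assert not rep["age_significant"]
        assert all(v["estimate"] == 0.0 for v in rep["age_pairwise"].values())

    def test_default_cohort_reproduces_early_rise_pattern(self, default_design,
                                                          default_effects):
        # Shannon diversity on the calibrated cohort: week 18 below weeks
        # 30 and 42, with 30 vs 42 similar
        genus, _, _ = generate_counts(default_design, default_effects, seed=7)
        rep = fit_diversity_trend(shannon_per_sample(genus), default_design)
        assert rep["age_pairwise"]["18-30"]["significant"]
        assert rep["age_pairwise"]["18-42"]["significant"]
        assert rep["age_pairwise"]["18-30"]["estimate"] > 0
        assert rep["age_pairwise"]["18-42"]["estimate"] > 0

    def test_injected_age_means_recovered_with_null_gender(self):
        # age means 3.9 / 4.8 / 4.9, residual sd 0.3, over replicate
        # cohorts: the 18-30 and 18-42 gaps reach p < 1e-5, the small
        # 30-42 gap mostly does not, and the null gender effect drops
        early, late_ns, sex_dropped = 0, 0, 0
        n_rep = 10
        for seed in range(n_rep):
            rng = np.random.default_rng(100 + seed)
            design = generate_design(CohortSpec(seed=100 + seed))
            meta = design.indexed()
            mu = {18: 3.9, 30: 4.8, 42: 4.9}
            kit = {k: rng.normal(0, 0.15) for k in meta["kitten_id"].unique()}
            vals = pd.Series({s: mu[meta.loc[s, "age_week"]]
                              + kit[meta.loc[s, "kitten_id"]]
                              + rng.normal(0, 0.3) for s in meta.index})
            rep = fit_diversity_trend(vals, design)
            early += (rep["age_pairwise"]["18-30"]["p_tukey"] < 1e-5
                      and rep["age_pairwise"]["18-42"]["p_tukey"] < 1e-5)
            late_ns += not rep["age_pairwise"]["30-42"]["significant"]
            sex_dropped += "C(sex)" not in rep["final_terms"]
        assert early >= 9
        assert late_ns >= 7
        # a null covariate survives backward elimination with probability
        # roughly the union of the per-term test sizes, so "dropped" holds
        # in most but not ~95% of replicates
        assert sex_dropped >= 5

    def test_single_age_rejected(self):
        import pandas as pd

        from catgut.tables import StudyDesign
        rows = [dict(sample_id=f"s{i}", kitten_id=f"k{i}", litter_id="L",
                     sex="F", neuter_group="EN", age_week=18, denominator=10)
                for i in range(4)]
        d = StudyDesign(pd.DataFrame(rows))
        with pytest.raises(ValueError, match="2 ages"):
            fit_diversity_trend(pd.Series(1.0, index=d.sample_ids), d)
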