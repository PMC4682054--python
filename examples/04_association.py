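"""Per-feature longitudinal association testing with the binomial GEE.

Builds a small cohort with one injected age effect (log-odds-ratio 1.0
at both later ages on a 5% baseline feature), runs the zero filter, the
backward-eliminated binomial-logit GEE per feature, and Sidak
family-wise control, then prints the odds-ratio table.
"""

from catgut import analyze_table
from catgut.association import results_frame
from catgut.simulate import CohortSpec, generate_counts, generate_design, small_effect_spec

effects = small_effect_spec(baseline={"Clostridium": 0.05},
                            age_log_or={"Clostridium": (1.0, 1.0)}, seed=8)
design = generate_design(CohortSpec(seed=8))
genus, _, _ = generate_counts(design, effects, seed=8)

results, filter_log, threshold = analyze_table(genus, design, family="genus")
print(f"features analysed: {len(results)}  (removed by zero filter: "
      f"{len(filter_log)})")
print(f"Sidak critical p for this family: {threshold:.6f}")

frame = results_frame(results)
cols = ["feature_id", "OR_18_30", "OR_18_42", "p_age", "significant",
        "direction"]
print(frame[cols].round(3).to_string(index=False))

print("\nThe injected feature is called 'up' with odds ratios near "
      "exp(1.0) = 2.72. Because abundances are proportions, raising one "
      "feature necessarily depresses the rest (compositional closure); "
      "the dominant genus can therefore show a real, significant "
      "compensatory decrease. The remaining features stay below the "
      "Sidak bar.")
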