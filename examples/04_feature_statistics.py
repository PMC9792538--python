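"""Feature-significance screening across stages.

Samples a modest synthetic feature table, then prints per-feature one-way
ANOVA F/p, pooled skewness and excess kurtosis (normality screen: both in
[-2, 2]), and the max/min variance-homogeneity ratio.
"""

from mfbrain import feature_significance_table, sample_feature_table

data = sample_feature_table("kaggle", n_per_stage=40, seed=2)
table = feature_significance_table(data.to_frame(), critical=1.394)

cols = ["feature", "F", "p_value", "skewness", "kurtosis", "homogeneity_F"]
print(table[cols].to_string(index=False, float_format=lambda v: f"{v:.3g}"))
print("\nAll p-values are far below 0.05: every feature separates the "
      "synthetic stages, mirroring the screening that justifies the 10-feature set.")
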