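"""The full statistical battery on a small synthetic cohort.

Runs two groups end-to-end (without artifact injection, so the ICA stage
is skipped for speed) and prints the mixed ANOVAs, the FDR-corrected
462-test connectivity comparison, and the MMSE correlations.
"""

import numpy as np

from dmnrest import pipeline, synth

space = synth.make_source_space(1, seed=0)
lf = synth.make_lead_field(space)
cohort = synth.make_cohort(
    synth.ad_like_spec(n_subjects=8, duration_s=62.0),
    synth.mci_like_spec(n_subjects=8, duration_s=62.0),
    space, lf)

cfg = pipeline.RunConfig()
cfg.preprocess.ica = False
result = pipeline.analyze_cohort(cohort, space, lf, cfg)
report = pipeline.run_stats(result, cfg)

print("Three-way mixed ANOVA on normalized band power "
      "(Group x Band x Region):")
cols = ["effect", "F", "df1", "df2", "p_gg"]
print(report.anova_power[cols].round(4).to_string(index=False))

c = report.connectivity_contrasts
print(f"\nconnectivity battery: {len(c)} tests, "
      f"{int(c.significant.sum())} significant after FDR (q = 0.05)")
for _, row in c[c.significant].head(6).iterrows():
    larger = "AD" if row.direction > 0 else "MCI"
    print(f"  {row['pair']:>14} {row['band']:>6}: larger in {larger}, "
          f"p_fdr = {row.p_fdr:.4f}")

pc = report.power_correlations
post_alpha = pc[(pc.band == "alpha2") & pc.roi.str.startswith("PCu")]
print("\nMMSE vs normalized alpha2 power (precuneus):")
print(post_alpha.round(3).to_string(index=False))
print("\nthe Group x Band interaction and the posterior alpha/theta")
print("correlations with MMSE reflect the injected disease-like profile.")
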