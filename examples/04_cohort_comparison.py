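"""Cohort-level statistics: young vs adult binocular matching.

Simulates small young and adult voltage-clamp cohorts, analyzes every
cell, and runs the between/within-cohort test battery (two-sample K-S,
K-S against the Uniform(0,90) random-matching null, paired t, Pearson).
"""

from binomatch import (GeneratorConfig, analyze_dataset, compare_cohorts,
                       generate_cohort)

results = {}
for cohort, n in (("young", 12), ("adult", 10)):
    cfg = GeneratorConfig.preset(cohort, n_cells=n, seed=17)
    ds, _ = generate_cohort(cfg)
    results[cohort] = analyze_dataset(ds)

young, adult, tests = compare_cohorts(results["young"], results["adult"])

for s in (young, adult):
    print(f"{s.label} cohort (n = {s.n_cells}):")
    for name in ("delta_o_total", "delta_o_thalamic",
                 "thal_cort_diff_contra", "thal_cort_diff_ipsi"):
        m = s.metrics[name]
        print(f"  {name:24s} {m.mean:5.1f} +/- {m.sem:4.1f} deg")
print("\ntest battery:")
for t in tests:
    print(f"  {t.name:14s} {t.groups:42s} stat = {t.statistic:6.3f}  "
          f"p = {t.p_value:.3f}")
print()
print("Under the presets the young cohort's inter-ocular differences are")
print("larger (weak binocular matching before the critical period) and")
print("its ipsilateral thalamic-cortical difference approaches the 45-deg")
print("random level, while adult values are small for both eyes.")
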