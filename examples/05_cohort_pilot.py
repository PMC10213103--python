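"""Two-arm synthetic tumour pilot: screen, intersect, differentiate.

Generates two cohorts of nine subjects whose tumour texture differs by a
configurable effect size, screens scan-rescan reliability per arm, and runs
paired t-tests on the features robust in both arms.
"""

from cbctrad import StudyConfig, run_cohort_pilot

config = StudyConfig(wavelet=False, seed=42)
res = run_cohort_pilot(config)
print(res.report.summary().to_string(index=False))
print(f"\nfeatures robust in both arms: {len(res.robust_features)}")
if res.comparison is None:
    print(res.message)
else:
    sig = res.comparison[res.comparison["significant"]]
    print(f"significant at p < 0.05 (paired t, n = 9): {len(sig)}")
    print(sig.sort_values("p").head(6).to_string(index=False))
# With the default 1.5-sd texture shift, intensity-driven features separate
# the arms; with effect_size 0 the significant fraction calibrates to ~5%.
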