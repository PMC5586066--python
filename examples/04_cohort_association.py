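"""End-to-end synthetic case-control study with a planted spatial effect.

Generates a cohort whose case log-odds depend on the dense-tissue location
(log-odds coefficient 1 per SD of the latent angle), renders one phantom
per subject, and runs the whole pipeline: preprocessing, segmentation,
forces histograms, functional PCA, and the adjusted global likelihood-ratio
test with optimism-corrected validation.

Takes a few minutes (600 subjects at 128 x 128).
"""

from mammospat import CohortSpec, RunConfig, run_pipeline

config = RunConfig(
    cohort_spec=CohortSpec(
        n_cases=300, n_controls=300, seed=7, beta={"z_dense_angle": 1.0}
    ),
    bootstrap_B=100,
    do_stepwise=True,
    seed=7,
)
result = run_pipeline(config)

stat, df, p = result.global_test
print(f"global LRT: statistic {stat:.2f} on {df} df, p = {p:.3g}")
print(f"stepwise-selected components: {result.selected_fpcs}")
v = result.validation
print(f"spatial-relations score, per-SD OR: apparent {v.apparent_per_sd_or:.2f}, "
      f"honest {v.honest_per_sd_or:.2f}")
print(f"AUC (full model): apparent {v.apparent['auc_full']:.3f}, "
      f"honest {v.honest['auc_full']:.3f}")
# The global test rejects (the planted dense-location effect is recovered
# through the image pipeline) and the honest estimates sit below the
# apparent ones -- the optimism correction at work.
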