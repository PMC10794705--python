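"""Compare simulated 'pipelines' of different quality across communities.

Simulates three pipelines with increasing corruption over four replicate
communities, summarizes the metrics per (community, pipeline), and runs
the cross-pipeline Kruskal-Wallis test with pairwise post-hoc
comparisons under Benjamini-Hochberg FDR control.
"""

from taxabench import (
    SimulationConfig,
    compare_pipelines,
    evaluate_sample,
    generate_expected,
    metric_table,
    metrics_frame,
    simulate_observed,
    summarize,
)

PIPELINE_QUALITY = {
    "sharp": dict(dropout_prob=0.02, fp_mass_pct=1.0, noise_sigma=0.1),
    "decent": dict(dropout_prob=0.10, fp_mass_pct=5.0, noise_sigma=0.3),
    "noisy": dict(dropout_prob=0.25, fp_mass_pct=15.0, noise_sigma=0.6),
}

results = []
for c, community_seed in enumerate((1, 2, 3, 4)):
    base = SimulationConfig(seed=community_seed, n_species=20, design="staggered")
    expected = generate_expected(base)
    expected.community_id = f"community-{c}"
    for p_i, (pipeline, quality) in enumerate(PIPELINE_QUALITY.items()):
        config = SimulationConfig(
            seed=100 * community_seed + p_i, n_species=20, design="staggered",
            n_replicates=3, n_false_positives=4, **quality,
        )
        profiles, _ = simulate_observed(expected, config, pipeline_id=pipeline)
        results += [evaluate_sample(expected, profile) for profile in profiles]

metrics = metrics_frame(results)
summaries = summarize(metrics)
print("AD summary (mean per community, grand average in the last row):")
print(metric_table(summaries, "AD").round(2).to_string())

kw, pairwise = compare_pipelines(metrics, metric="AD", unit="community")
print(f"\nKruskal-Wallis across pipelines: H={kw.statistic:.2f}, p={kw.p_value:.4f}")
print("\npairwise rank tests (BH-adjusted):")
print(pairwise.round(4).to_string(index=False))
print("\nsmall adjusted p-values flag pipeline pairs whose AD distributions "
      "genuinely differ; with only 4 communities per group, power is limited.")
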