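"""Re-derive the published five-pipeline benchmark aggregates from the
bundled per-community summary cells.

The package ships the per-community mean metric cells of a published
mock-community benchmark.  Feeding them back through the aggregation
operations reproduces the published per-pipeline grand averages, the
per-community difficulty scores, and the panel F1 harmonic means.
"""

from taxabench import (
    PIPELINES,
    community_average,
    harmonic_mean_ignoring_missing,
    load_benchmark_f1,
    load_benchmark_means,
    pipeline_average,
)

means = load_benchmark_means()
ad = means[means.metric == "AD"]

print("grand-average Aitchison distance per pipeline (lower = closer to truth):")
for pipeline in PIPELINES:
    cells = ad[ad.pipeline_id == pipeline]["mean"].tolist()
    grand, sd = pipeline_average(cells)
    print(f"  {pipeline:12s} {grand:6.2f} +/- {sd:.2f}  (n={len(cells)} communities)")

print("\ncommunity difficulty (mean AD across pipelines; higher = harder):")
for community in ("BMock12", "NIST-MIX-C", "Amos-HiLo"):
    cells = ad[ad.community_id == community]["mean"].tolist()
    print(f"  {community:12s} {community_average(cells):6.2f}")

f1 = load_benchmark_f1()
print("\npanel F1 harmonic means per pipeline:")
for threshold in (0.0, 0.01):
    row = []
    for pipeline in PIPELINES:
        col = f1[(f1.threshold_pct == threshold) & (f1.pipeline_id == pipeline)].f1
        row.append(f"{pipeline}={harmonic_mean_ignoring_missing(col.tolist()):.3f}")
    print(f"  at {threshold}%: " + ", ".join(row))
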