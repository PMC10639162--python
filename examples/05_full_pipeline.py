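"""Run the whole two-track analysis from one config and list its artifacts.

Writes per-district classification metrics, per-district top-5 Shapley
factors, and the GWLASSO coefficient summary — the three table shapes the
analysis reports — plus GeoJSON layers and a run log, into ./scratch_run.
"""

from pathlib import Path

from obesifact.report import PipelineConfig, run_pipeline

cfg = PipelineConfig(seed=0, n_individuals=2000, trees=50, folds=5, shap_sample=50)
result = run_pipeline(cfg, Path("scratch_run"))

print("selected features:", result.survivors)
print("\nper-district classification (last rows; Total = mean ± sd):")
print(result.metrics.tail(3).to_string(index=False))
print("\ntop factors for the first district:")
print(result.top_features.head(cfg.top_k).to_string(index=False))
print("\nGWLASSO summary:")
print(result.gwlasso_summary.to_string(index=False))
print("\nartifacts written to:", result.out_dir.resolve())
for p in sorted(result.out_dir.iterdir()):
    print("  ", p.name)
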