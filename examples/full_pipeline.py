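"""Run the whole analysis through the config-driven pipeline.

Equivalent to ``predeath run-all`` on the command line; every stage's
artifacts land in the output directory together with a manifest recording
config hash, timings and artifact digests.
"""

from predeath.pipeline import PipelineConfig, run_pipeline

config = PipelineConfig(
    n_patients=200,
    seed=0,
    horizons=(1, 15, 30, 45, 60, 75, 90),
    embed_method="umap",
    outdir="pipeline_run",
)
manifest = run_pipeline(config)

print("stages:", ", ".join(manifest.stages_completed))
for key, value in manifest.report.items():
    print(f"  {key}: {value}")
print(f"{len(manifest.artifacts)} artifacts written to {config.outdir}/ "
      "(see manifest.json)")
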