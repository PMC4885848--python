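"""Run the whole analysis pipeline on a synthetic cohort.

Simulate -> fit -> model selection -> behavioral report in one call,
writing per-subject metrics and a JSON summary to ./pipeline_output.
With the default cohort size (31) this takes a few minutes; shrink
``cohort_size`` for a quick look.
"""

import json

from perceptlearn.pipeline import PipelineConfig, run_pipeline

config = PipelineConfig(cohort_size=8, seed=1, bms_samples=200_000)
cohort, evidence, fits, bms, metrics, summary = run_pipeline(
    config, out_dir="pipeline_output"
)

summary.pop("evidence")  # the full evidence matrix is too bulky to print
print(json.dumps(summary, indent=2))
print("\nArtifacts written to ./pipeline_output (metrics.csv, summary.json)")
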