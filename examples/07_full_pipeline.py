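"""Run the full pipeline end to end and render the Markdown report.

Equivalent to `electrome all --seed 3 --out runs/demo` on the command
line; every artefact (recordings, parameter tables, feature matrices,
model reports, figures, manifest) lands in one directory.
"""

from electrome import PipelineConfig, render_report, run_pipeline

cfg = PipelineConfig(
    out_dir="scratch/pipeline_demo",
    seed=3,
    n=8192,          # ~131 s per recording at 62.5 Hz: a desk-scale stand-in
    n_per_class=3,   # recordings per condition cell
    n_repeats=10,    # cross-validation repeats
    max_scale=10,    # multiscale-entropy depth
)
out = run_pipeline(cfg)
report = render_report(out)

print("artefacts:")
for p in sorted(out.iterdir()):
    print("  ", p.name)
print("report:", report)
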