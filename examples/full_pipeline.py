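"""Run the whole workflow end to end and render the candidate report."""

from offtarget import PipelineConfig, run_pipeline
from offtarget.pipeline import render_report

report = run_pipeline(PipelineConfig(seed=1))

print("top off-target candidates (combined rank = pocket-similarity rank "
      "+ pathway-evidence rank):")
cols = ["protein_id", "pocket_score", "pathway", "combined_rank"]
print(report.candidates[cols].head(5).to_string(index=False))

print("\nlesion hypotheses by correlation with the rescue pattern:")
print(report.scenario_ranking.head(3).to_string(index=False))

print("\nassay summary:")
for k, v in report.assay_summary.items():
    print(f"  {k}: {v:.4g}")

paths = render_report(report, "scratch/example_report")
print(f"\nwrote {len(paths)} report files under scratch/example_report/")
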