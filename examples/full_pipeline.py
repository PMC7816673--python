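"""Run the whole pipeline on the built-in synthetic study and score it.

Simulates 10 host strains (12 virus species, two co-infections, one
divided-RdRp virus), then calls termini, groups cognate segments,
annotates RdRp architectures, clusters OTUs, and compares every stage
with the simulator's ground truth.
"""

from fldskit.io import PipelineConfig
from fldskit.pipeline import evaluate_against_truth, run_pipeline

config = PipelineConfig(seed=1)
study, result = run_pipeline(config)
metrics = evaluate_against_truth(study, result)

print(f"strains: {len(study.segments)}, segments: {metrics['n_segments']}, "
      f"assemblies: {metrics['n_assemblies']}, OTUs: {len(result.otus)}")
print(f"terminus recall:            {metrics['terminus_recall']:.2f}")
print(f"completeness accuracy:      {metrics['completeness_accuracy']:.2f}")
print(f"segment-grouping ARI:       {metrics['grouping_ari']:.2f}")
print(f"RdRp architecture accuracy: {metrics['architecture_accuracy']:.2f}")
print(f"OTU partition ARI:          {metrics['otu_ari']:.2f}")
print("\n1.00 everywhere means the pipeline recovered the simulated truth")
print("exactly: every terminus, every cognate-segment grouping (including")
print("both co-infected strains), all four RdRp architecture classes, and")
print("the OTU partition (the species shared by two strains collapses")
print("into a single OTU).")
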