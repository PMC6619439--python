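"""Condition-specific co-expression networks with the q < 0.001 edge rule.

Runs the full brain pipeline on synthetic data in which withdrawal
astrocytes carry a shared activation factor across the inflammatory genes,
then prints per-condition edge counts and the degree gain of Tnf.
"""

import scdeltact as sd

bundle = sd.run_brain_pipeline(
    sd.PipelineConfig(seed=7, outdir="scratch/example_networks")
)

summary = bundle["edge_summary"]
print("edges per (treatment : cell type) network at q < 0.001:")
print(summary["edge_counts"].sort_index().to_string())

deg = summary["degree"]
print("\nTnf degree per condition (non-zero only):")
print(deg.loc["Tnf"][deg.loc["Tnf"] > 0].to_string())
print("\nOnly the withdrawal-astrocyte condition grows a dense network: its")
print("planted co-activation factor produces correlations strong enough to")
print("survive the q < 0.001 false-discovery cut; null conditions stay empty.")
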