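"""Pick stable housekeeping genes by variance + geNorm M, then normalize.

Generates a synthetic brain panel in which Ldha and Actb are the planted
most-stable candidates, ranks all housekeeping candidates, and prints the
stability table and the chosen reference pair.
"""

import scdeltact as sd

cfg = sd.default_brain_config(seed=1, cell_types=("neuron",))
ct, meta, truth = sd.generate_sc_qpcr(cfg)

ranking = sd.genorm_m(ct, list(cfg.housekeeping_sd))
refs = sd.select_reference_genes(ranking, n_refs=2, never_select=(cfg.control_gene,))

print("stability table (lower M / lower variance = more stable):")
print(ranking.table.round(4).to_string())
print("\ngeNorm iterative exclusion order (worst first):", ranking.exclusion_order)
print("selected reference pair:", refs)
print("planted most-stable pair:", list(truth.stable_pair))
# Gapdh is the designated independent control: normalized, never a reference
assert cfg.control_gene not in refs
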