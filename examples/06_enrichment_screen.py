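"""Label-free pull-down enrichment screen on a spiked synthetic matrix.

Simulates an intensity matrix (3 bait vs 3 control replicates, 30 truly
enriched proteins at 32-fold, missing-not-at-random dropout), runs the
filter -> normalize -> impute -> S0-Welch -> permutation-FDR chain, and
scores the calls against the spike-in truth.
"""

import cargoquant as cq

spec = cq.ProteomicsSimSpec(n_proteins=800, n_spiked=30,
                            spike_log2_effect=5.0, rep_log2_sd=0.5,
                            dropout_max=0.3, seed=42)
matrix, spiked = cq.simulate_proteomics_matrix(spec)
groups = {"bait": ["bait_1", "bait_2", "bait_3"],
          "ctrl": ["ctrl_1", "ctrl_2", "ctrl_3"]}

table = cq.run_enrichment(matrix, groups, s0=0.1, n_perm=250, seed=0)
called = set(table.index[table["enriched"]])
spiked = set(spiked) & set(table.index)  # spikes surviving the filters

print(f"proteins tested: {len(table)}")
print(f"enriched calls (log2FC > 3.322, q < 0.05): {len(called)}")
print(f"true positives: {len(called & spiked)} of {len(spiked)} spiked")
print(f"false positives: {len(called - spiked)}")
print("\ntop of the volcano table:")
v = cq.volcano_table(table).sort_values("neg_log10_q", ascending=False)
print(v.head(5).to_string(index=False))
# enriched proteins sit in the upper-right of the volcano: >10-fold
# enrichment on the bait at a permutation FDR below 5%.
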