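"""Ligand-receptor communication network of the acute phase.

A gene is 'expressed' by a cell type when at least 20% of that type's
cells carry at least one count. Each ligand-receptor couple whose
ligand is expressed by type S and receptor by type T adds a directed
link S -> T; the couple count per link is the network's edge weight.
"""

import cardiocomm as cc

cfg = cc.RunConfig(seed=0)
sim = cc.default_config(seed=0)
matrix, annot, truth = cc.simulate_dataset(sim)
expr, _ = cc.quantify_pipeline(matrix, cfg)
annot = annot.subset(list(expr.cell_ids))

networks = cc.build_condition_networks(expr, annot, sim.lr_table(), cfg)
net = networks["1dpIR"]
print("1dpIR network, couples per directed link:")
print(net.couple_counts().to_string(index=False))
print("\nsupporting couples:")
print(net.couples_frame().to_string(index=False))
print("\nautocrine loops (source = target) count signaling back to the "
      "sending type; every link is backed by the planted couples")
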