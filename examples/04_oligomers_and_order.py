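"""Identify oligomers and score their internal order.

Builds a frame holding one 8-peptide and one 25-peptide cluster plus a
well-separated random gas, clusters peptide centres of mass at the 11 A
(1.1 nm) cross-beta threshold, and reports per-oligomer size, nematic
order parameter P2 and radius of gyration.
"""

from strandscan import (
    identify_oligomers,
    make_clustered_aggregate,
    make_random_gas,
    order_report,
    peptide_centers,
)

frame, topology, designed = make_clustered_aggregate(
    cluster_sizes=[8, 25], intra_com_distance=10.0,
    inter_cluster_distance=50.0, seed=4,
)
oligomers = identify_oligomers(peptide_centers(frame, topology), cutoff=11.0)
print(f"designed clusters: {[len(c) for c in designed]}")
print(f"recovered:         {[len(c) for c in oligomers.components]}")
for o in order_report(frame, topology, oligomers).oligomers:
    print(f"  {o.size:2d}-mer  P2 = {o.p2:.3f}  Rg = {o.radius_of_gyration:.1f} A")

gas, gas_topology = make_random_gas(30, 10, box=250.0, min_separation=20.0, seed=4)
gas_oligomers = identify_oligomers(
    peptide_centers(gas, gas_topology), cutoff=11.0, box=gas.box
)
print(f"gas of 30 peptides at >=20 A separation: "
      f"{gas_oligomers.n_oligomers} oligomers, "
      f"{len(gas_oligomers.singletons)} singletons")

# Cluster membership is recovered exactly.  P2 is low here because the
# clustered peptides point in random directions — ordered (sheet-like)
# aggregates would score P2 near 1, disordered molten globules below 0.5.
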