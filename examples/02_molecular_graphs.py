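"""Turn SMILES strings into the attributed heavy-atom graphs the GNNs eat.

Nodes carry one-hot element/hybridization/aromaticity plus the hydrogen
count; hydrogens themselves are implicit. Carbon atoms are the K-edge
absorbers, so their indices matter downstream.
"""

import xasgnn as x

for smiles in ("CCO", "c1ccccc1", "CC(=O)N"):
    g = x.build_graph(smiles)
    print(f"{smiles:10s} -> {g.n_atoms} heavy atoms {g.elements}, "
          f"{g.n_edges} bonds, H counts {g.hydrogen_counts}, "
          f"carbons at {x.carbon_indices(g)}")
print("feature vector of atom 0 in ethanol:",
      x.build_graph("CCO").node_features[0].tolist())
# layout: element one-hot (C,N,O,F) | hybridization (sp,sp2,sp3,other)
#         | aromatic (no,yes) | number of hydrogens
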