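"""Chart how network parameters depend on species richness (rarefaction).

Repeatedly samples k species (with replacement, duplicates kept) and
rebuilds the network: edge density rises and modularity falls as more
species enter, because correlation tests gain power.
"""

import traitnet as tn

matrix = tn.log_transform(tn.generate(tn.SyntheticConfig(seed=42)))
counts = [10, 25, 50, 100, 188]
curve = tn.rarefaction(matrix, counts=counts, R=100, seed=0)

print("species  edge_density(mean±se)  modularity(mean±se)")
for c in counts:
    d = curve.summaries[c]["edge_density"]
    q = curve.summaries[c]["modularity"]
    print(f"{c:7d}  {d.mean:.3f} ± {d.se:.4f}       {q.mean:.3f} ± {q.se:.4f}")
print("(more species -> more significant edges -> denser, less modular nets)")
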