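"""Generate a synthetic drug-response benchmark with planted ground truth.

A designated set of driver genes is wired onto guaranteed
gene -> protein-complex -> pathway -> drug paths, and each (cell line, drug)
pair's ln IC50 is derived from the cell's driver values on paths reaching
the drug. Everything is a pure function of the spec and its seed.
"""

import numpy as np

from biodrp import SyntheticSpec, generate_dataset

spec = SyntheticSpec(n_cells=80, fingerprint_bits=128, seed=42)
ds = generate_dataset(spec)
bundle = ds.bundle

print(f"hierarchy nodes (genes/proteins/pathways/drugs): "
      f"{bundle.hierarchy.node_counts()}")
print(f"driver genes: {', '.join(ds.driver_genes)}")
for m in bundle.omics:
    print(f"  {m.kind:4s}: {len(m.cell_ids)} cells x {len(m.feature_ids)} features")

labels = np.array([r.label for r in bundle.responses])
print(f"{len(bundle.responses)} response pairs, "
      f"{labels.mean():.1%} sensitive (roughly 2:1 resistant:sensitive)")
print(f"example record: {bundle.responses[0]}")
# The label equals 1 exactly when exp(ln_ic50) <= the drug's maximum
# screening concentration, i.e. the cell is killed within the tested range.
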