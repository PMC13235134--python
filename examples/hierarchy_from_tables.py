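"""Build, filter and prune a biological hierarchy from annotation tables.

Edge tables (gene->protein-complex with interaction scores,
protein->pathway with enrichment p-values, pathway->drug targets) become a
four-level graph; insignificant pathways are removed, then iterative
forward/backward pruning keeps only nodes on a complete gene->drug path.
The surviving structure yields the binary masks of the network layers.
"""

import pandas as pd

from biodrp import (build_hierarchy, filter_significant_pathways,
                    masks_from_hierarchy, overrepresentation_pvalue,
                    prune_hierarchy)

gp = pd.DataFrame([("KRAS", "cplx1", 0.9), ("EGFR", "cplx1", 0.8),
                   ("STK11", "cplx2", 0.7), ("ORPHAN", "cplx3", 0.5)],
                  columns=["gene_id", "protein_id", "score"])
pk = pd.DataFrame([("cplx1", "hsa04010", 0.001, 1.8),
                   ("cplx2", "hsa04150", 0.02, 1.2),
                   ("cplx3", "hsa99999", 0.30, 0.4)],  # not significant
                  columns=["protein_id", "pathway_id", "p_value",
                           "combined_score"])
kd = pd.DataFrame([("hsa04010", "erlotinib"), ("hsa04150", "rapamycin")],
                  columns=["pathway_id", "drug_id"])

h = build_hierarchy(gp, pk, kd,
                    gene_universe=["KRAS", "EGFR", "STK11", "ORPHAN"],
                    drug_universe=["erlotinib", "rapamycin"])
print("built:", h.node_counts(), "(genes, proteins, pathways, drugs)")

h = filter_significant_pathways(h, alpha=0.05)   # drops hsa99999
pruned = prune_hierarchy(h)                      # then ORPHAN and cplx3
print("pruned:", pruned.node_counts())

m_gp, m_pk, m_kd = masks_from_hierarchy(pruned)
print("gene->protein mask:")
print(pd.DataFrame(m_gp.mask, index=m_gp.source_ids, columns=m_gp.target_ids))

# the over-representation stand-in: 3 of 4 drawn proteins in an 8-member
# pathway from a 40-protein universe
p = overrepresentation_pvalue(protein_set_size=4, pathway_size=8,
                              overlap=3, universe=40)
print(f"hypergeometric over-representation p-value: {p:.4f}")
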