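"""Quantify what each omics layer contributes to prediction.

Re-runs the full pipeline with the integration restricted to subsets of the
four omics kinds (the hierarchy is re-pruned against each reduced gene
universe). Because the planted signal is spread across all four layers, the
all-omics model should lead every single-omics configuration.
"""

from biodrp import SyntheticSpec, TrainConfig, generate_dataset, run_ablation

spec = SyntheticSpec(n_cells=200, signal_strength=4.0, noise_sd=0.3,
                     fingerprint_bits=128, edge_density_pk=0.6,
                     edge_density_kd=1.0, seed=2)
ds = generate_dataset(spec)
table = run_ablation(ds.bundle, TrainConfig(epochs=50, seed=2), k=3, seed=2)
print(table.to_string(index=False, float_format=lambda v: f"{v:.4f}"))
# "w/o X" rows integrate the three remaining layers; "only X" rows use one.
# A drop relative to "all" measures the unique information in the removed
# omics under this planted mechanism.
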