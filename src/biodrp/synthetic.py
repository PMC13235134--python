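"""Synthetic benchmark generator with a planted response mechanism.

Generates everything the pipeline consumes — a gene -> protein-complex ->
pathway -> drug hierarchy, four omics layers, a drug table with SMILES and
maximum screening concentrations, and labelled (cell line, drug) responses —
with known ground truth. A designated set of *driver genes* is wired onto
guaranteed gene->drug paths, and each pair's latent sensitivity is a linear
function of the cell's driver values on paths reaching the drug plus a small
drug-fingerprint term and Gaussian noise. ln IC50 values are emitted so that
binarizing against the stored per-drug max_conc reproduces the planted
label exactly.

Determinism: every quantity is a pure function of (spec, seed). One global
seed feeds named, independent substreams (hierarchy / omics / drugs /
responses / cancer types), so adding a generator never perturbs the others.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import norm

from .drugs import DrugSet, ResponseRecord, make_records
from .evaluation import DataBundle
from .hierarchy import BioHierarchy, drugs_reached_by
from .omics import OmicsMatrix

_STREAMS = {"hierarchy": 0, "omics": 1, "drugs": 2, "responses": 3, "cancer": 4}

# sensitive fraction ~ 1/3 at default noise: the latent score is standardized
# and thresholded at the 2/3 quantile of the standard normal
_SENSITIVE_OFFSET = float(norm.ppf(2.0 / 3.0))

_CANCER_TYPES = ("LUAD", "BRCA", "SKCM", "PAAD", "COAD", "GBM", "CLL", "LUSC")

_SMILES_ATOMS = ("C", "C", "C", "N", "O", "S")  # C-rich chains, always valid


@dataclass
class SyntheticSpec:
    """Generator parameters; defaults define a desk-scale benchmark with a
    recoverable planted signal and a roughly 2:1 resistant:sensitive ratio."""

    n_cells: int = 120
    n_genes: int = 60
    n_proteins: int = 24
    n_pathways: int = 10
    n_drugs: int = 8
    edge_density_gp: float = 0.12
    edge_density_pk: float = 0.30
    edge_density_kd: float = 0.35
    n_driver_genes: int = 6
    signal_strength: float = 3.0
    noise_sd: float = 0.5
    fingerprint_bits: int = 1024
    fingerprint_radius: int = 2
    n_cancer_types: int = 4
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_cells", "n_genes", "n_proteins", "n_pathways", "n_drugs",
                     "n_driver_genes", "fingerprint_bits", "n_cancer_types"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        for name in ("edge_density_gp", "edge_density_pk", "edge_density_kd"):
            d = getattr(self, name)
            if not 0.0 < d <= 1.0:
                raise ValueError(f"{name} must lie in (0, 1], got {d}")
        if self.n_driver_genes > self.n_genes:
            raise ValueError("n_driver_genes exceeds n_genes")
        if self.signal_strength < 0 or self.noise_sd < 0:
            raise ValueError("signal_strength and noise_sd must be >= 0")

    def rng(self, stream: str) -> np.random.Generator:
        return np.random.default_rng(
            np.random.SeedSequence(self.seed, spawn_key=(_STREAMS[stream],)))

    @property
    def gene_ids(self) -> list[str]:
        return [f"g{i:04d}" for i in range(1, self.n_genes + 1)]

    @property
    def driver_genes(self) -> list[str]:
        # drivers are the first genes of the universe; identity is part of
        # the ground truth, not hidden state
        return self.gene_ids[: self.n_driver_genes]


def generate_hierarchy(spec: SyntheticSpec) -> BioHierarchy:
    """Random four-level wiring at the stated densities, then repair: every
    driver gene is guaranteed at least one full gene->drug path (edges are
    added along a random walk where wiring left it disconnected)."""
    rng = spec.rng("hierarchy")
    genes = spec.gene_ids
    prots = [f"p{i:03d}" for i in range(1, spec.n_proteins + 1)]
    paths = [f"k{i:03d}" for i in range(1, spec.n_pathways + 1)]
    drugs = [f"d{i:03d}" for i in range(1, spec.n_drugs + 1)]

    def wire(sources, targets, density):
        hits = rng.random((len(sources), len(targets))) < density
        return {(s, t) for i, s in enumerate(sources)
                for j, t in enumerate(targets) if hits[i, j]}

    gp = wire(genes, prots, spec.edge_density_gp)
    pk = wire(prots, paths, spec.edge_density_pk)
    kd = wire(paths, drugs, spec.edge_density_kd)

    for g in spec.driver_genes:
        my_prots = {p for (gg, p) in gp if gg == g}
        if not my_prots:
            p = prots[rng.integers(len(prots))]
            gp.add((g, p))
            my_prots = {p}
        my_paths = {k for (p, k) in pk if p in my_prots}
        if not my_paths:
            p = sorted(my_prots)[rng.integers(len(my_prots))]
            k = paths[rng.integers(len(paths))]
            pk.add((p, k))
            my_paths = {k}
        if not any(k in my_paths for (k, _) in kd):
            k = sorted(my_paths)[rng.integers(len(my_paths))]
            kd.add((k, drugs[rng.integers(len(drugs))]))

    gp_scores = {e: float(rng.uniform(0.4, 1.0)) for e in sorted(gp)}
    pk_scores = {e: float(rng.uniform(0.5, 2.0)) for e in sorted(pk)}

    h = BioHierarchy(genes=genes, proteins=prots, pathways=paths, drugs=drugs,
                     edges_gp=gp, edges_pk=pk, edges_kd=kd,
                     gp_scores=gp_scores, pk_scores=pk_scores)
    # driver-path pathways are strongly enriched so the default significance
    # filter (alpha=0.05) never severs the planted mechanism
    driver_paths = set()
    for g in spec.driver_genes:
        ps = {p for (gg, p) in gp if gg == g}
        driver_paths |= {k for (p, k) in pk if p in ps}
    pvals = {}
    for k in paths:
        if k in driver_paths:
            pvals[k] = float(rng.uniform(0.0, 0.01))
        else:
            pvals[k] = float(rng.uniform(0.0, 0.2))
    h.pathway_pvalues = pvals
    return h


def generate_omics(spec: SyntheticSpec, hierarchy: BioHierarchy) -> list[OmicsMatrix]:
    """Four omics layers over overlapping but non-identical gene subsets.

    GE covers every gene (N(0,1)); CNV covers drivers plus even-indexed
    genes (discrete {0..4}/4); MUT covers drivers plus every third gene
    (Beta(2,5) variant-allele fractions); PROT covers drivers plus another
    third (N(0,1) product abundance, keyed by gene ID). Drivers therefore
    appear in all four layers, spreading the planted signal across omics,
    while some genes appear in exactly one.
    """
    rng = spec.rng("omics")
    cells = [f"c{i:04d}" for i in range(1, spec.n_cells + 1)]
    genes = spec.gene_ids
    drivers = set(spec.driver_genes)

    def subset(pred):
        return [g for i, g in enumerate(genes) if g in drivers or pred(i)]

    ge_feats = list(genes)
    cnv_feats = subset(lambda i: i % 2 == 0)
    mut_feats = subset(lambda i: i % 3 == 0)
    prot_feats = subset(lambda i: i % 3 == 1)

    ge = rng.normal(0.0, 1.0, (spec.n_cells, len(ge_feats)))
    cnv = rng.integers(0, 5, (spec.n_cells, len(cnv_feats))) / 4.0
    mut = rng.beta(2.0, 5.0, (spec.n_cells, len(mut_feats)))
    prot = rng.normal(0.0, 1.0, (spec.n_cells, len(prot_feats)))
    return [
        OmicsMatrix(cells, ge_feats, ge, "GE"),
        OmicsMatrix(cells, cnv_feats, cnv, "CNV"),
        OmicsMatrix(cells, mut_feats, mut, "MUT"),
        OmicsMatrix(cells, prot_feats, prot, "PROT"),
    ]


def generate_drugs(spec: SyntheticSpec, hierarchy: BioHierarchy) -> DrugSet:
    """Random linear heteroatom SMILES per drug (always parseable, distinct
    Morgan neighborhoods) with lognormal maximum screening concentrations."""
    rng = spec.rng("drugs")
    smiles, max_conc = {}, {}
    for d in hierarchy.drugs:
        length = int(rng.integers(4, 11))
        atoms = [_SMILES_ATOMS[i] for i in rng.integers(0, len(_SMILES_ATOMS), length)]
        smiles[d] = "".join(atoms)
        max_conc[d] = float(np.exp(rng.normal(0.0, 0.5)))
    return DrugSet.from_table(list(hierarchy.drugs), smiles, max_conc,
                              radius=spec.fingerprint_radius,
                              n_bits=spec.fingerprint_bits)


def driver_values(spec: SyntheticSpec, omics: list[OmicsMatrix]) -> pd.DataFrame:
    """Per-cell planted value of each driver gene: the mean of its z-scored
    columns over the omics layers that contain it."""
    cells = omics[0].cell_ids
    out = pd.DataFrame(0.0, index=cells, columns=spec.driver_genes)
    counts = pd.Series(0, index=spec.driver_genes, dtype=float)
    for m in omics:
        df = m.to_frame()
        for g in spec.driver_genes:
            if g in df.columns:
                col = df[g].to_numpy()
                sd = col.std()
                z = (col - col.mean()) / sd if sd > 0 else np.zeros_like(col)
                out[g] += z
                counts[g] += 1
    return out / counts.replace(0, 1)


def generate_responses(spec: SyntheticSpec, hierarchy: BioHierarchy,
                       omics: list[OmicsMatrix], drugs: DrugSet,
                       cancer_map: dict[str, str] | None = None,
                       ) -> tuple[list[ResponseRecord], pd.DataFrame]:
    """Planted-mechanism responses for every (cell, drug) pair.

    Latent score: signal_strength * (mean driver value over drivers with a
    hierarchy path to the drug) + a fingerprint-bit term, standardized over
    all pairs, plus N(0, noise_sd) noise, minus an offset placing the
    sensitive fraction near 1/3. ln IC50 = ln(max_conc) - score, so Eq-style
    binarization against the stored max_conc reproduces score >= 0 exactly.

    Returns (records, truth table with the latent score per pair).
    """
    rng = spec.rng("responses")
    cells = omics[0].cell_ids
    dv = driver_values(spec, omics)

    u = rng.normal(0.0, 1.0, drugs.n_bits)
    fp_term = {}
    for d in drugs.drug_ids:
        fp = drugs.fingerprint_of(d)
        nnz = max(1.0, fp.sum())
        fp_term[d] = float(fp @ u / np.sqrt(nnz))

    reach = {g: drugs_reached_by(hierarchy, g) for g in spec.driver_genes}
    drug_ids = list(drugs.drug_ids)
    raw = np.zeros((len(cells), len(drug_ids)))
    for j, d in enumerate(drug_ids):
        hitters = [g for g in spec.driver_genes if d in reach[g]]
        s = dv[hitters].mean(axis=1).to_numpy() if hitters else np.zeros(len(cells))
        raw[:, j] = spec.signal_strength * s + 0.5 * fp_term[d]
    sd = raw.std()
    raw_std = (raw - raw.mean()) / sd if sd > 0 else raw - raw.mean()
    z = raw_std + rng.normal(0.0, spec.noise_sd, raw.shape) - _SENSITIVE_OFFSET

    cell_col, drug_col, ln_ic50 = [], [], []
    for i, c in enumerate(cells):
        for j, d in enumerate(drug_ids):
            cell_col.append(c)
            drug_col.append(d)
            ln_ic50.append(np.log(drugs.max_conc[d]) - z[i, j])
    records = make_records(cell_col, drug_col, ln_ic50, drugs, cancer_map)
    truth = pd.DataFrame({"cell_id": cell_col, "drug_id": drug_col,
                          "latent": z.ravel(),
                          "label": [r.label for r in records]})
    return records, truth


def generate_cancer_map(spec: SyntheticSpec) -> dict[str, str]:
    """Random assignment of cells to cancer types (every type non-empty for
    n_cells >= n_cancer_types)."""
    rng = spec.rng("cancer")
    types = list(_CANCER_TYPES[: spec.n_cancer_types])
    if spec.n_cancer_types > len(_CANCER_TYPES):
        types += [f"TYPE{i}" for i in range(len(_CANCER_TYPES), spec.n_cancer_types)]
    cells = [f"c{i:04d}" for i in range(1, spec.n_cells + 1)]
    assign = [types[i % len(types)] for i in range(len(cells))]
    rng.shuffle(assign)
    return dict(zip(cells, assign))


@dataclass
class SyntheticDataset:
    """A complete generated benchmark plus its ground truth."""

    spec: SyntheticSpec
    bundle: DataBundle
    driver_genes: list[str]
    truth: pd.DataFrame = field(repr=False)


def generate_dataset(spec: SyntheticSpec) -> SyntheticDataset:
    """Run every generator in order and assemble the experiment bundle."""
    hierarchy = generate_hierarchy(spec)
    omics = generate_omics(spec, hierarchy)
    drugs = generate_drugs(spec, hierarchy)
    cancer_map = generate_cancer_map(spec)
    records, truth = generate_responses(spec, hierarchy, omics, drugs, cancer_map)
    bundle = DataBundle(hierarchy=hierarchy, omics=omics, drugs=drugs,
                        responses=records, cancer_map=cancer_map)
    return SyntheticDataset(spec=spec, bundle=bundle,
                            driver_genes=list(spec.driver_genes), truth=truth)
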