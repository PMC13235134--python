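"""Delimited-table readers and writers.

All on-disk formats are plain text: omics matrices as CSV with cell IDs as
row labels and feature IDs as column headers; annotation edge lists as TSV
with headers; drug, response and cancer-type tables as CSV. The synthetic
generator writes the exact formats the real-data readers consume, so the
full pipeline can round-trip through disk.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .drugs import DrugSet, make_records
from .evaluation import DataBundle
from .hierarchy import build_hierarchy
from .omics import OmicsMatrix


def write_omics_csv(m: OmicsMatrix, path: str | Path) -> None:
    m.to_frame().to_csv(path, index_label="cell_id")


def read_omics_csv(path: str | Path, kind: str) -> OmicsMatrix:
    df = pd.read_csv(path, index_col=0)
    return OmicsMatrix.from_frame(df, kind)


def write_dataset(dataset, outdir: str | Path) -> dict[str, Path]:
    """Write a :class:`~biodrp.synthetic.SyntheticDataset` as the standard
    table set; returns a name -> path map of everything written."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    b: DataBundle = dataset.bundle
    h = b.hierarchy
    paths: dict[str, Path] = {}

    for m in b.omics:
        p = out / f"omics_{m.kind.lower()}.csv"
        write_omics_csv(m, p)
        paths[f"omics_{m.kind}"] = p

    gp = pd.DataFrame(sorted(h.edges_gp), columns=["gene_id", "protein_id"])
    gp["score"] = [h.gp_scores.get(tuple(r), 1.0) for r in gp.itertuples(index=False)]
    pk = pd.DataFrame(sorted(h.edges_pk), columns=["protein_id", "pathway_id"])
    pk["p_value"] = [h.pathway_pvalues.get(k, 0.0) for k in pk["pathway_id"]]
    pk["combined_score"] = [h.pk_scores.get(tuple(r[:2]), 1.0)
                            for r in pk.itertuples(index=False)]
    kd = pd.DataFrame(sorted(h.edges_kd), columns=["pathway_id", "drug_id"])
    for name, df in (("edges_gp", gp), ("edges_pk", pk), ("edges_kd", kd)):
        p = out / f"{name}.tsv"
        df.to_csv(p, sep="\t", index=False)
        paths[name] = p

    drugs_df = pd.DataFrame({
        "drug_id": b.drugs.drug_ids,
        "smiles": [b.drugs.smiles[d] for d in b.drugs.drug_ids],
        "max_conc": [b.drugs.max_conc[d] for d in b.drugs.drug_ids],
    })
    paths["drugs"] = out / "drugs.csv"
    drugs_df.to_csv(paths["drugs"], index=False)

    resp = pd.DataFrame({
        "cell_id": [r.cell_id for r in b.responses],
        "drug_id": [r.drug_id for r in b.responses],
        "ln_ic50": [r.ln_ic50 for r in b.responses],
    })
    paths["responses"] = out / "responses.csv"
    resp.to_csv(paths["responses"], index=False)

    cmap = pd.DataFrame(sorted(b.cancer_map.items()),
                        columns=["cell_id", "cancer_type"])
    paths["cancer_types"] = out / "cancer_types.csv"
    cmap.to_csv(paths["cancer_types"], index=False)

    paths["truth"] = out / "truth.csv"
    dataset.truth.to_csv(paths["truth"], index=False)
    paths["driver_genes"] = out / "driver_genes.txt"
    paths["driver_genes"].write_text("\n".join(dataset.driver_genes) + "\n")
    return paths


def load_bundle(datadir: str | Path, radius: int = 2, n_bits: int = 1024,
                log10_scale: bool = False) -> DataBundle:
    """Load a dataset directory (as written by :func:`write_dataset`, or
    real-data tables in the same formats) into an experiment bundle."""
    d = Path(datadir)
    omics = []
    for kind in ("GE", "CNV", "MUT", "PROT"):
        p = d / f"omics_{kind.lower()}.csv"
        if p.exists():
            omics.append(read_omics_csv(p, kind))
    if not omics:
        raise FileNotFoundError(f"no omics_*.csv files under {d}")

    drugs_df = pd.read_csv(d / "drugs.csv", dtype={"drug_id": str})
    drugs = DrugSet.from_table(
        list(drugs_df["drug_id"]),
        dict(zip(drugs_df["drug_id"], drugs_df["smiles"].fillna(""))),
        dict(zip(drugs_df["drug_id"], drugs_df["max_conc"])),
        radius=radius, n_bits=n_bits)

    gp = pd.read_csv(d / "edges_gp.tsv", sep="\t")
    pk = pd.read_csv(d / "edges_pk.tsv", sep="\t")
    kd = pd.read_csv(d / "edges_kd.tsv", sep="\t")
    gene_universe = list(dict.fromkeys(g for m in omics for g in m.feature_ids))
    hierarchy = build_hierarchy(gp, pk, kd, gene_universe, list(drugs.drug_ids))

    cmap_path = d / "cancer_types.csv"
    cancer_map: dict[str, str] = {}
    if cmap_path.exists():
        cm = pd.read_csv(cmap_path)
        cancer_map = dict(zip(cm["cell_id"], cm["cancer_type"]))

    resp = pd.read_csv(d / "responses.csv")
    records = make_records(resp["cell_id"], resp["drug_id"], resp["ln_ic50"],
                           drugs, cancer_map or None, log10_scale=log10_scale)
    return DataBundle(hierarchy=hierarchy, omics=omics, drugs=drugs,
                      responses=records, cancer_map=cancer_map)


def write_masks(masks, outdir: str | Path) -> None:
    """Export layer masks as dense CSV plus node-order sidecar files."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    names = ("gene_protein", "protein_pathway", "pathway_drug")
    for name, lm in zip(names, masks):
        pd.DataFrame(lm.mask.astype(int), index=lm.source_ids,
                     columns=lm.target_ids).to_csv(out / f"mask_{name}.csv")
    orders = {"gene": masks[0].source_ids, "protein": masks[0].target_ids,
              "pathway": masks[1].target_ids, "drug": masks[2].target_ids}
    for level, ids in orders.items():
        (out / f"order_{level}.txt").write_text("\n".join(ids) + "\n")
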