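"""Four-level biological hierarchy (gene -> protein complex -> pathway -> drug).

The hierarchy is the scaffold of the masked network: each adjacent pair of
levels yields a binary mask matrix applied (Hadamard) to the corresponding
weight matrix, so only annotated biological connections are trainable.
Node order in the hierarchy is the single source of truth for all downstream
indexing (feature vectors, mask rows/columns, importance reports).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.stats import hypergeom

logger = logging.getLogger(__name__)

LEVELS = ("gene", "protein", "pathway", "drug")


class EmptyHierarchyError(ValueError):
    """Raised when filtering/pruning leaves no complete gene->drug path."""


@dataclass
class BioHierarchy:
    """Node lists (ordered, duplicate-free) and typed edge sets.

    ``pathway_pvalues`` holds the enrichment p-value per pathway;
    ``gp_scores`` and ``pk_scores`` hold interaction / combined enrichment
    scores as edge attributes. Attributes never gate connectivity.
    """

    genes: list[str]
    proteins: list[str]
    pathways: list[str]
    drugs: list[str]
    edges_gp: set[tuple[str, str]]
    edges_pk: set[tuple[str, str]]
    edges_kd: set[tuple[str, str]]
    pathway_pvalues: dict[str, float] = field(default_factory=dict)
    gp_scores: dict[tuple[str, str], float] = field(default_factory=dict)
    pk_scores: dict[tuple[str, str], float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name in ("genes", "proteins", "pathways", "drugs"):
            ids = getattr(self, name)
            if len(ids) != len(set(ids)):
                raise ValueError(f"duplicate IDs in {name}")
        gene_s, prot_s = set(self.genes), set(self.proteins)
        path_s, drug_s = set(self.pathways), set(self.drugs)
        for g, p in self.edges_gp:
            if g not in gene_s or p not in prot_s:
                raise ValueError(f"gene->protein edge ({g}, {p}) has unknown endpoint")
        for p, k in self.edges_pk:
            if p not in prot_s or k not in path_s:
                raise ValueError(f"protein->pathway edge ({p}, {k}) has unknown endpoint")
        for k, d in self.edges_kd:
            if k not in path_s or d not in drug_s:
                raise ValueError(f"pathway->drug edge ({k}, {d}) has unknown endpoint")

    def node_counts(self) -> tuple[int, int, int, int]:
        return (len(self.genes), len(self.proteins), len(self.pathways), len(self.drugs))

    def is_empty(self) -> bool:
        return not (self.genes and self.proteins and self.pathways and self.drugs
                    and self.edges_gp and self.edges_pk and self.edges_kd)


@dataclass
class LayerMask:
    """Binary connectivity matrix between two adjacent hierarchy levels."""

    source_ids: list[str]
    target_ids: list[str]
    mask: np.ndarray  # shape |source| x |target|, entries in {0,1}

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=np.float64)
        if self.mask.shape != (len(self.source_ids), len(self.target_ids)):
            raise ValueError("mask shape does not match ID lists")
        if not np.isin(self.mask, (0.0, 1.0)).all():
            raise ValueError("mask entries must be 0 or 1")

    @property
    def n_edges(self) -> int:
        return int(self.mask.sum())

    def density(self) -> float:
        return float(self.mask.mean())


def build_hierarchy(
    gp_edges: pd.DataFrame,
    pk_edges: pd.DataFrame,
    kd_edges: pd.DataFrame,
    gene_universe: list[str],
    drug_universe: list[str],
) -> BioHierarchy:
    """Assemble an unpruned hierarchy from annotation edge tables.

    Expected columns: gp ``(gene_id, protein_id[, score])``,
    pk ``(protein_id, pathway_id[, p_value, combined_score])``,
    kd ``(pathway_id, drug_id)``. Edges whose gene/drug endpoint falls
    outside the given universes are dropped with a logged count. Node order
    is first-appearance order in the (filtered) tables, genes/drugs ordered
    as in their universes.
    """
    for name, tab in (("gene-protein", gp_edges), ("protein-pathway", pk_edges),
                      ("pathway-drug", kd_edges)):
        if len(tab) == 0:
            raise ValueError(f"empty {name} edge table")

    gene_set = set(gene_universe)
    drug_set = set(drug_universe)

    gp = gp_edges.drop_duplicates(subset=["gene_id", "protein_id"])
    n_before = len(gp)
    gp = gp[gp["gene_id"].isin(gene_set)]
    if n_before - len(gp):
        logger.info("dropped %d gene-protein edges outside gene universe", n_before - len(gp))

    kd = kd_edges.drop_duplicates(subset=["pathway_id", "drug_id"])
    n_before = len(kd)
    kd = kd[kd["drug_id"].isin(drug_set)]
    if n_before - len(kd):
        logger.info("dropped %d pathway-drug edges outside drug universe", n_before - len(kd))

    pk = pk_edges.drop_duplicates(subset=["protein_id", "pathway_id"])

    genes = [g for g in gene_universe if g in set(gp["gene_id"])]
    proteins = list(dict.fromkeys(list(gp["protein_id"]) + list(pk["protein_id"])))
    pathways = list(dict.fromkeys(list(pk["pathway_id"]) + list(kd["pathway_id"])))
    drugs = [d for d in drug_universe if d in set(kd["drug_id"])]

    gp_scores = {}
    if "score" in gp.columns:
        gp_scores = {(r.gene_id, r.protein_id): float(r.score) for r in gp.itertuples()}
    pk_scores = {}
    if "combined_score" in pk.columns:
        pk_scores = {(r.protein_id, r.pathway_id): float(r.combined_score)
                     for r in pk.itertuples()}
    pathway_pvalues: dict[str, float] = {}
    if "p_value" in pk.columns:
        # enrichment p is a pathway-level quantity; tables repeat it per edge,
        # the most significant value wins if rows disagree
        pathway_pvalues = pk.groupby("pathway_id")["p_value"].min().to_dict()

    return BioHierarchy(
        genes=genes,
        proteins=proteins,
        pathways=pathways,
        drugs=drugs,
        edges_gp={(r.gene_id, r.protein_id) for r in gp.itertuples()},
        edges_pk={(r.protein_id, r.pathway_id) for r in pk.itertuples()},
        edges_kd={(r.pathway_id, r.drug_id) for r in kd.itertuples()},
        pathway_pvalues=pathway_pvalues,
        gp_scores=gp_scores,
        pk_scores=pk_scores,
    )


def filter_significant_pathways(hierarchy: BioHierarchy, alpha: float = 0.05) -> BioHierarchy:
    """Keep pathways whose enrichment p-value is <= ``alpha`` (boundary kept).

    Incident protein->pathway and pathway->drug edges of removed pathways are
    dropped; combined scores of survivors are retained.
    """
    missing = [k for k in hierarchy.pathways if k not in hierarchy.pathway_pvalues]
    if missing:
        raise ValueError(f"pathway(s) without p-value: {missing[:5]}")
    keep = {k for k in hierarchy.pathways if hierarchy.pathway_pvalues[k] <= alpha}
    if not keep:
        raise EmptyHierarchyError(
            f"no pathway passes the significance cutoff alpha={alpha}")
    out = replace(
        hierarchy,
        pathways=[k for k in hierarchy.pathways if k in keep],
        edges_pk={(p, k) for (p, k) in hierarchy.edges_pk if k in keep},
        edges_kd={(k, d) for (k, d) in hierarchy.edges_kd if k in keep},
        pathway_pvalues={k: v for k, v in hierarchy.pathway_pvalues.items() if k in keep},
        pk_scores={e: s for e, s in hierarchy.pk_scores.items() if e[1] in keep},
    )
    return out


def overrepresentation_pvalue(
    protein_set_size: int, pathway_size: int, overlap: int, universe: int
) -> float:
    """Hypergeometric upper-tail over-representation test, P[X >= overlap].

    X ~ Hypergeometric(universe, pathway_size, protein_set_size): the overlap
    between a protein set and a pathway when membership is random.
    """
    if not (0 <= overlap <= min(protein_set_size, pathway_size) <= universe):
        raise ValueError(
            f"inconsistent counts: overlap={overlap}, set={protein_set_size}, "
            f"pathway={pathway_size}, universe={universe}")
    if max(protein_set_size, pathway_size) > universe:
        raise ValueError("set sizes exceed universe")
    return float(hypergeom.sf(overlap - 1, universe, pathway_size, protein_set_size))


def _live_sets(h: BioHierarchy):
    return set(h.genes), set(h.proteins), set(h.pathways), set(h.drugs)


def prune_hierarchy(hierarchy: BioHierarchy) -> BioHierarchy:
    """Remove every node not on a complete gene->protein->pathway->drug path.

    Forward sweep: genes with no protein edge, proteins with no pathway edge,
    pathways with no drug edge, drugs with no pathway edge. Backward sweep:
    proteins with no surviving gene, pathways with no surviving protein.
    Sweeps repeat until a fixed point (node count strictly decreases, so
    termination is guaranteed); the result is idempotent under re-pruning.
    """
    genes, prots, paths, drugs = _live_sets(hierarchy)
    changed = True
    while changed:
        gp = {(g, p) for (g, p) in hierarchy.edges_gp if g in genes and p in prots}
        pk = {(p, k) for (p, k) in hierarchy.edges_pk if p in prots and k in paths}
        kd = {(k, d) for (k, d) in hierarchy.edges_kd if k in paths and d in drugs}
        new_genes = {g for (g, _) in gp}
        new_prots = {p for (_, p) in gp} & {p for (p, _) in pk}
        new_paths = {k for (_, k) in pk} & {k for (k, _) in kd}
        new_drugs = {d for (_, d) in kd}
        changed = (new_genes, new_prots, new_paths, new_drugs) != (genes, prots, paths, drugs)
        genes, prots, paths, drugs = new_genes, new_prots, new_paths, new_drugs

    if not (genes and prots and paths and drugs):
        raise EmptyHierarchyError("pruning removed every complete gene->drug path")

    return replace(
        hierarchy,
        genes=[g for g in hierarchy.genes if g in genes],
        proteins=[p for p in hierarchy.proteins if p in prots],
        pathways=[k for k in hierarchy.pathways if k in paths],
        drugs=[d for d in hierarchy.drugs if d in drugs],
        edges_gp={(g, p) for (g, p) in hierarchy.edges_gp if g in genes and p in prots},
        edges_pk={(p, k) for (p, k) in hierarchy.edges_pk if p in prots and k in paths},
        edges_kd={(k, d) for (k, d) in hierarchy.edges_kd if k in paths and d in drugs},
        pathway_pvalues={k: v for k, v in hierarchy.pathway_pvalues.items() if k in paths},
        gp_scores={e: s for e, s in hierarchy.gp_scores.items()
                   if e[0] in genes and e[1] in prots},
        pk_scores={e: s for e, s in hierarchy.pk_scores.items()
                   if e[0] in prots and e[1] in paths},
    )


def _mask_from_edges(sources: list[str], targets: list[str],
                     edges: set[tuple[str, str]]) -> LayerMask:
    s_idx = {s: i for i, s in enumerate(sources)}
    t_idx = {t: j for j, t in enumerate(targets)}
    m = np.zeros((len(sources), len(targets)))
    for s, t in edges:
        m[s_idx[s], t_idx[t]] = 1.0
    return LayerMask(list(sources), list(targets), m)


def masks_from_hierarchy(hierarchy: BioHierarchy) -> tuple[LayerMask, LayerMask, LayerMask]:
    """Emit the three layer masks of a pruned hierarchy, in stored node order.

    Raises if the hierarchy is unpruned (an all-zero row or column would
    create a dead network node).
    """
    m_gp = _mask_from_edges(hierarchy.genes, hierarchy.proteins, hierarchy.edges_gp)
    m_pk = _mask_from_edges(hierarchy.proteins, hierarchy.pathways, hierarchy.edges_pk)
    m_kd = _mask_from_edges(hierarchy.pathways, hierarchy.drugs, hierarchy.edges_kd)
    for name, lm in (("gene->protein", m_gp), ("protein->pathway", m_pk),
                     ("pathway->drug", m_kd)):
        if (lm.mask.sum(axis=1) == 0).any() or (lm.mask.sum(axis=0) == 0).any():
            raise ValueError(
                f"{name} mask has an all-zero row/column; prune the hierarchy first")
    return m_gp, m_pk, m_kd


def reachable_nodes(hierarchy: BioHierarchy) -> dict[str, set[str]]:
    """Independent reachability computation: nodes on a full gene->drug path.

    Plain set intersection of forward- and backward-reachable fronts; used as
    an oracle for :func:`prune_hierarchy` and by the synthetic generator.
    """
    fwd_prots = {p for (g, p) in hierarchy.edges_gp}
    fwd_paths = {k for (p, k) in hierarchy.edges_pk if p in fwd_prots}
    fwd_drugs = {d for (k, d) in hierarchy.edges_kd if k in fwd_paths}
    bwd_paths = {k for (k, d) in hierarchy.edges_kd if d in fwd_drugs}
    bwd_prots = {p for (p, k) in hierarchy.edges_pk if k in bwd_paths and p in fwd_prots}
    bwd_genes = {g for (g, p) in hierarchy.edges_gp if p in bwd_prots}
    return {"gene": bwd_genes, "protein": bwd_prots, "pathway": bwd_paths & fwd_paths,
            "drug": fwd_drugs}


def drugs_reached_by(hierarchy: BioHierarchy, gene: str) -> set[str]:
    """Drugs reachable from ``gene`` along gene->protein->pathway->drug edges."""
    prots = {p for (g, p) in hierarchy.edges_gp if g == gene}
    paths = {k for (p, k) in hierarchy.edges_pk if p in prots}
    return {d for (k, d) in hierarchy.edges_kd if k in paths}
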