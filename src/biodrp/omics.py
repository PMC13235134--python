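"""Per-omics preprocessing and availability-weighted multi-omics integration.

Four omics layers describe each cell line: RNA-seq gene expression (GE),
copy-number variation (CNV), mutation variant-allele frequency (MUT) and
protein expression (PROT). Each layer is filtered and min-max scaled on its
own, then the layers are merged into one cell x feature matrix: a feature
measured by several omics gets the average of the values from the omics that
contain it (its "availability").
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

OMICS_KINDS = ("GE", "CNV", "MUT", "PROT")


@dataclass
class OmicsMatrix:
    """One omics layer: cell lines x features with a kind tag."""

    cell_ids: list[str]
    feature_ids: list[str]
    values: np.ndarray
    kind: str

    def __post_init__(self) -> None:
        if self.kind not in OMICS_KINDS:
            raise ValueError(f"unknown omics kind {self.kind!r}; expected one of {OMICS_KINDS}")
        if len(self.cell_ids) != len(set(self.cell_ids)):
            raise ValueError("duplicate cell IDs")
        if len(self.feature_ids) != len(set(self.feature_ids)):
            raise ValueError("duplicate feature IDs")
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.shape != (len(self.cell_ids), len(self.feature_ids)):
            raise ValueError("matrix shape does not match ID lists")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.cell_ids, columns=self.feature_ids)

    @classmethod
    def from_frame(cls, df: pd.DataFrame, kind: str) -> "OmicsMatrix":
        """Build from a cells x features table; duplicate (cell, feature)
        entries are mean-aggregated."""
        if df.index.has_duplicates:
            df = df.groupby(level=0).mean()
        if df.columns.has_duplicates:
            df = df.T.groupby(level=0).mean().T
        return cls(list(df.index), list(df.columns), df.to_numpy(dtype=np.float64), kind)


@dataclass
class IntegratedCellFeatures:
    """Unified cell x feature matrix after multi-omics integration.

    ``provenance`` maps each feature to the omics kinds that contributed;
    every entry is non-empty by construction.
    """

    cell_ids: list[str]
    feature_ids: list[str]
    values: np.ndarray
    provenance: dict[str, list[str]] = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.cell_ids, columns=self.feature_ids)


def variance_filter(m: OmicsMatrix, drop_low_fraction: float,
                    keep_top_fraction: float) -> OmicsMatrix:
    """Two-stage variance filter: drop the lowest-variance fraction of
    features, then keep only the top fraction by variance of the remainder.

    Ties are broken by feature-ID lexicographic order so the result is
    deterministic for any input.
    """
    for name, f in (("drop_low_fraction", drop_low_fraction),
                    ("keep_top_fraction", keep_top_fraction)):
        if not 0.0 <= f <= 1.0:
            raise ValueError(f"{name} must lie in [0, 1], got {f}")
    df = m.to_frame()
    var = df.var(axis=0, ddof=1)

    # stage 1: ascending variance, lexicographic tie-break; drop the head
    order_up = sorted(m.feature_ids, key=lambda g: (var[g], g))
    n_drop = int(np.floor(len(order_up) * drop_low_fraction))
    survivors = set(order_up[n_drop:])

    # stage 2: descending variance among survivors; keep the head
    order_down = sorted(survivors, key=lambda g: (-var[g], g))
    n_keep = int(np.floor(len(order_down) * keep_top_fraction))
    kept = set(order_down[:n_keep])
    if not kept:
        raise ValueError("variance filter removed every feature")
    features = [g for g in m.feature_ids if g in kept]
    return OmicsMatrix(m.cell_ids, features, df[features].to_numpy(), m.kind)


def zero_fraction_filter(m: OmicsMatrix, max_zero_fraction: float = 0.05) -> OmicsMatrix:
    """Drop features whose fraction of exact zeros strictly exceeds the
    threshold (a feature at exactly the threshold is retained)."""
    if not 0.0 <= max_zero_fraction <= 1.0:
        raise ValueError(f"max_zero_fraction must lie in [0, 1], got {max_zero_fraction}")
    zero_frac = (m.values == 0.0).mean(axis=0)
    keep = zero_frac <= max_zero_fraction
    if not keep.any():
        raise ValueError("zero-fraction filter removed every feature")
    features = [g for g, k in zip(m.feature_ids, keep) if k]
    return OmicsMatrix(m.cell_ids, features, m.values[:, keep], m.kind)


def minmax_scale(m: OmicsMatrix) -> OmicsMatrix:
    """Per-feature (x - min) / (max - min) scaling into [0, 1].

    Constant features map to 0: they carry no information and zero keeps them
    inert in the network input.
    """
    lo = m.values.min(axis=0)
    hi = m.values.max(axis=0)
    span = hi - lo
    safe = np.where(span == 0.0, 1.0, span)
    scaled = (m.values - lo) / safe
    scaled[:, span == 0.0] = 0.0
    return OmicsMatrix(m.cell_ids, list(m.feature_ids), scaled, m.kind)


def integrate_omics(matrices: list[OmicsMatrix],
                    divisor: str = "availability") -> IntegratedCellFeatures:
    """Merge omics layers into one matrix by availability-weighted averaging.

    For each cell ``c`` and unique feature ``g``,

        F(c, g) = (1/|M_g|) * sum over layers M containing g of M(c, g)

    where ``|M_g|`` is, by default, the number of layers that contain ``g``
    (``divisor="availability"``), so a single-omics feature keeps its value.
    ``divisor="constant"`` divides by the total number of layers instead,
    shrinking features that are absent from some layers.

    Cell IDs are intersected across layers (logged when rows are lost);
    feature order is first-appearance order across the input layers.
    """
    if divisor not in ("availability", "constant"):
        raise ValueError(f"divisor must be 'availability' or 'constant', got {divisor!r}")
    if not matrices:
        raise ValueError("no omics matrices supplied")

    cells = set(matrices[0].cell_ids)
    for m in matrices[1:]:
        cells &= set(m.cell_ids)
    if not cells:
        raise ValueError("omics matrices share no cell lines")
    n_union = len(set().union(*(set(m.cell_ids) for m in matrices)))
    if n_union > len(cells):
        logger.info("integration restricted to %d common cell lines (of %d seen)",
                    len(cells), n_union)
    cell_ids = [c for c in matrices[0].cell_ids if c in cells]

    feature_ids: list[str] = list(dict.fromkeys(
        g for m in matrices for g in m.feature_ids))
    col = {g: j for j, g in enumerate(feature_ids)}

    total = np.zeros((len(cell_ids), len(feature_ids)))
    count = np.zeros(len(feature_ids))
    provenance: dict[str, list[str]] = {g: [] for g in feature_ids}
    for m in matrices:
        df = m.to_frame().loc[cell_ids]
        idx = np.array([col[g] for g in m.feature_ids])
        total[:, idx] += df.to_numpy()
        count[idx] += 1
        for g in m.feature_ids:
            provenance[g].append(m.kind)

    denom = count if divisor == "availability" else float(len(matrices))
    values = total / denom
    return IntegratedCellFeatures(cell_ids, feature_ids, values, provenance)
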