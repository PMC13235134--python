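"""Drug featurization (Morgan/ECFP fingerprints) and response binarization.

A drug is represented by a fixed-length hashed circular fingerprint of its
SMILES structure. A (cell line, drug) response is the natural-log IC50 from a
screening experiment, binarized against the drug's maximum screening
concentration: the pair is *sensitive* (label 1) when exp(ln IC50) is at or
below max_conc, *resistant* (label 0) otherwise.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Optional

import numpy as np
from rdkit import Chem, RDLogger
from rdkit.Chem import rdFingerprintGenerator

logger = logging.getLogger(__name__)
RDLogger.DisableLog("rdApp.*")

VALID_N_BITS = (512, 1024, 2048)


def morgan_fingerprint(smiles: str, radius: int = 2, n_bits: int = 1024) -> np.ndarray:
    """Hashed circular (Morgan/ECFP) fingerprint of a SMILES string.

    Radius 2 is the ECFP4 convention. Deterministic: equivalent SMILES
    spellings of the same molecule yield identical bit vectors. Raises
    ``ValueError`` for unparsable or empty SMILES.
    """
    if not smiles:
        raise ValueError("empty SMILES string")
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise ValueError(f"unparsable SMILES: {smiles!r}")
    gen = rdFingerprintGenerator.GetMorganGenerator(radius=radius, fpSize=n_bits)
    fp = gen.GetFingerprint(mol)
    arr = np.zeros(n_bits, dtype=np.float64)
    arr[list(fp.GetOnBits())] = 1.0
    return arr


def binarize_response(ln_ic50: float, max_conc: float) -> int:
    """Sensitive/resistant label: 1 iff exp(ln_ic50) <= max_conc (inclusive)."""
    if not math.isfinite(ln_ic50):
        raise ValueError(f"non-finite ln_ic50: {ln_ic50}")
    if max_conc <= 0:
        raise ValueError(f"max_conc must be positive, got {max_conc}")
    # compare on the log scale: exp is monotone, and ln avoids overflow
    return int(ln_ic50 <= math.log(max_conc))


@dataclass
class DrugSet:
    """Drugs with SMILES, maximum screening concentration, and fingerprints.

    ``max_conc`` must be on the same concentration scale as exp(ln IC50);
    no unit conversion is attempted.
    """

    drug_ids: list[str]
    smiles: dict[str, str]
    max_conc: dict[str, float]
    fingerprints: np.ndarray  # n_drugs x n_bits, entries in {0,1}

    def __post_init__(self) -> None:
        if len(self.drug_ids) != len(set(self.drug_ids)):
            raise ValueError("duplicate drug IDs")
        self.fingerprints = np.asarray(self.fingerprints, dtype=np.float64)
        if self.fingerprints.shape[0] != len(self.drug_ids):
            raise ValueError("fingerprint row count does not match drug list")
        if not np.isin(self.fingerprints, (0.0, 1.0)).all():
            raise ValueError("fingerprint entries must be 0 or 1")
        for d in self.drug_ids:
            if self.max_conc[d] <= 0:
                raise ValueError(f"max_conc for drug {d} must be positive")
        self._index = {d: i for i, d in enumerate(self.drug_ids)}

    @property
    def n_bits(self) -> int:
        return self.fingerprints.shape[1]

    def fingerprint_of(self, drug_id: str) -> np.ndarray:
        return self.fingerprints[self._index[drug_id]]

    @classmethod
    def from_table(cls, drug_ids: list[str], smiles: dict[str, str],
                   max_conc: dict[str, float], radius: int = 2,
                   n_bits: int = 1024) -> "DrugSet":
        """Fingerprint a drug table; drugs without a SMILES string are
        dropped with a logged count."""
        kept, dropped = [], []
        for d in drug_ids:
            s = smiles.get(d, "")
            if isinstance(s, str) and s.strip():
                kept.append(d)
            else:
                dropped.append(d)
        if dropped:
            logger.info("dropped %d drug(s) lacking SMILES: %s", len(dropped), dropped[:10])
        if not kept:
            raise ValueError("no drug has a SMILES string")
        fps = np.stack([morgan_fingerprint(smiles[d], radius=radius, n_bits=n_bits)
                        for d in kept])
        return cls(kept, {d: smiles[d] for d in kept},
                   {d: float(max_conc[d]) for d in kept}, fps)


@dataclass
class ResponseRecord:
    """One (cell line, drug) pair with its ln IC50 and binary label."""

    cell_id: str
    drug_id: str
    ln_ic50: float
    label: int
    cancer_type: Optional[str] = None

    def __post_init__(self) -> None:
        if self.label not in (0, 1):
            raise ValueError(f"label must be 0 or 1, got {self.label}")


def make_records(cell_ids, drug_ids, ln_ic50s, drugs: DrugSet,
                 cancer_map: Optional[dict[str, str]] = None,
                 log10_scale: bool = False) -> list[ResponseRecord]:
    """Build labelled response records from parallel columns.

    ``log10_scale=True`` converts log10 IC50 inputs to natural log before
    binarization.
    """
    records = []
    for c, d, v in zip(cell_ids, drug_ids, ln_ic50s):
        ln = float(v) * math.log(10.0) if log10_scale else float(v)
        label = binarize_response(ln, drugs.max_conc[d])
        ctype = cancer_map.get(c) if cancer_map else None
        records.append(ResponseRecord(c, d, ln, label, ctype))
    return records
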