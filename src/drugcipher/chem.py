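"""Chemical similarity: Tanimoto coefficient on binary 2D fingerprints.

The reference path takes explicit bit vectors; an optional backend computes
path-based fingerprints from SMILES with RDKit when it is installed.
"""

from __future__ import annotations

import logging
from typing import Sequence

import numpy as np
import pandas as pd

from .types import DrugRecord

logger = logging.getLogger(__name__)


def tanimoto(a: np.ndarray, b: np.ndarray) -> float:
    """|a ∧ b| / |a ∨ b| for equal-length bit vectors; two empty sets score 0."""
    a = np.asarray(a, dtype=bool)
    b = np.asarray(b, dtype=bool)
    if a.shape != b.shape:
        raise ValueError(f"fingerprint length mismatch: {a.size} vs {b.size}")
    union = np.logical_or(a, b).sum()
    if union == 0:
        logger.warning("both fingerprints all-zero; Tanimoto defined as 0")
        return 0.0
    return float(np.logical_and(a, b).sum() / union)


def cs_matrix(drugs: Sequence[DrugRecord]) -> pd.DataFrame:
    """Symmetric drug × drug Tanimoto matrix with unit diagonal.

    Computed via bit-count algebra: for rows X of the 0/1 fingerprint matrix,
    intersection = X Xᵀ and union = |a| + |b| − intersection.
    """
    ids = [d.drug_id for d in drugs]
    for d in drugs:
        if d.fingerprint is None:
            raise ValueError(f"drug {d.drug_id} has no fingerprint")
    lengths = {d.fingerprint.size for d in drugs}
    if len(lengths) > 1:
        raise ValueError(f"fingerprints have mixed lengths: {sorted(lengths)}")
    X = np.stack([np.asarray(d.fingerprint, dtype=np.float64) for d in drugs])
    inter = X @ X.T
    popcount = X.sum(axis=1)
    union = popcount[:, None] + popcount[None, :] - inter
    with np.errstate(invalid="ignore", divide="ignore"):
        sim = np.where(union > 0, inter / np.where(union > 0, union, 1.0), 0.0)
    np.fill_diagonal(sim, 1.0)
    return pd.DataFrame(sim, index=ids, columns=ids)


def fingerprint_from_smiles(smiles: str, n_bits: int = 2048) -> np.ndarray:
    """2D path-based fingerprint from a SMILES string (requires rdkit)."""
    try:
        from rdkit import Chem  # type: ignore
    except ImportError as exc:  # pragma: no cover
        raise ImportError("SMILES fingerprinting requires the 'rdkit' extra") from exc
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise ValueError(f"unparseable SMILES: {smiles!r}")
    fp = Chem.RDKFingerprint(mol, fpSize=n_bits)
    return np.frombuffer(fp.ToBitString().encode(), dtype=np.uint8) - ord("0")
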