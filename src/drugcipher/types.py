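"""Core containers shared across the package.

Matrices are labelled :class:`pandas.DataFrame` objects throughout: drug–drug
similarity matrices are square with identical index and columns, the
drug–protein closeness matrix is proteins × drugs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Optional

import numpy as np
import pandas as pd


@dataclass
class DrugRecord:
    """A drug with its therapeutic codes, structural fingerprint and targets.

    Parameters
    ----------
    drug_id:
        Unique string token identifying the drug.
    atc_codes:
        7-character ATC codes assigned to the drug (possibly empty).
    fingerprint:
        Binary fingerprint as a numpy bool/uint8 vector, or None.
    target_ids:
        Known target protein identifiers (possibly empty).
    """

    drug_id: str
    atc_codes: list[str] = field(default_factory=list)
    fingerprint: Optional[np.ndarray] = None
    target_ids: set[str] = field(default_factory=set)

    @property
    def n_targets(self) -> int:
        return len(self.target_ids)


@dataclass
class InteractionTable:
    """Known drug–target interactions, optionally with Ki affinities (nM)."""

    pairs: set[tuple[str, str]] = field(default_factory=set)
    affinity: Optional[dict[tuple[str, str], float]] = None

    def __post_init__(self) -> None:
        if self.affinity is not None:
            for pair, ki in self.affinity.items():
                if not ki > 0:
                    raise ValueError(f"Ki must be strictly positive, got {ki} for {pair}")

    def targets_of(self, drug_id: str) -> set[str]:
        return {p for d, p in self.pairs if d == drug_id}

    def drugs_of(self, protein_id: str) -> set[str]:
        return {d for d, p in self.pairs if p == protein_id}

    @property
    def drug_ids(self) -> set[str]:
        return {d for d, _ in self.pairs}

    @property
    def protein_ids(self) -> set[str]:
        return {p for _, p in self.pairs}

    def __len__(self) -> int:
        return len(self.pairs)


@dataclass
class ClosenessMatrix:
    """Drug–protein closeness Φ: proteins × drugs, with the transfer used.

    ``values.loc[p, d]`` is the summed distance-transformed proximity between
    protein p and every known target of drug d. A drug with no targets has an
    all-zero column.
    """

    values: pd.DataFrame
    transfer: Callable[[np.ndarray], np.ndarray]

    @property
    def proteins(self) -> list[str]:
        return list(self.values.index)

    @property
    def drugs(self) -> list[str]:
        return list(self.values.columns)


@dataclass
class RegressionFit:
    """Least-squares fit of a closeness vector on (TS, CS) similarity vectors."""

    a_prime: float
    b_prime: float
    intercept: float
    residual_norm: float
    collinear_fallback: bool = False


@dataclass
class ConcordanceResult:
    """Genome-wide concordance scores and ranks for one drug under one model.

    ``ranks`` is a 1-based ordering by descending score; ties are broken by
    protein id lexicographic order so the result is deterministic.
    """

    drug_id: str
    model: str
    scores: pd.Series
    ranks: pd.Series

    def rank_of(self, protein_id: str) -> int:
        return int(self.ranks.loc[protein_id])


@dataclass
class FingerprintMap:
    """Drugs × retained-proteins matrix of MS concordance scores."""

    scores: pd.DataFrame
    filter_meta: dict = field(default_factory=dict)

    @property
    def drugs(self) -> list[str]:
        return list(self.scores.index)

    @property
    def proteins(self) -> list[str]:
        return list(self.scores.columns)


@dataclass
class ResemblanceResult:
    """Unordered drug pairs with activity resemblance and significance flag."""

    pairs: list[tuple[str, str, float, bool]]
    threshold: float
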