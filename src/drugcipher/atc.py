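"""ATC-code parsing and information-content therapeutic similarity.

The WHO Anatomical Therapeutic Chemical (ATC) classification is a five-level
hierarchy encoded in a 7-character code: one anatomical-group letter, two
digits (therapeutic subgroup), one letter (pharmacological subgroup), one
letter (chemical subgroup) and two digits (chemical substance). The nested
prefixes of lengths 1, 3, 4, 5 and 7 are the five levels.

Two leaf codes are compared with Lin's information-content measure: the
similarity is twice the log-probability of their longest common level prefix
divided by the sum of their own log-probabilities, where probabilities are
prefix frequencies in a drug–code assignment corpus. Drug therapeutic
similarity (TS) is the maximum code similarity over all code pairs of the
two drugs.
"""

from __future__ import annotations

import logging
import math
import re
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .types import DrugRecord

logger = logging.getLogger(__name__)

LEVEL_LENGTHS = (1, 3, 4, 5, 7)
_ATC_RE = re.compile(r"^[A-Z][0-9]{2}[A-Z]{2}[0-9]{2}$")


@dataclass(frozen=True)
class AtcCode:
    """A validated 7-character leaf ATC code and its five level prefixes."""

    code: str

    @property
    def levels(self) -> tuple[str, ...]:
        return tuple(self.code[:n] for n in LEVEL_LENGTHS)


def parse_atc_code(text: str) -> AtcCode:
    """Validate and normalize a leaf ATC code (case-insensitive)."""
    if not isinstance(text, str):
        raise ValueError(f"ATC code must be a string, got {type(text).__name__}")
    code = text.strip().upper()
    if len(code) != 7:
        raise ValueError(f"ATC code {text!r} must have 7 characters (leaf level)")
    if not _ATC_RE.match(code):
        raise ValueError(f"ATC code {text!r} violates letter/digit layout LddLLdd")
    return AtcCode(code)


class CodeProbabilityTable:
    """Prefix frequencies estimated from a drug–ATC assignment corpus.

    ``prob(prefix)`` is the fraction of assignments whose code starts with the
    prefix; the virtual root has probability 1. Prefixes absent from the
    corpus are handled with a pseudo-count of one assignment (logged), so
    query drugs carrying unseen codes still score.
    """

    def __init__(self, counts: dict[str, int], total: int):
        if total <= 0:
            raise ValueError("empty assignment corpus")
        self._counts = counts
        self._total = total

    @property
    def total(self) -> int:
        return self._total

    def prob(self, prefix: str) -> float:
        if prefix == "":
            return 1.0
        count = self._counts.get(prefix)
        if count is None:
            logger.warning("prefix %s unseen in corpus; pseudo-count of 1 used", prefix)
            return 1.0 / (self._total + 1)
        return count / self._total

    def __contains__(self, prefix: str) -> bool:
        return prefix == "" or prefix in self._counts


def estimate_code_probabilities(
    assignments: Iterable[tuple[str, AtcCode | str]],
) -> CodeProbabilityTable:
    """Count prefix frequencies over (drug_id, code) assignments.

    Each assignment contributes once per code at every level; probabilities
    are therefore monotone non-increasing along any root-to-leaf path.
    """
    counts: dict[str, int] = {}
    total = 0
    for _drug_id, code in assignments:
        atc = code if isinstance(code, AtcCode) else parse_atc_code(code)
        total += 1
        for prefix in atc.levels:
            counts[prefix] = counts.get(prefix, 0) + 1
    if total == 0:
        raise ValueError("empty assignment corpus")
    return CodeProbabilityTable(counts, total)


def _longest_common_level_prefix(a: AtcCode, b: AtcCode) -> str:
    match = ""
    for la, lb in zip(a.levels, b.levels):
        if la == lb:
            match = la
        else:
            break
    return match


def code_similarity(i: AtcCode, j: AtcCode, probs: CodeProbabilityTable) -> float:
    """Lin similarity between two leaf codes: 2·ln p(prefix) / (ln p(i)+ln p(j)).

    Identical codes score 1 (by continuity even when the leaf frequency is 1);
    codes sharing only the root score 0.
    """
    if i.code == j.code:
        return 1.0
    prefix = _longest_common_level_prefix(i, j)
    if prefix == "":
        return 0.0
    p_common = probs.prob(prefix)
    p_i = probs.prob(i.code)
    p_j = probs.prob(j.code)
    if p_common >= 1.0:
        return 0.0  # shared prefix carries zero information
    denom = math.log(p_i) + math.log(p_j)
    return 2.0 * math.log(p_common) / denom


def therapeutic_similarity(
    d1: DrugRecord, d2: DrugRecord, probs: CodeProbabilityTable
) -> float:
    """TS: maximum code similarity over all (code of d1, code of d2) pairs."""
    if not d1.atc_codes or not d2.atc_codes:
        missing = d1.drug_id if not d1.atc_codes else d2.drug_id
        raise ValueError(f"drug {missing} has no ATC codes; TS undefined")
    return max(
        code_similarity(AtcCode(c1), AtcCode(c2), probs)
        for c1 in d1.atc_codes
        for c2 in d2.atc_codes
    )


def ts_matrix(drugs: Sequence[DrugRecord], probs: CodeProbabilityTable) -> pd.DataFrame:
    """Symmetric drug × drug TS matrix with unit diagonal."""
    ids = [d.drug_id for d in drugs]
    n = len(drugs)
    out = np.eye(n)
    for a in range(n):
        for b in range(a + 1, n):
            out[a, b] = out[b, a] = therapeutic_similarity(drugs[a], drugs[b], probs)
    return pd.DataFrame(out, index=ids, columns=ids)
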