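"""Drug biological fingerprints and activity resemblance.

A drug's biological fingerprint is its genome-wide vector of MS concordance
scores. Proteins that score near-identically for every drug ("unspecific"
proteins) carry no discriminating signal and are filtered out; activity
resemblance between two drugs is then the cosine of their fingerprint rows.
Unexpectedly related drug pairs are those whose resemblance exceeds a
data-driven significance threshold although their ATC first-level
(anatomical main group) classes are disjoint.
"""

from __future__ import annotations

import logging
from typing import Callable, Mapping, Optional, Sequence, Union

import numpy as np
import pandas as pd

from .scoring import _scores_for_drug
from .types import (
    ClosenessMatrix,
    DrugRecord,
    FingerprintMap,
    InteractionTable,
    ResemblanceResult,
)

logger = logging.getLogger(__name__)

# dispersion quantile below which a protein counts as unspecific; the default
# retains ~96.6% of proteins on dispersion-homogeneous data
DEFAULT_SD_QUANTILE = 0.0343


def build_fingerprint_map(
    drugs: Sequence[Union[DrugRecord, str]],
    ts: pd.DataFrame,
    cs: pd.DataFrame,
    phi: ClosenessMatrix,
) -> FingerprintMap:
    """Unfiltered drugs × proteins matrix of MS concordance scores."""
    if len(drugs) == 0:
        raise ValueError("empty drug list")
    ids = [d.drug_id if isinstance(d, DrugRecord) else d for d in drugs]
    rows = [_scores_for_drug(d, "MS", ts, cs, phi) for d in ids]
    scores = pd.DataFrame(rows, index=ids)
    return FingerprintMap(scores=scores, filter_meta={"criterion": None})


def filter_unspecific_proteins(
    fmap: FingerprintMap,
    criterion: Union[str, Callable[[pd.DataFrame], pd.Series]] = "sd_quantile",
    sd_quantile: float = DEFAULT_SD_QUANTILE,
) -> FingerprintMap:
    """Drop proteins whose score profile is consistent across drugs.

    Default criterion: across-drug standard deviation strictly below the
    ``sd_quantile`` quantile of all protein SDs (zero-variance proteins are
    always dropped). ``criterion`` may also be a callable returning a boolean
    retain-mask over protein columns.
    """
    scores = fmap.scores
    if scores.shape[0] < 2:
        raise ValueError("need at least 2 drugs to assess protein specificity")
    if callable(criterion):
        keep = criterion(scores).astype(bool)
        meta = {"criterion": "callable"}
    elif criterion == "sd_quantile":
        sds = scores.std(axis=0, ddof=0)
        prior = fmap.filter_meta
        if (
            prior.get("criterion") == "sd_quantile"
            and prior.get("sd_quantile") == sd_quantile
        ):
            # already filtered at this setting: reuse the absolute cutoff so
            # re-running is a no-op rather than shaving another quantile off
            cutoff = float(prior["cutoff"])
        else:
            cutoff = float(np.quantile(sds.to_numpy(), sd_quantile))
        keep = (sds > 0) & (sds >= cutoff)
        meta = {"criterion": "sd_quantile", "sd_quantile": sd_quantile, "cutoff": cutoff}
    else:
        raise ValueError(f"unknown criterion {criterion!r}")
    if not keep.any():
        raise ValueError("criterion removed every protein")
    n_dropped = int((~keep).sum())
    if n_dropped:
        logger.info("filtered %d unspecific protein(s)", n_dropped)
    return FingerprintMap(scores=scores.loc[:, keep], filter_meta=meta)


def activity_resemblance(f1: np.ndarray, f2: np.ndarray) -> float:
    """Cosine similarity of two fingerprint rows; zero vectors score 0."""
    a = np.asarray(f1, dtype=float).ravel()
    b = np.asarray(f2, dtype=float).ravel()
    if a.size != b.size:
        raise ValueError(f"fingerprint length mismatch: {a.size} vs {b.size}")
    denom = np.linalg.norm(a) * np.linalg.norm(b)
    if denom == 0.0:
        logger.warning("zero fingerprint vector; resemblance defined as 0")
        return 0.0
    return float(np.clip(a @ b / denom, -1.0, 1.0))


def resemblance_matrix(fmap: FingerprintMap) -> pd.DataFrame:
    """Drug × drug cosine resemblance of fingerprint rows."""
    X = fmap.scores.to_numpy(dtype=float)
    norms = np.linalg.norm(X, axis=1)
    safe = np.where(norms > 0, norms, 1.0)
    C = (X @ X.T) / np.outer(safe, safe)
    C[norms == 0, :] = 0.0
    C[:, norms == 0] = 0.0
    np.fill_diagonal(C, np.where(norms > 0, 1.0, 0.0))
    C = np.clip(C, -1.0, 1.0)
    return pd.DataFrame(C, index=fmap.drugs, columns=fmap.drugs)


def resemblance_threshold(
    fmap: FingerprintMap,
    alpha: float = 0.05,
    null_model: str = "empirical",
    n_perm: int = 200,
    seed: int = 0,
) -> float:
    """(1 − alpha) quantile of a null resemblance distribution.

    ``empirical`` uses all observed unordered pair resemblances as the null;
    ``permutation`` shuffles protein labels independently within each row for
    ``n_perm`` draws and pools the resulting pair resemblances.
    """
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must be in (0, 1)")
    n = len(fmap.drugs)
    iu = np.triu_indices(n, k=1)
    if null_model == "empirical":
        vals = resemblance_matrix(fmap).to_numpy()[iu]
    elif null_model == "permutation":
        rng = np.random.default_rng(seed)
        X = fmap.scores.to_numpy(dtype=float)
        pools = []
        for _ in range(n_perm):
            shuffled = np.stack([rng.permutation(row) for row in X])
            fm = FingerprintMap(scores=pd.DataFrame(shuffled, index=fmap.drugs))
            pools.append(resemblance_matrix(fm).to_numpy()[iu])
        vals = np.concatenate(pools)
    else:
        raise ValueError(f"unknown null model {null_model!r}")
    if vals.size < 2:
        raise ValueError(
            f"{vals.size} null value(s): too few drug pairs to estimate a quantile"
        )
    # order-statistic ("higher") quantile: at most an alpha fraction of the
    # null values exceed the returned threshold, and alpha → 0 gives the max
    return float(np.quantile(vals, 1.0 - alpha, method="higher"))


def _main_classes(codes: Sequence[str]) -> set[str]:
    return {c[0].upper() for c in codes}


def unexpected_relations(
    fmap: FingerprintMap,
    resemblances: Optional[pd.DataFrame],
    atc_assignments: Union[Mapping[str, Sequence[str]], Sequence[DrugRecord]],
    threshold: float,
    interactions: Optional[InteractionTable] = None,
) -> ResemblanceResult:
    """Drug pairs with resemblance ≥ threshold but disjoint ATC main classes.

    A pair is "unexpected" when no first-level (anatomical group) letter is
    shared between the two drugs' code sets. When ``interactions`` is given,
    each pair is flagged for whether the drugs share a known target.
    """
    if resemblances is None:
        resemblances = resemblance_matrix(fmap)
    if not isinstance(atc_assignments, Mapping):
        atc_assignments = {d.drug_id: d.atc_codes for d in atc_assignments}
    for d in fmap.drugs:
        if not atc_assignments.get(d):
            raise ValueError(f"drug {d} has no ATC codes")
    pairs: list[tuple[str, str, float, bool]] = []
    ids = fmap.drugs
    for i, a in enumerate(ids):
        for b in ids[i + 1 :]:
            r = float(resemblances.loc[a, b])
            if r < threshold:
                continue
            if _main_classes(atc_assignments[a]) & _main_classes(atc_assignments[b]):
                continue
            shares = bool(
                interactions is not None
                and interactions.targets_of(a) & interactions.targets_of(b)
            )
            pairs.append((a, b, r, shares))
    return ResemblanceResult(pairs=pairs, threshold=threshold)
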