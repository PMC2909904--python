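"""Evaluation machinery: leave-one-out cross-validation with negative
controls, pooled rank-threshold ROC/AUC, rank enrichment, similarity-bin
enrichment and permutation tests for similarity–relatedness correlations.

The cross-validation protocol hides, for each known drug–target pair, every
other target of the drug (the closeness column is adjusted accordingly), then
asks the model to rank the held-out target against randomly drawn negative
control proteins. A success requires the true target strictly at the top of
the candidate set; the precision is the success fraction over all known
pairs, repeated with fresh negative draws.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable, Sequence, Union

import numpy as np
import pandas as pd
from scipy import stats

from .closeness import DistanceCache, Transfer, resolve_transfer
from .scoring import _scores_for_drug
from .types import ClosenessMatrix, ConcordanceResult, DrugRecord, InteractionTable

logger = logging.getLogger(__name__)

N_NEGATIVES_DEFAULT = 19
N_REPEATS_DEFAULT = 100


@dataclass
class ValidationReport:
    """Cross-validation outcome: per-repeat precisions and optional ROC."""

    precisions: list[float]
    seed: int
    model: str
    n_negatives: int
    auc: float | None = None
    roc_points: pd.DataFrame | None = None

    @property
    def mean_precision(self) -> float:
        return float(np.mean(self.precisions))


def adjust_closeness_for_removed_targets(
    phi: ClosenessMatrix,
    drug: Union[DrugRecord, str],
    removed: set[str],
    distances: DistanceCache,
    transfer: Union[str, Transfer, None] = None,
) -> ClosenessMatrix:
    """Subtract removed targets' contributions from one drug's Φ column.

    Equivalent (to numerical precision) to recomputing the closeness with the
    reduced target set, because closeness is a sum of per-target terms.
    """
    if isinstance(drug, DrugRecord):
        if not removed <= drug.target_ids:
            raise ValueError("removed proteins must be known targets of the drug")
        if removed == drug.target_ids and removed:
            logger.warning("all targets of %s removed; zero column", drug.drug_id)
        drug = drug.drug_id
    fn = resolve_transfer(transfer) if transfer is not None else phi.transfer
    values = phi.values.copy()
    if removed:
        delta = np.zeros(len(values.index))
        idx = {n: i for i, n in enumerate(distances.nodes)}
        sel = [idx[p] for p in values.index]
        for t in sorted(removed):
            delta += fn(distances.row(t))[sel]
        values[drug] = values[drug].to_numpy() - delta
    return ClosenessMatrix(values=values, transfer=phi.transfer)


def loocv_precision(
    model: Union[str, Callable[[np.ndarray, int], np.ndarray]],
    drugs: Sequence[DrugRecord],
    interactions: InteractionTable,
    phi: ClosenessMatrix,
    ts: pd.DataFrame,
    cs: pd.DataFrame,
    distances: DistanceCache,
    n_negatives: int = N_NEGATIVES_DEFAULT,
    n_repeats: int = N_REPEATS_DEFAULT,
    seed: int = 0,
    allow_target_negatives: bool = False,
) -> ValidationReport:
    """Leave-one-out precision over all known drug–target pairs.

    For each pair, all other targets of the drug are removed (closeness
    adjusted), ``n_negatives`` control proteins are drawn uniformly from the
    network — excluding the drug's known targets unless
    ``allow_target_negatives`` — and the 1 + n_negatives candidates are
    scored. Success requires the true target strictly first; ties count as
    failure. ``model`` is "TS" | "CS" | "MS" | "random", or a callable
    ``scorer(rng, n_candidates) -> scores`` (the positive is candidate 0).
    """
    proteins = list(phi.values.index)
    if n_negatives < 1:
        raise ValueError("n_negatives must be >= 1")
    if n_negatives >= len(proteins):
        raise ValueError("n_negatives must be smaller than the network size")
    rng = np.random.default_rng(seed)
    records = {d.drug_id: d for d in drugs}
    pairs = sorted(interactions.pairs)
    if not pairs:
        raise ValueError("no known drug–target pairs to validate")

    fn = phi.transfer
    node_idx = {n: i for i, n in enumerate(distances.nodes)}
    prot_positions = {p: i for i, p in enumerate(proteins)}
    drug_cols = list(phi.values.columns)
    model_name = model.upper() if isinstance(model, str) else "callable"
    is_score_model = isinstance(model, str) and model.upper() in ("TS", "CS", "MS")

    # singleton closeness columns: transfer(distance to the one kept target)
    def singleton_column(target: str) -> np.ndarray:
        row = distances.row(target)
        sel = [node_idx[p] for p in proteins]
        return fn(row[sel])

    precisions: list[float] = []
    for _rep in range(n_repeats):
        successes = 0
        for d_id, positive in pairs:
            known = records[d_id].target_ids if d_id in records else interactions.targets_of(d_id)
            excluded = set(known) if not allow_target_negatives else {positive}
            pool = [p for p in proteins if p not in excluded]
            negatives = list(rng.choice(len(pool), size=n_negatives, replace=False))
            candidates = [positive] + [pool[i] for i in negatives]

            if is_score_model:
                sub = phi.values.loc[candidates].copy()
                col = singleton_column(positive)
                sub[d_id] = [col[prot_positions[p]] for p in candidates]
                sub_phi = ClosenessMatrix(values=sub, transfer=fn)
                scores = _scores_for_drug(d_id, model, ts, cs, sub_phi).to_numpy()
            elif callable(model):
                scores = np.asarray(model(rng, len(candidates)), dtype=float)
            elif isinstance(model, str) and model.lower() == "random":
                scores = rng.random(len(candidates))
            else:
                raise ValueError(f"unknown model {model!r}")
            if scores[0] > scores[1:].max():
                successes += 1
        precisions.append(successes / len(pairs))
    return ValidationReport(
        precisions=precisions,
        seed=seed,
        model=model_name,
        n_negatives=n_negatives,
    )


def pooled_rank_roc(
    results: Sequence[ConcordanceResult], gold: InteractionTable
) -> tuple[pd.DataFrame, float]:
    """ROC over rank thresholds, pooling (drug, protein) pairs across drugs.

    At threshold r, every protein ranked ≤ r for any drug is a predicted
    target; sensitivity is the fraction of gold pairs recovered, specificity
    the fraction of non-gold pairs left unpredicted. AUC by the trapezoid rule.
    """
    if not gold.pairs:
        raise ValueError("empty gold-standard interaction table")
    by_drug = {r.drug_id: r for r in results}
    missing = {d for d, _ in gold.pairs if d not in by_drug}
    if missing:
        raise ValueError(f"no ranking result for gold drug(s): {sorted(missing)[:5]}")
    n_proteins = len(results[0].ranks)
    n_drugs = len(results)

    gold_ranks = []
    for d, p in gold.pairs:
        res = by_drug[d]
        if p not in res.ranks.index:
            raise ValueError(f"gold protein {p} absent from ranking of drug {d}")
        gold_ranks.append(int(res.ranks.loc[p]))
    n_pos = len(gold_ranks)
    n_total = n_drugs * n_proteins
    n_neg = n_total - n_pos

    tp_at_rank = np.bincount(gold_ranks, minlength=n_proteins + 1)
    tp_cum = np.cumsum(tp_at_rank)  # tp_cum[r] = gold pairs with rank <= r
    r = np.arange(0, n_proteins + 1)
    predicted = n_drugs * r
    fp = predicted - tp_cum
    sens = tp_cum / n_pos
    fpr = fp / n_neg if n_neg > 0 else np.zeros_like(fp, dtype=float)
    curve = pd.DataFrame(
        {"rank_threshold": r, "sensitivity": sens, "specificity": 1.0 - fpr}
    )
    auc = float(np.trapezoid(sens, fpr))
    return curve, auc


def rank_enrichment(
    target_ranks: Sequence[int], n_candidates: int
) -> tuple[float, float]:
    """Fold enrichment of target ranks at the worst-target-rank cutoff.

    With k targets all ranked within r_max = max(rank) of n_candidates
    proteins, the fold is (k/r_max)/(k/N) = N/r_max. The one-sided p-value is
    the Fisher exact (hypergeometric) tail of the 2×2 table targets vs
    non-targets × within vs beyond the cutoff.
    """
    ranks = [int(r) for r in target_ranks]
    if not ranks:
        raise ValueError("empty rank list")
    if len(set(ranks)) != len(ranks):
        raise ValueError("target ranks must be distinct")
    if min(ranks) < 1 or max(ranks) > n_candidates:
        raise ValueError("ranks must lie in 1..n_candidates")
    k = len(ranks)
    r_max = max(ranks)
    fold = n_candidates / r_max
    table = [[k, 0], [r_max - k, n_candidates - r_max]]
    _, p = stats.fisher_exact(table, alternative="greater")
    return fold, float(p)


def similarity_bin_enrichment(
    sim: pd.DataFrame,
    interactions: InteractionTable,
    n_bins: int = 10,
) -> pd.DataFrame:
    """Fold enrichment of common-target drug pairs per similarity bin.

    Pairs of drugs (both with known targets) are binned by similarity into
    ``n_bins`` equal-width bins on [0, 1]; the fold in a bin is the share of
    common-target pairs there divided by the overall share.
    """
    druggable = sorted(set(sim.index) & interactions.drug_ids)
    if len(druggable) < 2:
        raise ValueError("need at least 2 drugs with known targets")
    targets = {d: interactions.targets_of(d) for d in druggable}
    sims, common = [], []
    for i, a in enumerate(druggable):
        for b in druggable[i + 1 :]:
            sims.append(float(sim.loc[a, b]))
            common.append(bool(targets[a] & targets[b]))
    sims = np.asarray(sims)
    common = np.asarray(common)
    overall = common.mean()
    edges = np.linspace(0.0, 1.0, n_bins + 1)
    which = np.clip(np.digitize(sims, edges, right=False) - 1, 0, n_bins - 1)
    rows = []
    for b in range(n_bins):
        mask = which == b
        n_pairs = int(mask.sum())
        n_common = int(common[mask].sum())
        if overall == 0:
            fold = np.nan
        elif n_pairs == 0:
            fold = np.nan
        else:
            fold = (n_common / n_pairs) / overall
        rows.append((edges[b], edges[b + 1], n_pairs, n_common, fold))
    if overall == 0:
        logger.warning("no common-target pairs; folds are NaN")
    return pd.DataFrame(
        rows, columns=["bin_lo", "bin_hi", "n_pairs", "n_common_target", "fold"]
    )


def _upper_triangle(m: np.ndarray) -> np.ndarray:
    iu = np.triu_indices(m.shape[0], k=1)
    return m[iu]


def correlation_with_permutation(
    sim: pd.DataFrame,
    gr: pd.DataFrame,
    n_perm: int = 10_000,
    seed: int = 0,
) -> tuple[float, float]:
    """Spearman correlation of two symmetric drug matrices with a label-
    shuffling null.

    The correlation is computed over upper-triangle entries. Each permutation
    relabels the drugs of one matrix (joint row/column shuffle); the one-sided
    empirical p uses the (count + 1)/(n_perm + 1) estimator.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    if sim.shape != gr.shape:
        raise ValueError("matrices must have the same shape")
    common = [d for d in sim.index if d in gr.index]
    A = sim.loc[common, common].to_numpy(dtype=float)
    B = gr.loc[common, common].to_numpy(dtype=float)
    n = A.shape[0]
    iu = np.triu_indices(n, k=1)

    # rank-transform entries once; a joint row/column shuffle only re-pairs
    # entries, so Spearman rho = Pearson on the pre-ranked matrices
    def rank_matrix(m: np.ndarray) -> np.ndarray:
        vals = stats.rankdata(m[iu])
        out = np.zeros_like(m)
        out[iu] = vals
        out.T[iu] = vals
        return out

    RA, RB = rank_matrix(A), rank_matrix(B)
    a = RA[iu]

    def rho_against(rb: np.ndarray) -> float:
        b = rb[iu]
        ac, bc = a - a.mean(), b - b.mean()
        denom = np.linalg.norm(ac) * np.linalg.norm(bc)
        return float(ac @ bc / denom) if denom > 0 else 0.0

    rho = rho_against(RB)
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(n)
        if rho_against(RB[np.ix_(perm, perm)]) >= rho:
            count += 1
    p = (count + 1) / (n_perm + 1)
    return rho, p
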