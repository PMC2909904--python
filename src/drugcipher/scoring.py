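"""Concordance scoring: the TS, CS and MS regression models.

Each model relates a drug's pharmacological similarity vector over all n
drugs (therapeutic TS_d, chemical CS_d, or both) to a protein's closeness
vector Φ_p over the same drugs, and scores how well the protein's network
position explains the drug's similarity profile. The concordance is the
Pearson correlation between Φ_p and the similarity vector (TS/CS models) or
between Φ_p and its least-squares fit a′·TS_d + b′·CS_d + c (MS model); the
exact functional is isolated in one function per model so an alternative
fitness measure can be substituted without touching callers.

The MS concordance is evaluated on the non-negative-coefficient cone: the
regression premise is that pharmacological similarity contributes
non-negatively to closeness, so when the unconstrained fit turns a
coefficient negative the score falls back to the best single-predictor fit
with a positive slope (the exact non-negative least-squares solution for
two predictors with a free intercept). This keeps the MS score comparable
with the signed TS/CS scores: a protein whose closeness profile is merely
anti-correlated with the similarity vectors scores low under every model
instead of being rewarded for a good sign-flipped fit.

Scores lie in [−1, 1]; larger means the protein is a more likely target.
Any zero-variance vector yields concordance 0 rather than NaN.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .types import ClosenessMatrix, ConcordanceResult, DrugRecord, RegressionFit

MODELS = ("TS", "CS", "MS")

_COLLINEAR_TOL = 1e-10


def _as_vec(x) -> np.ndarray:
    return np.asarray(x, dtype=float).ravel()


def pearson(a: np.ndarray, b: np.ndarray) -> float:
    """Pearson correlation with the zero-variance convention: score 0."""
    a, b = _as_vec(a), _as_vec(b)
    if a.size != b.size:
        raise ValueError(f"vector length mismatch: {a.size} vs {b.size}")
    ac = a - a.mean()
    bc = b - b.mean()
    na = np.linalg.norm(ac)
    nb = np.linalg.norm(bc)
    if na == 0.0 or nb == 0.0:
        return 0.0
    return float(np.clip(ac @ bc / (na * nb), -1.0, 1.0))


def concordance_ts(ts_vec, phi_vec) -> float:
    """TS-model score: correlation between TS_d and Φ_p."""
    return pearson(ts_vec, phi_vec)


def concordance_cs(cs_vec, phi_vec) -> float:
    """CS-model score: correlation between CS_d and Φ_p."""
    return pearson(cs_vec, phi_vec)


def fit_ms(ts_vec, cs_vec, phi_vec) -> RegressionFit:
    """Least-squares fit Φ_p ≈ a′·TS_d + b′·CS_d + intercept.

    A collinear design (TS and CS proportional after centering, or either
    constant) falls back to the single predictor whose centered fit has the
    larger magnitude, with the fallback flagged.
    """
    ts, cs, phi = _as_vec(ts_vec), _as_vec(cs_vec), _as_vec(phi_vec)
    if not (ts.size == cs.size == phi.size):
        raise ValueError("TS, CS and Φ vectors must have equal length")
    n = ts.size
    if n < 3:
        raise ValueError("MS fit needs at least 3 observations")

    tc = ts - ts.mean()
    cc = cs - cs.mean()
    gram = np.array([[tc @ tc, tc @ cc], [cc @ tc, cc @ cc]])
    scale = max(gram[0, 0], gram[1, 1])
    collinear = scale == 0.0 or abs(np.linalg.det(gram)) <= _COLLINEAR_TOL * scale**2

    if collinear:
        pc = phi - phi.mean()
        beta_t = (tc @ pc) / (tc @ tc) if tc @ tc > 0 else 0.0
        beta_c = (cc @ pc) / (cc @ cc) if cc @ cc > 0 else 0.0
        if abs(beta_t) >= abs(beta_c):
            a, b = float(beta_t), 0.0
        else:
            a, b = 0.0, float(beta_c)
        intercept = float(phi.mean() - a * ts.mean() - b * cs.mean())
        resid = phi - (a * ts + b * cs + intercept)
        return RegressionFit(a, b, intercept, float(np.linalg.norm(resid)), True)

    X = np.column_stack([ts, cs, np.ones(n)])
    beta, *_ = np.linalg.lstsq(X, phi, rcond=None)
    resid = phi - X @ beta
    return RegressionFit(
        float(beta[0]), float(beta[1]), float(beta[2]), float(np.linalg.norm(resid))
    )


def concordance_ms(fit: RegressionFit, ts_vec, cs_vec, phi_vec) -> float:
    """MS-model score: correlation between Φ_p and the fitted combination.

    With both coefficients non-negative this is the multiple correlation of
    the fit. A negative coefficient projects the fit onto the non-negative
    cone, which for two predictors reduces to the better positively-sloped
    single-predictor correlation (0 if neither slope is positive).
    """
    ts, cs, phi = _as_vec(ts_vec), _as_vec(cs_vec), _as_vec(phi_vec)
    if fit.a_prime >= 0.0 and fit.b_prime >= 0.0:
        fitted = fit.a_prime * ts + fit.b_prime * cs
        return pearson(phi, fitted)
    return max(pearson(phi, ts), pearson(phi, cs), 0.0)


def _scores_for_drug(
    drug_id: str,
    model: str,
    ts_matrix: pd.DataFrame,
    cs_matrix: pd.DataFrame,
    phi: ClosenessMatrix,
) -> pd.Series:
    """Vectorized per-protein concordance scores for one drug.

    The MS branch exploits that every protein shares the same design matrix
    [TS_d, CS_d, 1]: a single ``lstsq`` solves all per-protein fits at once,
    and the score equals the correlation of each Φ row with its fitted values.
    """
    model = model.upper()
    if model not in MODELS:
        raise ValueError(f"unknown model {model!r}; expected one of {MODELS}")
    drug_order = list(phi.values.columns)
    if drug_id not in ts_matrix.index and model in ("TS", "MS"):
        raise KeyError(f"drug {drug_id} absent from TS matrix")
    if drug_id not in cs_matrix.index and model in ("CS", "MS"):
        raise KeyError(f"drug {drug_id} absent from CS matrix")

    P = phi.values.to_numpy(dtype=float)  # proteins × drugs
    Pc = P - P.mean(axis=1, keepdims=True)
    pnorm = np.linalg.norm(Pc, axis=1)

    def corr_with(vec: np.ndarray) -> np.ndarray:
        vc = vec - vec.mean()
        vn = np.linalg.norm(vc)
        if vn == 0.0:
            return np.zeros(P.shape[0])
        with np.errstate(invalid="ignore", divide="ignore"):
            r = (Pc @ vc) / (pnorm * vn)
        r[pnorm == 0.0] = 0.0
        return np.clip(r, -1.0, 1.0)

    if model == "TS":
        vec = ts_matrix.loc[drug_id, drug_order].to_numpy(dtype=float)
        scores = corr_with(vec)
    elif model == "CS":
        vec = cs_matrix.loc[drug_id, drug_order].to_numpy(dtype=float)
        scores = corr_with(vec)
    else:
        ts = ts_matrix.loc[drug_id, drug_order].to_numpy(dtype=float)
        cs = cs_matrix.loc[drug_id, drug_order].to_numpy(dtype=float)
        tc, cc = ts - ts.mean(), cs - cs.mean()
        gram = np.array([[tc @ tc, tc @ cc], [cc @ tc, cc @ cc]])
        scale = max(gram[0, 0], gram[1, 1])
        rt = corr_with(ts)
        rc = corr_with(cs)
        boundary = np.maximum(np.maximum(rt, rc), 0.0)
        if scale == 0.0 or abs(np.linalg.det(gram)) <= _COLLINEAR_TOL * scale**2:
            # collinear design: the cone solution is a single-predictor fit
            scores = boundary
        else:
            X = np.column_stack([ts, cs, np.ones(ts.size)])
            beta, *_ = np.linalg.lstsq(X, P.T, rcond=None)  # 3 × proteins
            fitted = (X @ beta).T  # proteins × drugs
            Fc = fitted - fitted.mean(axis=1, keepdims=True)
            fnorm = np.linalg.norm(Fc, axis=1)
            denom = pnorm * fnorm
            with np.errstate(invalid="ignore", divide="ignore"):
                multiple_r = np.einsum("ij,ij->i", Pc, Fc) / denom
            multiple_r[denom == 0.0] = 0.0
            interior = (beta[0] >= 0.0) & (beta[1] >= 0.0)
            scores = np.clip(np.where(interior, multiple_r, boundary), -1.0, 1.0)
    return pd.Series(scores, index=phi.values.index, name=drug_id)


def rank_proteins(
    drug: DrugRecord | str,
    model: str,
    ts_matrix: pd.DataFrame,
    cs_matrix: pd.DataFrame,
    phi: ClosenessMatrix,
) -> ConcordanceResult:
    """Score every protein in the network for one drug and rank descending.

    Ties are broken by protein id lexicographic order, making the ranking a
    deterministic permutation 1..n_proteins.
    """
    drug_id = drug.drug_id if isinstance(drug, DrugRecord) else drug
    scores = _scores_for_drug(drug_id, model, ts_matrix, cs_matrix, phi)
    order = sorted(scores.index, key=lambda p: (-scores.loc[p], p))
    ranks = pd.Series(
        np.arange(1, len(order) + 1), index=order, name=drug_id
    ).reindex(scores.index)
    return ConcordanceResult(
        drug_id=drug_id, model=model.upper(), scores=scores, ranks=ranks
    )
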