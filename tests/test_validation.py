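import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import drugcipher as dc
from drugcipher.types import ConcordanceResult, DrugRecord, InteractionTable


class TestAdjustCloseness:
    def test_removing_disconnected_target_changes_nothing(self, path_graph):
        drug = DrugRecord("d", target_ids={"p1", "p4"})
        phi = dc.closeness_matrix(path_graph, [drug])
        cache = dc.DistanceCache(path_graph)
        adjusted = dc.adjust_closeness_for_removed_targets(phi, drug, {"p4"}, cache)
        # p4 is isolated: its contribution to p1..p3 is already zero
        for p in ("p1", "p2", "p3"):
            assert adjusted.values.loc[p, "d"] == pytest.approx(phi.values.loc[p, "d"])
        # only p4's own self-term disappears
        assert adjusted.values.loc["p4", "d"] == pytest.approx(0.0)

    def test_empty_removal_is_identity(self, world, world_matrices):
        _, _, phi, cache = world_matrices
        drug = next(d for d in world.drugs if d.target_ids)
        adjusted = dc.adjust_closeness_for_removed_targets(phi, drug, set(), cache)
        pd.testing.assert_frame_equal(adjusted.values, phi.values)

    def test_equals_recomputation_oracle(self, world, world_matrices):
        _, _, phi, cache = world_matrices
        drugs = [d for d in world.drugs if len(d.target_ids) >= 2][:6]
        for drug in drugs:
            keep = sorted(drug.target_ids)[0]
            removed = drug.target_ids - {keep}
            adjusted = dc.adjust_closeness_for_removed_targets(phi, drug, removed, cache)
            fresh = dc.closeness_matrix(
                world.graph, {drug.drug_id: {keep}}, drug_ids=[drug.drug_id]
            )
            got = adjusted.values[drug.drug_id].to_numpy()
            want = fresh.values.loc[adjusted.values.index, drug.drug_id].to_numpy()
            assert np.allclose(got, want, atol=1e-12)

    def test_non_target_removal_rejected(self, world, world_matrices):
        _, _, phi, cache = world_matrices
        drug = next(d for d in world.drugs if d.target_ids)
        with pytest.raises(ValueError):
            dc.adjust_closeness_for_removed_targets(
                phi, drug, {"definitely-not-a-target"}, cache
            )


class TestLoocv:
    def test_oracle_scorer_gives_perfect_precision(self, world, world_matrices):
        ts, cs, phi, cache = world_matrices

        def oracle(rng, n_candidates):
            return np.linspace(1.0, 0.0, n_candidates)  # positive is candidate 0

        report = dc.loocv_precision(
            oracle, world.drugs, world.interactions, phi, ts, cs, cache,
            n_repeats=2, seed=11,
        )
        assert report.precisions == [1.0, 1.0]

    def test_random_scorer_matches_analytic_null(self, world, world_matrices):
        ts, cs, phi, cache = world_matrices
        n_pairs = len(world.interactions)
        n_repeats = max(1, 2000 // n_pairs + 1)
        report = dc.loocv_precision(
            "random", world.drugs, world.interactions, phi, ts, cs, cache,
            n_negatives=19, n_repeats=n_repeats, seed=5,
        )
        trials = n_pairs * n_repeats
        tol = 4 * math.sqrt(0.05 * 0.95 / trials)
        assert abs(report.mean_precision - 1 / 20) < tol

    def test_seeded_runs_reproduce_exactly(self, world, world_matrices):
        ts, cs, phi, cache = world_matrices
        kwargs = dict(n_negatives=5, n_repeats=2, seed=42)
        r1 = dc.loocv_precision(
            "random", world.drugs, world.interactions, phi, ts, cs, cache, **kwargs
        )
        r2 = dc.loocv_precision(
            "random", world.drugs, world.interactions, phi, ts, cs, cache, **kwargs
        )
        assert r1.precisions == r2.precisions

    def test_excessive_negatives_error(self, world, world_matrices):
        ts, cs, phi, cache = world_matrices
        with pytest.raises(ValueError):
            dc.loocv_precision(
                "random", world.drugs, world.interactions, phi, ts, cs, cache,
                n_negatives=10_000,
            )

    def test_model_scoring_beats_null(self, world, world_matrices):
        ts, cs, phi, cache = world_matrices
        report = dc.loocv_precision(
            "MS", world.drugs, world.interactions, phi, ts, cs, cache,
            n_negatives=19, n_repeats=2, seed=3,
        )
        assert report.mean_precision > 0.3  # far above the 0.05 null


def _result_from_scores(drug_id, scores: pd.Series) -> ConcordanceResult:
    order = sorted(scores.index, key=lambda p: (-scores[p], p))
    ranks = pd.Series(
        np.arange(1, len(order) + 1), index=order
    ).reindex(scores.index)
    return ConcordanceResult(drug_id, "X", scores, ranks)


class TestPooledRankRoc:
    def test_perfect_ranking_gives_auc_one(self):
        proteins = [f"p{i}" for i in range(10)]
        scores = pd.Series(np.linspace(1, 0, 10), index=proteins)
        res = _result_from_scores("d", scores)
        gold = InteractionTable(pairs={("d", "p0")})
        _, auc = dc.pooled_rank_roc([res], gold)
        assert auc == pytest.approx(1.0)

    def test_hand_computed_single_drug_auc(self):
        scores = pd.Series([0.9, 0.8, 0.7, 0.6], index=["a", "b", "c", "d"])
        res = _result_from_scores("drug", scores)
        gold = InteractionTable(pairs={("drug", "a"), ("drug", "c")})
        _, auc = dc.pooled_rank_roc([res], gold)
        assert auc == pytest.approx(0.75)

    def test_equals_mann_whitney_on_single_drug(self, rng):
        proteins = [f"p{i}" for i in range(40)]
        scores = pd.Series(rng.random(40), index=proteins)
        positives = set(rng.choice(proteins, size=8, replace=False))
        res = _result_from_scores("d", scores)
        gold = InteractionTable(pairs={("d", p) for p in positives})
        _, auc = dc.pooled_rank_roc([res], gold)
        pos = scores[list(positives)].to_numpy()
        neg = scores[[p for p in proteins if p not in positives]].to_numpy()
        u, _ = stats.mannwhitneyu(pos, neg, alternative="greater")
        assert auc == pytest.approx(u / (len(pos) * len(neg)))

    def test_random_scores_near_half(self, rng):
        proteins = [f"p{i}" for i in range(200)]
        results, pairs = [], set()
        for d in range(40):
            scores = pd.Series(rng.random(200), index=proteins)
            results.append(_result_from_scores(f"d{d}", scores))
            pairs.update((f"d{d}", p) for p in rng.choice(proteins, 5, replace=False))
        _, auc = dc.pooled_rank_roc(results, InteractionTable(pairs=pairs))
        assert abs(auc - 0.5) < 0.05

    def test_empty_gold_errors(self):
        with pytest.raises(ValueError):
            dc.pooled_rank_roc([], InteractionTable())


class TestRankEnrichment:
    def test_worked_fold_values_at_genome_scale(self):
        fold_db, p_db = dc.rank_enrichment([9, 12, 33, 267, 305], 9981)
        assert fold_db == pytest.approx(9981 / 305)
        assert round(fold_db) == 33
        fold_ki, p_ki = dc.rank_enrichment([32, 103, 119], 9981)
        assert fold_ki == pytest.approx(9981 / 119)
        assert round(fold_ki) == 84
        assert 0 < p_db < 1e-4 and 0 < p_ki < 1e-4

    def test_single_target_at_bottom_gives_fold_one(self):
        fold, p = dc.rank_enrichment([100], 100)
        assert fold == 1.0
        assert p == pytest.approx(1.0)

    def test_p_matches_hypergeometric_tail(self):
        ranks, n = [1, 2, 5], 50
        _, p = dc.rank_enrichment(ranks, n)
        k, r_max = len(ranks), max(ranks)
        expected = stats.hypergeom.sf(k - 1, n, k, r_max)
        assert p == pytest.approx(expected, rel=1e-9)

    @pytest.mark.parametrize("bad", [[], [1, 1], [0], [11]])
    def test_invalid_rank_lists_rejected(self, bad):
        with pytest.raises(ValueError):
            dc.rank_enrichment(bad, 10)


class TestSimilarityBinEnrichment:
    def test_random_targets_give_flat_folds(self, rng):
        n = 40
        ids = [f"d{i}" for i in range(n)]
        sim = rng.random((n, n))
        sim = (sim + sim.T) / 2
        np.fill_diagonal(sim, 1.0)
        sim_df = pd.DataFrame(sim, index=ids, columns=ids)
        pairs = set()
        for d in ids:
            for t in rng.choice(30, size=3, replace=False):
                pairs.add((d, f"p{t}"))
        table = dc.similarity_bin_enrichment(
            sim_df, InteractionTable(pairs=pairs), n_bins=4
        )
        populated = table.dropna(subset=["fold"])
        assert (populated["fold"] - 1).abs().max() < 0.8  # no strong trend

    def test_planted_high_similarity_sharing_enriched(self, world, world_matrices):
        _, cs, _, _ = world_matrices
        table = dc.similarity_bin_enrichment(cs, world.interactions, n_bins=5)
        # direct counting oracle, pooled over the high-similarity half
        high = table[table["bin_lo"] >= 0.5]
        low = table[table["bin_lo"] < 0.5]
        high_share = high["n_common_target"].sum() / high["n_pairs"].sum()
        low_share = low["n_common_target"].sum() / low["n_pairs"].sum()
        assert high_share > low_share

    def test_single_bin_fold_is_one(self, world, world_matrices):
        _, cs, _, _ = world_matrices
        table = dc.similarity_bin_enrichment(cs, world.interactions, n_bins=1)
        assert table["fold"].iloc[0] == pytest.approx(1.0)


class TestCorrelationWithPermutation:
    def test_self_correlation(self, world, world_matrices):
        _, cs, _, cache = world_matrices
        rho, p = dc.correlation_with_permutation(cs, cs, n_perm=99, seed=1)
        assert rho == pytest.approx(1.0)
        assert p <= 2 / 100

    def test_independent_matrices_null(self, rng):
        n = 20
        ids = [f"d{i}" for i in range(n)]

        def random_sym():
            m = rng.random((n, n))
            m = (m + m.T) / 2
            return pd.DataFrame(m, index=ids, columns=ids)

        rho, p = dc.correlation_with_permutation(
            random_sym(), random_sym(), n_perm=199, seed=2
        )
        assert abs(rho) < 0.2
        assert p > 0.01

    def test_matches_rank_then_pearson_oracle(self, rng):
        n = 6
        ids = [f"d{i}" for i in range(n)]

        def sym(m):
            m = (m + m.T) / 2
            return pd.DataFrame(m, index=ids, columns=ids)

        a, b = sym(rng.random((n, n))), sym(rng.random((n, n)))
        rho, _ = dc.correlation_with_permutation(a, b, n_perm=10, seed=3)
        iu = np.triu_indices(n, k=1)
        ra = stats.rankdata(a.to_numpy()[iu])
        rb = stats.rankdata(b.to_numpy()[iu])
        assert rho == pytest.approx(np.corrcoef(ra, rb)[0, 1])

    def test_bad_nperm_errors(self, world_matrices):
        _, cs, _, _ = world_matrices
        with pytest.raises(ValueError):
            dc.correlation_with_permutation(cs, cs, n_perm=0)

    def test_coupled_world_correlation_positive(self, world, world_matrices):
        ts, cs, _, cache = world_matrices
        drugs = [d for d in world.drugs if d.target_ids]
        gr = dc.gr_matrix(drugs, cache)
        ids = list(gr.index)
        rho_ts, p_ts = dc.correlation_with_permutation(
            ts.loc[ids, ids], gr, n_perm=199, seed=4
        )
        rho_cs, p_cs = dc.correlation_with_permutation(
            cs.loc[ids, ids], gr, n_perm=199, seed=4
        )
        assert rho_ts > 0 and rho_cs > 0
        assert p_ts <= 0.05 and p_cs <= 0.05
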