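# Methods

This note documents the model, the numerical choices, the synthetic-data
generator and the known limitations of `drugcipher`. It states no empirical
result that the test suite or `scripts/acceptance.py` does not itself
compute.

## The model

The method rests on three premises: (a) drugs with similar therapeutic
effects tend to act on functionally related proteins; (b) drugs with similar
chemical structure tend to bind related proteins; (c) functional relatedness
of proteins is visible as proximity in a protein–protein interaction (PPI)
network. The scoring machinery turns these premises into per-protein
regressions.

**Closeness.** For protein *p* and drug *d* with known target set `T(d)`,

    φ_pd = Σ_{t ∈ T(d)} f(L(p, t))

where `L` is the unweighted shortest-path distance and the transfer
`f(L) = exp(−L²)` maps distance to proximity (`f(0) = 1`, `f(∞) = 0` for
disconnected pairs). The transfer is a configurable pure function
(`closeness.TRANSFERS`); `exp(−L²)` is the package default and decays so
fast that in practice only the ≤3-step neighbourhood of a target
contributes. Targets absent from the network are added as isolated nodes, so
they contribute exactly their self-term. A protein that is itself a target
keeps its self-distance-0 term; it is not excluded.

**Therapeutic similarity (TS).** ATC codes are 7-character strings encoding
a 5-level hierarchy (prefix lengths 1, 3, 4, 5, 7). Code similarity is Lin's
information-content measure

    sim(i, j) = 2·ln P(prefix(i, j)) / (ln P(i) + ln P(j))

where `prefix(i, j)` is the longest common prefix *at a level boundary* —
never at arbitrary character positions — and `P(x)` is the fraction of
drug–code assignments in the corpus whose code starts with `x`. A drug
contributes one count per assigned code, not one per drug. Identical leaf
codes score 1 by continuity even in the degenerate single-code corpus where
the ratio would be 0/0. Codes absent from the training corpus receive a
pseudo-count of one assignment (logged) so query drugs with unseen codes
still score. The log base cancels in the ratio; natural log is used. TS
between two drugs is the maximum code similarity over their code pairs.

**Chemical similarity (CS).** Tanimoto coefficient `|a∧b| / |a∨b|` on
equal-length binary fingerprints. The reference path takes explicit bit
vectors (so the package runs without a chemistry toolkit); an optional RDKit
backend computes 2D path-based fingerprints from SMILES. A pair of all-zero
fingerprints scores 0, not NaN.

**Concordance.** Over the *n* drugs of the corpus, each drug has vectors
`TS_d`, `CS_d` and each protein the closeness vector `Φ_p`. The query drug's
own entries (TS_dd = CS_dd = 1, φ_pd) are retained: the self-entry pins the
strongest coordinate of the similarity vector to the drug's own closeness
column and carries real signal. The three scores are

* TS model: `corr(TS_d, Φ_p)` (Pearson),
* CS model: `corr(CS_d, Φ_p)`,
* MS model: least-squares fit `Φ_p ≈ a′·TS_d + b′·CS_d + c`, scored as
  `corr(Φ_p, a′·TS_d + b′·CS_d)` on the non-negative-coefficient cone.

Any correlation involving a zero-variance vector is defined as 0. Scores are
invariant under positive affine rescaling of `Φ_p`. Rankings sort by
descending score with ties broken by protein id, so results are
deterministic permutations.

**Why the cone?** The unconstrained two-predictor fit is sign-blind: its
multiple correlation is equally high for proteins whose closeness profile is
*anti*-correlated with the similarity vectors, because the regression simply
flips a coefficient's sign. Under the model's premise, similarity explains
closeness with non-negative weight, so a negative fitted coefficient means
the corresponding channel does not support the protein at all. The cone
projection — for two predictors, fall back to the better positively-sloped
single-predictor correlation, or 0 if neither slope is positive — is the
exact non-negative least-squares solution with a free intercept. It keeps
the MS score comparable with the signed TS/CS scores and preserves the
dominance property in its meaningful form: whenever both single-model scores
are non-negative, the MS score is at least their maximum. `fit_ms` itself
remains the unconstrained least-squares solution (it satisfies the normal
equations to 1e-8 relative and is tested against the closed form); the
projection happens at scoring time, and the collinear-design fallback
(single-predictor fit, flagged) uses the same rule.

## Validation machinery

**Cross-validation.** For each known (drug, target) pair, all *other*
targets of the drug are removed and the drug's closeness column is adjusted
by subtracting the removed targets' transfer terms — algebraically identical
(to 1e-12, tested against recomputation) to recomputing closeness with the
singleton target set. The held-out target plus 19 negative-control proteins
(the default; configurable) form the candidate set; negatives are drawn
uniformly without replacement from the network *excluding the drug's known
targets* — the package treats contaminated negatives as label noise, with an
`allow_target_negatives` toggle to sample from the whole network instead.
Success requires the true target strictly first; ties at rank 1 count as
failure (conservative). Precision is the success fraction over all pairs,
repeated with fresh negative draws. Under a uniformly random scorer the
expected precision is exactly 1/(1 + n_negatives) = 1/20 at defaults, which
the suite checks against the binomial tolerance.

**Pooled ROC.** Every (drug, protein) pair across all ranked drugs is one
instance; at rank threshold *r* the predicted positives are all pairs with
rank ≤ *r*. Sensitivity and specificity over the gold-standard pairs give
the curve; AUC is trapezoidal and equals the Mann–Whitney U normalization on
single-drug instances (tested).

**Fold enrichment.** With *k* targets all ranked within `r_max` (the worst
target rank) of *N* proteins, fold = `(k/r_max)/(k/N) = N/r_max`; the
one-sided p-value is the hypergeometric tail of the corresponding 2×2 table.
The fold is the reliable quantity; published p-values for this construction
are not reproducible from printed counts and are therefore computed but not
asserted against external values.

**Permutation tests.** Spearman correlation between two symmetric drug
matrices is computed over upper-triangle entries; the null relabels the
drugs of one matrix (joint row/column permutation). Because a relabeling
only re-pairs entries, both matrices are rank-transformed once and each
permutation costs one Pearson correlation. The empirical p uses the
(count+1)/(n_perm+1) estimator, so p is never 0.

## Fingerprint analysis

The drugs × proteins matrix of MS scores is the map of biological
fingerprints. "Unspecific" proteins — near-constant score profiles across
drugs — are dropped by an across-drug standard-deviation criterion: SD below
the `sd_quantile` quantile of all protein SDs (default 0.0343, which retains
≈96.6% of proteins when dispersions are homogeneous; zero-variance proteins
are always dropped). The criterion is configurable, a filtered map records
its absolute cutoff so re-filtering is a no-op, and the filter's behaviour
on i.i.d. noise (removes ≈ the quantile fraction) is tested against an
order-statistics oracle.

Activity resemblance is the cosine of two fingerprint rows. The
significance threshold at level α is the (1−α) order-statistic quantile
(method "higher", so at most an α fraction of null values exceed it and
α → 0 yields the maximum) of a null distribution: by default the empirical
distribution of all observed pair resemblances, alternatively a
protein-label permutation null. The threshold is always recomputed from the
data, never hard-coded, because it depends on the corpus. Unexpected
relations are pairs at or above the threshold whose ATC first-level letter
sets are disjoint ("different main classes" for multi-code drugs means *no*
shared first-level letter); each pair is flagged for sharing a known target.

## The synthetic world

No public corpus ships with the package, so `simulate.generate_world` builds
a seeded toy world with the structure the premises assume:

* **Graph**: proteins partitioned into `n_modules` modules, planted-partition
  edges (within-module probability 0.25, between 0.008), plus ~2% isolated
  nodes to exercise infinite distances.
* **Targets**: each drug gets a home module and 2–5 targets (uniform; mean
  3.5), each drawn from the home module with probability 0.9.
* **Therapeutic channel**: with probability `ts_strength` a drug's ATC codes
  carry its home module's first-level letter; otherwise the whole code set
  points at a random module. Middle hierarchy levels vary randomly so
  matched prefixes of different depths (and information contents) occur.
* **Chemical channel**: with probability `cs_strength` the fingerprint
  derives from the home module's prototype (per-module random prototypes,
  density 0.3, 192 bits, 15% per-bit noise); otherwise from a random
  module's prototype.

The two channels fail independently per drug, so they are complementary
rather than redundant: the drugs the therapeutic channel misleads are mostly
not the drugs the chemical channel misleads, which is exactly the situation
in which combining both channels (MS) recovers more targets than either
alone. Coupling defaults are `ts_strength = cs_strength = 0.75` — strong but
imperfect channels. At zero coupling the similarities are independent of the
network (tested via the permutation null); at full coupling same-module
pairs have strictly higher mean TS, CS and genomic relatedness than
cross-module pairs (tested).

What the generator does **not** emulate: realistic degree distributions
(hubs), overlapping module membership, the heavy-tailed target-set sizes of
real pharmacopoeias, fingerprint bit correlations, or the shallow/deep
imbalance of the real ATC tree. Passing tests therefore demonstrate internal
consistency and recoverability of planted structure, not performance on real
DrugBank/HPRD-scale data; the published headline precisions and AUCs depend
on those snapshots and are out of reach at desk scale.

## Problem sizes and defaults

The shared unit-test world uses 30 drugs × 150 proteins; model-comparison
and acceptance computations use 60 drugs × 300 proteins × 6 modules averaged
over 5 seeds, and the cross-validation nulls use ≥2000 trials. These sizes
were chosen so the full suite exercises every code path, including the
stochastic machinery, at statistically meaningful scale. Validation defaults
follow the method's stated protocol: 19 negatives, 100 repeats (CLI
default), strict top-rank success. All randomness flows from explicit seeds
through `numpy.random.default_rng`; seeded runs are bit-reproducible, and
set iteration never determines a floating-point summation order.

## Known limitations

* Concordance functionals are correlation-based readings of the underlying
  regression models; they are isolated in one function per model
  (`concordance_ts/cs/ms`) so an alternative fitness measure can be swapped
  in without touching callers.
* The unspecific-protein criterion and the resemblance null model are
  explicit stand-ins for procedure details that are configurable knobs here.
* Proteins outside the PPI network can only be scored as isolated nodes
  (their closeness column is their self-term); identifier mapping between
  vocabularies is out of scope — protein ids are opaque strings.
* The pipeline makes no binary "is a target" call: scores are likelihood
  orderings, and binding is a continuous phenomenon; thresholding is left to
  the user.
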