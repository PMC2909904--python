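"""Network closeness: shortest-path distances, drug–protein closeness Φ and
drug–drug genomic relatedness (GR) on the protein–protein interaction graph.

Closeness between protein p and drug d sums a distance→closeness transfer
over the drug's known targets: φ_pd = Σ_k f(L(p, p_k)), where L is the
unweighted shortest-path distance and disconnected pairs have L = ∞. The
default transfer f(L) = exp(−L²) decays fast enough that only the 2–3 step
network neighbourhood of a target contributes appreciably; f(∞) = 0.

GR between two drugs is the same transfer averaged over all cross pairs of
their target sets — high when their targets sit in the same network region.
"""

from __future__ import annotations

import logging
from typing import Callable, Iterable, Mapping, Sequence, Union

import networkx as nx
import numpy as np
import pandas as pd

from .types import ClosenessMatrix, DrugRecord, InteractionTable

logger = logging.getLogger(__name__)

Transfer = Callable[[np.ndarray], np.ndarray]


def exp_sq_transfer(L: np.ndarray) -> np.ndarray:
    """exp(−L²); maps distance 0 → 1 and ∞ → 0."""
    L = np.asarray(L, dtype=float)
    with np.errstate(over="ignore"):
        return np.exp(-np.square(L))


TRANSFERS: dict[str, Transfer] = {
    "exp_sq": exp_sq_transfer,
}


def resolve_transfer(transfer: Union[str, Transfer, None]) -> Transfer:
    if transfer is None:
        return exp_sq_transfer
    if callable(transfer):
        return transfer
    try:
        return TRANSFERS[transfer]
    except KeyError:
        raise ValueError(f"unknown transfer {transfer!r}; known: {sorted(TRANSFERS)}")


class DistanceCache:
    """Per-source BFS distances on a fixed graph, computed lazily and cached.

    Unreachable nodes get ``inf``. Repeated queries return identical values.
    """

    def __init__(self, graph: nx.Graph):
        self.graph = graph
        self._nodes = list(graph.nodes)
        self._index = {n: i for i, n in enumerate(self._nodes)}
        self._rows: dict[str, np.ndarray] = {}

    @property
    def nodes(self) -> list[str]:
        return self._nodes

    def row(self, source: str) -> np.ndarray:
        """Distances from ``source`` to every node, in ``self.nodes`` order."""
        if source not in self._index:
            raise KeyError(f"unknown source node {source!r}")
        cached = self._rows.get(source)
        if cached is None:
            lengths = nx.single_source_shortest_path_length(self.graph, source)
            cached = np.full(len(self._nodes), np.inf)
            for node, dist in lengths.items():
                cached[self._index[node]] = dist
            self._rows[source] = cached
        return cached

    def distance(self, source: str, target: str) -> float:
        return float(self.row(source)[self._index[target]])


def shortest_distances(graph: nx.Graph, sources: Iterable[str]) -> pd.DataFrame:
    """BFS distances from each source to every node (sources × nodes).

    Unreachable pairs get ``inf``; distance(p, p) = 0.
    """
    cache = DistanceCache(graph)
    sources = list(sources)
    rows = [cache.row(s) for s in sources]
    return pd.DataFrame(rows, index=sources, columns=cache.nodes, dtype=float)


def _target_sets(
    interactions: Union[InteractionTable, Sequence[DrugRecord], Mapping[str, set]],
) -> dict[str, set[str]]:
    if isinstance(interactions, InteractionTable):
        out: dict[str, set[str]] = {}
        for d, p in interactions.pairs:
            out.setdefault(d, set()).add(p)
        return out
    if isinstance(interactions, Mapping):
        return {d: set(ts) for d, ts in interactions.items()}
    return {d.drug_id: set(d.target_ids) for d in interactions}


def closeness_matrix(
    graph: nx.Graph,
    interactions: Union[InteractionTable, Sequence[DrugRecord], Mapping[str, set]],
    transfer: Union[str, Transfer, None] = None,
    drug_ids: Sequence[str] | None = None,
    cache: DistanceCache | None = None,
) -> ClosenessMatrix:
    """Proteins × drugs closeness matrix φ_pd = Σ_k transfer(L(p, p_k)).

    Target proteins absent from the graph are added as isolated nodes first.
    ``drug_ids`` may list drugs beyond those in ``interactions``; drugs with
    no targets get all-zero columns (logged).
    """
    fn = resolve_transfer(transfer)
    targets = _target_sets(interactions)
    missing = {t for ts in targets.values() for t in ts if t not in graph}
    if missing:
        logger.info("adding %d target protein(s) as isolated nodes", len(missing))
        graph = graph.copy()
        graph.add_nodes_from(missing)
    if cache is None or set(cache.graph.nodes) != set(graph.nodes):
        cache = DistanceCache(graph)

    if drug_ids is None:
        drug_ids = sorted(targets)
    nodes = cache.nodes
    values = np.zeros((len(nodes), len(drug_ids)))
    for j, d in enumerate(drug_ids):
        ts = targets.get(d, set())
        if not ts:
            logger.warning("drug %s has no known targets; zero closeness column", d)
            continue
        for t in sorted(ts):
            values[:, j] += fn(cache.row(t))
    df = pd.DataFrame(values, index=nodes, columns=list(drug_ids))
    return ClosenessMatrix(values=df, transfer=fn)


def genomic_relatedness(
    d1: DrugRecord,
    d2: DrugRecord,
    distances: DistanceCache,
    transfer: Union[str, Transfer, None] = None,
) -> float:
    """Average transfer(L) over all cross pairs of the two drugs' targets."""
    fn = resolve_transfer(transfer)
    if not d1.target_ids or not d2.target_ids:
        missing = d1.drug_id if not d1.target_ids else d2.drug_id
        raise ValueError(f"drug {missing} has no known targets; GR undefined")
    index = {n: i for i, n in enumerate(distances.nodes)}
    total = 0.0
    # sorted iteration fixes the float summation order across processes
    for t1 in sorted(d1.target_ids):
        row = distances.row(t1)
        for t2 in sorted(d2.target_ids):
            total += float(fn(np.array(row[index[t2]])))
    return total / (len(d1.target_ids) * len(d2.target_ids))


def gr_matrix(
    drugs: Sequence[DrugRecord],
    distances: DistanceCache,
    transfer: Union[str, Transfer, None] = None,
) -> pd.DataFrame:
    """Pairwise GR over all drugs with targets (symmetric, incl. self-GR)."""
    withT = [d for d in drugs if d.target_ids]
    ids = [d.drug_id for d in withT]
    n = len(withT)
    out = np.zeros((n, n))
    for a in range(n):
        for b in range(a, n):
            out[a, b] = out[b, a] = genomic_relatedness(
                withT[a], withT[b], distances, transfer
            )
    return pd.DataFrame(out, index=ids, columns=ids)
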