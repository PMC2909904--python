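"""Tabular input/output: TSV drug tables, PPI edge lists, labelled matrices.

Canonical dialect is tab-separated UTF-8 with a header row; lines starting
with ``#`` are comments. SIF (``a interacts b``) is accepted for PPI edges.
No science lives here.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Optional, Union

import networkx as nx
import numpy as np
import pandas as pd

from .atc import parse_atc_code
from .types import DrugRecord, InteractionTable

logger = logging.getLogger(__name__)

PathLike = Union[str, Path]

KI_THRESHOLD_NM = 10_000.0  # 10 µM: binding below this counts as an interaction


def _read_tsv(path: PathLike) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#", dtype=str)


def read_drug_tables(
    atc_path: Optional[PathLike] = None,
    fingerprint_path: Optional[PathLike] = None,
    target_path: Optional[PathLike] = None,
) -> list[DrugRecord]:
    """Assemble DrugRecords from up to three TSV tables.

    ``atc_path``: columns drug_id, atc_code. ``fingerprint_path``: columns
    drug_id, fingerprint (a literal bitstring such as ``0110...``).
    ``target_path``: columns drug_id, protein_id. A drug appearing in any one
    table gets a record; fields missing from the other tables stay empty.
    """
    atc: dict[str, list[str]] = {}
    fps: dict[str, np.ndarray] = {}
    targets: dict[str, set[str]] = {}

    if atc_path is not None:
        df = _read_tsv(atc_path)
        seen: set[tuple[str, str]] = set()
        for lineno, (drug_id, raw_code) in enumerate(
            zip(df.iloc[:, 0], df.iloc[:, 1]), start=2
        ):
            try:
                code = parse_atc_code(raw_code).code
            except ValueError as exc:
                raise ValueError(f"{atc_path}, line {lineno}: {exc}") from None
            if (drug_id, code) in seen:
                logger.warning("duplicate (drug, ATC) row %s/%s dropped", drug_id, code)
                continue
            seen.add((drug_id, code))
            atc.setdefault(drug_id, []).append(code)

    if fingerprint_path is not None:
        df = _read_tsv(fingerprint_path)
        for lineno, (drug_id, bits) in enumerate(
            zip(df.iloc[:, 0], df.iloc[:, 1]), start=2
        ):
            if not set(bits) <= {"0", "1"}:
                raise ValueError(
                    f"{fingerprint_path}, line {lineno}: fingerprint must be a 0/1 string"
                )
            if drug_id in fps:
                logger.warning("duplicate fingerprint row for %s dropped", drug_id)
                continue
            fps[drug_id] = np.frombuffer(bits.encode(), dtype=np.uint8) - ord("0")

    if target_path is not None:
        df = _read_tsv(target_path)
        for drug_id, protein_id in zip(df.iloc[:, 0], df.iloc[:, 1]):
            targets.setdefault(drug_id, set()).add(protein_id)

    lengths = {len(v) for v in fps.values()}
    if len(lengths) > 1:
        raise ValueError(f"fingerprints have mixed lengths: {sorted(lengths)}")

    drug_ids = sorted(set(atc) | set(fps) | set(targets))
    return [
        DrugRecord(
            drug_id=d,
            atc_codes=atc.get(d, []),
            fingerprint=fps.get(d),
            target_ids=targets.get(d, set()),
        )
        for d in drug_ids
    ]


def read_ppi_edgelist(path: PathLike) -> nx.Graph:
    """Read an undirected PPI edge list (TSV or SIF) into a simple graph.

    Self-loops are dropped with a warning; duplicate and reversed edges
    collapse. Extra columns beyond the two protein ids are ignored, except the
    SIF layout ``a <relation> b`` where the middle token is the relation.
    """
    graph = nx.Graph()
    n_rows = 0

    def is_sif(fields: list[str]) -> bool:
        return len(fields) >= 3 and fields[1].isalpha() and fields[1].islower()

    with open(path, encoding="utf-8") as fh:
        first_data_line = True
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) == 1:
                fields = line.split()
            if len(fields) < 2:
                raise ValueError(f"{path}, line {lineno}: need two protein columns")
            if first_data_line:
                first_data_line = False
                # canonical TSV carries a header row; SIF does not
                if not is_sif(fields):
                    continue
            if is_sif(fields):
                a, b = fields[0], fields[2]  # SIF: "a interacts b"
            else:
                a, b = fields[0], fields[1]
            n_rows += 1
            if a == b:
                logger.warning("%s line %d: self-loop %s dropped", path, lineno, a)
                graph.add_node(a)
                continue
            graph.add_edge(a, b)
    if n_rows == 0:
        raise ValueError(f"{path}: no edges found")
    return graph


def read_interactions(path: PathLike) -> InteractionTable:
    """Read a drug–target TSV (drug_id, protein_id[, ki_nM])."""
    df = _read_tsv(path)
    pairs: set[tuple[str, str]] = set()
    affinity: dict[tuple[str, str], float] = {}
    has_ki = df.shape[1] >= 3
    for row in df.itertuples(index=False):
        pair = (row[0], row[1])
        if pair in pairs:
            logger.warning("duplicate interaction %s dropped", pair)
            continue
        pairs.add(pair)
        if has_ki and row[2] is not None and not pd.isna(row[2]):
            affinity[pair] = float(row[2])
    return InteractionTable(pairs=pairs, affinity=affinity if affinity else None)


def apply_ki_filter(
    table: InteractionTable, threshold_nM: float = KI_THRESHOLD_NM
) -> InteractionTable:
    """Keep pairs with Ki strictly below the threshold (default 10 µM)."""
    if not table.pairs:
        return InteractionTable(pairs=set(), affinity={})
    if table.affinity is None or set(table.affinity) != table.pairs:
        missing = table.pairs - set(table.affinity or {})
        raise ValueError(f"Ki missing for {len(missing)} pair(s), e.g. {sorted(missing)[:3]}")
    kept = {p for p in table.pairs if table.affinity[p] < threshold_nM}
    return InteractionTable(pairs=kept, affinity={p: table.affinity[p] for p in kept})


def write_matrix(matrix: pd.DataFrame, path: PathLike) -> None:
    """Write a labelled matrix as TSV with row and column headers.

    Values are written as shortest round-trip representations and read back
    with a round-trip parser, so write→read reproduces them bit-exactly.
    """
    matrix.to_csv(path, sep="\t", index_label="id")


def read_matrix(path: PathLike) -> pd.DataFrame:
    df = pd.read_csv(
        path, sep="\t", index_col=0, comment="#", float_precision="round_trip"
    )
    df.index.name = None
    return df


def write_interactions(table: InteractionTable, path: PathLike) -> None:
    rows = []
    for d, p in sorted(table.pairs):
        if table.affinity and (d, p) in table.affinity:
            rows.append((d, p, table.affinity[(d, p)]))
        else:
            rows.append((d, p, ""))
    cols = ["drug_id", "protein_id", "ki_nM"]
    pd.DataFrame(rows, columns=cols).to_csv(path, sep="\t", index=False)


def write_ppi_edgelist(graph: nx.Graph, path: PathLike) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("protein_a\tprotein_b\n")
        for a, b in sorted(tuple(sorted(e)) for e in graph.edges()):
            fh.write(f"{a}\t{b}\n")
        for node in sorted(nx.isolates(graph)):
            fh.write(f"{node}\t{node}\n")  # self-row marks an isolated node
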