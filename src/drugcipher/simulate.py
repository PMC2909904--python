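"""Seeded synthetic-world generator.

Builds a toy corpus with the statistical structure the scoring framework
assumes: a module-structured (planted-partition) PPI graph with a few
isolated nodes, drugs anchored to a home module whose targets cluster there,
ATC leaf codes whose prefixes follow the home module with probability
``ts_strength``, and fingerprints mixed from a prototype with weight
``cs_strength`` so same-module Tanimoto similarity is elevated.

The two pharmacological channels are complementary per drug rather than
redundant: with probability ``ts_strength`` a drug's ATC codes follow its
home module (they carry the module's first-level letter), otherwise the
whole code points at a random module; independently, with probability
``cs_strength`` the drug's fingerprint derives from its home module's
prototype, otherwise from a random module's. Each channel therefore fails
outright for a fraction of drugs, and the drugs failed by the therapeutic
channel are (mostly) not the drugs failed by the chemical one — the
structure behind similarity blocks that appear in one pharmacological
matrix but not the other, and the reason combining both channels recovers
more targets than either alone.

At zero coupling the pharmacological similarities are independent of the
network structure. All randomness flows from one
``numpy.random.default_rng(seed)``; regeneration at a fixed seed is
bit-identical.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import networkx as nx
import numpy as np

from .types import DrugRecord, InteractionTable

# module level-1 letters follow the anatomical-group alphabet
_LEVEL1_LETTERS = "ABCDGHJLMNPRSV"

P_WITHIN_MODULE = 0.25
P_BETWEEN_MODULE = 0.008
ISOLATED_FRACTION = 0.02
HOME_TARGET_PROB = 0.9
TARGET_SET_SIZES = (2, 3, 4, 5)  # uniform; mean ~3.5 targets per drug
SECOND_CODE_PROB = 0.6
FINGERPRINT_BITS = 192
FINGERPRINT_DENSITY = 0.3
FINGERPRINT_BIT_NOISE = 0.15  # per-bit noise so same-prototype drugs differ

DEFAULT_COUPLING = {"ts_strength": 0.75, "cs_strength": 0.75}


@dataclass
class SyntheticWorld:
    """A generated corpus plus its ground truth."""

    drugs: list[DrugRecord]
    graph: nx.Graph
    interactions: InteractionTable
    truth: dict = field(default_factory=dict)
    seed: int = 0


def generate_world(
    n_drugs: int = 60,
    n_proteins: int = 300,
    n_modules: int = 6,
    coupling: Mapping[str, float] | None = None,
    seed: int = 0,
) -> SyntheticWorld:
    """Generate a seeded synthetic world. See module docstring for structure."""
    coupling = dict(DEFAULT_COUPLING if coupling is None else coupling)
    ts_strength = float(coupling["ts_strength"])
    cs_strength = float(coupling["cs_strength"])
    if not (0.0 <= ts_strength <= 1.0 and 0.0 <= cs_strength <= 1.0):
        raise ValueError("coupling strengths must lie in [0, 1]")
    if n_modules > len(_LEVEL1_LETTERS):
        raise ValueError(f"at most {len(_LEVEL1_LETTERS)} modules supported")
    n_isolated = max(1, int(round(ISOLATED_FRACTION * n_proteins)))
    if n_modules < 1 or n_modules > n_proteins - n_isolated:
        raise ValueError("n_modules must fit into the non-isolated proteins")
    if n_drugs < 1:
        raise ValueError("need at least one drug")

    rng = np.random.default_rng(seed)
    proteins = [f"P{i:04d}" for i in range(n_proteins)]
    member_count = n_proteins - n_isolated
    module_of = np.arange(member_count) % n_modules
    members = proteins[:member_count]
    isolated = proteins[member_count:]
    module_members: list[list[str]] = [
        [members[i] for i in np.flatnonzero(module_of == m)] for m in range(n_modules)
    ]

    graph = nx.Graph()
    graph.add_nodes_from(proteins)
    idx_pairs = np.triu_indices(member_count, k=1)
    same = module_of[idx_pairs[0]] == module_of[idx_pairs[1]]
    p_edge = np.where(same, P_WITHIN_MODULE, P_BETWEEN_MODULE)
    chosen = rng.random(p_edge.size) < p_edge
    for a, b in zip(idx_pairs[0][chosen], idx_pairs[1][chosen]):
        graph.add_edge(members[a], members[b])

    # one ATC letter and one fingerprint prototype per module
    prototypes = rng.random((n_modules, FINGERPRINT_BITS)) < FINGERPRINT_DENSITY

    def draw_code(module: int) -> str:
        # letter pins the module; middle levels vary so matched prefixes of
        # different depths (and information content) occur
        letter = _LEVEL1_LETTERS[module]
        lvl2 = int(rng.integers(1, 5))
        lvl3 = "AB"[int(rng.integers(2))]
        lvl4 = "AB"[int(rng.integers(2))]
        leaf = int(rng.integers(1, 11))
        return f"{letter}{lvl2:02d}{lvl3}{lvl4}{leaf:02d}"

    drugs: list[DrugRecord] = []
    truth: dict[str, dict] = {}
    pairs: set[tuple[str, str]] = set()
    for i in range(n_drugs):
        drug_id = f"D{i:03d}"
        home = i % n_modules

        n_targets = int(rng.choice(TARGET_SET_SIZES))
        targets: set[str] = set()
        while len(targets) < n_targets:
            m = home if rng.random() < HOME_TARGET_PROB else int(rng.integers(n_modules))
            targets.add(module_members[m][int(rng.integers(len(module_members[m])))])

        # per-drug channel failure: a miscoded drug points wholesale at a
        # random module in that channel
        ts_module = home if rng.random() < ts_strength else int(rng.integers(n_modules))
        cs_module = home if rng.random() < cs_strength else int(rng.integers(n_modules))

        n_codes = 2 if rng.random() < SECOND_CODE_PROB else 1
        codes = list(dict.fromkeys(draw_code(ts_module) for _ in range(n_codes)))

        keep = rng.random(FINGERPRINT_BITS) < 1.0 - FINGERPRINT_BIT_NOISE
        noise = rng.random(FINGERPRINT_BITS) < FINGERPRINT_DENSITY
        fingerprint = np.where(keep, prototypes[cs_module], noise).astype(np.uint8)

        drugs.append(
            DrugRecord(
                drug_id=drug_id,
                atc_codes=codes,
                fingerprint=fingerprint,
                target_ids=targets,
            )
        )
        truth[drug_id] = {
            "module": home,
            "targets": set(targets),
            "ts_module": ts_module,
            "cs_module": cs_module,
        }
        pairs.update((drug_id, t) for t in targets)

    truth["_params"] = {
        "n_modules": n_modules,
        "coupling": {"ts_strength": ts_strength, "cs_strength": cs_strength},
        "isolated": list(isolated),
        "module_members": [list(ms) for ms in module_members],
    }
    return SyntheticWorld(
        drugs=drugs,
        graph=graph,
        interactions=InteractionTable(pairs=pairs),
        truth=truth,
        seed=seed,
    )


def export_world(world: SyntheticWorld, directory: str | Path) -> list[Path]:
    """Write the four TSV tables (ATC, fingerprints, targets, PPI edges)."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    atc_path = directory / "atc.tsv"
    fp_path = directory / "fingerprints.tsv"
    target_path = directory / "targets.tsv"
    ppi_path = directory / "ppi.tsv"

    with open(atc_path, "w", encoding="utf-8") as fh:
        fh.write("drug_id\tatc_code\n")
        for d in world.drugs:
            for code in d.atc_codes:
                fh.write(f"{d.drug_id}\t{code}\n")
    with open(fp_path, "w", encoding="utf-8") as fh:
        fh.write("drug_id\tfingerprint\n")
        for d in world.drugs:
            bits = "".join(str(int(b)) for b in d.fingerprint)
            fh.write(f"{d.drug_id}\t{bits}\n")
    with open(target_path, "w", encoding="utf-8") as fh:
        fh.write("drug_id\tprotein_id\n")
        for d in world.drugs:
            for t in sorted(d.target_ids):
                fh.write(f"{d.drug_id}\t{t}\n")
    from .io import write_ppi_edgelist

    write_ppi_edgelist(world.graph, ppi_path)
    return [atc_path, fp_path, target_path, ppi_path]
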