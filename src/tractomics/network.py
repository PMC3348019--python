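"""Protein-protein interaction graph: degree filtering and seed-anchored
neighborhood tiers.

The graph is undirected and simple (duplicate and reversed-duplicate
edges collapsed, self-loops dropped with a counted warning).  Disease
genes are mapped to proteins, their unique-partner counts tabulated, and
genes with more than ``min_count`` interactions retained (strict
inequality).  Around a designated seed protein with a curated related
set, every other node adjacent to C = {seed} U related is tiered by its
number of unique neighbors inside C: >= 3, exactly 2, or exactly 1
("at-least-3" is the default reading of the three-partner tier; an
exact-3 rule is available via ``tier3_rule="exactly"``).
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

import networkx as nx
import pandas as pd


@dataclass
class BuildReport:
    n_self_loops: int = 0
    n_duplicates: int = 0


def build_graph(
    edges: Iterable[tuple[str, str]] | pd.DataFrame,
) -> tuple[nx.Graph, BuildReport]:
    """Undirected simple graph from protein-id pairs.

    Duplicates (including reversed pairs) are collapsed and counted;
    self-loops are dropped and counted.  A malformed pair is a hard
    error carrying its row number.
    """
    if isinstance(edges, pd.DataFrame):
        rows = list(edges.itertuples(index=False, name=None))
    else:
        rows = list(edges)
    g = nx.Graph()
    report = BuildReport()
    for lineno, row in enumerate(rows, start=1):
        if len(row) < 2 or any(
            not isinstance(x, str) or not x or x != x for x in row[:2]
        ):
            raise ValueError(f"malformed PPI edge at row {lineno}: {row!r}")
        a, b = row[0], row[1]
        if a == b:
            report.n_self_loops += 1
            continue
        if g.has_edge(a, b):
            report.n_duplicates += 1
            continue
        g.add_edge(a, b)
    return g, report


def read_edges_tsv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype=str)
    if df.shape[1] < 2:
        raise ValueError("PPI edge table needs two protein-id columns")
    return df.iloc[:, :2].set_axis(["protein_a", "protein_b"], axis=1)


def interaction_counts(
    graph: nx.Graph,
    disease_genes: Sequence[str],
    gene_protein: pd.DataFrame,
) -> tuple[pd.DataFrame, list[str]]:
    """Unique-partner counts of each mapped disease gene's protein.

    Returns ``(table, unmapped)``: one row (gene, protein, n_ppi) per
    gene with a protein mapping, and the list of genes with none.  A
    mapped protein absent from the graph counts 0.  Self-interactions
    never contribute (the graph is simple).
    """
    mapping = dict(zip(gene_protein["gene"], gene_protein["protein"]))
    rows = []
    unmapped = []
    for g in disease_genes:
        prot = mapping.get(g)
        if prot is None:
            unmapped.append(g)
            continue
        count = graph.degree(prot) if prot in graph else 0
        rows.append((g, prot, int(count)))
    return (
        pd.DataFrame(rows, columns=["gene", "protein", "n_ppi"]),
        unmapped,
    )


def filter_by_degree(table: pd.DataFrame, min_count: int = 10) -> list[str]:
    """Genes with STRICTLY more than ``min_count`` unique partners."""
    if min_count < 0:
        raise ValueError("min_count must be >= 0")
    return table.loc[table["n_ppi"] > min_count, "gene"].tolist()


def seed_related_set(
    graph: nx.Graph,
    seed_protein: str,
    restriction: set[str] | None = None,
) -> set[str]:
    """The seed's direct neighbors, optionally intersected with a
    curated roster (the related set is curated in practice, not purely
    topological)."""
    if seed_protein not in graph:
        raise KeyError(f"seed protein {seed_protein!r} absent from graph")
    neighbors = set(graph.neighbors(seed_protein))
    if restriction is not None:
        neighbors &= restriction
    return neighbors


@dataclass
class TierAssignment:
    """Partition of the seed-anchored subnetwork."""

    seed: str
    related: set[str]
    tier3plus: set[str]
    tier2: set[str]
    peripheral: set[str]

    @property
    def nodes(self) -> set[str]:
        return (
            {self.seed}
            | self.related
            | self.tier3plus
            | self.tier2
            | self.peripheral
        )

    def tier_of(self, node: str) -> str:
        if node == self.seed:
            return "seed"
        for name in ("related", "tier3plus", "tier2", "peripheral"):
            if node in getattr(self, name):
                return name
        raise KeyError(f"{node!r} not in subnetwork")

    def to_frame(self) -> pd.DataFrame:
        rows = [(n, self.tier_of(n)) for n in sorted(self.nodes)]
        return pd.DataFrame(rows, columns=["protein", "tier"])


def classify_nodes(
    graph: nx.Graph,
    seed_protein: str,
    related: set[str],
    tier3_rule: str = "at_least",
) -> TierAssignment:
    """Tier every node adjacent to C = {seed} U related by k(v), its
    number of unique neighbors inside C.

    Default rule: k >= 3 -> tier3plus, k == 2 -> tier2, k == 1 ->
    peripheral.  ``tier3_rule="exactly"`` demands k == 3 for the top
    tier, leaving k > 3 nodes out of the subnetwork entirely — the
    reason "at least 3" is the default reading.  Related members keep
    tier "related" regardless of their own k; nodes not adjacent to C
    are outside the subnetwork.
    """
    if not related <= set(graph.nodes):
        raise ValueError("related set must be a subset of graph nodes")
    if tier3_rule not in ("at_least", "exactly"):
        raise ValueError("tier3_rule must be 'at_least' or 'exactly'")
    core = {seed_protein} | related
    tier3: set[str] = set()
    tier2: set[str] = set()
    peripheral: set[str] = set()
    for v in graph.nodes:
        if v in core:
            continue
        k = sum(1 for u in graph.neighbors(v) if u in core)
        if k == 0:
            continue
        if k >= 3:
            if tier3_rule == "at_least" or k == 3:
                tier3.add(v)
        elif k == 2:
            tier2.add(v)
        else:
            peripheral.add(v)
    return TierAssignment(
        seed=seed_protein,
        related=set(related),
        tier3plus=tier3,
        tier2=tier2,
        peripheral=peripheral,
    )


def extract_subnetwork(
    graph: nx.Graph, tiers: TierAssignment
) -> tuple[nx.Graph, pd.DataFrame]:
    """Induced subgraph on tiered nodes plus a tier-annotated edge table."""
    sub = graph.subgraph(tiers.nodes & set(graph.nodes)).copy()
    for n in tiers.nodes - set(sub.nodes):
        sub.add_node(n)
    rows = [
        (a, tiers.tier_of(a), b, tiers.tier_of(b)) for a, b in sorted(sub.edges)
    ]
    table = pd.DataFrame(
        rows, columns=["protein_a", "tier_a", "protein_b", "tier_b"]
    )
    return sub, table


def load_reference_gene_table() -> pd.DataFrame:
    """Packaged worked-example table: 33 Alzheimer-related genes with
    their HPRD protein ids and unique-partner counts (index, gene,
    protein id, n_ppi)."""
    with resources.files("tractomics.data").joinpath(
        "alzheimer_gene_ppi_counts.tsv"
    ).open() as fh:
        return pd.read_csv(fh, sep="\t")
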