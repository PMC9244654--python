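"""Same-day co-prescription mining and graph analysis.

Transactions are baskets of distinct drugs prescribed to one patient on one
day.  Frequent itemsets are mined with FP-growth (a compressed prefix tree
over support-ordered transactions, mined recursively through conditional
pattern bases — no candidate generation).  The support of a drug pair is

    S(Di -> Dj) = N(Di, Dj) / N(s)

with N(Di, Dj) the number of baskets containing both drugs and N(s) the total
number of baskets.  Pairs at support >= 0.05 become edges of an undirected
co-prescription graph whose topology (degree, average shortest path) ranks
drugs by how centrally they are co-prescribed.  Mining is run separately per
patient group; the sepsis and control networks are compared downstream.
"""

from __future__ import annotations

import math
from collections import defaultdict
from dataclasses import dataclass, field

import networkx as nx
import pandas as pd

MIN_SUPPORT = 0.05


class MiningError(ValueError):
    pass


@dataclass(frozen=True)
class TransactionSet:
    """Same-day prescription baskets; ``n_transactions`` is the miner's N(s)."""

    transactions: tuple[tuple[str, str, frozenset[str]], ...]  # (patient, date, drugs)

    @property
    def n_transactions(self) -> int:
        return len(self.transactions)

    def baskets(self) -> list[frozenset[str]]:
        return [t[2] for t in self.transactions]


@dataclass(frozen=True)
class PairSupport:
    """Co-occurrence statistics of one unordered drug pair."""

    drug_i: str
    drug_j: str
    n_cooccur: int
    support: float

    def __post_init__(self):
        assert self.drug_i < self.drug_j, "pair must be stored lexicographically"
        assert 0.0 <= self.support <= 1.0


def build_transactions(prescriptions: pd.DataFrame) -> TransactionSet:
    """One transaction per (patient, date) with a deduplicated drug set."""
    if prescriptions.empty:
        return TransactionSet(transactions=())
    grouped = prescriptions.groupby(["patient_id", "date"], sort=True)["drug_id"]
    tx = tuple(
        (pid, str(date), frozenset(drugs))
        for (pid, date), drugs in grouped
    )
    return TransactionSet(transactions=tx)


# ---------------------------------------------------------------------------
# FP-growth
# ---------------------------------------------------------------------------

class _Node:
    __slots__ = ("item", "count", "parent", "children")

    def __init__(self, item, parent):
        self.item = item
        self.count = 0
        self.parent = parent
        self.children: dict = {}


def _build_tree(baskets_with_counts, min_count):
    """Build an FP-tree; returns (root, header) with header item -> [nodes]."""
    freq: dict[str, int] = defaultdict(int)
    for basket, cnt in baskets_with_counts:
        for item in basket:
            freq[item] += cnt
    freq = {i: c for i, c in freq.items() if c >= min_count}
    # support-descending, lexicographic tie-break: a canonical insertion order
    order = {i: k for k, i in enumerate(sorted(freq, key=lambda i: (-freq[i], i)))}
    root = _Node(None, None)
    header: dict[str, list[_Node]] = defaultdict(list)
    for basket, cnt in baskets_with_counts:
        items = sorted((i for i in basket if i in freq), key=order.__getitem__)
        node = root
        for item in items:
            child = node.children.get(item)
            if child is None:
                child = _Node(item, node)
                node.children[item] = child
                header[item].append(child)
            child.count += cnt
            node = child
    return root, header, freq, order


def fpgrowth(baskets, min_count: int) -> dict[frozenset, int]:
    """All itemsets (size >= 1) with absolute support >= ``min_count``."""
    result: dict[frozenset, int] = {}

    def mine(baskets_with_counts, suffix):
        _, header, freq, order = _build_tree(baskets_with_counts, min_count)
        # least-frequent first: standard bottom-up header traversal
        for item in sorted(freq, key=lambda i: (-order[i])):
            newset = suffix | {item}
            result[frozenset(newset)] = freq[item]
            # conditional pattern base: prefix paths of every node of `item`
            cond = []
            for node in header[item]:
                path = []
                p = node.parent
                while p is not None and p.item is not None:
                    path.append(p.item)
                    p = p.parent
                if path:
                    cond.append((frozenset(path), node.count))
            if cond:
                mine(cond, newset)

    mine([(b, 1) for b in baskets], set())
    return result


def mine_frequent_pairs(
    transactions: TransactionSet, min_support: float = MIN_SUPPORT
) -> list[PairSupport]:
    """Exactly the unordered drug pairs with support >= ``min_support``.

    Deterministic order: support descending, then lexicographic pair.
    """
    if not 0.0 < min_support <= 1.0:
        raise MiningError("min_support must be in (0, 1]")
    n = transactions.n_transactions
    if n == 0:
        raise MiningError("empty transaction set")
    min_count = math.ceil(min_support * n - 1e-9)
    itemsets = fpgrowth(transactions.baskets(), max(min_count, 1))
    pairs = []
    for items, count in itemsets.items():
        if len(items) == 2:
            i, j = sorted(items)
            pairs.append(PairSupport(i, j, count, count / n))
    pairs.sort(key=lambda p: (-p.support, p.drug_i, p.drug_j))
    return pairs


# ---------------------------------------------------------------------------
# graph topology
# ---------------------------------------------------------------------------

@dataclass
class DrugGraph:
    graph: nx.Graph
    node_stats: pd.DataFrame = field(default=None)  # drug, degree, avg_shortest_path

    @property
    def nodes(self):
        return list(self.graph.nodes)

    @property
    def edges(self):
        return list(self.graph.edges)


def build_coprescription_graph(pairs: list[PairSupport]) -> DrugGraph:
    """Undirected simple graph over selected pairs with topology attributes.

    Per node: degree (incident edges) and the average unweighted shortest-path
    distance to the other nodes of its connected component (∞ for an isolated
    node).
    """
    if not pairs:
        raise MiningError("no pairs to graph")
    g = nx.Graph()
    for p in pairs:
        g.add_edge(p.drug_i, p.drug_j, support=p.support, n_cooccur=p.n_cooccur)
    rows = []
    for node in g.nodes:
        dists = nx.single_source_shortest_path_length(g, node)
        others = [d for n2, d in dists.items() if n2 != node]
        asp = sum(others) / len(others) if others else math.inf
        g.nodes[node]["degree"] = g.degree[node]
        g.nodes[node]["avg_shortest_path"] = asp
        rows.append({"drug": node, "degree": g.degree[node], "avg_shortest_path": asp})
    stats = pd.DataFrame(rows).sort_values("drug").reset_index(drop=True)
    return DrugGraph(graph=g, node_stats=stats)


def rank_nodes(graph: DrugGraph, by: str = "degree") -> list[str]:
    """Drugs ordered by topological centrality.

    ``degree``: descending (more co-prescription partners first);
    ``avg_shortest_path``: ascending (closer to everything first).
    Ties break lexicographically.
    """
    stats = graph.node_stats
    if by == "degree":
        key = stats.sort_values(["degree", "drug"], ascending=[False, True])
    elif by == "avg_shortest_path":
        key = stats.sort_values(["avg_shortest_path", "drug"], ascending=[True, True])
    else:
        raise MiningError(f"unknown ranking key {by!r}")
    return key["drug"].tolist()


def selected_drugs(pairs: list[PairSupport]) -> list[str]:
    """Sorted set of drugs appearing in any selected pair."""
    out = set()
    for p in pairs:
        out.update((p.drug_i, p.drug_j))
    return sorted(out)


def pairs_to_frame(pairs: list[PairSupport], group: str | None = None) -> pd.DataFrame:
    df = pd.DataFrame(
        [
            {
                "drug_i": p.drug_i,
                "drug_j": p.drug_j,
                "n_cooccur": p.n_cooccur,
                "support": p.support,
            }
            for p in pairs
        ]
    )
    if group is not None:
        df["group"] = group
    return df
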