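"""Evidence-typed gene-gene networks: loading, merging, neighbour ranking,
two-hop subnetwork selection and guilt-by-association gene classification.

Each network carries edges of one or more evidence types (physical
interaction, genetic interaction, shared pathway, co-expression,
co-localization).  Within a single evidence type an unordered gene pair has
at most one edge; a merged network keeps parallel edges of distinct origin
so that evidence multiplicity drives neighbour ranking: neighbours are
ordered by number of supporting edges, then total edge weight, then symbol.
"""

from __future__ import annotations

import csv
from enum import Enum
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np

__all__ = [
    "EvidenceType",
    "GeneNetwork",
    "load_network",
    "write_network",
    "merge_networks",
    "rank_neighbors",
    "select_subnetwork",
    "classify_vus_gene",
    "cross_validate_classification",
]


class EvidenceType(str, Enum):
    PHYSICAL = "physical"
    GENETIC = "genetic"
    PATHWAY = "pathway"
    COEXPRESSION = "coexpression"
    COLOCALIZATION = "colocalization"


class GeneNetwork:
    """Undirected weighted multigraph over gene symbols.

    Backed by a :class:`networkx.MultiGraph`; every edge has ``weight`` > 0
    and ``evidence`` (an :class:`EvidenceType`) attributes.  No self-loops.
    """

    def __init__(self, graph: nx.MultiGraph | None = None):
        self.graph = graph if graph is not None else nx.MultiGraph()

    @classmethod
    def from_edges(
        cls, edges: Iterable[tuple[str, str, float, EvidenceType]]
    ) -> "GeneNetwork":
        """Build from (gene_a, gene_b, weight, evidence) tuples.

        Duplicate pairs within one evidence type are weight-summed;
        self-loops are rejected.
        """
        agg: dict[tuple[str, str, EvidenceType], float] = {}
        for a, b, w, ev in edges:
            a, b = a.upper(), b.upper()
            if a == b:
                raise ValueError(f"self-loop on {a}")
            if w <= 0:
                raise ValueError(f"edge {a}-{b} has non-positive weight {w}")
            key = (min(a, b), max(a, b), EvidenceType(ev))
            agg[key] = agg.get(key, 0.0) + float(w)
        g = nx.MultiGraph()
        for (a, b, ev), w in agg.items():
            g.add_edge(a, b, weight=w, evidence=ev)
        return cls(g)

    @property
    def nodes(self) -> set[str]:
        return set(self.graph.nodes)

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    @property
    def evidence_types(self) -> set[EvidenceType]:
        return {d["evidence"] for _, _, d in self.graph.edges(data=True)}

    def __contains__(self, gene: str) -> bool:
        return gene.upper() in self.graph

    def edge_multiset(self) -> dict[tuple[str, str, EvidenceType], list[float]]:
        out: dict[tuple[str, str, EvidenceType], list[float]] = {}
        for a, b, d in self.graph.edges(data=True):
            key = (min(a, b), max(a, b), d["evidence"])
            out.setdefault(key, []).append(d["weight"])
        return {k: sorted(v) for k, v in out.items()}


def load_network(path, evidence: EvidenceType) -> GeneNetwork:
    """Load an edge-list TSV (gene_a, gene_b[, weight]) as one evidence type.

    Symbols are uppercased; self-loop rows are dropped (counted on the
    returned network as ``n_self_loops``); duplicate pairs are weight-summed.
    """
    evidence = EvidenceType(evidence)
    edges: list[tuple[str, str, float, EvidenceType]] = []
    n_self = 0
    with open(path, newline="") as fh:
        for lineno, row in enumerate(csv.reader(fh, delimiter="\t"), start=1):
            if not row or row[0].startswith("#"):
                continue
            if lineno == 1 and row[0].lower() in ("gene_a", "gene1", "source"):
                continue
            if len(row) < 2:
                raise ValueError(f"{path}:{lineno}: expected >=2 columns")
            a, b = row[0].upper(), row[1].upper()
            w = float(row[2]) if len(row) > 2 and row[2] != "" else 1.0
            if w <= 0:
                raise ValueError(f"{path}:{lineno}: non-positive weight {w}")
            if a == b:
                n_self += 1
                continue
            edges.append((a, b, w, evidence))
    if not edges:
        raise ValueError(f"{path}: no usable edges")
    net = GeneNetwork.from_edges(edges)
    net.n_self_loops = n_self  # type: ignore[attr-defined]
    return net


def write_network(net: GeneNetwork, path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(["gene_a", "gene_b", "weight", "evidence"])
        for a, b, d in sorted(
            net.graph.edges(data=True),
            key=lambda e: (min(e[0], e[1]), max(e[0], e[1]), e[2]["evidence"].value),
        ):
            writer.writerow([min(a, b), max(a, b), repr(d["weight"]), d["evidence"].value])


def merge_networks(nets: Sequence[GeneNetwork]) -> GeneNetwork:
    """Union of networks by common genes, keeping evidence multiplicity.

    A pair supported by two evidence sources contributes two parallel edges
    in the merged network.  Inputs must overlap: each network after the
    first must share at least one gene with the running union.
    """
    if len(nets) < 2:
        raise ValueError("need at least two networks to merge")
    merged = nx.MultiGraph()
    merged.add_nodes_from(nets[0].graph.nodes)
    merged.add_edges_from(nets[0].graph.edges(data=True))
    for net in nets[1:]:
        if not (set(merged.nodes) & set(net.graph.nodes)):
            raise ValueError("networks share no genes; cannot merge")
        merged.add_edges_from(net.graph.edges(data=True))
        merged.add_nodes_from(net.graph.nodes)
    return GeneNetwork(merged)


def rank_neighbors(net: GeneNetwork, gene: str) -> list[tuple[str, int, float]]:
    """Neighbours of ``gene`` ordered by edge multiplicity (desc), then total
    weight (desc), then symbol (asc).  Deterministic total order."""
    gene = gene.upper()
    if gene not in net.graph:
        raise KeyError(f"gene {gene!r} not in network")
    stats: dict[str, tuple[int, float]] = {}
    for _, nbr, d in net.graph.edges(gene, data=True):
        count, weight = stats.get(nbr, (0, 0.0))
        stats[nbr] = (count + 1, weight + d["weight"])
    ranked = sorted(stats.items(), key=lambda kv: (-kv[1][0], -kv[1][1], kv[0]))
    return [(g, c, w) for g, (c, w) in ranked]


def select_subnetwork(net: GeneNetwork, seed: str, k: int = 2) -> set[str]:
    """Two-hop subnetwork around ``seed``: the top-k neighbours, then each of
    their top-k neighbours excluding genes already selected (processed in
    rank order).  Size is bounded by 1 + k + k^2."""
    if k < 1:
        raise ValueError("k must be >= 1")
    seed = seed.upper()
    first = [g for g, _, _ in rank_neighbors(net, seed)[:k]]
    selected = {seed, *first}
    for nbr in first:
        picks = 0
        for g, _, _ in rank_neighbors(net, nbr):
            if g in selected:
                continue
            selected.add(g)
            picks += 1
            if picks == k:
                break
    return selected


UNCLASSIFIED = "unclassified"


def classify_vus_gene(
    net: GeneNetwork, gene: str, labels: Mapping[str, str], k: int = 2
) -> str:
    """Guilt-by-association label for ``gene`` from its top-k labelled
    neighbours: majority vote, ties resolved toward the highest-ranked
    neighbour; ``unclassified`` if no neighbour is labelled."""
    labels = {g.upper(): c for g, c in labels.items()}
    voters = [(g, labels[g]) for g, _, _ in rank_neighbors(net, gene) if g in labels][:k]
    if not voters:
        return UNCLASSIFIED
    counts: dict[str, int] = {}
    for _, lab in voters:
        counts[lab] = counts.get(lab, 0) + 1
    best = max(counts.values())
    winners = {lab for lab, c in counts.items() if c == best}
    if len(winners) == 1:
        return winners.pop()
    for _, lab in voters:  # tie -> highest-ranked voter's label
        if lab in winners:
            return lab
    raise AssertionError("unreachable")


def cross_validate_classification(
    labeled: Mapping[str, str],
    net: GeneNetwork,
    n_runs: int = 100,
    split_frac: float = 0.5,
    k: int = 2,
    seed: int = 0,
) -> float:
    """Mean split-half accuracy of neighbour-vote classification.

    Per run the labelled genes are stratified-split into training and test;
    test genes are classified from training labels only and unclassified
    genes count as errors.  Reproducible given ``seed``.
    """
    labeled = {g.upper(): c for g, c in labeled.items()}
    by_condition: dict[str, list[str]] = {}
    for g, c in labeled.items():
        by_condition.setdefault(c, []).append(g)
    if len(by_condition) < 2:
        raise ValueError("need at least two distinct conditions")
    for cond, genes in by_condition.items():
        if len(genes) < 2:
            raise ValueError(f"condition {cond!r} has fewer than 2 genes; cannot stratify")
    rng = np.random.default_rng(seed)
    accuracies = []
    for _ in range(n_runs):
        train: set[str] = set()
        for genes in by_condition.values():
            genes = sorted(genes)
            n_train = max(1, int(round(len(genes) * split_frac)))
            n_train = min(n_train, len(genes) - 1)
            picks = rng.choice(len(genes), size=n_train, replace=False)
            train.update(genes[i] for i in picks)
        test = [g for g in sorted(labeled) if g not in train]
        train_labels = {g: labeled[g] for g in train}
        correct = 0
        for g in test:
            if g in net:
                pred = classify_vus_gene(net, g, train_labels, k=k)
            else:
                pred = UNCLASSIFIED
            correct += pred == labeled[g]
        accuracies.append(correct / len(test))
    return float(np.mean(accuracies))
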