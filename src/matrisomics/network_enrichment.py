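"""High-confidence PPI networks, disease-gene overlay and set enrichment.

Networks are undirected networkx graphs with a confidence score in [0, 1] on
every edge; "high confidence" defaults to score >= 0.7 (the conventional
STRING tier).  Over-representation p-values are hypergeometric upper tails
(sampling without replacement from a background of annotated and
non-annotated genes, observed count included); Fisher's exact test is
available for 2x2 pathway contrasts.  Backgrounds are always explicit — for
pathway tests over matrisome gene sets, the matrisome itself is the
background.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import networkx as nx
from scipy import stats

from .formats_io import EdgeList, GeneSetCollection

logger = logging.getLogger("matrisomics")


@dataclass
class InteractionNetwork:
    """Weighted undirected gene network with node attribute flags."""

    graph: nx.Graph

    @property
    def nodes(self) -> set[str]:
        return set(self.graph.nodes)

    def __len__(self) -> int:
        return self.graph.number_of_nodes()


@dataclass(frozen=True)
class EnrichmentResult:
    """(k, n, K, N) over-representation summary for one gene set."""

    set_id: str
    k: int  # overlap
    n: int  # query size
    K: int  # annotated in background
    N: int  # background size
    p_value: float
    fold_enrichment: float
    fdr: float | None = None


def _check_table(k: int, n: int, K: int, N: int) -> None:
    if min(k, n, K, N) < 0 or k > min(n, K) or n > N or K > N:
        raise ValueError(f"impossible contingency (k={k}, n={n}, K={K}, N={N})")


def hypergeometric_test(k: int, n: int, K: int, N: int) -> float:
    """Upper-tail P(X >= k) for X ~ Hypergeom(N, K, n), observed included."""
    _check_table(k, n, K, N)
    return float(stats.hypergeom.sf(k - 1, N, K, n))


def fisher_exact(k: int, n: int, K: int, N: int, sided: str = "greater") -> float:
    """Fisher's exact test on the 2x2 table [[k, n-k], [K-k, N-n-K+k]]."""
    _check_table(k, n, K, N)
    if N - n - K + k < 0:
        raise ValueError("negative cell in 2x2 table")
    if sided not in {"greater", "two_sided"}:
        raise ValueError(f"unknown sidedness {sided!r}")
    table = [[k, n - k], [K - k, N - n - K + k]]
    alternative = "greater" if sided == "greater" else "two-sided"
    return float(stats.fisher_exact(table, alternative=alternative)[1])


def fold_enrichment(k: int, n: int, K: int, N: int) -> float:
    """Observed over expected overlap proportion: (k/n) / (K/N)."""
    _check_table(k, n, K, N)
    if n == 0 or K == 0:
        raise ValueError("fold enrichment undefined for n == 0 or K == 0")
    return (k / n) / (K / N)


def build_network(
    edges: EdgeList,
    nodes: set[str],
    min_score: float = 0.7,
    reduce: str = "main_component",
) -> InteractionNetwork:
    """Restrict edges to ``nodes``, keep scores >= min_score, reduce.

    ``main_component`` keeps the largest connected component (ties broken by
    the smallest lexicographic node label); ``drop_isolated`` keeps every
    component of size >= 2.  An empty result is returned with a warning, not
    an error.
    """
    if not nodes:
        raise ValueError("node set must be non-empty")
    if reduce not in {"main_component", "drop_isolated"}:
        raise ValueError(f"unknown reduction {reduce!r}")
    g = nx.Graph()
    for a, b, score in edges.edges:
        if a in nodes and b in nodes and score >= min_score:
            g.add_edge(a, b, score=score)
    if g.number_of_edges() == 0:
        logger.warning("no edges survive the score/node filter; empty network")
        return InteractionNetwork(graph=nx.Graph())
    components = list(nx.connected_components(g))
    if reduce == "main_component":
        biggest = max(len(c) for c in components)
        chosen = min((c for c in components if len(c) == biggest), key=min)
        g = g.subgraph(chosen).copy()
    else:
        keep = set().union(*(c for c in components if len(c) >= 2))
        g = g.subgraph(keep).copy()
    return InteractionNetwork(graph=g)


def gene_set_enrichment(
    query: set[str],
    collection: GeneSetCollection,
    background: set[str],
    min_overlap: int = 3,
    test: str = "hypergeometric",
) -> list[EnrichmentResult]:
    """Over-representation of ``query`` in each gene set, FDR across tested sets.

    Query symbols outside the background are dropped with a warning; each set
    is intersected with the background before testing; sets overlapping the
    query by fewer than ``min_overlap`` genes are not tested (and do not count
    toward the FDR correction).
    """
    from .differential_abundance import bh_adjust

    if not background:
        raise ValueError("empty background")
    if test not in {"hypergeometric", "fisher"}:
        raise ValueError(f"unknown test {test!r}")
    stray = query - background
    if stray:
        logger.warning("%d query symbols outside background dropped", len(stray))
    query = query & background
    N, n = len(background), len(query)
    results = []
    for set_id in sorted(collection.sets):
        _, members = collection.sets[set_id]
        annotated = members & background
        k = len(query & annotated)
        if k < min_overlap:
            continue
        K = len(annotated)
        p = (
            hypergeometric_test(k, n, K, N)
            if test == "hypergeometric"
            else fisher_exact(k, n, K, N, sided="greater")
        )
        results.append(
            EnrichmentResult(
                set_id=set_id, k=k, n=n, K=K, N=N,
                p_value=p, fold_enrichment=fold_enrichment(k, n, K, N),
            )
        )
    if results:
        fdrs = bh_adjust([r.p_value for r in results])
        results = [
            EnrichmentResult(
                set_id=r.set_id, k=r.k, n=r.n, K=r.K, N=r.N,
                p_value=r.p_value, fold_enrichment=r.fold_enrichment, fdr=float(f),
            )
            for r, f in zip(results, fdrs)
        ]
    return results


def overlay_disease_genes(
    network: InteractionNetwork,
    disease_genes: set[str],
) -> tuple[InteractionNetwork, set[str]]:
    """Flag disease genes on the network; return those present in it."""
    connected = network.nodes & disease_genes
    for node in network.graph.nodes:
        network.graph.nodes[node]["disease"] = node in disease_genes
    return network, connected


def network_enrichment_test(
    network_nodes: set[str],
    disease_genes: set[str],
    background_size: int,
) -> EnrichmentResult:
    """Hypergeometric enrichment of disease genes among network nodes.

    The background size must be supplied explicitly (e.g. the number of
    genome-wide symbols the disease lists were drawn from).
    """
    if background_size < len(network_nodes | disease_genes):
        raise ValueError("background smaller than the union of nodes and disease genes")
    k = len(network_nodes & disease_genes)
    n, K, N = len(network_nodes), len(disease_genes), background_size
    p = hypergeometric_test(k, n, K, N)
    fold = fold_enrichment(k, n, K, N) if n and K else 0.0
    return EnrichmentResult(
        set_id="disease_genes", k=k, n=n, K=K, N=N, p_value=p, fold_enrichment=fold
    )


def degree_hubs(network: InteractionNetwork, top_k: int) -> list[tuple[str, int]]:
    """Nodes ranked by degree (descending), ties by symbol; first ``top_k``."""
    if top_k <= 0:
        raise ValueError("top_k must be positive")
    ranked = sorted(network.graph.degree, key=lambda t: (-t[1], t[0]))
    return [(s, int(d)) for s, d in ranked[:top_k]]
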