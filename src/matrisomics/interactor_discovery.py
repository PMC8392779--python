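"""Three-step nomination of putative ECM-interacting proteins.

Starting from proteins at least 2-fold higher on average in the ECM-enriched
fraction (or exclusive to it) and not already matrisome-annotated, the
cascade keeps those with (1) extracellular location/function annotation,
(2) membership in a computationally predicted secretome, and (3) a predicted
signal peptide or transmembrane domain; finally only candidates with a
high-confidence interaction to a matrisome protein survive.  Every list the
cascade consumes is data (a configured file), not logic, so the steps are
reproducible offline.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

from .differential_abundance import DifferentialRecord, ECM_EXCLUSIVE_STATUS
from .formats_io import GeneSetCollection
from .matrisome_annotate import AnnotatedProtein
from .network_enrichment import InteractionNetwork

logger = logging.getLogger("matrisomics")


@dataclass
class InteractorCandidate:
    symbol: str
    passed_location: bool = False
    passed_secreted: bool = False
    has_signal_or_tm: bool = False
    connected_to_matrisome: bool = False


def select_enriched_nonmatrisome(
    differential: list[DifferentialRecord],
    annotations: list[AnnotatedProtein],
    fold_min: float = 2.0,
) -> set[str]:
    """Proteins >= fold_min-fold higher in the ECM fraction or ECM-exclusive,
    minus matrisome-annotated symbols."""
    matrisome = {a.symbol for a in annotations if a.division != "non-matrisome"}
    lfc_min = math.log2(fold_min)
    out = set()
    for r in differential:
        if r.status == ECM_EXCLUSIVE_STATUS or r.log2fc >= lfc_min:
            out.add(r.symbol)
    return out - matrisome


def filter_by_location(
    candidates: set[str],
    location_sets: GeneSetCollection | None,
    passthrough: bool = False,
) -> set[str]:
    """Keep candidates annotated to extracellular/ECM location or function sets."""
    if passthrough:
        return set(candidates)
    if location_sets is None or len(location_sets) == 0:
        raise ValueError("location step needs annotation sets (or explicit passthrough)")
    return candidates & location_sets.union()


def filter_by_secreted_list(candidates: set[str], secreted: set[str]) -> set[str]:
    """Keep candidates in the predicted-secretome list."""
    return candidates & secreted


def filter_by_signal_tm(
    candidates: set[str],
    signal_tm_table: dict[str, tuple[bool, bool]],
) -> set[str]:
    """Keep candidates with a predicted signal peptide OR transmembrane domain.

    Symbols absent from the prediction table count as (False, False).
    """
    missing = candidates - set(signal_tm_table)
    if missing:
        logger.warning("%d candidates missing from signal/TM table; treated as negative",
                       len(missing))
    out = set()
    for sym in candidates:
        has_signal, has_tm = signal_tm_table.get(sym, (False, False))
        if has_signal or has_tm:
            out.add(sym)
    return out


def connect_to_matrisome(
    candidates: set[str],
    network: InteractionNetwork,
    matrisome_nodes: set[str],
    mode: str = "direct_edge",
) -> set[str]:
    """Candidates linked to the matrisome in the filtered network.

    ``direct_edge``: at least one retained edge to a matrisome-annotated node.
    ``component``: shares a connected component with a matrisome node.
    """
    if mode not in {"direct_edge", "component"}:
        raise ValueError(f"unknown connection mode {mode!r}")
    g = network.graph
    out = set()
    for sym in candidates & set(g.nodes):
        if mode == "direct_edge":
            if any(nb in matrisome_nodes for nb in g.neighbors(sym)):
                out.add(sym)
        else:
            import networkx as nx

            component = nx.node_connected_component(g, sym)
            if component & matrisome_nodes:
                out.add(sym)
    return out


def run_cascade(
    differential: list[DifferentialRecord],
    annotations: list[AnnotatedProtein],
    location_sets: GeneSetCollection | None,
    secreted: set[str],
    signal_tm_table: dict[str, tuple[bool, bool]],
    network: InteractionNetwork,
    matrisome_nodes: set[str],
    fold_min: float = 2.0,
    location_passthrough: bool = False,
    connection_mode: str = "direct_edge",
) -> tuple[list[InteractorCandidate], set[str]]:
    """Run all cascade steps; returns per-candidate flags and the survivors."""
    start = select_enriched_nonmatrisome(differential, annotations, fold_min=fold_min)
    located = filter_by_location(start, location_sets, passthrough=location_passthrough)
    secreted_hits = filter_by_secreted_list(located, secreted)
    signal_hits = filter_by_signal_tm(secreted_hits, signal_tm_table)
    connected = connect_to_matrisome(signal_hits, network, matrisome_nodes, mode=connection_mode)
    records = [
        InteractorCandidate(
            symbol=s,
            passed_location=s in located,
            passed_secreted=s in secreted_hits,
            has_signal_or_tm=s in signal_hits,
            connected_to_matrisome=s in connected,
        )
        for s in sorted(start)
    ]
    return records, connected
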