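"""Matrisome classification, basement-membrane flags, orthology and overlaps.

Classification is an exact-match lookup against a species-specific matrisome
reference (symbol -> division/category per matrisome.org's partition into the
core matrisome — collagens, ECM glycoproteins, proteoglycans — and
matrisome-associated proteins).  A bundled reference transcribes the mouse and
human brain-vascular ECM gene lists of the source study's printed table,
including its basement-membrane markings, and serves as the packaged worked
example.

Mouse-to-human orthology uses symbol case-normalization (the MGI/HGNC
convention where orthologous pairs differ only in case) with a small explicit
exception map for predicted genes and fusion symbols that have no such
counterpart.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import pandas as pd

from .formats_io import (
    CATEGORY_DIVISION,
    NON_MATRISOME,
    MatrisomeReference,
    normalize_symbol,
)

#: Mouse symbols whose human ortholog is not the uppercased symbol.
#: ``None`` marks symbols with no one-to-one human ortholog.
DEFAULT_ORTHOLOG_EXCEPTIONS: dict[str, str | None] = {
    "Gm5409": None,  # predicted gene, no curated human counterpart
}


@dataclass(frozen=True)
class AnnotatedProtein:
    symbol: str
    division: str  # "Core matrisome", "Matrisome-associated" or "non-matrisome"
    category: str | None
    is_basement_membrane: bool

    def __post_init__(self) -> None:
        if self.is_basement_membrane and self.division == NON_MATRISOME:
            raise ValueError(f"{self.symbol}: basement-membrane flag on non-matrisome protein")


@dataclass(frozen=True)
class OverlapSummary:
    only_a: int
    shared: int
    only_b: int
    shared_symbols: frozenset[str]


def load_brain_vascular_matrisome(species: str) -> pd.DataFrame:
    """The packaged brain-vascular matrisome table for one species.

    Columns: gene, division, category, basement_membrane (0/1), mean_intensity.
    """
    if species not in {"mouse", "human"}:
        raise ValueError(f"unknown species {species!r}")
    with resources.files("matrisomics.data").joinpath(f"brain_vascular_matrisome_{species}.tsv").open() as fh:
        return pd.read_csv(fh, sep="\t")


def brain_vascular_reference(species: str) -> MatrisomeReference:
    """Build a MatrisomeReference from the packaged table."""
    df = load_brain_vascular_matrisome(species)
    entries = {
        normalize_symbol(r.gene, species): (r.division, r.category)
        for r in df.itertuples()
    }
    bm = {normalize_symbol(r.gene, species) for r in df.itertuples() if r.basement_membrane}
    return MatrisomeReference(entries=entries, bm_genes=bm, species=species)


def classify_gene(symbol: str, reference: MatrisomeReference) -> AnnotatedProtein:
    """Exact-match matrisome lookup; unknown symbols come back non-matrisome."""
    hit = reference.entries.get(symbol)
    if hit is None:
        return AnnotatedProtein(symbol, NON_MATRISOME, None, False)
    division, category = hit
    return AnnotatedProtein(symbol, division, category, symbol in reference.bm_genes)


def annotate_table(
    symbols: list[str],
    reference: MatrisomeReference,
) -> tuple[list[AnnotatedProtein], dict[str, int]]:
    """Annotate a symbol list; returns (annotations, category counts).

    Duplicates are collapsed (each symbol counted once).  Category counts
    partition the matrisome-annotated subset; the non-matrisome count is
    reported under the key ``"non-matrisome"``.
    """
    seen: list[str] = []
    for s in symbols:
        if s not in seen:
            seen.append(s)
    annotations = [classify_gene(s, reference) for s in seen]
    counts = {c: 0 for c in CATEGORY_DIVISION}
    counts[NON_MATRISOME] = 0
    for a in annotations:
        counts[a.category if a.category is not None else NON_MATRISOME] += 1
    return annotations, counts


def count_basement_membrane(symbols: list[str], reference: MatrisomeReference) -> int:
    """Number of distinct basement-membrane genes in a symbol list."""
    return sum(
        1 for s in dict.fromkeys(symbols) if classify_gene(s, reference).is_basement_membrane
    )


def map_orthologs(
    mouse_symbols: set[str],
    exception_map: dict[str, str | None] | None = None,
) -> tuple[dict[str, str], set[str]]:
    """Map mouse symbols to human: uppercase rule with explicit exceptions.

    Returns (mouse -> human pairs, unmapped mouse symbols).
    """
    exceptions = DEFAULT_ORTHOLOG_EXCEPTIONS if exception_map is None else exception_map
    pairs: dict[str, str] = {}
    unmapped: set[str] = set()
    for m in mouse_symbols:
        if m in exceptions:
            target = exceptions[m]
            if target is None:
                unmapped.add(m)
            else:
                pairs[m] = target
        else:
            pairs[m] = m.upper()
    return pairs, unmapped


def overlap_summary(set_a: set[str], set_b: set[str]) -> OverlapSummary:
    """Two-set partition (Venn counts) of symbol sets in a common name space."""
    shared = frozenset(set_a & set_b)
    return OverlapSummary(
        only_a=len(set_a - set_b),
        shared=len(shared),
        only_b=len(set_b - set_a),
        shared_symbols=shared,
    )


def overlap_with_reference(
    query: set[str],
    reference_list: set[str],
    background_size: int,
) -> tuple[float, float]:
    """Percent of the query found in a reference proteome, with enrichment p.

    The p-value is the hypergeometric upper tail of drawing ``|query|`` genes
    from a background of ``background_size`` of which ``|reference_list|`` are
    in the reference.
    """
    from .network_enrichment import hypergeometric_test

    if background_size < len(query | reference_list):
        raise ValueError("background smaller than the union of query and reference")
    if not query:
        return 0.0, 1.0
    k = len(query & reference_list)
    percent = 100.0 * k / len(query)
    p = hypergeometric_test(k, len(query), len(reference_list), background_size)
    return percent, p
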