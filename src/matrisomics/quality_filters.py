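"""Detection, organelle-contaminant and exclusivity filters.

A protein is *identified* in a fraction when its raw intensity is nonzero in
at least ``min_replicates`` replicates and the group carries at least
``min_unique_peptides`` unique peptides.  *ECM-exclusive* proteins pass that
rule in the ECM-enriched fraction while their LFQ values are zero in every
cellular replicate.  Identification reads the intensity columns; quantitative
exclusivity reads the LFQ columns, mirroring the identification/quantification
column split of the MaxQuant output.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .formats_io import CELLULAR, ECM, DesignError, GeneSetCollection, ProteinGroupTable

import logging

logger = logging.getLogger("matrisomics")


@dataclass
class FilterReport:
    input_count: int
    retained_count: int
    dropped_by_rule: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        total = self.retained_count + sum(self.dropped_by_rule.values())
        if total != self.input_count or min(
            [self.input_count, self.retained_count, *self.dropped_by_rule.values()], default=0
        ) < 0:
            raise ValueError("inconsistent filter report counts")

    def to_dict(self) -> dict:
        return {
            "input": self.input_count,
            "retained": self.retained_count,
            "dropped": dict(self.dropped_by_rule),
        }


def _detected(values: list[float], min_replicates: int) -> bool:
    return sum(v > 0 for v in values) >= min_replicates


def apply_detection_rule(
    table: ProteinGroupTable,
    fraction: str,
    min_replicates: int = 2,
    min_unique_peptides: int = 2,
    use: str = "intensity",
) -> tuple[ProteinGroupTable, FilterReport]:
    """Keep proteins identified in ``fraction``: nonzero in >= min_replicates
    replicates and >= min_unique_peptides unique peptides."""
    if fraction not in table.design.fractions:
        raise DesignError(f"fraction {fraction!r} not in design")
    if min_replicates > table.design.n_replicates(fraction):
        raise ValueError(
            f"min_replicates={min_replicates} exceeds the "
            f"{table.design.n_replicates(fraction)} replicates of {fraction}"
        )
    kept, few_reps, few_peps = [], 0, 0
    for row in table.rows:
        if row.unique_peptides < min_unique_peptides:
            few_peps += 1
            continue
        if not _detected(table.values(row, fraction, kind=use), min_replicates):
            few_reps += 1
            continue
        kept.append(row.group_id)
    report = FilterReport(
        input_count=len(table),
        retained_count=len(kept),
        dropped_by_rule={"min_unique_peptides": few_peps, "min_replicates": few_reps},
    )
    return table.subset(kept), report


def exclude_organellar(
    table: ProteinGroupTable,
    exclusion_sets: GeneSetCollection,
) -> tuple[ProteinGroupTable, FilterReport]:
    """Remove proteins annotated to chromatin/nuclear/mitochondrial exclusion sets.

    A symbol occurring in several sets is dropped once, attributed to the first
    set in collection order.
    """
    if len(exclusion_sets) == 0:
        logger.warning("empty exclusion collection; table returned unchanged")
        return table, FilterReport(len(table), len(table), {})
    per_set = {set_id: 0 for set_id in exclusion_sets.sets}
    kept = []
    for row in table.rows:
        hit = None
        for set_id, (_, members) in exclusion_sets.sets.items():
            if row.gene_symbol in members:
                hit = set_id
                break
        if hit is None:
            kept.append(row.group_id)
        else:
            per_set[hit] += 1
    report = FilterReport(
        input_count=len(table),
        retained_count=len(kept),
        dropped_by_rule=per_set,
    )
    return table.subset(kept), report


def find_exclusive(
    ecm: ProteinGroupTable,
    cellular: ProteinGroupTable,
    min_replicates: int = 2,
    min_unique_peptides: int = 2,
) -> set[str]:
    """Symbols identified in the ECM fraction but at zero LFQ in every cellular
    replicate.

    ``ecm`` and ``cellular`` may be the same joint table; identification uses
    the intensity columns, the all-zero rule uses LFQ.
    """
    n_ecm = ecm.design.n_replicates(ECM)
    n_cell = cellular.design.n_replicates(CELLULAR)
    if n_ecm == 0 or n_cell == 0:
        raise DesignError("both tables must carry their respective fraction")
    if n_ecm != n_cell:
        raise DesignError(f"replicate count mismatch: ECM {n_ecm} vs cellular {n_cell}")
    detected, _ = apply_detection_rule(
        ecm, ECM, min_replicates=min_replicates, min_unique_peptides=min_unique_peptides
    )
    cell_rows = {r.gene_symbol: r for r in cellular.rows}
    out = set()
    for row in detected.rows:
        cell = cell_rows.get(row.gene_symbol)
        if cell is None:
            out.add(row.gene_symbol)  # absent from the cellular table entirely
            continue
        if all(v == 0 for v in cellular.values(cell, CELLULAR, kind="lfq")):
            out.add(row.gene_symbol)
    return out
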