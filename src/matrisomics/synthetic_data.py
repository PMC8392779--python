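"""Synthetic paired-fraction LFQ tables and planted networks with known truth.

The generator emulates the statistical structure of a label-free experiment
comparing an ECM-enriched against a cellular fraction: per-protein baseline
abundances on the log2 scale, a planted symmetric fold change for enriched
classes, structural zeros for ECM-exclusive proteins, replicate-level Gaussian
noise, and abundance-dependent logistic dropout.  Every draw comes from a
single seeded generator in fixed order, so a given parameter set is
reproducible bit-for-bit.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np
import pandas as pd

from .formats_io import (
    CELLULAR,
    ECM,
    EdgeList,
    GeneSetCollection,
    ProteinGroup,
    ProteinGroupTable,
    SampleDesign,
    SampleInfo,
)

# Planted truth classes.
ECM_ENRICHED = "ECM_ENRICHED"
CELLULAR_ENRICHED = "CELLULAR_ENRICHED"
SHARED_FLAT = "SHARED_FLAT"
ECM_EXCLUSIVE = "ECM_EXCLUSIVE"
ORGANELLE_CONTAMINANT = "ORGANELLE_CONTAMINANT"
CLASSES = (ECM_ENRICHED, CELLULAR_ENRICHED, SHARED_FLAT, ECM_EXCLUSIVE, ORGANELLE_CONTAMINANT)


def _default_proportions() -> dict[str, float]:
    return {
        ECM_ENRICHED: 0.15,
        CELLULAR_ENRICHED: 0.10,
        SHARED_FLAT: 0.60,
        ECM_EXCLUSIVE: 0.10,
        ORGANELLE_CONTAMINANT: 0.05,
    }


@dataclass
class SimulationParams:
    """Parameters of the paired-fraction LFQ simulation.

    Defaults describe a small but realistic label-free experiment: log2 LFQ
    baselines around 25 (~3e7 on the raw scale) with 2 log2-units of
    between-protein spread, 0.5 log2-units of replicate noise, a planted
    8-fold (log2fc = 3) enrichment, and logistic dropout centred 7 log2-units
    below the typical protein so that detection is common but not certain in
    the low-abundance tail.
    """

    n_proteins: int = 200
    replicates: int = 3
    class_proportions: dict[str, float] = field(default_factory=_default_proportions)
    planted_log2fc: float = 3.0
    base_log2_mean: float = 25.0
    base_log2_sd: float = 2.0
    noise_sd: float = 0.5
    dropout_midpoint: float = 18.0
    dropout_slope: float = 1.0
    dropout_enabled: bool = True
    peptide_rate: float = 6.0
    seed: int = 0

    def validate(self) -> None:
        total = sum(self.class_proportions.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"class proportions sum to {total}, expected 1")
        unknown = set(self.class_proportions) - set(CLASSES)
        if unknown:
            raise ValueError(f"unknown classes {sorted(unknown)}")
        if self.replicates < 2:
            raise ValueError("need at least 2 replicates")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.peptide_rate < 2:
            raise ValueError("peptide_rate must be >= 2")


@dataclass
class SyntheticTruth:
    """Ground truth per protein plus an echo of the generating parameters."""

    table: pd.DataFrame  # columns: group_id, symbol, class, true_log2fc, true_mean
    params: SimulationParams
    seed: int

    def symbols_of(self, cls: str) -> set[str]:
        return set(self.table.loc[self.table["class"] == cls, "symbol"])


def largest_remainder_counts(n: int, proportions: Mapping[str, float]) -> dict[str, int]:
    """Apportion n items among classes by largest-remainder rounding.

    Deterministic: exact quotas floor-ed, leftover units go to the largest
    fractional remainders (ties broken by class-name order).
    """
    items = sorted(proportions.items())
    quotas = [(name, n * p) for name, p in items]
    counts = {name: int(np.floor(q)) for name, q in quotas}
    leftover = n - sum(counts.values())
    remainders = sorted(
        ((q - np.floor(q), name) for name, q in quotas),
        key=lambda t: (-t[0], t[1]),
    )
    for _, name in remainders[:leftover]:
        counts[name] += 1
    return counts


def _paired_design(replicates: int) -> SampleDesign:
    samples = {}
    for r in range(1, replicates + 1):
        samples[f"ECM_{r}"] = SampleInfo(fraction=ECM, replicate=r, subject=f"S{r}")
        samples[f"CELL_{r}"] = SampleInfo(fraction=CELLULAR, replicate=r, subject=f"S{r}")
    return SampleDesign(samples)


def generate_dataset(params: SimulationParams) -> tuple[ProteinGroupTable, SyntheticTruth]:
    """Simulate a paired ECM/cellular protein-group table with known truth.

    Per replicate, log2 LFQ = class mean +/- planted_log2fc/2 (ECM-enriched up
    in ECM, cellular-enriched up in cellular) + N(0, noise_sd).  ECM-exclusive
    proteins carry structural zeros in every cellular replicate (never subject
    to dropout).  Detection dropout zeroes a value with probability
    1 - logistic(slope * (x - midpoint)).  Unique peptide counts are drawn as
    2 + Poisson(peptide_rate - 2), i.e. every simulated group meets the
    two-unique-peptide identification rule by construction so the planted
    truth is exactly recoverable.
    """
    params.validate()
    rng = np.random.default_rng(params.seed)
    R = params.replicates
    counts = largest_remainder_counts(params.n_proteins, params.class_proportions)
    labels: list[str] = []
    for cls in CLASSES:
        labels.extend([cls] * counts.get(cls, 0))

    n = params.n_proteins
    base = rng.normal(params.base_log2_mean, params.base_log2_sd, size=n)
    peptides = 2 + rng.poisson(params.peptide_rate - 2, size=n)
    half = params.planted_log2fc / 2.0
    shift = np.zeros(n)
    for i, cls in enumerate(labels):
        if cls == ECM_ENRICHED:
            shift[i] = half
        elif cls == CELLULAR_ENRICHED:
            shift[i] = -half

    ecm_log2 = base[:, None] + shift[:, None] + rng.normal(0.0, params.noise_sd, size=(n, R))
    cell_log2 = base[:, None] - shift[:, None] + rng.normal(0.0, params.noise_sd, size=(n, R))

    ecm_vals = np.exp2(ecm_log2)
    cell_vals = np.exp2(cell_log2)

    if params.dropout_enabled:
        p_ecm = 1.0 / (1.0 + np.exp(-params.dropout_slope * (ecm_log2 - params.dropout_midpoint)))
        p_cell = 1.0 / (1.0 + np.exp(-params.dropout_slope * (cell_log2 - params.dropout_midpoint)))
        ecm_vals[rng.random(size=(n, R)) > p_ecm] = 0.0
        cell_vals[rng.random(size=(n, R)) > p_cell] = 0.0

    exclusive = np.array([cls == ECM_EXCLUSIVE for cls in labels])
    cell_vals[exclusive, :] = 0.0  # structural zeros, independent of dropout

    design = _paired_design(R)
    rows = []
    width = len(str(n))
    truth_rows = []
    for i in range(n):
        sym = f"SYN{i:0{width}d}"
        intensity = {f"ECM_{r+1}": float(ecm_vals[i, r]) for r in range(R)}
        intensity.update({f"CELL_{r+1}": float(cell_vals[i, r]) for r in range(R)})
        rows.append(
            ProteinGroup(
                group_id=sym,
                gene_symbol=sym,
                species="human",
                unique_peptides=int(peptides[i]),
                intensity=dict(intensity),
                lfq_intensity=dict(intensity),
            )
        )
        cls = labels[i]
        true_fc = {ECM_ENRICHED: params.planted_log2fc,
                   CELLULAR_ENRICHED: -params.planted_log2fc}.get(cls, 0.0)
        if cls == ECM_EXCLUSIVE:
            true_fc = float("inf")
        truth_rows.append((sym, sym, cls, true_fc, float(base[i])))

    table = ProteinGroupTable(rows=rows, design=design)
    truth = SyntheticTruth(
        table=pd.DataFrame(
            truth_rows, columns=["group_id", "symbol", "class", "true_log2fc", "true_mean"]
        ),
        params=replace(params),
        seed=params.seed,
    )
    return table, truth


def truth_exclusion_sets(truth: SyntheticTruth) -> GeneSetCollection:
    """Organelle-contaminant exclusion sets implied by the planted truth."""
    members = frozenset(truth.symbols_of(ORGANELLE_CONTAMINANT))
    if not members:
        return GeneSetCollection(sets={})
    return GeneSetCollection(sets={"organelle": ("planted organelle contaminants", members)})


def generate_network(
    n_nodes: int,
    background_edge_prob: float,
    planted_module: set[str],
    within_module_edge_prob: float,
    score_range: tuple[float, float] = (0.7, 1.0),
    seed: int = 0,
    node_labels: list[str] | None = None,
) -> EdgeList:
    """Erdős–Rényi background graph plus a denser planted module.

    Edge confidence scores are drawn uniformly from ``score_range``.  The
    planted module must be a subset of the node labels (defaults
    ``N0000..``).
    """
    for p in (background_edge_prob, within_module_edge_prob):
        if not 0.0 <= p <= 1.0:
            raise ValueError(f"edge probability {p} outside [0, 1]")
    if node_labels is None:
        node_labels = [f"N{i:04d}" for i in range(n_nodes)]
    if len(node_labels) != n_nodes:
        raise ValueError("node_labels length must equal n_nodes")
    if not planted_module <= set(node_labels):
        raise ValueError("planted module is not a subset of the node set")
    rng = np.random.default_rng(seed)
    module = set(planted_module)
    edges: list[tuple[str, str, float]] = []
    lo, hi = score_range
    for i in range(n_nodes):
        for j in range(i + 1, n_nodes):
            a, b = node_labels[i], node_labels[j]
            p = within_module_edge_prob if (a in module and b in module) else background_edge_prob
            if rng.random() < p:
                edges.append((a, b, float(rng.uniform(lo, hi))))
    return EdgeList(edges=edges)
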