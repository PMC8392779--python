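import math
from fractions import Fraction

import pytest
from hypothesis import HealthCheck, settings

from matrisomics import (
    CELLULAR,
    ECM,
    ProteinGroup,
    ProteinGroupTable,
    SampleDesign,
    SampleInfo,
)

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


def paired_design(replicates: int = 3) -> SampleDesign:
    samples = {}
    for r in range(1, replicates + 1):
        samples[f"ECM_{r}"] = SampleInfo(fraction=ECM, replicate=r)
        samples[f"CELL_{r}"] = SampleInfo(fraction=CELLULAR, replicate=r)
    return SampleDesign(samples)


def make_table(specs, replicates: int = 3) -> ProteinGroupTable:
    """Build a paired-fraction table from (symbol, peptides, ecm_vals, cell_vals)."""
    design = paired_design(replicates)
    rows = []
    for sym, peptides, ecm_vals, cell_vals in specs:
        vals = {f"ECM_{r+1}": float(v) for r, v in enumerate(ecm_vals)}
        vals.update({f"CELL_{r+1}": float(v) for r, v in enumerate(cell_vals)})
        rows.append(
            ProteinGroup(
                group_id=sym, gene_symbol=sym, species="human",
                unique_peptides=peptides,
                intensity=dict(vals), lfq_intensity=dict(vals),
            )
        )
    return ProteinGroupTable(rows=rows, design=design)


def hypergeom_upper_tail_exact(k: int, n: int, K: int, N: int) -> Fraction:
    """Enumeration oracle: P(X >= k) as an exact rational number."""
    total = math.comb(N, n)
    acc = Fraction(0)
    for i in range(k, min(n, K) + 1):
        acc += Fraction(math.comb(K, i) * math.comb(N - K, n - i), total)
    return acc


def fisher_two_sided_exact(k: int, n: int, K: int, N: int) -> Fraction:
    """Sum of probabilities of tables no more likely than the observed one."""
    total = math.comb(N, n)
    lo, hi = max(0, n + K - N), min(n, K)
    probs = {
        i: Fraction(math.comb(K, i) * math.comb(N - K, n - i), total)
        for i in range(lo, hi + 1)
    }
    observed = probs[k]
    return sum((p for p in probs.values() if p <= observed), Fraction(0))


@pytest.fixture
def design3():
    return paired_design(3)
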