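"""Two-group empirical-Bayes moderated t-test on log2 LFQ intensities.

Model
-----
For protein g with detected log2 LFQ values in both fractions, the ordinary
two-sample statistics are the available-case group means, the pooled residual
variance ``s2_g`` and residual degrees of freedom ``df_g = n1 + n2 - 2``.
The per-protein variances are assumed exchangeable a priori,

    s2_g | sigma2_g ~ sigma2_g * chi2(df_g) / df_g,
    1 / sigma2_g    ~ chi2(d0) / (d0 * s0^2),

i.e. a scaled inverse-chi-square prior with ``d0`` prior degrees of freedom
and prior variance ``s0^2``.  The posterior mean of sigma2_g,

    s~2_g = (d0 * s0^2 + df_g * s2_g) / (d0 + df_g),

replaces s2_g in the t-statistic, which then has ``d0 + df_g`` degrees of
freedom under the null.  ``(d0, s0^2)`` are estimated by moment matching on
``e_g = log s2_g - digamma(df_g/2) + log(df_g/2)``: the excess of ``var(e)``
over the mean trigamma term identifies ``trigamma(d0/2)``, and the mean of
``e`` identifies ``s0^2`` after undoing the log-scale bias.  When the
observed spread does not exceed the sampling noise, ``d0`` is infinite and
every variance shrinks fully to ``s0^2`` (normal reference distribution).

This is the standard moderated-t hierarchy for label-free proteomics; p-values
are Benjamini-Hochberg adjusted, and the volcano classification adds the
ECM-exclusive class (proteins identified in the ECM-enriched fraction but at
zero LFQ in all cellular replicates), which is reported alongside, not
within, the tested set.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
from scipy import special, stats
from statsmodels.stats.multitest import multipletests

from .formats_io import CELLULAR, ECM, ProteinGroupTable

# Volcano statuses.
ECM_ENRICHED_STATUS = "ECM_enriched"
CELLULAR_ENRICHED_STATUS = "cellular_enriched"
NOT_SIGNIFICANT = "not_significant"
ECM_EXCLUSIVE_STATUS = "ECM_exclusive"


@dataclass
class GroupFitRecord:
    """Ordinary two-sample summary for one protein (log2 scale)."""

    symbol: str
    mean_ecm: float
    mean_cell: float
    log2fc: float
    s2: float
    df: int
    n_ecm: int
    n_cell: int
    testable: bool = True


@dataclass(frozen=True)
class EBayesPrior:
    """Hyperparameters of the variance prior; ``d0`` may be ``math.inf``."""

    d0: float
    s0_sq: float

    def __post_init__(self) -> None:
        if not (self.d0 > 0 and self.s0_sq > 0):
            raise ValueError("prior requires d0 > 0 and s0_sq > 0")


@dataclass
class DifferentialRecord:
    symbol: str
    log2fc: float
    t_moderated: float | None
    p_value: float | None
    fdr: float | None = None
    status: str | None = None


def fit_two_group(log2_ecm, log2_cell, symbol: str = "") -> GroupFitRecord:
    """Available-case two-sample fit: means, pooled variance, df = n1 + n2 - 2.

    A group with fewer than two detected values yields an untestable record.
    """
    a = np.asarray(log2_ecm, dtype=float)
    b = np.asarray(log2_cell, dtype=float)
    n1, n2 = len(a), len(b)
    if n1 < 2 or n2 < 2:
        return GroupFitRecord(symbol, np.nan, np.nan, np.nan, np.nan, 0, n1, n2, testable=False)
    m1, m2 = a.mean(), b.mean()
    df = n1 + n2 - 2
    ss = ((a - m1) ** 2).sum() + ((b - m2) ** 2).sum()
    return GroupFitRecord(
        symbol=symbol,
        mean_ecm=float(m1),
        mean_cell=float(m2),
        log2fc=float(m1 - m2),
        s2=float(ss / df),
        df=df,
        n_ecm=n1,
        n_cell=n2,
    )


def select_testable(
    ecm: ProteinGroupTable,
    cellular: ProteinGroupTable,
    min_replicates: int = 2,
    min_unique_peptides: int = 2,
) -> list[GroupFitRecord]:
    """Fit records for proteins quantified (LFQ > 0) in >= ``min_replicates``
    of *both* fractions with >= ``min_unique_peptides`` unique peptides."""
    cell_rows = {r.gene_symbol: r for r in cellular.rows}
    out = []
    for row in ecm.rows:
        if row.unique_peptides < min_unique_peptides:
            continue
        cell = cell_rows.get(row.gene_symbol)
        if cell is None:
            continue
        ev = [v for v in ecm.values(row, ECM, kind="lfq") if v > 0]
        cv = [v for v in cellular.values(cell, CELLULAR, kind="lfq") if v > 0]
        if len(ev) < min_replicates or len(cv) < min_replicates:
            continue
        out.append(fit_two_group(np.log2(ev), np.log2(cv), symbol=row.gene_symbol))
    return out


def trigamma_inverse(y: float) -> float:
    """Solve trigamma(x) = y for x > 0 by monotone Newton iteration."""
    if y <= 0:
        raise ValueError("trigamma_inverse requires y > 0")
    if y > 1e7:
        return 1.0 / math.sqrt(y)
    if y < 1e-6:
        return 1.0 / y
    x = 0.5 + 1.0 / y
    for _ in range(50):
        tri = float(special.polygamma(1, x))
        dif = tri * (1.0 - tri / y) / float(special.polygamma(2, x))
        x += dif
        if abs(dif / x) < 1e-10:
            break
    return x


def estimate_prior(s2, df) -> EBayesPrior:
    """Moment-matching estimate of the variance prior (d0, s0^2).

    Zero variances (constant replicate values) are offset to the smallest
    positive variance times 1e-3 rather than dropped, so fully reproducible
    proteins still inform — and benefit from — the shrinkage.
    """
    s2 = np.asarray(s2, dtype=float).copy()
    df = np.asarray(df, dtype=float)
    if len(s2) < 2:
        raise ValueError("need at least two variances to estimate a prior")
    if np.all(s2 == 0):
        raise ValueError("all variances are zero; more data needed to estimate the prior")
    if np.any(s2 == 0):
        s2[s2 == 0] = s2[s2 > 0].min() * 1e-3
    e = np.log(s2) - special.digamma(df / 2.0) + np.log(df / 2.0)
    e_mean = float(e.mean())
    # var(e) in excess of the mean sampling variance of log s2 given df.
    evar = float(e.var(ddof=1)) - float(np.mean(special.polygamma(1, df / 2.0)))
    if evar > 0:
        d0 = 2.0 * trigamma_inverse(evar)
        s0_sq = math.exp(e_mean + float(special.digamma(d0 / 2.0)) - math.log(d0 / 2.0))
    else:
        d0 = math.inf
        s0_sq = math.exp(e_mean)
    return EBayesPrior(d0=d0, s0_sq=s0_sq)


def moderate(records: list[GroupFitRecord], prior: EBayesPrior) -> list[DifferentialRecord]:
    """Moderated t and two-sided p for each testable record.

    Posterior variance s~2 = (d0 s0^2 + df s2) / (d0 + df); the reference
    distribution is t with d0 + df degrees of freedom (normal when d0 is
    infinite).
    """
    out = []
    for r in records:
        if not r.testable:
            continue
        if math.isinf(prior.d0):
            s2_post = prior.s0_sq
        else:
            s2_post = (prior.d0 * prior.s0_sq + r.df * r.s2) / (prior.d0 + r.df)
        se = math.sqrt(s2_post * (1.0 / r.n_ecm + 1.0 / r.n_cell))
        t = r.log2fc / se
        if math.isinf(prior.d0):
            p = 2.0 * float(stats.norm.sf(abs(t)))
        else:
            p = 2.0 * float(stats.t.sf(abs(t), prior.d0 + r.df))
        out.append(DifferentialRecord(symbol=r.symbol, log2fc=r.log2fc, t_moderated=t, p_value=p))
    return out


def bh_adjust(p) -> np.ndarray:
    """Benjamini-Hochberg step-up FDR adjustment (order preserved)."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def classify_volcano(
    records: list[DifferentialRecord],
    exclusive: set[str],
    fdr_max: float = 0.05,
    lfc_min: float = 1.0,
) -> list[DifferentialRecord]:
    """Attach BH-FDR and volcano status; append ECM-exclusive records.

    A protein is ECM-enriched when fdr <= fdr_max and log2fc >= lfc_min,
    cellular-enriched with the sign flipped, otherwise not significant.
    The exclusive set must be disjoint from the tested records (they were
    not quantified in the cellular fraction, so no test exists for them).
    """
    tested_symbols = {r.symbol for r in records}
    overlap = tested_symbols & exclusive
    if overlap:
        raise ValueError(f"symbols both tested and exclusive: {sorted(overlap)[:5]}")
    ordered = sorted(records, key=lambda r: (r.p_value, r.symbol))
    fdrs = bh_adjust([r.p_value for r in ordered])
    out = []
    for r, fdr in zip(ordered, fdrs):
        if fdr <= fdr_max and r.log2fc >= lfc_min:
            status = ECM_ENRICHED_STATUS
        elif fdr <= fdr_max and r.log2fc <= -lfc_min:
            status = CELLULAR_ENRICHED_STATUS
        else:
            status = NOT_SIGNIFICANT
        out.append(replace(r, fdr=float(fdr), status=status))
    for sym in sorted(exclusive):
        out.append(
            DifferentialRecord(
                symbol=sym, log2fc=math.inf, t_moderated=None,
                p_value=None, fdr=None, status=ECM_EXCLUSIVE_STATUS,
            )
        )
    return out


def run_differential(
    ecm: ProteinGroupTable,
    cellular: ProteinGroupTable,
    exclusive: set[str] | None = None,
    min_replicates: int = 2,
    min_unique_peptides: int = 2,
    fdr_max: float = 0.05,
    lfc_min: float = 1.0,
) -> tuple[list[DifferentialRecord], EBayesPrior]:
    """Select, fit, shrink, test and classify in one call."""
    fits = select_testable(
        ecm, cellular, min_replicates=min_replicates, min_unique_peptides=min_unique_peptides
    )
    testable = [f for f in fits if f.testable]
    if not testable:
        return [], EBayesPrior(d0=math.inf, s0_sq=1.0)
    prior = estimate_prior([f.s2 for f in testable], [f.df for f in testable])
    tested = moderate(testable, prior)
    exclusive = set(exclusive or set()) - {t.symbol for t in tested}
    return classify_volcano(tested, exclusive, fdr_max=fdr_max, lfc_min=lfc_min), prior
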