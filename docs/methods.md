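# Methods

## Data model and conventions

The pipeline consumes MaxQuant-style `proteinGroups` tables. Following the
usual role split, the raw **intensity** columns decide identification
(detection) and the **LFQ intensity** columns provide quantification. Empty
or missing intensity cells are stored as 0 and interpreted as non-detection
throughout; there is no minimum-intensity floor. Reverse-database and
contaminant-flagged rows are removed at load and counted. Semicolon-separated
multi-gene groups collapse to their first symbol (the MaxQuant majority
convention; deterministic). Symbols are case-normalized per species — human
uppercase, mouse capitalized-first — and all matching is exact and
case-sensitive thereafter, which keeps mouse and human name spaces disjoint
until orthology mapping is applied explicitly.

## Detection and exclusivity rules

A protein is *identified* in a fraction when its intensity is nonzero in at
least `min_replicates` (default 2) replicates of that fraction and the group
has at least `min_unique_peptides` (default 2) unique peptides. Whether the
replicate count should read the intensity or LFQ columns is not fixed by the
format; the default is intensity, and the choice is a keyword argument.

A protein is *ECM-exclusive* when it passes the identification rule in the
ECM-enriched fraction and its LFQ value is zero in **every** cellular
replicate. Exclusive proteins cannot be tested (no cellular variance exists)
and are therefore reported alongside, never within, the tested set; the
volcano classifier enforces disjointness.

Organelle exclusion removes proteins whose symbol occurs in any of the
configured chromatin/nuclear/mitochondrial gene sets; a symbol in several
sets is removed once and attributed to the first set in collection order.
Filtering precedes differential testing (the alternative order yields the
same retained set — the filters commute, and the test suite checks this).

## Moderated t-test

For each testable protein the two-group fit uses available-case statistics
over detected (nonzero) log2 LFQ values: group means, pooled variance
s²_g and residual degrees of freedom df_g = n₁ + n₂ − 2. No imputation is
performed and no between-sample normalization is applied (MaxLFQ values are
assumed normalized upstream).

Variances are assumed exchangeable with a scaled inverse-chi-square prior
(d₀, s₀²). Hyperparameters are estimated by moment matching on

    e_g = log s²_g − ψ(df_g/2) + log(df_g/2),

where ψ is the digamma function: `var(e)` in excess of the mean
`ψ′(df_g/2)` term identifies `ψ′(d₀/2)`, inverted by a monotone Newton
iteration, and `mean(e)` identifies s₀² after undoing the log-scale bias.
When the observed spread does not exceed the sampling noise, d₀ = ∞ and all
variances shrink fully to s₀² (normal reference). Zero pooled variances
(perfectly reproducible proteins) are offset to 10⁻³ × the smallest positive
variance rather than dropped, so they participate in — and benefit from —
the shrinkage. The posterior variance s̃²_g replaces s²_g in the t-statistic,
referenced against t(d₀ + df_g). The implementation is cross-checked against
the Bioconductor limma `eBayes` chain in a test (agreement to ~1e-14 on
complete data), but limma is an oracle only; the estimation code is this
package's own.

P-values are Benjamini–Hochberg adjusted (delegated to statsmodels;
an independent step-up formula serves as the test oracle). Volcano statuses
use FDR ≤ 0.05 and |log2fc| ≥ 1 by default; the significance threshold is
interpreted as the FDR-adjusted p-value, configurable to raw p.

## Enrichment statistics

Over-representation p-values are hypergeometric upper tails P(X ≥ k)
including the observed count — sampling without replacement from an explicit
background of annotated and non-annotated genes. Fisher's exact test (the
same tail one-sided; two-sided by summing tables no more probable than the
observed one) is available for pathway contrasts. Backgrounds are never
defaulted silently: pathway tests over matrisome gene sets use the matrisome
itself as background, and genome-scale tests require a user-supplied
background size, because the correct N depends on the provenance of the gene
lists being overlaid. Gene sets overlapping the query by fewer than
`min_overlap` (default 3) genes are not tested and do not count toward the
BH correction, whose result is invariant to collection order. Fold
enrichment is (k/n)/(K/N).

## Networks

Edge lists use the STRING export dialect; per-mille integer scores (0–999)
are rescaled to [0, 1], self-edges dropped, and undirected duplicates merged
keeping the maximum score. "High confidence" is operationalized as combined
score ≥ 0.700 — STRING's documented high-confidence tier — and is
configurable, since the tier name rather than a number is what analyses
typically cite. Network reduction keeps the largest connected component
(ties broken by the smallest lexicographic node label, for determinism) or,
alternatively, drops only isolated nodes. The interactor cascade's final
step requires a direct retained edge to a matrisome-annotated node by
default (a component-level rule is available); each earlier step consumes a
configured gene list or flag table, never a live database query, so runs are
reproducible offline.

## Synthetic data generator

The generator emulates the statistical structure the differential test
assumes, not the mass spectrometry that produces it. Each protein belongs to
one of five classes — ECM-enriched, cellular-enriched, shared-flat,
ECM-exclusive, organelle-contaminant — apportioned by largest-remainder
rounding (deterministic truth, no multinomial jitter). Log2 LFQ values are

    baseline N(base_log2_mean, base_log2_sd²)
    ± planted_log2fc/2 for the enriched classes (symmetric split)
    + replicate noise N(0, noise_sd²),

with detection dropout applied per value with probability
1 − logistic(slope · (x − midpoint)). ECM-exclusive proteins carry
*structural* zeros in every cellular replicate that dropout never touches,
keeping the all-zero exclusivity rule exactly testable. All draws come from
one seeded generator in fixed order.

Defaults describe a small, realistic experiment: 3 replicates,
base_log2_mean 25 (≈3·10⁷ raw LFQ), base_log2_sd 2, noise_sd 0.5 (typical
replicate CVs for label-free data), planted_log2fc 3, dropout midpoint 18
and slope 1 (detection is near-certain for average proteins and degrades in
the low-abundance tail), mean unique-peptide count 6. Unique peptides are
drawn as 2 + Poisson(peptide_rate − 2): every simulated group meets the
two-peptide identification rule by construction, so the planted truth —
in particular the exclusive class — is exactly recoverable; the peptide
threshold itself is exercised on hand-built tables in the unit tests.

What the generator does **not** model: peptide-level quantification and
razor-peptide ambiguity, intensity-dependent variance trends, correlated
(sample-level) missingness, batch effects, or shared-peptide protein groups.
Passing recovery tests on this generator therefore demonstrates correctness
of the statistical machinery under its stated assumptions, not robustness to
every pathology of real LFQ data.

## Problem sizes and numerical choices

The recovery experiments use 200 proteins with 30 planted at log2fc = 3
(noise 0.5, 3 replicates) over 50 seeds for sensitivity/FDR, 2000-protein
null simulations over 50 seeds for type-I control, and 5000 simulated
variances for prior recovery — sizes at which the Monte-Carlo error of the
reported rates is well below the margins being checked, while the whole
acceptance run stays under a minute. The trigamma inversion iterates Newton
steps to a relative tolerance of 1e-10 (closed-form asymptotes outside
[1e-6, 1e7]). Degenerate inputs fail loudly: all-zero variances, empty
backgrounds, impossible contingency tables and mismatched designs raise
typed errors rather than propagating NaNs.

## Known limitations

- Two-group, unpaired design only; no multi-factor or paired models.
- Orthology is symbol-case mapping plus a curated exception table — adequate
  for matrisome gene symbols, not a general orthology method.
- The bundled matrisome reference covers the brain-vascular worked example;
  full-genome matrisome lists should be supplied as files for real analyses.
- Enrichment backgrounds are the analyst's responsibility by design; the
  package refuses to guess genome sizes.
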