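# Methods

## The screening model

The pipeline's substrate is a normalized genes × samples expression matrix
on the log2 scale (the package does not process raw array files; the
`already_log2` config flag declares the stored scale). The default design
is 9 tissue groups × 3 replicates — early (HH4) and late (HH6) Hensen's
node, HH4 posterior primitive streak, ventral and dorsal neural tube, and
posterior/anterior wing bud at HH20 and HH24 — yielding the six
organizer-vs-neighbour comparisons C1–C6 listed in
`orgscreen.config.DEFAULT_COMPARISONS`. "Enriched" always means higher in
the comparison's first-listed (organizer-side) group.

### Differential stage

Per gene and comparison, the log2 fold change is the difference of group
means. Gene variances are modelled hierarchically: conditional on a gene's
true variance σ², the observed residual variance is σ²·χ²_df/df, and σ²
follows a scaled inverse-chi-square prior d₀s₀²/χ²_{d₀} across genes. The
prior is fitted by method of moments on the log-variance scale: with
z = log s², e = z − ψ(df/2) + log(df/2), the excess of Var(e) over
ψ′(df/2) equals ψ′(d₀/2), solved by Newton inversion of the trigamma
function; s₀² follows from the mean relation. Two degenerate regimes are
explicit: d₀ = 0 disables moderation (ordinary pooled t), and when the
observed spread of log-variances does not exceed the sampling term the
prior is reported as d₀ = ∞ with s₀² the mean variance, so every gene is
tested against the common variance (normal tail).

The moderated statistic is t = log2FC / (s̃·√(1/nₐ+1/n_b)) with
s̃² = (d₀s₀² + df·s²)/(d₀+df), referred to Student t on d₀+df degrees of
freedom. Genes with zero residual variance and zero fold change get t = 0,
p = 1; a zero variance with a nonzero fold change is only testable with a
proper prior (d₀ > 0) and raises otherwise. Benjamini–Hochberg adjustment
is applied per comparison across all genes (delegated to statsmodels), and
calls follow |log2FC| ≥ τ ∧ q ≤ α with defaults τ = 1.2 (log2) and
α = 0.05. The fold-change rule is deliberately configurable: `fc_scale:
log2` reads the 1.2 threshold on the log2 scale (default), `fc_scale:
linear` reads it as a linear fold change (|log2FC| ≥ log2 1.2 ≈ 0.263);
the two readings of "FC ≥ 1.2" are one flag apart because the verbal rule
is ambiguous and the gene lists needed to adjudicate it would require the
original arrays.

**Variance pooling.** By default the screen shares one residual variance
per gene across all comparisons, computed from the one-way fit over the
whole design (df = 27 − 9 = 18), as a joint linear model would. The
per-pair alternative (`variance_pooling: "pair"`, df = nₐ+n_b−2 = 4) is
retained but markedly under-powered with triplicates: under the default
simulation its mean planted-gene sensitivity drops from ≈0.92 to ≈0.83,
because heavy-tailed variance draws swamp a 4-df estimate. Fold changes
are always computed from the pair.

### Boolean combination

Per-comparison calls are combined with a Boolean expression over
comparison names (grammar: `NAME | (expr) | expr AND expr | expr OR expr`,
AND binding tighter than OR, keywords case-insensitive). A leaf is true
for a gene iff that comparison's call equals the direction being evaluated,
so the same expression defines the enriched and the depleted set
sign-consistently. The shipped default is
`(C1 AND (C2 OR C3)) AND C4 AND (C5 OR C6)`: enriched (depleted) in the
early node vs streak, with the early-node state either persisting at HH6
or distinguishing HH4 from HH6; and in the notochord/floor-plate; and in
the posterior limb at either stage. The source description of the
combination is syntactically garbled (unbalanced parentheses), and this
grouping follows its narrative reading — the first comparison block
"selects genes enriched or depleted in the early node, some of which remain
expressed the same way later". The literal-precedence alternative
`(C1 AND C3) OR C2` for the node block can be expressed directly via
`expression_text`; no dedicated flag is needed. Under the default
expression the enriched and depleted sets are provably disjoint (C1 and C4
are conjunctive and a gene has one call per comparison). Genes missing
from any comparison table are a consistency error, not imputed: the
combination semantics require complete call vectors.

### Candidate screen

A candidate region is a map signature-gene → detected/absent/unknown; one
status per gene summarizes a stage window (detected at *any* stage in the
window counts as detected). Concordance is a pure set computation:
enriched ∧ detected or depleted ∧ absent; unknown is excluded from both
numerator and denominator, which is also how stage-restricted cases (a
depleted gene absent only before some stage) can be encoded without
temporal logic. Ranking is by concordant fraction, ties broken by number
of scored genes (more evidence first) then region name; regions with no
scored genes rank last. No null model is attached to the match score — the
screen is a prioritization device, not a test.

### Explant statistics

Explants are scored positive / patchy / negative / excluded; tabulation
maps positive (plus patchy when `patchy_as_positive`) against negative per
condition, dropping excluded records unless `include_excluded` counts them
as negative. The two-tailed Fisher exact p sums hypergeometric point
probabilities ≤ the observed table's probability × (1 + 1e-7); the relative
tolerance absorbs floating-point ties in what is mathematically an exact
tie. Probabilities are accumulated from log-factorials (lgamma), keeping
absolute error near 1e-15 for the totals used here and well under 1e-12 up
to N ≈ 1000. A table with any zero margin carries no information and
returns p = 1. Star labels are inclusive at their thresholds
(*** ≤ 0.0005, ** ≤ 0.005, * ≤ 0.05).

## The synthetic-data generator

`simulate_expression` emulates the 27-array design: per gene a baseline
µ ~ Uniform(4, 12) log2, a true variance σ² ~ d₀s₀²/χ²_{d₀} (defaults
d₀ = 4, s₀² = 0.0625, i.e. typical replicate SD 0.25 log2 with a heavy
tail), and i.i.d. Normal(0, σ²) replicate noise. Group structure is
planted per *group*, not per comparison, because comparisons share tissues:
each comparison in a gene's planting pattern adds ±effect (default 2.0
log2) to that comparison's organizer-side group. Under the default
all-six-comparisons pattern HH4 HN therefore carries 2×effect (named by
both C1 and C3) and every comparison's noise-free difference is ≥ effect.
The realized noise-free call vector is re-derived from the accumulated
offsets and checked: planted genes must satisfy the Boolean expression in
their direction, decoys (default: 200 genes perturbed in C1 only, signs
alternating) must fail it — a requested pattern violating either is
"group-inconsistent" and raises. With effect = 0 nothing is plantable and
the check is skipped (all patterns ns), which keeps the zero-noise,
zero-effect degenerate case generable. Planted counts default to the
31 enriched / 17 depleted scale of interest in a 10,000-gene universe
(32,773-gene runs are one parameter away but add nothing to the tested
behaviour).

What the generator does *not* emulate: probe-level effects,
cross-hybridization, batch and spatial artifacts, intensity-dependent
variance, and correlated genes. Passing recovery tests therefore
demonstrate the statistical machinery under the stated generative model,
not robustness to real-array artifacts.

`simulate_candidate_profile` draws per-gene Bernoulli concordance
(enriched genes detected with p₁, depleted genes absent with p₂);
`simulate_assay_records` draws per-explant categories
(positive/patchy/negative) per arm. All generators are deterministic given
their seed.

## Numerical and design choices

- Trigamma inversion: Newton iteration from x₀ = 0.5 + 1/y with closed-form
  guards for very large/small arguments; converges to ~1e-10 relative.
- p-values are clipped to (tiny, 1]; q ≥ p and BH monotonicity hold by
  construction.
- TSV dialect is fixed (tab, UTF-8, "." decimal, header cell `gene_id`);
  floats are written at repr precision so write→read round-trips exactly.
- Gene identifiers are opaque probe-level strings; no probe→gene
  collapsing is attempted (no collapsing rule is defined for the design).
- Problem sizes in the test suite (10,000-gene universes, 20-seed
  recovery averages, exhaustive Fisher enumeration to N = 30) were chosen
  as the smallest sizes at which the targeted behaviours are stable.

## Known limitations

- The screen assumes equal within-group variance across groups per gene
  (one-way homoscedastic model); group-specific variances are not modelled.
- Per-comparison BH is the only multiplicity scheme; no global-FDR or
  hierarchical variant is provided.
- The candidate screen has no significance model; concordant fractions
  from profiles with few scored genes rank on thin evidence (mitigated by
  the evidence tie-break).
- The Fisher implementation targets 2×2 tables only; stratified or mid-p
  variants are out of scope.
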