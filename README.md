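# orgscreen

Embryonic **organizers** (Hensen's node, the notochord/floor-plate, the
limb's zone of polarizing activity) are signalling regions that can both
induce new fates and pattern neighbouring tissue. `orgscreen` implements a
transcriptome-based strategy for discovering new ones: if organizers share
a "synexpression" signature of transcripts jointly enriched or depleted
relative to their most-similar non-organizer neighbours, that signature can
be used to scan the embryo for further regions with organizer character —
such as the endoderm of the anterior intestinal portal (AIP), the foregut
entrance that behaves as a heart organizer.

The package covers the full computational chain on a chick microarray-style
design (9 tissues × 3 replicates = 27 arrays), with a synthetic-data
generator that plants ground truth so every stage is testable end to end:

1. **Differential screen** — six pairwise comparisons (C1: HH4 node vs HH4
   posterior streak, C2: HH6 node vs HH4 streak, C3: HH4 vs HH6 node,
   C4: ventral vs dorsal neural tube, C5/C6: posterior vs anterior wing bud
   at HH20 and HH24). Per gene and comparison: log2 fold change
   `log2FC = x̄_a − x̄_b`, empirical-Bayes moderated t

   `s̃² = (d₀s₀² + df·s²)/(d₀ + df)`,  `t = log2FC / (s̃·√(1/nₐ + 1/n_b))`,

   with the scaled inverse-chi-square prior (d₀, s₀²) fitted by method of
   moments on log-variances, Benjamini–Hochberg FDR, and calls
   *enriched*/*depleted* at |log2FC| ≥ 1.2 and q ≤ 0.05.
2. **Boolean combination** — calls are combined with the expression
   `(C1 AND (C2 OR C3)) AND C4 AND (C5 OR C6)`, evaluated separately in the
   enriched and depleted directions, yielding the organizer signature
   (31 enriched + 17 depleted planted genes in the default simulation).
3. **Candidate-region screen** — a region's presence/absence profile over
   the signature genes is scored for concordance (enriched gene detected,
   or depleted gene absent) and regions are ranked by concordant fraction.
4. **Explant statistics** — scored co-culture outcomes
   (positive/patchy/negative/excluded) collapse to 2×2 tables tested with
   a two-tailed Fisher exact test (labels * p≤0.05, ** p≤0.005,
   *** p≤0.0005).

## Worked example

Score an AIP-like candidate region in which 20 of the 31
organizer-enriched genes are detected and 15 of the 17 organizer-depleted
genes are appropriately absent:

```python
import orgscreen as og

enriched = tuple(f"ENR{i:02d}" for i in range(1, 32))
depleted = tuple(f"DEP{i:02d}" for i in range(1, 18))
sig = og.SignatureSet(enriched, depleted)

status = {g: ("detected" if i < 20 else "absent") for i, g in enumerate(enriched)}
status |= {g: ("absent" if i < 15 else "detected") for i, g in enumerate(depleted)}
score = og.score_candidate(sig, og.CandidateProfile("AIP_endoderm", status))
print(score.n_concordant, score.n_scored, round(score.fraction, 4))
```

prints `35 48 0.7292`: the region matches the signature at 35 of 48 scored
genes — 20/31 on the enriched side plus 15/17 on the depleted side — the
concordance level that flags a strong organizer candidate.

The numbered drivers under `analysis/` run the whole chain on simulated
data and write their tables to `results/` (large intermediates go to
`scratch/`): `01` simulates the screen, `02` runs the six comparisons
(e.g. 30 enriched / 14 depleted calls in C6 at the default thresholds),
`03` derives the signature and measures recovery of the planted genes
(mean sensitivity ≈ 0.92 enriched / 0.95 depleted, set-FDR 0.0 over five
seeds), `04` ranks candidate regions (the AIP-like profile tops the
ranking at 35/48), and `05` computes Fisher statistics for explant
scenarios (e.g. 8/10 vs 0/10 positives → p = 7.1×10⁻⁴, `**`).

A thin CLI mirrors the stages:
`orgscreen simulate | de | combine | screen | assay | recover`.

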