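# Methods

## Scope and model

`cernet` infers lncRNA–mRNA competitive regulation from two ingredients:
shared miRNA targeting and strong within-condition positive co-expression.
It deliberately stops short of causal claims: an edge states that the pair
is consistent with sponge competition under one condition, nothing more.
Differential-expression calls, read alignment and interaction-database
retrieval are upstream of the package — DE status and the target tables
are consumed as inputs.

## Rules and their boundaries

- **Shared-miRNA rule**: a candidate needs *more than 3* shared miRNAs,
  implemented strictly as ≥ 4; a pair sharing exactly 3 is excluded.
- **Correlation rule**: Spearman ρ ≥ 0.9 over the condition's samples
  (0.8–1 is conventionally "strong"; 0.9 keeps only clearly strong pairs).
  The comparison carries a 1e-9 absolute guard so a boundary value of
  exactly 0.9, computed as Pearson of ranks, is not dropped to floating-
  point roundoff. Only positive ρ can pass, so the positive-correlation
  requirement needs no separate check.
- **Crosstalk highlight**: pathway pairs sharing *more than 20* genes are
  flagged; 20 exactly is not flagged.
- Spearman uses midranks on ties (likely at n = 5 with count-like data);
  a constant profile yields an undefined correlation, reported as NaN and
  excluded — it neither passes nor fails the cutoff.

## Overlap significance

For candidate (L, M), p_shared is the hypergeometric upper tail
P(X ≥ |T(L) ∩ T(M)|) with population the union of miRNA ids observed in
either table, draws |T(L)| and successes |T(M)|. The universe is a design
choice (no canonical value exists when tables come from heterogeneous
sources); union-of-observed is the default and is documented on the
operation. p_shared is annotated, not thresholded, by default; the CLI
exposes `--p-shared-max` for optional filtering. Enrichment uses the same
tail with the analysis background (all mRNA ids in the target table) as
the default universe, overridable; Benjamini–Hochberg q-values accompany
raw p-values since no single significance convention is assumed.

## Synthetic data generator

The generator emulates the targeted study design: two sparse bipartite
target tables, a 5 + 5 two-condition expression matrix, DE flags, and a
labeled miRNA panel.

- **Interactions**: planted pairs (disjoint lncRNAs and mRNAs) each
  receive `shared_mirna_min` common miRNAs; background edges are
  independent Bernoulli draws at `background_density` (default 0.05 over
  a 100-miRNA universe — each regulator targets ~5 miRNAs, the sparse
  regime of CLIP-supported tables, which keeps spurious ≥ 4-miRNA overlaps
  rare, as they are in practice).
- **Correlation planting**: within a pair's active condition the mRNA
  copies the lncRNA's latent Gaussian draw per sample with probability
  `rho_target`, otherwise takes a fresh independent draw. For this
  comonotone/independent mixture copula the population Spearman
  correlation equals `rho_target` exactly, and `rho_target = 1` gives
  identical ranks deterministically. The mixture was chosen over a plain
  bivariate Gaussian deliberately: at equal asymptotic Spearman (say
  0.98), the Gaussian scrambles small-sample ranks so often that at n = 5
  the chance of an empirical ρ ≥ 0.9 is only ≈ 0.54, which would make
  strong plants undetectable by design at the sample sizes the package
  targets; the mixture keeps that probability ≈ 0.94 while preserving the
  advertised population rank correlation. Latents are mapped through
  `exp`, so values are positive and only ranks are meaningful — whether
  real inputs are normalized is irrelevant to every downstream statistic,
  which is rank- or set-based.
- **DE flags** are generated, not computed (DE calling is out of scope):
  flagged transcripts get a +2 SD latent shift in the cytokines condition,
  which never alters within-condition ranks.
- **miRNA panel**: balanced groups; effect miRNAs are shifted by
  `effect_size` latent SDs in the direction given per miRNA (so a panel
  consistent with the signs of a coefficient set — negative-coefficient
  miRNAs lower in cases — is one call away). `effect_size = 0` makes the
  groups exchangeable.
- **Determinism**: one integer seed; per-output substreams derived via
  CRC32-keyed `SeedSequence` spawn keys, so identical configs give
  identical bytes after serialization.

What the generator does *not* emulate: count overdispersion, sequencing
depth, normalization artifacts, correlated background structure, or
batch effects. Passing recovery tests therefore demonstrates correctness
of the inference rules and their thresholds, not robustness to the full
noise structure of real exosome RNA-seq.

## Risk model

With 19 features and ~10 training samples ordinary regression is
underdetermined, so fitting uses minimum-norm least squares on
standardized features (`numpy.linalg.lstsq`), mapped back to the raw
scale — deterministic and exactly reproducible. The reference path is a
*loaded* fixed coefficient set: the packaged 19-miRNA table
(`cernet.reference_coefficients()`), stored with standard miRBase-style
lowercase `hsa-miR-…` ids. Exact reproduction of those coefficient
magnitudes from data is not attempted — the regression family and
preprocessing behind them are not specified, and the package treats them
as given model parameters. On transfer, model miRNAs absent from a
validation panel contribute zero and coefficients are not renormalized;
the evaluation reports which features were available. AUC is the midrank
Mann–Whitney statistic (ties count half), with the ROC curve swept over
unique score thresholds; single-feature ROC reports both orientations
since a marker's direction is not known a priori.

## Reporting conventions and numerics

- Sharing percentages are *truncated* (not rounded) to one decimal
  (197/296 → 66.5, 230/5163 → 4.4); raw fractions are always emitted
  alongside.
- Edge identity for network comparison is the ordered (lncRNA, mRNA) id
  pair; correlations are annotations.
- Ids are opaque and case-sensitive; readers and writers never normalize
  case. All artifacts are TSV/JSON; edge lists import directly into
  Cytoscape.
- Rank correlations require ≥ 4 samples per condition (below that the
  statistic is too coarse to threshold meaningfully; the targeted design
  has 5).
- Jaccard of two empty sets, and DE fractions of an empty node set, are
  undefined and reported as NaN with a warning rather than coerced to 0.

## Problem sizes in the shipped checks

The test suite and `scripts/acceptance.py` run the pipeline at the
generator's default scale — 120 + 120 transcripts over a 100-miRNA
universe with 20 planted pairs and 5 samples per condition, ten
replicates for recovery statistics, and 50 samples per group for
biomarker transfer. These sizes give stable Monte-Carlo estimates
(recovery standard error < 0.02) while a full run stays in seconds.

## Known limitations

- The inference is correlational and condition-marginal; no partial
  correlation on miRNA expression, no direction, no mRNA–mRNA edges.
- The hypergeometric overlap test assumes exchangeable target sets;
  CLIP-derived tables violate this (hub miRNAs), so p_shared is best
  used as a ranking, which is how the pipeline treats it.
- At n = 5 per condition the Spearman null puts ≈ 4% mass at |ρ| ≥ 0.9,
  so sizable candidate sets necessarily admit some false edges at the
  default cutoff; the planted-recovery precision quantifies this under
  the generator's conditions.
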