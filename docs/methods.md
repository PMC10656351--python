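# Methods

## Model and assumptions

`cosinet` quantifies condition-specific rewiring of gene co-expression at
single-sample resolution. The statistical model has three layers.

**Correlation-difference z-test.** Within each condition the co-expression
of a gene pair is summarized by Spearman's rank correlation (average ranks
for ties), chosen for tolerance to outliers and monotone-nonlinear
relationships. Fisher's transformation makes the coefficients approximately
normal with variance c/(n−3); the difference statistic

    z = (z_r2 − z_r1) / sqrt(c/(n2−3) + c/(n1−3)),   c = 1.06 (Spearman), 1 (Pearson)

pools the two variances. The 1.06 factor corrects the slightly inflated
variance of transformed rank correlations; the acceptance checks verify the
test is calibrated (rejection rate at |z| > 1.96 within [0.04, 0.06] under a
shared-correlation null at n = 200 per group). Assumptions: samples are
exchangeable within conditions, and n per condition is large enough
(n ≥ 4 hard floor; tens in practice) for the normal approximation.

**Centrality and enrichment.** Eigenvector centrality of M = |Z| ranks genes
by embedding in rewired neighbourhoods. The sign of z is deliberately
discarded: a pair that loses correlation is as rewired as one that gains it.
Pre-ranked GSEA then asks which annotated gene sets concentrate at the top
of this ranking. Because the ranking metric is a single vector, the null is
gene-label permutation (random same-size sets from the ranked universe);
phenotype permutation is structurally unavailable at this stage.

**Single-sample box statistic.** Local dependence of pair (x, y) at sample
k's position in condition i is estimated by comparing the joint box
frequency with the product of marginal box frequencies:

    rho = max{ n_xy/n − (n_x/n)(n_y/n), 0 }

Boxes are centred on the sample's values with closed boundaries; each box
spans a fixed proportion b of the gene's per-condition expression range
(optionally quantile-trimmed, see below). A negative raw value marks the
sample as an outlier of that condition's co-expression cloud and is floored
at zero. No variance normalization is applied to rho: the sub-network pairs
are strongly dependent by construction, so the independence assumption such
a normalization needs does not hold, and rho values are aggregated rather
than thresholded. Every sample is projected onto both conditions regardless
of its own membership; the designated sample contributes to a condition's
counts only when it is a member of that condition (projections never
inflate n). The per-pair direction Δ = 100 (rho₂ − rho₁) is aggregated over
the sub-network's edges, weighted by |z| and divided by the edge count
(Eq. form; a `--weighted-mean` flag divides by Σ|z| instead for sensitivity
analysis).

## Parameters

| parameter | default | meaning and guidance |
|---|---|---|
| `min_samples` | 20 | a gene must exceed `floor` in this many samples of *both* conditions; guards correlations against tie-dominated vectors |
| `floor` | 0.0 | "expressed" threshold on the stored values; on log2(FPKM+0.1) data zero expression is log2(0.1) ≈ −3.32, so set `floor` accordingly if that reading is wanted |
| `tol`, `max_iter` | 1e−6, 1000 | power-iteration stopping rule (L∞ change of the max-scaled vector); non-convergence is reported, not raised |
| `n_perm` | 10000 | permutation count; raw p resolution is 1/(n_same_sign+1) |
| `min_size`, `max_size` | 10, 500 | gene-set size bounds after intersection with the ranked universe |
| `padj_cutoff` | 0.01 | BH-adjusted significance threshold for enrichment |
| `weight_p` | 1 | exponent on centralities in the running sum |
| `t` | 3.0 | |z| threshold for sub-network edges (two-sided normal tail ≈ 0.0027); no canonical value exists — sweep it in case studies |
| `b` | 0.1 | box width as a proportion of the per-condition expression range, half on either side of the sample value |
| `q` | 1.0 | central quantile mass defining that range; q < 1 blunts extreme values when computing box *size* only — counts always use all condition samples |

## Numerical choices

- **Identity shift in the power iteration.** The iteration multiplies by
  M + I rather than M. Both share eigenvectors, but for bipartite-like
  networks M has paired ±λ eigenvalues and the plain iteration oscillates
  between two phases forever; the shift makes the Perron eigenvalue strictly
  dominant so convergence is guaranteed, and the result is unchanged
  wherever the plain loop converges. Scale invariance of the output then
  holds up to the convergence tolerance (the operator is cM + I, not scale
  free); tests verify it at tolerance 1e−12.
- **Clamping before the Fisher transform.** |r| is clamped to 1 − 1e−7;
  perfect correlations (common at small n) would otherwise map to infinity.
- **Constant genes.** A gene constant across a condition's samples has no
  rank information; its correlations are set to 0 (no rewiring evidence)
  and it is flagged, rather than letting NaNs poison the power iteration.
- **Degenerate pairs in scoring.** A pair whose gene has zero trimmed range
  in either condition is excluded from both the numerator and denominator of
  the score, keeping CS a mean over informative pairs.
- **Closed box boundaries.** A value exactly half a box-width away counts as
  inside; this keeps counts stable under exact ties, common in rank-like
  data. A full-range box (b = 1) covers every sample only when evaluated at
  the range midpoint, since boxes are centred on the sample value.
- **All-hit gene sets.** If a set covers the whole ranked universe there are
  no miss steps; the running sum is monotone to 1 and ES = 1 with the whole
  set as leading edge.
- **Ties and determinism.** Gene ranking breaks centrality ties
  lexicographically; all randomness (permutations, simulation) flows from
  explicit seeds, and repeated runs are bit-identical.
- **"Hochberg's adjusted P."** Benjamini–Hochberg is the default adjustment
  (the convention of the GSEA tooling ecosystem); Hochberg's step-up is
  available via `--adjust hochberg`. Sets without same-sign permutations get
  NES = NaN and are excluded from adjustment.

## Synthetic data: what it emulates and what it does not

The generator plants equicorrelated gene modules via a Gaussian copula
(Spearman target r_s mapped to the latent Pearson value 2 sin(π r_s/6)),
with marginals on a log-expression-like scale (location 5, sd 2). The
reference scenario — 1,000 genes, one 50-gene module rewired from r = 0.0
to 0.7, 200 samples per condition, 19 size-matched decoy sets — exercises
every stage: the planted module is recovered as the top enrichment hit at
padj < 0.01, and the score is exactly antisymmetric under condition swap.
An optional per-module `mean_shift` moves the module's expression level in
condition 2, emulating the common situation where rewiring co-occurs with
an expression shift (e.g. receptor-target programs collapsing in
receptor-negative tumours). Canonical nonlinear co-expression shapes
(linear ±, L, reversed-L, N, X) are available as parameterized piecewise
rules with analytic ground truth; the N shape is drawn as two vertical
strokes joined by a descending diagonal and retains a small negative global
correlation (|r| ≲ 0.2), while the X shape's mixture symmetry forces its
global correlation toward 0.

What the generator does *not* emulate: realistic marginal distributions
(zero inflation, bimodality), gene-length or library-size effects, overlap
structure among real gene-set collections, and covariance beyond
equicorrelated blocks. Passing tests therefore demonstrate correctness of
the computations and recovery under controlled rewiring, not performance on
any particular cohort.

## Behaviour at the zero point of the score

The sign of CS(k) is meaningful only when the sub-network's pairs are
locally dependent in at least one condition *at the sample's position*. In
the boundary regime where condition 1 is exactly independent (r₁ = 0) and
condition 2 gains correlation with *unchanged marginals*, the average
joint-box excess near a typical point is slightly positive for the
correlated cloud (for Gaussian clouds, the overlap integral
1/(2π√(4−ρ²)) exceeds the independent value 1/(4π)), so with the rho floor
both conditions' samples acquire a small positive score offset: condition-2
samples score strongly positive, but condition-1 samples hover just above
zero instead of below it. The score distributions still separate almost
perfectly (empirical AUC > 0.95 in the reference scenario) — the *ranking*
is informative — but the raw sign is not a reliable classifier in this
regime at the default b = 0.1. When rewiring co-occurs with an expression
shift of about two marginal standard deviations, as in real
receptor-status programs, sign recovery exceeds 90% in both conditions
(see `tests/test_pipeline.py`). Practitioners scoring marginal-preserving
rewiring should calibrate a decision threshold on reference samples rather
than using zero.

## Problem sizes used in the validation suite

The test and acceptance workloads are sized for a laptop-class single CPU:
the reference scenario (1,000 genes × 400 samples) runs end to end in a few
seconds; the z-test calibration uses 5,000 replicates at n = 200; the
enrichment null-safety check uses 20 replicates at 2,000 permutations each
(raw-p resolution ≈ 5 × 10⁻⁴, comfortably below the 0.01 threshold);
oracle-equivalence checks use 200 random fixtures. Larger cohorts scale as
O(G² n) for the network and O(E · n_cond · n_samples) for scoring.

## Known limitations

- Sub-network choice is driven by one enrichment record at a time; scores
  from overlapping gene sets are correlated and should not be treated as
  independent features.
- The box statistic needs enough samples per condition (tens) for stable
  counts at b = 0.1; very small conditions warrant larger b.
- The z-test assumes within-condition exchangeability; batch structure
  should be removed beforehand.
- Only two-condition designs are supported; multi-condition rewiring
  requires pairwise runs.
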