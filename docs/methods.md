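# Methods

## The problem being modelled

In RNA-seq, only a minority of annotated genes are expressed highly enough
to be measured — typically well under half of a ~39,000-gene human
annotation passes a 10-reads-per-sample filter. Over-representation
analysis implicitly conditions on the background universe: the set of genes
that could have entered the query list. Using the whole annotation instead
of the detected genes therefore changes the null model, and doing so while
also skipping multiple-testing correction compounds the error. The package
implements the correct procedures, the erroneous variants, and the
divergence measures between them.

## Enrichment core

* **ORA** computes the hypergeometric upper tail P(X ≥ k) via the survival
  function (never 1 − CDF, which loses precision in the far tail). The
  set-size window (default K ∈ [10, 500], the defaults of the widely used
  ORA implementations) is applied *before* BH adjustment so the
  multiplicity burden counts only tested sets. Up- and down-regulated DEG
  lists (DE-table FDR < 0.05 split by log₂FC sign, no magnitude cut) are
  tested separately; a result's identity is the (set, direction) pair.
* **Background enforcement** is strict by default: query genes absent from
  the background raise an error. Lenient mode unions them in with a logged
  warning. Silent union would hide precisely the identifier-mismatch and
  background-selection errors the package measures.
* **FCS** ranks genes by sign(log₂FC)·(−log₁₀ p) (p floored at 1e-300;
  the metric is injectable for other choices), assigns midranks to ties,
  and runs a two-sided rank-sum test per set. With both group sizes ≤ 10
  the p-value is exact by enumeration over all C(N, k) equally likely
  member-rank subsets, which remains valid under ties; otherwise the normal
  approximation with the standard tie-correction term and a 0.5 continuity
  correction is used. The signed score s = 2(mean member rank − mean
  rank)/N is bounded in (−1, 1) and its sign defines the reported
  direction. Sets with zero or all detected genes have no rank contrast and
  are skipped (logged), not assigned p = 1, which would distort the FDR
  denominator.
* **BH adjustment** is the step-up rule q₍ᵢ₎ = min₍ⱼ≥ᵢ₎ p₍ⱼ₎·m/j capped at
  1, applied per run (per direction for ORA). It is implemented directly —
  its step-up semantics at discrete, tied p-values are part of what the
  misuse scenarios measure — and cross-checked against
  `statsmodels.multipletests(method="fdr_bh")` in the tests.
* **Significance is strict** (< α, default α = 0.05) in both FDR and
  nominal modes. At exactly α a set is not significant. An inclusive
  boundary is a defensible alternative; strict was chosen and applied
  uniformly so FDR/nominal comparisons are never confounded by boundary
  asymmetry.

## Misuse engine

The canonical grid is FCS, FCS_nom, ORA, ORA_nom, ORA\*, ORA\*nom, where \*
marks the whole-annotation background and `nom` the nominal threshold. FCS
has no background concept (it consumes all detected genes), so FCS ×
whole-annotation configurations are rejected at validation rather than
silently mapped.

Jaccard indices are computed over signed (set, direction) pairs by default;
an unsigned, direction-pooled variant is available via `signed=False` since
either convention appears in practice. A Jaccard of two empty collections
is undefined and propagates as NaN — never 0 or 1, either of which would
bias averages over replicates. The erroneous fraction requires the
FDR-called set to be a subset of the nominal-called set; a violation means
the two collections did not come from the same run and raises.

## Synthetic data generator

The generator emulates a two-group (3 vs 3) bulk RNA-seq contrast:

* **Abundances** are log-normal (σ = 1.6 on the natural-log scale, a
  long-tailed shape typical of bulk RNA-seq), rescaled so the empirical
  (1 − detected_fraction) quantile of true means sits exactly at the
  detection threshold; the realised detected fraction then matches the
  target (default 0.38) in expectation. Counts are negative-binomial with
  dispersion α = 0.05 (var = μ + αμ²), a low-biological-variability
  cell-line-like setting.
* **DE genes** (default 20% of detectable genes, half up, half down) get a
  symmetric half-shift: control means ×2^(∓f/2), case ×2^(±f/2) with
  f = 3 (8-fold), which leaves overall means — and hence detectability —
  roughly unchanged.
* **The DE surrogate** is a moderated pooled-variance t-test on
  log₂(normalized count + 1), counts scaled to the mean library size.
  Per-gene variances are shrunk toward the median gene variance with a
  fixed prior of 4 degrees of freedom (t degrees of freedom = prior +
  residual), in the spirit of empirical-Bayes moderation. An unmoderated
  two-sample t-test at n = 3 + 3 has 2–4 residual degrees of freedom and
  cannot produce small p-values even for large fold changes, which made the
  unmoderated design unable to reach realistic DEG sensitivity; the
  moderated test recovers essentially all planted DE genes at the default
  effect size while staying slightly conservative under the null (~4% of
  null genes at p < 0.05). It is a transparent stand-in that exercises the
  enrichment stages end to end, not a DE method for real data.
* **The library** mixes planted and null sets (default 50 of 500, sizes
  10–100). Planted sets draw 80% of members from true DE genes of one
  direction and the rest from detected non-DE genes. Null sets draw 80% of
  members from detected genes and 20% from undetected ones
  (`null_set_detected_bias`). This bias is deliberate and load-bearing:
  curated pathway databases are strongly biased toward expressed
  protein-coding genes, and that bias is the mechanism of the
  whole-annotation background artefact — any detected-gene query looks
  enriched in any detected-concentrated set when judged against a
  mostly-undetected universe. Had null sets been sampled uniformly from the
  annotation, their detected share would mirror the whole annotation's and
  the hypergeometric test would remain calibrated under either background,
  making the artefact unobservable.
* **Survey records** are Bernoulli draws at per-item rates chosen to match
  the reporting frequencies a literature survey of enrichment analyses
  observes (e.g. ~92% omit the library version, ~46% of test-conducting
  analyses skip FDR correction, ~4% of ORA analyses describe an appropriate
  background; the rate of leaving the statistical test unstated is only
  characterised as "most analyses" in such surveys and is set to 0.65).
  Background fields are drawn conditionally: the appropriateness question
  only arises when a background was defined, and only for ORA analyses —
  non-ORA records carry no background deduction. Journals, SJR values and
  citation counts are generated independently of the scores, so bibliometric
  correlations are near zero by construction.

What the generator does *not* emulate: gene–gene expression correlation
(major real-data caveat for both methods' independence assumptions),
library-size imbalance, batch effects, overlapping/hierarchical gene sets,
and annotation identifier mismatches. Passing tests therefore demonstrate
the statistical machinery and the direction and mechanism of the misuse
effects, not their exact magnitudes on any particular real dataset.

## Survey scoring

"Unknown" answers count as the deduction: the score measures *reporting*,
so absence of evidence is the deficiency. The two background rows ("not
defined", "inappropriate") are mutually exclusive — they grade the same
flaw at different visibility — so the attainable floor is −8 even though
the nominal schema range is [−9, +2]; double-deducting a single flaw was
judged worse than an unreachable floor. Frequencies use item-appropriate
denominators: FDR correction among analyses that conducted a test,
background items among ORA analyses. The citation transform is
log₂(x + 1), since zero-citation articles exist. Correlations are Pearson
with two-sided t-based p-values (df = n − 2); constant inputs yield NaN
rather than an arbitrary value.

## Problem sizes and determinism

Default simulations use 39,000 annotation genes, 500 gene sets and 3 + 3
samples; the acceptance script averages 5 replicates and the test suite
uses 20 replicates for direction checks and scaled-down studies (4,000
genes) for unit tests — sizes at which replicate-to-replicate variation in
the reported quantities is already small. Every stochastic routine takes an
explicit seed via `numpy.random.default_rng`; there is no hidden global
state, and identical seeds give byte-identical CLI outputs.

## Reproducing published analyses from files

The file-based path (`enrichbench scenarios`) reproduces a published
enrichment analysis only as faithfully as its inputs: the counts, the DE
table produced by the original DE tool at its original version, the gene
set library snapshot of the original date, and the annotation list. These
are deliberately inputs, not downloads — the package performs no network
access. Divergences from published numbers trace to those pins, to the FCS
tool's ranking metric (tool defaults vary and are frequently unreported —
itself one of the reporting gaps the survey arm scores), and to the
significance-boundary convention noted above.
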