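# Methods

This note documents the statistical model, the synthetic world, the numerical
choices and the known limitations of the package.  It states no empirical
result that the test suite does not itself compute.

## Experimental design assumed

Five genotypes — two diploid parents (`parentA`, `parentD`), their in-silico
equal-mass mixture (`Mix`), a euploid allotetraploid (`EUP`) and an
HE-carrying allotetraploid (`X190`) — each measured under four conditions
(`mock-2d`, `PEG6000-2d`, `mock-5d`, `NaCl-5d`) with replicated bulk RNA-seq
gene counts against a concatenated A+D reference.  All tetraploid-vs-parent
comparisons use Mix as the parental reference: at fixed sequencing depth a
1:1 read mixture gives every gene half its pure-parent rate, which matches
the per-copy depth of a tetraploid expressing both subgenomes.

## Filtering

Rules are applied in a fixed order and tallied exactly
(`filter_report.tsv`): HE-region genes (any ≥ 1 bp overlap, half-open BED
coordinates), unplaced scaffold genes, then the mean-count screen.  Reading
the removal conditions "below 10 or above 5000" literally, the retained
interval [10, 5000] is closed at both ends.  HE exclusion is applied
identically to euploid and HE-line analyses so the DEG universes coincide.

Two operational choices the underlying design leaves open, both configurable:

* the transcript-length disparity denominator is the **longer** transcript
  (`|l_A − l_D| / max`), the conservative reading (removes more pairs);
* "expressed in at least one subgenome" reuses the gene-level lower bound:
  mean raw count ≥ 10 for at least one copy.

## Differential expression

A deliberately small NB engine with the standard contract:

* **Size factors** — median over genes (with all-positive counts) of
  `count_{g,s} / geomean_g`.  Only factor *ratios* are identifiable: scaling
  one sample's counts by *c* scales that sample's factor relative to the
  others by exactly *c*, while the absolute factors move because the per-gene
  geometric mean moves too.  Factors are reported exactly as the formula
  returns them.  Because every gene is subgenome-specific, pure-parent
  samples contain structural zeros for half the genes; size factors are
  therefore estimated per contrast (over the samples actually compared),
  never over the full genotype panel.
* **Dispersion** — gene-wise method of moments on normalized counts pooled
  within groups, clipped to [1e-8, 10], then shrunk toward a fitted trend
  `α(μ) = a₀ + a₁/μ` (non-negative least squares; median fallback) with
  weight `df / (df + prior_df)`, `prior_df = 10`.  With 3-vs-3 designs the
  raw moment estimate is extremely noisy (df = 4), so the trend dominates;
  this is what makes the Wald test calibrate (the suite checks a null
  type-I error in [0.03, 0.07] at 5000 genes).  Shrinkage can be disabled.
* **Wald test** — `log2FC = log₂(q̂₂/q̂₁)` from group mean normalized counts
  (no shrinkage of the fold change itself), standard error from the NB
  Fisher information `I_g = Σ_j μ_gj/(1 + α μ_gj)` by the delta method,
  two-sided normal p, BH adjustment across tested units, DEG at
  `padj < 0.05` with no fold-change cutoff.
* **Zeros** — a pseudocount of 0.5 normalized counts enters only when a
  group mean is exactly zero; it then necessarily also enters that unit's
  Wald statistic (the information at a zero mean is zero), which makes the
  zero-vs-expressed case conservative but finite.  Units with both group
  means zero report `log2FC = 0, p = 1`.  Non-degenerate units are untouched.
* **Copy contrasts** — the A-copy vs D-copy comparison treats the two
  copies' counts over the *same* samples as the two groups, with those
  samples' size factors.  The upstream 10% length filter is what justifies
  skipping transcript-length normalization here.  BH runs within each copy
  contrast across analyzed pairs only.

No independent filtering, outlier replacement or multi-factor GLM: the
mean-count screen is the only gene screen, matching the analysis contract
this package implements.  `pydeseq2` (an independent NB-GLM implementation)
is used in the test suite as a cross-check oracle on a small fixture, never
as the engine.

## Mode classification

The parental A-vs-D contrast is computed **within Mix samples**, the progeny
contrast within the tetraploid's samples, same condition, making the two
calls structurally symmetric.  The 3×3 table of calls maps to modes 1–9;
regulation types group modes (1–3 conserved, 4–5 convergent, 6–7 divergent,
8–9 reversed).  Relabeling the subgenomes permutes modes 1↔2, 4↔5, 6↔7, 8↔9
exactly, because swapping the contrast groups negates the log fold change
and leaves the p-value unchanged — the suite asserts this pair by pair.
Summary percentages are rounded half-up to two decimals, the convention of
published mode-summary tables.  Mode attribution labels each copy up / down
/ unchanged from the gene-level progeny-vs-Mix test at `padj < 0.05`; copies
that failed the gene-level expression screen are labeled unchanged.

## Synthetic world

The generator is first-class, tested code; its defaults are the stated
conditions of the emulated design.

* 3000 homoeolog pairs on 7 chromosomes per subgenome (750 Mb each, genes
  evenly spaced, pair members collinear), 150 singletons and 25 unplaced
  scaffold genes per subgenome.
* Planted per-condition mode proportions default to the euploid columns of
  the published-style summary table (e.g. ~60% mode 3 under mock, more
  modes 1–2 under stress).
* Fold magnitude 4 for every unequal state; conserved pairs transmit the
  parental ratio unchanged; convergent/divergent transitions are realized by
  changing the A copy only, the D copy only, or both (probabilities
  0.45/0.45/0.10 — one-copy changes dominate, as observed in this kind of
  data); reversed modes must move both copies.
* Counts are gamma-Poisson: `NB(mean = rate × library factor × copy-number
  multiplier, dispersion 0.05)`, 3 replicates per group, library factors
  log-uniform in [0.7, 1.4].  Pure parents express only their own subgenome
  at twice the Mix rate; `X190` multiplies genes inside the default HE
  intervals (Chr2A 0.8–51.8 Mb and Chr3A 684.6 Mb–end duplicated ×2;
  Chr2D 0.4–58.0 Mb and Chr3D 557.4 Mb–end deleted ×0).
* Baseline rates are log-uniform on [60, 1000] with planted clearly-low
  (1.5) and clearly-high (60000) fractions.  The ranges are chosen so that
  after the fold structure (per-copy rates span base/4 … base×4) every
  gene's expected mean count stays many standard deviations away from the
  10 and 5000 thresholds; the truth table's expected-mean filter rule and
  the realized-count rule then agree, which is what makes exact
  truth-vs-filter tally tests meaningful.
* A planted fraction of pairs (default 20%) violates the 10% length rule by
  construction (length ratio drawn in [0.70, 0.85] vs [0.92, 1.0]), so the
  violating set is known exactly.
* The GO map assigns ~2 background terms per gene at random plus one
  designated term whose odds are inflated (default ×8) for truly changed
  genes.
* One master seed; per-stage sub-streams derived via `SeedSequence.spawn`,
  so byte-identical outputs per seed and stage-level reproducibility.

What the generator does **not** emulate: read-level noise and mapping
artifacts, isoforms, correlated expression across conditions or co-regulated
gene modules, GO-term correlation structure, and partial (heterozygous) HEs.
A green recovery test therefore establishes that the statistics recover the
planted generative structure, not that they are robust to real-data
artifacts outside that structure.

## Numerical choices and degenerate inputs

* Dispersion floor 1e-8 (constant counts), ceiling 10.
* BH via the standard step-up implementation (`statsmodels`), validated in
  the suite against a brute-force transcription of the rule.
* Hypergeometric upper tails via `scipy.stats.hypergeom.sf(k−1, N, K, n)`,
  validated exhaustively against `math.comb` enumeration for all N ≤ 25.
* Enrichment output ordering is deterministic: (padj, term id).
* Empty DEG sets, empty mode tables and empty tracks all produce well-formed
  empty/zero outputs rather than errors.
* Replicate count per group is configurable (default 3) — the emulated
  design does not pin it down.

## Known limitations

* The Wald test assumes a common dispersion per unit across groups and a
  log-normal-ish sampling distribution of group mean ratios; at n = 3 it
  leans on dispersion-trend shrinkage for calibration and will be optimistic
  if the mean–dispersion relationship is strongly non-monotone.
* Mode calls inherit the multiple-testing behaviour of two BH-corrected
  contrasts: with many true effects, BH's per-test threshold loosens and a
  small excess of spurious non-conserved (especially "reversed") calls over
  the planted proportions is expected.
* No GO-graph propagation; annotations are taken as given.
* The pipeline is two-group only by design; multi-factor models, outlier
  moderation and fold-change shrinkage are out of scope.
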