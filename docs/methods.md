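# Methods

## The calling procedure

`dmrkit` compares exactly two whole-genome bisulfite libraries — a baseline
(sample A, "wild type") and a contrast (sample B, "mutant") — one library
per genotype, with no replicate model. The unit of evidence is the
per-cytosine 2×2 count table (methylated/unmethylated reads in A vs B),
and the unit of discovery is a genomic window.

1. **Coverage filter.** Only cytosines covered by at least `min_cov`
   (default 4) reads are used. The filter is applied in *both* libraries:
   a site that is untestable in either sample cannot contribute to a
   two-sample contrast, so the one-library reading would only add
   untestable noise to the pools.
2. **Windowed testing.** Counts are pooled in `window_bp` = 200 bp windows
   sliding by `step_bp` = 50 bp (windows start at every multiple of the
   step below the chromosome length; the trailing frames are clipped).
   Each window with pooled coverage in both samples receives a two-sided
   Fisher exact p-value; empty windows are dropped before testing.
3. **FDR and effect size.** Window p-values are Benjamini–Hochberg
   adjusted in one family per run — genome-wide, across both eventual
   directions, within one context mode — and windows are retained when
   q < 0.01 *and* the methylation-level fold change exceeds 2
   (fold = larger level / smaller level; infinite when the smaller level
   is exactly 0, undefined — hence rejected — when both are 0; no
   pseudocounts).
4. **DMC refinement.** Retained windows overlap by construction (50 bp
   step), so same-direction overlapping or book-ended windows are unioned
   into maximal candidate regions before counting evidence. Every
   qualifying cytosine inside a candidate region is tested individually;
   a site with raw (unadjusted) Fisher p < 0.01 whose own change matches
   the region's direction is a differentially methylated cytosine (DMC).
   DMC p-values are deliberately raw: the window family already controls
   the FDR of the discovery step, and the DMC step is a within-region
   refinement.
5. **Retention, merging, trimming.** Regions with fewer than 7 DMCs are
   dropped; surviving same-direction neighbours merge while the gap
   (next start − previous end, half-open coordinates) is strictly below
   100 bp; each final region is trimmed to start at its first DMC and end
   after its last one, and its pooled levels and fold change are
   recomputed over the trimmed span. Trimming can only shrink regions, so
   same-direction output regions always sit ≥ 100 bp apart.

Direction ("hyper"/"hypo") is sample B relative to sample A and is decided
by the pooled levels; significance always comes from the two-sided test,
so swapping the samples mirrors every call exactly.

### Numerical choices

- The two-sided Fisher p is the sum of hypergeometric probabilities of all
  tables with the observed margins that are no more probable than the
  observed table. Probabilities within a relative factor 1 + 1e−7 of the
  observed one count as ties (the same convention scipy uses). For the
  totals a per-cytosine table can reach, distinct hypergeometric
  probabilities within one margin family are separated by at least
  1/C(N, c₁), orders of magnitude more than the tolerance, so exactly the
  true ties are included; the test suite verifies equality with exact
  rational enumeration for all tables with total ≤ 30.
- The p-value loop runs on a shared log-factorial (gammaln) table rather
  than through per-call scipy objects: one run tests tens of thousands of
  windows. Per-site p-values are memoised, since site-level tables repeat
  heavily at moderate coverage.
- All significance comparisons are strict (<), the fold threshold is
  strict (>), and the merge gap is strict (< 100 bp), matching the
  procedure's wording; ties therefore never pass.
- Sites and windows are processed in (chrom, position, strand)
  lexicographic order and every output is sorted, so results are
  byte-deterministic for identical inputs.

### Coordinates and strand

Cytosine reports and GFF3 are 1-based; everything internal and all BED
output is 0-based half-open. The two strands are independent sites
throughout: symmetric CG pairs are *not* pooled, the conservative reading
of a per-cytosine analysis. Context follows the plant convention (CG, CHG,
CHH with H ∈ {A, T, C}) read 5'→3' on the cytosine's own strand; a
cytosine whose deciding context base is missing (chromosome end) or N is
skipped rather than guessed.

## The synthetic methylome generator

The simulator produces the two-genotype comparison the caller is built
for, with Arabidopsis-like structure at desk scale:

- a random genome at GC fraction 0.36 with non-overlapping gene and TE
  intervals (a configurable fraction of TEs nested in genes);
- feature-class base methylation per context — TE: CG 0.85, CHG 0.60,
  CHH 0.15; gene body: CG 0.30, CHG 0.02, CHH 0.02; intergenic: CG 0.10,
  CHG 0.02, CHH 0.02. These are simulator conventions reflecting the
  qualitative biology (TE-dense heterochromatin carries all three
  contexts, gene bodies mainly CG), not measured values;
- per site and sample, a latent level drawn from Beta(p·k, (1−p)·k) with
  precision k = 50 — real bisulfite data are overdispersed relative to
  binomial, and a pure binomial simulation would flatter the caller;
- coverage Poisson around 20× per sample (sites drawn below `min_cov`
  exercise the coverage filter naturally), methylated counts binomial.

Truth regions override sample B's latent base level for the affected
contexts; sample A keeps its feature-class base unless the request pins
`level_a` explicitly (used by the validation experiments, which implant
0.05 → 0.9 shifts regardless of the underlying feature class). Truth
regions are returned with realized baseline levels and feed
`evaluate_recovery`, which matches called regions to truth by
same-direction overlap (≥ 1 bp by default, or a fraction of the truth
length).

What the generator does **not** emulate: read-level artefacts (mapping
bias, incomplete bisulfite conversion, PCR duplicates), strand-coupled CG
methylation, spatial autocorrelation of methylation outside implanted
regions, and replicate structure. Passing recovery tests therefore show
that the algorithm finds the differential signal it is defined to find
under overdispersed counts — not that it is robust to alignment artefacts
or biological replication variance.

## Validation experiments and problem sizes

The package validates itself end to end at sizes chosen to keep the whole
suite comfortably interactive:

- exactness of the Fisher primitive for all 2×2 tables with total ≤ 30
  against exhaustive rational enumeration, and of BH against the step-up
  closed form on 1,000 random vectors;
- implant recovery: 1 Mb genome, 20× coverage, ten 400 bp hyper implants
  (0.05 → 0.9, ≥ 10 CG sites each), ten seeds, default parameters —
  average precision and recall both ≥ 0.9 (observed 1.0);
- null calibration: the same simulation with no implants over twenty
  seeds — the fraction of seeds yielding any DMR must stay ≤ 5%
  (observed 0). The ≥ 7-DMC requirement at site p < 0.01 is the
  conservative stage: window-level overdispersion occasionally produces a
  significant window, but seven individually significant same-direction
  cytosines essentially never arise under the null at 20×;
- equivalence with an independent straight-line reimplementation of the
  procedure on twenty random 5 kb instances (identical coordinates,
  directions, DMC counts);
- structural invariants of every DMR over fifty fuzzed simulations, and
  byte-level determinism of the CLI.

`scripts/acceptance.py` re-runs the recovery, null and a two-mutant
overlap experiment (two contrasts sharing 70% of their implants, measured
by `venn_classify`) from scratch under a user seed.

## Open design points and how they were resolved

- *Pooled counts vs combined p-values per window*: counts are pooled —
  the only reading under which a single window-level 2×2 Fisher table
  exists.
- *"First/last 5mC" trimming*: interpreted as first/last **DMC**.
  Trimming to differential evidence is what makes the adjusted boundaries
  meaningful; trimming to any methylated cytosine would leave boundaries
  dependent on non-differential background methylation.
- *BH family*: one family per run (context mode), hyper and hypo jointly,
  over testable windows only.
- *Venn membership*: same-direction overlap of ≥ 1 bp by default — the
  weakest consistent rule — exposed as `min_overlap_bp`.
- *Feature classes*: the four location classes (TE overlapping gene, TE
  outside gene, gene body, intergenic) are made exclusive by precedence
  in that order; TE wins over gene body because TE methylation pathways
  dominate wherever a TE is present.
- *Chromosome distribution* counts each DMR once, at its midpoint.
- *TE length strata* default to boundaries at 500 bp and 4 kb (short /
  medium / long), configurable.

## Known limitations

- No replicate handling and no dispersion-aware test: the Fisher test
  treats read counts as binomial within each library, so with genuinely
  replicated data a beta-binomial caller would be better powered and
  better calibrated. The ≥ 7-DMC rule is what keeps the false-positive
  rate low here.
- BH is applied to heavily overlapping (hence correlated) windows; the
  procedure inherits this property by design.
- Fold change with a zero denominator is infinite, so regions appearing
  from (or vanishing to) complete unmethylation always pass the fold
  filter; with no pseudocount this is the faithful reading of the bare
  2-fold rule.
- The caller loads both methylomes into memory (a few hundred MB for a
  full plant genome at single-cytosine resolution); it is not streamed.
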