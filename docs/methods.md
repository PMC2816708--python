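# Methods

`eboxlink` re-implements, as a tested library, a promoter-regulatory analysis
workflow for linking a drug-responsive gene set (rapamycin/mTORC1 inhibition
in paired rat cell lines) to transcription-factor control, in particular the
c-Myc/Max network and its canonical E-box element CACGTG.  The pipeline has
five analytical stages — motif over-representation in promoters, E-box
positional analysis, differential-expression set logic across two cell
lines, gene-set overlap enrichment against a clustered target catalog, and
pathway enrichment with bipartite network reconstruction — plus a
synthetic-data generator that produces every input with known ground truth.

## Promoter windows and coordinates

Genomic coordinates are 0-based half-open (BED native).  The TSS base is the
first downstream base, so a window of `window_up` upstream and `window_down`
downstream bases has length exactly `window_up + window_down`.  Two presets
are used: the proximal preset (−1000/+200) for motif over-representation and
the wide preset (−3000/+500) for E-box positional analysis.  Minus-strand
windows are reverse complemented so promoter sequences always read 5′→3′ on
the gene strand; offsets are signed bp relative to the TSS (upstream
negative).  Promoters are taken from a local FASTA + BED6 pair rather than a
remote annotation service — a deliberate substitution that makes runs
reproducible and self-contained.  One TSS per gene is assumed.

## PWM scanning and the hit rule

Matrices are position frequency matrices over (A, C, G, T), built from
TRANSFAC-flat or JASPAR count blocks with a pseudocount (default 0.01)
distributed proportionally to the background base frequencies.  The
background model is order-0 (a 4-vector of base probabilities), either
supplied directly or estimated by counting over a background promoter FASTA;
order-0 was chosen because it matches the expected-frequency model used by
the over-representation stage and keeps the brute-force oracle analytic.

A window `x` of motif width is a hit iff

    log P(x | motif) − log P(x | background) > log((1 − prior) / prior),

i.e. iff the posterior odds of "site" versus "background" exceed 1 when
every window carries prior probability `prior` of being a site.  The default
prior is 0.1, the setting used for the promoter scans this package
emulates.  The original scanner's exact internal threshold function is not
documented; this posterior-odds rule is our committed interpretation and is
deliberately exposed as a single interpretable knob.  Both strands are
scanned (minus strand by reverse complementing the window against the same
matrix); for strand-symmetric matrices the minus pass would duplicate every
hit and is skipped.  Windows containing N are skipped and tallied in the
debug log.  Overlapping hits are all reported — real promoter hit tables
contain nested and overlapping site variants.

Consensus scanning (used for the canonical E-box) is exact IUPAC matching;
windows containing N never match, and self-reverse-complementary patterns
such as CACGTG are reported once per position.

## Motif over-representation

For each matrix, the expected hit rate per promoter is estimated by scanning
a background promoter collection with identical parameters; rates are
rescaled per-bp when foreground and background window lengths differ.  The
observed foreground count of hit *instances* (`n`, not promoters-with-a-hit)
is tested against Binomial(g·W, r/W) — g foreground promoters, W scanned
windows per promoter, r expected rate — with an exact upper tail
P(X ≥ n); above 10⁶ trials a Poisson tail with λ = g·r is used.  The
per-matrix report score is

    significance = −log10(probability × n_matrices_tested),

a Bonferroni-style transform that is positive exactly when the corrected p
is below 1.  The multiplier is the number of matrices scanned in the run and
is echoed in the output metadata.  (Back-calculation from the five published
probability→significance pairs this package's report format mirrors is
consistent with a multiplier of 264; that value is a consistency
observation, not a constant of the method.)  A probability that underflows
to exactly 0 is capped at significance 350 with a warning.

## E-box positional analysis

Canonical E-boxes are located by exact matching in wide-preset promoters.
Positional density is a 50-bp-bin histogram normalized to integrate to 1,
with an optional Gaussian kernel (Silverman bandwidth) for plotting; the
estimator behind the published density curves is unstated, so both are
available and the bin width is recorded in output metadata.  Per-promoter
count distributions are compared between up- and down-regulated groups with
a two-sided Fisher exact test on the 2×2 table {≥k, <k} × {up, down};
k defaults to 2 (the "promoters with two E-boxes" contrast) and both k and
the table construction are parameters rather than a single hard-wired
choice, because the original table construction is not recoverable.

## Differential expression

Per-gene two-sample t-tests use pooled variance (df = n₁+n₂−2) by default —
the classical choice for triplicate arrays — with Welch available by flag.
Genes with zero within-group variance and zero mean difference get p = 1.
P-values are Benjamini–Hochberg adjusted (statsmodels step-up).  A gene is
called differentially expressed iff |linear fold change| ≥ 1.2 AND raw
p ≤ 0.01 AND BH q ≤ 0.05; the two p-value rules are composed as a
conjunction since the filter description lists both, and composition order
cannot change the surviving set.  Fold changes are displayed in the
signed-reciprocal convention (ratio 0.61 → −1.64).  A one-way F-test screen
across ≥2 experimental groups (with BH) is provided, flag-gated, as an
explicit stand-in for the unnamed multi-group statistic behind
"significant anywhere across four groups" gene sets; it is not claimed to
replicate that statistic.  `median_center` centers each gene's ratios to
median 0 across analyses.  `cross_compare` decomposes two cell lines' DE
calls into exclusive/shared sets and splits shared into co-up, co-down and
opposite; the invariant |shared| = |co-regulated| + |opposite| is enforced
by construction.

## Gene-set overlap enrichment

Probe lists are first collapsed to unique genes through a probe→gene mapping
so multi-probe genes cannot inflate intersections.  The expected overlap of
a responsive set with a catalog scope (whole catalog or one cluster) is the
hypergeometric mean |responsive ∩ U|·|scope|/|U| over a *declared* universe:
the universe is a required, logged input, never implicit, because expected
counts are meaningless without it.  Observed vs expected is tested with a
1-df goodness-of-fit chi-square on the target/non-target split of the
responsive set (no continuity correction) — the only framing consistent with
reporting (observed, expected, total) triples.  Direction splits of each
overlap (how many overlap genes were up vs down) are reported descriptively
with a two-sided binomial sign test, since the original statistic for those
splits is unstated.  Control catalogs (e.g. an unrelated transcription
factor's target list) run through identical machinery.

## Pathway enrichment and bipartite network

Pathways are read from GMT.  Each pathway is tested with a one-sided Fisher
exact test on the (in-pathway × significant) 2×2 table over the declared
universe; raw and BH-adjusted p-values are emitted side by side because the
correction behind published "corrected" pathway p-values is unstated.
Pathway direction is the majority sign of its significant genes (ties
labelled "mixed").  The bipartite network contains a node for every pathway
with ≥1 significant member gene and an edge for each (significant gene,
containing pathway) pair; a gene's hub score is its degree, and "critical"
genes are those connected to ≥k significant pathways (default 2), ranked by
hub score.  This commits to a specific reconstruction — the published
network method is cited to external work — and outputs are labelled
accordingly.

## Synthetic data generator

Every generator is a pure function of (parameters, seed): one fresh numpy
`Generator` per call, no global state, so identical inputs give
byte-identical outputs, and every planted truth entry is re-derivable from
the emitted files alone.

* **Genome/TSS**: one i.i.d. order-0 chromosome; TSS placed with margins
  wide enough that every gene admits the −3000/+500 window on either strand.
* **Motif planting**: overwrites bases (never inserts, so coordinates never
  shift) at offsets drawn uniformly, at a fixed offset, or from a normal law
  peaked near the TSS (default −50 ± 30 bp, emulating the observed
  concentration of E-boxes within ~100 bp upstream of the start site);
  out-of-window draws are resampled with a bounded retry count.
* **Expression**: genes × 2·n_reps log2 matrix; defaults are three
  replicates per condition, 5% of genes shifted by ±1 log2 unit, and
  replicate noise of 0.25 log2 units — the documented design of the
  two-condition triplicate experiments this generator stands in for.
* **Target catalog**: disjoint clusters sampled without replacement in
  cluster order, with responsive genes weighted by an enrichment factor
  (1 = independence null, 0 = exclusion); default cluster sizes
  (1712, 1643, 616, 178, 30) mirror the five usable temporal-response
  clusters of the emulated c-Myc target catalog.
* **Pathways**: uniform draws from the universe, with a configurable number
  of pathways oversampling a significant set.

The generator does **not** emulate probe-level intensities, normalization
artifacts, batch effects, correlated genes, or heteroskedastic noise.
Passing tests therefore demonstrate correctness of the statistical machinery
under idealized sampling assumptions, not robustness to real microarray
pathologies.

## Numerical choices

Exact tails throughout (scipy `binom.sf`, `chi2.sf`, `fisher_exact`,
`hypergeom`); no normal approximations at desk scale.  Matrix rows must sum
to 1 within 1e-9 after pseudocount normalization; background frequencies
must be strictly positive (log-odds undefined otherwise).  Deterministic
orderings everywhere a table or graph is emitted (matrix id, pathway id,
alphabetical tie-breaks in critical-gene ranking).  Degenerate inputs —
empty promoter sets, zero-width windows, all-N windows, empty catalogs —
return empty results rather than errors wherever a count of zero is
meaningful, and raise `ValidationError` where a statistic is undefined.

## Known limitations

* **DE recovery power.**  Under the generator's default expression
  conditions (triplicates, 0.25 log2 replicate noise, 2-fold planted
  effects, 10,000 genes), the full filter cascade has essentially no power:
  a pooled t-test with 4 degrees of freedom gives planted genes raw
  p ≈ 8×10⁻³, while the BH step-up over 10,000 genes requires roughly
  p ≤ 0.05·k/m, and the step-up has no useful fixed point — observed
  sensitivity is ~0.2% (a noncentral-t calculation confirms that even the
  raw p ≤ 0.01 gate alone passes only ~55% of planted genes).  This is a
  property of small-replicate genome-wide designs, not an implementation
  defect; the acceptance suite documents it as a failing sensitivity check
  rather than weakening the conditions.  Detecting 2-fold effects at ≥90%
  sensitivity under these filters would require replicate noise ≲0.12 log2
  units or moderated-variance test statistics, both outside this package's
  remit.
* The chi-square goodness-of-fit treats the responsive set as a binomial
  sample from the universe; for responsive fractions ≳10% of the universe
  the neglected finite-population correction makes it slightly conservative
  (observed null rejection ≈3–4% at nominal 5%).
* Cluster-level published significance claims of the emulated study are not
  all reproducible under the goodness-of-fit framing (one printed "P<0.05"
  for a 44-observed/37-expected cluster corresponds to p ≈ 0.24 here); the
  original construction is unknown and deliberately not imitated.
* The over-representation binomial ignores the weak positive dependence of
  overlapping scan windows; its null calibration is verified by simulation
  (rejection rate within 0.05 ± 0.02 across 400 null replicates) rather
  than assumed.

## Problem sizes used in the test and acceptance suites

Oracle-equivalence checks run on 200 random 1.2-kb promoters (PWM scan vs
exhaustive enumeration), all 2×2 tables with margins ≤12 (Fisher), binomial
tails to n = 20, and 500-element p-vectors (BH).  Calibration studies use
400 null matrix-set replicates (300 background + 50 foreground promoters
each), 200 null catalog replicates over a 5,000-gene universe, and 400 null
pathways over a 4,000-gene universe.  Recovery studies use 500 wide-preset
promoters (positional), 10,000 genes (DE), a 5,000-gene universe with a
1,000-gene catalog at 2× enrichment (overlap), and a 12-pathway network with
a planted hub (criticality).  These sizes were chosen to keep each study's
Monte-Carlo error well inside its tolerance band.
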