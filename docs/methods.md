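# Methods

## Model

`regset` tests annotation terms for over-representation in an input list
drawn from a finite background of `M` elements. A term occupying `n`
background elements, an input of `N` background elements and an overlap of
`x` form the contingency counts of a sampling-without-replacement model.

Two sampling models are implemented:

* **Central hypergeometric** (Fisher exact): every background element is
  equally likely to enter the input. `p(x) = C(n,x)C(M−n,N−x)/C(M,N)`.
* **Wallenius noncentral hypergeometric**: in-term elements carry odds `w`
  against out-of-term elements in each sequential draw,

  `p(x) = C(n,x) C(M−n,N−x) ∫₀¹ (1−t^{w/D})^x (1−t^{1/D})^{N−x} dt`,
  `D = w(n−x) + ((M−n)−(N−x))`.

Both tests are one-sided upper tails `P(X ≥ x)` including the observed
point; depletion is never tested. Terms with `x = 0` or `n = 0` after
universe intersection are not tested and do not enter the multiplicity.
FDR (Benjamini–Hochberg) is applied per database over the tested terms;
co-annotation runs correct within the co-annotation result set. P-values
are floored at 1e-300 so TSV output round-trips.

The Wallenius model addresses a concrete failure of the central test: a
target-gene list projected from miRNAs/TFs/CpGs over-samples genes with
many regulators (or probes, or length), so terms concentrated on such
genes reject far too often under the uniform-sampling null.

## Probability weighting function (PWF)

The per-gene selection probability is estimated by a monotone logistic
spline: the binary indicator (1 = gene is in the input / is a target of
the input) is regressed on the bias covariate via a cubic B-spline basis
re-parameterised in integrated ("I-spline") form — intercept plus
cumulative basis columns, each nondecreasing in the covariate. Nonnegative
bounds on the non-intercept coefficients (L-BFGS-B on the penalised
logistic likelihood, ridge 1e-6) make the fitted curve nondecreasing by
construction, the shape constraint the selection mechanism justifies:
more regulators can only make selection more likely.

* basis size 6 (three interior knots at covariate quantiles), configurable;
* covariate per input type: regulator count per gene (miRNA/TF), probe
  count per gene (CpG), gene length (genes) — always computed on the full
  interactome/platform map, not just input hits, because the bias is a
  property of the measurement system;
* degenerate covariates (< 3 distinct values) fall back to the constant
  weight `mean(membership)`; a failed constrained fit falls back to
  isotonic regression with light rank-window smoothing (same contract:
  monotone, bounded);
* weights are clamped to [1e-6, 1−1e-6]; genes with equal covariate values
  share one weight.

The per-term odds are `w = mean(weight | in term) / mean(weight | out of
term)` — a ratio of average bias scores. An `odds-of-means` variant
`(p̄_in/(1−p̄_in))/(p̄_out/(1−p̄_out))`, the form used by the GOseq
lineage, is available behind `--odds-mode`; the ratio-of-means is the
default. `w` is clamped to [1e-3, 1e3], which keeps `D` and the integrand
well conditioned.

## Numerical evaluation of the Wallenius integral

The integral is evaluated per outcome, in log space throughout (the
binomial prefactor and the integral can overflow/underflow double range
separately while their product is a probability):

1. substitute `t = s^c` with `c = max(1, D, D/w)`. All exponents of the
   transformed integrand `c·s^{c−1}(1−s^{wc/D})^x(1−s^{c/D})^{N−x}` are
   then ≥ 1, removing endpoint cusps that defeat polynomial quadrature;
2. scout the log-integrand on a dense grid (201 uniform + 2×60 geometric
   points hugging both endpoints), keep the contiguous region within 46
   nats of the maximum (mass outside < 1e-20 of the peak);
3. integrate with 12 composite 24-point Gauss–Legendre panels over that
   region, shifted by the scouted maximum.

Against exact rational arithmetic (w = 1), scipy's independent
implementation and a sequential biased-urn simulation, the evaluator is
accurate to ~1e-12 relative error across `M` up to several thousand and
`w` across the full clamp range; pmfs normalise to 1 within 5e-15 on the
exhaustive small-`M` grid. Tail p-values sum per-outcome pmfs from `x`
upward with early termination once terms fall below 1e-18 and 1e-12 of the
running sum.

## Co-annotation mining

Input elements become transactions (their term sets, namespaced
`source:term`, at most two sources). An FP-tree with header table ordered
by descending support (ties lexicographic — fixed for determinism) yields
all frequent itemsets; closed sets are those with no equal-support proper
superset, maximal sets those with no frequent proper superset. Support
thresholds round **up** from the fraction ("minimum number of elements"
semantics), default 10 % of the input list; inputs are capped at 1000
elements and two sources because itemset counts grow combinatorially.
Mining is exact, so worst-case cost is exponential in the largest
transaction; at the enforced input caps this is not a practical concern.

Each mined co-annotation is tested as one composite term. Its background
set is the **intersection** of the member terms' element sets (elements
annotated with *all* members), consistent with the support definition on
the input side; a union variant is available behind
`composite_background="union"` since the right construction is a genuine
design choice. Singleton co-annotations reproduce the corresponding
singular rows exactly (up to the FDR multiplicity).

## Synthetic data

The fixture generator emulates the structure that creates selection bias,
not the nomenclature of real databases:

* **Interactome** — regulator out-degrees from a discretised Pareto(α),
  scale 5, truncated to [1, n_genes] (`power_law`), or a fixed out-degree
  (`uniform`). In power-law mode genes also carry Pareto popularity
  weights and regulators attach preferentially, which is what makes the
  per-gene regulator count heavy-tailed — out-degree skew alone would
  Poissonise it away.
* **Annotations** — with coupling β, term genes are sampled with
  probability ∝ (1−β) + β·regulator_count(g); β = 0 gives unbiased terms,
  β = 1 terms concentrated on heavily-targeted genes.
* **Null inputs** — uniform regulator samples without replacement, the
  randomised control against which false-positive rates are measured.
* **miRNA map** — toy precursors with one or two -5p/-3p mature arms.

All randomness flows from the explicit config seed; identical configs give
byte-identical files. The generator does not mimic real GO term-size
distributions, overlapping term hierarchies, or miRBase naming; passing
tests demonstrate the statistical mechanism (bias in, correction out), not
performance on any particular organism's databases.

Validation sizes, chosen to keep the full suite in a few minutes on one
CPU: exhaustive exactness grids at `M ≤ 15`; urn comparisons at `M ≤ 30`
with 200 000 replicates; PWF recovery on 2000 genes against a logistic
selection curve; false-positive rates on a 1000-gene, 200-regulator,
50-term fixture over 500 null inputs of 10 regulators each, at α = 0.05 on
raw p-values. Under full coupling the naive hypergeometric rejects ~15 %
of null term-tests while the Wallenius pipeline stays near the nominal
5 % band; with coupling off the two tests agree to well under two
percentage points.

## Design decisions and limitations

* The universe scope defaults to `annotated` (per selected database);
  `whole` takes a catalogue file, `custom` a user list. After database
  transformation the miRNA-space "whole" universe is the interactome's
  regulator set — the gene-space definitions mirrored symmetrically.
* Tied results order deterministically by (padj, p, term_id); result files
  are byte-stable across processes (all float reductions iterate in sorted
  order).
* The miRNA converter handles precursor↔mature expansion only; family
  expansion (miR-1 → mir-1-1, mir-1-2) is database-version dependent and
  left to the user.
* Unmapped input identifiers warn and are excluded from `N` rather than
  failing the run; the QC report carries the counts.
* The spline basis dimension and ridge strength are defaults, not fitted;
  extremely discrete covariates (many ties) lean on the equal-value
  weight-sharing rule.
* Composite-term testing inherits the conservativeness of testing
  intersections: heavily overlapping members give small composite sets and
  discrete, conservative tails.
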