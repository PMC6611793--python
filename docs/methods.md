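# Methods

## The problem

Curated gene sets (e.g. the 50 MSigDB Hallmark collections, 30–200 genes
each) describe biological processes, but only some of them carry enough
coordinated expression signal to distinguish tissue or tumour classes in an
RNA-seq matrix — and within a useful set, a minority of genes usually carry
most of that signal. `genesieve` answers two questions: *does this gene set
classify better than chance?* (Phase I) and *which of its genes do the
work?* (Phase II).

## Classification potential

The unit of measurement throughout is the **classification potential** of a
gene list: the mean top-1 held-out accuracy of a classifier over `n_runs`
random stratified 70/30 train/test partitions of the samples. Run *r* uses
seed `rng_seed + r`, so any logged evaluation can be replayed. Each gene is
z-scored with statistics fitted on the training partition only (a constant
training gene maps to zeros); no test information reaches the scaler.

Splits are stratified by class with largest-remainder apportionment, each
class contributing at least one sample to both partitions (this requires
every class to have ≥ 2 samples; unstratified splitting is available but
can orphan small classes). Stratification is a deliberate choice: the
protocol only requires *random* partitions, but real compendia have classes
with a handful of samples.

Two classifier backends:

* **`mlp`** — three hidden layers of 512/256/128 ReLU units, Adam at
  learning rate 0.001, softmax output sized to the number of classes
  (scikit-learn `MLPClassifier`; `epochs` and `batch_size` are exposed
  because no canonical values exist — defaults 30 and 128 converge on
  desk-scale data).
* **`linear_fallback`** — multinomial logistic (softmax) regression,
  zero-initialized and trained full-batch with a fixed budget of 80 Adam
  steps at learning rate 0.1 (L2 1e-3), in float32. There is no stopping
  tolerance, so the op sequence — and hence the result — is bit-identical
  on replay. The step budget sits well past the point where subset
  *rankings* stop moving (rank correlation > 0.998 against a 3× budget on
  planted-signal fixtures). Because it is written as batched matrix
  products, it scores hundreds of equally-sized gene subsets in one pass,
  which is what makes exhaustive subset enumeration affordable on one CPU.
  All determinism guarantees (replayable logs, byte-identical reruns) are
  stated for this backend; the MLP mirrors the reference architecture for
  fidelity runs.

## Phase I — the random-set screen

A gene set of size *n* is compared against `n_random_sets` (default 50)
random gene sets of the same size drawn uniformly without replacement from
all genes in the matrix (the tested set is not excluded from the universe;
an `exclude` option exists). The set and its background are evaluated on
**shared** bootstrap partitions — a paired design in which split-to-split
noise is common mode and cancels from the comparison; it is also what lets
all 51 evaluations run as one batched fit.

Significance is a one-sided Student *t*-test of the observed classification
potential (OCP) against the empirical distribution of the random-set means
(the background potential, BCP):

    t = (OCP − mean(BCP_j)) / (s_B · sqrt(1 + 1/m)),   df = m − 1,

with `s_B` the sample SD of the *m* random-set means. The set's own per-run
accuracies are deliberately **not** used as a dispersion estimate: bootstrap
runs share most of their training samples, so their spread reflects split
noise only and omits the between-set variance that dominates under the
null; a two-sample construction built on them is structurally
anti-conservative (measured null false-positive rate 0.06–0.09 at
alpha = 0.01 versus 0.02 for the one-sample form, under the calibration
benchmark below). A set is **significant** when `p < alpha` (default 0.01)
*and* its OCP exceeds the mean BCP. No multiple-testing correction gates the
screen (matching the raw per-set threshold of the original protocol); a
Benjamini–Hochberg column is reported for reference.

## Phase II — combinatorial decomposition

For a significant set of *n* genes, all C(*n*, *k*) subsets are enumerated
and scored exhaustively for *k* = 1, 2, 3 (configurable; a budget guard
lowers the exhaustive depth with a warning if C(*n*, 3) exceeds
`exhaustive_budget`). From then on, iteration *k* → *k*+1:

1. the **M** highest-accuracy subsets (default 60; ties broken by
   lexicographic tuple order so replays are deterministic), plus
2. **M/2** subsets drawn uniformly at random from the remaining evaluated
   records (diversity seeds; drawn from the iteration's own repository so
   the log stays self-contained),

are each extended by every absent set gene, giving at most
(3/2)·M·(*n* − *k*) children of size *k*+1; duplicates are removed by
sorted-tuple key and the unique children are scored. A 36-gene set thus
produces 7140 exhaustive triples and then 90·33 = 2970 children of size 4.
The loop ends at *k* = *n* (the full set, one subset). Every evaluated
subset is logged with its accuracy. Subsets of different sizes can never
coincide, so nothing is ever re-trained.

## Candidate selection

For each iteration the frequency of every gene over all evaluated subsets
is tallied (at an exhaustive iteration each gene appears in exactly
C(*n*−1, *k*−1) subsets, so those rows are constant; the contrast builds in
the seeded iterations). A gene's **aggregate frequency** is the sum over
all iterations — constant rows included, since they shift every gene
equally and cannot change the ranking. Candidates are the genes with
aggregate frequency ≥ mean + 0.5·SD (sample SD, divisor *n*−1; inclusion is
`≥`, so exact ties are candidates; an all-equal distribution is flagged
degenerate and returns every gene). `compare_split` then evaluates the full
set, the candidates and the non-candidates, each against 50 size-matched
random sets, reporting the foreground classification potential
FCP = OCP − BCP per arm.

## Synthetic data

The generator emulates a log2-scale bulk RNA-seq matrix: gene baselines
b_g ~ N(μ0 = 5, τ² = 1), planted genes get class offsets δ·u_{g,c} with
u ∈ {−1, +1} per (gene, class) (redrawn if constant across classes), and
N(0, σ²) noise on every value. Sign patterns — rather than one-vs-rest
shifts — mean multi-class separation generally needs gene *combinations*,
which is the polygenic premise the decomposition probes. The generator does
not model library-size effects, count overdispersion, batch structure or
gene–gene correlation, so passing benchmarks demonstrate the machinery
recovers planted signal under idealized noise, not performance on real
compendia. Two quirks of the design matter for interpretation: patterns may
repeat across planted genes (redundant genes split the credit), and two
classes may share their entire signature (capping attainable accuracy).

## Benchmark conditions

All reference numbers come from `genesieve.benchmark`, at sizes chosen to
run on a single CPU:

* **Recovery**: 500 genes × 200 samples, 4 balanced classes, 5 planted
  genes (δ = 2, σ = 1); a 30-gene set holding the 5 planted genes plus 25
  random noise genes; M = 30; 3 bootstrap splits per subset during the
  decomposition (~22 000 subset evaluations per run), 5 seeds. The filler
  genes are drawn at random per seed: a fixed low-id filler would
  systematically win the deterministic lexicographic tie-breaks against
  randomly-positioned planted genes. Three splits are enough here because
  candidate selection depends on frequency *rankings*, which are stable in
  this regime (ten splits was checked and does not change which genes are
  missed — the misses trace to pattern redundancy in the generator).
* **Validation**: each recovery split's arms vs 50 size-matched random
  sets, 10 splits per evaluation.
* **Null calibration**: 300 genes × 120 samples, 3 classes, no planted
  genes; 100 repetitions of the full screen (10-run evaluations, 50 random
  sets, alpha = 0.01) with freshly drawn tested sets.

## Numerical and degenerate-input choices

* Binomial counts use exact integer arithmetic (`math.comb`).
* Subsets are keyed by canonically sorted tuple; gene order inside a
  subset never affects evaluation.
* Top-M ties: accuracy descending, then lexicographic tuple.
* Constant genes z-score to zeros rather than NaN.
* Zero-variance backgrounds in the screen fall back to a direct mean
  comparison (p = 0 or 1).
* A single-class evaluation errors unless explicitly allowed, in which
  case accuracy is trivially 1.
* Identifier matching is case-insensitive with Ensembl version suffixes
  stripped; unmatched gene-set members are dropped with a log message and
  all downstream math uses the resolved set size.

## Known limitations

* The MLP backend inherits scikit-learn's threading/BLAS floating-point
  nondeterminism; byte-identical replays are guaranteed only for
  `linear_fallback`.
* The screen's t-test assumes the null distribution of set means is
  approximately normal; with very few random sets (< ~20) the empirical
  quantiles are noisy.
* The heuristic stage explores only single-gene extensions of seed
  subsets; gene pairs that classify well *only* jointly and never appear
  in a surviving seed can be missed.
* Aggregate frequencies mix iterations with different subset counts; no
  per-iteration normalization is attempted.
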