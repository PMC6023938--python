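# Methods

## Model and inference

`dcascape` models a selected pool of fixed-length nucleotide sequences
(`L = 20` by default, alphabet A/C/G/U with T mapped to U) by the
maximum-entropy pairwise (Potts) distribution

    P(x₁…x_L) ∝ exp( Σ_{i<j} e_ij(x_i, x_j) + Σ_i h_i(x_i) ).

Inference is mean-field DCA:

1. **Frequencies.** Single-site and pair frequencies with a pseudocount
   `α`: `f_i(x) = (1−α)·c_i(x)/M + α/q` and
   `f_ij(x,y) = (1−α)·c_ij(x,y)/M + α/q²` for `i ≠ j`.  Diagonal blocks
   follow the convention `f_ii(x,y) = f_i(x)·δ_xy`, which is what the
   correlation-matrix construction requires.  Duplicate reads count with
   their multiplicity — in a selected pool, multiplicity *is* the
   enrichment signal — and an optional collapse-to-counts mode exists
   purely for memory.  No similarity-based reweighting is applied (the
   pool is intentionally redundant); an identity-threshold reweighting
   flag could be added but is deliberately absent from the default path.
2. **Couplings.** For a reference nucleotide `N_k`, the connected
   correlation matrix `C[(i,x),(j,y)] = f_ij(x,y) − f_i(x)f_j(y)` is built
   over the `L(q−1)` coordinates that exclude `N_k` at every position
   (60×60 for 20-mers) and inverted exactly;
   `e_ij(x,y) = −(C⁻¹)[(i,x),(j,y)]`.  All parameters touching `N_k` are
   identically zero (the gauge condition), which the tests assert
   elementwise.
3. **Fields.** Mean-field self-consistency,
   `h_i(x) = ln(f_i(x)/f_i(N_k)) − Σ_{j≠i} Σ_y e_ij(x,y) f_j(y)`, with no
   iterative refinement — matching the accuracy class of the mean-field
   coupling estimate.
4. **Gauge averaging.** Steps 2–3 are repeated for each of the four
   reference nucleotides and the four parameter sets averaged
   elementwise.

The pseudocount default is `α = 0.1`.  At pool sizes of 10⁴–10⁶ reads the
estimates need little regularization, but `C` must be strictly positive
definite; `α` is exposed everywhere.  Since background subtraction,
gauge averaging and scoring are all linear, their order does not matter;
the background model (fit with the identical pipeline and `α` to a
control selection or the unselected library) is subtracted parameter-wise,
and scoring with the difference model equals the difference of scores
exactly.

Coupling magnitudes are compared (e.g. planted vs inferred) through
Frobenius norms of the pair blocks **after projecting to the zero-sum
gauge**; raw norms are gauge-dependent and not comparable across models.

## Scoring and mutational analysis

`H(σ) = −Σ_{i<j} ē_ij(σ_i,σ_j) − Σ_i h̄_i(σ_i)`; lower is better.  Single-
mutant ΔH values are computed incrementally (`O(L²q)` for the full scan)
and are exactly equal to full rescoring.  Mutants are classed
enhancer / neutral / inhibitor with a neutral half-width `τ`; the default
`τ` is the SD of single-mutant ΔH under a parameter-shuffled control
model, a data-driven scale for "no effect".

Trajectories between two elements differing at `k ≤ 8` positions are
enumerated exhaustively (`k!` substitution orders, each intermediate
scored).  The scalar ranking of a trajectory is its **bottleneck** — the
worst intermediate — with the summed intermediates as tie-break: a single
unbindable intermediate breaks an evolutionary bridge regardless of how
good the remaining steps are.  Both statistics are reported so either view
(per-step or cumulative) can be exported.

Enumeration guards (10⁷ variants for `rank_variants`, `k ≤ 8` for paths)
keep everything exact and desk-scale; beyond them the functions refuse and
suggest an explicit candidate list.

## Genome scanning statistics

Every length-`L` window (step 1, `G − L + 1` windows per strand; forward
strand by default, reverse complement behind a flag since selected
elements live on transcribed RNA) is scored with `H_eff`.  Windows
containing ambiguity codes get missing scores and are excluded from
ranking.  Coordinates are 0-based half-open throughout (BED convention).

The null model draws sequences i.i.d. per position from the genome's
global ACGU composition — the simplest reading of "composition-matched" —
and keeps only the mean `μ` and SD `s` of their `H_eff`.  The default
null size is 10⁶ (configurable; the reference studies use 2×10⁵, where the
standard errors of `μ` and `s` are already far below anything that could
move a conclusion).  p-values are one-tailed lower z-tests,
`p = Φ((H_eff − μ)/s)`, because more negative scores mean stronger
predicted binding; q-values use Storey's procedure with
`π̂₀ = min(1, #{p > λ}/(m(1−λ)))` at `λ = 0.5`.

**Calibration caveat.** The z-test is exact only if null scores are
normal.  For effective models fit to *unselected* (no-signal) data the
null `H_eff` distribution is close enough to normal that p-values of null
draws are uniform to KS ≈ 0.01 at n = 10,000.  Effective models fit after
strong multi-round selection carry a reproducible negative skew
(skewness ≈ −0.2 to −0.3 in our studies), which distorts uniformity at
the KS ≈ 0.02 level — immaterial for ranking and for the extreme tail
calls made here (planted-site p ≈ 10⁻¹³), but worth remembering when
p-values near conventional thresholds matter.  An empirical-quantile null
would remove the assumption at the cost of storing the full sample.

AUC against truth intervals is the Mann–Whitney probability that a random
positive window outscores a random negative one (ties 0.5), computed by
rank statistic and verified against the all-pairs count.  By default any
window overlapping a truth interval by ≥ 1 base is positive; for the
planted-element studies the evaluation uses full overlap (`min_overlap =
L`) because a window shifted by even one base places the shared bases at
the wrong model positions — a position-specific model assigns such
near-miss windows essentially random scores, so counting them as
positives only measures dilution, not discovery.

## Direct information and landscapes

For each pair `i < j`, the two-site direct distribution
`P^dir(x,y) ∝ exp(ē_ij(x,y))·a_x·b_y` is fitted by iterative proportional
scaling until both marginals match `f_i` and `f_j` (tolerance 10⁻⁶, cap
500 iterations, both configurable; non-convergence is fatal and names the
pair).  `DI_ij` is the mutual information of `P^dir` — the KL divergence
from the independent product `f_i f_j`.  An alternative mode computing
`KL(f_ij ‖ P^dir)` (empirical joint vs direct distribution) is available
behind a flag for comparison; the mutual-information form is the default
and the one used everywhere else in the package.

The landscape export lays all couplings out as an `(L·q)×(L·q)` labeled
matrix (position-major, nucleotide-minor; 80×80 for 20-mers) with
zero diagonal blocks and transposed symmetric off-diagonal blocks,
written as a labeled TSV that round-trips exactly, plus an optional
heatmap.

## Synthetic study systems

The generator produces every fixture the pipeline needs, so all claims are
tested against known ground truth without any downloads:

* **Planted models** — chosen coupled pairs with Watson–Crick-style
  blocks (complementary combinations maximal), per-position field biases,
  and optionally weak zero-sum random couplings on *all* pairs.  The
  reference study model has five WC pairs (three at strength 1.5, two at
  1.0), fields of scale 0.3, and background couplings of scale 0.15.  The
  background couplings emulate the diffuse residual covariation a real
  selected pool shows at every position pair; they also make "rank
  correlation of coupling norms over all pairs" a meaningful statistic —
  with strictly zero background, 185 of 190 planted norms tie at zero and
  the rank correlation is bounded near 0.28 by the tie structure alone,
  regardless of inference quality.
* **Gibbs sampler** — single-site updates with conditional
  `∝ exp(h̄_i(x) + Σ_{j≠i} ē_ij(x, σ_j))`, run as a pool of parallel
  chains (default 1024) with 100 burn-in sweeps and 3 sweeps between
  collections; verified against exact enumeration on two-site models.
* **Selection simulator** — each round resamples the pool with
  replacement with weight `∝ exp(−H/τ)`.  No binding kinetics, PCR bias
  or sequencing error are modeled: weighted resampling is the minimal
  process that produces the enrichment structure the inference assumes.
  The operation default is `τ = 1`; the genome-discovery study uses
  `τ = 3` because against the reference model `τ = 1` collapses a
  100,000-read library to ~100 unique sequences within five rounds —
  real selected pools remain diverse — and a mean-field fit to such a
  degenerate pool is meaninglessly overfit.  At `τ = 3` the pool keeps
  thousands of unique reads while mean `H` still falls by several null
  SDs over five rounds.
* **Genomes** — i.i.d. background of chosen composition with elements
  spliced at known coordinates and truth emitted as BED.

What passing these studies does *not* show: robustness to sequencing
error, PCR amplification bias, length heterogeneity, carry-over between
rounds, or model mis-specification (real binding energies are not exactly
pairwise).  The synthetic pools are drawn from the very model family the
inference assumes, so the studies measure correctness of the machinery,
not biological adequacy of the pairwise approximation.

## Reference study conditions (dcascape.benchmarks)

* *Recovery*: planted study model → Gibbs pool of M = 50,000 → refit at
  `α = 0.1`.  Measured: planted pairs among the top-5 DI pairs (5/5 in
  typical runs) and Spearman correlation of zero-sum coupling norms over
  all 190 pairs (≈ 0.95).
* *Discovery*: 100,000-read library, five rounds at `τ = 3`, target fit on
  the final pool and background on the library, greedy-optimal element of
  the effective model planted at the midpoint of a 50-kb random genome,
  null n = 2×10⁵.  Measured: planted-window rank (1), full-overlap AUC
  (1.0), planted-window p (≈ 10⁻¹³).
* *Calibration*: effective model from two independent unselected
  libraries (control vs control), null n = 2×10⁵, 10⁴ fresh null draws.
  Measured: KS of p-values against uniform (≈ 0.01), p at the null mean
  (0.5 exactly).
* *Selection sanity*: 20,000-read library, five rounds at `τ = 3` under
  the planted model (mean `H` non-increasing every round) and under a
  zero model (mean `H` statistically flat).

All sizes were chosen as the smallest at which the measured quantities are
stable across seeds; every random draw descends from one explicit seed.

## Numerical choices

* Matrix inversion is exact (`numpy.linalg.inv` on the 60×60 reduced
  correlation matrix); a singular matrix (degenerate pool at `α = 0`)
  aborts with advice to use a positive pseudocount.
* Model files store floats as `%.17g`, which round-trips IEEE doubles
  bit-exactly; loading validates version, header completeness and block
  lengths, and truncation is fatal.
* Ranking tie-breaks are deterministic everywhere: variants by Hamming
  distance then lexicographic sequence; windows by coordinate; DI pairs
  by (i, j).
* Degenerate inputs are errors, not warnings: empty pools, zero surviving
  reads, zero-variance nulls, identical path endpoints, AUC without both
  classes.

## Known limitations

* Mean-field DCA underestimates strong couplings (inversion of a
  regularized correlation matrix shrinks); rank structure is preserved,
  which is what site discovery and pair detection use.
* The z-test p-value assumes null normality (see calibration caveat).
* Selection inference uses the final-round pool only; round-to-round
  trajectory information is used for validation, not for fitting.
* Adapter trimming, demultiplexing and quality filtering are upstream of
  this package: pools are expected as clean fixed-length reads.
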