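# Methods

## The problem

After prolonged LPS exposure, macrophages become *tolerant*: a second LPS
stimulation fails to re-induce many inflammatory genes while genes needed
for antibacterial defence keep being expressed.  Given a three-condition
expression matrix — untreated (N), naive + 4 h LPS (N+L), and 24 h LPS
followed by 4 h re-stimulation (T+L), two replicates each — the package
separates *pro-inflammatory* (tolerizable) from *antibacterial*
(non-tolerizable) genes, predicts the transcription-factor binding motifs
that discriminate them with three independent engines, intersects the
engines' top predictions into a consensus, and validates curated TF-target
relationships against the expression signature.

## Phenotype classification

With condition averages X = N_avg, Y = (N+L)_avg, Z = (T+L)_avg per probe:

* pro-inflammatory: Y/X > 1, Z/Y < 1 and Welch two-tailed p < α;
* antibacterial: Y/X > 1, Z/Y > 1 (strictly) and p < α;
* otherwise unclassified.  Zero denominators make a probe unclassified
  with a recorded reason.

The Welch test contrasts the naive (N) and tolerant (T+L) replicates by
default; `contrast="N_vs_NL"` switches to the induction contrast.
Degenerate conventions: two zero-variance groups give p = 1 for equal
means and p = 0 otherwise (the limit of the t statistic).  α defaults to
0.05 and no multiple-testing correction is applied (an optional
Benjamini-Hochberg adjustment across probes exists, off by default); all expression
computation is probe-level, and "gene" counts collapse probes by symbol
keeping the probe with the highest overall mean intensity.  Both
probe-level and symbol-level counts are reported because deposited-array
analyses rarely state which they use.

The relaxed *two-fold signature* replaces the one-fold strict inequalities
and the p-value filter with inclusive two-fold cutoffs (Y/X ≥ 2 and
Y/Z ≥ 2).  Relative expression profiles divide each gene's three condition
averages by the global maximum N average of the full matrix, so the most
expressed untreated gene maps to 1.  The cross-dataset tolerizability check
for four-condition (N, N+L, T, T+L) layouts flags a gene when
(N+L)/N > 1 and (T+L)/T < (N+L)/N strictly — re-stimulation of tolerant
cells falls short of the naive response.

Power note: with duplicate arrays the Welch–Satterthwaite degrees of
freedom lie between 1 and 2 (two-sided critical t between 4.3 and 12.7),
and multiplicative noise makes the induced group's variance dominate, so
the filter's sensitivity has a ceiling near 97% even for very large fold
changes, and its joint null false-positive rate is ≈0.5% per direction at
α = 0.05.  This is why the antibacterial class — 2% of genes against an
~88% null background — cannot exceed ≈0.8 precision under the default
conditions, a base-rate limit rather than an implementation artifact.

## Motif engine 1: EM/ZOOPS de-novo discovery

A two-component finite mixture: with probability γ a sequence carries
exactly one motif occurrence at a uniformly chosen admissible position (on
either strand when `revcomp`), otherwise it is 0-order background.  The
E-step computes per-window site posteriors; the M-step re-estimates the
PWM columns (pseudocount 1e-3 × background per cell) and γ.  The objective
(data log-likelihood ratio against background-only) is non-decreasing
every iteration and iteration stops when the gain drops below `tol`
(default 1e-4) or `max_iter` is reached.  Windows containing N (masked
repeats, pads) are excluded outright.  Site calls combine both strands'
posterior at an offset, so palindromic motifs still yield confident sites.

Starting points are deterministic: the `n_starts` width-mers with the
highest Hamming-1-neighbourhood counts (instances of a real motif scatter
around its consensus, so exact word counts are diluted), with seeds within
one mismatch of an already chosen seed skipped for diversity.  Each start
runs `start_iters` EM iterations; the best `n_refine` short-run
likelihoods continue to convergence and the best final likelihood wins.

Multi-motif extraction is sequential: after each motif, its confident
sites (combined posterior > 0.5) are hard-masked with N.  Width is chosen
per motif over a grid (default {6, 8, 10, 12, 15}, capped at 15) by the
best E-value.  The E-value is a Monte-Carlo calibration: the fit is
repeated on dinucleotide-shuffled copies of the input (Altschul–Erickson
Eulerian-path shuffle, masked runs held in place, so first-order
composition is preserved) and the observed log-likelihood ratio is ranked
among the null refits, with the add-one estimate scaled by the number of
widths tried.  Its floor is therefore `n_widths / (n_shuffles + 1)`.  Null
refits use a deliberately cheaper EM configuration (fewer starts and
iterations) than the observed fit; this biases the E-value slightly
anti-conservative, which is harmless because the score is only used to
rank motifs within the engine.  The null-uniformity test matches the fit
configuration on both sides.

## Motif engine 2: transcription contribution scores

Motifs (fixed-size words, default k = 8 pruned to those with ≥ 3 promoter
hits, or a supplied PWM library scored at 80% of the maximum log-odds)
are counted in each promoter — overlapping occurrences, once per strand,
N never matches.  Each of `n_iterations` seeded draws samples
`subset_size` motifs and fits ordinary least squares of the response on
the count sub-matrix (constant columns are confounded with the intercept
and flagged; singular designs fall back to a flagged ridge with
λ = 1e-6·trace(XᵀX)).  A sampled motif accumulates its absolute
standardized coefficient; TCS = accumulation / times sampled (a "sum"
normalization is available), and the sign of the mean raw coefficient
labels the motif stimulatory or inhibitory.  The default response in the
pipeline is log2(T+L/N+L) per gene — the tolerance contrast the phenotype
turns on.  Random-gene companion runs draw their response uniformly within
the observed range.

## Motif engine 3: affinity/hypergeometric association

Promoter affinity for a PWM is Σ exp(log-odds) over all windows and both
strands against a 0-order background estimated from the promoter set — an
occupancy-flavoured score that rewards strong single sites and multiple
weak ones; N-containing windows contribute 0.  Genes are ranked by
affinity and by a specificity score (pipeline default: log2(N+L/N), the
induction contrast).  For every cutoff pair (i, j) from a grid (default
{5, 10, 20, 50, 100, 200} ∩ [1, n]) the overlap k of the top-i affinity
genes with the top-j specificity genes is scored with the exact
hypergeometric tail P(X ≥ k), and the minimum over the grid is reported
uncorrected, with the attaining cutoffs (an optional Bonferroni factor
of the number of cutoff pairs exists, off by default).  Ranking ties break
lexicographically, making the engine invariant to monotone transforms of
either score and fully deterministic.

## Consensus

Each engine's predictions are retained at the top 70% in its own score
orientation (discovery: E-value ascending; TCS: descending; association:
p ascending), with ⌈0.7·n⌉ rounding and boundary ties all kept.  De-novo
motifs are mapped to library accessions before retention by an ungapped
comparator: over all offsets with ≥ 4 aligned columns and both
orientations, similarity is the mean Pearson correlation of aligned
probability columns (zero-variance columns score 0, so a uniform query
cannot match); a hit needs similarity ≥ 0.75, and de-novo motifs mapping
to the same accession merge keeping the best score.  (A retain-first
toggle applies the 70% cut to raw de-novo motifs before mapping.)  The
consensus is the
set of accessions present in all three retained sets.  A companion run on
a random unclassified gene set (seeded sample, random response, random
specificity ranking) feeds a per-accession, per-engine test-vs-random
contrast table; an accession the engine did not retain on random data is
marked "absent".

## Literature-target validation

Curated TF → target lists (a 12-row fixture of profile TFs with
literature-validated targets ships with the package; symbols compared
case-insensitively with verbatim spellings preserved) are intersected with
the two-fold signature.  Overlapping targets are checked for the
pro-inflammatory pattern, given relative expression profiles, optionally
re-checked in an independent four-condition matrix, and contrasted with
seeded random gene sets of the same size (whose pattern counts should sit
near the binomial expectation, i.e. close to zero).  On a signature built
from the same matrix the pattern check passes by construction; the
informative uses are different matrices or thresholds.

## Synthetic study conditions

The generator emulates the statistical structure of a deposited
two-replicate macrophage tolerance array and its promoter/TF-library
inputs.  Defaults, chosen once as the study conditions:

| parameter | default | rationale |
|---|---|---|
| genes | 1000 (10% pro, 2% anti) | study-scale class imbalance |
| baseline | lognormal, ln-mean 5.5, ln-sd 1.0 | intensity-scale arrays |
| induction fold (N→N+L) | 20 | strong cytokine-type LPS induction |
| carrier repression (N+L→T+L) | 2.5× | tolerance = failure to re-induce; T+L stays 8× above N |
| non-carrier repression | 2.0× | partial tolerization without the motif |
| anti escalation (N+L→T+L) | 1.5× | sustained antibacterial expression |
| replicate CV | 0.05, duplicates | deposited-array noise scale |
| promoters | 1300 bp (−1000..+300), 0-order, ~2% masked N runs | promoter windows with repeat masking |
| planted PWM | width 10, 0.92 dominant base (~14.7 bits) | curated-matrix information content; a motif below ~11.3 bits cannot be localized in a 1300-bp window even in principle |
| insertion probability | 0.6 per pro gene, 1 site, random offset/strand | partial penetrance |
| decoys | 8, per-column letter permutations in shuffled order | exact information-content match prevents trivial discrimination |

Motif occupancy is causal in the generator: pro genes carrying the planted
site get the full repression fold, carrier-free pro genes the weaker one.
Without this coupling the expression response would carry no information
about motif occupancy inside the gene set and the motif-expression engine
would have nothing to find.  Curated targets of the planted TF are a
subset of its carrier genes; decoy TFs get null-class genes.

What the generator does **not** emulate: probe-level Affymetrix artifacts,
MAS5/RMA normalization, cross-hybridization, correlated replicate noise,
higher-order promoter composition, motif co-occurrence structure, and
alias/ortholog ambiguity in gene symbols.  Passing tests therefore show
the algorithms recover structure they are designed for at realistic noise
— not that the pipeline is robust to everything real arrays do.

All randomness flows through seeded NumPy generators (stage-derived seed
sequences), and emitted files are byte-identical across runs at a fixed
seed.

## Problem sizes used in tests and the acceptance script

The end-to-end sweeps run the full pipeline on ten seeded default bundles
with engine settings sized for ~100-promoter gene sets: 3 extracted
motifs, width grid {8, 12} (deliberately not containing the planted width),
30 starts, 5 shuffles per E-value, 200 TCS iterations over the 9-matrix
library, and the full cutoff grid for association.  Unit and property
tests use 40–150-gene bundles, 50–400-bp sequences, and exhaustive oracles
(≤ 12-element universes for the hypergeometric check, ≤ 50-record matrices
for the classification oracle).

## Known limitations

* Anti-class precision is bounded near 0.8 by the α = 0.05 duplicate-array
  filter and the 44:1 null-to-anti base rate (see the power note above).
* The Monte-Carlo E-value saturates at its floor for every strong motif,
  so ranking among clearly significant motifs falls back to the
  likelihood ratio.
* The TCS engine's word universe treats motifs as exact words; PWM-library
  universes rely on a single 80%-of-max log-odds threshold.
* Gene matching is symbol-equality only; no alias or ortholog resolution.
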