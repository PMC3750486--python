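# Methods

## Model

A read set is encoded as a binary design matrix A over a fixed, ordered
list of canonical k-mers: A_ij = 1 iff the j-th k-mer — or its reverse
complement — occurs as a substring of read i. The response b is 1 for
enriched (bound) reads and 0 for random (unbound) reads; affinities x
minimise ‖Ax − b‖² + λ‖x‖². A sequence's predicted affinity is the sum of
the affinities of the model k-mers it contains, with the same binary
presence rule used in training, so a training read's score equals its row
of A·x exactly. Because presence is binary, repeated occurrences of a
k-mer within one read do not raise its score; the rationale is that with
deep sequencing, strongly bound k-mers already recur across many reads.

Assumptions worth keeping in mind: every bound read is treated as equally
bound (a binary label, not a measured intensity), presence on either
strand is equivalent, and affinities combine additively across k-mers.

### Canonical k-mers

Binding is detected on both strands, so a k-mer and its reverse
complement are merged into one feature, keyed by the lexicographically
smaller of the pair. Keeping them separate would put two exactly
collinear columns in A for every non-palindromic word and make the
least-squares problem singular. Palindromic words map to themselves.

### Ridge term

The default λ = 1e−6 exists purely for numerical conditioning: k-mers
that co-occur in exactly the same reads (common for overlapping words)
make A rank deficient, and a tiny ridge picks the minimum-norm solution
smoothly. λ = 0 is supported and used in the exact-recovery tests, but an
all-zero column is then rejected because its coefficient is
unidentifiable. Underdetermined systems (more k-mers than reads) are
solved with the same ridge normal equations and logged as a warning.
Columns are always ordered by (k, lexicographic) so refits are
bit-reproducible.

## Feature selection

* **Most frequent**: rank by count_bound + count_unbound. Favours short
  k-mers, which are statistically more common.
* **Most enriched**: rank by count_bound − count_unbound, or by fold
  change (count_bound + c)/(count_unbound + c). The pseudocount c = 1
  keeps the ratio defined when a k-mer never appears in the unbound set.
* **CV backward elimination**: starting from a given set (typically the
  most frequent k-mers), repeatedly remove the k-mer whose removal gives
  the highest mean 10-fold cross-validated accuracy, down to a requested
  size. Folds are stratified by label and fixed by an explicit seed; the
  classification threshold is re-optimised inside each fold's training
  part, never on its validation part; candidate ties remove the
  lexicographically last k-mer. The search is greedy — one removal per
  step, no re-addition — and never touches the external test set, so the
  final test accuracy is free of selection bias. Internally the
  per-fold Gram matrix AᵀA is precomputed once and candidate subsets are
  solved on its submatrices, which keeps a 10-fold scan over dozens of
  candidates per step interactive.

## Evaluation

Enriched reads are split 7:3 into training and test sets; uniform random
sequences matched in number serve as negatives for each half (the SELEX
initial pool contains all words of the read length evenly, so the uniform
null is the right reference, rather than genomic shuffles). The
classification rule is score ≥ threshold ⇒ positive (ties positive), with
the threshold maximising training accuracy; among equally accurate
candidate thresholds the lowest is returned, which in the separable case
is the midpoint of the separating gap. Accuracy intervals are
normal-approximation (Wald) at 95%; degenerate edges are clipped to
[0, 1].

For long peak sequences a read-level threshold does not transfer, so
performance is the Mann–Whitney AUC — the probability a bound sequence
outscores a random one, ties counted ½ — with the Hanley–McNeil
normal-approximation interval (Q1 = A/(2−A), Q2 = 2A²/(1+A)). Peaks can
be scored over their full length or over a fixed 50/100 nt window centred
on the sequence midpoint (or a supplied summit offset); sequences shorter
than the window are skipped with a warning.

## PWM benchmark

PWMs are consumed from MEME minimal, JASPAR count, or plain L×4 matrix
files; counts get pseudocount 1, frequency matrices 0.01 (0 if already
strictly positive). Scanning assigns each read the maximum over all
windows and both strands of the summed natural-log odds against a uniform
background; N-containing windows are excluded, and reads shorter than the
motif are skipped with a warning. PWM classification then follows exactly
the same optimal-threshold protocol as the k-mer model. For simulations
the benchmark PWM is the naive count matrix over the planted motif
instances, whose alignment is known by construction — no motif discovery
is performed. The k-mer alignment helper places each k-mer (both
orientations, any overlapping offset) where its summed log probability
under the PWM is maximal, scoring overhanging positions at background.

## Synthetic data

The simulator emulates cycle-wise SELEX enrichment: cycle 0 is an i.i.d.
uniform pool of 14-mers (the pool length of the protocol the model
targets), and each subsequent pool is drawn with replacement from the
previous one with probability ∝ exp(β · affinity), where affinity is
either a k-mer-map sum (matching the linear model) or a PWM max score.
Boltzmann selection is the standard idealisation of binding competition;
β tunes the per-cycle enrichment rate. Resampling with replacement keeps
the pool size constant, standing in for PCR amplification. The defaults —
pool 5000, 3 cycles, β in the 1.5–4 range, a single planted 6-mer
consensus at affinity 1 — give cycle-wise consensus frequencies that
climb from background (~0.5%) to near saturation, spanning the regimes
from barely classifiable early cycles to nearly separable late ones.

What the simulator does *not* model: PCR bias, sequencing error,
non-specific carryover between cycles, and affinity heterogeneity among
reads carrying the same k-mers. Passing tests on simulated data therefore
demonstrate correctness of the machinery and the qualitative behaviour of
the method (enrichment trend, PWM comparison, wrapper value), not
performance on any real SELEX library.

`simulate_dependent_motif_reads` plants exactly one of several motif
variants per read (weighted choice, uniform offset and strand). Two or
more variants with no positional consensus create dependencies that no
single PWM can represent while remaining trivially representable by
k-mers — the cleanest construction of the regime where the k-mer model
should win. `simulate_peaks` plants a motif uniformly within the central
50 nt of otherwise-uniform peak-length sequences with a given
probability, so center-window evaluation always covers it.

## Problem sizes and numerical choices

The shipped experiments use pool 5000 × 3 cycles (motif recovery, 20
replicates), pool 2000 × 4 cycles (cycle trend, 5 replicates), 2000 reads
(PWM comparison) and 1000 reads with a 40 → 4 backward elimination (CV
wrapper); each completes in seconds while leaving comfortable margins on
every tested effect. Word length defaults to k ∈ {4..8} for general use;
the simulation studies fix the k matching their planted motifs. Solver
tolerances are those of LAPACK solve/lstsq; exact-recovery tests assert
at 1e−8 and score/row-identity at 1e−12.

## Known limitations

* Training is binary least squares, not logistic regression; scores are
  not probabilities and can leave [0, 1].
* The wrapper's greedy search can keep a redundant short k-mer when a
  removal tie is broken lexicographically; it never revisits removals.
* Model files store the k-mer list and affinities only; the training
  reads are not persisted, so retraining requires the original inputs.
* Peak handling expects pre-extracted FASTA sequences; there is no
  genome/BED extraction or peak calling.
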