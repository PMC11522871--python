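# Methods

## Model

The classifier treats a read's unique minimizers as conditionally
independent features of its source genome (the naive-Bayes assumption)
and uses presence/absence rather than occurrence counts: a minimizer
present in genome *G* contributes `log(1/count(G))` to the read's
log-score for *G*, where `count(G)` is the genome's total number of
valid k-mer positions, and an absent minimizer contributes a flat
penalty φ in place of a vanishing log-probability. Uniform genome
priors are assumed, so the posterior ranking is the likelihood ranking.
Because closely related reference genomes often score within a hair of
each other, the final verdict is not a bare argmax: the sorted distinct
scores are walked downwards while consecutive gaps stay ≤ θ, and the
species with the most genomes in the resulting candidate set wins
(plurality vote). θ = 0 degenerates to argmax.

Unknown-organism rejection happens before scoring: a genome sharing
fewer than a fraction μ of the read's minimizers — or sharing none,
regardless of μ — is discarded, and a read that discards every genome
is reported unclassified with a reason code (`below_mu`, or
`no_minimizers` for reads shorter than k or all-ambiguous).

## Minimizer scheme

Windows span k consecutive k-mer positions (2k−1 bases); each window
contributes its lexicographically smallest canonical k-mer, and the k−1
shorter windows anchored at each end of every sequence record (1, 2, …,
k−1 consecutive k-mers) contribute likewise, so terminal k-mers are
representable. Canonical means the smaller of the k-mer and its reverse
complement, which makes sketches and therefore verdicts strand-
invariant (tested end to end). The base-4 hash is an order-preserving
bijection, so all comparisons run on integers; for k = 15 hashes fit
unsigned 32-bit. Multi-record genomes (contigs) get end windows at the
ends of every record, since contigs are independent sequences.

Ambiguous bases: the 2-bit base map is defined only on A/C/G/T, so any
k-mer containing another character is excluded from every window's
candidate list; a window with no valid k-mer yields no minimizer, and
`count(G)` likewise counts only valid positions on one strand. Input is
uppercased first (soft-masked genomes are common). Counting one strand
rather than both shifts every score by a constant per shared minimizer
and so cannot change a ranking within this convention.

## Parameters

| parameter | default | meaning |
|---|---|---|
| k | 15 | k-mer length; sketch density and specificity both rise with k |
| μ | 0.35 | minimum shared-minimizer fraction; higher → more unknowns rejected, lower recall on knowns |
| φ | −2000 | penalty per absent minimizer; must be < log(1/count) of the largest genome (validated at classify time) |
| θ | 1500 | maximum gap between consecutive distinct sorted scores when extending the candidate set |
| seed | 0 | global seed; each read's tie-break RNG derives from (seed, read_id) |
| coverage | 0.05 | expected depth of simulated fragments |

The score logarithm is natural by default and configurable
(`log_base`); φ and θ are calibrated for whichever base is in use, and
the shipped defaults assume natural log. Gaps for θ are computed
between consecutive *distinct* score values, with all genomes sharing
an included value entering together — with float scores produced by
identical arithmetic, ties occur exactly when the shared/absent counts
and `count(G)` coincide, which is the intended grouping. μ comparison
is strict (`< μ` rejects) so that μ = 0 still rejects genomes sharing
nothing.

Deriving each read's tie-break RNG from a CRC32 of `(seed, read_id)`
makes every verdict independent of batching, ordering and thread count;
parallel classification and parallel database building are contracts
(bit-identical to serial), implemented with a thread pool over
independent units of work.

## Simulation and the synthetic community

Simulated reads are error-free fragments: records chosen with
probability proportional to their number of valid start positions,
starts uniform, strands uniform. The fragment count at coverage *c* and
fragment length *L* from a genome of length *N* is `ceil(c·N/L)`; the
ceiling is forced by the reference negative-read counts (10143 and 5072
fragments of 150 and 300 bp from a 30,427,671 bp chromosome at 0.05×,
which floor would miss by one). Variable-length mode draws from
Normal(5500, 1500) truncated to [1000, 10000] bp — the midpoint-mean
reading of "normally distributed 1–10 kb" — with the count computed at
the mean length (`ceil(0.05·N/5500)` = 277 for the same chromosome);
all four knobs are exposed. No sequencing-error model is applied, and
none is planned: the benchmark isolates database and scoring behaviour
from error-profile modelling.

The strain holdout assigns `ceil(f·T)` of each species' T ≥ 2 strains
to the test set (f = 0.2 by default); the ceiling guarantees every
eligible species is actually tested, and single-strain species train
only.

The synthetic community generator emulates one thing: species that are
far apart (i.i.d. random ancestors, so two 100 kb species share < 1 %
of 15-mer minimizers by chance) containing strains that are close
(point substitutions at a per-base rate, default 0.5 %). Lineages come
from a deterministic binary-ish hierarchy (2 species per genus, 2
genera per family, …) so every rank is exercised by the evaluator. It
does **not** emulate horizontal transfer, repeats, mobile elements,
uneven genome sizes, compositional bias or real inter-species sequence
similarity — so passing the desk-scale benchmark shows the machinery is
correct and well-calibrated on its stated assumptions, not that the
same precision figures transfer to a real reference collection.

Problem sizes for the shipped benchmark were chosen at desk scale — 20
species × 3 strains of 100 kb, ~700 positive and ~170 negative 150 bp
reads — large enough that species-level precision/recall and negative
accuracy are stable to a few percent across seeds while the whole run
stays in seconds.

## Evaluation

On positive reads, precision at rank r = correctly-classified-at-r /
classified, recall = correctly-classified-at-r / all positives (so
recall = precision × classified fraction, identically); correct at r
means the predicted species' ancestor at r equals the source genome's
ancestor at r. An empty taxon name is treated as unranked and never
counts as correct at that rank. On negative reads, accuracy is the
percentage left unclassified. All metrics are percentages in [0, 100];
a precision with zero classified reads is reported as 0.

## Numerical and degenerate-input choices

- Scores compare by exact float equality for grouping; identical
  arithmetic on identical inputs yields identical doubles, so this is
  deterministic.
- Reads shorter than k, or with no valid k-mer, are unclassified with
  reason `no_minimizers`; the empty-minimizer score is never evaluated.
- Index files store hashes sorted ascending; an unsorted file is
  accepted, re-sorted and logged rather than rejected.
- Genomes with no valid k-mer are refused at indexing time (a database
  entry must have ≥ 1 k-mer and ≥ 1 minimizer).
- `fragment_count` returns 0 with a warning when the fragment length
  exceeds the genome; variable-length draws are capped at the longest
  record when a genome is shorter than the drawn length.

## Known limitations

- The database lives wholly in memory during classification; the format
  favours transparency (plain text, diffable) over compactness and is
  not meant for collections of tens of thousands of full-size genomes.
- Occurrence-count scoring (using how often a minimizer appears in a
  genome) is intentionally not implemented; presence/absence is the
  model.
- Paired-end mates are classified independently; there is no abundance
  profiling, LCA fallback, or confidence statistic.
- Taxonomy is an explicit 8-column TSV; importing NCBI dump files is
  out of scope.
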