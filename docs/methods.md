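# Methods

## The essentiality model

A saturated transposon library approximates a per-base Bernoulli process on
dispensable DNA: each base carries an insertion independently with
probability equal to the library density (default 1/11 per bp).  The
insertion index of a gene — unique insertion sites divided by gene length —
is then approximately Binomial(L, p)/L, which for typical gene lengths is
well described by a gamma distribution concentrated around p.  Essential
genes receive (nearly) no insertions, producing a second component near zero
that we model as exponential: it is the maximum-entropy choice for a
non-negative quantity with a small mean, it tolerates exact zeros, and its
MLE is closed-form.

Because the two components overlap in the transition region, the fit is
*sectioned* rather than solved as a latent-class mixture (no EM): indices in
`[0, 0.013)` fit the exponential by `λ = n/Σx` (zeros included), indices in
`[0.022, 0.25]` fit the gamma by numerical MLE with location pinned at 0
(`scipy.stats.gamma.fit(..., floc=0)`), and indices in the transition band
`[0.013, 0.022)` or above 0.25 are excluded from fitting but still scored.
The cutoffs are the classical manual choices for a saturated library and are
exposed as configuration; they should be re-inspected on the index histogram
(the `fit` subcommand writes one) whenever the library density differs
substantially from ~0.09.

Scores are `s = log2(f_exp(x)/f_gamma(x))`.  Classification uses a
symmetric likelihood-ratio factor k (default 12):

* essential: `s > log2(k)`
* non-essential: `s < −log2(k)`
* unclear: otherwise (boundary values inclusive — a gene exactly at the
  threshold is *not* called).

### Numerical conventions

* **Index 0.** The gamma density vanishes at zero for shape > 1, so the
  score diverges; `log_likelihood_score` returns `+inf` as an explicit
  sentinel.  This preserves the invariant that a zero-index gene never scores
  below any gene with insertions.
* **All-zero exponential section.** When every index below the first cutoff
  is exactly zero (a leak-free library), `λ = n/Σx = +inf` — the degenerate
  point-mass-at-zero limit of the exponential.  Scoring remains well defined
  (`+inf` at index 0, `−inf` elsewhere) and classification degenerates to
  "insertion-free ⇒ essential", which is the correct limit.  Real libraries
  have leak insertions and produce a finite rate.
* **Sparse sections.** Fitting refuses to run when either section holds fewer
  than `min_section` (default 5) observations and asks for cutoff
  adjustment instead of extrapolating.
* **Gene ends.** No 3'/5' trimming is applied before counting; the window
  scan likewise starts at the annotated start regardless of strand.

## Domain essentiality

A 300-bp window slides in 150-bp steps from the gene start; a window with
zero unique insertion sites marks an essential fragment.  Trailing partial
windows are discarded (a window must be exactly 300 bp and lie inside the
gene), so genes shorter than 300 bp are never flagged.  Only unclear and
non-essential calls are upgraded to `domain_essential`; essential calls are
final.  Geometry note: an insertion-free block is *guaranteed* to contain a
full window only when it spans at least `window + step − 1` = 449 bp; shorter
blocks are detected only when a window start happens to align, so the scan is
conservative for blocks between 300 and 449 bp.

## The synthetic library

`SimConfig` defaults define the study conditions: 2000 genes with
gamma-distributed lengths (shape 4, mean 900 bp), ~15% of the genome
intergenic, 15% essential genes with zero leak density, 2% domain-essential
genes, density 1/11 per bp elsewhere, geometric read counts per site.  The
insertion process is per-base Bernoulli per region — saturated libraries show
even coverage, so no hotspot or sequence-bias model is included.  The
domain-essential free block defaults to 450 bp, the smallest round size at
which the 300/150 window scan detects the block with certainty regardless of
placement; smaller planted blocks would make recovery a coin flip of window
alignment rather than a property of the method.

What the generator deliberately does **not** emulate: sequencing error, PCR
duplicates, read-mapping artefacts, insertion-orientation effects, gene-end
trimming biases, and chromatin/condensation accessibility bias (regions
inaccessible to the transposase masquerade as essential in real data).
Passing recovery tests on this generator therefore validates the statistical
machinery, not robustness to those real-data artefacts.

## Comparative stages

* **Hit filtering.** Keep a hit iff `evalue ≤ 1e−5` and query *and* subject
  coverage ≥ 70% (boundaries inclusive).  Coverage is
  `100·alignment_length/length`; BLAST-6 input must carry `qlen`/`slen`
  columns for the filter to apply.
* **BBH.** Best hit per query ranks by bit score, then percent identity,
  then lexicographic subject id (deterministic across platforms and input
  order).  A pair is an ortholog iff each side is the other's best hit and
  neither side has a runner-up with bit score ≥ 0.9× its best — the
  operational reading of "discard paralogies that are hard to resolve".  The
  margin is configurable; exact bit-score ties are always discarded since the
  runner-up equals the best.
* **Conservation.** Hits collapse to species before counting, and levels are
  nested (Planctomycetes ⊆ PVC ⊆ Prokaryotes by default).  A gene is
  *specific to* a level when every species with a surviving hit lies inside
  it; a gene with no surviving hits is specific to the innermost level by
  convention and flagged `no_external_homologs`.  The summary counts genes
  specific to each level per essentiality label, so counts nest
  monotonically from the innermost level up to the total.
* **Paralog groups.** Similarity requires the shorter protein ≥ 60% of the
  longer, and a cross bit score (max of the two directions) ≥ 0.1× the larger
  self-score when the pair shares a COG label, 0.2× otherwise.  Grouping
  anchors on the protein with the most second-order neighbours (the union of
  its neighbours' neighbours, itself excluded; ties break lexicographically),
  admits second-order neighbours whose own count is ≥ 20% of the anchor's,
  removes the group and repeats on the remaining subgraph, recomputing
  neighbourhoods there.  Consequences worth knowing: an isolated similar
  *pair* has empty second-order sets and is never reported as a group
  (two-member groups arise only through intermediate proteins, e.g. a path
  a–b–c yields {a, c}); and a hub protein whose neighbours are not otherwise
  connected can end up outside the group formed by its satellites.  Reported
  groups have ≥ 2 members; singletons exist internally so that the partition
  property (every protein assigned exactly once) holds.
* **Phyletic profiles.** Frequency of each ortholog group per taxonomic
  class is the fraction of the class's organisms with ≥ 1 occurrence
  (duplicates within an organism collapse); classes under 5 organisms are
  dropped.  Row ordering for display uses complete-linkage agglomeration on
  Euclidean distances (`scipy.cluster.hierarchy`), with rows pre-sorted by id
  so tie distances resolve deterministically.  Pattern extraction
  (universal / lineage-restricted / other) uses thresholds τ_high = 0.5 and
  τ_low = 0.1 by default; these boundaries are presentation choices, not
  statistics, and are fully configurable, including user-supplied predicates.

## Design choices that were genuinely open

* **Score orientation.** The ratio is defined essential-over-dispensable, so
  essential genes score *high*; the factor-12 rule is applied symmetrically
  on both sides.
* **Pseudogenes, tRNA, rRNA** are pooled with CDS in both fitting and
  classification — depleted insertion density is evidence of essentiality
  regardless of feature type, and essential "pseudogenes" are a known
  annotation-error signal.
* **Insertion orientation** is collapsed; a position is one unique site
  whichever strand the junction reads support.
* **Plot files** sum their forward and reverse count columns before
  unique-site counting.
* **Cross bit score** for the paralog rule is the max of the two directed
  hits (not min or mean), the lenient choice consistent with using the max of
  the two self-scores as the normalizer.
* **Membership counts during clustering** are taken on the remaining
  subgraph, the direct consequence of removing assigned proteins from
  further analysis.

## Problem sizes

The test suite and the acceptance script run entirely on generated data: the
default 2000-gene library (~2.1 Mb, ~165k sites, seconds to analyze), 100
small libraries for counting oracles, a 200-ortholog BBH universe and a
20-family paralog universe.  These sizes give binomial sampling errors well
inside the tolerances asserted (e.g. the gamma-mean recovery at ±10%) while
keeping a full run under a few seconds.

## Known limitations

* Cutoffs are manual by design; there is no automatic trough detection.
* The gamma section fits an untruncated MLE to a truncated sample; with the
  default density the mass outside `[0.022, 0.25]` is negligible, but for
  sparse libraries (density ≲ 0.03) the truncation bias becomes material and
  the cutoffs must be moved.
* The BBH paralogy margin is a heuristic; ortholog counts are sensitive to
  it and should be reported together with its value.
* The paralog algorithm is order-deterministic but greedy; it does not
  optimize any global objective, and the two-member-group blind spot above is
  inherent to the literal second-order rule.
* Conservation profiling trusts the caller-supplied organism→species→taxon
  maps; no taxonomy is downloaded or inferred.
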