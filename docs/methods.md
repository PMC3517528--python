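# Methods

This note documents the models, algorithms and parameter choices in
`mitekit`, and what the synthetic-data tests do and do not demonstrate
about real genomes.

## The analysis model

A MITE family is treated as a set of genomic copies descended from a
single master element. Each copy decays independently by substitutions
and indels; structurally intact copies retain two hallmarks: terminal
inverted repeats (TIRs, 11 bp in the modelled family) and an 8-bp
target site duplication (TSD) — a direct repeat of host sequence on
both flanks created at insertion. The family-level questions
(consensus reconstruction, divergence structure, phylogeny, hAT family
assignment from TSD target preference) are all computed from the mined
copy set.

## Reference element

The bundled reference (`src/mitekit/data/mar_reference_synthetic.fasta`)
is a **synthetic** 610-bp element constructed to carry the modelled
family's structural constants: 11-bp TIRs matching the consensus
`CAG(G/A)GGTAGGC` (the two ends differ at the variable position, so the
longest terminal repeat within a 1-mismatch budget is exactly 11 bp),
an AT-rich interior (GC ≈ 0.39), the MarF primer site, and the MarR
reverse site placed so that the predicted product is exactly 455 bp.
The backbone between those landmarks is random AT-rich sequence; it is
not a GenBank record, and analyses of real elements should supply their
own reference FASTA.

## Copy mining

Seeds are exact shared k-mers (default k=12, both genome strands,
k ≥ 8 enforced). Seeds are clustered by strand and alignment diagonal
(tolerance 50 bp absorbs indel drift within one copy while keeping
tandem copies apart), and each cluster is resolved by a local alignment
of the query against a genome window sized to allow full-length
extension (scores: match +1, mismatch −1, gap open −2, extend −1, via
Biopython's `PairwiseAligner`). Window-bounded alignment plays the role
of a banded extension: work per cluster is proportional to query ×
window, not query × genome.

Two refinements matter in practice:

- **Terminal restoration.** A local alignment clips element termini
  whose first bases mismatch (negative-scoring prefix/suffix). Up to 15
  unaligned terminal query bases per end are restored by ungapped
  projection, with identity re-accounted over the restored columns.
  Without this, a mismatch in the first few bases shifts the reported
  boundary by more than the ±5 bp a downstream TSD check tolerates.
  Genuinely truncated fragments (more than 15 missing bases) are left
  clipped.
- **Redundancy suppression.** Overlapping same-strand hits (overlap
  > 50% of the shorter) are collapsed to the longest, then
  highest-identity hit, so one locus yields one copy even when two seed
  clusters cover it.

Hits must span ≥ 200 bp at ≥ 0.75 identity (configurable). These
thresholds re-express the usual "long, high-identity hit" criterion for
a ~600-bp query as explicit cutoffs; no E-value statistics are
computed, and the mined census on a real assembly will depend on them.
Tie-breaking everywhere is leftmost-start, then longest, for
determinism.

## Structural annotation

- **TIR**: scan candidate lengths L from 30 down to 5 and call the
  first (longest) L whose prefix vs reverse-complemented suffix Hamming
  distance is within the budget (default 1 of 11). Longest-first is the
  conventional TIR call and makes the result deterministic; note that a
  copy with perfect 11-bp TIRs plus a chance-complementary 12th base
  would legitimately be called at 12.
- **TSD**: Hamming comparison of the 8-mer immediately 5' of the copy
  with the 8-mer immediately 3'; budget 1 of 8 by default. Both budgets
  are explicit package defaults, not claims about any particular
  published criterion.
- **Classes**: `full_length_candidate` if length ≥ 1.5× reference
  (relic of an autonomous partner); `intact_mite` if TIR and TSD are
  present and length is within [0.8, 1.2]× reference; otherwise
  `degenerate`, with the failed rules recorded.
- **ORF scan**: all ATG→stop ORFs ≥ 100 codons in six frames (a stop is
  required; ORFs running off the sequence end are not called). This is
  a coding-capacity flag, not a gene predictor.
- **Gene context**: distance between half-open intervals; `inside` on
  overlap, `near` if strictly < 2000 bp, else `distal`; 0 means
  adjacent.

## Consensus reconstruction

Each copy is globally aligned to the reference and projected into a
shared matrix: one column per reference base, plus per-reference-
position insertion blocks sized to the longest insertion observed there
(shorter insertions padded right). The consensus takes each column's
most frequent symbol over {A,C,G,T,−} (N not counted); columns won by
the gap or below 50% non-gap coverage are dropped; base ties resolve
alphabetically, and a base beats the gap on a tie so borderline columns
are kept. No post-hoc "repair" of the consensus toward a functional
sequence is attempted — the output is the raw majority call plus the
ORF report.

With the default affine gap scores, a length-2 insertion can tie with
a mismatch + length-1 insertion; the aligner's deterministic traceback
picks one, so insertion-column counts are reproducible but not unique
optima.

## Distances and trees

- **p-distance** uses pairwise deletion: sites where either row has a
  gap or N are skipped per pair, so fragments contribute over the
  region they cover. A pair with no comparable sites is NaN
  ("undefined") rather than an error.
- **T92**: with transition fraction P, transversion fraction Q and h =
  2θ(1−θ) for the pair's mean G+C content θ,
  d = −h ln(1 − P/h − Q) − ((1−h)/2) ln(1 − 2Q); the gamma form with
  shape a replaces each −ln(x) with a(x^(−1/a) − 1). Default shape 2.0.
  Non-positive log/power arguments mean saturation: the pair is NaN and
  `drop_saturated` greedily removes the fewest taxa needed (with a
  warning) before NJ. All-AT or all-GC pairs (h = 0) fall back to the
  transversion term alone.
- **NJ** is the standard Saitou–Nei agglomeration on the Q-criterion;
  ties join the lowest-index pair; negative branch lengths are clamped
  to 0; 3 taxa close with the three-point formulas. On additive
  matrices the topology and all path lengths are exact (tested to
  1e-9, with exhaustive least-squares topology search as the oracle at
  n = 4, 5, and scikit-bio's NJ as an independent cross-check).
- **Bootstrap** resamples alignment columns with replacement, rebuilds
  the distance matrix and tree per replicate, and labels each internal
  edge of the full-data tree with the percentage of replicates
  containing the same bipartition (canonicalized by the side not
  containing the alphabetically first leaf, so supports are invariant
  to leaf order). Default 1000 replicates (100 in the pipeline's
  default configuration, where trees are rebuilt per run); fully
  reproducible from the seed.

## TSD family call

Observed TSDs are tallied into a position-frequency matrix (N bases
excluded per position but tracked). A position is written as its base
when that base's frequency reaches the dominance threshold (default
0.5, a simple majority), else `n`. The family call is binary:
`buster` iff positions 4–5 are TA — the Buster-family target
preference — else `unassigned`. No other family motif is asserted; an
extension hook is simply another rule on the consensus string.

## In-silico PCR

A primer anneals where it matches within the mismatch budget (default
2) and its three 3'-terminal bases match exactly — a crude proxy for
extensibility; melting temperature is not modelled. Products are
predicted for convergent pairs in both orientations (so the product
set is invariant under reverse-complementing the template), measured
from the forward primer's 5' end to the reverse locus's 3' end, capped
at 5000 bp (the cap deliberately exceeds the ~2.6-kb product a
full-length relic would yield).

## Synthetic data: what it models and what it does not

`plant_copies` draws an i.i.d. background at GC 0.35 (AT-rich host),
inserts n copies at uniformly chosen points with ≥ 200 bp spacing
(spacing prevents artifactual merges from confounding recovery
statistics), each flanked by a direct TSD drawn from the `nnnTAnnn`
motif. Defaults model the regime the package was designed around:
79% of copies with intact TIRs and TSDs, per-copy divergence uniform
in 5–10%, random strand. Corrupted TSDs get ≥ 2 mismatches on one
flank; ablated TIRs are randomized; fragments are truncated to 30–70%;
burst copies descend from a shared recent ancestor at ≤ 1% divergence.
Substitutions are uniform over alternatives by default, with an
optional transition/transversion ratio so T92's P/Q terms are
exercised; mutation protects the terminal 11 bp when a copy's TIRs are
flagged intact, so truth flags and annotations correspond.
`simulate_species_set` evolves copies down a star species tree
(ancestors at between/2 from the master, copies at within/2 from their
ancestor).

Not modelled: nested insertions, segmental duplications, repeat-dense
backgrounds, GC heterogeneity, selection, and realistic indel length
spectra beyond the geometric(mean 3) model. Passing recovery tests on
these genomes therefore shows the miner handles divergence, indels,
strand and fragmentation — not that it resolves nested or tandem
repeat structure in real assemblies.

## Problem sizes and determinism

The test suite and acceptance script use desk-scale problems chosen to
exercise every code path: 500-kb genomes with 50 planted copies for
recovery, 1000 random pairs for the distance oracles, trees of 4–8
taxa for NJ exactness, 10-taxon alignments with 100 bootstrap
replicates, 200 TSD sites for the motif pipeline. Every stochastic
component takes an explicit seed (numpy `default_rng`); identical
config + seed reproduces every output file byte for byte, which the
suite asserts.

## Known limitations

- The mined copy census depends on the length/identity cutoffs; no
  attempt is made to reproduce any specific published census from a
  specific assembly and search engine.
- The TIR/TSD mismatch budgets are package defaults; published calls
  of "conserved" may have used different implicit criteria.
- Maximum-likelihood and Bayesian tree inference are out of scope; NJ
  is the implemented method.
- The bundled reference is synthetic (see above); exact checks against
  it validate the package's structural logic, not any database record.
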