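# Methods

## Background

A covariance model (CM) is a profile stochastic context-free grammar over an
RNA family: a guide tree of nodes (ROOT, MATL, MATR, MATP, BIF, BEGL, BEGR,
END), each owning a handful of states. States emit one nucleotide leftward
(ML, IL), one rightward (MR, IR), a base pair (MP), or nothing (S, D, B, E);
B states split the parse into two independent subtrees, which is what lets a
CM describe multiloop structures such as the tRNA cloverleaf. A parse of a
sequence is a derivation of the whole sequence by the whole grammar; its
score, in bits, is the sum of transition scores (log2 transition
probabilities) and emission scores (log2 odds of the emitted nucleotides
against the model's background distribution).

Model databases accumulate families, and two models can accept overlapping
sequence populations — because one duplicates the other, because one lacks
specificity, or because the families genuinely share ancestry (a *clan*).
The discriminating quantity computed here is the **Link score** of a model
pair: the score of the single sequence that does best in both models
*simultaneously*, where "does best" means maximizing the lower of its two
model scores. A Link score of x bits certifies a witness sequence scoring at
least x bits in each model. The witness is the **Link sequence**, and each
model's optimal parse of it proposes a per-model consensus structure, so one
can see which stems survive in both families.

## Single-model scoring

`optimal_parse_score` is a standard CYK maximization over (state,
subsequence) cells; global alignment only — the whole sequence against the
whole model, no local begins/ends and no EL (local end) states. The empty
sequence is legal and is scored through pure-deletion parses. Ties are
broken deterministically: lower child state index, then leftmost bifurcation
split, then alphabetical nucleotide order. `best_sequence` maximizes over
states only (each emitter contributes its best emission; bifurcations sum
their subtrees), which is valid because insert self-loops are required to
have strictly negative gain — `validate_model` flags any insert whose
self-transition plus best emission is >= 0 as a non-termination hazard, and
both `best_sequence` and the linker refuse such models.

Two independent brute-force routes serve as oracles in the test suite:
exhaustive parse-tree recursion without memoization for a fixed sequence,
and an enumeration DP (`all_sequence_scores`) that computes the optimal
score of *every* sequence up to a length bound (guarded at 8, i.e. 87k
sequences).

## The product dynamic program

The objective — maximize over sequences the minimum of two model scores —
does not decompose like a single-grammar optimum, and the recursion here is
this package's own design. Its elements:

* **Cells** pair one state of each model, plus a small amount of side
  information (below); the table is therefore O(n·m) cells for models with
  n and m states, the quadratic footprint expected of pairwise CM
  comparison.
* **Joint emission**: both models read the identical sequence, generated
  outside-in. Left emitters pair with left emitters, right with right, MP
  with MP; the nucleotide (or pair) is chosen once and scored in both
  models. Silent states advance one model while the other waits.
* **Pareto frontiers**: each cell stores every score pair (a, b) not
  dominated in both coordinates, rather than one greedy representative.
  Score pairs add componentwise along a parse, so propagating whole
  frontiers and taking max-min at the root is exact over the space of
  representable joint parses. A greedy per-cell choice (keep the pair with
  the best min) is *not* exact — a suffix with the best min can be dominated
  once a prefix is added — which is why frontiers were chosen despite their
  extra cost. `max_frontier` optionally caps frontier width (beam search)
  for large comparisons; the default is exact.
* **MP splits**: an MP of one model may be matched against a left emitter
  and, later, a right emitter of the other model; the deferred half of the
  pair is carried in the cell key as an "owed characters" ledger. This is
  what lets a hairpin link to an unpaired family at all.
* **Solo match emissions**: when the two optimal parses emit the same
  character in different order — one model reaching it rightward early, the
  other leftward late — one model may emit it alone and the partner owes it
  as a pending discharge. Solo moves are restricted to match states facing
  an opposite-direction emitter, since in every other configuration the
  paired move or a silent advance covers the same parse.
* **One-sided bifurcation**: when exactly one model bifurcates, the linear
  model's remaining state run is split at a chosen state between the two
  branches. Inside the left branch the linear model is restricted to left
  emissions, which makes the split a genuine parse of the common string —
  the reported scores are always certified by one admissible parse per
  model, so re-scoring the link sequence can only score higher (the
  "at-least" guarantee is structural, not empirical).
* **Termination**: product cycles arise only from simultaneous insert
  self-loops. Simultaneous self-loops are strictly negative in both
  coordinates under the validated models and are excluded from the move
  set; the linker additionally refuses a pair if any such cycle would have
  non-negative min-gain.

The representable joint-parse space is a strict subset of all parse pairs:
the owed-characters ledger is bounded (`max_pending`, default 2, so stems
nested deeper than two against an unpaired partner are not fully matched),
and a subtree inside a one-sided branch cannot bifurcate again. The
computed Link score is therefore an exact max-min over that space, a
certified lower bound in general, and empirically equal to exhaustive
enumeration on bifurcation-free pairs of the sizes the suite enumerates.

## Synthetic models

`build_toy_cm` compiles a consensus sequence plus dot-bracket structure into
a fully valid CM with the standard node layout; unpaired columns become MATL
(or MATR when consumed from the right), pairs become MATP, branch points
become BIF/BEGL/BEGR. Parameters: `match_emit_boost` (default 3 bits) is the
log-odds of the consensus nucleotide over each alternative — chosen so a
single matched column is worth about 1.5 bits and toy self-scores land in
the 10-20 bit range typical of real family models; `transition_spread`
(default 0.05) gives off-consensus transitions the small probabilities that
make deletions and inserts cost roughly 4-5 bits, comparable to real CMs. A
seeded jitter (a few percent, multiplicative) decorrelates models built from
the same consensus, and the null distribution is jittered around uniform.

What these toys emulate: state topology, bit-score bookkeeping,
bifurcations, insert penalties, and the match/mismatch trade-offs that
drive link scores. What they do not emulate: maximum-likelihood estimation
from real alignments, Dirichlet priors, entropy weighting, E-value
calibration, and the length scale of real families (toys have 1-32 columns,
tRNA has ~70). Passing tests therefore demonstrate algorithmic correctness
on faithful miniature grammars, not numerical agreement with scores of any
published model database.

The clan fixture plants a known relationship pattern: four models share an
eight-column core and differ in a five-column flank (links near 10 bits);
a satellite model carries the first model's flank behind a mutated core, so
it links at ~7 bits to that one model and at or below ~3 bits to the rest.
The shipped threshold (5 bits) sits between the two populations by
construction; recovering the 4-clique plus degree-one satellite checks the
graph workflow end to end.

## Numerical and interface choices

* All internal comparisons run at full float precision; display rounds to
  one decimal. Scores are bits throughout (log2).
* Impossibility is float ``-inf`` — absorbing under addition, below any
  finite score, written as ``*`` in CM files.
* CM files: both dialect generations share the record skeleton; the older
  dialect stores emissions as log-odds bits, the newer as log2
  probabilities, converted against the record's NULL line on read so the
  in-memory model is dialect-agnostic. Calibration statistics and
  provenance lines are preserved verbatim but never interpreted; E-values
  play no role in link computation. Stockholm alignments are not parsed —
  an optional hook shells out to Infernal's cmbuild when present.
* DNA input is accepted anywhere (T maps to U); IUPAC ambiguity codes are
  rejected.
* Batch workflows isolate failures per pair, emit results in canonical
  order regardless of scheduling, and the renderers (TSV, matrix, DOT,
  detail) are pure and byte-deterministic.

## Problem sizes used in tests

The suite and the acceptance script regenerate everything they measure:
self-link identity on 20 models of 1-8 columns (with and without
bifurcation), the at-least margin on 50 pairs, oracle equality on 20
bifurcation-free pairs of up to 4 columns (brute force enumerates all
sequences to consensus+3), CYK-vs-enumeration on models up to 25 states
over all sequences to length 5, and a chain-model ladder spanning n·m from
about 10^2 to 10^4 for the quadratic-growth check. These sizes keep the
brute-force oracles exhaustive while exercising every state type and move
rule.

## Known limitations

* Exact frontiers make large dissimilar comparisons expensive (minutes for
  two ~100-state models); `max_frontier` trades exactness for speed and is
  the intended setting for database-scale scans.
* Numeric agreement with the original published comparison tool is not
  expected pair-by-pair: the max-min objective is the same, but the
  recursion (MP splits, solo emissions, one-sided bifurcation policy) is
  this package's own, and the published tool's recursion details are not
  public record.
* Local-alignment mode, EL states, and HMM filter sections of newer CM
  files are out of scope; files carrying them parse only if their core
  sections fit the supported skeleton.
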