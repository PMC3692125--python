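# cmlink

Pairwise comparison of RNA family covariance models via **Link scores**.

Covariance models (CMs) — profile stochastic context-free grammars built by
Infernal from structural alignments — describe RNA families by conserved
sequence *and* secondary structure. Before a new family model joins a
database like Rfam, a curator wants to know whether a similar model already
exists, whether the model lacks specificity, or whether the overlap reflects
real shared ancestry (a candidate *clan*). `cmlink` answers these questions
by computing, for any pair of models, the sequence that both models like at
once:

> For models *A* and *B*, the **Link sequence** is the sequence *s*
> maximizing `min(score_A(s), score_B(s))`, where `score_M(s)` is the
> optimal global parse score of *s* under *M* in bits. The maximized value
> is the **Link score**. A Link score of 20 bits certifies a concrete
> sequence scoring at least 20 bits in *each* model.

High Link scores flag duplicated or non-specific models; a group of models
with mutually high Link scores but low scores to everything else is a clan
candidate. The computation is a dynamic program over the product of the two
state machines (quadratic in the state counts) that jointly emits one common
sequence and keeps, per state pair, the Pareto frontier of achievable score
pairs, so the final max-min selection is exact over the representable
joint-parse space. See `docs/methods.md` for the recursion and its
guarantees.

The package reads and writes both generations of the Infernal CM ASCII
format (multi-model files included), scores sequences against single models
(CYK), computes each model's best achievable sequence, runs
one-vs-database and all-vs-all comparisons with filtering, and renders
results as TSV tables, Link-score matrices, weighted DOT graphs and per-pair
detail views. A generator for small, fully valid synthetic CMs supports
testing and benchmarking without any external data.

## Worked example

Build three small models — two hairpins estimated from the same family with
different seeds, and one model of the same consensus without the stem — and
compare them all against all:

```sh
$ cmlink all-vs-all hairpinA.cm hairpinB.cm loopy.cm
modelA	modelB	scoreA	scoreB	linkScore	linkSequence	structureA	structureB
hairpinB	loopy	10.6	11.6	10.6	GCGAAAGC	((....))	........
hairpinA	hairpinB	10.5	10.6	10.5	GCGAAAGC	((....))	((....))
hairpinA	loopy	10.5	11.6	10.5	GCGAAAGC	((....))	........
```

Every pair shares the consensus `GCGAAAGC` as its Link sequence. The two
hairpin models link at 10.5 bits — essentially their best achievable scores,
so one of them is redundant. The unpaired model links to both hairpins just
as strongly: the stem contributes structure, but the sequence signal alone
is enough for either model to accept the other's best sequence — exactly the
specificity problem Link scores are designed to expose. The two structure
columns show each model's proposed consensus structure for the link
sequence: the hairpin keeps its stem, the unpaired model reads the same
positions as single-stranded.

The per-pair detail view adds each model's re-optimized score of the link
sequence (the joint parse is one admissible parse; a model's own optimum may
be higher):

```sh
$ cmlink report detail hairpinA.cm loopy.cm
model A       : hairpinA
model B       : loopy
score A       : 10.5 bits
score B       : 11.6 bits
Link score    : 10.5 bits
Link sequence : GCGAAAGC
structure A   : ((....))
structure B   : ........
re-optimized A: 10.5 bits
re-optimized B: 11.6 bits
```

The matrix view (`--format matrix`) prints all pairwise Link scores with
each model's best achievable score on the diagonal; `--format dot` emits the
thresholded weighted graph for graphviz. `cmlink vs-db -q query.cm --db
models/` compares queries against a directory of CM files, with
`--min-link`, `--name` and `--top` filters matching the result-list
filtering of the comparison workflow.

The demo models above were generated with the built-in fixture recipe:

```python
from cmlink import ToyModelSpec, build_toy_cm, write_cm_file, Dialect
spec = ToyModelSpec("GCGAAAGC", "((....))", seed=11, name="hairpinA")
open("hairpinA.cm", "w").write(write_cm_file([build_toy_cm(spec)], Dialect.INFERNAL_1_0))
```

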