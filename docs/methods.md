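# Methods

## The model

`lcsurp` implements an incremental probabilistic left-corner parser used as
a surprisal estimator. Surprisal of word *t* is the negative log ratio of
prefix probabilities,

    S(w_t) = -log [ P(w_1..t) / P(w_1..t-1) ],

with prefix probabilities obtained by marginalizing the forward
probabilities of a transition model over hidden parser states:

    P(w_1..t) = Σ_q P(w_1..t, q_t),
    P(w_1..t, q_t) = Σ_{q_t-1} P(w_t, q_t | q_t-1) P(w_1..t-1, q_t-1).

A parser state (store) is a bounded stack of at most *D* nested derivation
fragments. A fragment is an apex/base pair: the apex is a node whose
subtree has been partially built, the base a predicted descendant yet to
come. Each word triggers exactly two decisions:

* a **lexical decision** — either the word's preterminal completes the
  deepest predicted base (*match*), or it starts fresh material
  (*no-match*), together with a lexical predicate-context vector and, on a
  no-match, a preterminal category;
* a **grammatical decision** — either the constituent completed in the
  lexical phase attaches under the next prediction (*match*), or it
  becomes the left corner of a new fragment (*no-match*), together with a
  composition operator and the categories of the new fragment.

The store update carries fragments above the new nonterminal forward,
replaces fragment *d* = depth + 1 − m_lex − m_gram, and nulls everything
deeper. A no-match that would push beyond *D* keeps its probability in the
decision distribution but yields no successor: that mass is pruned, as in
any bounded-memory parser. For an *n*-word sentence the decisions generate
the *n* unary and *n* − 1 binary branches of a CNF tree.

### Categories and predicate contexts

Nodes carry a syntactic category (a label with a valence count and a
non-local-dependency count, in the generalized-categorial-grammar style)
and a binary **predicate context vector** in {0,1}^H with
H = K + V·K + E·K: one block of K entries for the node's own referent, one
block per local argument slot 1..V, and one per non-local slot 1..E. Each
of the K entries is a ⟨predicate, role⟩ pair, laid out as
`predicate * (V+1) + role`. The block order is a package convention; only
the total dimension is fixed by the model.

Composition operators carry two sparse binary matrices: `A` (H×H), whose
transpose maps the completed left child's vector into the parent apex, and
`B` (H×2H), mapping `[outer predicted base ; left child]` into the newly
predicted sibling base. On a grammatical no-match, the base half of B's
input is zeroed. A per-fragment matrix Z propagates contexts from right
progeny back up to fragment apexes; it is pushed as `[0, I] B^T` on a
no-match, right-multiplied by the same factor on a match, and popped when a
fragment completes. Vector "addition" in the node-construction equations
is saturating elementwise OR (the vectors are binary by type, and sums can
exceed one). Z matrices are binarized after every product: only
`sat(Z h)` is ever consumed downstream, so binarization is exact and makes
beam merge keys canonical.

The operator inventory is constructed programmatically from the block
layout — identity carry, conjunction carry, argument attachment (role 0
shifted to role k on the predicted sibling), modifier attachment (head
into the modifier's first argument block), and gap introduction/filling
between the own and non-local blocks. This inventory is a
**reconstruction** of the intended operator semantics from the block
structure; it is the part of the model where the package had to make its
own concrete choices, and alternative inventories can be supplied by
replacing `operators.build_operators`.

### Sentence boundaries

The sentence-initial store is empty, with an implicit axiom fragment at
depth 0 whose base is a reserved START category with an all-zero context
vector. The lexical match is unavailable at depth 0 (there is nothing to
complete), and the grammatical match against the axiom is the
sentence-termination event, valid only when it empties the store; it is
collapsed onto a single outcome (operator 0, no category decisions) in the
masked softmax. Prefix probabilities at word t < T sum over live
(continuable) hypotheses; at the final word the reported prefix is the
termination mass, so the last word's surprisal includes the
end-of-sentence decision and per-sentence surprisals telescope exactly to
the negative full-sentence log probability.

### Category sub-decisions

When the lexical decision is a match, the preterminal's category is
inherited from the prediction, so no category is generated (probability
one); likewise the parent category of a grammatical match is the satisfied
prediction's category. Only genuinely free categories are generated by the
classifiers. This keeps every decision distribution normalized over its
true support; the same masks are applied in training and decoding.

## Parameterizations

Two interchangeable parameterizations drive the transition:

**Neural** (the estimator proper): embedding matrices with one row per
category and one per context entry (a node embeds as its category row plus
the rows of its active contexts); one-hidden-layer tanh feedforward
scorers over `[one-hot depth, embedded conditioning nodes]` for the joint
(match, context-vector) and (match, operator) decisions; chained category
classifiers; and a character-level word model. The word model generates a
lemma character-by-character with a recurrent network conditioned on the
preterminal category and lexical context vector (framed by start/end
symbols), then classifies a morphological rule from a second recurrent
pass over the lemma without framing symbols. A word's probability sums
over all ⟨lemma, rule⟩ analyses that regenerate it exactly; the identity
rule guarantees at least one analysis, which is how out-of-vocabulary
forms receive finite probability. The recurrent cell is gated (GRU) by
default with hidden size 128, configurable down to a simple recurrent
cell; the experiments in this repository use hidden size 24, which is
ample for the toy grammars. All layers are plain numpy with hand-written
gradients (verified against finite differences in the test suite) and are
trained with Adam on the exact per-decision cross-entropies; runs are
bit-reproducible given a seed.

**Tabular**: explicit conditional tables over the same supports, keyed by
the same conditioning features the neural scorers see (depth, category
ids, lexical context). The synthetic-grammar module compiles toy grammars
into tabular parameterizations and uses them as generators, which makes
maximum-likelihood recovery well-posed: the generator's conditionals are
functions of features the student observes.

Morphological rules are single-leading-wildcard suffix substitutions
(`%ay→%aid`), with reserved ids 0/1 for the identity and "no semantics"
rules. Unknown characters map to a reserved UNK character embedding;
unknown categories/contexts map to reserved UNK ids at decode time.
Lexical context vectors are enumerated over the inventory observed in
training plus the all-zero vector — the full {0,1}^H support is
intractable and training data defines the reachable set.

### Ablations

* **-cat** zeroes the category contribution in the lexical and grammatical
  conditioning features (the word model keeps its category input), and is
  retrained from scratch under the ablated architecture.
* **-morph** replaces the character-based word model with a
  relative-frequency table of words conditioned on the preterminal
  category, with additive smoothing (α = 1) over the training vocabulary
  plus one unknown cell. Novel forms receive exactly the unknown-cell
  floor, regardless of their morphological decomposability.

## Inference

`exact_forward` keeps every reachable (store, Z) hypothesis and raises
rather than truncating when a state budget is exceeded; it is the oracle
for small models. `beam_forward` merges duplicate hypotheses by summing
probability, keeps the top `beam_size` by forward probability (canonical
tie-breaking on the serialized state), and reports prefix probabilities
that lower-bound the exact values and are non-decreasing in beam size.
The default beam width is 5000. An emptied beam is a parse failure: the
affected words receive a configurable floor surprisal (default 25 nats)
and are flagged, rather than aborting a corpus run. Corpus perplexity is
`exp(mean per-token surprisal in nats)`; internal log base is natural and
outputs report both nats and bits.

`accepted_mass` computes the total probability of terminating within a
length cap by a state-level aggregated forward pass (marginalizing the
word support at each step) — polynomial where sentence-level enumeration
is exponential. `enumerate_language` does enumerate sentences, and is
practical only for small, termination-heavy tabular models.

## Synthetic data

The generator defines toy grammars: categories with bounded valence,
weighted binary rewrite rules with operator assignments, a lexicon of
(lemma, category, predicate) entries, and morphological rules with
application weights. Sampling is ancestral through the transition model
itself (the grammar is compiled to tables first); rewrite weights enter as
the relative weights of compatible grammatical decisions, so production
frequencies follow the *renormalized* weights per conditioning state.
Sampled trees are annotated by replay: preterminals store the lexical
increment vector, internal nodes their creation-time vector — the
convention the left-corner oracle inverts. Draws that exceed the length
cap or the depth bound are rejected and counted; the rejected mass is
exactly the complement of `accepted_mass`, which matters when comparing
perplexities (below). Every category is guaranteed to occur as a left
corner (a category that never does would dead-end its derivations).

What the toy grammars do **not** emulate: lexical scale (tens of lemmas,
not tens of thousands), attachment ambiguity of natural treebanks, rich
morphological paradigms, and any discourse or frequency structure. Passing
tests therefore certify the algorithmic machinery — transform
bijectivity, normalization, marginalization, recovery — not psycholinguistic
adequacy on real corpora.

## The recovery study

The parameter-recovery check trains the neural model on 10,000 sentences
sampled from a fixed toy generator (two categories, two predicates, V = 1,
E = 0, D = 2, substitution morphology) and compares held-out per-token
perplexity (150 sentences, beam 300) against the generator's own
perplexity. Because sampling rejects overlength (> 10 tokens) and
depth-pruned draws, the sample follows the generator's *length-bounded,
renormalized* language; the generator reference is therefore its raw
held-out perplexity corrected by the enumerated accepted mass Z:

    ppl_gen = exp( (Σ_s -log P(s) + N·log Z) / Σ_s |s| ).

Both quantities are computed on the same held-out sentences, so sentence
sampling noise largely cancels in the ratio. Optimizer settings (Adam,
learning rate 0.01, batch 32, 10 epochs, embedding width 12, hidden 24)
were chosen for reliable convergence at this scale; the training
likelihood plateaus after two to three epochs.

## Numerical choices

* probability space: float64 throughout; log-sum-exp for all
  marginalizations; distributions checked to 1e-9.
* saturation: binary vectors via `> 0`; exact for all downstream uses.
* tie-breaking: canonical lexicographic order on (match bit, operator id,
  category id, serialized context vector) wherever outcomes tie — beam
  boundaries, operator inference in the oracle.
* depth one-hot input covers 0..D; deeper values clamp to D.
* degenerate inputs: empty stores mid-sentence, matches above the store
  top, and non-finite losses raise typed errors rather than propagating
  NaNs; malformed treebank/rule lines report their line numbers.

## Oracle (tree ↔ decisions)

`tree_to_decisions` recovers match bits and categories structurally and
infers each binary branch's composition operator by inverting the
annotated context vectors against the operator inventory, with depth-first
backtracking across steps and lowest-id tie-breaking where several
operators explain the same annotations (operator ids are not stored in the
treebank dialect). On generator-produced treebanks the transform is exact:
tree → decisions → tree is the identity, and re-extraction of a rebuilt
tree is idempotent. Distinct operators that are annotation-equivalent on a
particular tree (same visible vectors, different hidden Z effects) are
canonicalized to the lowest id; this is the one place where a sampled
decision sequence and its extracted counterpart can differ.

## Response-data preprocessing

The self-paced-reading filter drops sentence-initial/final words, subjects
below the comprehension threshold (fewer than four correct), and durations
strictly below 100 ms or strictly above 3000 ms; the eye-tracking filter
drops unfixated words, words following saccades strictly longer than four
words, and words at starts/ends of sentences, screens, documents, and
lines. Boundary strictness can be flipped with `closed=True`. Filters are
idempotent (boundary flags are materialized on first application) and
order-independent. Alignment with a surprisal table is by sentence and
token index with the word form checked, an explicit detokenization map for
tokenization mismatches, and a hard error below a configurable alignment
rate; unmatched tokens are always reported. Exploratory/held-out
partitioning of response data is deliberately left to a user-supplied
assignment — the package computes totals without imposing a scheme.

## Known limitations

* The composition-operator inventory is a reconstruction (above); models
  trained with a different inventory are not interchangeable.
* Beam prefix probabilities are lower bounds; surprisal from small beams
  is biased upward, most visibly on high-ambiguity prefixes.
* The neural scorers are CPU-bound, single-example numpy: adequate for toy
  inventories, far from treebank scale.
* Lexical-context support enumeration is global (one inventory shared by
  all categories), a superset of the per-(category, rule) supports seen in
  training.
* `enumerate_language` is exponential in sentence length and intended for
  termination-heavy toy grammars only; use `accepted_mass` for
  normalizers.
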