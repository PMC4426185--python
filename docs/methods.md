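# Methods

## The extraction task and its representation

A document is read into a layered structure: paragraphs, sentences, tokens,
each token carrying surface form, lemma, POS tag, dependency head and
relation, an optional external concept tag, capitalization and stopword
flags.  Gold annotations are standoff: typed character spans (Bacterium,
Habitat; spans 0-based and end-exclusive, possibly discontinuous) and binary
Localization relations between a bacterium and a habitat.  In relation
arguments the corpus convention types the habitat role "Localization"; the
parser maps it back to Habitat.

The output of the model is a set of binary labels attached to *candidates*:

* phrase candidates — contiguous token runs proposed by a chunker and kept
  only if they share a token with the habitat lexicon (habitat candidate,
  `lm`), with the bacterium taxonomy (`tr`), or both.  Every candidate also
  carries the auxiliary no-role label `nrol`.
* relation candidates — the full cross product of bacterium and habitat
  candidates of the document, each carrying `loc` and its complement `nloc`.
* relation-pair candidates — each relation chained with its successor in the
  canonical ordering (bacterium span start, then habitat span start).  This
  keeps the pair set linear in the number of relations; the unconstrained
  pairing would be quartic in the number of entity candidates.  Pairs carry
  the label `rr` ("both relations hold").

Six templates tie each label type to a feature function and a block of the
weight vector.  The no-role template reuses the phrase feature function with
its own block; no-localization reuses the pair features.  A per-template
`bias` feature is included in every vector — standard linear-model plumbing.
The score of an assignment is the sum over templates and active candidates
of the block–feature dot products, and equals `<W, f(x, y)>` for the joint
feature map that sums each candidate's vector into its block when its label
is on (an identity the tests check numerically).

Hard constraints make the output coherent: exactly one of `tr/lm/nrol` per
phrase; exactly one of `loc/nloc` per relation; `loc_ij ≤ tr_i` and
`loc_ij ≤ lm_j` (a relation needs both entities); `rr ≤ loc` for both
members of a chained pair.  Labels a candidate is not eligible for (e.g.
`tr` of a habitat-only phrase) are fixed to zero rather than given
variables.

## Features

Four families, namespaced `word:` / `phrase:` / `pair:` / `relpair:`.  All
are indicators with value 1 except the parse-distance stand-in and the
relation-pair similarity, which are reals in [0, 1].

* word: surface, lemma, POS, dependency relation, concept tag,
  capitalization, stopword membership.
* phrase: the head token's word features (`head:`), the remaining tokens'
  (`nhead:`), concatenated surface, POS-tag sequence, and
  overlap/containment/inverse-containment flags against both lexicons after
  normalization.  The head is the token whose dependency head lies outside
  the phrase, falling back to the last token.
* pair: same-paragraph, same-sentence, bacterium-in-title; when the
  arguments share a sentence, the verb and the preposition strictly between
  them that lie closest to the habitat argument (ties broken leftmost), a
  token distance normalized by sentence length, the POS sequence between the
  arguments, and the dependency path between the heads; always, the
  concatenated head lemmas and head POS tags.  The token-distance and
  POS-sequence features stand in for parse-tree distance and parse path when
  no constituency layer exists (the synthetic corpus has none); the
  substitution sits behind the `parse_fallback` feature-config flag.
* relation pair: a shared-bacterium indicator (same candidate instance), and
  the similarity of two relations: the geometric mean of the edit similarity
  of the normalized bacterium mentions and the edit similarity of the
  habitats' representatives.  Each habitat is represented by its
  best-matching ontology node's name; when the ontology offers no match the
  normalized surface phrase stands in (a documented fallback, since the
  behaviour in that case is otherwise undefined).

Normalization: bacterium names drop the strain/species marker tokens
{str., str, spp., spp, strain, sp., sp, subsp} (matched with or without a
trailing period), habitat phrases drop a small bundled stopword list; both
case-fold by default (ontology matching case sensitivity is configurable;
folded is the default).  Edit similarity is 1 − Levenshtein/max-length,
computed by edlib, defined as 1 for two empty strings.

## Inference

Prediction and loss-augmented inference are binary linear programs solved
exactly with HiGHS (`scipy.optimize.milp`, `mip_rel_gap=0`).  Tie-breaking
is deterministic: among optima the lexicographically smallest variable
vector in the canonical order (tr, lm, loc, then the auxiliaries nrol,
nloc, rr) is returned, implemented by fixing variables to zero one at a time
whenever the optimum is preserved.  With all-zero weights this yields the
all-no-role / all-no-localization output.  A brute-force enumerator with the
identical contract (refusing problems above 24 variables) serves as the
validation oracle; the equivalence suite compares the two on random
instances in all four constraint regimes.  The training loop skips the
lexicographic refinement — any optimum is a most-violated competitor — which
keeps it one solver call per example per iteration.

## Training

n-slack cutting-plane structured SVM with margin rescaling:

    min ½‖W‖² + C Σ_i ξ_i   s.t.  <W, Ψ(x_i,y_i) − Ψ(x_i,y)> ≥ Δ(y_i, y) − ξ_i

The loss is the decomposed Hamming loss `Δ_p = (1/|C_p|)(Σ(1−2y'_i)y_i +
Σ y'_i)` — algebraically the normalized Hamming distance for binary labels —
averaged over the label types that are the direct targets (tr, lm, loc);
the per-type weights of the average are configurable, unweighted by
default, and an empty candidate set contributes zero.  In the loss-augmented
objective the loss adds `(1−2·gold_i)/(m·|C_p|)` to each included variable's
coefficient; the constant term drops out of the argmax.

Defaults are the untuned setting C = 0.01 and termination tolerance
e = 1e-4.  The slack term is `C Σξ` (the common n-slack implementation
convention) rather than `C/n Σξ`: with the latter, C = 0.01 at this corpus
scale over-regularizes to the point that even linearly separable data is
not fit, which contradicts the behaviour the model family is meant to
exhibit.  The working-set QP is solved in the dual — one
simplex-with-slack of radius C per example — by deterministic coordinate
ascent plus within-example pairwise exchange (SMO-style) steps, iterated to
a relative objective change of 1e-14 (capped at 5000 passes), well below
the outer tolerance.  Constraints are deduplicated by label signature.  The
random seed controls only the order in which examples are visited; inference
and the QP are deterministic.  The QP objective sequence is non-decreasing
across iterations (a tested invariant), and at termination every stored
constraint is violated by at most its example's slack plus e.  Training on
class-imbalanced relation candidates is done as-is, without subsampling:
the joint formulation, not resampling, is the mechanism addressing the
imbalance.

Variants:

| variant  | training                          | prediction        |
|----------|-----------------------------------|-------------------|
| LO       | entity model (constraint: entity exclusivity, loss tr+lm) and relation model (relation exclusivity, loss loc), independently | independent |
| L+I      | LO weights                        | joint             |
| IBT-I    | joint (role links active)         | independent       |
| IBT+I    | joint                             | joint             |
| IBT+IG1  | joint + rr links, Same-B feature  | joint + rr        |
| IBT+IG2  | as IG1 plus Sim-BH                | joint + rr        |

Including both entity types in the LO entity loss (mean of tr and lm) is a
choice consistent with "loss over the directly targeted labels"; the paper
family leaves the split's exact weighting open.

## Evaluation

Precision, recall and F1 per target (Bacterium, Habitat, Localization),
micro-averaged over documents; zero denominators score zero.  Entities are
matched one-to-one greedily in span order — strict mode requires the exact
span set and type, relaxed mode any one-character overlap of any fragment
(the official scorer's matching algorithm and overlap threshold are not
published; these conventions are documented so scores are reproducible
within this artifact).  A relation is correct when both arguments are
matched to the arguments of one gold relation.  Sentence-level evaluation
restricts predicted and gold relations to argument pairs within a single
sentence before counting.  Discontinuous gold entities match strictly only
on the full span set, relaxed on any fragment.  Relation types that were
not modelled (e.g. part-of links between habitats) can either be dropped
from gold or counted as unrecoverable misses.

## The synthetic corpus

The generator emulates the corpus structure the model exploits, at desk
scale, using a template grammar rather than natural prose so that the
linguistic layers stay self-consistent and recoverability is provable:

* a title naming the document's main bacterium with probability
  `p_title_bacterium` (default 0.9);
* a title paragraph whose habitat-only sentences ("The <habitat> was
  sampled .") are exactly the habitats related to the title bacterium
  across sentence boundaries (drawn with `p_cross_sentence_relation`,
  default 0.3);
* a body paragraph with intra-sentence relation sentences ("<Bacterium>
  colonizes the <habitat> .", `p_intra_sentence_relation`, default 0.4,
  localization verbs colonize/infect/populate/inhabit), distractor habitat
  mentions with no relation (`p_distractor_mention`, default 0.15, half of
  them co-occurring with a bacterium under a neutral verb), and filler;
* bacterium surface variants inserting strain markers ("str.", "subsp.")
  so normalization and the similarity features are exercised; the taxonomy
  contains both the plain and the strain-qualified names, so gazetteer
  longest-match chunking recovers every gold mention span (candidate recall
  is 1 on zero-noise corpora — a tested invariant);
* deterministic lemma/POS/dependency layers from the template slots; no
  constituency layer.

Intra-sentence relation sentences are placed outside the title paragraph.
This makes gold a deterministic function of the pair-feature signature
(localization verb for same-sentence pairs; same-paragraph ∧ in-title ∧
different-sentence for cross links) and gives every habitat mention exactly
one gold relation when distractors and noise are off.  The `noise` knob
flips relation labels after generation and is the only source of
feature/label inconsistency.

`planted_weights` returns oracle weights under which the gold labeling is
the argmax with margin ≥ 1 over every other feasible assignment when the rr
template is disabled: lexicon-overlap flags carry the entity labels (gap 2),
the verb indicator carries intra-sentence relations (+1 vs 0), same-par +
in-title carry cross links (+1 vs at most −1).  With rr enabled, the small
rr bias (0.25) switches rr on exactly where both chained relations hold but
gives rr-only deviations a gap of only 0.25 — a full unit gap on rr would
let an rr gain pay for flipping a gold no-relation label on, so the margin
guarantee is stated for the no-rr scope and the margin test runs there.

What passing on this corpus does and does not show: the generator has no
anaphora, no nested or discontinuous gold entities, no boundary ambiguity
(every gold mention is a lexicon term), and its relations are a
deterministic function of shallow features.  Results on it validate the
machinery — exact inference, convergence, recoverability, the relative
behaviour of the variants — not performance on real biomedical prose, where
candidate recall, coreference and boundary detection dominate.

## Problem sizes and numerical choices

The bundled experiments use 50 documents of 4–8 body sentences (40
training / 10 held-out), lexicons of 12 bacteria (plus strain-qualified
forms) and 15 habitat terms; training a joint variant takes seconds on one
CPU and the full variant comparison a few minutes.  Solver exactness is
checked on random instances of ≤ 12 variables against enumeration, with
zero MIP gap and a 1e-9 comparison tolerance; the lexicographic refinement
re-solves with a tolerance of 1e-9 scaled by the optimum.  Degenerate
inputs are defined: empty documents produce empty candidate sets and empty
problems (score 0, empty assignment); an empty training corpus returns zero
weights after zero iterations; empty candidate sets contribute zero loss.

## Known limitations

* No coreference or anaphora handling; cross-sentence recall on real data
  would be bounded by it.
* No nested-entity candidates; discontinuous entities are parsed and scored
  but never proposed by the bundled chunkers.
* The official shared-task scorer is not reproduced byte-for-byte; strict /
  relaxed / sentence-level conventions are as documented above.
* Ontology graph structure (is-a traversal) is unused; matching is purely
  lexical over names, synonyms and related terms.
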