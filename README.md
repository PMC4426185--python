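# lalex

Joint extraction of **bacteria**, their **habitats**, and the **localization
relations** between them from text with standoff annotations, using a
constrained structured-prediction model ("link-and-label") trained as a
margin-rescaling structured SVM.

Finding where a bacterium lives — *Bifidobacterium longum* in the *human
gut*, *Listeria* in *raw milk* — means solving two coupled problems: typing
candidate phrases as Bacterium, Habitat or neither, and deciding which
bacterium–habitat pairs stand in a localization relation, often across
sentence boundaries.  Pipelines that decide these independently do poorly on
the relations: most candidate pairs are negative, and a relation asserted on
a phrase that was not even recognized as an entity is incoherent.  `lalex`
couples the decisions through joint constrained inference.

## The model

For a document, candidate phrases (token runs overlapping a habitat ontology
or a bacterium taxonomy) carry binary labels `tr` (bacterium), `lm`
(habitat) and `nrol` (no role); candidate pairs carry `loc` / `nloc`;
chained pairs of relations carry `rr`.  The score of a full assignment *y*
is linear in blocked weights:

```
Obj = Σ_k <W_tr,  φ(x_k)> tr_k + Σ_k <W_lm, φ(x_k)> lm_k + Σ_k <W_nrol, φ(x_k)> nrol_k
    + Σ_ij <W_loc, φ(x_ij)> loc_ij + Σ_ij <W_nloc, φ(x_ij)> nloc_ij
    + Σ <W_rr, φ(..)> rr_...
```

subject to: `tr_k + lm_k + nrol_k = 1`, `loc_ij + nloc_ij = 1`,
`loc_ij ≤ tr_i`, `loc_ij ≤ lm_j`, and `rr ≤ loc` for both chained relations.
Prediction is an exact 0/1 linear program (HiGHS).  Training minimizes
`½‖W‖² + C Σ_i ξ_i` with margin-rescaled constraints via cutting planes; the
loss is the decomposed Hamming loss `Δ_p = (1/|C_p|)(Σ(1−2y'_i)y_i + Σy'_i)`
averaged over the targeted label types (tr, lm, loc).  Six experimental
variants cover independent vs joint training × independent vs joint
prediction (`LO`, `L+I`, `IBT-I`, `IBT+I`) plus relation-pair features
(`IBT+IG1` with the shared-bacterium indicator, `IBT+IG2` adding the
argument-similarity score).

Inputs are BioNLP-ST-style standoff files (`.txt` + `.ann` with T/R lines,
plus CoNLL-style token layers), an OBO or TSV habitat lexicon and a
newline-delimited taxonomy list.  A bundled synthetic-corpus generator
produces all of these with the statistical structure the model assumes
(titles naming the document's bacterium, intra- and cross-sentence links,
distractor mentions, lexicon-overlapping surface variants).

## Worked example

```python
import lalex as lx
from lalex.synthetic import GeneratorConfig, generate_corpus
from lalex.training import TrainingConfig, train, predict, to_standoff

corpus, ont, tax = generate_corpus(GeneratorConfig(n_docs=50, seed=1))
pcfg = lx.PipelineConfig()                      # gazetteer chunking, exact alignment
train_ex = [lx.prepare_example(d, a, ont, tax, pcfg) for d, a in corpus.items[:40]]
test     = corpus.items[40:]
test_ex  = [lx.prepare_example(d, a, ont, tax, pcfg) for d, a in test]

model = train(train_ex, TrainingConfig(variant="IBT+I", seed=1))
triples = [(to_standoff(predict(model, ex), ex, doc, strict=False), ann, doc)
           for (doc, ann), ex in zip(test, test_ex)]
rep = lx.evaluate_corpus(triples, mode="strict")
for t in ("Bacterium", "Habitat", "Localization"):
    c = rep[t]
    print(f"{t:12s} P={c.precision:.3f} R={c.recall:.3f} F1={c.f1:.3f}")
```

prints

```
Bacterium    P=1.000 R=1.000 F1=1.000
Habitat      P=1.000 R=1.000 F1=1.000
Localization P=1.000 R=1.000 F1=1.000
```

i.e. on the zero-noise synthetic corpus the jointly trained model recovers
the generating rule exactly on held-out documents: entities are carried by
the lexicon-overlap features, intra-sentence relations by the localization
verb between the arguments, and cross-sentence relations by the
same-paragraph and bacterium-in-title features.  The same run from the
shell:

```bash
lalex run-all --seed 1 --n-test 10 --report variants.json
```

## Command line

```bash
lalex simulate --config gen.yaml --out-dir corpus/      # corpus + lexicons
lalex train    --corpus corpus/corpus --ontology corpus/ontology.obo \
               --taxonomy corpus/taxonomy.txt --variant IBT+I --out model.json
lalex predict  --corpus ... --model model.json --out-dir preds/
lalex evaluate --pred-dir preds/ --gold-dir corpus/corpus \
               --mode strict --level document --report report.json
```

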