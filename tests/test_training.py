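"""Cutting-plane structured-SVM training, variants and prediction."""

import pytest

import lalex as lx
from lalex.candidates import LabelAssignment, align_gold, build_candidate_set
from lalex.features import attach_features
from lalex.inference import VariantConfigError
from lalex.lexicons import HabitatOntology, OntologyNode, TaxonomyLexicon
from lalex.model import WeightVector, is_feasible
from lalex.standoff import AnnotationSet, EntityAnnotation, RelationAnnotation, TextSpan
from lalex.synthetic import GeneratorConfig, generate_corpus
from lalex.training import (
    TrainedModel,
    TrainingConfig,
    predict,
    to_standoff,
    train,
    training_loss,
)
from tests.conftest import make_doc


def _separable_fixture():
    """Two-sentence documents where the verb separates relations and the
    lexicon flags separate entity types."""
    ont = HabitatOntology([OntologyNode("O1", "soil"), OntologyNode("O2", "milk")])
    tax = TaxonomyLexicon(["Listeria", "Bacillus"])
    docs = []
    for i, (bact, verb, hab, verb2, hab2) in enumerate(
        [
            ("Listeria", "colonizes", "soil", "resembles", "milk"),
            ("Bacillus", "colonizes", "milk", "resembles", "soil"),
            ("Listeria", "colonizes", "milk", "resembles", "soil"),
            ("Bacillus", "colonizes", "soil", "resembles", "milk"),
            ("Listeria", "colonizes", "soil", "resembles", "milk"),
            ("Bacillus", "colonizes", "milk", "resembles", "soil"),
            ("Listeria", "colonizes", "milk", "resembles", "soil"),
            ("Bacillus", "colonizes", "soil", "resembles", "milk"),
        ]
    ):
        doc = make_doc(
            f"sep{i}",
            [
                [(bact, bact.lower(), "NNP", 1, "nsubj", "Organism"),
                 (verb, verb[:-1], "VBZ", None, "root"),
                 (hab, hab, "NN", 1, "obj", "Habitat"),
                 (".", ".", ".", 1, "punct")],
                [(bact, bact.lower(), "NNP", 1, "nsubj", "Organism"),
                 (verb2, verb2[:-1], "VBZ", None, "root"),
                 (hab2, hab2, "NN", 1, "obj", "Habitat"),
                 (".", ".", ".", 1, "punct")],
            ],
        )
        spans = []
        cursor = 0
        for w in (bact, hab, bact, hab2):
            start = doc.text.index(w, cursor)
            spans.append(TextSpan(start, start + len(w)))
            cursor = start + len(w)
        entities = [
            EntityAnnotation("T1", "Bacterium", (spans[0],), bact),
            EntityAnnotation("T2", "Habitat", (spans[1],), hab),
            EntityAnnotation("T3", "Bacterium", (spans[2],), bact),
            EntityAnnotation("T4", "Habitat", (spans[3],), hab2),
        ]
        relations = [RelationAnnotation("R1", "Localization", "T1", "T2")]
        ann = AnnotationSet(entities, relations)
        cands = build_candidate_set(doc, [e.spans[0] for e in entities], ont, tax)
        attach_features(cands, ont, tax)
        align_gold(cands, ann)
        docs.append((doc, ann, cands))
    return docs


class TestCuttingPlane:
    def test_empty_corpus_yields_zero_weights_and_no_iterations(self):
        model = train([], TrainingConfig(variant="IBT+I"))
        assert model.report.iterations == 0
        assert model.weights.norm_sq() == 0.0

    def test_separable_fixture_reaches_zero_training_loss(self):
        fixture = _separable_fixture()
        examples = [c for _, _, c in fixture]
        model = train(examples, TrainingConfig(variant="IBT+I", seed=0))
        assert model.report.converged
        assert model.report.final_max_violation <= 1e-4
        assert training_loss(model, examples) == 0.0
        # the separating verb indicator carries positive relation weight
        assert model.weights["loc"].get("pair:verb=colonize", 0.0) > 0.0

    def test_lo_training_reaches_zero_loss_independently(self):
        fixture = _separable_fixture()
        examples = [c for _, _, c in fixture]
        model = train(examples, TrainingConfig(variant="LO", seed=0))
        assert model.report.converged
        assert training_loss(model, examples) == 0.0

    def test_qp_objective_is_non_decreasing(self):
        fixture = _separable_fixture()
        examples = [c for _, _, c in fixture]
        model = train(examples, TrainingConfig(variant="IBT+I", seed=0))
        objs = model.report.qp_objectives
        assert len(objs) >= 1
        assert all(b >= a - 1e-12 for a, b in zip(objs, objs[1:]))

    def test_margin_constraints_hold_at_termination(self):
        from lalex.inference import build_problem, solve
        from lalex.model import score as model_score

        fixture = _separable_fixture()
        examples = [c for _, _, c in fixture]
        cfg = TrainingConfig(variant="IBT+I", seed=0)
        model = train(examples, cfg)
        # up to its slack, no example's most-violating competitor beats the
        # margin-rescaled constraint by more than the tolerance e
        slacks = model.report.slacks
        assert len(slacks) == len(examples)
        for ex, xi in zip(examples, slacks):
            prob = build_problem(
                model.weights, ex, "joint", loss_terms=(ex.gold, cfg.loss_types)
            )
            y_hat = solve(prob, lexicographic=False)
            loss = lx.hamming_loss(ex, y_hat, ex.gold, cfg.loss_types)
            margin = model_score(model.weights, ex, ex.gold) - model_score(
                model.weights, ex, y_hat
            )
            assert xi >= -1e-12
            assert loss - margin <= xi + cfg.tol + 1e-9


class TestPredict:
    def test_zero_weight_model_predicts_all_auxiliary(self):
        fixture = _separable_fixture()
        _, _, cands = fixture[0]
        model = TrainedModel(weights=WeightVector.zeros(), config=TrainingConfig(variant="LO"))
        y = predict(model, cands, mode="independent")
        assert y.nrol.all() and y.nloc.all()

    def test_joint_prediction_satisfies_all_constraints(self):
        corpus, ont, tax = generate_corpus(GeneratorConfig(n_docs=8, seed=6))
        pcfg = lx.PipelineConfig()
        examples = [lx.prepare_example(d, a, ont, tax, pcfg) for d, a in corpus]
        model = train(examples[:6], TrainingConfig(variant="IBT+I", seed=0))
        for ex in examples:
            y = predict(model, ex, mode="joint")
            assert is_feasible(ex, y)

    def test_joint_mode_suppresses_relation_without_entities(self):
        fixture = _separable_fixture()
        _, _, cands = fixture[0]
        W = WeightVector.zeros()
        W["loc"]["bias"] = 1.0   # relations look attractive on their own
        W["nrol"]["bias"] = 1.0  # but entity models prefer no-role
        model = TrainedModel(weights=W, config=TrainingConfig(variant="LO"))
        y_ind = predict(model, cands, mode="independent")
        assert y_ind.loc.any() and y_ind.nrol.all()  # inconsistent local views
        y_joint = predict(model, cands, mode="joint")
        assert not y_joint.loc.any()  # role links arbitrate
        assert is_feasible(cands, y_joint)

    def test_ig_variant_requires_relation_pair_features(self):
        fixture = _separable_fixture()
        examples = [c for _, _, c in fixture]
        with pytest.raises(VariantConfigError):
            train(examples, TrainingConfig(variant="IBT+IG1", seed=0))


class TestToStandoff:
    def test_all_auxiliary_prediction_gives_empty_annotations(self):
        fixture = _separable_fixture()
        doc, _, cands = fixture[0]
        y = LabelAssignment.zeros(cands)
        y.nrol[:] = 1
        y.nloc[:] = 1
        ann = to_standoff(y, cands, doc)
        assert ann == AnnotationSet()

    def test_entities_and_relation_materialize(self):
        fixture = _separable_fixture()
        doc, gold_ann, cands = fixture[0]
        ann = to_standoff(cands.gold, cands, doc)
        assert len(ann.entities) == 4 and len(ann.relations) == 1
        assert ann == gold_ann

    def test_alignment_round_trip_recovers_the_labels(self):
        fixture = _separable_fixture()
        for doc, _, cands in fixture:
            y = cands.gold
            ann = to_standoff(y, cands, doc)
            y2 = align_gold(cands, ann)
            assert y2 == y

    def test_strict_mode_rejects_infeasible_predictions(self):
        fixture = _separable_fixture()
        doc, _, cands = fixture[0]
        y = LabelAssignment.zeros(cands)
        y.nrol[:] = 1
        y.nloc[:] = 1
        y.loc[0], y.nloc[0] = 1, 0
        with pytest.raises(ValueError):
            to_standoff(y, cands, doc, strict=True)
        ann = to_standoff(y, cands, doc, strict=False)
        assert len(ann.relations) == 1 and len(ann.entities) == 2
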