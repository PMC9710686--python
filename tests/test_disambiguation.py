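"""Sense classifiers: featurization, training, CV, selection, application."""

import json
import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from bioground.disambiguation import (
    DisambModel,
    DisambRegistry,
    LabeledCorpus,
    LabeledDocument,
    apply_to_matches,
    crossvalidate,
    disambiguate,
    featurize,
    load_corpus_jsonl,
    macro_f1,
    save_corpus_jsonl,
    select_models,
    train_model,
)
from bioground.fixtures import SyntheticCorpusSpec, generate_ambiguous_corpus
from bioground.lexicon import Term, TermStatus
from bioground.stringmatch import MatchFeatures, ScoredMatch

A = ("XNS", "S1")
B = ("XNS", "S2")


def corpus_from(texts_a, texts_b, entity="AMB"):
    docs = [
        LabeledDocument(doc_id=f"a{i}", text=t, label=A)
        for i, t in enumerate(texts_a)
    ] + [
        LabeledDocument(doc_id=f"b{i}", text=t, label=B)
        for i, t in enumerate(texts_b)
    ]
    return LabeledCorpus(entity_text=entity, documents=tuple(docs))


class TestLabeledCorpus:
    def test_requires_two_senses(self):
        with pytest.raises(ValueError, match="senses"):
            corpus_from(["aa bb"], [])

    def test_requires_nonempty_documents(self):
        with pytest.raises(ValueError, match="non-empty"):
            corpus_from(["aa"], [""])

    def test_jsonl_round_trip(self, tmp_path):
        corpus = corpus_from(["alpha kinase", "alpha tumor"], ["beta cell", "beta mouse"])
        path = tmp_path / "corpus.jsonl"
        save_corpus_jsonl(corpus, path)
        assert load_corpus_jsonl(path, "AMB") == corpus


class TestFeaturize:
    def test_disjoint_vocabularies_disjoint_support(self):
        corpus = corpus_from(["aa bb"], ["cc dd"])
        X, vocab, _ = featurize(corpus)
        x0, x1 = X.toarray()
        assert np.sum((x0 > 0) & (x1 > 0)) == 0

    def test_repeated_document_identical_rows(self):
        corpus = corpus_from(["aa bb cc"], ["aa bb cc"])
        X, _, _ = featurize(corpus)
        rows = X.toarray()
        assert np.allclose(rows[0], rows[1])

    def test_hand_computed_tfidf(self):
        """tf-idf of a 3-document corpus against a by-hand oracle using
        idf = ln((1+N)/(1+df)) + 1 and L2 row normalization."""
        corpus = corpus_from(["aa bb", "aa cc"], ["dd dd"])
        X, vocab, idf = featurize(corpus)
        n = 3

        def oracle_idf(df):
            return math.log((1 + n) / (1 + df)) + 1

        # document frequencies: aa:2, bb:1, cc:1, dd:1; bigrams each 1
        assert idf[vocab["aa"]] == pytest.approx(oracle_idf(2))
        assert idf[vocab["bb"]] == pytest.approx(oracle_idf(1))
        # row 0: counts {aa:1, bb:1, "aa bb":1}
        raw = {g: oracle_idf(1) for g in ("bb", "aa bb")}
        raw["aa"] = oracle_idf(2)
        norm = math.sqrt(sum(v * v for v in raw.values()))
        row0 = X.toarray()[0]
        for gram, value in raw.items():
            assert row0[vocab[gram]] == pytest.approx(value / norm)
        # row 2: single repeated token -> weight 1 after normalization
        row2 = X.toarray()[2]
        assert row2[vocab["dd"]] == pytest.approx(
            (2 * oracle_idf(1)) / math.hypot(2 * oracle_idf(1), oracle_idf(1))
        )

    def test_empty_corpus_rejected(self):
        corpus = corpus_from(["aa"], ["bb"])
        object.__setattr__(corpus, "documents", ())
        with pytest.raises(ValueError):
            featurize(corpus)


class TestMacroF1:
    def test_perfect(self):
        assert macro_f1(["a", "b", "a"], ["a", "b", "a"]) == 1.0

    def test_symmetric_confusion(self):
        """TP=3 FP=1 FN=1 per class gives F1 = 0.75 for each class."""
        true = ["a"] * 4 + ["b"] * 4
        pred = ["a"] * 3 + ["b"] + ["b"] * 3 + ["a"]
        assert macro_f1(true, pred) == pytest.approx(0.75)

    def test_all_one_class_predictions(self):
        # class a: P=1/2, R=1 -> F1=2/3 ; class b: no predictions -> 0
        true = ["a", "b"]
        pred = ["a", "a"]
        assert macro_f1(true, pred) == pytest.approx((2 / 3) / 2)

    def test_matches_sklearn_when_all_classes_supported(self):
        from sklearn.metrics import f1_score

        rng = np.random.default_rng(0)
        labels = ["x", "y", "z"]
        true = [labels[i] for i in rng.integers(0, 3, size=60)]
        pred = [labels[i] for i in rng.integers(0, 3, size=60)]
        assert macro_f1(true, pred) == pytest.approx(
            f1_score(true, pred, average="macro", labels=labels)
        )

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            macro_f1(["a"], ["a", "b"])


@pytest.fixture(scope="module")
def three_sense_model():
    corpus = generate_ambiguous_corpus(
        SyntheticCorpusSpec(
            n_senses=3, docs_per_sense=10, vocab_size_per_sense=15,
            doc_length=10, seed=2,
        )
    )
    return train_model(corpus, seed=2, folds=5)


@pytest.fixture(scope="module")
def separable_corpus():
    return generate_ambiguous_corpus(
        SyntheticCorpusSpec(
            n_senses=2, docs_per_sense=100, vocab_size_per_sense=40,
            shared_vocab_fraction=0.0, doc_length=30, seed=11,
        )
    )


class TestTrainModel:
    def test_separable_training_accuracy(self, separable_corpus):
        model = train_model(separable_corpus, seed=1)
        correct = 0
        for doc in separable_corpus.documents:
            probs = disambiguate(model, doc.text)
            if max(probs, key=probs.get) == doc.label:
                correct += 1
        assert correct == len(separable_corpus.documents)

    def test_single_sense_rejected(self):
        with pytest.raises(ValueError):
            corpus_from(["aa bb"] * 5, [])

    def test_sense_below_minimum_named(self):
        corpus = corpus_from(["aa bb"] * 10, ["cc dd"] * 2)
        with pytest.raises(ValueError, match="S2"):
            train_model(corpus, seed=0, folds=5)

    def test_deterministic(self, separable_corpus):
        m1 = train_model(separable_corpus, seed=3)
        m2 = train_model(separable_corpus, seed=3)
        assert np.array_equal(m1.coefficients, m2.coefficients)
        assert m1.cv_macro_f1 == m2.cv_macro_f1

    def test_metadata_populated(self, separable_corpus):
        model = train_model(separable_corpus, seed=3)
        assert model.metadata["seed"] == 3
        assert model.metadata["folds"] == 5
        assert model.metadata["n_docs"] == {"XNS:S1": 100, "XNS:S2": 100}
        assert 0.0 <= model.cv_macro_f1 <= 1.0


class TestCrossvalidate:
    def test_separable_high_f1(self, separable_corpus):
        assert crossvalidate(separable_corpus, folds=5, seed=0) >= 0.95

    def test_shuffled_labels_near_chance(self, separable_corpus):
        rng = np.random.default_rng(5)
        labels = [d.label for d in separable_corpus.documents]
        shuffled = [labels[i] for i in rng.permutation(len(labels))]
        docs = tuple(
            LabeledDocument(doc_id=d.doc_id, text=d.text, label=lbl)
            for d, lbl in zip(separable_corpus.documents, shuffled)
        )
        corpus = LabeledCorpus(entity_text="AMB1", documents=docs)
        assert abs(crossvalidate(corpus, folds=5, seed=0) - 0.5) <= 0.15

    def test_folds_one_rejected(self, separable_corpus):
        with pytest.raises(ValueError):
            crossvalidate(separable_corpus, folds=1, seed=0)

    def test_insufficient_documents_rejected(self):
        corpus = corpus_from(["aa bb"] * 3, ["cc dd"] * 3)
        with pytest.raises(ValueError):
            crossvalidate(corpus, folds=5, seed=0)


class TestSelectModels:
    @staticmethod
    def fake_model(f1):
        model = DisambModel(
            entity_text="X", senses=[A, B],
            vocabulary={"aa": 0}, idf=np.ones(1),
            coefficients=np.zeros((2, 1)), intercepts=np.zeros(2),
            cv_macro_f1=f1,
        )
        return model

    def test_threshold(self):
        models = [self.fake_model(f) for f in (0.65, 0.70, 0.95)]
        kept = select_models(models)
        assert [m.cv_macro_f1 for m in kept] == [0.70, 0.95]

    def test_empty(self):
        assert select_models([]) == []

    def test_cutoff_zero_keeps_all(self):
        models = [self.fake_model(f) for f in (0.1, 0.5)]
        assert select_models(models, cutoff=0.0) == models

    def test_unscored_model_rejected(self):
        with pytest.raises(ValueError):
            select_models([self.fake_model(None)])


class TestDisambiguate:
    def test_sense_vocabulary_context(self, separable_corpus):
        model = train_model(separable_corpus, seed=1)
        sense_a = separable_corpus.senses[0]
        doc = next(d for d in separable_corpus.documents if d.label == sense_a)
        probs = disambiguate(model, doc.text)
        assert probs[sense_a] > 0.9

    def test_out_of_vocabulary_context_gives_intercept_distribution(
        self, separable_corpus
    ):
        model = train_model(separable_corpus, seed=1)
        probs = disambiguate(model, "zzzz qqqq wwww")
        z = model.intercepts - model.intercepts.max()
        expected = np.exp(z) / np.exp(z).sum()
        assert np.allclose(sorted(probs.values()), sorted(expected))

    def test_empty_context_rejected(self, separable_corpus):
        model = train_model(separable_corpus, seed=1)
        with pytest.raises(ValueError):
            disambiguate(model, "  ")

    @settings(derandomize=True, max_examples=100, deadline=None)
    @given(st.text(alphabet="abcdefg s0w1", min_size=1, max_size=60))
    def test_probabilities_sum_to_one(self, three_sense_model, context):
        if not context.strip():
            return
        probs = disambiguate(three_sense_model, context)
        assert abs(sum(probs.values()) - 1.0) < 1e-9
        assert len(probs) == 3


def scored(ns, ident, score, organism=None):
    term = Term(
        namespace=ns, identifier=ident, text=f"T{ident}",
        status=TermStatus.SYNONYM, standard_name=f"STD{ident}", source="x",
        organism=organism,
    )
    features = MatchFeatures(
        query=f"T{ident}", ref=f"T{ident}", exact=True,
        space_dash_mismatch=0, cap_profile=(), plural_dropped=False,
    )
    return ScoredMatch(term=term, score=score, features=features,
                       variant_used=f"t{ident}")


class TestApplyToMatches:
    def test_probability_reorders_ties(self):
        matches = [scored("XNS", "S1", 0.9), scored("XNS", "S2", 0.9)]
        out = apply_to_matches(matches, {A: 0.1, B: 0.9})
        assert out[0].entity == B
        assert out[0].disamb_probability == 0.9

    def test_uniform_probabilities_keep_order(self):
        matches = [scored("XNS", "S1", 0.9), scored("XNS", "S2", 0.9)]
        out = apply_to_matches(matches, {A: 0.5, B: 0.5})
        assert [m.entity for m in out] == [A, B]

    def test_empty(self):
        assert apply_to_matches([], {A: 1.0}) == []

    def test_entity_set_preserved(self):
        matches = [scored("XNS", "S1", 0.8), scored("XNS", "S2", 0.7),
                   scored("YNS", "9", 0.6)]
        out = apply_to_matches(matches, {A: 0.99, B: 0.01})
        assert {m.entity for m in out} == {m.entity for m in matches}

    def test_scores_stay_bounded(self):
        out = apply_to_matches([scored("XNS", "S1", 1.0)], {A: 1.0})
        assert 0.0 <= out[0].score <= 1.0


class TestSerialization:
    def test_round_trip_bit_identical(self, tmp_path, separable_corpus):
        model = train_model(separable_corpus, seed=4)
        model.save(tmp_path / "m")
        loaded = DisambModel.load(tmp_path / "m")
        assert loaded.senses == model.senses
        assert loaded.vocabulary == model.vocabulary
        assert np.array_equal(loaded.idf, model.idf)
        assert np.array_equal(loaded.coefficients, model.coefficients)
        assert np.array_equal(loaded.intercepts, model.intercepts)
        assert loaded.cv_macro_f1 == model.cv_macro_f1
        for doc in separable_corpus.documents[:5]:
            assert disambiguate(loaded, doc.text) == disambiguate(model, doc.text)

    def test_registry_round_trip(self, tmp_path, separable_corpus):
        model = train_model(separable_corpus, seed=4)
        registry = DisambRegistry([model])
        registry.save(tmp_path / "models")
        loaded = DisambRegistry.load(tmp_path / "models")
        assert len(loaded) == 1
        assert loaded.entity_texts() == registry.entity_texts()
        assert loaded.get("amb1") is not None
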