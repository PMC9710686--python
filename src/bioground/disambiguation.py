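"""Per-string sense classifiers for context-aware disambiguation.

Many synonyms are shared between distinct entities (e.g. "DAP4" names
both DLGAP4 and THAP12); string matching alone assigns such candidates
identical scores.  Under the one-sense-per-discourse assumption — an
ambiguous string is used with a single meaning within one document —
each document in which the string appears can carry a single sense
label, and disambiguation becomes document classification: one
classifier per ambiguous string, choosing among that string's senses
given surrounding text.

Models are multinomial logistic regressions over tf-idf weighted
unigram + bigram features.  Generalization is estimated by stratified
5-fold cross-validation scored with macro-averaged F1, and models below
a cutoff (0.7 by default) are excluded from deployment.

The classifier is fitted with scikit-learn; the fitted model is stored
self-contained (vocabulary, idf weights, coefficient matrix) so that
prediction and serialization are independent of the training library
and round-trip bit-identically through JSON.
"""

from __future__ import annotations

import json
import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import sparse

from .stringmatch import ScoredMatch, canonicalize

logger = logging.getLogger(__name__)

__all__ = [
    "LabeledDocument",
    "LabeledCorpus",
    "DisambModel",
    "DisambRegistry",
    "featurize",
    "train_model",
    "crossvalidate",
    "macro_f1",
    "select_models",
    "disambiguate",
    "apply_to_matches",
    "load_corpus_jsonl",
    "save_corpus_jsonl",
]

#: macro-F1 cross-validation cutoff below which models are not deployed
DEFAULT_F1_CUTOFF = 0.7

#: mixing floor for score adjustment: adjusted = score * (EPS + (1-EPS) * P)
ADJUST_EPSILON = 0.05

#: L2 regularization strength (inverse), fixed for determinism
LOGREG_C = 1.0

_TOKEN_RE = re.compile(r"(?u)\b\w\w+\b")


# ---------------------------------------------------------------------------
# labeled corpora
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class LabeledDocument:
    doc_id: str
    text: str
    label: tuple[str, str]  # (namespace, identifier) of the sense


@dataclass(frozen=True)
class LabeledCorpus:
    """Documents with sense labels for one ambiguous entity string."""

    entity_text: str
    documents: tuple[LabeledDocument, ...]

    def __post_init__(self) -> None:
        if not self.entity_text:
            raise ValueError("entity_text must be non-empty")
        docs = tuple(self.documents)
        object.__setattr__(self, "documents", docs)
        if any(not d.text for d in docs):
            raise ValueError("every document must be non-empty")
        if len(self.senses) < 2:
            raise ValueError(
                f"corpus for {self.entity_text!r} needs >= 2 distinct senses, "
                f"got {len(self.senses)}"
            )

    @property
    def senses(self) -> list[tuple[str, str]]:
        """Distinct sense labels in sorted order."""
        return sorted({d.label for d in self.documents})

    def counts(self) -> dict[tuple[str, str], int]:
        out: dict[tuple[str, str], int] = {}
        for d in self.documents:
            out[d.label] = out.get(d.label, 0) + 1
        return out


def load_corpus_jsonl(path: str | Path, entity_text: str) -> LabeledCorpus:
    """Load a labeled corpus from JSONL (doc_id, text, label per line)."""
    docs = []
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            try:
                rec = json.loads(line)
                docs.append(
                    LabeledDocument(
                        doc_id=str(rec["doc_id"]),
                        text=rec["text"],
                        label=(rec["label"][0], rec["label"][1]),
                    )
                )
            except (KeyError, ValueError, TypeError) as err:
                raise ValueError(f"{path}:{lineno}: malformed record: {err}") from None
    return LabeledCorpus(entity_text=entity_text, documents=tuple(docs))


def save_corpus_jsonl(corpus: LabeledCorpus, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for d in corpus.documents:
            fh.write(
                json.dumps(
                    {"doc_id": d.doc_id, "text": d.text, "label": list(d.label)},
                    ensure_ascii=False,
                )
                + "\n"
            )


# ---------------------------------------------------------------------------
# featurization
# ---------------------------------------------------------------------------


def _make_vectorizer(vocabulary: Mapping[str, int] | None = None, min_df: int = 1):
    from sklearn.feature_extraction.text import TfidfVectorizer

    # tokens: lowercase, split on non-word characters, length >= 2;
    # idf = ln((1+N)/(1+df)) + 1 (smooth), L2 row normalization
    return TfidfVectorizer(
        ngram_range=(1, 2),
        lowercase=True,
        token_pattern=_TOKEN_RE.pattern,
        min_df=min_df,
        smooth_idf=True,
        sublinear_tf=False,
        norm="l2",
        vocabulary=vocabulary,
    )


def featurize(
    corpus: LabeledCorpus,
    vocabulary: Mapping[str, int] | None = None,
    min_df: int = 1,
) -> tuple[sparse.csr_matrix, dict[str, int], np.ndarray]:
    """tf-idf feature table for a corpus.

    Returns (docs x features sparse matrix, vocabulary mapping feature
    string -> column, idf weight per column).  Deterministic given the
    corpus order and vocabulary.
    """
    if not corpus.documents:
        raise ValueError("cannot featurize an empty corpus")
    vec = _make_vectorizer(vocabulary=vocabulary, min_df=min_df)
    X = vec.fit_transform([d.text for d in corpus.documents])
    return X.tocsr(), dict(vec.vocabulary_), np.asarray(vec.idf_, dtype=float)


def _ngrams(text: str) -> list[str]:
    """Unigrams + bigrams of a text, matching the training tokenizer."""
    tokens = _TOKEN_RE.findall(text.lower())
    grams = list(tokens)
    grams.extend(" ".join(pair) for pair in zip(tokens, tokens[1:]))
    return grams


# ---------------------------------------------------------------------------
# the model
# ---------------------------------------------------------------------------


@dataclass
class DisambModel:
    """Self-contained sense classifier for one ambiguous entity string.

    ``coefficients`` has one row per sense (senses in ``senses`` order)
    and one column per feature; probabilities are
    ``softmax(x @ coefficients.T + intercepts)`` over a tf-idf feature
    vector built from the stored vocabulary and idf weights.
    """

    entity_text: str
    senses: list[tuple[str, str]]
    vocabulary: dict[str, int]
    idf: np.ndarray
    coefficients: np.ndarray
    intercepts: np.ndarray
    cv_macro_f1: float | None = None
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.idf = np.asarray(self.idf, dtype=float)
        self.coefficients = np.asarray(self.coefficients, dtype=float)
        self.intercepts = np.asarray(self.intercepts, dtype=float)
        n_senses, n_features = self.coefficients.shape
        if n_senses != len(self.senses):
            raise ValueError("one coefficient row per sense required")
        if n_features != len(self.vocabulary) or self.idf.shape != (n_features,):
            raise ValueError("vocabulary, idf and coefficients disagree on size")

    def transform(self, text: str) -> np.ndarray:
        """tf-idf vector of a context text under the stored vocabulary."""
        x = np.zeros(len(self.vocabulary))
        for gram in _ngrams(text):
            col = self.vocabulary.get(gram)
            if col is not None:
                x[col] += 1.0
        x *= self.idf
        norm = np.linalg.norm(x)
        if norm > 0:
            x /= norm
        return x

    def predict_proba(self, context: str) -> np.ndarray:
        z = self.transform(context) @ self.coefficients.T + self.intercepts
        z -= z.max()
        p = np.exp(z)
        return p / p.sum()

    # -- serialization ------------------------------------------------------

    def save(self, path: str | Path) -> None:
        """Write a model bundle directory (metadata.json + coefficients.json)."""
        path = Path(path)
        path.mkdir(parents=True, exist_ok=True)
        vocab_in_order = [None] * len(self.vocabulary)
        for gram, col in self.vocabulary.items():
            vocab_in_order[col] = gram
        metadata = {
            "schema_version": 1,
            "entity_text": self.entity_text,
            "senses": [list(s) for s in self.senses],
            "vocabulary": vocab_in_order,
            "cv_macro_f1": self.cv_macro_f1,
            "metadata": self.metadata,
        }
        with open(path / "metadata.json", "w", encoding="utf-8") as fh:
            json.dump(metadata, fh, ensure_ascii=False, indent=1)
        coef = {
            "idf": self.idf.tolist(),
            "coefficients": self.coefficients.tolist(),
            "intercepts": self.intercepts.tolist(),
        }
        with open(path / "coefficients.json", "w", encoding="utf-8") as fh:
            json.dump(coef, fh)

    @classmethod
    def load(cls, path: str | Path) -> "DisambModel":
        path = Path(path)
        with open(path / "metadata.json", encoding="utf-8") as fh:
            metadata = json.load(fh)
        if metadata.get("schema_version") != 1:
            raise ValueError(f"unsupported model bundle version in {path}")
        with open(path / "coefficients.json", encoding="utf-8") as fh:
            coef = json.load(fh)
        return cls(
            entity_text=metadata["entity_text"],
            senses=[tuple(s) for s in metadata["senses"]],
            vocabulary={g: i for i, g in enumerate(metadata["vocabulary"])},
            idf=np.array(coef["idf"]),
            coefficients=np.array(coef["coefficients"]),
            intercepts=np.array(coef["intercepts"]),
            cv_macro_f1=metadata["cv_macro_f1"],
            metadata=metadata["metadata"],
        )


# ---------------------------------------------------------------------------
# training and evaluation
# ---------------------------------------------------------------------------


def _fit_logreg(X, labels: Sequence[str], seed: int):
    from sklearn.linear_model import LogisticRegression

    # default l2 penalty with fixed strength; lbfgs is deterministic
    clf = LogisticRegression(
        C=LOGREG_C, solver="lbfgs", max_iter=2000, random_state=seed
    )
    clf.fit(X, labels)
    return clf


def _full_coefficients(clf, n_classes: int) -> tuple[np.ndarray, np.ndarray]:
    """Per-class softmax coefficients, expanding sklearn's 2-class form."""
    coef = np.asarray(clf.coef_, dtype=float)
    intercept = np.asarray(clf.intercept_, dtype=float)
    if n_classes == 2 and coef.shape[0] == 1:
        coef = np.vstack([np.zeros_like(coef[0]), coef[0]])
        intercept = np.array([0.0, intercept[0]])
    return coef, intercept


def train_model(
    corpus: LabeledCorpus,
    seed: int = 0,
    folds: int = 5,
    min_docs_per_sense: int | None = None,
    min_df: int = 1,
) -> DisambModel:
    """Train the sense classifier for one ambiguous string.

    Fits the tf-idf vocabulary and a multinomial logistic regression on
    the full corpus and records the stratified ``folds``-fold
    cross-validated mean macro-F1 (the deployment-selection statistic).
    Deterministic given the corpus and seed.
    """
    minimum = folds if min_docs_per_sense is None else min_docs_per_sense
    for sense, count in sorted(corpus.counts().items()):
        if count < minimum:
            raise ValueError(
                f"sense {sense} has {count} documents; {minimum} required"
            )
    X, vocabulary, idf = featurize(corpus, min_df=min_df)
    labels = ["{}:{}".format(*d.label) for d in corpus.documents]
    clf = _fit_logreg(X, labels, seed)
    senses = [tuple(lbl.split(":", 1)) for lbl in clf.classes_]
    coef, intercept = _full_coefficients(clf, len(senses))
    cv = crossvalidate(corpus, folds=folds, seed=seed, min_df=min_df)
    return DisambModel(
        entity_text=corpus.entity_text,
        senses=senses,
        vocabulary=vocabulary,
        idf=idf,
        coefficients=coef,
        intercepts=intercept,
        cv_macro_f1=cv,
        metadata={
            "n_docs": {"{}:{}".format(*k): v for k, v in sorted(corpus.counts().items())},
            "seed": seed,
            "folds": folds,
        },
    )


def crossvalidate(
    corpus: LabeledCorpus,
    folds: int = 5,
    seed: int = 0,
    min_df: int = 1,
) -> float:
    """Mean macro-F1 over stratified cross-validation folds.

    The tf-idf vocabulary is refitted inside each fold on the training
    split only, so the estimate does not leak test vocabulary.
    """
    from sklearn.model_selection import StratifiedKFold

    if folds < 2:
        raise ValueError("cross-validation requires folds >= 2")
    counts = corpus.counts()
    for sense, count in sorted(counts.items()):
        if count < folds:
            raise ValueError(
                f"sense {sense} has {count} documents; >= {folds} required "
                f"for {folds}-fold cross-validation"
            )
    texts = [d.text for d in corpus.documents]
    labels = ["{}:{}".format(*d.label) for d in corpus.documents]
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    scores = []
    for train_idx, test_idx in skf.split(texts, labels):
        vec = _make_vectorizer(min_df=min_df)
        X_train = vec.fit_transform([texts[i] for i in train_idx])
        X_test = vec.transform([texts[i] for i in test_idx])
        y_train = [labels[i] for i in train_idx]
        y_test = [labels[i] for i in test_idx]
        clf = _fit_logreg(X_train, y_train, seed)
        y_pred = list(clf.predict(X_test))
        scores.append(macro_f1(y_test, y_pred))
    return float(np.mean(scores))


def macro_f1(true_labels: Sequence, predicted_labels: Sequence) -> float:
    """Macro-averaged F1: unweighted mean of per-class F1 scores.

    Classes are those with support in the truth; a class for which
    precision + recall is zero contributes F1 = 0.
    """
    if len(true_labels) != len(predicted_labels):
        raise ValueError("label lists must have equal length")
    if not true_labels:
        raise ValueError("label lists must be non-empty")
    classes = sorted(set(true_labels))
    f1s = []
    for cls in classes:
        tp = sum(1 for t, p in zip(true_labels, predicted_labels) if t == cls and p == cls)
        fp = sum(1 for t, p in zip(true_labels, predicted_labels) if t != cls and p == cls)
        fn = sum(1 for t, p in zip(true_labels, predicted_labels) if t == cls and p != cls)
        if tp == 0:
            f1s.append(0.0)
            continue
        precision = tp / (tp + fp)
        recall = tp / (tp + fn)
        f1s.append(2 * precision * recall / (precision + recall))
    return float(np.mean(f1s))


def select_models(
    models: Iterable[DisambModel], cutoff: float = DEFAULT_F1_CUTOFF
) -> list[DisambModel]:
    """Keep exactly the models whose CV macro-F1 meets the cutoff."""
    selected = []
    for model in models:
        if model.cv_macro_f1 is None:
            raise ValueError(
                f"model for {model.entity_text!r} has no cv_macro_f1; "
                "train with cross-validation before selection"
            )
        if model.cv_macro_f1 >= cutoff:
            selected.append(model)
    return selected


# ---------------------------------------------------------------------------
# applying models
# ---------------------------------------------------------------------------


def disambiguate(model: DisambModel, context: str) -> dict[tuple[str, str], float]:
    """Sense probabilities for a context text; they sum to 1."""
    if not context or not context.strip():
        raise ValueError("context must be non-empty")
    proba = model.predict_proba(context)
    return {sense: float(p) for sense, p in zip(model.senses, proba)}


def apply_to_matches(
    matches: Sequence[ScoredMatch],
    probabilities: Mapping[tuple[str, str], float],
) -> list[ScoredMatch]:
    """Adjust match scores by sense probabilities and re-sort.

    ``adjusted = score * (eps + (1 - eps) * P(sense))`` with eps = 0.05:
    monotone in both the string score and the probability, and bounded
    in [0, 1].  The set of entities is unchanged; matches whose entity
    the model does not know keep their score; model senses absent from
    the matches are noted at debug level.
    """
    present = {m.entity for m in matches}
    for sense in probabilities:
        if sense not in present:
            logger.debug("model sense %s not among matches; ignored", sense)
    adjusted = []
    for m in matches:
        p = probabilities.get(m.entity)
        if p is None:
            adjusted.append(m)
            continue
        new_score = m.score * (ADJUST_EPSILON + (1.0 - ADJUST_EPSILON) * p)
        adjusted.append(
            ScoredMatch(
                term=m.term,
                score=min(1.0, max(0.0, new_score)),
                features=m.features,
                variant_used=m.variant_used,
                disamb_probability=float(p),
            )
        )
    adjusted.sort(key=lambda m: -m.score)
    return adjusted


# ---------------------------------------------------------------------------
# model registry
# ---------------------------------------------------------------------------


class DisambRegistry:
    """Deployed models keyed by the canonicalized ambiguous string."""

    def __init__(self, models: Iterable[DisambModel] = ()) -> None:
        self._models: dict[str, DisambModel] = {}
        for model in models:
            self.add(model)

    def add(self, model: DisambModel) -> None:
        self._models[canonicalize(model.entity_text)] = model

    def get(self, canonical_text: str) -> DisambModel | None:
        return self._models.get(canonical_text)

    def entity_texts(self) -> list[str]:
        return sorted(m.entity_text for m in self._models.values())

    def __len__(self) -> int:
        return len(self._models)

    def save(self, path: str | Path) -> None:
        """Write one bundle subdirectory per model."""
        path = Path(path)
        path.mkdir(parents=True, exist_ok=True)
        for i, key in enumerate(sorted(self._models)):
            self._models[key].save(path / f"model_{i:04d}")

    @classmethod
    def load(cls, path: str | Path) -> "DisambRegistry":
        path = Path(path)
        models = [
            DisambModel.load(sub)
            for sub in sorted(path.iterdir())
            if (sub / "metadata.json").exists()
        ]
        return cls(models)
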