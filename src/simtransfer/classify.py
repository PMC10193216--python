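"""Pluggable 4-class text classification with early stopping on dev loss.

The default backend is deliberately lightweight: hashed token-count features
(a stateless feature-hashing vectorizer, so no vocabulary pass is needed)
feeding a regularized multinomial logistic model trained by epochs of
stochastic gradient descent.  After each epoch the development-set
cross-entropy is recorded; the returned model carries the parameters of the
epoch with the smallest dev loss (earliest epoch on ties), the standard
minimum-validation-loss early-stopping rule.

Any object exposing ``fit(train, dev, config)``/``predict(corpus)`` with the
same contracts can replace this backend in the transfer experiments — e.g. a
fine-tuned transformer encoder classifying from its CLS representation.
Relative transfer performance, which is what the experiments measure, is
defined for any backend.

Tokenization is whitespace-based for the synthetic corpora; a character
2-3-gram mode is available for unsegmented text such as Japanese.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import joblib
import numpy as np
import scipy.sparse as sp
from sklearn.feature_extraction.text import HashingVectorizer
from sklearn.linear_model import SGDClassifier
from sklearn.metrics import log_loss

from .corpus import LABELS, Corpus

_MODEL_FORMAT = "simtransfer-linear-model"
_MODEL_VERSION = 1


@dataclass(frozen=True)
class TrainConfig:
    """Settings for the default linear backend.

    ``max_epochs``/``patience`` govern early stopping: training halts once
    the dev loss has not improved for ``patience`` consecutive epochs (or at
    ``max_epochs``), and the best-epoch parameters are kept either way.
    """

    max_epochs: int = 12
    patience: int = 3
    alpha: float = 1e-5  # L2 regularization strength of the SGD updates
    seed: int = 0
    tokenizer: str = "whitespace"  # or "char_ngram" for unsegmented text
    ngram_range: tuple[int, int] = (2, 3)
    n_features: int = 2**14

    def __post_init__(self) -> None:
        if self.max_epochs < 1:
            raise ValueError("max_epochs must be >= 1")
        if self.patience < 0:
            raise ValueError("patience must be >= 0")
        if self.tokenizer not in {"whitespace", "char_ngram"}:
            raise ValueError(f"unknown tokenizer {self.tokenizer!r}")


def make_vectorizer(config: TrainConfig) -> HashingVectorizer:
    if config.tokenizer == "whitespace":
        return HashingVectorizer(
            analyzer=str.split, n_features=config.n_features, norm=None
        )
    return HashingVectorizer(
        analyzer="char_wb",
        ngram_range=config.ngram_range,
        n_features=config.n_features,
        norm=None,
    )


class FeatureCache:
    """Vectorize a corpus once; serve feature rows for any sub/oversampled view.

    Oversampled copies (doc_ids carrying the ``#os`` suffix) resolve to their
    source document's row, so repeated training runs over overlapping
    subcorpora never re-tokenize.
    """

    def __init__(self, corpus: Corpus, config: TrainConfig) -> None:
        self.config = config
        self.vectorizer = make_vectorizer(config)
        texts = [d.text for d in corpus]
        self.X = sp.csr_matrix(self.vectorizer.transform(texts))
        self._row = {d.doc_id: i for i, d in enumerate(corpus)}

    def rows(self, corpus: Corpus) -> sp.csr_matrix:
        idx = [self._row[d.source_id()] for d in corpus]
        return self.X[idx]


@dataclass
class LinearTextModel:
    """A fitted multinomial linear classifier over hashed token counts."""

    config: TrainConfig
    classes: tuple[str, ...]
    coef: np.ndarray = field(repr=False)
    intercept: np.ndarray = field(repr=False)
    majority_label: str
    best_epoch: int
    dev_loss_trace: tuple[float, ...]

    def _scores(self, X: sp.csr_matrix) -> np.ndarray:
        return X @ self.coef.T + self.intercept

    def predict(self, docs: Corpus, cache: FeatureCache | None = None) -> list[str]:
        """One label per document, order preserved.

        Documents with no active features (fully out-of-vocabulary) fall
        back to the training-majority label.
        """
        if len(docs) == 0:
            return []
        X = cache.rows(docs) if cache is not None else sp.csr_matrix(
            make_vectorizer(self.config).transform([d.text for d in docs])
        )
        scores = np.asarray(self._scores(X))
        if scores.ndim == 2 and scores.shape[1] == 1:
            # binary model: one decision column, positive side = classes[1]
            winners = (scores.ravel() > 0).astype(int)
        else:
            winners = np.argmax(scores, axis=1)
        pred = [self.classes[k] for k in winners]
        empty = np.asarray(X.getnnz(axis=1) == 0).ravel()
        return [self.majority_label if e else p for p, e in zip(pred, empty)]

    def save(self, path: str | Path) -> None:
        joblib.dump(
            {
                "format": _MODEL_FORMAT,
                "version": _MODEL_VERSION,
                "config": self.config,
                "classes": self.classes,
                "coef": self.coef,
                "intercept": self.intercept,
                "majority_label": self.majority_label,
                "best_epoch": self.best_epoch,
                "dev_loss_trace": self.dev_loss_trace,
            },
            path,
        )

    @classmethod
    def load(cls, path: str | Path) -> "LinearTextModel":
        blob = joblib.load(path)
        if blob.get("format") != _MODEL_FORMAT:
            raise ValueError(f"{path}: not a {_MODEL_FORMAT} file")
        if blob.get("version") != _MODEL_VERSION:
            raise ValueError(f"{path}: unsupported model version {blob.get('version')}")
        return cls(
            config=blob["config"],
            classes=tuple(blob["classes"]),
            coef=blob["coef"],
            intercept=blob["intercept"],
            majority_label=blob["majority_label"],
            best_epoch=blob["best_epoch"],
            dev_loss_trace=tuple(blob["dev_loss_trace"]),
        )


def fit(
    train: Corpus,
    dev: Corpus,
    config: TrainConfig,
    cache: FeatureCache | None = None,
) -> LinearTextModel:
    """Train the linear backend with minimum-dev-loss early stopping.

    Deterministic under ``config.seed``: the same data and config always
    yield the same parameters and predictions.
    """
    if len(train) == 0:
        raise ValueError("training corpus is empty")
    if len(dev) == 0:
        raise ValueError("development corpus is empty")
    y_train = np.asarray(train.labels())
    y_dev = np.asarray(dev.labels())
    # scikit-learn orders classes by np.unique; mirror that so coefficient
    # rows and our label order agree
    classes = tuple(np.unique(y_train))
    if len(classes) < 2:
        raise ValueError("training corpus must contain >= 2 distinct labels")
    counts = train.label_counts()
    majority = max(classes, key=lambda l: (counts[l], -classes.index(l)))

    if cache is not None:
        X_train, X_dev = cache.rows(train), cache.rows(dev)
    else:
        vec = make_vectorizer(config)
        X_train = sp.csr_matrix(vec.transform([d.text for d in train]))
        X_dev = sp.csr_matrix(vec.transform([d.text for d in dev]))

    rng = np.random.default_rng(config.seed)
    clf = SGDClassifier(
        loss="log_loss",
        alpha=config.alpha,
        random_state=int(rng.integers(0, 2**31 - 1)),
    )
    class_arr = np.asarray(classes)
    trace: list[float] = []
    best_loss = np.inf
    best_epoch = -1
    best_coef: np.ndarray | None = None
    best_intercept: np.ndarray | None = None
    for epoch in range(config.max_epochs):
        perm = rng.permutation(X_train.shape[0])
        clf.partial_fit(X_train[perm], y_train[perm], classes=class_arr)
        proba = clf.predict_proba(X_dev)
        loss = float(log_loss(y_dev, proba, labels=clf.classes_))
        trace.append(loss)
        if loss < best_loss:  # strict: ties keep the earliest epoch
            best_loss = loss
            best_epoch = epoch
            best_coef = clf.coef_.copy()
            best_intercept = clf.intercept_.copy()
        elif epoch - best_epoch > config.patience:
            break
    assert best_coef is not None and best_intercept is not None
    assert best_epoch == int(np.argmin(trace))
    return LinearTextModel(
        config=config,
        classes=classes,
        coef=best_coef,
        intercept=best_intercept,
        majority_label=majority,
        best_epoch=best_epoch,
        dev_loss_trace=tuple(trace),
    )
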