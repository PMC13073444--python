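"""Classifier backends: text -> three-class urgency logits.

Every backend satisfies one contract: after fitting, ``predict_logits``
maps a segment text to a real score triple z = (z_GREEN, z_YELLOW,
z_RED); probabilities are p = softmax(z) and the predicted label is the
arg-max, with exact ties broken toward the more urgent class.

The mandatory, self-contained backend is ``sparse_linear``: token
frequencies with inverse-document-frequency scaling feeding a
multinomial logistic regression trained with inverse-frequency class
weights w_c = n / (3 n_c). A ``transformer`` backend (fine-tuned
pretrained encoder, per-epoch checkpoint selection by validation
macro-F1) implements the same contract but requires the optional
``transformers``/``torch`` dependencies.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import joblib
import numpy as np
from pydantic import BaseModel, Field
from scipy.special import softmax as _scipy_softmax
from sklearn.feature_extraction.text import TfidfVectorizer
from sklearn.linear_model import LogisticRegression
from sklearn.pipeline import Pipeline

from .ingest import SegmentCorpus
from .labels import N_CLASSES, TriageLabel
from .text import simplify

__all__ = [
    "TrainConfig",
    "SparseLinearBackend",
    "TransformerBackend",
    "train_backend",
    "compute_class_weights",
    "softmax",
    "predict_label",
    "predict_labels",
    "save_backend",
    "load_backend",
]


class TrainConfig(BaseModel):
    """Training recipe shared by all backends.

    Optimizer fields (learning rate, weight decay, warm-up, batch sizes,
    token truncation) apply to the transformer backend; the sparse
    baseline uses only ``seed`` and ``class_weighting`` and always sees
    the full text.
    """

    learning_rate: float = Field(2e-5, gt=0)
    weight_decay: float = Field(0.01, ge=0)
    max_epochs: int = Field(6, ge=1)
    warmup_fraction: float = Field(0.10, ge=0, le=1)
    batch_train: int = Field(16, ge=1)
    batch_eval: int = Field(32, ge=1)
    max_tokens: int = Field(256, ge=8)
    seed: int = 42
    class_weighting: bool = True


def compute_class_weights(labels: Sequence[TriageLabel]) -> np.ndarray:
    """Inverse-frequency class weights w_c = n / (3 n_c), mean ~= 1.

    Scales the per-class loss contribution so minority urgency classes
    are not swamped by the prevalent middle class. Requires every class
    to be present.
    """
    counts = np.bincount([int(l) for l in labels], minlength=N_CLASSES)
    if (counts == 0).any():
        empty = [TriageLabel(i).name for i in np.flatnonzero(counts == 0)]
        raise ValueError(f"cannot weight empty classes: {empty}")
    n = counts.sum()
    return n / (N_CLASSES * counts.astype(float))


def softmax(z: np.ndarray) -> np.ndarray:
    """Stable softmax along the last axis; rejects non-finite input."""
    z = np.asarray(z, dtype=float)
    if not np.isfinite(z).all():
        raise ValueError("softmax requires finite logits")
    return _scipy_softmax(z, axis=-1)


def predict_label(scores: Sequence[float] | np.ndarray) -> TriageLabel:
    """Arg-max label; exact ties break toward the more urgent class."""
    v = np.asarray(scores, dtype=float)
    if v.shape != (N_CLASSES,):
        raise ValueError(f"expected a score triple, got shape {v.shape}")
    return TriageLabel(int(np.flatnonzero(v == v.max())[-1]))


def predict_labels(scores: np.ndarray) -> list[TriageLabel]:
    """Row-wise :func:`predict_label` for an (n, 3) score matrix."""
    return [predict_label(row) for row in np.atleast_2d(scores)]


def _check_training_labels(corpus: SegmentCorpus) -> list[TriageLabel]:
    labels = corpus.labels()
    present = {int(l) for l in labels}
    if present != set(range(N_CLASSES)):
        missing = [TriageLabel(i).name for i in set(range(N_CLASSES)) - present]
        raise ValueError(f"training corpus lacks classes: {missing}")
    return labels


class SparseLinearBackend:
    """TF-IDF features + multinomial logistic regression.

    Texts pass through the simplified fold before tokenization so that
    diacritic/casing variants share features. Deterministic for a fixed
    seed, config, and corpus.
    """

    backend_kind = "sparse_linear"

    def __init__(self, config: Optional[TrainConfig] = None):
        self.config = config or TrainConfig()
        self.fitted = False
        self._pipeline: Optional[Pipeline] = None

    def fit(self, train: SegmentCorpus, validation: Optional[SegmentCorpus] = None
            ) -> "SparseLinearBackend":
        labels = _check_training_labels(train)
        y = np.array([int(l) for l in labels])
        weights = (
            dict(enumerate(compute_class_weights(labels)))
            if self.config.class_weighting
            else None
        )
        self._pipeline = Pipeline(
            [
                (
                    "tfidf",
                    TfidfVectorizer(
                        preprocessor=simplify,
                        ngram_range=(1, 2),
                        sublinear_tf=True,
                    ),
                ),
                (
                    "logreg",
                    LogisticRegression(
                        C=10.0,
                        max_iter=2000,
                        class_weight=weights,
                        random_state=self.config.seed,
                    ),
                ),
            ]
        )
        self._pipeline.fit(train.texts(), y)
        self.fitted = True
        return self

    def predict_logits(self, texts: str | Sequence[str]) -> np.ndarray:
        """Score triple(s): shape (3,) for one text, (n, 3) for a list."""
        if not self.fitted or self._pipeline is None:
            raise RuntimeError("backend is not fitted")
        single = isinstance(texts, str)
        batch = [texts] if single else list(texts)
        z = self._pipeline.decision_function(batch)
        z = np.atleast_2d(np.asarray(z, dtype=float))
        return z[0] if single else z

    def predict(self, texts: str | Sequence[str]) -> TriageLabel | list[TriageLabel]:
        z = self.predict_logits(texts)
        return predict_label(z) if z.ndim == 1 else predict_labels(z)


class TransformerBackend:
    """Fine-tuned pretrained encoder satisfying the same contract.

    Trains with AdamW, a linear schedule with warm-up, class-weighted
    cross-entropy, truncation to ``max_tokens``, and keeps the epoch
    checkpoint with the best validation macro-F1. Requires the optional
    ``transformers`` and ``torch`` dependencies.
    """

    backend_kind = "transformer"

    def __init__(self, model_name: str, config: Optional[TrainConfig] = None):
        try:
            import torch  # noqa: F401
            import transformers  # noqa: F401
        except ImportError as exc:
            raise RuntimeError(
                "the transformer backend requires the optional 'transformers' "
                "and 'torch' dependencies (pip install msktriage[transformer])"
            ) from exc
        self.model_name = model_name
        self.config = config or TrainConfig()
        self.fitted = False
        self._model = None
        self._tokenizer = None

    # pragma: no cover — exercised only when optional deps are installed
    def fit(self, train: SegmentCorpus, validation: SegmentCorpus
            ) -> "TransformerBackend":
        import copy

        import torch
        from torch.utils.data import DataLoader
        from transformers import (AutoModelForSequenceClassification,
                                  AutoTokenizer, get_linear_schedule_with_warmup)

        from .metrics import confusion_matrix, macro_f1

        cfg = self.config
        torch.manual_seed(cfg.seed)
        tok = AutoTokenizer.from_pretrained(self.model_name)
        model = AutoModelForSequenceClassification.from_pretrained(
            self.model_name, num_labels=N_CLASSES
        )
        labels = _check_training_labels(train)
        y = torch.tensor([int(l) for l in labels])
        enc = tok(train.texts(), truncation=True, max_length=cfg.max_tokens,
                  padding=True, return_tensors="pt")
        dataset = list(zip(enc["input_ids"], enc["attention_mask"], y))
        loader = DataLoader(dataset, batch_size=cfg.batch_train, shuffle=True,
                            generator=torch.Generator().manual_seed(cfg.seed))
        steps = len(loader) * cfg.max_epochs
        opt = torch.optim.AdamW(model.parameters(), lr=cfg.learning_rate,
                                weight_decay=cfg.weight_decay)
        sched = get_linear_schedule_with_warmup(
            opt, int(cfg.warmup_fraction * steps), steps
        )
        weight = (
            torch.tensor(compute_class_weights(labels), dtype=torch.float32)
            if cfg.class_weighting else None
        )
        loss_fn = torch.nn.CrossEntropyLoss(weight=weight)
        best_f1, best_state = -1.0, None
        val_y = [int(l) for l in validation.labels()]
        for _epoch in range(cfg.max_epochs):
            model.train()
            for ids, mask, yb in loader:
                opt.zero_grad()
                out = model(input_ids=ids, attention_mask=mask)
                loss = loss_fn(out.logits, yb)
                loss.backward()
                opt.step()
                sched.step()
            model.eval()
            self._model, self._tokenizer, self.fitted = model, tok, True
            preds = [int(predict_label(z)) for z in
                     self.predict_logits(validation.texts())]
            f1 = macro_f1(confusion_matrix(val_y, preds))
            if f1 > best_f1:
                best_f1, best_state = f1, copy.deepcopy(model.state_dict())
        model.load_state_dict(best_state)
        self._model, self._tokenizer, self.fitted = model, tok, True
        return self

    def predict_logits(self, texts: str | Sequence[str]) -> np.ndarray:
        import torch

        if not self.fitted:
            raise RuntimeError("backend is not fitted")
        single = isinstance(texts, str)
        batch = [texts] if single else list(texts)
        out = []
        with torch.no_grad():
            for i in range(0, len(batch), self.config.batch_eval):
                enc = self._tokenizer(
                    batch[i : i + self.config.batch_eval], truncation=True,
                    max_length=self.config.max_tokens, padding=True,
                    return_tensors="pt",
                )
                out.append(self._model(**enc).logits.numpy())
        z = np.concatenate(out, axis=0)
        return z[0] if single else z


def train_backend(
    train: SegmentCorpus,
    validation: Optional[SegmentCorpus],
    config: Optional[TrainConfig] = None,
    kind: str = "sparse_linear",
    model_name: str = "dbmdz/bert-base-turkish-cased",
):
    """Fit a backend of the requested kind on a labeled train corpus."""
    if len(train) == 0:
        raise ValueError("empty training corpus")
    if kind == "sparse_linear":
        return SparseLinearBackend(config).fit(train, validation)
    if kind == "transformer":
        if validation is None or len(validation) == 0:
            raise ValueError("transformer backend requires a validation corpus")
        return TransformerBackend(model_name, config).fit(train, validation)
    raise ValueError(f"unknown backend kind: {kind!r}")


def save_backend(backend, path) -> None:
    """Serialize a fitted backend (with its config echo) to one file."""
    joblib.dump(backend, path)


def load_backend(path):
    return joblib.load(path)
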