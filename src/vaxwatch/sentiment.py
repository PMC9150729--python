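"""Hybrid ensemble sentiment classification.

The ensemble combines two continuous lexicon polarity scorers by fixed
convex weighting — a VADER-role scorer at 0.45 and a TextBlob-role scorer
at 0.55 — and then applies a rule-based combination with a categorical
(transformer-class) model:

    IF   weighted lexicon score > positive_threshold:  label = positive
    ELSE                                               label = categorical model's label

Lexicon scorers tend to be stronger on positive sentiment while a tuned
sequence classifier is stronger on the negative/neutral distinction; the
IF-ELSE rule routes each regime to the stronger component.  The categorical
model is invoked lazily, only on the ELSE branch.

Scorer adapters
---------------
:class:`VaderScorer`, :class:`TextBlobScorer` and
:class:`TransformerLabeler` adapt the third-party scorers when those
packages are installed; they raise :class:`ScorerUnavailableError`
otherwise (never a silent fallback).  :class:`MiniLexiconScorer` and
:class:`MiniLexiconLabeler` are small, fully deterministic built-in
valence-lexicon scorers that satisfy the same contracts with no external
model, and are the defaults everywhere reproducibility matters.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Iterable, Protocol, Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.utils.validation import check_is_fitted

from .records import PostRecord, ValidationError

LABELS = ("positive", "negative", "neutral")


class ScorerUnavailableError(RuntimeError):
    """An optional third-party scorer was requested but is not installed."""


class ContinuousScorer(Protocol):
    def score(self, text: str) -> float: ...


class CategoricalScorer(Protocol):
    def label(self, text: str) -> str: ...


@dataclass(frozen=True)
class EnsembleConfig:
    """Weights of the two lexicon scorers and the positivity cutoff.

    ``weight_lexA`` applies to the VADER-role scorer, ``weight_lexB`` to the
    TextBlob-role scorer; they must form a convex combination.  A weighted
    score strictly above ``positive_threshold`` (default 0.05, the
    conventional compound-score positivity cutoff) takes the IF branch; the
    boundary value itself goes to the ELSE branch.
    """

    weight_lexA: float = 0.45
    weight_lexB: float = 0.55
    positive_threshold: float = 0.05

    def __post_init__(self):
        if self.weight_lexA < 0 or self.weight_lexB < 0:
            raise ValidationError("weights: must be non-negative")
        if abs(self.weight_lexA + self.weight_lexB - 1.0) > 1e-9:
            raise ValidationError("weights: weight_lexA + weight_lexB must equal 1")


# ---------------------------------------------------------------------------
# Built-in deterministic valence-lexicon scorers

#: Small valence lexicon; aligned with the synthetic generator's phrase banks
#: so end-to-end label recovery is exact up to sampling noise.
POSITIVE_WORDS = frozenset(
    "love loved brilliant great happy happier wonderful amazing excellent "
    "fantastic grateful relieved delighted superb thankful".split()
)
NEGATIVE_WORDS = frozenset(
    "awful hate hated terrible horrible angry disgusting worst dreadful "
    "furious miserable appalling useless scared".split()
)

def _tokens(text: str) -> list[str]:
    import re

    return re.findall(r"[a-z']+", text.casefold())


class MiniLexiconScorer:
    """Continuous polarity from a small built-in valence lexicon.

    Score is (positive hits - negative hits) / total valenced hits, hence in
    [-1, 1] and 0 for text with no valenced words.  Deterministic and pure.
    """

    def score(self, text: str) -> float:
        toks = _tokens(text)
        pos = sum(t in POSITIVE_WORDS for t in toks)
        neg = sum(t in NEGATIVE_WORDS for t in toks)
        if pos + neg == 0:
            return 0.0
        return (pos - neg) / (pos + neg)


class MiniLexiconLabeler:
    """Categorical counterpart of :class:`MiniLexiconScorer`."""

    def label(self, text: str) -> str:
        s = MiniLexiconScorer().score(text)
        if s > 0:
            return "positive"
        if s < 0:
            return "negative"
        return "neutral"


# ---------------------------------------------------------------------------
# Optional third-party adapters (lazy imports)


class VaderScorer:
    """Adapter to the VADER compound score (requires ``vaderSentiment``)."""

    def __init__(self):
        try:
            from vaderSentiment.vaderSentiment import SentimentIntensityAnalyzer
        except ImportError as exc:
            raise ScorerUnavailableError(
                "vaderSentiment is not installed; install the 'scorers' extra"
            ) from exc
        self._analyzer = SentimentIntensityAnalyzer()

    def score(self, text: str) -> float:
        return float(self._analyzer.polarity_scores(text)["compound"])


class TextBlobScorer:
    """Adapter to TextBlob polarity (requires ``textblob``)."""

    def __init__(self):
        try:
            from textblob import TextBlob
        except ImportError as exc:
            raise ScorerUnavailableError(
                "textblob is not installed; install the 'scorers' extra"
            ) from exc
        self._cls = TextBlob

    def score(self, text: str) -> float:
        return float(self._cls(text).sentiment.polarity)


class TransformerLabeler:
    """Adapter to a transformer sequence classifier (requires ``transformers``).

    ``model_name`` must name a locally available 3-class sentiment model;
    its labels are mapped onto {positive, negative, neutral}.
    """

    def __init__(self, model_name: str, label_map: dict[str, str] | None = None):
        try:
            from transformers import pipeline
        except ImportError as exc:
            raise ScorerUnavailableError(
                "transformers is not installed; install the 'scorers' extra"
            ) from exc
        self._pipe = pipeline("text-classification", model=model_name)
        self._label_map = label_map or {}

    def label(self, text: str) -> str:
        raw = self._pipe(text)[0]["label"]
        lab = self._label_map.get(raw, raw).lower()
        if lab not in LABELS:
            raise ValidationError(f"label: model produced unmapped label {raw!r}")
        return lab


# ---------------------------------------------------------------------------
# Ensemble operations


def weighted_lexicon_score(
    text: str,
    scorerA: ContinuousScorer,
    scorerB: ContinuousScorer,
    config: EnsembleConfig = EnsembleConfig(),
) -> float:
    """Convex combination ``wA * scorerA(text) + wB * scorerB(text)``."""
    return config.weight_lexA * scorerA.score(text) + config.weight_lexB * scorerB.score(text)


def ensemble_classify(
    text: str,
    scorerA: ContinuousScorer,
    scorerB: ContinuousScorer,
    categorical: CategoricalScorer | None,
    config: EnsembleConfig = EnsembleConfig(),
) -> tuple[str, float, str]:
    """Apply the IF-ELSE combination rule to one text.

    Returns ``(label, weighted_score, branch)`` where branch is "lexicon"
    (IF) or "categorical" (ELSE).  The categorical model is only touched on
    the ELSE branch; if it is needed and absent this raises
    :class:`ScorerUnavailableError` rather than silently guessing.
    """
    score = weighted_lexicon_score(text, scorerA, scorerB, config)
    if score > config.positive_threshold:
        return "positive", score, "lexicon"
    if categorical is None:
        raise ScorerUnavailableError(
            "categorical scorer required on the ELSE branch but none was provided"
        )
    lab = categorical.label(text)
    if lab not in LABELS:
        raise ValidationError(f"label: categorical scorer produced {lab!r}")
    return lab, score, "categorical"


class EnsembleSentimentClassifier(BaseEstimator, ClassifierMixin):
    """Scikit-learn-style wrapper around the hybrid ensemble.

    Parameters
    ----------
    scorerA, scorerB : continuous scorers (VADER role / TextBlob role)
        Default to the built-in deterministic lexicon scorer.
    categorical : categorical scorer for the ELSE branch
        Defaults to the built-in lexicon labeler.
    weight_lexA, weight_lexB, positive_threshold : floats
        See :class:`EnsembleConfig`.
    fail_fast : bool
        If False, per-text scorer errors are collected (label "error" rows
        are excluded from the returned table) instead of aborting the batch.

    The estimator is stateless in the statistical sense — ``fit`` validates
    the configuration and records ``classes_`` — which makes it compose with
    sklearn model-selection utilities for threshold/weight sweeps.
    """

    def __init__(
        self,
        scorerA: ContinuousScorer | None = None,
        scorerB: ContinuousScorer | None = None,
        categorical: CategoricalScorer | None = None,
        weight_lexA: float = 0.45,
        weight_lexB: float = 0.55,
        positive_threshold: float = 0.05,
        fail_fast: bool = True,
    ):
        self.scorerA = scorerA
        self.scorerB = scorerB
        self.categorical = categorical
        self.weight_lexA = weight_lexA
        self.weight_lexB = weight_lexB
        self.positive_threshold = positive_threshold
        self.fail_fast = fail_fast

    def _components(self):
        a = self.scorerA if self.scorerA is not None else MiniLexiconScorer()
        b = self.scorerB if self.scorerB is not None else MiniLexiconScorer()
        c = self.categorical if self.categorical is not None else MiniLexiconLabeler()
        return a, b, c

    def fit(self, X=None, y=None) -> "EnsembleSentimentClassifier":
        self.config_ = EnsembleConfig(
            weight_lexA=self.weight_lexA,
            weight_lexB=self.weight_lexB,
            positive_threshold=self.positive_threshold,
        )
        self.classes_ = np.array(LABELS)
        return self

    def predict(self, X: Iterable[str]) -> np.ndarray:
        check_is_fitted(self, "config_")
        a, b, c = self._components()
        return np.array(
            [ensemble_classify(t, a, b, c, self.config_)[0] for t in X], dtype=object
        )

    def decision_scores(self, X: Iterable[str]) -> np.ndarray:
        """Weighted lexicon scores (the IF-branch decision variable)."""
        check_is_fitted(self, "config_")
        a, b, _ = self._components()
        return np.array([weighted_lexicon_score(t, a, b, self.config_) for t in X])


def classify_corpus(
    records: Sequence[PostRecord],
    scorerA: ContinuousScorer | None = None,
    scorerB: ContinuousScorer | None = None,
    categorical: CategoricalScorer | None = None,
    config: EnsembleConfig = EnsembleConfig(),
    fail_fast: bool = True,
) -> tuple[pd.DataFrame, list[dict]]:
    """Label every record; returns (label table, error report).

    The label table has one row per successfully scored record with columns
    platform, post_id, label, weighted_score, branch_taken.  With
    ``fail_fast=False`` per-record scorer failures are collected into the
    error report and the run continues.
    """
    a = scorerA if scorerA is not None else MiniLexiconScorer()
    b = scorerB if scorerB is not None else MiniLexiconScorer()
    c = categorical if categorical is not None else MiniLexiconLabeler()
    rows, errors = [], []
    for rec in records:
        try:
            lab, score, branch = ensemble_classify(rec.text, a, b, c, config)
        except Exception as exc:  # noqa: BLE001 - error report contract
            if fail_fast:
                raise
            errors.append({"platform": rec.platform, "post_id": rec.post_id, "error": str(exc)})
            continue
        rows.append(
            {
                "platform": rec.platform,
                "post_id": rec.post_id,
                "label": lab,
                "weighted_score": score,
                "branch_taken": branch,
            }
        )
    table = pd.DataFrame(rows, columns=["platform", "post_id", "label", "weighted_score", "branch_taken"])
    return table, errors


def evaluate_labels(label_table: pd.DataFrame, truth: pd.DataFrame) -> pd.DataFrame:
    """Per-class accuracy of predicted labels against ground-truth labels.

    ``truth`` needs columns post_id and sentiment.  Useful for re-fitting the
    lexicon weights on one's own labeled data.
    """
    merged = label_table.merge(truth[["post_id", "sentiment"]], on="post_id", how="inner")
    out = []
    for lab in LABELS:
        sub = merged[merged["sentiment"] == lab]
        acc = float((sub["label"] == lab).mean()) if len(sub) else float("nan")
        out.append({"class": lab, "n": len(sub), "accuracy": acc})
    overall = float((merged["label"] == merged["sentiment"]).mean()) if len(merged) else float("nan")
    out.append({"class": "overall", "n": len(merged), "accuracy": overall})
    return pd.DataFrame(out)
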