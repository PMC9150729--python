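"""Grouped adverse-effect (AEFI) mention counting, time binning, and
per-user activity statistics.

An AEFI lexicon maps symptom group names (clots, headache, injection_site,
...) to term lists informed by passive-surveillance reporting categories
(Yellow Card / VAERS style groupings).  Counting is *mention-level*: a post
can contribute several mentions, across several groups, so group totals can
far exceed the post count.  Counts are accumulated over consecutive 2-week
bins anchored at the campaign start date.

:class:`MentionCounter` is the estimator-shaped core (a keyword-restricted
cousin of ``CountVectorizer``): ``fit`` compiles the lexicon, ``transform``
maps texts to a (n_texts, n_groups) count frame.  The module functions are
thin wrappers.
"""

from __future__ import annotations

import math
import re
import warnings
from dataclasses import dataclass, field
from datetime import date, datetime, timedelta, timezone
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_is_fitted

from .filtering import _compile_terms, DEFAULT_DATE_START, DEFAULT_DATE_END
from .records import PostRecord, ValidationError

#: Default symptom groupings.  Term lists are seeds, configurable via YAML.
#: Deliberately nesting-free: no default term contains another default term
#: as a word-boundary submatch, so one occurrence yields exactly one mention.
DEFAULT_AEFI_LEXICON: dict[str, list[str]] = {
    "appetite": ["appetite", "not hungry"],
    "allergy": ["allergy", "allergic", "anaphylaxis", "hives"],
    "injection_site": ["injection site", "sore arm", "arm pain", "arm redness", "arm swelling"],
    "clots": ["clot", "clots", "thrombosis", "thrombocytopenia"],
    "bell_palsy": ["bell palsy", "bells palsy", "facial paralysis"],
    "guillain_barre": ["guillain-barre", "guillain barre", "gbs"],
    "headache": ["headache", "headaches", "migraine"],
    "fever": ["fever", "feverish", "high temperature", "chills"],
    "diarrhea": ["diarrhea", "diarrhoea"],
    "generalized": ["lethargy", "lethargic", "muscle ache", "muscle aches", "flu",
                    "vomit", "vomiting", "nausea", "fatigue", "tiredness"],
    # catch-all for the long tail of reported symptom categories
    "other": ["rash", "dizziness", "dizzy", "numbness", "tingling",
              "swollen glands", "palpitations"],
}


@dataclass(frozen=True)
class AEFILexicon:
    """Named symptom groups, each with a non-empty term list."""

    groups: dict[str, tuple[str, ...]]

    def __post_init__(self):
        norm = {}
        for name, terms in self.groups.items():
            terms = tuple(terms)
            if not terms:
                raise ValidationError(f"groups: group {name!r} has no terms")
            if any(t == "" for t in terms):
                raise ValidationError(f"groups: group {name!r} contains an empty term")
            norm[name] = terms
        object.__setattr__(self, "groups", norm)
        seen: dict[str, str] = {}
        for name, terms in norm.items():
            for t in terms:
                tl = t.casefold()
                if tl in seen and seen[tl] != name:
                    warnings.warn(
                        f"term {t!r} appears in groups {seen[tl]!r} and {name!r}; "
                        "it will count toward both"
                    )
                seen.setdefault(tl, name)

    @property
    def group_names(self) -> list[str]:
        return list(self.groups)

    @classmethod
    def default(cls) -> "AEFILexicon":
        return cls({k: tuple(v) for k, v in DEFAULT_AEFI_LEXICON.items()})


class MentionCounter(BaseEstimator, TransformerMixin):
    """Count non-overlapping lexicon-term occurrences per symptom group.

    Occurrences are found on the case-folded text under word-boundary
    matching; each term is scanned left-to-right without overlap, and
    distinct terms count independently (so "blood clot" and "clot" can both
    fire on "blood clot" when both are listed).

    Parameters
    ----------
    lexicon : AEFILexicon or mapping, optional
        Group -> term list.  Defaults to the built-in symptom groups.

    Attributes
    ----------
    group_names_ : list of str
        Column order of the transform output.
    patterns_ : dict of group -> list of compiled per-term patterns
    """

    def __init__(self, lexicon: AEFILexicon | Mapping[str, Sequence[str]] | None = None):
        self.lexicon = lexicon

    def fit(self, X=None, y=None) -> "MentionCounter":
        lex = self.lexicon
        if lex is None:
            lex = AEFILexicon.default()
        elif not isinstance(lex, AEFILexicon):
            lex = AEFILexicon({k: tuple(v) for k, v in lex.items()})
        self.lexicon_ = lex
        self.group_names_ = lex.group_names
        # one pattern per term: the same term's matches must not overlap, but
        # distinct terms are counted independently
        self.patterns_ = {
            g: [_compile_terms([t], "word_boundary") for t in terms]
            for g, terms in lex.groups.items()
        }
        return self

    def transform(self, X: Iterable[str]) -> pd.DataFrame:
        """Texts -> (n_texts, n_groups) integer count frame."""
        check_is_fitted(self, "patterns_")
        rows = []
        for text in X:
            folded = text.casefold()
            rows.append(
                [
                    sum(len(pat.findall(folded)) for pat in self.patterns_[g])
                    for g in self.group_names_
                ]
            )
        return pd.DataFrame(rows, columns=self.group_names_, dtype=int)


def count_mentions(
    records: Sequence[PostRecord],
    lexicon: AEFILexicon | Mapping[str, Sequence[str]] | None = None,
) -> pd.DataFrame:
    """Per-record group mention counts, indexed like ``records``."""
    counter = MentionCounter(lexicon=lexicon).fit()
    return counter.transform(r.text for r in records)


@dataclass
class MentionCountTable:
    """Group x time-bin mention counts.

    ``counts`` is indexed by group name with one column per bin start date
    (left-closed, right-open bins of ``bin_width_days``).
    """

    counts: pd.DataFrame
    bin_origin: date
    bin_width_days: int

    @property
    def totals(self) -> pd.Series:
        return self.counts.sum(axis=1)

    @property
    def grand_total(self) -> int:
        return int(self.counts.to_numpy().sum())

    def bin_edges(self) -> list[tuple[date, date]]:
        w = timedelta(days=self.bin_width_days)
        return [(d, d + w) for d in self.counts.columns]

    def to_tidy(self) -> pd.DataFrame:
        w = timedelta(days=self.bin_width_days)
        long = self.counts.stack().rename("count").reset_index()
        long.columns = ["group", "bin_start", "count"]
        long["bin_end"] = long["bin_start"] + w
        return long[["group", "bin_start", "bin_end", "count"]]


def bin_mentions(
    per_record_counts: pd.DataFrame,
    records: Sequence[PostRecord],
    bin_origin: date = DEFAULT_DATE_START,
    bin_width_days: int = 14,
    window_end: date | None = None,
) -> MentionCountTable:
    """Accumulate per-record counts into consecutive bins from ``bin_origin``.

    A record at timestamp *t* lands in bin ``floor((t - origin) / width)``.
    The table always spans every bin from the origin through ``window_end``
    (default: the study window end, or the last record if later), so empty
    bins appear as zero columns.
    """
    if len(per_record_counts) != len(records):
        raise ValidationError("per_record_counts: row count must match records")
    if window_end is None:
        window_end = DEFAULT_DATE_END
        if records:
            last = max(r.timestamp.date() for r in records)
            window_end = max(window_end, last)
    n_bins = (window_end - bin_origin).days // bin_width_days + 1
    bin_starts = [bin_origin + timedelta(days=bin_width_days * i) for i in range(n_bins)]
    groups = list(per_record_counts.columns)
    mat = np.zeros((len(groups), n_bins), dtype=int)
    counts_arr = per_record_counts.to_numpy()
    for i, rec in enumerate(records):
        offset = (rec.timestamp.date() - bin_origin).days
        if offset < 0:
            raise ValidationError(
                f"timestamp: record {rec.post_id} predates bin origin {bin_origin}"
            )
        b = offset // bin_width_days
        if b >= n_bins:
            raise ValidationError(
                f"timestamp: record {rec.post_id} falls after window end {window_end}"
            )
        mat[:, b] += counts_arr[i]
    counts = pd.DataFrame(mat, index=groups, columns=bin_starts)
    return MentionCountTable(counts=counts, bin_origin=bin_origin, bin_width_days=bin_width_days)


def mention_percentages(table: MentionCountTable, decimals: int = 0) -> pd.Series:
    """Each group's share of all grouped mentions, as percentages.

    Default rounding is to the nearest integer, the convention used when such
    tables are reported alongside raw counts.
    """
    grand = table.grand_total
    if grand == 0:
        raise ValidationError("grand total is 0; percentages undefined")
    pct = 100.0 * table.totals / grand
    return pct.round(decimals)


@dataclass
class UserActivityStats:
    """Descriptive statistics of posts-per-user.

    ``sd_posts_per_user`` is the sample standard deviation (n-1 denominator).
    ``log_hist`` is a histogram of natural-log post counts for density plots
    (posts-per-user is typically close to log-normal on these platforms).
    """

    n_posts: int
    n_users: int
    mean_posts_per_user: float
    sd_posts_per_user: float
    per_user_counts: pd.Series
    log_hist: tuple[np.ndarray, np.ndarray]


def user_activity(records: Sequence[PostRecord], bins: int = 30) -> UserActivityStats:
    """Posts-per-user summary over distinct ``user_id``."""
    if not records:
        raise ValidationError("records: non-empty input required")
    counts = pd.Series([r.user_id for r in records]).value_counts().sort_index()
    return user_activity_from_counts(counts, bins=bins)


def user_activity_from_counts(per_user_counts: pd.Series, bins: int = 30) -> UserActivityStats:
    """Same summary computed from an already-tallied per-user count table."""
    if per_user_counts.empty:
        raise ValidationError("per_user_counts: non-empty input required")
    n_posts = int(per_user_counts.sum())
    n_users = int(len(per_user_counts))
    mean = n_posts / n_users
    sd = float(per_user_counts.std(ddof=1)) if n_users > 1 else float("nan")
    log_hist = np.histogram(np.log(per_user_counts.to_numpy(dtype=float)), bins=bins)
    return UserActivityStats(
        n_posts=n_posts,
        n_users=n_users,
        mean_posts_per_user=mean,
        sd_posts_per_user=sd,
        per_user_counts=per_user_counts,
        log_hist=log_hist,
    )
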