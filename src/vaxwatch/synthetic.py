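"""Synthetic social-media corpus generation.

Real vaccine-surveillance corpora (Facebook page extracts, public COVID-19
tweet collections) cannot be redistributed, so every downstream stage here
is exercised on generated corpora that reproduce the statistical
structure the analysis assumes:

* posts-per-user follows a discretized log-normal law,
  ``max(1, round(exp(Normal(mu, sigma))))``;
* timestamps are uniform over the study window (the UK COVID-19 vaccination
  campaign, 2020-12-08 through 2021-04-30, by default);
* post text is neutral filler into which, with configured probabilities,
  theme keywords (stage-1 COVID terms and stage-2 vaccine terms),
  adverse-effect group terms, and sentiment-bearing phrases are embedded;
* true sentiment labels are drawn from a configurable mix, defaulting to
  58/22/19 positive/negative/neutral.

Ground truth (true label, mentioned adverse-effect groups, theme-pass flag
per post) is returned alongside the records, which is what makes
parameter-recovery testing of the whole pipeline possible.  Identical specs
produce byte-identical corpora.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from datetime import date, datetime, timedelta, timezone
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .filtering import DEFAULT_DATE_START, DEFAULT_DATE_END, DEFAULT_STAGE1_TERMS, DEFAULT_STAGE2_TERMS
from .mentions import DEFAULT_AEFI_LEXICON
from .records import PostRecord, ValidationError, PLATFORMS

#: Default per-post probability of mentioning each adverse-effect group,
#: mirroring the relative shares observed in UK social-media AEFI monitoring
#: (appetite 14%, injection site 10%, allergy 9%, clots 8%, generalized
#: symptoms 13%, ...); "other" carries the long tail of remaining symptom
#: categories so the probabilities form the full mention-share distribution.
DEFAULT_AEFI_GROUP_PROBS: dict[str, float] = {
    "appetite": 0.14,
    "allergy": 0.09,
    "injection_site": 0.10,
    "clots": 0.08,
    "bell_palsy": 0.02,
    "guillain_barre": 0.02,
    "headache": 0.02,
    "fever": 0.02,
    "diarrhea": 0.03,
    "generalized": 0.13,
    "other": 0.35,
}

#: Activity-law presets calibrated so the continuous log-normal mean/SD match
#: the observed 3.26 (SD 6.40) posts/user on Facebook and 2.01 (SD 1.76) on
#: Twitter.  Discretization shifts the realized moments slightly.
ACTIVITY_PRESETS = {
    "facebook": (0.392, 1.257),
    "twitter": (0.414, 0.754),
}

DEFAULT_SENTIMENT_MIX = (0.58, 0.22, 0.19)

# Phrase banks.  Positive/negative phrases are built from the built-in
# valence lexicon's vocabulary so lexicon scorers agree with the true label;
# neutral phrases and filler carry no valenced, theme, or symptom words.
_POSITIVE_PHRASES = [
    "absolutely love it, what a brilliant experience",
    "feeling great and so happy today",
    "this is wonderful news, truly amazing",
    "really excellent, could not be happier",
    "so grateful and relieved, fantastic work",
    "delighted with it all, superb effort",
]
_NEGATIVE_PHRASES = [
    "this is awful and i hate it",
    "terrible experience, really horrible",
    "so angry about this, utterly disgusting",
    "worst thing ever, completely dreadful",
    "furious and miserable about the whole thing",
    "appalling and useless, i hated every minute",
]
_NEUTRAL_PHRASES = [
    "posted an update earlier today",
    "saw the announcement this afternoon",
    "reading the schedule for next week",
    "noted the figures in the bulletin",
    "the meeting moved to thursday",
    "the queue outside the centre was long",
]
_FILLER = [
    "morning walk by the river",
    "coffee and the paper",
    "the garden needs weeding",
    "football on this weekend",
    "trying a new recipe tonight",
    "the bus was on time for once",
    "photos from the seaside trip",
    "the bookshop reopened on the high street",
]
_THEME_TEMPLATES = [
    "{s1} update and the {s2} rollout",
    "talking about {s1} and the {s2} programme",
    "{s2} news amid {s1} restrictions",
    "my {s2} appointment during {s1} times",
]
_AEFI_TEMPLATES = [
    "someone mentioned {term} afterwards",
    "heard reports of {term}",
    "a friend had {term} after the first dose",
    "discussion of {term} in the group",
]
_OFFTOPIC_COUNTRIES = ["US", "FR", "DE", "IE", "AU"]


@dataclass(frozen=True)
class CorpusSpec:
    """Full parameterization of the synthetic-corpus generator.

    ``sentiment_mix`` is (positive, negative, neutral); a mix summing to
    anything in [0.98, 1.02] is accepted and renormalized, so reported
    rounded mixes like (0.58, 0.22, 0.19) can be used verbatim.
    """

    n_users: int = 1000
    platform: str = "facebook"
    date_start: date = DEFAULT_DATE_START
    date_end: date = DEFAULT_DATE_END
    activity_mu: float | None = None
    activity_sigma: float | None = None
    sentiment_mix: tuple[float, float, float] = DEFAULT_SENTIMENT_MIX
    aefi_group_probs: Mapping[str, float] | None = None
    theme_pass_prob: float = 0.9
    repost_prob: float = 0.05
    offtopic_country_prob: float = 0.05
    seed: int = 0

    def __post_init__(self):
        if self.n_users <= 0:
            raise ValidationError("n_users: must be a positive integer")
        if self.platform not in PLATFORMS:
            raise ValidationError(f"platform: {self.platform!r} not in {PLATFORMS}")
        if self.date_start > self.date_end:
            raise ValidationError("date_start: must be <= date_end")
        mu, sigma = ACTIVITY_PRESETS[self.platform]
        if self.activity_mu is None:
            object.__setattr__(self, "activity_mu", mu)
        if self.activity_sigma is None:
            object.__setattr__(self, "activity_sigma", sigma)
        if self.activity_sigma <= 0:
            raise ValidationError("activity_sigma: must be > 0")
        mix = tuple(float(x) for x in self.sentiment_mix)
        if len(mix) != 3 or any(x < 0 or x > 1 for x in mix):
            raise ValidationError("sentiment_mix: three probabilities in [0, 1] required")
        total = sum(mix)
        if not (0.98 <= total <= 1.02):
            raise ValidationError("sentiment_mix: components must sum to 1 (±0.02)")
        object.__setattr__(self, "sentiment_mix", tuple(x / total for x in mix))
        probs = self.aefi_group_probs
        if probs is None:
            probs = dict(DEFAULT_AEFI_GROUP_PROBS)
        for g, p in probs.items():
            if g not in DEFAULT_AEFI_LEXICON:
                raise ValidationError(f"aefi_group_probs: unknown group {g!r}")
            if not 0 <= p <= 1:
                raise ValidationError(f"aefi_group_probs: probability for {g!r} not in [0, 1]")
        object.__setattr__(self, "aefi_group_probs", dict(probs))
        for name in ("theme_pass_prob", "repost_prob", "offtopic_country_prob"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValidationError(f"{name}: must be in [0, 1]")


GROUND_TRUTH_COLUMNS = ["platform", "post_id", "sentiment", "aefi_groups", "theme_pass"]


def generate_corpus(spec: CorpusSpec) -> tuple[list[PostRecord], pd.DataFrame]:
    """Generate (records, ground_truth) under ``spec``.

    Ground truth is a DataFrame with one row per post: the true sentiment
    label, the list of adverse-effect groups embedded in the text, and
    whether theme keywords were embedded (the theme-pass flag).
    """
    rng = np.random.default_rng(spec.seed)
    prefix = "fb" if spec.platform == "facebook" else "tw"

    counts = np.maximum(
        1, np.rint(np.exp(rng.normal(spec.activity_mu, spec.activity_sigma, spec.n_users)))
    ).astype(int)
    n_posts = int(counts.sum())

    t0 = datetime.combine(spec.date_start, datetime.min.time(), tzinfo=timezone.utc)
    t1 = datetime.combine(spec.date_end + timedelta(days=1), datetime.min.time(), tzinfo=timezone.utc)
    span = int((t1 - t0).total_seconds())
    offsets = rng.integers(0, span, size=n_posts)

    labels = rng.choice(3, size=n_posts, p=spec.sentiment_mix)
    theme = rng.random(n_posts) < spec.theme_pass_prob
    repost = rng.random(n_posts) < spec.repost_prob
    offtopic = rng.random(n_posts) < spec.offtopic_country_prob
    group_names = list(spec.aefi_group_probs)
    group_hits = {
        g: rng.random(n_posts) < p for g, p in spec.aefi_group_probs.items()
    }

    label_names = ("positive", "negative", "neutral")
    phrase_banks = (_POSITIVE_PHRASES, _NEGATIVE_PHRASES, _NEUTRAL_PHRASES)

    records: list[PostRecord] = []
    truth_rows: list[dict] = []
    i = 0
    for u in range(spec.n_users):
        user_id = f"u{u:06d}"
        for _ in range(counts[u]):
            pieces = [_FILLER[rng.integers(len(_FILLER))]]
            if theme[i]:
                tmpl = _THEME_TEMPLATES[rng.integers(len(_THEME_TEMPLATES))]
                s1 = DEFAULT_STAGE1_TERMS[rng.integers(len(DEFAULT_STAGE1_TERMS))]
                s2 = DEFAULT_STAGE2_TERMS[rng.integers(len(DEFAULT_STAGE2_TERMS))]
                pieces.append(tmpl.format(s1=s1, s2=s2))
            groups_here = [g for g in group_names if group_hits[g][i]]
            for g in groups_here:
                terms = DEFAULT_AEFI_LEXICON[g]
                term = terms[rng.integers(len(terms))]
                tmpl = _AEFI_TEMPLATES[rng.integers(len(_AEFI_TEMPLATES))]
                pieces.append(tmpl.format(term=term))
            bank = phrase_banks[labels[i]]
            pieces.append(bank[rng.integers(len(bank))])
            text = ". ".join(pieces).capitalize() + "."
            if repost[i] and spec.platform == "twitter":
                text = f"RT @{user_id} " + text
            post_id = f"{prefix}{i:07d}"
            records.append(
                PostRecord(
                    platform=spec.platform,
                    post_id=post_id,
                    user_id=user_id,
                    timestamp=t0 + timedelta(seconds=int(offsets[i])),
                    text=text,
                    country=_OFFTOPIC_COUNTRIES[rng.integers(len(_OFFTOPIC_COUNTRIES))]
                    if offtopic[i]
                    else "GB",
                    is_repost=bool(repost[i]),
                )
            )
            truth_rows.append(
                {
                    "platform": spec.platform,
                    "post_id": post_id,
                    "sentiment": label_names[labels[i]],
                    "aefi_groups": groups_here,
                    "theme_pass": bool(theme[i]),
                }
            )
            i += 1
    truth = pd.DataFrame(truth_rows, columns=GROUND_TRUTH_COLUMNS)
    return records, truth


def write_ground_truth(truth: pd.DataFrame, path) -> None:
    """Ground truth to JSONL, one object per post, keyed by post_id."""
    with open(path, "w", encoding="utf-8") as fh:
        for row in truth.to_dict(orient="records"):
            fh.write(json.dumps(row, sort_keys=True) + "\n")


def read_ground_truth(path) -> pd.DataFrame:
    rows = []
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            if line.strip():
                rows.append(json.loads(line))
    return pd.DataFrame(rows, columns=GROUND_TRUTH_COLUMNS)
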