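"""Two-step thematic keyword filtering.

Corpora are narrowed in two keyword stages: stage 1 retains posts mentioning
the disease topic (COVID-19 terms) and feeds adverse-effect mention counting;
stage 2 further retains posts mentioning vaccines or their manufacturers and
feeds sentiment analysis.  A date window restricts everything to the study
period (the UK vaccination campaign, 2020-12-08 through 2021-04-30, both
inclusive).

Matching is case-insensitive (unicode case fold).  In ``word_boundary`` mode
a term matches only where delimited by non-alphanumeric characters or string
edges; multi-word phrases match as contiguous whitespace-separated token
runs.  ``substring`` mode exists for hashtag-dense text ("#covidvaccine").
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from datetime import date, datetime, time, timezone
from typing import Sequence

from .records import PostRecord, ValidationError

# Seed lexicons for the two stages; configurable, not a claim of fidelity to
# any particular appendix list.
DEFAULT_STAGE1_TERMS = [
    "covid", "covid-19", "covid19", "coronavirus", "sars-cov-2", "pandemic",
]
DEFAULT_STAGE2_TERMS = [
    "vaccine", "vaccines", "vaccination", "vaccinated", "jab", "jabs",
    "booster", "astrazeneca", "oxford-astrazeneca", "pfizer", "moderna",
    "biontech",
]

DEFAULT_DATE_START = date(2020, 12, 8)
DEFAULT_DATE_END = date(2021, 4, 30)

MATCH_MODES = ("word_boundary", "substring")

# Alphanumeric = word char minus underscore; boundaries are anything else or edges.
_BOUND_L = r"(?<![^\W_])"
_BOUND_R = r"(?![^\W_])"


def _compile_terms(terms: Sequence[str], match_mode: str) -> re.Pattern:
    parts = []
    for term in terms:
        esc = r"\s+".join(re.escape(tok) for tok in term.casefold().split())
        if match_mode == "word_boundary":
            esc = _BOUND_L + esc + _BOUND_R
        parts.append(esc)
    return re.compile("|".join(parts))


@dataclass(frozen=True)
class FilterStage:
    """One named keyword stage: retain texts matching any of ``terms``."""

    name: str
    terms: tuple[str, ...]
    match_mode: str = "word_boundary"

    def __post_init__(self):
        object.__setattr__(self, "terms", tuple(self.terms))
        if not self.terms:
            raise ValidationError(f"terms: stage {self.name!r} has no terms")
        if any(t == "" for t in self.terms):
            raise ValidationError(f"terms: stage {self.name!r} contains an empty term")
        if self.match_mode not in MATCH_MODES:
            raise ValidationError(f"match_mode: {self.match_mode!r} not in {MATCH_MODES}")

    def pattern(self) -> re.Pattern:
        return _compile_terms(self.terms, self.match_mode)


@dataclass(frozen=True)
class FilterSpec:
    """Ordered keyword stages plus an inclusive UTC calendar date window."""

    stages: tuple[FilterStage, ...]
    date_start: date = DEFAULT_DATE_START
    date_end: date = DEFAULT_DATE_END

    def __post_init__(self):
        object.__setattr__(self, "stages", tuple(self.stages))
        if not self.stages:
            raise ValidationError("stages: at least one stage required")
        if self.date_start > self.date_end:
            raise ValidationError("date_start: must be <= date_end")


def default_filter_spec() -> FilterSpec:
    return FilterSpec(
        stages=(
            FilterStage("covid", tuple(DEFAULT_STAGE1_TERMS)),
            FilterStage("vaccine", tuple(DEFAULT_STAGE2_TERMS)),
        )
    )


def match_any(text: str, stage: FilterStage) -> bool:
    """True iff at least one stage term matches the case-folded text."""
    return stage.pattern().search(text.casefold()) is not None


@dataclass
class FilterReport:
    """Survivor counts after the date window and after each stage, in order."""

    n_input: int
    n_in_window: int
    stage_names: list[str] = field(default_factory=list)
    stage_survivors: list[int] = field(default_factory=list)

    def as_dict(self) -> dict:
        d = {"input": self.n_input, "in_window": self.n_in_window}
        d.update(dict(zip(self.stage_names, self.stage_survivors)))
        return d


@dataclass
class FilterResult:
    """Outputs of :func:`apply_filter`.

    ``stage_outputs[i]`` holds survivors of stages 0..i (within the window).
    For the canonical two-stage spec, ``aefi_records`` (stage-1 output) feeds
    mention counting and ``sentiment_records`` (stage-2 output) feeds the
    sentiment classifier.
    """

    in_window: list[PostRecord]
    stage_outputs: list[list[PostRecord]]
    report: FilterReport

    @property
    def aefi_records(self) -> list[PostRecord]:
        return self.stage_outputs[0]

    @property
    def sentiment_records(self) -> list[PostRecord]:
        return self.stage_outputs[-1]


def in_date_window(record: PostRecord, date_start: date, date_end: date) -> bool:
    d = record.timestamp.astimezone(timezone.utc).date()
    return date_start <= d <= date_end


def apply_filter(records: Sequence[PostRecord], spec: FilterSpec) -> FilterResult:
    """Run the date window then each keyword stage cumulatively.

    Deterministic and order-preserving; stage-(k+1) survivors are a subset of
    stage-k survivors by construction.
    """
    window = [r for r in records if in_date_window(r, spec.date_start, spec.date_end)]
    report = FilterReport(n_input=len(records), n_in_window=len(window))
    outputs: list[list[PostRecord]] = []
    current = window
    for stage in spec.stages:
        pat = stage.pattern()
        current = [r for r in current if pat.search(r.text.casefold()) is not None]
        outputs.append(current)
        report.stage_names.append(stage.name)
        report.stage_survivors.append(len(current))
    return FilterResult(in_window=window, stage_outputs=outputs, report=report)
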