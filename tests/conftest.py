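"""Shared fixtures and independent (regex-free, brute-force) oracles."""

from __future__ import annotations

import pytest

from vaxwatch import CorpusSpec, generate_corpus


# ---------------------------------------------------------------------------
# Independent oracles, deliberately implemented without the package's
# regex machinery so they can arbitrate its behavior.


def naive_term_count(text: str, term: str) -> int:
    """Non-overlapping left-to-right occurrences of ``term`` in ``text``,
    delimited by non-alphanumerics or string edges.  Pure str.find scan."""
    t = text.casefold()
    term = term.casefold()
    n = 0
    i = 0
    while True:
        j = t.find(term, i)
        if j < 0:
            return n
        k = j + len(term)
        before_ok = j == 0 or not t[j - 1].isalnum()
        after_ok = k >= len(t) or not t[k].isalnum()
        if before_ok and after_ok:
            n += 1
            i = k
        else:
            i = j + 1


def naive_group_totals(texts, lexicon_groups) -> dict[str, int]:
    """Total mentions per group via the naive scan."""
    return {
        g: sum(naive_term_count(t, term) for t in texts for term in terms)
        for g, terms in lexicon_groups.items()
    }


def naive_single_word_match(text: str, terms) -> bool:
    """Tokenize on non-alphanumerics and test set membership (single-word
    terms only — the domain where tokenization and boundary-regex agree)."""
    toks = set("".join(c if c.isalnum() else " " for c in text.casefold()).split())
    return any(term.casefold() in toks for term in terms)


# ---------------------------------------------------------------------------
# Corpora


@pytest.fixture(scope="session")
def small_corpus():
    """~500 Facebook posts with ground truth; shared read-only."""
    spec = CorpusSpec(n_users=150, seed=3)
    return generate_corpus(spec)


@pytest.fixture(scope="session")
def twitter_corpus():
    spec = CorpusSpec(n_users=120, platform="twitter", seed=5, repost_prob=0.15)
    return generate_corpus(spec)
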