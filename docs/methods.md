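# Methods

`vaxwatch` implements a social-media pharmacovigilance pipeline for the UK
COVID-19 vaccination campaign window (2020-12-08 through 2021-04-30): corpus
normalization, two-step thematic keyword filtering, grouped adverse-effect
(AEFI) mention surveillance over 2-week bins, and a hybrid ensemble sentiment
classifier aggregated into weekly trends. Because platform data (CrowdTangle
Facebook extracts, public tweet collections) cannot be redistributed, the
package ships a synthetic-corpus generator that reproduces the statistical
structure the analysis assumes, with ground truth attached so every stage is
testable by parameter recovery.

## Corpus model and preprocessing

The unit of analysis is a post: platform, post id, user id, UTC timestamp,
text, optional ISO-3166 alpha-2 country code, repost flag. Preprocessing is
deliberately record-local and order-preserving:

- **Deduplication** keeps the first occurrence of each `(platform, post_id)`
  pair. Identical text cross-posted by different users is legitimately
  distinct content and is retained.
- **Repost exclusion** drops records flagged `is_repost`, plus tweets whose
  text starts with the conventional `RT @` prefix (Twitter only; the prefix
  has no such meaning on Facebook).
- **Geographic filtering** retains records whose country code equals the
  target (case-insensitive). Records with *no* country code are dropped:
  when a geographic filter is applied across a data set, unlocatable records
  cannot be shown to satisfy it. This is the conservative choice; the
  alternative (retain unlocated posts) inflates counts with posts of unknown
  provenance.
- Timestamps are normalized to UTC on load; the study window is interpreted
  as inclusive calendar days in UTC.

All three operations are idempotent, and the geographic filter commutes with
deduplication (both are tested).

## Two-step thematic filter

Stage 1 retains posts matching any disease-topic keyword (COVID-19 terms);
its survivors feed AEFI mention counting. Stage 2 further retains posts
matching vaccine/manufacturer keywords; its survivors feed sentiment
analysis. Stages compose cumulatively, so stage-2 survivors are a subset of
stage-1 survivors by construction.

Matching is case-insensitive under Unicode case folding (social-media
capitalization is noise). The default mode requires word boundaries: a term
matches only where delimited by non-alphanumeric characters or string edges,
with multi-word phrases matching as contiguous whitespace-separated token
runs. A `substring` mode is available per stage for hashtag-dense text
(`#covidvaccine` contains `covid` only as a substring). The shipped stage
lexicons (covid/coronavirus/sars-cov-2; vaccine/jab/AstraZeneca/Pfizer/
Moderna/...) are configurable seeds, not canonical lists. No stemming,
lemmatization, or semantic expansion is attempted.

## AEFI mention counting

A configurable lexicon maps symptom group names to term lists; the default
groups (appetite, allergy, injection site, clots, Bell palsy,
Guillain-Barre, headache, fever, diarrhea, generalized symptoms, other)
follow the categories prominent in UK passive-surveillance reporting.
Counting is **mention-level**: for each record and group, the number of
term occurrences in the case-folded text under word-boundary matching.
Occurrences of the *same* term are counted by a non-overlapping
left-to-right scan; *distinct* terms count independently, so a lexicon
listing both "blood clot" and "clot" yields two mentions for one phrase.
The default lexicon is therefore constructed nesting-free (no default term
contains another as a word-boundary submatch), so one occurrence yields one
mention; loading a lexicon in which one term appears in two groups emits a
warning and counts toward both. Whether repeated occurrences within one
post should count once or many times is a genuinely open convention; the
non-overlapping occurrence count is this package's documented choice, and
it is why group mention totals can far exceed the post count.

Counts accumulate into consecutive left-closed right-open bins of 14 days
anchored at the campaign start (2020-12-08); the final partial bin is
retained, empty bins appear as zero columns, and a record before the bin
origin is a contract violation. Group percentages are shares of the grand
mention total, reported by default at integer rounding alongside the
full-precision values. Per-user activity is summarized as mean and sample
(n−1) standard deviation of posts per user, plus a histogram of natural-log
counts for density plots.

Known limitations, deliberate: no negation handling ("no headache" counts),
no distinction between experienced and discussed symptoms, no MedDRA
coding.

## Hybrid ensemble sentiment classifier

Two continuous lexicon polarity scorers are combined by fixed convex
weights — 0.45 on the VADER-role scorer, 0.55 on the TextBlob-role scorer —
and the result is rule-combined with a categorical (transformer-class)
model:

```
score = 0.45 * scorerA(text) + 0.55 * scorerB(text)
label = "positive"            if score > 0.05
      = categorical(text)     otherwise
```

Lexicon scorers are the stronger component on positive text while a tuned
sequence classifier is stronger on the negative/neutral distinction; the
IF-ELSE rule routes each regime to its stronger component, and the
negative/neutral information in the lexicon score is deliberately unused on
the ELSE branch. The categorical model is invoked lazily (only on the ELSE
branch); if it is needed and unavailable, that is an explicit error, never
a silent fallback.

Numerical conventions: "positive output of the weighted averaging" is
operationalized as `score > +0.05`, the conventional lexicon compound-score
positivity cutoff; the boundary value itself takes the ELSE branch. The
threshold and weights are configuration, not fitted here — re-deriving the
0.45/0.55 split requires labeled data, and `evaluate_labels` provides the
per-class accuracy harness for users who want to re-fit on their own
corpora. Text reaches scorers un-normalized because lexicon scorers use
capitalization as an intensity cue.

Adapters for VADER, TextBlob, and a transformer sequence classifier are
optional lazy imports (`pip install vaxwatch[scorers]`). The package also
provides `MiniLexiconScorer`/`MiniLexiconLabeler`, small deterministic
valence-lexicon scorers satisfying the same contracts with no external
model; they are the defaults wherever reproducibility matters and are what
the test suite exercises, so no model download is ever required.

## Trend aggregation and reporting

"Average weekly sentiment" is operationalized as the per-week
label-proportion triple (counts/n per 7-day bin from the campaign start),
since reported results are percentages of positive/negative/neutral; a
secondary numeric series (mean weighted lexicon score per week) is emitted
as well because a trend curve could equally be drawn from either. Empty
weeks carry an explicit flag rather than fabricated proportions. Key events
can be annotated onto their containing bins without touching numeric
content. Overall percentages are integer-rounded for reporting with
full-precision proportions retained alongside; a rounded triple like
58/22/19 summing to 99 is rounding residue, not an unclassified class.
Platforms are combined by default, as the study design combines them to
mitigate per-platform sample size.

The run report is one markdown document plus tidy CSVs (filter survivor
counts, user activity, the binned mention table with shares, overall
sentiment, weekly trend), every number recomputed from the stage outputs
written next to it.

## Synthetic corpus generator

What it emulates, and the defaults (all configurable on `CorpusSpec`):

| parameter | default | meaning |
| --- | --- | --- |
| posts-per-user law | `max(1, round(exp(N(mu, sigma))))` | discretized log-normal; clamping guarantees every counted user has ≥1 post |
| (mu, sigma) presets | facebook (0.392, 1.257); twitter (0.414, 0.754) | solved from the continuous log-normal moment equations so mean/SD ≈ 3.26/6.40 and 2.01/1.76 posts per user; a calibration convenience, since fitted parameters are not published |
| timestamps | uniform over the window | no within-window density is published |
| sentiment_mix | (0.58, 0.22, 0.19), renormalized | ground-truth label distribution; mixes summing to 1 ± 0.02 are accepted so printed rounded mixes can be used verbatim |
| aefi_group_probs | appetite .14, allergy .09, injection_site .10, clots .08, bell_palsy .02, guillain_barre .02, headache .02, fever .02, diarrhea .03, generalized .13, other .35 | per-post probability of one mention of the group; the "other" catch-all carries the long tail of symptom categories so the named shares sit on the observed percentage scale |
| theme_pass_prob | 0.9 | probability a post carries both stage-1 and stage-2 keywords |
| repost_prob | 0.05 | flagged reposts; on Twitter also `RT @`-prefixed |
| offtopic_country_prob | 0.05 | non-GB country code |

Text is assembled from a neutral filler bank plus, per the drawn
indicators, a theme template (embedding one stage-1 and one stage-2 term),
one term per drawn AEFI group, and a sentiment phrase from a per-label
phrase bank. The phrase banks are built from the built-in valence lexicon's
vocabulary, so the deterministic scorers agree with the true label
essentially always; filler and neutral phrases avoid valenced, theme, and
symptom words. Identical specs produce byte-identical corpora (single
seeded generator, fixed serialization).

What it does **not** emulate — and hence what passing recovery tests do not
show about real data: linguistic variety (sarcasm, misspellings, slang,
negation), retweet cascades and reply threads, bot behavior, user-level
topic correlation, within-window posting waves, or any coupling between
sentiment and symptom mentions. Recovery tests demonstrate that the
pipeline measures without bias what the generator planted, at binomial
sampling error; they say nothing about lexicon coverage of real social
media language.

## Problem sizes and tolerances in the test suite

Recovery tests use corpora of ≥10,000 posts (3,200–4,500 users at the
facebook preset), where binomial error on a 20% share is about 0.4 points,
comfortably inside the ±2-point assertion bands; survivor-fraction recovery
uses ±0.03 at n≈5,000. The ensemble rule is tested exhaustively on a
21-cell grid rather than statistically. Mention counting is arbitrated by a
regex-free `str.find` scan oracle, and user-activity statistics by a
brute-force tally. The full suite runs in well under a minute on one CPU.

## Design choices where the design was open

- Bin origin anchored at the campaign start, bins left-closed right-open,
  final partial bin kept.
- Missing-country records dropped by the geographic filter (conservative
  reading; see above).
- Boundary weighted score exactly at the threshold goes to the ELSE branch.
- Sample (n−1) standard deviation for posts-per-user.
- Terms shared between groups count toward both, with a load-time warning.
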