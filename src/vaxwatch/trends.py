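"""Sentiment trend aggregation and run reporting.

Per-record sentiment labels are aggregated into consecutive weekly bins
anchored at the campaign start (2020-12-08): a record at timestamp *t*
contributes to week ``floor((t - origin) / 7 days)``.  Each bin carries
label counts, label proportions (undefined and flagged when the bin is
empty), and its n.  A secondary numeric series — mean weighted lexicon
score per bin — is emitted alongside the proportion series, since either
can serve as the "average weekly sentiment" curve.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import date, timedelta, timezone
from pathlib import Path
from typing import Sequence
import warnings

import pandas as pd

from .filtering import DEFAULT_DATE_START, DEFAULT_DATE_END, FilterReport
from .mentions import MentionCountTable, UserActivityStats, mention_percentages
from .records import PostRecord, ValidationError
from .sentiment import LABELS


@dataclass
class TrendSeries:
    """Per-bin sentiment label counts and proportions.

    ``table`` is indexed by bin start date with columns: n, one count and
    one proportion column per label, empty (bool flag), and mean_score
    (mean weighted lexicon score, NaN for empty bins).  ``events`` maps bin
    start dates to annotation strings.
    """

    table: pd.DataFrame
    origin: date
    width_days: int
    events: dict[date, list[str]] = field(default_factory=dict)


def sentiment_trend(
    label_table: pd.DataFrame,
    records: Sequence[PostRecord],
    origin: date = DEFAULT_DATE_START,
    width_days: int = 7,
    window_end: date | None = None,
) -> TrendSeries:
    """Aggregate a per-record label table into fixed-width time bins.

    ``label_table`` must carry platform, post_id, label and (optionally)
    weighted_score columns referencing records present in ``records``.
    """
    by_key = {(r.platform, r.post_id): r for r in records}
    if window_end is None:
        window_end = DEFAULT_DATE_END
        if records:
            window_end = max(window_end, max(r.timestamp.date() for r in records))
    n_bins = (window_end - origin).days // width_days + 1
    bin_starts = [origin + timedelta(days=width_days * i) for i in range(n_bins)]
    counts = pd.DataFrame(0, index=bin_starts, columns=list(LABELS))
    score_sum = pd.Series(0.0, index=bin_starts)
    has_scores = "weighted_score" in label_table.columns
    for row in label_table.itertuples(index=False):
        rec = by_key.get((row.platform, row.post_id))
        if rec is None:
            raise ValidationError(f"post_id: label table references unknown post {row.post_id!r}")
        offset = (rec.timestamp.date() - origin).days
        if offset < 0 or offset // width_days >= n_bins:
            raise ValidationError(f"timestamp: record {row.post_id} outside the trend window")
        b = bin_starts[offset // width_days]
        counts.loc[b, row.label] += 1
        if has_scores:
            score_sum[b] += row.weighted_score
    n = counts.sum(axis=1)
    out = pd.DataFrame(index=bin_starts)
    out["n"] = n
    for lab in LABELS:
        out[f"count_{lab}"] = counts[lab]
    for lab in LABELS:
        out[f"prop_{lab}"] = counts[lab].where(n > 0).div(n.where(n > 0))
    out["empty"] = n == 0
    out["mean_score"] = (score_sum / n.where(n > 0)) if has_scores else float("nan")
    return TrendSeries(table=out, origin=origin, width_days=width_days)


def weekly_trend(
    label_table: pd.DataFrame,
    records: Sequence[PostRecord],
    origin: date = DEFAULT_DATE_START,
    window_end: date | None = None,
) -> TrendSeries:
    """Weekly (7-day) sentiment trend from the campaign start."""
    return sentiment_trend(label_table, records, origin=origin, width_days=7, window_end=window_end)


def overall_proportions(label_table: pd.DataFrame) -> tuple[dict[str, float], dict[str, int]]:
    """Overall label mix: (full-precision proportions, rounded percentages).

    Rounded percentages may not sum to exactly 100; full-precision
    proportions always sum to 1.
    """
    if label_table.empty:
        raise ValidationError("label_table: non-empty input required")
    vc = label_table["label"].value_counts()
    total = int(vc.sum())
    props = {lab: float(vc.get(lab, 0)) / total for lab in LABELS}
    pcts = {lab: round(100.0 * props[lab]) for lab in LABELS}
    return props, pcts


def annotate_events(series: TrendSeries, events: Sequence[tuple[date, str]]) -> TrendSeries:
    """Attach key events to their containing bins; numeric content untouched.

    Events outside the covered window are skipped with a warning.
    """
    bin_starts = list(series.table.index)
    window_end = bin_starts[-1] + timedelta(days=series.width_days)
    annotated = dict(series.events)
    for d, text in events:
        offset = (d - series.origin).days
        if offset < 0 or d >= window_end:
            warnings.warn(f"event on {d} is outside the trend window; skipped")
            continue
        b = bin_starts[min(offset // series.width_days, len(bin_starts) - 1)]
        annotated.setdefault(b, []).append(text)
    return TrendSeries(
        table=series.table, origin=series.origin, width_days=series.width_days, events=annotated
    )


def trend_to_tidy(series: TrendSeries) -> pd.DataFrame:
    """Tidy (week_start, label, count, proportion) frame for CSV output."""
    rows = []
    for b, row in series.table.iterrows():
        for lab in LABELS:
            rows.append(
                {
                    "week_start": b,
                    "label": lab,
                    "count": int(row[f"count_{lab}"]),
                    "proportion": row[f"prop_{lab}"],
                }
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Run report


def build_report(
    out_dir,
    filter_report: FilterReport,
    activity: dict[str, UserActivityStats],
    mention_table: MentionCountTable,
    label_table: pd.DataFrame,
    trend: TrendSeries,
    title: str = "Vaccine surveillance run report",
) -> Path:
    """Assemble the single-run report: markdown plus accompanying CSVs.

    Every number in the markdown is recomputed from the stage outputs passed
    in, and the CSVs written next to it are those same outputs, so the
    report is traceable file-by-file.  Returns the markdown path.
    """
    for name, value in [
        ("filter_report", filter_report),
        ("mention_table", mention_table),
        ("label_table", label_table),
        ("trend", trend),
    ]:
        if value is None:
            raise ValidationError(f"{name}: missing stage output")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    mention_table.to_tidy().to_csv(out_dir / "mentions_by_bin.csv", index=False)
    wide = mention_table.counts.copy()
    wide.columns = [str(c) for c in wide.columns]
    wide.to_csv(out_dir / "mentions_wide.csv", index_label="group")
    label_table.to_csv(out_dir / "labels.csv", index=False)
    trend_to_tidy(trend).to_csv(out_dir / "weekly_trend.csv", index=False)

    props, pcts = overall_proportions(label_table)
    pct_by_group = mention_percentages(mention_table)

    lines = [f"# {title}", "", "## Corpus filtering", ""]
    lines.append("| stage | records |")
    lines.append("| --- | --- |")
    for k, v in filter_report.as_dict().items():
        lines.append(f"| {k} | {v} |")
    lines += ["", "## User activity", ""]
    lines.append("| platform | posts | users | mean posts/user | SD |")
    lines.append("| --- | --- | --- | --- | --- |")
    for platform, stats in activity.items():
        lines.append(
            f"| {platform} | {stats.n_posts} | {stats.n_users} "
            f"| {stats.mean_posts_per_user:.2f} | {stats.sd_posts_per_user:.2f} |"
        )
    lines += ["", "## Adverse-effect mentions", ""]
    lines.append("| group | mentions | % of all mentions |")
    lines.append("| --- | --- | --- |")
    totals = mention_table.totals
    for g in totals.index:
        lines.append(f"| {g} | {int(totals[g])} | {pct_by_group[g]:.0f}% |")
    lines.append(f"| **total** | {mention_table.grand_total} | 100% |")
    lines += ["", "## Overall sentiment", ""]
    lines.append("| label | % (rounded) | proportion |")
    lines.append("| --- | --- | --- |")
    for lab in LABELS:
        lines.append(f"| {lab} | {pcts[lab]}% | {props[lab]:.4f} |")
    lines += [
        "",
        "## Weekly sentiment trend",
        "",
        f"{len(trend.table)} weekly bins from {trend.origin}; "
        f"{int(trend.table['empty'].sum())} empty. See weekly_trend.csv.",
        "",
    ]
    report_path = out_dir / "report.md"
    report_path.write_text("\n".join(lines), encoding="utf-8")
    return report_path
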