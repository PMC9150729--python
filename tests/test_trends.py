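"""Weekly sentiment trends, overall proportions, annotations, reporting."""

from datetime import date, datetime

import pandas as pd
import pytest

from vaxwatch import (
    CorpusSpec,
    ValidationError,
    annotate_events,
    apply_filter,
    bin_mentions,
    build_report,
    classify_corpus,
    count_mentions,
    default_filter_spec,
    generate_corpus,
    overall_proportions,
    sentiment_trend,
    trend_to_tidy,
    user_activity,
    weekly_trend,
)
from vaxwatch.records import PostRecord


def post(text, ts, post_id, platform="facebook"):
    return PostRecord(
        platform=platform,
        post_id=post_id,
        user_id="u1",
        timestamp=datetime.fromisoformat(ts),
        text=text,
        country="GB",
    )


def label_row(r, label, score=0.5):
    return {"platform": r.platform, "post_id": r.post_id, "label": label,
            "weighted_score": score, "branch_taken": "lexicon"}


# ---------------------------------------------------------------------------
# weekly_trend


def test_all_positive_week():
    records = [post("x", f"2020-12-{8+i:02d}T10:00:00+00:00", f"p{i}") for i in range(4)]
    labels = pd.DataFrame([label_row(r, "positive") for r in records])
    series = weekly_trend(labels, records, window_end=date(2020, 12, 21))
    wk1 = series.table.iloc[0]
    assert wk1["n"] == 4
    assert (wk1["prop_positive"], wk1["prop_negative"], wk1["prop_neutral"]) == (1.0, 0.0, 0.0)


def test_empty_corpus_all_bins_flagged_empty():
    labels = pd.DataFrame(columns=["platform", "post_id", "label", "weighted_score"])
    series = weekly_trend(labels, [], window_end=date(2021, 4, 30))
    assert series.table["empty"].all()
    assert series.table["prop_positive"].isna().all()


def test_unknown_post_id_raises_consistency_error():
    records = [post("x", "2020-12-10T00:00:00+00:00", "p1")]
    labels = pd.DataFrame([{"platform": "facebook", "post_id": "ghost",
                            "label": "positive", "weighted_score": 0.1}])
    with pytest.raises(ValidationError, match="ghost"):
        weekly_trend(labels, records)


def test_week_binning_floor_arithmetic():
    records = [
        post("x", "2020-12-14T23:59:59+00:00", "a"),  # day 6 -> week 0
        post("x", "2020-12-15T00:00:00+00:00", "b"),  # day 7 -> week 1
    ]
    labels = pd.DataFrame([label_row(r, "neutral") for r in records])
    series = weekly_trend(labels, records, window_end=date(2020, 12, 28))
    assert series.table.iloc[0]["n"] == 1 and series.table.iloc[1]["n"] == 1


def test_per_week_proportions_match_ground_truth_mixes():
    """Recovered per-week proportions equal the generator's bin-conditional
    label mixes when the scorers are the exact oracle doubles."""
    records, truth = generate_corpus(CorpusSpec(n_users=400, seed=23))
    labels, _ = classify_corpus(records)
    series = weekly_trend(labels, records)
    tdf = truth.merge(
        pd.DataFrame({"post_id": [r.post_id for r in records],
                      "day": [(r.timestamp.date() - series.origin).days for r in records]}),
        on="post_id",
    )
    tdf["week"] = tdf["day"] // 7
    for week, grp in tdf.groupby("week"):
        row = series.table.iloc[week]
        truth_prop = (grp["sentiment"] == "positive").mean()
        if row["n"] >= 30:
            assert abs(row["prop_positive"] - truth_prop) < 0.05


def test_weekly_pairs_reaggregate_to_biweekly(small_corpus):
    records, _ = small_corpus
    labels, _ = classify_corpus(records)
    w7 = sentiment_trend(labels, records, width_days=7, window_end=date(2021, 4, 30))
    w14 = sentiment_trend(labels, records, width_days=14, window_end=date(2021, 4, 30))
    for lab in ("positive", "negative", "neutral"):
        col = f"count_{lab}"
        paired = [
            int(w7.table[col].iloc[i : i + 2].sum()) for i in range(0, len(w7.table) - 1, 2)
        ]
        direct = [int(x) for x in w14.table[col][: len(paired)]]
        assert paired == direct


def test_weekly_counts_conserve_overall(small_corpus):
    records, _ = small_corpus
    labels, _ = classify_corpus(records)
    series = weekly_trend(labels, records)
    for lab in ("positive", "negative", "neutral"):
        assert series.table[f"count_{lab}"].sum() == (labels["label"] == lab).sum()


# ---------------------------------------------------------------------------
# overall_proportions


def test_overall_hand_counts():
    labels = pd.DataFrame(
        [{"platform": "facebook", "post_id": f"p{i}", "label": lab}
         for i, lab in enumerate(["positive", "positive", "negative", "neutral"])]
    )
    props, pcts = overall_proportions(labels)
    assert pcts == {"positive": 50, "negative": 25, "neutral": 25}
    assert sum(props.values()) == pytest.approx(1.0)


def test_all_neutral():
    labels = pd.DataFrame([{"platform": "f", "post_id": "p", "label": "neutral"}])
    _, pcts = overall_proportions(labels)
    assert pcts == {"positive": 0, "negative": 0, "neutral": 100}


def test_empty_table_raises():
    with pytest.raises(ValidationError):
        overall_proportions(pd.DataFrame(columns=["label"]))


def test_order_invariance(small_corpus):
    records, _ = small_corpus
    labels, _ = classify_corpus(records)
    shuffled = labels.sample(frac=1, random_state=0).reset_index(drop=True)
    assert overall_proportions(labels) == overall_proportions(shuffled)


# ---------------------------------------------------------------------------
# annotate_events


def test_event_attaches_to_first_week():
    records = [post("x", "2020-12-09T00:00:00+00:00", "p1")]
    labels = pd.DataFrame([label_row(records[0], "neutral")])
    series = weekly_trend(labels, records, window_end=date(2021, 1, 4))
    out = annotate_events(series, [(date(2020, 12, 10), "rollout begins")])
    assert out.events[date(2020, 12, 8)] == ["rollout begins"]
    assert out.table.equals(series.table)


def test_empty_event_list_is_identity(small_corpus):
    records, _ = small_corpus
    labels, _ = classify_corpus(records)
    series = weekly_trend(labels, records)
    out = annotate_events(series, [])
    assert out.events == {} and out.table.equals(series.table)


def test_event_on_window_end_goes_to_final_bin():
    records = [post("x", "2020-12-09T00:00:00+00:00", "p1")]
    labels = pd.DataFrame([label_row(records[0], "neutral")])
    series = weekly_trend(labels, records, window_end=date(2021, 4, 30))
    out = annotate_events(series, [(date(2021, 4, 30), "campaign milestone")])
    last_bin = series.table.index[-1]
    assert out.events[last_bin] == ["campaign milestone"]


def test_out_of_window_event_warns_and_skips(small_corpus):
    records, _ = small_corpus
    labels, _ = classify_corpus(records)
    series = weekly_trend(labels, records)
    with pytest.warns(UserWarning, match="outside"):
        out = annotate_events(series, [(date(2019, 1, 1), "too early")])
    assert out.events == {}


# ---------------------------------------------------------------------------
# build_report


def run_pipeline(records):
    result = apply_filter(records, default_filter_spec())
    per_record = count_mentions(result.aefi_records)
    table = bin_mentions(per_record, result.aefi_records)
    labels, _ = classify_corpus(result.sentiment_records)
    series = weekly_trend(labels, result.sentiment_records)
    activity = {"facebook": user_activity(result.aefi_records)}
    return result, table, labels, series, activity


def test_report_sections_and_consistency(tmp_path, small_corpus):
    records, _ = small_corpus
    result, table, labels, series, activity = run_pipeline(records)
    path = build_report(tmp_path, result.report, activity, table, labels, series)
    text = path.read_text()
    for heading in ("Corpus filtering", "User activity", "Adverse-effect mentions",
                    "Overall sentiment", "Weekly sentiment trend"):
        assert heading in text
    # cross-file consistency: totals in CSVs equal stage outputs
    tidy = pd.read_csv(tmp_path / "mentions_by_bin.csv")
    assert tidy["count"].sum() == table.grand_total
    trend_csv = pd.read_csv(tmp_path / "weekly_trend.csv")
    assert trend_csv["count"].sum() == len(labels)
    labels_csv = pd.read_csv(tmp_path / "labels.csv")
    assert len(labels_csv) == len(labels)


def test_report_missing_stage_output_raises(tmp_path, small_corpus):
    records, _ = small_corpus
    result, table, labels, series, activity = run_pipeline(records)
    with pytest.raises(ValidationError, match="mention_table"):
        build_report(tmp_path, result.report, activity, None, labels, series)


def test_report_rerun_is_byte_identical(tmp_path, small_corpus):
    records, _ = small_corpus
    outs = []
    for i in (1, 2):
        d = tmp_path / str(i)
        result, table, labels, series, activity = run_pipeline(records)
        build_report(d, result.report, activity, table, labels, series)
        outs.append({p.name: p.read_bytes() for p in d.iterdir() if p.suffix in (".md", ".csv")})
    assert outs[0] == outs[1]
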