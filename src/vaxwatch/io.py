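"""Corpus reading, writing, deduplication, repost exclusion, and
geographical filtering.

Corpora are exchanged as JSONL (UTF-8, one object per line) or CSV (header
row, RFC-4180 quoting) with columns/keys: platform, post_id, user_id,
timestamp (ISO-8601, normalized to UTC on load), text, country (optional),
is_repost.  Malformed rows are counted, logged at WARNING, and skipped;
order is preserved.
"""

from __future__ import annotations

import csv
import json
import logging
from datetime import datetime, timezone
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .records import PostRecord, ValidationError

logger = logging.getLogger(__name__)

REQUIRED_FIELDS = ["platform", "post_id", "user_id", "timestamp", "text"]
ALL_FIELDS = REQUIRED_FIELDS + ["country", "is_repost"]


class SchemaError(ValueError):
    """Input file is missing a required column or field."""


class FormatError(ValueError):
    """Input file cannot be parsed in the declared format."""


def _record_from_row(row: dict) -> PostRecord:
    missing = [f for f in REQUIRED_FIELDS if f not in row or row[f] in (None, "")]
    if missing:
        raise SchemaError(f"missing required field(s): {', '.join(missing)}")
    ts = row["timestamp"]
    if isinstance(ts, str):
        ts = datetime.fromisoformat(ts.replace("Z", "+00:00"))
    if ts.tzinfo is None:
        ts = ts.replace(tzinfo=timezone.utc)
    country = row.get("country") or None
    is_repost = row.get("is_repost", False)
    if isinstance(is_repost, str):
        is_repost = is_repost.strip().lower() in ("true", "1", "yes")
    return PostRecord(
        platform=str(row["platform"]),
        post_id=str(row["post_id"]),
        user_id=str(row["user_id"]),
        timestamp=ts,
        text=str(row["text"]),
        country=country,
        is_repost=bool(is_repost),
    )


def load_corpus(path, format: str | None = None) -> list[PostRecord]:
    """Load and validate a corpus file.

    ``format`` is "jsonl" or "csv"; inferred from the suffix when omitted.
    Malformed rows are skipped with a logged warning; a file-level problem
    (unreadable, wrong format, CSV missing a required column) raises.
    """
    path = Path(path)
    if format is None:
        format = "csv" if path.suffix.lower() == ".csv" else "jsonl"
    if format not in ("jsonl", "csv"):
        raise FormatError(f"unknown format {format!r}")
    records: list[PostRecord] = []
    n_skipped = 0
    if format == "jsonl":
        with open(path, encoding="utf-8") as fh:
            for lineno, line in enumerate(fh, 1):
                if not line.strip():
                    continue
                try:
                    row = json.loads(line)
                except json.JSONDecodeError as exc:
                    raise FormatError(f"{path}:{lineno}: not valid JSON: {exc}") from exc
                try:
                    records.append(_record_from_row(row))
                except (SchemaError, ValidationError, ValueError) as exc:
                    n_skipped += 1
                    logger.warning("%s:%d: skipping malformed row: %s", path, lineno, exc)
    else:
        with open(path, encoding="utf-8", newline="") as fh:
            reader = csv.DictReader(fh)
            header = reader.fieldnames or []
            missing = [f for f in REQUIRED_FIELDS if f not in header]
            if missing:
                raise SchemaError(f"{path}: missing required column(s): {', '.join(missing)}")
            for lineno, row in enumerate(reader, 2):
                try:
                    records.append(_record_from_row(row))
                except (SchemaError, ValidationError, ValueError) as exc:
                    n_skipped += 1
                    logger.warning("%s:%d: skipping malformed row: %s", path, lineno, exc)
    if n_skipped:
        logger.warning("%s: skipped %d malformed row(s)", path, n_skipped)
    return records


def write_corpus(records: Sequence[PostRecord], path, format: str | None = None) -> None:
    """Write a corpus as JSONL or CSV (inferred from suffix when omitted)."""
    path = Path(path)
    if format is None:
        format = "csv" if path.suffix.lower() == ".csv" else "jsonl"
    if format == "jsonl":
        with open(path, "w", encoding="utf-8") as fh:
            for r in records:
                fh.write(json.dumps(r.to_dict(), sort_keys=True) + "\n")
    elif format == "csv":
        with open(path, "w", encoding="utf-8", newline="") as fh:
            writer = csv.DictWriter(fh, fieldnames=ALL_FIELDS)
            writer.writeheader()
            for r in records:
                d = r.to_dict()
                d["country"] = d["country"] or ""
                writer.writerow(d)
    else:
        raise FormatError(f"unknown format {format!r}")


def deduplicate(records: Sequence[PostRecord]) -> list[PostRecord]:
    """Keep the first occurrence of each (platform, post_id)."""
    seen: set[tuple[str, str]] = set()
    out = []
    for r in records:
        key = (r.platform, r.post_id)
        if key not in seen:
            seen.add(key)
            out.append(r)
    return out


def exclude_reposts(records: Sequence[PostRecord]) -> list[PostRecord]:
    """Drop reshared content: ``is_repost`` records, and tweets whose text
    starts with the conventional "RT @" retweet prefix."""
    return [
        r
        for r in records
        if not r.is_repost and not (r.platform == "twitter" and r.text.startswith("RT @"))
    ]


def geo_filter(records: Sequence[PostRecord], target_country: str = "GB") -> list[PostRecord]:
    """Retain records located in ``target_country`` (case-insensitive);
    records with no country code are dropped."""
    if not (isinstance(target_country, str) and len(target_country) == 2 and target_country.isalpha()):
        raise ValidationError("target_country: must be an ISO-3166 alpha-2 code")
    tc = target_country.upper()
    return [r for r in records if r.country is not None and r.country.upper() == tc]
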