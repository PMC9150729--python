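"""The unit of analysis: one social-media post.

A :class:`PostRecord` is one post (a Facebook post or a tweet) with just
enough structure for surveillance work: who posted, when (UTC), on which
platform, the free text, an optional ISO-3166 alpha-2 country code, and a
repost flag.  Everything downstream — thematic filtering, adverse-effect
mention counting, sentiment classification — consumes sequences of these.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from datetime import datetime, timezone
from typing import Iterable, Sequence

import pandas as pd

PLATFORMS = ("facebook", "twitter")


class ValidationError(ValueError):
    """A record or spec field failed validation; the message names the field."""


@dataclass(frozen=True)
class PostRecord:
    """One social-media post.

    Parameters
    ----------
    platform : {"facebook", "twitter"}
    post_id : str
        Opaque identifier, unique within a platform after deduplication.
    user_id : str
        Opaque author identifier.
    timestamp : datetime
        Timezone-aware, normalized to UTC.
    text : str
        Post body, unmodified unicode.
    country : str or None
        ISO-3166 alpha-2 code, upper-cased, or None when unlocated.
    is_repost : bool
        True for reshared content (retweets, shares).
    """

    platform: str
    post_id: str
    user_id: str
    timestamp: datetime
    text: str
    country: str | None = None
    is_repost: bool = False

    def __post_init__(self) -> None:
        if self.platform not in PLATFORMS:
            raise ValidationError(f"platform: {self.platform!r} not in {PLATFORMS}")
        if not self.post_id:
            raise ValidationError("post_id: must be non-empty")
        ts = self.timestamp
        if not isinstance(ts, datetime):
            raise ValidationError("timestamp: must be a datetime")
        if ts.tzinfo is None:
            raise ValidationError("timestamp: must be timezone-aware")
        object.__setattr__(self, "timestamp", ts.astimezone(timezone.utc))
        if self.country is not None:
            object.__setattr__(self, "country", self.country.upper())

    def to_dict(self) -> dict:
        d = asdict(self)
        d["timestamp"] = self.timestamp.isoformat()
        return d


def to_frame(records: Sequence[PostRecord]) -> pd.DataFrame:
    """Tabulate records into a DataFrame (one row per post, ISO timestamps parsed)."""
    if not records:
        return pd.DataFrame(
            columns=["platform", "post_id", "user_id", "timestamp", "text", "country", "is_repost"]
        )
    df = pd.DataFrame([r.to_dict() for r in records])
    df["timestamp"] = pd.to_datetime(df["timestamp"], utc=True)
    return df


def from_frame(df: pd.DataFrame) -> list[PostRecord]:
    """Inverse of :func:`to_frame`; rows failing validation raise."""
    out = []
    for row in df.itertuples(index=False):
        ts = row.timestamp
        if isinstance(ts, str):
            ts = datetime.fromisoformat(ts)
        elif isinstance(ts, pd.Timestamp):
            ts = ts.to_pydatetime()
        country = row.country if isinstance(row.country, str) and row.country else None
        out.append(
            PostRecord(
                platform=row.platform,
                post_id=str(row.post_id),
                user_id=str(row.user_id),
                timestamp=ts,
                text=row.text,
                country=country,
                is_repost=bool(row.is_repost),
            )
        )
    return out
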