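"""Timestamp conventions shared across the pipeline.

All instants are timezone-aware UTC datetimes at millisecond precision;
durations are plain decimal seconds, because the problem rules compare
activity durations in seconds.
"""

from __future__ import annotations

from datetime import datetime, timedelta, timezone


def parse_instant(value: str | datetime) -> datetime:
    """Parse an ISO 8601 instant into an aware UTC datetime.

    Naive inputs are interpreted as UTC; aware inputs are converted.
    """
    if isinstance(value, datetime):
        dt = value
    else:
        try:
            dt = datetime.fromisoformat(value)
        except ValueError as exc:
            raise ValueError(f"unparseable timestamp {value!r}") from exc
    if dt.tzinfo is None:
        dt = dt.replace(tzinfo=timezone.utc)
    return dt.astimezone(timezone.utc)


def format_instant(dt: datetime) -> str:
    """Render an instant as ``YYYY-MM-DDTHH:MM:SS.mmmZ`` (UTC, ms precision)."""
    dt = parse_instant(dt)
    return dt.strftime("%Y-%m-%dT%H:%M:%S.") + f"{dt.microsecond // 1000:03d}Z"


def seconds_between(start: datetime, end: datetime) -> float:
    """Signed duration ``end - start`` in seconds."""
    return (end - start).total_seconds()


def add_seconds(dt: datetime, seconds: float) -> datetime:
    """Offset an instant by a number of seconds, rounded to milliseconds."""
    return dt + timedelta(milliseconds=round(seconds * 1000.0))


def epoch_ms(dt: datetime) -> int:
    """Milliseconds since the Unix epoch (used for deterministic ids)."""
    return round(dt.timestamp() * 1000.0)
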