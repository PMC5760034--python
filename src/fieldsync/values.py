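"""Typed attribute values.

The store is schema-free: every datum is a (entity, attribute, value)
triple, and the value carries its own type tag so it round-trips through
persistence, sync messages and CSV export without loss.  Supported tags:

====================  =========================================
tag                   Python type
====================  =========================================
``text``              str (also datetime.date, stored ISO)
``integer``           int
``real``              float
``boolean``           bool
``timestamp``         timezone-aware datetime, stored ISO 8601
``null``              None
====================  =========================================

Timestamps must carry an explicit UTC offset: field devices have
unreliable clocks and naive times are ambiguous, so they are rejected.
"""

from __future__ import annotations

import datetime as _dt

from .errors import ValueTypeError

TAGS = ("text", "integer", "real", "boolean", "timestamp", "null")


def encode(value) -> tuple[str, str]:
    """Return the ``(tag, payload)`` text form of a Python value."""
    if value is None:
        return "null", ""
    if isinstance(value, bool):
        return "boolean", "true" if value else "false"
    if isinstance(value, int):
        return "integer", str(value)
    if isinstance(value, float):
        return "real", repr(value)
    if isinstance(value, _dt.datetime):
        if value.tzinfo is None or value.utcoffset() is None:
            raise ValueTypeError(
                "timestamps must be timezone-aware (explicit UTC offset)"
            )
        return "timestamp", value.isoformat()
    if isinstance(value, _dt.date):
        return "text", value.isoformat()
    if isinstance(value, str):
        return "text", value
    raise ValueTypeError(f"unsupported value type: {type(value).__name__}")


def decode(tag: str, payload: str):
    """Inverse of :func:`encode`."""
    if tag == "null":
        return None
    if tag == "boolean":
        if payload == "true":
            return True
        if payload == "false":
            return False
        raise ValueTypeError(f"bad boolean payload: {payload!r}")
    if tag == "integer":
        return int(payload)
    if tag == "real":
        return float(payload)
    if tag == "timestamp":
        ts = _dt.datetime.fromisoformat(payload)
        if ts.tzinfo is None:
            raise ValueTypeError(f"stored timestamp lacks offset: {payload!r}")
        return ts
    if tag == "text":
        return payload
    raise ValueTypeError(f"unknown value tag: {tag!r}")
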