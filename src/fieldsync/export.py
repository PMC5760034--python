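"""Typed CSV export of a store or downloaded snapshot.

Mirrors the post-field processing step: researchers pick record types
and get one CSV table per type for analysis.  The export is fully
deterministic — fixed column order per type, the store's stable row
order (entity creation sequence), RFC 4180 quoting, UTF-8, ``\\n``
newlines — so two exports of the same store are byte-identical.

Cell values are the canonical text payloads of the typed values
(integers as digits, reals as ``repr``, booleans ``true``/``false``,
timestamps ISO 8601 with offset), so re-parsing reproduces every stored
value exactly.  Attributes outside a type's fixed schema (e.g. the
per-individual presence entries of a session) are carried in an
``extra`` column as canonical JSON with their type tags.
"""

from __future__ import annotations

import csv
import datetime as _dt
import json
import os
from dataclasses import dataclass, field

from . import values as _values
from .errors import ExportError
from .store import DELETED_ATTRIBUTE, ENTITY_TYPES, TYPE_ATTRIBUTE, EavStore, Entity

#: Fixed, documented column schema per record type (attribute order).
SCHEMAS: dict[str, list[str]] = {
    "pack": ["name", "active"],
    "individual": ["name", "pack", "sex", "date-of-birth", "litter-code",
                   "removed"],
    "group-composition-session": ["pack", "date", "start-time", "end-time"],
    "weight": ["session", "individual", "grams", "period", "session-time"],
    "pregnancy": ["session", "female", "pregnant"],
    "mate-guard": ["session", "male", "female", "strength", "accuracy",
                   "primary"],
    "escort": ["session", "pup", "escort", "strength", "accuracy"],
    "babysit": ["session", "individual", "evidence"],
    "gps-fix": ["session", "timestamp", "lat", "lon"],
    "focal-follow": ["protocol", "focal", "start-time", "state", "pauses"],
    "focal-scan": ["follow", "minute-index", "nearest", "within-2m", "empty"],
    "focal-interaction": ["follow", "kind", "partner", "initiator",
                          "intensity", "context", "winner", "offset-seconds"],
    "group-event": ["pack", "event-type", "timestamp", "participants",
                    "other-pack", "outcome", "cause", "target"],
    "note": ["pack", "event-type", "timestamp", "free-text"],
}

#: Attributes that reference an individual; exported with a *-name column.
_INDIVIDUAL_REFS = {"individual", "female", "male", "pup", "escort", "focal",
                    "partner"}
#: Attributes that reference a pack.
_PACK_REFS = {"pack", "other-pack"}


@dataclass
class ExportSpec:
    """What to export and where.

    At least one record type; optional date range (inclusive) and pack
    filter; soft-deleted records are excluded unless requested, in which
    case rows gain a ``deleted`` column.
    """

    record_types: list[str]
    output_dir: str
    date_range: tuple[_dt.date, _dt.date] | None = None
    pack_filter: str | None = None
    include_deleted: bool = False


def list_record_types(store: EavStore) -> list[tuple[str, int]]:
    """Counts of non-deleted entities per type present in the store."""
    out = []
    for etype in ENTITY_TYPES:
        n = len(store.query_entities(etype))
        if n:
            out.append((etype, n))
    return out


def _record_date(ent: Entity) -> _dt.date | None:
    for attr in ("date", "timestamp", "session-time", "start-time"):
        val = ent.get(attr)
        if isinstance(val, _dt.datetime):
            return val.date()
        if isinstance(val, str) and attr == "date":
            return _dt.date.fromisoformat(val)
    return None


def _cell(ent: Entity, attr: str) -> str:
    entry = ent.attributes.get(attr)
    if entry is None:
        return ""
    return _values.encode(entry.value)[1]


def _columns(etype: str, spec: ExportSpec) -> list[str]:
    cols = ["id"]
    for attr in SCHEMAS[etype]:
        cols.append(attr)
        if attr in _INDIVIDUAL_REFS or attr in _PACK_REFS:
            cols.append(f"{attr}-name")
    cols.append("extra")
    if spec.include_deleted:
        cols.append("deleted")
    return cols


def export(store: EavStore, spec: ExportSpec) -> list[str]:
    """Write one CSV per requested record type; return the paths."""
    if not spec.record_types:
        raise ExportError("at least one record type is required")
    for etype in spec.record_types:
        if etype not in SCHEMAS:
            raise ExportError(f"unknown record type: {etype!r}")
    try:
        os.makedirs(spec.output_dir, exist_ok=True)
    except OSError as exc:
        raise ExportError(f"cannot create output dir: {exc}") from exc

    name_cache: dict[str, str] = {}

    def lookup_name(ref_id: str) -> str:
        if not ref_id or ref_id in (None, ""):
            return ""
        if ref_id not in name_cache:
            try:
                name_cache[ref_id] = store.get_entity(ref_id).get("name", "")
            except Exception:  # dangling reference in a partial snapshot
                name_cache[ref_id] = ""
        return name_cache[ref_id]

    paths = []
    for etype in spec.record_types:
        path = os.path.join(spec.output_dir, f"{etype}.csv")
        cols = _columns(etype, spec)
        # Free-text notes get full quoting, never truncated.
        quoting = csv.QUOTE_ALL if etype == "note" else csv.QUOTE_MINIMAL
        try:
            fh = open(path, "w", newline="", encoding="utf-8")
        except OSError as exc:
            raise ExportError(f"cannot write {path}: {exc}") from exc
        with fh:
            writer = csv.writer(fh, quoting=quoting, lineterminator="\n")
            writer.writerow(cols)
            for ent in store.query_entities(
                    etype, include_deleted=spec.include_deleted):
                if spec.pack_filter and _entity_pack(store, ent) != spec.pack_filter:
                    continue
                if spec.date_range is not None:
                    d = _record_date(ent)
                    if d is not None and not (
                            spec.date_range[0] <= d <= spec.date_range[1]):
                        continue
                writer.writerow(_row(store, ent, etype, spec, lookup_name))
        paths.append(path)
    return paths


def _entity_pack(store: EavStore, ent: Entity) -> str | None:
    direct = ent.get("pack")
    if direct is not None:
        return direct
    for ref_attr in ("session", "follow", "individual", "focal"):
        ref = ent.get(ref_attr)
        if ref is not None:
            try:
                return _entity_pack(store, store.get_entity(ref))
            except Exception:
                return None
    return None


def _row(store, ent, etype, spec, lookup_name) -> list[str]:
    schema = SCHEMAS[etype]
    row = [ent.id]
    for attr in schema:
        row.append(_cell(ent, attr))
        if attr in _INDIVIDUAL_REFS or attr in _PACK_REFS:
            row.append(lookup_name(ent.get(attr, "")))
    extra = {}
    known = set(schema) | {TYPE_ATTRIBUTE, DELETED_ATTRIBUTE}
    for attr in sorted(ent.attributes):
        if attr not in known:
            entry = ent.attributes[attr]
            extra[attr] = [entry.tag, _values.encode(entry.value)[1]]
    row.append(json.dumps(extra, sort_keys=True) if extra else "")
    if spec.include_deleted:
        row.append("true" if ent.deleted else "false")
    return row


def read_export(path: str) -> list[dict[str, str]]:
    """Parse an exported CSV back into a list of row dicts (text cells)."""
    with open(path, newline="", encoding="utf-8") as fh:
        return list(csv.DictReader(fh))
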