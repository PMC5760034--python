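"""Versioned entity-attribute-value store.

One store backs each field device (replica) and the hub, identically.
Every datum is a single entry — e.g. the date of birth of one individual
— keyed by ``(entity_id, attribute)`` and carrying a version number that
only the hub ever assigns.  Local edits mark entries dirty; the sync
layer pushes dirty entries and clears the flag on acknowledgement.

Persistence is a single SQLite file (journal mode DELETE, so the file
can be copied or emailed as-is).  Deletion is soft only: a reserved
``_deleted`` boolean attribute that syncs like any other entry, so data
are never destroyed and deletions propagate between devices.
"""

from __future__ import annotations

import hashlib
import json
import sqlite3
from dataclasses import dataclass, field

from . import values as _values
from .errors import (
    EntityNotFoundError,
    EntryNotFoundError,
    InvalidAttributeError,
    UnknownEntityTypeError,
    ValueTypeError,
    VersionConflictError,
)

#: The documented entity-type enumeration.
ENTITY_TYPES = (
    "pack",
    "individual",
    "group-composition-session",
    "weight",
    "pregnancy",
    "mate-guard",
    "escort",
    "babysit",
    "gps-fix",
    "focal-follow",
    "focal-scan",
    "focal-interaction",
    "group-event",
    "note",
)

#: Reserved attribute holding the entity type (set once, immutable).
TYPE_ATTRIBUTE = "_type"
#: Reserved attribute implementing soft deletion.
DELETED_ATTRIBUTE = "_deleted"

_SCHEMA = """
CREATE TABLE IF NOT EXISTS meta (
    key   TEXT PRIMARY KEY,
    value TEXT NOT NULL
);
CREATE TABLE IF NOT EXISTS entities (
    id          TEXT PRIMARY KEY,
    entity_type TEXT NOT NULL,
    created_seq INTEGER NOT NULL
);
CREATE TABLE IF NOT EXISTS entries (
    entity_id    TEXT NOT NULL,
    attribute    TEXT NOT NULL,
    tag          TEXT NOT NULL,
    payload      TEXT NOT NULL,
    version      INTEGER NOT NULL,
    dirty        INTEGER NOT NULL,
    origin       TEXT NOT NULL,
    modified_seq INTEGER NOT NULL,
    PRIMARY KEY (entity_id, attribute)
);
"""


@dataclass(frozen=True)
class Entry:
    """One versioned datum: the unit of synchronisation."""

    entity_id: str
    attribute: str
    value: object
    tag: str
    version: int
    dirty: bool
    origin: str  # "local" or "remote"
    modified_seq: int


@dataclass
class Entity:
    """A materialised entity with all its entries (including ``_deleted``)."""

    id: str
    entity_type: str
    attributes: dict[str, Entry] = field(default_factory=dict)

    @property
    def deleted(self) -> bool:
        entry = self.attributes.get(DELETED_ATTRIBUTE)
        return bool(entry and entry.value is True)

    def get(self, attribute: str, default=None):
        entry = self.attributes.get(attribute)
        return entry.value if entry is not None else default


class EavStore:
    """A replica or hub database.

    Parameters
    ----------
    path:
        SQLite file path, or ``":memory:"`` for an ephemeral store.
    device_tag:
        Short unique tag for the device minting entity ids (e.g. ``"T1"``).
        Ids are ``<device-tag>-<per-device counter>``, so two devices with
        distinct tags can never mint the same id.  Required before
        :meth:`create_entity` is first called; a tag already persisted in
        the file wins over the argument.
    """

    def __init__(self, path: str = ":memory:", device_tag: str | None = None):
        self.path = path
        self._conn = sqlite3.connect(path, check_same_thread=False)
        self._conn.execute("PRAGMA journal_mode=DELETE")
        self._conn.executescript(_SCHEMA)
        stored = self._get_meta("device_tag")
        if stored is None and device_tag is not None:
            self._set_meta("device_tag", device_tag)
            stored = device_tag
        self.device_tag = stored
        self._conn.commit()

    # -- low-level helpers -------------------------------------------------

    def _get_meta(self, key: str) -> str | None:
        row = self._conn.execute(
            "SELECT value FROM meta WHERE key=?", (key,)
        ).fetchone()
        return row[0] if row else None

    def _set_meta(self, key: str, value: str) -> None:
        self._conn.execute(
            "INSERT INTO meta(key, value) VALUES(?,?) "
            "ON CONFLICT(key) DO UPDATE SET value=excluded.value",
            (key, value),
        )

    def _next_counter(self, key: str) -> int:
        n = int(self._get_meta(key) or "0") + 1
        self._set_meta(key, str(n))
        return n

    def _row_entry(self, row) -> Entry:
        eid, attr, tag, payload, version, dirty, origin, seq = row
        return Entry(eid, attr, _values.decode(tag, payload), tag,
                     version, bool(dirty), origin, seq)

    _ENTRY_COLS = ("entity_id, attribute, tag, payload, version, dirty, "
                   "origin, modified_seq")

    def _write_entry(self, entity_id: str, attribute: str, value,
                     *, version: int, dirty: bool, origin: str) -> Entry:
        tag, payload = _values.encode(value)
        seq = self._next_counter("modified_counter")
        self._conn.execute(
            "INSERT INTO entries(entity_id, attribute, tag, payload, version,"
            " dirty, origin, modified_seq) VALUES(?,?,?,?,?,?,?,?) "
            "ON CONFLICT(entity_id, attribute) DO UPDATE SET "
            "tag=excluded.tag, payload=excluded.payload, "
            "version=excluded.version, dirty=excluded.dirty, "
            "origin=excluded.origin, modified_seq=excluded.modified_seq",
            (entity_id, attribute, tag, payload, version,
             int(dirty), origin, seq),
        )
        self._conn.commit()
        return Entry(entity_id, attribute, value, tag, version,
                     dirty, origin, seq)

    def _entry_row(self, entity_id: str, attribute: str):
        return self._conn.execute(
            f"SELECT {self._ENTRY_COLS} FROM entries "
            "WHERE entity_id=? AND attribute=?",
            (entity_id, attribute),
        ).fetchone()

    def _require_entity(self, entity_id: str) -> str:
        row = self._conn.execute(
            "SELECT entity_type FROM entities WHERE id=?", (entity_id,)
        ).fetchone()
        if row is None:
            raise EntityNotFoundError(f"no such entity: {entity_id}")
        return row[0]

    # -- public API --------------------------------------------------------

    def create_entity(self, entity_type: str,
                      device_tag: str | None = None) -> str:
        """Mint a new entity id and record its (immutable) type.

        The type is itself stored as a dirty, version-0 entry so that new
        entities synchronise exactly like any other edit.
        """
        if entity_type not in ENTITY_TYPES:
            raise UnknownEntityTypeError(f"unknown entity type: {entity_type}")
        tag = device_tag or self.device_tag
        if not tag:
            raise ValueTypeError("store has no device tag; cannot mint ids")
        if self.device_tag is None:
            self._set_meta("device_tag", tag)
            self.device_tag = tag
        suffix = self._next_counter(f"id_counter:{tag}")
        entity_id = f"{tag}-{suffix}"
        seq = self._next_counter("entity_counter")
        self._conn.execute(
            "INSERT INTO entities(id, entity_type, created_seq) VALUES(?,?,?)",
            (entity_id, entity_type, seq),
        )
        self._write_entry(entity_id, TYPE_ATTRIBUTE, entity_type,
                          version=0, dirty=True, origin="local")
        return entity_id

    def set_value(self, entity_id: str, attribute: str, value) -> Entry:
        """Upsert one local datum; the entry becomes dirty (needs sync).

        Local edits never change the version number — versions are
        assigned by the hub on receipt (see the sync layer).
        """
        self._require_entity(entity_id)
        if not attribute:
            raise InvalidAttributeError("attribute name must be non-empty")
        if attribute == TYPE_ATTRIBUTE:
            raise InvalidAttributeError("entity type is immutable")
        row = self._entry_row(entity_id, attribute)
        version = row[4] if row else 0
        return self._write_entry(entity_id, attribute, value,
                                 version=version, dirty=True, origin="local")

    def get_entity(self, entity_id: str) -> Entity:
        """Return the entity with all entries; soft-deleted ones included."""
        entity_type = self._require_entity(entity_id)
        rows = self._conn.execute(
            f"SELECT {self._ENTRY_COLS} FROM entries WHERE entity_id=? "
            "ORDER BY attribute",
            (entity_id,),
        ).fetchall()
        ent = Entity(entity_id, entity_type)
        for row in rows:
            entry = self._row_entry(row)
            ent.attributes[entry.attribute] = entry
        return ent

    def query_entities(self, entity_type: str,
                       where: dict | None = None,
                       include_deleted: bool = False) -> list[Entity]:
        """All entities of a type whose attributes match ``where``.

        Order is stable and documented: entity creation sequence, so
        exports are reproducible.  Soft-deleted entities are excluded
        unless ``include_deleted`` is set.
        """
        if entity_type not in ENTITY_TYPES:
            raise UnknownEntityTypeError(f"unknown entity type: {entity_type}")
        rows = self._conn.execute(
            "SELECT id FROM entities WHERE entity_type=? ORDER BY created_seq",
            (entity_type,),
        ).fetchall()
        out = []
        for (eid,) in rows:
            ent = self.get_entity(eid)
            if ent.deleted and not include_deleted:
                continue
            if where and any(ent.get(k) != v for k, v in where.items()):
                continue
            out.append(ent)
        return out

    def dirty_entries(self) -> list[Entry]:
        """Entries awaiting sync, in modification order."""
        rows = self._conn.execute(
            f"SELECT {self._ENTRY_COLS} FROM entries WHERE dirty=1 "
            "ORDER BY modified_seq",
        ).fetchall()
        return [self._row_entry(r) for r in rows]

    def mark_synced(self, entity_id: str, attribute: str,
                    assigned_version: int) -> Entry:
        """Acknowledge a pushed entry: clear dirty, adopt the hub version."""
        row = self._entry_row(entity_id, attribute)
        if row is None:
            raise EntryNotFoundError(f"no entry {entity_id}/{attribute}")
        if not row[5]:
            raise EntryNotFoundError(
                f"entry {entity_id}/{attribute} is not dirty")
        if assigned_version < row[4]:
            raise VersionConflictError(
                f"version may not decrease: {row[4]} -> {assigned_version}")
        value = _values.decode(row[2], row[3])
        return self._write_entry(entity_id, attribute, value,
                                 version=assigned_version,
                                 dirty=False, origin=row[6])

    def apply_remote(self, entity_id: str, attribute: str, value,
                     version: int, entity_type: str | None = None) -> Entry | None:
        """Adopt a hub entry that is newer than the local copy.

        Returns ``None`` (a logged no-op, not an error) when the local
        version is already >= ``version``.  Unknown entities are
        materialised from ``entity_type``.
        """
        row = self._conn.execute(
            "SELECT entity_type FROM entities WHERE id=?", (entity_id,)
        ).fetchone()
        if row is None:
            if entity_type is None:
                raise EntityNotFoundError(
                    f"unknown entity {entity_id} and no type given")
            if entity_type not in ENTITY_TYPES:
                raise UnknownEntityTypeError(
                    f"unknown entity type: {entity_type}")
            seq = self._next_counter("entity_counter")
            self._conn.execute(
                "INSERT INTO entities(id, entity_type, created_seq) "
                "VALUES(?,?,?)",
                (entity_id, entity_type, seq),
            )
        erow = self._entry_row(entity_id, attribute)
        if erow is not None and version <= erow[4]:
            return None
        return self._write_entry(entity_id, attribute, value,
                                 version=version, dirty=False, origin="remote")

    def soft_delete_entity(self, entity_id: str) -> Entity:
        """Flag an entity deleted; its data stay fully readable forever.

        The flag is an ordinary dirty entry, so the deletion propagates
        through sync exactly like any edit.
        """
        self._require_entity(entity_id)
        row = self._entry_row(entity_id, DELETED_ATTRIBUTE)
        version = row[4] if row else 0
        self._write_entry(entity_id, DELETED_ATTRIBUTE, True,
                          version=version, dirty=True, origin="local")
        return self.get_entity(entity_id)

    def version_list(self) -> list[tuple[str, str, int]]:
        """One ``(entity_id, attribute, version)`` tuple per stored entry."""
        rows = self._conn.execute(
            "SELECT entity_id, attribute, version FROM entries "
            "ORDER BY entity_id, attribute",
        ).fetchall()
        return [tuple(r) for r in rows]

    def entity_type_of(self, entity_id: str) -> str:
        return self._require_entity(entity_id)

    def entity_exists(self, entity_id: str) -> bool:
        row = self._conn.execute(
            "SELECT 1 FROM entities WHERE id=?", (entity_id,)).fetchone()
        return row is not None

    # -- snapshots, dumps, hashing -----------------------------------------

    def schema_hash(self) -> str:
        """Hash of the SQLite structural schema (tables/indexes).

        New attribute names never change this — the point of the EAV
        layout is that the structure is fixed while the data vocabulary
        grows.
        """
        rows = self._conn.execute(
            "SELECT type, name, sql FROM sqlite_master ORDER BY type, name"
        ).fetchall()
        return hashlib.sha256(json.dumps(rows).encode()).hexdigest()

    def snapshot_bytes(self) -> bytes:
        """Byte-faithful copy of the single database file."""
        self._conn.commit()
        if self.path != ":memory:":
            with open(self.path, "rb") as fh:
                return fh.read()
        return bytes(self._conn.serialize())

    def dump_json(self) -> str:
        """Canonical JSON dump of the whole store, for diffing in tests."""
        out = {"device_tag": self.device_tag, "entities": {}}
        rows = self._conn.execute(
            "SELECT id, entity_type FROM entities ORDER BY created_seq"
        ).fetchall()
        for eid, etype in rows:
            ent = self.get_entity(eid)
            out["entities"][eid] = {
                "type": etype,
                "entries": {
                    a: {"tag": e.tag,
                        "payload": _values.encode(e.value)[1],
                        "version": e.version,
                        "dirty": e.dirty}
                    for a, e in sorted(ent.attributes.items())
                },
            }
        return json.dumps(out, sort_keys=True, indent=1)

    @classmethod
    def load_json(cls, text: str, path: str = ":memory:") -> "EavStore":
        """Rebuild a store from :meth:`dump_json` output."""
        data = json.loads(text)
        store = cls(path, device_tag=data.get("device_tag"))
        for eid, ent in data["entities"].items():
            seq = store._next_counter("entity_counter")
            store._conn.execute(
                "INSERT INTO entities(id, entity_type, created_seq) "
                "VALUES(?,?,?)", (eid, ent["type"], seq))
            for attr, e in ent["entries"].items():
                store._write_entry(
                    eid, attr, _values.decode(e["tag"], e["payload"]),
                    version=e["version"], dirty=e["dirty"],
                    origin="local" if e["dirty"] else "remote")
        store._conn.commit()
        return store

    def state_set(self) -> set[tuple[str, str, str, str, int]]:
        """The ``(entity, attribute, tag, payload, version)`` set.

        Two stores that have fully converged have equal state sets.
        """
        rows = self._conn.execute(
            "SELECT entity_id, attribute, tag, payload, version FROM entries"
        ).fetchall()
        return {tuple(r) for r in rows}

    def entry_count(self, include_deleted: bool = True) -> int:
        return self._conn.execute("SELECT COUNT(*) FROM entries").fetchone()[0]

    def close(self) -> None:
        self._conn.commit()
        self._conn.close()

    # context manager convenience
    def __enter__(self) -> "EavStore":
        return self

    def __exit__(self, *exc) -> None:
        self.close()
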