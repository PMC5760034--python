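"""Two-way replica/hub reconciliation.

The protocol mirrors the original field deployment: many devices hold
full copies of the data and reconcile against a single hub whenever they
are in range.  A sync has two phases, always initiated by the replica:

1. *Push*: every dirty entry is sent one at a time; the hub overwrites
   its copy unconditionally, bumps that entry's version (first receipt
   is version 1) and returns an ack carrying the assigned version.  The
   replica marks the entry clean only on ack, so a transfer killed
   mid-push can simply be retried — already-acked entries stay clean,
   unacked ones stay dirty.
2. *Pull*: the replica sends its full version list; the hub answers with
   every entry it holds at a strictly greater version (entries absent
   from the list count as version 0, which is how entities created on
   other devices propagate).

Conflicts are resolved by hub arrival order — the last device to sync
wins — and device clocks are never consulted.
"""

from __future__ import annotations

import os
import threading
from dataclasses import dataclass

from .errors import MalformedMessageError, TransportError
from .store import ENTITY_TYPES, EavStore
from . import values as _values


@dataclass(frozen=True)
class Ack:
    """Hub acknowledgement of one pushed entry."""

    entity_id: str
    attribute: str
    assigned_version: int


@dataclass
class SyncReport:
    """Counts from one full sync: entries pushed, acked and pulled."""

    pushed: int = 0
    acked: int = 0
    pulled: int = 0


# ---------------------------------------------------------------------------
# Hub-side operations (used directly by in-process transports and by the
# HTTP server).


def server_receive_entry(hub: EavStore, entity_id: str, entity_type: str,
                         attribute: str, tag: str, payload: str) -> Ack:
    """Accept one pushed entry: last writer wins, version increments.

    The hub accepts unknown entities and attribute names it has never
    seen — no structural change is ever needed.  Malformed messages are
    rejected before any state change and produce no ack.
    """
    if not entity_id or not attribute:
        raise MalformedMessageError("entity_id and attribute are required")
    if entity_type not in ENTITY_TYPES:
        raise MalformedMessageError(f"unknown entity type: {entity_type}")
    if tag not in _values.TAGS:
        raise MalformedMessageError(f"unknown value tag: {tag}")
    try:
        value = _values.decode(tag, payload)
    except Exception as exc:  # noqa: BLE001 - any decode failure is malformed
        raise MalformedMessageError(f"undecodable payload: {exc}") from exc
    row = hub._entry_row(entity_id, attribute)
    new_version = (row[4] if row else 0) + 1
    if not hub.entity_exists(entity_id):
        seq = hub._next_counter("entity_counter")
        hub._conn.execute(
            "INSERT INTO entities(id, entity_type, created_seq) VALUES(?,?,?)",
            (entity_id, entity_type, seq))
    hub._write_entry(entity_id, attribute, value,
                     version=new_version, dirty=False, origin="remote")
    return Ack(entity_id, attribute, new_version)


def server_diff(hub: EavStore,
                versions: list[tuple[str, str, int]]) -> list[tuple]:
    """Entries newer than the reported versions.

    Returns ``(entity_id, entity_type, attribute, tag, payload, version)``
    tuples; an entry the requester did not report is treated as reported
    at version 0.  Never returns an entry at an equal version.
    """
    reported = {(e, a): v for e, a, v in versions}
    out = []
    rows = hub._conn.execute(
        "SELECT en.entity_id, et.entity_type, en.attribute, en.tag,"
        " en.payload, en.version FROM entries en"
        " JOIN entities et ON et.id = en.entity_id"
        " ORDER BY et.created_seq, en.attribute").fetchall()
    for eid, etype, attr, tag, payload, version in rows:
        if version > reported.get((eid, attr), 0):
            out.append((eid, etype, attr, tag, payload, version))
    return out


# ---------------------------------------------------------------------------
# Transports


class Transport:
    """Abstract replica-side view of the hub.

    Implementations must serialize entry updates; the protocol layer is
    transport-agnostic so tests can run fully in-process.
    """

    def push_entry(self, entity_id: str, entity_type: str, attribute: str,
                   tag: str, payload: str) -> Ack:
        raise NotImplementedError

    def diff(self, versions: list[tuple[str, str, int]]) -> list[tuple]:
        raise NotImplementedError

    def snapshot(self) -> bytes:
        raise NotImplementedError

    def ping(self) -> bool:
        raise NotImplementedError


class InProcessTransport(Transport):
    """Directly wired to a hub store; used by tests and simulations."""

    def __init__(self, hub: EavStore, lock: threading.Lock | None = None):
        self.hub = hub
        self._lock = lock or threading.Lock()

    def push_entry(self, entity_id, entity_type, attribute, tag, payload):
        with self._lock:
            return server_receive_entry(
                self.hub, entity_id, entity_type, attribute, tag, payload)

    def diff(self, versions):
        with self._lock:
            return server_diff(self.hub, versions)

    def snapshot(self) -> bytes:
        with self._lock:
            return self.hub.snapshot_bytes()

    def ping(self) -> bool:
        return True


class FlakyTransport(Transport):
    """Wrapper that fails after a fixed number of pushes.

    Exercises crash-retry safety: entries acked before the failure stay
    clean, the rest stay dirty, and a retry converges to the same state
    as an uninterrupted sync.
    """

    def __init__(self, inner: Transport, fail_after_pushes: int):
        self.inner = inner
        self.remaining = fail_after_pushes

    def push_entry(self, *args):
        if self.remaining <= 0:
            raise TransportError("simulated transport failure")
        self.remaining -= 1
        return self.inner.push_entry(*args)

    def diff(self, versions):
        if self.remaining <= 0:
            raise TransportError("simulated transport failure")
        return self.inner.diff(versions)

    def snapshot(self):
        return self.inner.snapshot()

    def ping(self):
        return self.remaining > 0


# ---------------------------------------------------------------------------
# Replica-side sync driver


def full_sync(replica: EavStore, transport: Transport) -> SyncReport:
    """Push all dirty entries, then pull everything newer from the hub.

    Safe against interruption at any point: pushes are per-entry with
    per-entry acks, and diff application is atomic per entry.
    """
    report = SyncReport()
    for entry in replica.dirty_entries():
        etype = replica.entity_type_of(entry.entity_id)
        tag, payload = _values.encode(entry.value)
        report.pushed += 1
        ack = transport.push_entry(
            entry.entity_id, etype, entry.attribute, tag, payload)
        replica.mark_synced(entry.entity_id, entry.attribute,
                            ack.assigned_version)
        report.acked += 1
    diff = transport.diff(replica.version_list())
    for eid, etype, attr, tag, payload, version in diff:
        applied = replica.apply_remote(
            eid, attr, _values.decode(tag, payload), version,
            entity_type=etype)
        if applied is not None:
            report.pulled += 1
    return report


def download_snapshot(transport: Transport, destination_path: str) -> str:
    """Write a byte-faithful copy of the hub database to ``destination_path``.

    A partial transfer removes the destination and raises, never leaving
    a truncated file behind.
    """
    tmp = destination_path + ".part"
    try:
        data = transport.snapshot()
        with open(tmp, "wb") as fh:
            fh.write(data)
        os.replace(tmp, destination_path)
    except Exception as exc:
        for p in (tmp, destination_path):
            if os.path.exists(p):
                os.remove(p)
        raise TransportError(f"snapshot download failed: {exc}") from exc
    return destination_path
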