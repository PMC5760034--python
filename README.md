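# fieldsync

Offline-first data collection, synchronisation and export for long-term
individual-based field studies.

Long-running behavioural-ecology projects — the motivating case is a
banded-mongoose study following ~250 known individuals in 10–12 social
groups for decades — collect structured observations every day with no
internet: presence/absence on each group visit, weekly weights in grams,
reproductive statuses (pregnancy, mate-guarding, pup escorting,
babysitting), 20-minute focal-animal follows with per-minute neighbour
scans, group-level events, and an automatic GPS track. Several
fieldworkers record simultaneously on separate devices and must end each
day with one consistent central database, without ever losing or
silently overwriting a record.

`fieldsync` is a Python toolkit for exactly that workflow: each device
holds a full local replica; replicas reconcile with a single hub over a
two-way versioned sync protocol; data are soft-deleted only; and a typed
CSV exporter turns any replica, hub or snapshot into analysis-ready
tables. A seeded synthetic-season generator stands in for real field
data, so everything is testable end to end.

## The core model

**Storage** is entity–attribute–value (EAV): every datum is a triple
*(entity, attribute, value)* — e.g. the date of birth of one mongoose is
one entry — carried in a single SQLite file per device. Because values
are self-describing (text / integer / real / boolean / timestamp /
null), new attributes and whole new observation categories appear with
no schema migration on the hub.

**Synchronisation** is two-phase and always replica-initiated. For an
entry *e* with hub version *v(e)*:

1. *Push*: the replica sends each dirty (locally edited) entry and waits
   for a per-entry acknowledgement; on receipt the hub overwrites its
   copy unconditionally and assigns *v(e) ← v(e) + 1* (first receipt
   gives *v = 1*). The replica marks the entry clean only on ack, so an
   interrupted transfer is simply retried.
2. *Pull*: the replica sends its full version list
   {(entity, attribute, v)}; the hub returns every entry it holds at a
   strictly greater version (entries absent from the list count as
   *v = 0*), which the replica applies atomically per entry.

Conflicts resolve by hub arrival order — *the last device to sync wins*
— and device clocks are never consulted. Deletion is a reserved
`_deleted` attribute that syncs like any edit, so nothing is ever
destroyed and deletions still propagate.

**Protocol gating** keeps bad records out at entry time: presence on the
first screen of a visit controls what later screens accept; pregnancy
records require a female strictly older than 10 months (age in months =
days / 30.4375); mate-guards need a present male and a present female;
focal follows are a 1200 s countdown that pauses without losing scan
slots; GPS fixes are taken at visit start and every 180 s of session
clock.

## Worked example

`examples/02_sync_devices.py` (two tablets and an HTTP hub on
localhost) prints:

```
A first sync: pushed 2, pulled 0
B first sync: pushed 0, pulled 2
hub holds: "B's version"
A holds: "B's version"
B holds: "B's version"
repeat sync: pushed 0, pulled 0
snapshot holds 2 entries, identical to hub: True
```

Tablet A creates a note (its type entry plus one body entry: 2 pushes);
B pulls both. Both tablets then edit the same entry offline; B syncs
after A, so after one more round every store — hub included — holds B's
value: last-writer-wins. The immediate repeat sync moves nothing
(idempotence), and the downloaded snapshot is a byte-faithful copy of
the hub's single database file, usable as a backup replica.

The other examples cover a full field day (gating, GPS cadence, paused
focal follow, review-and-edit) and a synthetic season (population
generation, the 720-weight weighing fixture with 18 injected
single-digit typos recovered exactly by the feasibility screen, CSV
export). Run them with `python examples/01_field_day.py` etc.

A thin CLI mirrors the field workflow: `fieldsync serve`, `fieldsync
sync`, `fieldsync download`, `fieldsync export`, `fieldsync simulate
population|season|scenario`, `fieldsync observe --script events.json`,
`fieldsync packs …`, `fieldsync review`.

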