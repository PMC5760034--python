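# Methods

This note documents the data model, the synchronisation semantics, the
observation-protocol rules and the synthetic-data generator in enough
detail to reason about what the tests do and do not demonstrate.

## Storage model

Each device (replica) and the hub hold the same store: a single SQLite
file with two data tables, `entities(id, entity_type, created_seq)` and
`entries(entity_id, attribute, tag, payload, version, dirty, origin,
modified_seq)`. The journal mode is DELETE so the file is always
self-contained and can be copied, emailed or downloaded as-is.

- **Entity ids** are `<device-tag>-<per-device counter>`. Two devices
  with distinct tags cannot mint the same id, so id collisions are
  impossible by construction rather than improbable.
- **Values** carry a type tag (`text`, `integer`, `real`, `boolean`,
  `timestamp`, `null`). Timestamps must be timezone-aware and are stored
  as ISO 8601 with offset; naive datetimes are rejected because field
  device clocks are unreliable and ambiguous local times are worse than
  an error. Floats are stored as `repr` so they round-trip exactly.
- **Versions are hub-assigned.** A local edit marks an entry dirty but
  never changes its version; the version changes only when the hub acks
  a push or when a newer hub entry is applied. First receipt at the hub
  is version 1; a replica-local entry that has never synced is version
  0. Versions never decrease anywhere, which is asserted, not assumed.
- **Soft deletion** is the reserved boolean attribute `_deleted`,
  written dirty like any edit. Data are never destroyed; deleted
  entities are merely excluded from default queries and flagged in
  exports. The entity type is likewise the reserved entry `_type`, so a
  newly created entity synchronises with no special machinery.
- Query order is (entity creation sequence) with attributes sorted by
  name — documented so exports are reproducible byte for byte.

## Synchronisation semantics

Sync is replica-initiated and two-phase: push all dirty entries with
per-entry acks, then send the full version list and apply the hub's
diff. Design choices that were genuinely open:

- **Conflict policy** is hub arrival order (last device to sync wins).
  Device timestamps are never consulted — ordering by unreliable clocks
  would make the winner depend on battery-backed hardware state.
- **Diff contents**: the hub returns entries *strictly* newer than
  reported, and treats entries absent from the report as reported at
  version 0. The second rule is what lets entities created on one
  device reach all others.
- **Crash safety** comes from per-entry granularity: entries acked
  before an interruption are clean, the rest stay dirty, and a retry is
  indistinguishable from a first attempt. There is no transactional
  session state on the hub to repair.
- **Re-pushing the same entry twice in one session** (e.g. edit, sync,
  edit, sync) bumps the hub version twice. Each push is an independent
  update; no dedup window is applied.
- The transport is an interface; tests run in-process, the CLI uses
  HTTP + JSON on a trusted local network (no authentication, matching
  the isolated-field-network deployment). The HTTP hub serializes entry
  updates under one lock, so interleaved clients apply in a well-defined
  arrival order and every pulled entry is internally consistent.
- The hub never pushes; a fully synced replica therefore contains every
  hub entry and can serve as a backup.

## Observation-protocol rules

Parameters live in `ProtocolConfig`; defaults and rationale:

| parameter | default | why |
| --- | --- | --- |
| `month_days` | 30.4375 | 365.25 / 12; age thresholds are quoted in months but data carry day-resolution dates |
| `adult_female_min_months` | 10.0, strict `>` | pregnancy eligibility; a female at exactly 10.0 months is rejected |
| `pup_age_max_days` | 90 | dependent-pup bound for escorting and pup focals; the den period covers roughly the first month and escorting follows once pups travel with the group, so 90 d is a deliberate, configurable cut-off |
| `gps_interval_s` | 180 | fix at visit start, then every 180 s of session clock (fix-at-start convention; a 20-min visit gives 7 fixes, a zero-length visit gives 1) |
| `focal_duration_s` | 1200 | the focal countdown; only *active* time counts, pauses shift completion by exactly the paused time |
| `score_range` | 1–4 | ordinal strength/accuracy scores; the scale is a configurable enumeration |
| `weight_bounds` | off | optional entry-time feasibility screen; the retrospective screen (`screen_weights`) is separate and always available |

Other behavioural decisions:

- A session's presence map is the gate for all later records: weights,
  mate-guards and escorts require `present is True`; an *inferred*
  babysit requires `present is False` (it is inferred precisely from
  absence); an *observed* babysit requires presence.
- A scan's nearest neighbour is auto-included in the within-2 m set
  rather than rejected when omitted — less friction at the entry point,
  same invariant.
- A completed follow always has exactly 20 scan slots: a minute whose
  prompt was missed is stored as an explicit empty scan (`empty=true`),
  never a silent gap, so "no data" and "nobody within 2 m" remain
  distinguishable.
- Each skipped screen stores an explicit `skip:<kind>` marker so "not
  applicable" differs from "not recorded".
- `end_visit` accepts a zero-length visit (start == end, one GPS fix);
  only end-before-start is an error.
- Review-mode edits rewrite the underlying entry, which re-dirties it;
  an edit is validated with the same gating as original entry.
- Clocks are injectable (`SimulatedClock` in tests and generators, wall
  clock in the CLI), so all timing behaviour is deterministic under
  test.

## CSV export

One file per record type with a fixed, documented column order
(`fieldsync.export.SCHEMAS`): the entity id, the type's attributes in
schema order, a human-readable `*-name` column after each individual or
pack reference, an `extra` column holding any out-of-schema attributes
as canonical JSON with their type tags, and a `deleted` column when
soft-deleted rows are requested. Cells are the canonical text payloads
of the typed values, so export → parse reproduces every stored value
exactly, and two exports of one store are byte-identical (UTF-8, `\n`,
RFC 4180 quoting; note free-text is fully quoted).

## Synthetic generator

The generator emulates the study conditions, not mongoose biology:

- **Population**: 11 packs of 10–30 individuals (uniform), sex ratio
  0.5, ages uniform over 0–8 years at the census date (2015-03-01).
  These defaults reproduce the documented study scale (~250 individuals
  in 10–12 groups).
- **Visits**: presence Bernoulli(0.95) per individual; weights only on
  weekly weighing days; pregnancy recorded for eligible females with
  p = 0.10; occasional mate-guards, escorts (only when dependent pups
  are present) and inferred babysits; a random-walk GPS source around
  the site coordinates; default duration 20 min.
- **Weights**: integer grams from a normal(1500, 250) truncated to
  ±3 sd, scaled by age class (×0.25 under 90 d, ×0.7 under 1 yr, ×1
  adult), with the truncation and feasibility bounds scaled alike.
  These distributions are invented defaults — no empirical weight
  distribution is claimed.
- **Typo injection** replaces one digit of a stored weight (the classic
  1234 → 1334 slip), in place, returning the ground-truth list. When
  feasibility bounds are supplied the substitution is chosen to land
  outside them, so the canonical fixture — one pack of 24 adults, 30
  weekly weighings, 720 records, 18 typos — is recovered by the screen
  with recall 1.0 *by construction*. That fixture validates the
  screening plumbing at the documented scale; it says nothing about the
  real-world detectability of entry errors, where a typo can land
  inside the feasible range.
- **Scenarios**: a script of `(logical_time, device, op, args)` replayed
  over in-process transports, logging every hub arrival. The
  convergence oracle replays that push log through a plain-dict state
  machine, independent of the store and protocol code. Random scenarios
  use globally unique values so last-writer-wins outcomes are
  unambiguous, and end with two full sync rounds per replica in random
  order.
- **Determinism**: every generator draws from its own RNG stream,
  derived from the master seed via a labelled `SeedSequence`
  (CRC-32 of the label), so adding one generator never perturbs
  another; all arithmetic on days and grams is integer.

Because the generator uses only the public protocol APIs, everything it
produces satisfies the gating rules; the gating fuzz tests therefore
demonstrate that the gates *hold* under heavy valid-and-boundary load
and that direct violations raise, not that the generator can smuggle
invalid data past them.

## Problem sizes and limitations

The default verification workloads are: 3 replicas × 200 edits for
convergence, 500 fuzz cases for version monotonicity, 50 crash-retry
trials, 400–1000 fuzzed sessions for gating, and the 720-record
screening fixture — sizes chosen to exercise every code path at the
study's real scale while keeping a full verification run near a minute.

Known limitations: no authentication or encryption on the wire (trusted
local network assumed); no hard-delete API at all, by design; no
retrospective life-history inference (e.g. inferring deaths from
absences); no demographic dynamics in the generator; conflict
resolution is whole-entry last-writer-wins, with no field-level merge —
acceptable because an entry is a single datum and conflicts are rare.
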