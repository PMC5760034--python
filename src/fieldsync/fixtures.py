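"""Seeded synthetic field seasons.

No external data ship with this package: everything the other modules
need for testing — a study population, group visits, focal follows,
entry errors, and multi-device edit/sync scenarios — is generated here,
deterministically from a seed, through the public protocol APIs (never
raw store writes, so generated data always satisfy the gating rules).

The population defaults emulate the study system the toolkit was built
for: ~250 individuals in 11 social groups of 10–30, groups visited
every 1–3 days, weekly weighing visits, and 20-minute focal follows.
Visit-level rates (presence probability, interaction rate, weight
distributions) are invented defaults, documented in the methods note;
the fixtures exercise the software, they do not model mongooses.

Randomness discipline: one RNG stream per generator, derived from the
master seed by a labelled substream, so adding a generator never
perturbs the draws of another.
"""

from __future__ import annotations

import datetime as _dt
import zlib
from dataclasses import dataclass, field

import numpy as np

from . import protocols as fp
from .clock import SimulatedClock
from .errors import ScenarioError
from .store import EavStore
from .sync import InProcessTransport, Transport, full_sync

#: Field-site timezone (UTC+3).
TZ = _dt.timezone(_dt.timedelta(hours=3))
#: Anchor date for generated seasons (field-test period).
BASE_DATE = _dt.date(2015, 3, 1)

#: Adult weight model: normal(1500, 250) grams, truncated to +-3 sd;
#: younger age classes are scaled down.
WEIGHT_MEAN = 1500
WEIGHT_SD = 250
WEIGHT_FLOOR = 300
AGE_CLASS_SCALES = ((90, 0.25), (365, 0.7), (None, 1.0))  # (< days, scale)


def substream(seed: int, label: str) -> np.random.Generator:
    """Independent RNG stream for one generator, from the master seed."""
    return np.random.default_rng(
        np.random.SeedSequence([int(seed) & 0x7FFFFFFF,
                                zlib.crc32(label.encode())]))


@dataclass
class PopulationSpec:
    """Study-population shape: 11 groups of 10–30, even sex ratio,
    ages uniform over 0–8 years."""

    n_packs: int = 11
    pack_size_range: tuple[int, int] = (10, 30)
    sex_ratio: float = 0.5
    max_age_years: float = 8.0
    min_age_days: int = 0
    census_date: _dt.date = BASE_DATE
    seed: int = 0


_PACK_LETTERS = "HBKFGDELMNPQRSTV"


def simulate_population(spec: PopulationSpec,
                        store: EavStore | None = None,
                        device_tag: str = "SIM") -> EavStore:
    """Build a deterministic roster of packs and individuals."""
    if spec.n_packs <= 0:
        raise ScenarioError("population needs at least one pack")
    lo, hi = spec.pack_size_range
    if lo <= 0 or hi < lo:
        raise ScenarioError(f"bad pack size range: {spec.pack_size_range}")
    if not (0.0 <= spec.sex_ratio <= 1.0):
        raise ScenarioError(f"sex ratio outside [0, 1]: {spec.sex_ratio}")
    rng = substream(spec.seed, "population")
    store = store or EavStore(device_tag=device_tag)
    counter = 0
    max_days = int(spec.max_age_years * 365.25)
    for i in range(spec.n_packs):
        name = f"{i + 1}{_PACK_LETTERS[i % len(_PACK_LETTERS)]}"
        pack = fp.add_pack(store, name)
        size = int(rng.integers(lo, hi + 1))
        for _ in range(size):
            counter += 1
            sex = "F" if rng.random() < spec.sex_ratio else "M"
            age_days = int(rng.integers(spec.min_age_days, max_days + 1))
            dob = spec.census_date - _dt.timedelta(days=age_days)
            fp.add_individual(store, pack.id, f"BM{counter:03d}", sex, dob,
                              today=spec.census_date)
    return store


def _age_scale(age_days: int) -> float:
    for limit, scale in AGE_CLASS_SCALES:
        if limit is None or age_days < limit:
            return scale
    return 1.0


def weight_bounds(age_days: int) -> tuple[int, int]:
    """Feasible grams range for an age class (mean +- 3 sd, floored)."""
    s = _age_scale(age_days)
    lo = max(int(WEIGHT_FLOOR * s), int((WEIGHT_MEAN - 3 * WEIGHT_SD) * s))
    return lo, int((WEIGHT_MEAN + 3 * WEIGHT_SD) * s)


def draw_weight(rng: np.random.Generator, age_days: int) -> int:
    """Integer grams from the truncated, age-scaled normal model."""
    s = _age_scale(age_days)
    lo, hi = weight_bounds(age_days)
    while True:
        g = int(round(rng.normal(WEIGHT_MEAN * s, WEIGHT_SD * s)))
        if lo <= g <= hi:
            return g


def make_gps_source(rng: np.random.Generator,
                    center: tuple[float, float] = (-0.1917, 29.9000),
                    step_deg: float = 0.0005):
    """A random-walk GPS source around the study site centre."""
    pos = list(center)

    def source(elapsed_s: int) -> tuple[float, float]:
        pos[0] += float(rng.normal(0, step_deg))
        pos[1] += float(rng.normal(0, step_deg))
        return (max(-90.0, min(90.0, pos[0])),
                max(-180.0, min(180.0, pos[1])))

    return source


def simulate_visit(store: EavStore, pack_id: str, visit_date: _dt.date,
                   seed: int = 0, presence_p: float = 0.95,
                   weighing_day: bool | None = None,
                   duration_s: int = 1200,
                   config: fp.ProtocolConfig = fp.DEFAULT_CONFIG,
                   ) -> fp.GroupCompositionSession:
    """One group-composition visit with realistic record mix.

    Presence is drawn per individual (default P=0.95); weights are taken
    only on weekly weighing days (default: Mondays); pregnancies only
    ever reference eligible adult females; a visit of at least 20
    minutes logs at least 7 GPS fixes.
    """
    rng = substream(seed, f"visit:{pack_id}:{visit_date.isoformat()}")
    if weighing_day is None:
        weighing_day = visit_date.isoweekday() == 1
    start = _dt.datetime.combine(visit_date, _dt.time(8, 0), tzinfo=TZ)
    session = fp.start_visit(store, pack_id, start,
                             gps_source=make_gps_source(rng), config=config)
    roster = fp.pack_roster(store, pack_id)
    present, absent = [], []
    for ind in roster:
        here = bool(rng.random() < presence_p)
        session.record_presence(ind.id, here)
        (present if here else absent).append(ind)

    if weighing_day:
        for ind in present:
            grams = draw_weight(rng, fp.age_days(fp.date_of_birth(ind),
                                                 visit_date))
            session.record_weight(ind.id, grams, "morning")
    for ind in present:
        if (fp.eligible_for_pregnancy(ind, visit_date, config)
                and rng.random() < 0.10):
            session.record_pregnancy(ind.id)
    males = [i for i in present if i.get("sex") == "M"]
    females = [i for i in present
               if fp.eligible_for_pregnancy(i, visit_date, config)]
    if males and females and rng.random() < 0.2:
        session.record_mate_guard(
            males[int(rng.integers(len(males)))].id,
            females[int(rng.integers(len(females)))].id,
            int(rng.integers(1, 5)), int(rng.integers(1, 5)),
            bool(rng.random() < 0.5))
    pups = [i for i in present if fp.is_pup(i, visit_date, config)]
    adults = [i for i in present if not fp.is_pup(i, visit_date, config)]
    for pup in pups:
        if adults and rng.random() < 0.5:
            session.record_escort(
                pup.id, adults[int(rng.integers(len(adults)))].id,
                int(rng.integers(1, 5)), int(rng.integers(1, 5)))
    if absent and rng.random() < 0.3:
        session.record_babysit(
            absent[int(rng.integers(len(absent)))].id, "inferred")
    session.end_visit(start + _dt.timedelta(seconds=duration_s))
    return session


def simulate_focal(store: EavStore, protocol: str, focal_id: str,
                   seed: int = 0, interaction_mean: float = 3.0,
                   pause: tuple[int, int] | None = None,
                   start: _dt.datetime | None = None,
                   config: fp.ProtocolConfig = fp.DEFAULT_CONFIG,
                   ) -> fp.FocalFollow:
    """A completed focal follow: 20 scans of packmates, Poisson-drawn
    interactions (mean 3 per follow), and an optional injected pause
    ``(at_minute, pause_seconds)``."""
    rng = substream(seed, f"focal:{focal_id}")
    focal = store.get_entity(focal_id)
    start = start or _dt.datetime.combine(BASE_DATE, _dt.time(9, 0), tzinfo=TZ)
    clock = SimulatedClock(start)
    follow = fp.start_focal(store, protocol, focal_id, clock, config)
    mates = [i for i in fp.pack_roster(store, focal.get("pack"))
             if i.id != focal_id]
    n_inter = int(rng.poisson(interaction_mean))
    inter_minutes = set(
        int(m) for m in rng.integers(1, 21, size=n_inter)) if n_inter else set()
    minutes = config.focal_duration_s // 60
    for minute in range(1, minutes + 1):
        if pause and pause[0] == minute:
            follow.pause()
            clock.advance(pause[1])
            follow.resume()
        clock.advance(60)
        if mates:
            nearest = mates[int(rng.integers(len(mates)))]
            k = int(rng.integers(0, min(3, len(mates)) + 1))
            within = [mates[int(j)].id
                      for j in rng.choice(len(mates), size=k, replace=False)]
            follow.record_scan(minute, nearest.id, tuple(within))
        else:
            follow.record_scan(minute, fp.NONE_VISIBLE)
        if minute in inter_minutes and mates:
            partner = mates[int(rng.integers(len(mates)))]
            kind = "agonistic" if rng.random() < 0.5 else "affiliative"
            follow.record_interaction(
                kind, partner.id,
                "focal" if rng.random() < 0.5 else "partner",
                "attack" if kind == "agonistic" else "groom",
                "food" if rng.random() < 0.5 else "social-partner",
                "focal" if kind == "agonistic" else "none")
    follow.complete()
    return follow


# ---------------------------------------------------------------------------
# Entry-error injection


def inject_typos(store: EavStore, n_errors: int | None = None,
                 rate: float | None = None, seed: int = 0,
                 bounds: tuple[int, int] | None = None,
                 ) -> list[tuple[str, int, int]]:
    """Corrupt stored weight records with single-digit substitutions.

    Emulates the classic field typo (1234 g entered as 1334 g).  When
    ``bounds`` is given, each substitution is chosen so the corrupted
    value falls *outside* the feasible range, so a feasibility screen at
    those bounds recovers the corrupted set exactly.  Returns the ground
    truth as ``(weight_entity_id, original, corrupted)`` tuples.
    """
    weights = store.query_entities("weight")
    if rate is not None:
        if not (0.0 <= rate <= 1.0):
            raise ScenarioError(f"typo rate outside [0, 1]: {rate}")
        n_errors = int(round(rate * len(weights)))
    if n_errors is None:
        raise ScenarioError("give n_errors or rate")
    if n_errors > len(weights):
        raise ScenarioError(
            f"cannot corrupt {n_errors} of {len(weights)} records")
    rng = substream(seed, "typos")
    chosen = rng.choice(len(weights), size=n_errors, replace=False)
    truth = []
    for idx in sorted(int(i) for i in chosen):
        rec = weights[idx]
        original = rec.get("grams")
        corrupted = _typo(rng, original, bounds)
        fp.edit_record(store, rec.id, "grams", corrupted)
        truth.append((rec.id, original, corrupted))
    return truth


def _typo(rng: np.random.Generator, value: int,
          bounds: tuple[int, int] | None) -> int:
    """A single-digit substitution of ``value``; if bounds are given the
    result is guaranteed to fall outside them."""
    digits = str(value)
    candidates = []
    for pos in range(len(digits)):
        for d in "0123456789":
            if d == digits[pos]:
                continue
            new = int(digits[:pos] + d + digits[pos:][1:])
            if new <= 0 or new == value:
                continue
            if bounds is not None and bounds[0] <= new <= bounds[1]:
                continue
            candidates.append(new)
    if not candidates:
        raise ScenarioError(f"no valid typo for {value} outside {bounds}")
    return candidates[int(rng.integers(len(candidates)))]


def canonical_weight_fixture(seed: int = 0,
                             ) -> tuple[EavStore, list[tuple[str, int, int]],
                                        tuple[int, int]]:
    """The 720-weight / 18-typo screening fixture.

    One pack of 24 adults weighed on 30 weekly visits (presence forced
    to 1) gives exactly 720 weight records; 18 are then corrupted with
    out-of-bounds single-digit typos.  Returns ``(store, ground_truth,
    bounds)`` where screening at ``bounds`` flags exactly the corrupted
    records.
    """
    spec = PopulationSpec(n_packs=1, pack_size_range=(24, 24),
                          min_age_days=366, seed=seed)
    store = simulate_population(spec)
    pack = store.query_entities("pack")[0]
    bounds = weight_bounds(366)  # all members are adults
    for week in range(30):
        visit_date = spec.census_date + _dt.timedelta(weeks=week)
        simulate_visit(store, pack.id, visit_date, seed=seed,
                       presence_p=1.0, weighing_day=True)
    truth = inject_typos(store, n_errors=18, seed=seed, bounds=bounds)
    return store, truth, bounds


# ---------------------------------------------------------------------------
# Multi-device scenarios


@dataclass
class ScenarioScript:
    """A replayable multi-device schedule.

    ``ops`` is a list of ``(logical_time, device_index, op, args)`` with
    strictly ordered logical times.  Ops: ``("create", alias,
    entity_type)``, ``("set", alias, attribute, value)``, ``("delete",
    alias)``, ``("sync",)``.  Aliases name entities across devices; a
    device may only touch an alias it has created or pulled via sync.
    """

    n_devices: int
    ops: list[tuple] = field(default_factory=list)
    seed: int = 0

    def validate(self) -> None:
        if self.n_devices <= 0:
            raise ScenarioError("scenario needs at least one device")
        last_t = None
        for item in self.ops:
            if len(item) != 4:
                raise ScenarioError(f"malformed op record: {item!r}")
            t, dev, op, args = item
            if last_t is not None and t < last_t:
                raise ScenarioError("logical times must be non-decreasing")
            last_t = t
            if not (0 <= dev < self.n_devices):
                raise ScenarioError(f"device index out of range: {dev}")
            if op not in ("create", "set", "delete", "sync"):
                raise ScenarioError(f"unknown op: {op!r}")


@dataclass
class ScenarioResult:
    replicas: list[EavStore]
    hub: EavStore
    #: Arrival-order event log: ("push", device, entity_id, attribute,
    #: tag, payload, assigned_version) plus the executed script ops.
    log: list[tuple]


class _LoggingTransport(Transport):
    def __init__(self, inner: Transport, device: int, log: list):
        self.inner, self.device, self.log = inner, device, log

    def push_entry(self, entity_id, entity_type, attribute, tag, payload):
        ack = self.inner.push_entry(entity_id, entity_type, attribute,
                                    tag, payload)
        self.log.append(("push", self.device, entity_id, attribute,
                         tag, payload, ack.assigned_version))
        return ack

    def diff(self, versions):
        return self.inner.diff(versions)

    def snapshot(self):
        return self.inner.snapshot()

    def ping(self):
        return self.inner.ping()


def run_scenario(script: ScenarioScript) -> ScenarioResult:
    """Execute a scenario in logical-time order over an in-process hub."""
    script.validate()
    hub = EavStore(device_tag="HUB")
    replicas = [EavStore(device_tag=f"T{i + 1}")
                for i in range(script.n_devices)]
    base = InProcessTransport(hub)
    log: list[tuple] = []
    aliases: dict[str, str] = {}  # alias -> entity id
    for t, dev, op, args in script.ops:
        store = replicas[dev]
        if op == "create":
            alias, etype = args
            if alias in aliases:
                raise ScenarioError(f"alias {alias!r} already created")
            aliases[alias] = store.create_entity(etype)
        elif op == "set":
            alias, attribute, value = args
            eid = aliases.get(alias)
            if eid is None or not store.entity_exists(eid):
                raise ScenarioError(
                    f"device {dev} does not know alias {alias!r} at t={t}")
            store.set_value(eid, attribute, value)
        elif op == "delete":
            (alias,) = args
            eid = aliases.get(alias)
            if eid is None or not store.entity_exists(eid):
                raise ScenarioError(
                    f"device {dev} does not know alias {alias!r} at t={t}")
            store.soft_delete_entity(eid)
        elif op == "sync":
            full_sync(store, _LoggingTransport(base, dev, log))
        log.append(("op", t, dev, op, args))
    return ScenarioResult(replicas, hub, log)


def random_scenario(n_devices: int = 3, n_edits: int = 200,
                    n_entities: int = 12, n_attributes: int = 6,
                    seed: int = 0) -> ScenarioScript:
    """A randomized interleaved edit/sync schedule.

    Device 0 seeds ``n_entities`` shared entities and every device pulls
    them; then each device performs ``n_edits`` random attribute writes
    (globally unique values, so last-writer-wins outcomes are
    unambiguous) interleaved with random syncs; the script ends with two
    full sync rounds per replica in random order.
    """
    rng = substream(seed, "scenario")
    ops: list[tuple] = []
    t = 0

    def emit(dev, op, args=()):
        nonlocal t
        ops.append((t, dev, op, tuple(args)))
        t += 1

    names = [f"e{i}" for i in range(n_entities)]
    for alias in names:
        emit(0, "create", (alias, "note"))
    emit(0, "sync")
    for dev in range(1, n_devices):
        emit(dev, "sync")

    remaining = [n_edits] * n_devices
    counter = 0
    while any(remaining):
        dev = int(rng.integers(n_devices))
        if rng.random() < 0.05:
            emit(dev, "sync")
            continue
        if remaining[dev] == 0:
            continue
        alias = names[int(rng.integers(n_entities))]
        attr = f"a{int(rng.integers(n_attributes))}"
        counter += 1
        emit(dev, "set", (alias, attr, f"v{counter}-d{dev}"))
        remaining[dev] -= 1
    for _ in range(2):
        order = list(rng.permutation(n_devices))
        for dev in order:
            emit(int(dev), "sync")
    return ScenarioScript(n_devices=n_devices, ops=ops, seed=seed)


def replay_hub_oracle(log: list[tuple]) -> dict[tuple[str, str],
                                                tuple[str, str, int]]:
    """Independent arrival-order replay of the push log.

    A plain-dict state machine: each push overwrites the key's value and
    bumps a counter, independent of the store and protocol code.  The
    result maps ``(entity_id, attribute)`` to ``(tag, payload,
    version)`` — what the hub must hold if last-writer-wins holds.
    """
    state: dict[tuple[str, str], tuple[str, str, int]] = {}
    for event in log:
        if event[0] != "push":
            continue
        _, _dev, eid, attr, tag, payload, _ack = event
        prev = state.get((eid, attr))
        version = (prev[2] if prev else 0) + 1
        state[(eid, attr)] = (tag, payload, version)
    return state
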