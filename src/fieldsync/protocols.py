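"""Observation protocols for a long-term individual-based field study.

This layer encodes the observation modes of a banded-mongoose style
project — pack and individual management, group-composition visits,
timed focal follows and ad-hoc group events — together with the gating
rules that keep bad records out of the database at entry time:

- presence first: whether an individual is marked present on a visit
  determines what can be recorded about them later in the visit;
- pregnancy records are only accepted for adult females, defined as
  strictly older than 10 months (a month is 30.4375 days by default);
- mate-guard records require a male guard and a female guarded, both
  present; escorts require a pup and a distinct escort, both present;
- babysitting can be *observed* (individual present) or *inferred* from
  the individual's temporary absence from the group;
- a focal follow is a 20-minute countdown with a scan slot per minute,
  pausable when the focal goes out of sight.

Everything written here is plain entity-attribute-value data, so all of
it synchronises and exports with no special cases.
"""

from __future__ import annotations

import datetime as _dt
import json
from dataclasses import dataclass

from .errors import (
    DuplicateError,
    EntityNotFoundError,
    GatingError,
    LifecycleError,
    ValueTypeError,
)
from .store import EavStore, Entity

#: Scan marker when no neighbour is visible.
NONE_VISIBLE = "none-visible"

FOCAL_PROTOCOLS = ("pup", "pregnant-female", "oestrus-female")
STATUS_KINDS = ("pregnancy", "mate-guard", "escort", "babysit")
GROUP_EVENT_TYPES = ("intergroup-interaction", "alarm", "movement", "note")


@dataclass(frozen=True)
class ProtocolConfig:
    """Tunable protocol parameters.

    month_days:
        Length of a month in days used for age arithmetic (365.25 / 12).
    adult_female_min_months:
        Strict lower age bound for pregnancy eligibility; a female at
        exactly this age is *not* eligible.
    pup_age_max_days:
        Upper age bound defining a dependent pup (escorting, pup focals).
    gps_interval_s:
        Seconds between automatic GPS fixes during a group visit; the
        first fix is taken at visit start.
    focal_duration_s:
        Length of the focal-follow countdown.
    score_range:
        Inclusive bounds of the ordinal strength/accuracy scores.
    weight_bounds:
        Optional ``(low, high)`` grams feasibility screen applied at
        entry time; ``None`` (the default) disables the screen.
    """

    month_days: float = 30.4375
    adult_female_min_months: float = 10.0
    pup_age_max_days: int = 90
    gps_interval_s: int = 180
    focal_duration_s: int = 1200
    score_range: tuple[int, int] = (1, 4)
    weight_bounds: tuple[int, int] | None = None


DEFAULT_CONFIG = ProtocolConfig()


# ---------------------------------------------------------------------------
# Pack and individual management


def add_pack(store: EavStore, name: str) -> Entity:
    """Register a new group; names must be unique among active packs."""
    if not name:
        raise ValueTypeError("pack name must be non-empty")
    for pack in store.query_entities("pack"):
        if pack.get("name") == name and pack.get("active", False):
            raise DuplicateError(f"active pack named {name!r} already exists")
    pid = store.create_entity("pack")
    store.set_value(pid, "name", name)
    store.set_value(pid, "active", True)
    return store.get_entity(pid)


def retire_pack(store: EavStore, pack_id: str) -> Entity:
    """Mark a group inactive (it died out or left the study area).

    All its data, and its members, are retained.
    """
    pack = store.get_entity(pack_id)
    if pack.entity_type != "pack":
        raise EntityNotFoundError(f"{pack_id} is not a pack")
    if not pack.get("active", False):
        raise LifecycleError(f"pack {pack_id} is not active")
    store.set_value(pack_id, "active", False)
    return store.get_entity(pack_id)


def active_packs(store: EavStore) -> list[Entity]:
    return [p for p in store.query_entities("pack") if p.get("active", False)]


def add_individual(store: EavStore, pack_id: str, name: str, sex: str,
                   date_of_birth: _dt.date, litter_code: str | None = None,
                   today: _dt.date | None = None) -> Entity:
    """Add an individual to a pack roster.

    ``today`` anchors the no-future-birth check; it defaults to the
    current date and is injectable for simulations.
    """
    pack = store.get_entity(pack_id)
    if pack.entity_type != "pack" or not pack.get("active", False):
        raise GatingError(f"pack {pack_id} is not an active pack")
    if sex not in ("F", "M", "unknown"):
        raise ValueTypeError(f"sex must be F, M or unknown, got {sex!r}")
    today = today or _dt.date.today()
    if date_of_birth > today:
        raise ValueTypeError(f"birth date {date_of_birth} is in the future")
    iid = store.create_entity("individual")
    store.set_value(iid, "name", name)
    store.set_value(iid, "pack", pack_id)
    store.set_value(iid, "sex", sex)
    store.set_value(iid, "date-of-birth", date_of_birth)
    if litter_code is not None:
        store.set_value(iid, "litter-code", litter_code)
    return store.get_entity(iid)


def remove_individual(store: EavStore, individual_id: str) -> Entity:
    """Soft removal from the group list (death or emigration).

    The individual's records remain; they are simply no longer
    selectable in new sessions.
    """
    ind = store.get_entity(individual_id)
    if ind.entity_type != "individual":
        raise EntityNotFoundError(f"{individual_id} is not an individual")
    store.set_value(individual_id, "removed", True)
    return store.get_entity(individual_id)


def pack_roster(store: EavStore, pack_id: str,
                include_removed: bool = False) -> list[Entity]:
    """Current members of a pack, in creation order."""
    members = store.query_entities("individual", where={"pack": pack_id})
    if not include_removed:
        members = [m for m in members if not m.get("removed", False)]
    return members


def date_of_birth(individual: Entity) -> _dt.date:
    dob = individual.get("date-of-birth")
    if dob is None:
        raise ValueTypeError(f"{individual.id} has no date of birth")
    return _dt.date.fromisoformat(dob)


def age_months(born: _dt.date, on_date: _dt.date,
               config: ProtocolConfig = DEFAULT_CONFIG) -> float:
    """Age in months: day count divided by the configured month length."""
    if on_date < born:
        raise ValueTypeError(
            f"observation date {on_date} precedes birth date {born}")
    return (on_date - born).days / config.month_days


def age_days(born: _dt.date, on_date: _dt.date) -> int:
    if on_date < born:
        raise ValueTypeError(
            f"observation date {on_date} precedes birth date {born}")
    return (on_date - born).days


def eligible_for_pregnancy(individual: Entity, on_date: _dt.date,
                           config: ProtocolConfig = DEFAULT_CONFIG) -> bool:
    """Adult female check: sex F and age strictly over the threshold."""
    if individual.get("sex") != "F":
        return False
    months = age_months(date_of_birth(individual), on_date, config)
    return months > config.adult_female_min_months


def is_pup(individual: Entity, on_date: _dt.date,
           config: ProtocolConfig = DEFAULT_CONFIG) -> bool:
    return age_days(date_of_birth(individual), on_date) < config.pup_age_max_days


# ---------------------------------------------------------------------------
# Group composition sessions


class GroupCompositionSession:
    """One visit to a group.

    Create with :func:`start_visit`.  Presence must be recorded before
    any per-individual data; the session gates every later record on
    that presence map.  GPS fixes are logged automatically from visit
    start, every ``gps_interval_s`` seconds of session clock, until the
    visit ends.
    """

    def __init__(self, store: EavStore, session_id: str,
                 gps_source=None, config: ProtocolConfig = DEFAULT_CONFIG):
        self.store = store
        self.id = session_id
        self.gps_source = gps_source
        self.config = config

    # -- state helpers

    @property
    def entity(self) -> Entity:
        return self.store.get_entity(self.id)

    @property
    def pack_id(self) -> str:
        return self.entity.get("pack")

    @property
    def date(self) -> _dt.date:
        return _dt.date.fromisoformat(self.entity.get("date"))

    @property
    def start_time(self) -> _dt.datetime:
        return self.entity.get("start-time")

    @property
    def end_time(self) -> _dt.datetime | None:
        return self.entity.get("end-time")

    @property
    def closed(self) -> bool:
        return self.end_time is not None

    def _require_open(self) -> None:
        if self.closed:
            raise LifecycleError(f"session {self.id} is closed")

    def _roster_member(self, individual_id: str) -> Entity:
        ind = self.store.get_entity(individual_id)
        if (ind.entity_type != "individual"
                or ind.get("pack") != self.pack_id
                or ind.get("removed", False)):
            raise GatingError(
                f"{individual_id} is not on the roster of {self.pack_id}")
        return ind

    def presence_map(self) -> dict[str, bool]:
        """Explicitly recorded presence, individual id → present flag."""
        out = {}
        for attr, entry in self.entity.attributes.items():
            if attr.startswith("present:"):
                out[attr.split(":", 1)[1]] = entry.value
        return out

    def _require_present(self, individual_id: str) -> None:
        if self.presence_map().get(individual_id) is not True:
            raise GatingError(
                f"{individual_id} is not marked present on this visit")

    # -- recording operations

    def record_presence(self, individual_id: str, present: bool) -> None:
        """First screen: who is here today?  Gates all later screens."""
        self._require_open()
        self._roster_member(individual_id)
        self.store.set_value(self.id, f"present:{individual_id}",
                             bool(present))

    def record_weight(self, individual_id: str, grams: int, period: str,
                      at: _dt.datetime | None = None) -> Entity:
        self._require_open()
        self._require_present(individual_id)
        if period not in ("morning", "evening"):
            raise ValueTypeError(f"period must be morning/evening: {period!r}")
        if not isinstance(grams, int) or isinstance(grams, bool) or grams <= 0:
            raise ValueTypeError(f"weight must be a positive integer: {grams!r}")
        if self.config.weight_bounds is not None:
            lo, hi = self.config.weight_bounds
            if not (lo <= grams <= hi):
                raise GatingError(
                    f"weight {grams} g outside feasible range [{lo}, {hi}]")
        wid = self.store.create_entity("weight")
        self.store.set_value(wid, "session", self.id)
        self.store.set_value(wid, "individual", individual_id)
        self.store.set_value(wid, "grams", grams)
        self.store.set_value(wid, "period", period)
        self.store.set_value(wid, "session-time", at or self.start_time)
        return self.store.get_entity(wid)

    def record_pregnancy(self, female_id: str) -> Entity:
        self._require_open()
        self._require_present(female_id)
        ind = self._roster_member(female_id)
        if not eligible_for_pregnancy(ind, self.date, self.config):
            raise GatingError(
                f"{female_id} is not an adult female "
                f"(> {self.config.adult_female_min_months} months)")
        rid = self.store.create_entity("pregnancy")
        self.store.set_value(rid, "session", self.id)
        self.store.set_value(rid, "female", female_id)
        self.store.set_value(rid, "pregnant", True)
        return self.store.get_entity(rid)

    def _check_score(self, label: str, score: int) -> None:
        lo, hi = self.config.score_range
        if not isinstance(score, int) or not (lo <= score <= hi):
            raise ValueTypeError(
                f"{label} score must be an integer in [{lo}, {hi}]: {score!r}")

    def record_mate_guard(self, male_id: str, female_id: str,
                          strength: int, accuracy: int,
                          primary: bool) -> Entity:
        self._require_open()
        male = self._roster_member(male_id)
        female = self._roster_member(female_id)
        if male.get("sex") != "M":
            raise GatingError(f"mate-guard male {male_id} is not male")
        if female.get("sex") != "F":
            raise GatingError(f"mate-guard female {female_id} is not female")
        self._require_present(male_id)
        self._require_present(female_id)
        self._check_score("strength", strength)
        self._check_score("accuracy", accuracy)
        rid = self.store.create_entity("mate-guard")
        self.store.set_value(rid, "session", self.id)
        self.store.set_value(rid, "male", male_id)
        self.store.set_value(rid, "female", female_id)
        self.store.set_value(rid, "strength", strength)
        self.store.set_value(rid, "accuracy", accuracy)
        self.store.set_value(rid, "primary", bool(primary))
        return self.store.get_entity(rid)

    def record_escort(self, pup_id: str, escort_id: str,
                      strength: int, accuracy: int) -> Entity:
        self._require_open()
        if pup_id == escort_id:
            raise GatingError("pup and escort must be distinct")
        pup = self._roster_member(pup_id)
        self._roster_member(escort_id)
        if not is_pup(pup, self.date, self.config):
            raise GatingError(
                f"{pup_id} is older than {self.config.pup_age_max_days} days"
                " — not a dependent pup")
        self._require_present(pup_id)
        self._require_present(escort_id)
        self._check_score("strength", strength)
        self._check_score("accuracy", accuracy)
        rid = self.store.create_entity("escort")
        self.store.set_value(rid, "session", self.id)
        self.store.set_value(rid, "pup", pup_id)
        self.store.set_value(rid, "escort", escort_id)
        self.store.set_value(rid, "strength", strength)
        self.store.set_value(rid, "accuracy", accuracy)
        return self.store.get_entity(rid)

    def record_babysit(self, individual_id: str, evidence: str) -> Entity:
        """Babysitting at the den: observed directly, or inferred from
        the individual's temporary absence from the visit."""
        self._require_open()
        self._roster_member(individual_id)
        if evidence not in ("observed", "inferred"):
            raise ValueTypeError(
                f"evidence must be observed/inferred: {evidence!r}")
        present = self.presence_map().get(individual_id)
        if evidence == "observed" and present is not True:
            raise GatingError(
                f"observed babysitter {individual_id} must be marked present")
        if evidence == "inferred" and present is not False:
            raise GatingError(
                f"inferred babysitter {individual_id} must be marked absent")
        rid = self.store.create_entity("babysit")
        self.store.set_value(rid, "session", self.id)
        self.store.set_value(rid, "individual", individual_id)
        self.store.set_value(rid, "evidence", evidence)
        return self.store.get_entity(rid)

    def record_status(self, kind: str, payload: dict) -> Entity:
        """Dispatch a status record by kind (one screen per kind)."""
        if kind == "pregnancy":
            return self.record_pregnancy(payload["female"])
        if kind == "mate-guard":
            return self.record_mate_guard(
                payload["male"], payload["female"], payload["strength"],
                payload["accuracy"], payload["primary"])
        if kind == "escort":
            return self.record_escort(
                payload["pup"], payload["escort"], payload["strength"],
                payload["accuracy"])
        if kind == "babysit":
            return self.record_babysit(payload["individual"],
                                       payload["evidence"])
        raise ValueTypeError(f"unknown status kind: {kind!r}")

    def skip_screen(self, kind: str) -> None:
        """Mark a screen explicitly not applicable (vs. not recorded)."""
        self._require_open()
        if kind not in STATUS_KINDS + ("weight",):
            raise ValueTypeError(f"unknown screen kind: {kind!r}")
        self.store.set_value(self.id, f"skip:{kind}", True)

    # -- closing

    def end_visit(self, end_time: _dt.datetime) -> Entity:
        """Close the visit, record the end time, and log the GPS track.

        Fixes are taken at session clock 0, then every configured
        interval, up to and including the visit duration.  A degenerate
        zero-length visit still logs the start fix.
        """
        self._require_open()
        start = self.start_time
        if end_time < start:
            raise LifecycleError(
                f"end time {end_time} precedes start time {start}")
        duration = int((end_time - start).total_seconds())
        if self.gps_source is not None:
            for t in range(0, duration + 1, self.config.gps_interval_s):
                pos = self.gps_source(t)
                if pos is None:
                    continue
                lat, lon = pos
                if not (-90.0 <= lat <= 90.0 and -180.0 <= lon <= 180.0):
                    raise ValueTypeError(
                        f"GPS fix out of range: ({lat}, {lon})")
                fid = self.store.create_entity("gps-fix")
                self.store.set_value(fid, "session", self.id)
                self.store.set_value(
                    fid, "timestamp", start + _dt.timedelta(seconds=t))
                self.store.set_value(fid, "lat", float(lat))
                self.store.set_value(fid, "lon", float(lon))
        self.store.set_value(self.id, "end-time", end_time)
        return self.entity

    def gps_track(self) -> list[Entity]:
        fixes = self.store.query_entities("gps-fix", where={"session": self.id})
        return sorted(fixes, key=lambda f: f.get("timestamp"))


def start_visit(store: EavStore, pack_id: str, start_time: _dt.datetime,
                gps_source=None,
                config: ProtocolConfig = DEFAULT_CONFIG) -> GroupCompositionSession:
    """Open a group-composition session; logs the start time.

    A second open session for the same pack and date is rejected.
    """
    pack = store.get_entity(pack_id)
    if pack.entity_type != "pack" or not pack.get("active", False):
        raise GatingError(f"pack {pack_id} is not an active pack")
    date = start_time.date().isoformat()
    for s in store.query_entities("group-composition-session",
                                  where={"pack": pack_id, "date": date}):
        if s.get("end-time") is None:
            raise DuplicateError(
                f"pack {pack_id} already has an open session on {date}")
    sid = store.create_entity("group-composition-session")
    store.set_value(sid, "pack", pack_id)
    store.set_value(sid, "date", date)
    store.set_value(sid, "start-time", start_time)
    return GroupCompositionSession(store, sid, gps_source, config)


def load_session(store: EavStore, session_id: str,
                 config: ProtocolConfig = DEFAULT_CONFIG) -> GroupCompositionSession:
    ent = store.get_entity(session_id)
    if ent.entity_type != "group-composition-session":
        raise EntityNotFoundError(f"{session_id} is not a session")
    return GroupCompositionSession(store, session_id, None, config)


# ---------------------------------------------------------------------------
# Focal follows


class FocalFollow:
    """A 20-minute focal-animal follow with per-minute scan slots.

    The countdown only consumes *active* time: pausing (focal out of
    sight) freezes it, so a follow paused for five minutes completes at
    wall-clock twenty-five.  Completion always yields exactly 20 scan
    slots — a minute whose prompt was missed is stored as an explicit
    empty scan rather than a silent gap.
    """

    def __init__(self, store: EavStore, follow_id: str, clock,
                 config: ProtocolConfig = DEFAULT_CONFIG):
        self.store = store
        self.id = follow_id
        self.clock = clock
        self.config = config

    @property
    def entity(self) -> Entity:
        return self.store.get_entity(self.id)

    @property
    def state(self) -> str:
        return self.entity.get("state")

    @property
    def focal_id(self) -> str:
        return self.entity.get("focal")

    @property
    def start_time(self) -> _dt.datetime:
        return self.entity.get("start-time")

    def _pauses(self) -> list[list[str]]:
        return json.loads(self.entity.get("pauses", "[]"))

    def paused_seconds(self) -> float:
        """Total logged pause time; an open pause counts up to now."""
        total = 0.0
        for pair in self._pauses():
            start = _dt.datetime.fromisoformat(pair[0])
            end = (_dt.datetime.fromisoformat(pair[1]) if pair[1]
                   else self.clock.now())
            total += (end - start).total_seconds()
        return total

    def active_elapsed(self) -> float:
        wall = (self.clock.now() - self.start_time).total_seconds()
        return wall - self.paused_seconds()

    @property
    def remaining_seconds(self) -> float:
        return max(0.0, self.config.focal_duration_s - self.active_elapsed())

    def _require_state(self, *states: str) -> None:
        if self.state not in states:
            raise LifecycleError(
                f"follow {self.id} is {self.state}, needs {'/'.join(states)}")

    def scans(self) -> list[Entity]:
        recs = self.store.query_entities("focal-scan",
                                         where={"follow": self.id})
        return sorted(recs, key=lambda r: r.get("minute-index"))

    def interactions(self) -> list[Entity]:
        return self.store.query_entities("focal-interaction",
                                         where={"follow": self.id})

    # -- recording

    def _check_neighbour(self, individual_id: str) -> None:
        if individual_id == self.focal_id:
            raise ValueTypeError("focal cannot be its own neighbour")
        ind = self.store.get_entity(individual_id)
        focal = self.store.get_entity(self.focal_id)
        if (ind.entity_type != "individual"
                or ind.get("pack") != focal.get("pack")):
            raise GatingError(
                f"{individual_id} is not a packmate of the focal")

    def record_scan(self, minute_index: int, nearest: str,
                    within_2m: tuple[str, ...] = ()) -> Entity:
        """One scan slot: nearest neighbour plus everyone within 2 m.

        The nearest neighbour is auto-included in the 2 m set if the
        user omitted it there.
        """
        self._require_state("running")
        if not (1 <= minute_index <= self.config.focal_duration_s // 60):
            raise ValueTypeError(f"minute index out of range: {minute_index}")
        if any(s.get("minute-index") == minute_index for s in self.scans()):
            raise DuplicateError(f"minute {minute_index} already recorded")
        within = list(dict.fromkeys(within_2m))
        if nearest != NONE_VISIBLE:
            self._check_neighbour(nearest)
            if nearest not in within:
                within.insert(0, nearest)
        for iid in within:
            self._check_neighbour(iid)
        sid = self.store.create_entity("focal-scan")
        self.store.set_value(sid, "follow", self.id)
        self.store.set_value(sid, "minute-index", minute_index)
        self.store.set_value(sid, "nearest", nearest)
        self.store.set_value(sid, "within-2m", ",".join(within))
        self.store.set_value(sid, "empty", False)
        return self.store.get_entity(sid)

    def record_interaction(self, kind: str, partner: str, initiator: str,
                           intensity: str, context: str,
                           winner: str = "none") -> Entity:
        """An affiliative or agonistic interaction involving the focal.

        A winner is only meaningful for agonistic interactions; for
        affiliative ones it is stored as ``none``.
        """
        self._require_state("running", "paused")
        if kind not in ("affiliative", "agonistic"):
            raise ValueTypeError(f"kind must be affiliative/agonistic: {kind!r}")
        if initiator not in ("focal", "partner"):
            raise ValueTypeError(f"initiator must be focal/partner: {initiator!r}")
        if winner not in ("focal", "partner", "none"):
            raise ValueTypeError(f"winner must be focal/partner/none: {winner!r}")
        if partner == self.focal_id:
            raise ValueTypeError("partner cannot be the focal itself")
        self._check_neighbour(partner)
        if kind == "affiliative":
            winner = "none"
        rid = self.store.create_entity("focal-interaction")
        self.store.set_value(rid, "follow", self.id)
        self.store.set_value(rid, "kind", kind)
        self.store.set_value(rid, "partner", partner)
        self.store.set_value(rid, "initiator", initiator)
        self.store.set_value(rid, "intensity", intensity)
        self.store.set_value(rid, "context", context)
        self.store.set_value(rid, "winner", winner)
        self.store.set_value(rid, "offset-seconds", float(self.active_elapsed()))
        return self.store.get_entity(rid)

    # -- lifecycle

    def pause(self) -> None:
        """Freeze the countdown (e.g. focal out of sight)."""
        self._require_state("running")
        pauses = self._pauses()
        pauses.append([self.clock.now().isoformat(), None])
        self.store.set_value(self.id, "pauses", json.dumps(pauses))
        self.store.set_value(self.id, "state", "paused")

    def resume(self) -> None:
        self._require_state("paused")
        pauses = self._pauses()
        pauses[-1][1] = self.clock.now().isoformat()
        self.store.set_value(self.id, "pauses", json.dumps(pauses))
        self.store.set_value(self.id, "state", "running")

    def abort(self) -> None:
        """Terminate early; partial data are retained."""
        self._require_state("running", "paused")
        if self.state == "paused":
            self.resume()
        self.store.set_value(self.id, "state", "aborted")

    def complete(self) -> Entity:
        """Finish after the countdown has elapsed.

        Missing minutes are filled with explicit empty scans so a
        completed follow always has exactly one slot per minute.
        """
        self._require_state("running")
        if self.active_elapsed() < self.config.focal_duration_s:
            raise LifecycleError(
                f"countdown not elapsed: {self.remaining_seconds:.0f}s left")
        recorded = {s.get("minute-index") for s in self.scans()}
        for minute in range(1, self.config.focal_duration_s // 60 + 1):
            if minute in recorded:
                continue
            sid = self.store.create_entity("focal-scan")
            self.store.set_value(sid, "follow", self.id)
            self.store.set_value(sid, "minute-index", minute)
            self.store.set_value(sid, "nearest", NONE_VISIBLE)
            self.store.set_value(sid, "within-2m", "")
            self.store.set_value(sid, "empty", True)
        self.store.set_value(self.id, "state", "completed")
        return self.entity


def start_focal(store: EavStore, protocol: str, focal_id: str, clock,
                config: ProtocolConfig = DEFAULT_CONFIG) -> FocalFollow:
    """Begin a focal follow under one of the three protocols.

    The protocol must match the focal: the pup protocol requires a
    dependent pup; the pregnant-female and oestrus-female protocols
    require a female.
    """
    if protocol not in FOCAL_PROTOCOLS:
        raise ValueTypeError(f"unknown focal protocol: {protocol!r}")
    focal = store.get_entity(focal_id)
    if focal.entity_type != "individual":
        raise EntityNotFoundError(f"{focal_id} is not an individual")
    now = clock.now()
    if protocol == "pup":
        if not is_pup(focal, now.date(), config):
            raise GatingError(f"{focal_id} is not a dependent pup")
    else:
        if focal.get("sex") != "F":
            raise GatingError(
                f"{protocol} protocol requires a female focal")
    fid = store.create_entity("focal-follow")
    store.set_value(fid, "protocol", protocol)
    store.set_value(fid, "focal", focal_id)
    store.set_value(fid, "start-time", now)
    store.set_value(fid, "state", "running")
    store.set_value(fid, "pauses", "[]")
    return FocalFollow(store, fid, clock, config)


# ---------------------------------------------------------------------------
# Group events


def record_group_event(store: EavStore, pack_id: str, event_type: str,
                       details: dict, timestamp: _dt.datetime) -> Entity:
    """Ad-hoc group-level event: intergroup interaction, alarm,
    movement decision, or a free-text note.

    Each type has required detail fields: an intergroup interaction
    needs the other pack; a note needs its text.
    """
    pack = store.get_entity(pack_id)
    if pack.entity_type != "pack" or not pack.get("active", False):
        raise GatingError(f"pack {pack_id} is not an active pack")
    if event_type not in GROUP_EVENT_TYPES:
        raise ValueTypeError(f"unknown event type: {event_type!r}")
    if event_type == "intergroup-interaction" and not details.get("other_pack"):
        raise ValueTypeError("intergroup-interaction requires other_pack")
    if event_type == "note" and not details.get("free_text"):
        raise ValueTypeError("note requires free_text")
    etype = "note" if event_type == "note" else "group-event"
    eid = store.create_entity(etype)
    store.set_value(eid, "pack", pack_id)
    store.set_value(eid, "event-type", event_type)
    store.set_value(eid, "timestamp", timestamp)
    if details.get("participants"):
        for iid in details["participants"]:
            ind = store.get_entity(iid)
            if ind.entity_type != "individual":
                raise GatingError(f"participant {iid} is not an individual")
        store.set_value(eid, "participants", ",".join(details["participants"]))
    for key in ("other_pack", "outcome", "cause", "target", "free_text"):
        if details.get(key) is not None:
            store.set_value(eid, key.replace("_", "-"), details[key])
    return store.get_entity(eid)


# ---------------------------------------------------------------------------
# Review & edit


#: Record types attached to a session, with their session-pointer attribute.
_SESSION_CHILD_TYPES = ("weight", "pregnancy", "mate-guard", "escort",
                        "babysit", "gps-fix")


def session_records(store: EavStore, session_id: str) -> dict[str, list]:
    """All records collected during one visit, grouped by kind.

    This is the review-mode listing: presence first, then each record
    type in collection order.
    """
    session = store.get_entity(session_id)
    if session.entity_type != "group-composition-session":
        raise EntityNotFoundError(f"{session_id} is not a session")
    out: dict[str, list] = {"presence": [], "skips": []}
    for attr, entry in sorted(session.attributes.items()):
        if attr.startswith("present:"):
            out["presence"].append((attr.split(":", 1)[1], entry.value))
        elif attr.startswith("skip:"):
            out["skips"].append(attr.split(":", 1)[1])
    for etype in _SESSION_CHILD_TYPES:
        out[etype] = store.query_entities(etype, where={"session": session_id})
    return out


def edit_presence(store: EavStore, session_id: str, individual_id: str,
                  present: bool) -> None:
    """Flip a presence record (review mode); re-dirties the entry."""
    session = load_session(store, session_id)
    if individual_id not in session.presence_map():
        raise EntityNotFoundError(
            f"no presence record for {individual_id} in {session_id}")
    store.set_value(session_id, f"present:{individual_id}", bool(present))


def edit_record(store: EavStore, record_id: str, field: str,
                new_value, config: ProtocolConfig = DEFAULT_CONFIG) -> Entity:
    """Correct one field of a collected record.

    The same gating that applied at entry applies again: a weight cannot
    be re-pointed at an individual who is marked absent, grams must stay
    positive, scores stay in range.  The rewritten entry is dirty again
    and will re-sync.
    """
    rec = store.get_entity(record_id)
    etype = rec.entity_type
    if etype == "weight":
        if field == "grams":
            if (not isinstance(new_value, int) or isinstance(new_value, bool)
                    or new_value <= 0):
                raise ValueTypeError(f"weight must be positive: {new_value!r}")
        elif field == "individual":
            session = load_session(store, rec.get("session"), config)
            if session.presence_map().get(new_value) is not True:
                raise GatingError(
                    f"{new_value} is not marked present in that session")
    elif etype == "pregnancy" and field == "female":
        session = load_session(store, rec.get("session"), config)
        ind = store.get_entity(new_value)
        if session.presence_map().get(new_value) is not True:
            raise GatingError(f"{new_value} is not marked present")
        if not eligible_for_pregnancy(ind, session.date, config):
            raise GatingError(f"{new_value} is not an adult female")
    elif etype in ("mate-guard", "escort") and field in ("strength", "accuracy"):
        lo, hi = config.score_range
        if not isinstance(new_value, int) or not (lo <= new_value <= hi):
            raise ValueTypeError(f"score out of range: {new_value!r}")
    store.set_value(record_id, field, new_value)
    return store.get_entity(record_id)


# ---------------------------------------------------------------------------
# Feasibility screening (post-hoc error check)


def screen_weights(store: EavStore,
                   bounds: tuple[int, int]) -> list[Entity]:
    """Flag stored weight records outside a feasible grams range.

    Returns the flagged weight entities in store order.  This is the
    retrospective error screen; the optional entry-time screen is
    :attr:`ProtocolConfig.weight_bounds`.
    """
    lo, hi = bounds
    flagged = []
    for rec in store.query_entities("weight"):
        grams = rec.get("grams")
        if grams is None or not (lo <= grams <= hi):
            flagged.append(rec)
    return flagged
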