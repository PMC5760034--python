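"""Observation-protocol gating, timing and review/edit behaviour."""

import datetime as dt

import pytest

from fieldsync import (
    DuplicateError,
    GatingError,
    LifecycleError,
    SimulatedClock,
    ValueTypeError,
)
from fieldsync import protocols as fp
from fieldsync.fixtures import TZ


class TestPackManagement:
    def test_add_and_retire(self, store):
        pack = fp.add_pack(store, "1H")
        assert pack.get("active") is True
        fp.retire_pack(store, pack.id)
        assert fp.active_packs(store) == []
        # members retained after retirement
        assert store.get_entity(pack.id).get("name") == "1H"

    def test_duplicate_active_name_rejected(self, store):
        fp.add_pack(store, "1H")
        with pytest.raises(DuplicateError):
            fp.add_pack(store, "1H")

    def test_retired_name_reusable(self, store):
        pack = fp.add_pack(store, "1H")
        fp.retire_pack(store, pack.id)
        assert fp.add_pack(store, "1H").get("active") is True

    def test_future_birth_date_rejected(self, store):
        pack = fp.add_pack(store, "1H")
        with pytest.raises(ValueTypeError):
            fp.add_individual(store, pack.id, "X", "F", dt.date(2016, 1, 1),
                              today=dt.date(2015, 1, 1))

    def test_removed_individual_not_selectable(self, store):
        pack = fp.add_pack(store, "1H")
        ind = fp.add_individual(store, pack.id, "X", "F", dt.date(2012, 1, 1),
                                today=dt.date(2015, 1, 1))
        fp.remove_individual(store, ind.id)
        assert fp.pack_roster(store, pack.id) == []
        session = fp.start_visit(store, pack.id,
                                 dt.datetime(2015, 3, 2, 8, 0, tzinfo=TZ))
        with pytest.raises(GatingError):
            session.record_presence(ind.id, True)


class TestAgeArithmetic:
    # expected values from day-count arithmetic: days / 30.4375
    @pytest.mark.parametrize("born, on, months", [
        (dt.date(2015, 1, 1), dt.date(2015, 1, 1), 0.0),
        (dt.date(2015, 1, 1), dt.date(2015, 11, 12), 315 / 30.4375),
        (dt.date(2015, 1, 1), dt.date(2015, 10, 1), 273 / 30.4375),
    ])
    def test_age_months(self, born, on, months):
        assert fp.age_months(born, on) == pytest.approx(months)

    def test_age_before_birth_rejected(self):
        with pytest.raises(ValueTypeError):
            fp.age_months(dt.date(2015, 1, 1), dt.date(2014, 12, 31))

    def test_pregnancy_eligibility_boundary(self, store):
        """> 10 months is strict: exactly 10.0 months is rejected."""
        pack = fp.add_pack(store, "1H")
        on = dt.date(2015, 1, 1)
        # exactly 10 months = 304.375 days is not a whole day; use the
        # nearest whole days on either side of the threshold
        at_days = int(10 * 30.4375)  # 304 days -> 9.988 months, under
        over_days = at_days + 1      # 305 days -> 10.02 months, over
        male = fp.add_individual(store, pack.id, "M", "M",
                                 on - dt.timedelta(days=400), today=on)
        young = fp.add_individual(store, pack.id, "YF", "F",
                                  on - dt.timedelta(days=at_days), today=on)
        adult = fp.add_individual(store, pack.id, "AF", "F",
                                  on - dt.timedelta(days=over_days), today=on)
        assert not fp.eligible_for_pregnancy(male, on)
        assert not fp.eligible_for_pregnancy(young, on)
        assert fp.eligible_for_pregnancy(adult, on)

    def test_exactly_ten_months_rejected_with_integer_month(self, store):
        """With a 30-day month, a 300-day-old female is exactly 10.0
        months and must be rejected (strict threshold)."""
        cfg = fp.ProtocolConfig(month_days=30.0)
        pack = fp.add_pack(store, "1H")
        on = dt.date(2015, 1, 1)
        f = fp.add_individual(store, pack.id, "F", "F",
                              on - dt.timedelta(days=300), today=on)
        assert fp.age_months(fp.date_of_birth(f), on, cfg) == 10.0
        assert not fp.eligible_for_pregnancy(f, on, cfg)


class TestVisitLifecycle:
    def test_start_logs_start_time(self, visit_setup):
        _, _, _, session, start = visit_setup
        assert session.start_time == start

    def test_second_open_session_same_pack_day_rejected(self, visit_setup):
        store, pack, _, _, start = visit_setup
        with pytest.raises(DuplicateError):
            fp.start_visit(store, pack.id, start + dt.timedelta(minutes=5))

    @pytest.mark.parametrize("minutes, fixes", [(20, 7), (25, 9), (0, 1)])
    def test_gps_fix_counts(self, visit_setup, minutes, fixes):
        """Fix at start then every 3 minutes: 20 min -> 7, 25 -> 9, 0 -> 1."""
        _, _, _, session, start = visit_setup
        session.end_visit(start + dt.timedelta(minutes=minutes))
        track = session.gps_track()
        assert len(track) == fixes
        times = [f.get("timestamp") for f in track]
        deltas = {(b - a).total_seconds() for a, b in zip(times, times[1:])}
        assert deltas <= {180.0}

    def test_end_before_start_rejected(self, visit_setup):
        _, _, _, session, start = visit_setup
        with pytest.raises(LifecycleError):
            session.end_visit(start - dt.timedelta(seconds=1))

    def test_records_after_close_rejected(self, visit_setup):
        _, _, adults, session, start = visit_setup
        session.end_visit(start + dt.timedelta(minutes=20))
        with pytest.raises(LifecycleError):
            session.record_presence(adults["AF1"].id, True)


class TestVisitGating:
    def test_weight_for_absent_individual_rejected(self, visit_setup):
        _, _, adults, session, _ = visit_setup
        session.record_presence(adults["AF1"].id, False)
        with pytest.raises(GatingError):
            session.record_weight(adults["AF1"].id, 1234, "morning")

    def test_unrecorded_presence_blocks_weight(self, visit_setup):
        _, _, adults, session, _ = visit_setup
        assert session.presence_map() == {}
        with pytest.raises(GatingError):
            session.record_weight(adults["AF1"].id, 1234, "morning")

    def test_presence_map_counts(self, visit_setup):
        _, _, adults, session, _ = visit_setup
        for i, ind in enumerate(adults.values()):
            session.record_presence(ind.id, i != 0)
        pmap = session.presence_map()
        assert len(pmap) == 6 and sum(pmap.values()) == 5

    def test_weight_round_trip_and_validation(self, visit_setup):
        store, _, adults, session, _ = visit_setup
        session.record_presence(adults["AF1"].id, True)
        rec = session.record_weight(adults["AF1"].id, 1234, "morning")
        assert store.get_entity(rec.id).get("grams") == 1234
        with pytest.raises(ValueTypeError):
            session.record_weight(adults["AF1"].id, 0, "morning")

    def test_entry_time_feasibility_screen_when_enabled(self, store):
        cfg = fp.ProtocolConfig(weight_bounds=(750, 2250))
        pack = fp.add_pack(store, "2B")
        ind = fp.add_individual(store, pack.id, "A", "F",
                                dt.date(2012, 1, 1),
                                today=dt.date(2015, 1, 1))
        session = fp.start_visit(store, pack.id,
                                 dt.datetime(2015, 3, 2, 8, 0, tzinfo=TZ),
                                 config=cfg)
        session.record_presence(ind.id, True)
        session.record_weight(ind.id, 1234, "morning")
        with pytest.raises(GatingError):
            session.record_weight(ind.id, 9234, "morning")

    def test_pregnancy_gating(self, visit_setup):
        _, _, adults, session, _ = visit_setup
        for name in ("AF1", "AM1", "YF1"):
            session.record_presence(adults[name].id, True)
        session.record_pregnancy(adults["AF1"].id)  # adult female: ok
        with pytest.raises(GatingError):
            session.record_pregnancy(adults["AM1"].id)  # male
        with pytest.raises(GatingError):
            session.record_pregnancy(adults["YF1"].id)  # ~7 months

    def test_mate_guard_gating_and_storage(self, visit_setup):
        store, _, adults, session, _ = visit_setup
        for name in ("AF1", "AM1", "AM2"):
            session.record_presence(adults[name].id, True)
        rec = session.record_mate_guard(adults["AM1"].id, adults["AF1"].id,
                                        3, 4, primary=True)
        assert rec.get("primary") is True
        with pytest.raises(GatingError):  # two males
            session.record_mate_guard(adults["AM1"].id, adults["AM2"].id,
                                      3, 4, primary=False)
        with pytest.raises(GatingError):  # female absent
            session.record_mate_guard(adults["AM1"].id, adults["AF2"].id,
                                      3, 4, primary=False)

    def test_escort_requires_present_pup_and_distinct_escort(self, visit_setup):
        _, _, adults, session, _ = visit_setup
        for name in ("PUP1", "AF1"):
            session.record_presence(adults[name].id, True)
        session.record_escort(adults["PUP1"].id, adults["AF1"].id, 2, 3)
        with pytest.raises(GatingError):
            session.record_escort(adults["AF1"].id, adults["PUP1"].id, 2, 3)
        with pytest.raises(GatingError):
            session.record_escort(adults["PUP1"].id, adults["PUP1"].id, 2, 3)

    def test_babysit_inferred_requires_absence(self, visit_setup):
        _, _, adults, session, _ = visit_setup
        session.record_presence(adults["AF1"].id, False)
        session.record_presence(adults["AF2"].id, True)
        rec = session.record_babysit(adults["AF1"].id, "inferred")
        assert rec.get("evidence") == "inferred"
        session.record_babysit(adults["AF2"].id, "observed")
        with pytest.raises(GatingError):
            session.record_babysit(adults["AF2"].id, "inferred")

    def test_skip_marker_distinct_from_not_recorded(self, visit_setup):
        store, _, _, session, _ = visit_setup
        session.skip_screen("babysit")
        records = fp.session_records(store, session.id)
        assert records["skips"] == ["babysit"]


class TestFocalFollows:
    def mk_follow(self, store, protocol="oestrus-female", n_mates=4):
        pack = fp.add_pack(store, "3K")
        focal_dob = (dt.date(2015, 2, 1) if protocol == "pup"
                     else dt.date(2012, 1, 1))
        sex = "M" if protocol == "pup" else "F"
        focal = fp.add_individual(store, pack.id, "FOC", sex, focal_dob,
                                  today=dt.date(2015, 3, 2))
        mates = [fp.add_individual(store, pack.id, f"N{i}", "M",
                                   dt.date(2012, 1, 1),
                                   today=dt.date(2015, 3, 2))
                 for i in range(n_mates)]
        clock = SimulatedClock(dt.datetime(2015, 3, 2, 9, 0, tzinfo=TZ))
        follow = fp.start_focal(store, protocol, focal.id, clock)
        return follow, clock, focal, mates

    def test_fresh_follow_running_with_no_scans(self, store):
        follow, _, _, _ = self.mk_follow(store)
        assert follow.state == "running"
        assert follow.scans() == []
        assert follow.remaining_seconds == 1200

    def test_protocol_mismatch_rejected(self, store):
        pack = fp.add_pack(store, "3K")
        male = fp.add_individual(store, pack.id, "M1", "M",
                                 dt.date(2012, 1, 1),
                                 today=dt.date(2015, 3, 2))
        clock = SimulatedClock(dt.datetime(2015, 3, 2, 9, 0, tzinfo=TZ))
        with pytest.raises(GatingError):
            fp.start_focal(store, "oestrus-female", male.id, clock)
        with pytest.raises(GatingError):  # adult male is no pup either
            fp.start_focal(store, "pup", male.id, clock)

    def test_completed_follow_has_twenty_scan_slots(self, store):
        follow, clock, _, mates = self.mk_follow(store)
        for minute in range(1, 21):
            clock.advance(60)
            if minute % 3:  # some prompts missed on purpose
                follow.record_scan(minute, mates[0].id)
        follow.complete()
        scans = follow.scans()
        assert follow.state == "completed"
        assert [s.get("minute-index") for s in scans] == list(range(1, 21))
        assert all(s.get("empty") for s in scans
                   if s.get("minute-index") % 3 == 0)

    def test_pause_shifts_completion_by_paused_time(self, store):
        """5 min paused at t=10 -> completes at wall 25 min, 20 scans."""
        follow, clock, _, mates = self.mk_follow(store)
        for minute in range(1, 21):
            if minute == 10:
                follow.pause()
                with pytest.raises(LifecycleError):
                    follow.pause()  # pause when paused
                with pytest.raises(LifecycleError):
                    follow.record_scan(minute, mates[0].id)  # prompts off
                clock.advance(300)
                follow.resume()
            clock.advance(60)
            follow.record_scan(minute, mates[0].id)
        wall = (clock.now() - follow.start_time).total_seconds()
        assert wall == 25 * 60
        assert follow.paused_seconds() == 300
        follow.complete()
        assert len(follow.scans()) == 20

    def test_early_completion_rejected(self, store):
        follow, clock, _, _ = self.mk_follow(store)
        clock.advance(600)
        with pytest.raises(LifecycleError):
            follow.complete()

    def test_scan_validation(self, store):
        follow, clock, focal, mates = self.mk_follow(store)
        clock.advance(60)
        rec = follow.record_scan(3, mates[0].id, (mates[1].id,))
        # nearest auto-included in the 2 m set
        assert rec.get("within-2m") == f"{mates[0].id},{mates[1].id}"
        with pytest.raises(DuplicateError):
            follow.record_scan(3, mates[0].id)
        with pytest.raises(ValueTypeError):
            follow.record_scan(4, focal.id)  # focal as own neighbour

    def test_interaction_rules(self, store):
        follow, clock, focal, mates = self.mk_follow(store)
        clock.advance(60)
        rec = follow.record_interaction("agonistic", mates[0].id, "focal",
                                        "attack", "food", "focal")
        assert rec.get("winner") == "focal"
        rec = follow.record_interaction("affiliative", mates[0].id, "partner",
                                        "groom", "social-partner", "focal")
        assert rec.get("winner") == "none"  # winner meaningless here
        with pytest.raises(ValueTypeError):
            follow.record_interaction("agonistic", focal.id, "focal",
                                      "attack", "food", "focal")

    def test_abort_keeps_partial_data(self, store):
        follow, clock, _, mates = self.mk_follow(store)
        clock.advance(60)
        follow.record_scan(1, mates[0].id)
        follow.pause()
        follow.abort()
        assert follow.state == "aborted"
        assert len(follow.scans()) == 1  # retained, not padded
        with pytest.raises(LifecycleError):
            follow.record_interaction("agonistic", mates[0].id, "focal",
                                      "attack", "food", "focal")


class TestGroupEvents:
    def test_event_types_and_required_details(self, visit_setup):
        store, pack, adults, _, start = visit_setup
        other = fp.add_pack(store, "2B")
        ev = fp.record_group_event(
            store, pack.id, "intergroup-interaction",
            {"other_pack": other.id, "outcome": "other-retreated",
             "participants": [adults["AM1"].id]}, start)
        assert ev.get("other-pack") == other.id
        with pytest.raises(ValueTypeError):
            fp.record_group_event(store, pack.id, "intergroup-interaction",
                                  {}, start)
        alarm = fp.record_group_event(store, pack.id, "alarm",
                                      {"cause": "predator-sighting"}, start)
        assert alarm.get("cause") == "predator-sighting"
        move = fp.record_group_event(store, pack.id, "movement",
                                     {"target": "water-source"}, start)
        assert move.get("target") == "water-source"

    def test_note_stored_verbatim(self, visit_setup):
        store, pack, _, _, start = visit_setup
        text = 'saw "odd" weights, re-check BM012\nline 2'
        note = fp.record_group_event(store, pack.id, "note",
                                     {"free_text": text}, start)
        assert note.entity_type == "note"
        assert note.get("free-text") == text
        with pytest.raises(ValueTypeError):
            fp.record_group_event(store, pack.id, "note", {}, start)


class TestReviewAndEdit:
    def test_listing_groups_records_by_session(self, visit_setup):
        store, _, adults, session, _ = visit_setup
        session.record_presence(adults["AF1"].id, True)
        session.record_presence(adults["AF2"].id, False)
        session.record_weight(adults["AF1"].id, 1334, "morning")
        records = fp.session_records(store, session.id)
        assert sorted(records["presence"]) == sorted(
            [(adults["AF1"].id, True), (adults["AF2"].id, False)])
        assert len(records["weight"]) == 1

    def test_flip_absent_to_present_unlocks_weight(self, visit_setup):
        store, _, adults, session, _ = visit_setup
        session.record_presence(adults["AF1"].id, False)
        with pytest.raises(GatingError):
            session.record_weight(adults["AF1"].id, 1234, "morning")
        fp.edit_presence(store, session.id, adults["AF1"].id, True)
        session.record_weight(adults["AF1"].id, 1234, "morning")

    def test_weight_edit_redirties_for_resync(self, visit_setup):
        store, _, adults, session, _ = visit_setup
        session.record_presence(adults["AF1"].id, True)
        rec = session.record_weight(adults["AF1"].id, 1334, "morning")
        # pretend everything synced
        for e in list(store.dirty_entries()):
            store.mark_synced(e.entity_id, e.attribute, 1)
        fp.edit_record(store, rec.id, "grams", 1234)
        dirty = store.dirty_entries()
        assert [(e.entity_id, e.attribute) for e in dirty] \
            == [(rec.id, "grams")]
        assert store.get_entity(rec.id).get("grams") == 1234

    def test_edit_violating_gating_rejected(self, visit_setup):
        store, _, adults, session, _ = visit_setup
        session.record_presence(adults["AF1"].id, True)
        session.record_presence(adults["AF2"].id, False)
        rec = session.record_weight(adults["AF1"].id, 1234, "morning")
        with pytest.raises(GatingError):
            fp.edit_record(store, rec.id, "individual", adults["AF2"].id)
        with pytest.raises(ValueTypeError):
            fp.edit_record(store, rec.id, "grams", -5)
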