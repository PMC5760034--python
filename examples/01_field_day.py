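"""One field day on one device: roster, group visit, focal follow, review.

Builds a small pack by hand, runs a 20-minute group-composition visit
with presence gating, weighs and statuses, then a paused focal follow,
and finally reviews and corrects a typo'd weight.
"""

import datetime as dt

from fieldsync import EavStore, GatingError, SimulatedClock
from fieldsync import protocols as fp
from fieldsync.fixtures import TZ

store = EavStore(device_tag="T1")  # in-memory replica

pack = fp.add_pack(store, "1H")
af = fp.add_individual(store, pack.id, "BM101", "F", dt.date(2012, 4, 1),
                       today=dt.date(2015, 3, 2))
am = fp.add_individual(store, pack.id, "BM102", "M", dt.date(2011, 9, 1),
                       today=dt.date(2015, 3, 2))
yf = fp.add_individual(store, pack.id, "BM103", "F", dt.date(2014, 8, 1),
                       today=dt.date(2015, 3, 2))
aunt = fp.add_individual(store, pack.id, "BM104", "F", dt.date(2010, 6, 1),
                         today=dt.date(2015, 3, 2))

start = dt.datetime(2015, 3, 2, 8, 0, tzinfo=TZ)
session = fp.start_visit(store, pack.id, start,
                         gps_source=lambda t: (-0.1917, 29.9000))
session.record_presence(af.id, True)
session.record_presence(am.id, True)
session.record_presence(yf.id, True)
session.record_presence(aunt.id, False)

session.record_weight(af.id, 1334, "morning")  # oops — meant 1234
session.record_pregnancy(af.id)
try:
    session.record_pregnancy(yf.id)  # present but only ~7 months old
except GatingError as exc:
    print(f"pregnancy gate: {exc}")
session.record_babysit(aunt.id, "inferred")  # absent -> inferred babysitter
session.skip_screen("escort")
session.end_visit(start + dt.timedelta(minutes=20))
print(f"visit closed with {len(session.gps_track())} GPS fixes "
      "(one at start, then every 3 minutes)")

# a focal follow with a 2-minute pause: wall time 22 min, still 20 scans
clock = SimulatedClock(start + dt.timedelta(hours=1))
follow = fp.start_focal(store, "oestrus-female", af.id, clock)
for minute in range(1, 21):
    if minute == 5:
        follow.pause()
        clock.advance(120)
        follow.resume()
    clock.advance(60)
    follow.record_scan(minute, am.id)
follow.complete()
wall = (clock.now() - follow.start_time).total_seconds() / 60
print(f"focal follow completed: {len(follow.scans())} scans, "
      f"wall clock {wall:.0f} min ({follow.paused_seconds():.0f}s paused)")

# review mode: fix the weight typo before syncing
records = fp.session_records(store, session.id)
weight = records["weight"][0]
fp.edit_record(store, weight.id, "grams", 1234)
print(f"weight corrected to {store.get_entity(weight.id).get('grams')} g; "
      f"{len(store.dirty_entries())} entries now wait for sync")
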