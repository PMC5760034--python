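"""Injectable clocks.

Timed protocols (group visits, focal-follow countdowns) never read the
wall clock directly: they take a clock object, so tests and simulations
can drive time deterministically while the CLI uses real time.
"""

from __future__ import annotations

import datetime as _dt


class SimulatedClock:
    """A clock that only moves when told to."""

    def __init__(self, start: _dt.datetime):
        if start.tzinfo is None:
            raise ValueError("simulated clock needs a timezone-aware start")
        self._now = start

    def now(self) -> _dt.datetime:
        return self._now

    def advance(self, seconds: float) -> _dt.datetime:
        if seconds < 0:
            raise ValueError("clocks do not run backwards")
        self._now = self._now + _dt.timedelta(seconds=seconds)
        return self._now


class WallClock:
    """Real time, always UTC with explicit offset."""

    def now(self) -> _dt.datetime:
        return _dt.datetime.now(_dt.timezone.utc)
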