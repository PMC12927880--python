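"""Request-spacing rate limiter for E-utilities compliance.

Two constraints are enforced jointly:

* spacing — consecutive granted slots are separated by at least
  ``min_interval`` (0.1 s by default);
* keyed ceiling — with an API key, at most ``ceiling`` grants fall inside
  any sliding 1-second window (10 by default).

``acquire_slot`` is a pure function over an explicit state and a caller-
supplied monotonic timestamp, so the schedule is testable on a simulated
clock; :class:`RateLimiter` is the thin thread-safe wrapper that sleeps.
"""

from __future__ import annotations

import threading
import time
from dataclasses import dataclass, field, replace

from .config import DEFAULT_KEYED_RPS_CEILING, DEFAULT_MIN_INTERVAL

_WINDOW = 1.0  # seconds


@dataclass(frozen=True)
class RateLimiterState:
    """Immutable limiter state: last grant plus the recent-grant window."""

    last_grant: float | None = None
    recent_grants: tuple[float, ...] = field(default_factory=tuple)


def acquire_slot(
    state: RateLimiterState,
    now: float,
    keyed: bool = False,
    min_interval: float = DEFAULT_MIN_INTERVAL,
    ceiling: int = DEFAULT_KEYED_RPS_CEILING,
) -> tuple[float, RateLimiterState]:
    """Return ``(wait, new_state)`` granting the earliest admissible slot.

    ``wait`` is the smallest non-negative delay such that the grant time
    ``now + wait`` honours the spacing constraint and, when ``keyed``, keeps
    at most ``ceiling`` grants in any trailing 1-second window.
    """
    grant = now
    if state.last_grant is not None:
        grant = max(grant, state.last_grant + min_interval)
    if keyed:
        window = [t for t in state.recent_grants if t > grant - _WINDOW]
        if len(window) >= ceiling:
            # earliest grant time at which the oldest blocking grant ages out
            grant = max(grant, window[-ceiling] + _WINDOW)
    recent = tuple(t for t in state.recent_grants if t > grant - _WINDOW) + (grant,)
    return grant - now, RateLimiterState(last_grant=grant, recent_grants=recent)


class RateLimiter:
    """Thread-safe wall-clock wrapper around :func:`acquire_slot`."""

    def __init__(
        self,
        min_interval: float = DEFAULT_MIN_INTERVAL,
        ceiling: int = DEFAULT_KEYED_RPS_CEILING,
        keyed: bool = False,
        clock=time.monotonic,
        sleep=time.sleep,
    ):
        self.min_interval = min_interval
        self.ceiling = ceiling
        self.keyed = keyed
        self._clock = clock
        self._sleep = sleep
        self._state = RateLimiterState()
        self._lock = threading.Lock()

    def wait_for_slot(self) -> float:
        """Block until a slot is granted; returns the wait that was applied."""
        with self._lock:
            wait, self._state = acquire_slot(
                self._state,
                self._clock(),
                keyed=self.keyed,
                min_interval=self.min_interval,
                ceiling=self.ceiling,
            )
        if wait > 0:
            self._sleep(wait)
        return wait
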