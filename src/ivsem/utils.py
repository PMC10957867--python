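"""Small shared helpers: seeding, hashing, interval estimation."""

from __future__ import annotations

import hashlib
import json
from typing import Iterable

import numpy as np


def spawn_seeds(seed: int | None, n: int) -> list[int]:
    """Derive ``n`` independent child seeds (< 2**31) from one master seed."""
    ss = np.random.SeedSequence(seed)
    return [int(s) for s in ss.generate_state(n) % (2**31 - 1)]


def config_hash(obj) -> str:
    """Stable short hash of a (dataclass-like or dict) configuration."""
    if hasattr(obj, "__dict__"):
        obj = vars(obj)
    payload = json.dumps(obj, sort_keys=True, default=str).encode()
    return hashlib.sha256(payload).hexdigest()[:16]


def hpd_interval(draws: Iterable[float], prob: float = 0.95) -> tuple[float, float]:
    """Highest-posterior-density interval via the shortest-sorted-interval rule.

    Scans every window containing ``ceil(prob * n)`` of the sorted draws and
    returns the narrowest one.  For unimodal posteriors this is the HPD
    interval; for skewed posteriors it is shorter than the central interval.
    A point mass collapses to a zero-width interval.
    """
    x = np.sort(np.asarray(draws, dtype=float).ravel())
    n = x.size
    if n == 0:
        raise ValueError("cannot compute an HPD interval from zero draws")
    if not 0 < prob < 1:
        raise ValueError(f"prob must be in (0, 1), got {prob}")
    k = int(np.ceil(prob * n))     # number of draws inside the interval
    if k >= n:
        return float(x[0]), float(x[-1])
    widths = x[k - 1:] - x[: n - k + 1]
    i = int(np.argmin(widths))
    return float(x[i]), float(x[i + k - 1])


def check_finite(name: str, value) -> None:
    arr = np.asarray(value, dtype=float)
    if not np.all(np.isfinite(arr)):
        raise ValueError(f"configuration field {name!r} must be finite, got {value!r}")
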