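"""Shared numeric helpers: bounded proportional scaling and exact integerization."""

from __future__ import annotations

import zlib

import numpy as np


class AllocationError(ValueError):
    """Target sum cannot be met inside the element bounds."""


def unit_rng(seed: int, unit_id: str) -> np.random.Generator:
    """Per-unit RNG stream, stable under processing order.

    Derived from the run seed and a CRC32 of the unit id so every unit gets an
    independent stream regardless of how many units run before it.
    """
    return np.random.default_rng(
        np.random.SeedSequence([int(seed), zlib.crc32(unit_id.encode())])
    )


def scale_to_sum(
    values: np.ndarray,
    free: np.ndarray,
    target: float,
    lo: np.ndarray | float = 0.0,
    hi: np.ndarray | float = np.inf,
    max_inner: int = 64,
) -> np.ndarray:
    """Proportionally rescale the ``free`` entries of ``values`` so the vector
    sums to ``target``, clamping to [lo, hi].

    Non-free (pinned) entries are untouched.  Entries that hit a bound are
    frozen and the remaining free entries rescaled, repeating until the sum is
    met or every free entry is clamped.  With no pinned entries and infinite
    bounds this is one multiplicative raking step.
    """
    v = np.asarray(values, dtype=float).copy()
    lo = np.broadcast_to(np.asarray(lo, dtype=float), v.shape)
    hi = np.broadcast_to(np.asarray(hi, dtype=float), v.shape)
    free = np.asarray(free, dtype=bool).copy()
    for _ in range(max_inner):
        resid = target - v[~free].sum()
        fsum = v[free].sum()
        if not free.any():
            break
        if fsum <= 0.0:
            # degenerate free mass: split the residual evenly
            v[free] = max(resid, 0.0) / free.sum()
        else:
            v[free] *= resid / fsum
        over = free & (v > hi)
        under = free & (v < lo)
        if not (over.any() or under.any()):
            break
        v[over] = hi[over]
        v[under] = lo[under]
        free &= ~(over | under)
    return v


def distribute_integer(
    values: np.ndarray,
    target: int,
    lo: np.ndarray | int = 0,
    hi: np.ndarray | int | None = None,
    adjustable: np.ndarray | None = None,
) -> np.ndarray:
    """Round ``values`` to integers summing exactly to ``target`` within bounds.

    Largest-remainder rounding on the adjustable entries followed by a
    correction pass that walks the residual one (or a bulk quotient) at a time
    into entries with headroom.  Entries outside ``adjustable`` are taken as
    already-integer pins.
    """
    v = np.asarray(values, dtype=float)
    n = v.size
    lo_a = np.broadcast_to(np.asarray(lo, dtype=np.int64), v.shape).copy()
    hi_a = (
        np.full(v.shape, np.iinfo(np.int64).max // 4, dtype=np.int64)
        if hi is None
        else np.broadcast_to(np.asarray(hi, dtype=np.int64), v.shape).copy()
    )
    adj = (
        np.ones(v.shape, dtype=bool)
        if adjustable is None
        else np.asarray(adjustable, dtype=bool)
    )
    x = np.clip(np.round(v), lo_a, hi_a).astype(np.int64)
    x[~adj] = np.round(v[~adj]).astype(np.int64)
    # pins cannot move: tighten their bounds to their value
    lo_a[~adj] = x[~adj]
    hi_a[~adj] = x[~adj]
    if lo_a.sum() > target or hi_a.sum() < target:
        raise AllocationError(
            "target %d outside feasible range [%d, %d]"
            % (target, lo_a.sum(), hi_a.sum())
        )
    frac = v - np.floor(v)
    while True:
        d = int(target - x.sum())
        if d == 0:
            return x
        if d > 0:
            room = hi_a - x
            open_ = room > 0
            n_open = int(open_.sum())
            q = d // n_open
            if q > 0:
                add = np.minimum(room, q)
                add[~open_] = 0
                x += add
            else:
                # hand out the last few to the largest fractional remainders
                idx = np.flatnonzero(open_)
                order = idx[np.argsort(-frac[idx], kind="stable")][:d]
                x[order] += 1
        else:
            room = x - lo_a
            open_ = room > 0
            n_open = int(open_.sum())
            q = (-d) // n_open
            if q > 0:
                sub = np.minimum(room, q)
                sub[~open_] = 0
                x -= sub
            else:
                idx = np.flatnonzero(open_)
                order = idx[np.argsort(frac[idx], kind="stable")][: -d]
                x[order] -= 1
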