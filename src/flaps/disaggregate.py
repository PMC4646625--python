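"""Downscale a unit's complete 7-bin population distribution to single farms.

For each size bin, farm populations are drawn i.i.d. from the uniform
distribution over the bin (a null distribution — nothing is assumed about the
within-bin structure beyond its bounds), then raked one-dimensionally against
the bin's population subtotal: the row is rescaled multiplicatively toward the
subtotal, values pushed past a bin bound are clamped and nudged back toward
the bin midpoint, and the loop repeats until the residual is below half an
animal.  A final largest-remainder integerization makes every bin sum — and
hence the unit total — exact for any seed.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from . import census as cs
from ._util import AllocationError, distribute_integer, unit_rng

__all__ = ["FarmDraft", "draw_initial", "fit_bin", "disaggregate_unit"]

#: raking iteration cap (shared with the missing-data model)
M_MAX = 2000
#: fraction of the bound-to-midpoint distance used when repairing out-of-bin values
REPAIR_STEP = 0.1


@dataclass(frozen=True)
class FarmDraft:
    """One simulated farm before placement: county, size bin, head count."""

    unit_id: str
    bin: int
    population: int


def draw_initial(n: int, a: float, b: float, rng: np.random.Generator) -> np.ndarray:
    """``n`` i.i.d. U(a, b) draws (degenerate at a when a == b)."""
    if b < a:
        raise ValueError("upper bound %s below lower bound %s" % (b, a))
    if n < 0:
        raise ValueError("negative count")
    return rng.uniform(a, b, size=n)


def fit_bin(
    values: np.ndarray, subtotal: int, a: int, b: int, m_max: int = M_MAX
) -> np.ndarray:
    """Rake ``values`` to sum exactly to ``subtotal`` while staying in [a, b].

    Returns integers.  Raises :class:`flaps._util.AllocationError` when the
    subtotal is infeasible for ``len(values)`` farms of this size class.
    """
    v = np.asarray(values, dtype=float).copy()
    n = v.size
    if n == 0:
        if subtotal != 0:
            raise AllocationError("no farms but subtotal %d" % subtotal)
        return np.zeros(0, dtype=np.int64)
    if not (n * a <= subtotal <= n * b):
        raise AllocationError(
            "subtotal %d infeasible for %d farms in [%d, %d]" % (subtotal, n, a, b)
        )
    mid = (a + b) / 2.0
    for _ in range(m_max):
        s = v.sum()
        if abs(s - subtotal) < 0.5:
            break
        v *= subtotal / s
        out = (v < a) | (v > b)
        if out.any():
            np.clip(v, a, b, out=v)
            v[out] += REPAIR_STEP * (mid - v[out])
    return distribute_integer(v, int(subtotal), int(a), int(b))


def disaggregate_unit(
    rec: cs.UnitRecord,
    seed: int,
    cap: Optional[int] = None,
) -> list[FarmDraft]:
    """Simulate individual farm populations for one complete unit.

    Emits one draft per farm; per-bin sums equal the unit's bin subtotals and
    the grand sum equals its population total, exactly, for every seed.  The
    top bin's draw ceiling is the unit's unknown population: its subtotal
    less the minimum head the bin's other farms must hold.
    """
    if not rec.complete:
        raise ValueError("unit %s still has redacted entries" % rec.unit_id)
    rng = unit_rng(seed, rec.unit_id)
    drafts: list[FarmDraft] = []
    for b in range(1, cs.N_BINS + 1):
        n = rec.farm_counts[b - 1]
        subtotal = int(rec.pop_cells[b - 1])
        if n == 0:
            continue
        lo, hi = cs.BIN_BOUNDS[b - 1]
        if hi is None:
            ceiling = subtotal - (n - 1) * lo
            if cap is not None:
                ceiling = min(ceiling, cap)
            hi = max(lo, ceiling)
        v = draw_initial(n, lo, hi, rng)
        pops = fit_bin(v, subtotal, lo, hi)
        drafts.extend(FarmDraft(rec.unit_id, b, int(p)) for p in pops)
    return drafts
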