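"""Attach geographic coordinates to disaggregated farms.

Placement matches each farm to a pixel whose occurrence probability resembles
a value drawn from the empirical pool of predicted probabilities at observed
presence locations — so simulated farms, like real ones, do not always sit on
the highest-probability pixels.  Larger farms are placed first and claim an
exclusion neighborhood (5×5 pixels for the unbounded top size class, 3×3 for
the intermediate classes, none for the smallest) that later farms must avoid.
Farms are confined to their own county's pixels; aggregate census data are
county-level, so crossing a county line would break reaggregation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from . import census as cs
from ._util import unit_rng
from .disaggregate import FarmDraft, disaggregate_unit
from .impute import impute_all
from .raster import ProbabilitySurface
from .sdm import AveragedModel

__all__ = [
    "FarmRecord",
    "PlacementError",
    "presence_probability_pool",
    "neighborhood",
    "place_farms",
    "run_flaps",
    "records_to_frame",
]

log = logging.getLogger(__name__)

#: starting probability-matching half-width, relative to the target value
DELTA0 = 0.01


class PlacementError(RuntimeError):
    """A county ran out of available pixels; carries the unplaced drafts."""

    def __init__(self, fips: str, unplaced: Sequence[FarmDraft]):
        self.fips = fips
        self.unplaced = list(unplaced)
        super().__init__(
            "county %s: no available pixels for %d farms" % (fips, len(unplaced))
        )


@dataclass(frozen=True)
class FarmRecord:
    """One simulated farm: location, size and commodity."""

    fips: str
    state: str
    lat: float
    lon: float
    population: int
    commodity: str = "swine"


def presence_probability_pool(
    model: AveragedModel, sample: pd.DataFrame
) -> np.ndarray:
    """Predicted probabilities at the observed presence points.

    Sampling placement targets from this pool reproduces the empirical spread
    of probabilities at which farms actually occur.
    """
    pres = sample[sample["y"] == 1]
    if pres.empty:
        raise ValueError("sample contains no presence points")
    return np.asarray(model.predict(pres), dtype=float)


def neighborhood(bin: int) -> int:
    """Exclusion half-width in pixels for a size bin.

    The top bin claims a 5×5 (25-pixel) window, the five intermediate bins a
    3×3 (9-pixel) window, and the smallest farms none beyond their own pixel.
    """
    if not 1 <= bin <= cs.N_BINS:
        raise ValueError("bin index out of range: %r" % bin)
    if bin == cs.N_BINS:
        return 2
    if bin == 1:
        return 0
    return 1


def _block_window(blocked: np.ndarray, row: int, col: int, half: int) -> None:
    nr, nc = blocked.shape
    blocked[
        max(0, row - half) : min(nr, row + half + 1),
        max(0, col - half) : min(nc, col + half + 1),
    ] = True


def place_farms(
    drafts: Sequence[FarmDraft],
    surf: ProbabilitySurface,
    pool: np.ndarray,
    rng: np.random.Generator,
    state_name: str = "",
    commodity: str = "swine",
    occupied: Optional[np.ndarray] = None,
    blocked: Optional[np.ndarray] = None,
) -> list[FarmRecord]:
    """Place one county's drafts on the surface, largest size class first.

    For each farm a target probability is drawn from ``pool`` and a pixel is
    chosen uniformly among the county's available pixels whose probability is
    within ±δ·target of the target (a multiplicative window — occurrence
    probabilities are typically log-skewed, so an additive window would swamp
    small targets), with δ doubling from 0.01 until candidates exist.  The
    chosen pixel and its exclusion window become unavailable.  When exclusion
    windows exhaust the county they are relaxed to single pixels before
    giving up.  ``occupied``/``blocked`` may be shared across counties so
    exclusion windows act across county borders.
    """
    if not drafts:
        return []
    fips = drafts[0].unit_id
    if any(d.unit_id != fips for d in drafts):
        raise ValueError("place_farms expects drafts from a single county")
    county_flat = surf.county_pixels(fips)
    probs = surf.grid.ravel()[county_flat]
    floor = max(1e-6 * (float(np.max(pool)) - float(np.min(pool))), 1e-300)
    if occupied is None:
        occupied = np.zeros(surf.shape, dtype=bool)
    if blocked is None:
        blocked = np.zeros(surf.shape, dtype=bool)
    # sorted-probability index over this county's pixels: candidate lookup is
    # a binary search instead of a full scan
    sort_idx = np.argsort(probs, kind="stable")
    sorted_p = probs[sort_idx]
    local_of = np.full(surf.grid.size, -1, dtype=np.int64)
    local_of[county_flat] = np.arange(county_flat.size)
    pos_of_local = np.empty(county_flat.size, dtype=np.int64)
    pos_of_local[sort_idx] = np.arange(county_flat.size)
    base = surf.available.ravel()[county_flat]
    occ_l = occupied.ravel()[county_flat]
    blk_l = blocked.ravel()[county_flat]
    avail_s = (base & ~occ_l & ~blk_l)[sort_idx]
    occfree_s = (base & ~occ_l)[sort_idx]
    n_avail = int(avail_s.sum())
    n_occfree = int(occfree_s.sum())

    order = sorted(
        range(len(drafts)),
        key=lambda i: (-drafts[i].bin, -drafts[i].population),
    )
    records: list[FarmRecord] = [None] * len(drafts)  # type: ignore[list-item]
    unplaced: list[FarmDraft] = []
    nr, nc = surf.shape
    for i in order:
        d = drafts[i]
        if n_avail > 0:
            mask_s, relaxed = avail_s, False
        elif n_occfree > 0:
            # relaxation ladder: ignore neighbors' windows, keep occupancy/mask
            mask_s, relaxed = occfree_s, True
        else:
            unplaced.append(d)
            continue
        target = float(rng.choice(pool))
        delta = DELTA0
        while True:
            w = delta * max(target, floor)
            lo, hi = np.searchsorted(sorted_p, [target - w, target + w])
            cand = lo + np.flatnonzero(mask_s[lo:hi])
            if cand.size:
                break
            delta *= 2.0
        pos = int(cand[rng.integers(cand.size)])
        local = int(sort_idx[pos])
        pick = int(county_flat[local])
        row, col = divmod(pick, nc)
        occupied[row, col] = True
        win = 0 if relaxed else neighborhood(d.bin)
        _block_window(blocked, row, col, win)
        # update the county-local sorted availability for the claimed window
        for r in range(max(0, row - win), min(nr, row + win + 1)):
            for c in range(max(0, col - win), min(nc, col + win + 1)):
                loc = local_of[r * nc + c]
                if loc >= 0:
                    p = pos_of_local[loc]
                    if avail_s[p]:
                        avail_s[p] = False
                        n_avail -= 1
        p = pos_of_local[local]
        if avail_s[p]:
            avail_s[p] = False
            n_avail -= 1
        if occfree_s[p]:
            occfree_s[p] = False
            n_occfree -= 1
        lon, lat = surf.transform.pixel_center(row, col)
        records[i] = FarmRecord(
            fips=fips, state=state_name, lat=float(lat), lon=float(lon),
            population=d.population, commodity=commodity,
        )
        if relaxed:
            log.info("county %s: exclusion window relaxed for bin-%d farm", fips, d.bin)
    if unplaced:
        raise PlacementError(fips, unplaced)
    return [r for r in records if r is not None]


def records_to_frame(records: Sequence[FarmRecord]) -> pd.DataFrame:
    """Output table with the standard field order."""
    return pd.DataFrame(
        [(r.fips, r.state, r.lat, r.lon, r.population, r.commodity) for r in records],
        columns=["fips", "state", "lat", "lon", "population", "commodity"],
    )


def run_flaps(
    table: cs.CensusTable,
    surf: ProbabilitySurface,
    model: AveragedModel,
    sample: pd.DataFrame,
    scope: str = "national",
    scope_id: Optional[str] = None,
    seed: int = 0,
    commodity: str = "swine",
    state_names: Optional[dict[str, str]] = None,
    cross_county_exclusion: bool = True,
):
    """Full pipeline: impute → disaggregate → place, for the requested scope.

    ``scope`` is ``national``, ``state`` or ``county`` (with ``scope_id``
    naming the state or county).  Returns (records, report) where the report
    is the farm→county reaggregation check of the imputed table.
    """
    from .verify import reaggregation_check  # local import: avoids a cycle

    bad = cs.validate(table)
    if bad:
        raise ValueError("input table invalid: %s" % "; ".join(map(str, bad[:5])))
    complete = impute_all(table)
    counties = complete.at_level(cs.Level.COUNTY)
    if scope == "state":
        counties = [c for c in counties if c.parent_id == scope_id]
    elif scope == "county":
        counties = [c for c in counties if c.unit_id == scope_id]
    elif scope != "national":
        raise ValueError("scope must be national, state or county")
    if not counties:
        raise ValueError("no counties in scope %s/%s" % (scope, scope_id))
    pool = presence_probability_pool(model, sample)
    occupied = np.zeros(surf.shape, dtype=bool)
    blocked = np.zeros(surf.shape, dtype=bool)
    records: list[FarmRecord] = []
    placed_totals: dict[str, float] = {}
    for county in sorted(counties, key=lambda c: c.unit_id):
        drafts = disaggregate_unit(county, seed)
        recs = place_farms(
            drafts, surf, pool, unit_rng(seed, "place:" + county.unit_id),
            state_name=(state_names or {}).get(county.parent_id or "", ""),
            commodity=commodity,
            occupied=occupied,
            blocked=blocked if cross_county_exclusion else np.zeros(surf.shape, bool),
        )
        records.extend(recs)
        placed_totals[county.unit_id] = float(sum(r.population for r in recs))
    report = reaggregation_check(
        fine=placed_totals,
        coarse={c.unit_id: float(c.pop_total) for c in counties},
        grouping={c.unit_id: c.unit_id for c in counties},
        level="county",
    )
    return records, report
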