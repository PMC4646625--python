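"""Generators for census tables, landscapes and presence/absence samples.

Every stage of the pipeline is testable without the real census extract or
covariate layers: the census generator emulates the publication rules of an
agricultural census (farm counts always public, population cells redacted for
small units plus complementary-suppression partners, hierarchy exactly
consistent), and the landscape generator builds smooth covariate fields with
a known true occurrence model so recovery can be checked against ground
truth.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Optional

import numpy as np
import pandas as pd

from . import census as cs
from .raster import GeoTransform, ProbabilitySurface
from .sdm import AveragedModel, builtin_swine_model

__all__ = ["SynthConfig", "Landscape", "make_census", "make_landscape", "sample_pa"]

#: plausible value ranges used to scale the smooth covariate fields
COVARIATE_RANGES: dict[str, tuple[float, float]] = {
    "dOpen": (0.0, 2000.0),      # m to nearest open area
    "dCrop": (0.0, 5000.0),      # m to nearest cropland
    "Temp": (0.0, 25.0),         # mean annual temperature, °C
    "dRoads": (0.0, 3000.0),     # m to nearest road
    "Slope": (0.0, 15.0),        # degrees
    "Precip": (100.0, 2000.0),   # mean annual precipitation, mm
    "dForest": (0.0, 10000.0),   # m to nearest upland forest
    "dUrban": (0.0, 50000.0),    # m to nearest high-intensity development
    "dWetland": (0.0, 20000.0),  # m to nearest lowland area
    "dBarren": (0.0, 50000.0),   # m to nearest barren land
}


@dataclass(frozen=True)
class SynthConfig:
    """Study conditions for the generators.

    The defaults emulate the published scenario: a hierarchy whose county
    population totals are redacted at roughly the 19% rate seen in the 2012
    swine census, a 10-covariate landscape, and a presence/absence sample of
    10,000 points at prevalence 0.14.
    """

    n_states: int = 10
    counties_per_state: int = 8
    #: mean farm count per county in each of the seven size bins
    bin_farm_means: tuple[float, ...] = (20.0, 2.0, 1.2, 0.8, 1.0, 1.0, 5.0)
    #: counties with fewer farms than this may have populations redacted
    redact_threshold: int = 25
    #: target fraction of county population totals redacted
    redact_fraction: float = 0.19
    #: fraction of states whose own totals are redacted
    redact_state_fraction: float = 0.1
    #: also redact bin cells with fewer farms than this (0 disables)
    redact_bin_threshold: int = 3
    landscape_shape: tuple[int, int] = (120, 160)
    true_model: Optional[AveragedModel] = None
    sample_size: int = 10000
    prevalence: float = 0.14
    mask_fraction: float = 0.1
    #: sd of unobserved per-pixel heterogeneity added to the true logit;
    #: keeps the landscape's discrimination "good, not excellent"
    logit_noise_sd: float = 3.5
    #: shift the true intercept so mean occurrence equals ``prevalence``
    calibrate_intercept: bool = True
    seed: int = 0

    def model(self) -> AveragedModel:
        return self.true_model if self.true_model is not None else builtin_swine_model()


# ---------------------------------------------------------------------------
# census generator


def _draw_unit_population(
    farm_counts: np.ndarray, rng: np.random.Generator
) -> tuple[int, ...]:
    cells = []
    for b, n in enumerate(farm_counts, start=1):
        if n == 0:
            cells.append(0)
            continue
        lo, hi = cs.BIN_BOUNDS[b - 1]
        if hi is None:
            # heavy-tailed sizes for the unbounded class
            sizes = np.minimum(
                (1000 * rng.pareto(2.5, size=n) + 1000).astype(np.int64), 200000
            )
            cells.append(int(sizes.sum()))
        else:
            cells.append(int(rng.integers(lo, hi + 1, size=n).sum()))
    return tuple(cells)


def _aggregate(children: list[cs.UnitRecord], unit_id, level, parent) -> cs.UnitRecord:
    fc = tuple(int(sum(c.farm_counts[b] for c in children)) for b in range(cs.N_BINS))
    pc = tuple(int(sum(c.pop_cells[b] for c in children)) for b in range(cs.N_BINS))
    return cs.UnitRecord(unit_id, level, parent, fc, pc, int(sum(pc)))


def make_census(cfg: SynthConfig) -> tuple[cs.CensusTable, cs.CensusTable]:
    """Simulate a (truth, observed) pair of hierarchically consistent tables.

    Farm counts are Poisson per county and bin; within-bin populations are
    sums of uniformly drawn farm sizes (heavy-tailed in the top bin); states
    and the nation are exact sums of their children.  The observed copy
    redacts population data for the smallest counties — up to the configured
    fraction — plus a complementary-suppression partner wherever a lone
    redacted county would otherwise be recoverable by subtraction, and bin
    cells whose farm counts are below the disclosure threshold.
    """
    rng = np.random.default_rng(cfg.seed)
    counties: list[cs.UnitRecord] = []
    states: list[cs.UnitRecord] = []
    means = np.asarray(cfg.bin_farm_means, dtype=float)
    for s in range(1, cfg.n_states + 1):
        sid = "%02d" % s
        kids = []
        for c in range(1, cfg.counties_per_state + 1):
            fid = "%02d%03d" % (s, c)
            fc = rng.poisson(means)
            if fc.sum() == 0:
                fc[0] = 1  # every county holds at least one farm
            pc = _draw_unit_population(fc, rng)
            kids.append(
                cs.UnitRecord(fid, cs.Level.COUNTY, sid, tuple(int(x) for x in fc),
                              pc, int(sum(pc)))
            )
        counties.extend(kids)
        states.append(_aggregate(kids, sid, cs.Level.STATE, "00"))
    national = _aggregate(states, "00", cs.Level.NATIONAL, None)
    truth = cs.CensusTable([national] + states + counties)

    observed_units: dict[str, cs.UnitRecord] = {u.unit_id: u for u in truth.units}
    if cfg.redact_fraction > 0:
        # county totals: smallest candidates first, until the target count
        target = int(round(cfg.redact_fraction * len(counties)))
        candidates = sorted(
            (c for c in counties if c.n_farms < cfg.redact_threshold or cfg.redact_fraction >= 1),
            key=lambda c: (c.n_farms, c.unit_id),
        )
        redacted: set[str] = set()
        for c in candidates:
            if len(redacted) >= target:
                break
            redacted.add(c.unit_id)
            # complementary suppression: a lone redacted sibling is recoverable
            sibs = [x for x in counties if x.parent_id == c.parent_id]
            red_sibs = [x for x in sibs if x.unit_id in redacted]
            if len(red_sibs) == 1 and len(sibs) > 1:
                partner = min(
                    (x for x in sibs if x.unit_id not in redacted),
                    key=lambda x: (x.n_farms, x.unit_id),
                )
                redacted.add(partner.unit_id)
        for uid in redacted:
            u = observed_units[uid]
            observed_units[uid] = replace(
                u,
                pop_cells=tuple(
                    cs.REDACTED if n > 0 else 0 for n in u.farm_counts
                ),
                pop_total=cs.REDACTED,
            )
        # bin-cell disclosure rule for the remaining counties
        if cfg.redact_bin_threshold > 0:
            for c in counties:
                if c.unit_id in redacted:
                    continue
                u = observed_units[c.unit_id]
                cells = tuple(
                    cs.REDACTED if 0 < n < cfg.redact_bin_threshold else v
                    for n, v in zip(u.farm_counts, u.pop_cells)
                )
                if cells != u.pop_cells:
                    observed_units[c.unit_id] = replace(u, pop_cells=cells)
        # state-level redaction (two-step imputation exercise)
        n_red_states = int(round(cfg.redact_state_fraction * len(states)))
        for st in sorted(states, key=lambda x: (x.n_farms, x.unit_id))[:n_red_states]:
            u = observed_units[st.unit_id]
            observed_units[st.unit_id] = replace(
                u,
                pop_cells=tuple(
                    cs.REDACTED if n > 0 else 0 for n in u.farm_counts
                ),
                pop_total=cs.REDACTED,
            )
    observed = cs.CensusTable(
        [observed_units[u.unit_id] for u in truth.units], schema=truth.schema
    )
    return truth, observed


# ---------------------------------------------------------------------------
# landscape generator


def _smooth_field(
    shape: tuple[int, int], rng: np.random.Generator, n_waves: int = 6
) -> np.ndarray:
    """Seeded low-frequency cosine mixture scaled to [0, 1].

    f(r, c) = Σ_k a_k · cos(2π(u_k·r/R + v_k·c/C) + φ_k) with |u|,|v| ≤ 3,
    then min-max normalized — smooth, anisotropic, reproducible.
    """
    R, C = shape
    rr, cc = np.meshgrid(np.arange(R), np.arange(C), indexing="ij")
    f = np.zeros(shape)
    for _ in range(n_waves):
        u, v = rng.uniform(-3, 3, size=2)
        amp = rng.uniform(0.3, 1.0)
        phase = rng.uniform(0, 2 * np.pi)
        f += amp * np.cos(2 * np.pi * (u * rr / R + v * cc / C) + phase)
    f -= f.min()
    if f.max() > 0:
        f /= f.max()
    return f


@dataclass
class Landscape:
    """Synthetic covariate stack with known true occurrence surface."""

    covariates: dict[str, np.ndarray]
    mask: np.ndarray  # True = excluded (urban / water analog)
    surface: ProbabilitySurface  # truth: inverse-logit of the true model
    transform: GeoTransform


def _county_index(
    shape: tuple[int, int], county_fips: list[str]
) -> np.ndarray:
    """Tile the grid into contiguous rectangles, one per county."""
    n = len(county_fips)
    nrows_c = int(np.floor(np.sqrt(n)))
    ncols_c = int(np.ceil(n / nrows_c))
    R, C = shape
    idx = np.full(shape, -1, dtype=np.int32)
    r_edges = np.linspace(0, R, nrows_c + 1).astype(int)
    c_edges = np.linspace(0, C, ncols_c + 1).astype(int)
    k = 0
    for i in range(nrows_c):
        for j in range(ncols_c):
            if k >= n:
                break
            idx[r_edges[i]:r_edges[i + 1], c_edges[j]:c_edges[j + 1]] = k
            k += 1
    # leftover pixels (when n doesn't tile evenly) go to the last county
    idx[idx == -1] = n - 1
    return idx


def make_landscape(
    cfg: SynthConfig, county_fips: Optional[list[str]] = None
) -> Landscape:
    """Smooth covariate rasters, an exclusion mask, and the true surface.

    The true occurrence logit is the model applied to the covariates plus
    optional unobserved heterogeneity (white noise on the logit scale), with
    the intercept optionally re-centered so the landscape-mean occurrence
    probability equals the configured prevalence — real farms occur across a
    wide spread of predicted probabilities, and a noiseless smooth landscape
    would be unrealistically easy to discriminate.
    """
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 0x1A5D]))
    model = cfg.model()
    shape = cfg.landscape_shape
    covs: dict[str, np.ndarray] = {}
    for name in model.term_forms:
        lo, hi = COVARIATE_RANGES.get(name, (0.0, 1.0))
        covs[name] = lo + (hi - lo) * _smooth_field(shape, rng)
    mask_field = _smooth_field(shape, rng)
    if cfg.mask_fraction <= 0:
        mask = np.zeros(shape, dtype=bool)
    elif cfg.mask_fraction >= 1:
        mask = np.ones(shape, dtype=bool)
    else:
        mask = mask_field < np.quantile(mask_field, cfg.mask_fraction)
    gt = GeoTransform(x0=-100.0, y0=45.0, dx=0.001, dy=0.001)
    if county_fips is None:
        county_fips = [
            "%02d%03d" % (s, c)
            for s in range(1, cfg.n_states + 1)
            for c in range(1, cfg.counties_per_state + 1)
        ]
    eta = model.logit(covs)
    if cfg.logit_noise_sd > 0:
        eta = eta + rng.normal(0.0, cfg.logit_noise_sd, size=shape)
    if cfg.calibrate_intercept:
        from scipy.optimize import brentq

        eta = eta + brentq(
            lambda s: (1.0 / (1.0 + np.exp(-(eta + s)))).mean() - cfg.prevalence,
            -50.0, 50.0,
        )
    surface = ProbabilitySurface(
        grid=1.0 / (1.0 + np.exp(-eta)),
        available=~mask,
        transform=gt,
        county_index=_county_index(shape, county_fips),
        county_fips=list(county_fips),
    )
    return Landscape(covariates=covs, mask=mask, surface=surface, transform=gt)


# ---------------------------------------------------------------------------
# presence/absence sampling


def sample_pa(
    cfg: SynthConfig,
    landscape: Landscape,
    census: Optional[cs.CensusTable] = None,
) -> pd.DataFrame:
    """Weighted presence/absence sample with labels from the true surface.

    Points are allocated to counties in proportion to their farm counts
    (uniform when no census is given), pixels drawn uniformly within each
    county, labels Bernoulli(true probability), and the sample is then
    thinned/augmented by class to hit the target prevalence at the target
    size.  Columns: y, the covariates, county.
    """
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 0x9A]))
    surf = landscape.surface
    fips = surf.county_fips
    if census is not None:
        weights = np.array(
            [census[f].n_farms if f in census else 0.0 for f in fips], dtype=float
        )
    else:
        weights = np.ones(len(fips))
    if weights.sum() == 0:
        weights[:] = 1.0
    weights /= weights.sum()
    n_target = cfg.sample_size
    want_pres = int(round(cfg.prevalence * n_target))
    want_abs = n_target - want_pres
    pres_rows, abs_rows = [], []
    flat_prob = surf.grid.ravel()
    county_flat = {f: surf.county_pixels(f) for f in fips}
    # draw in batches until both classes are filled (bounded effort)
    for _ in range(200):
        if len(pres_rows) >= want_pres and len(abs_rows) >= want_abs:
            break
        batch = max(n_target, 1000)
        cty = rng.choice(len(fips), size=batch, p=weights)
        for ci in np.bincount(cty, minlength=len(fips)).nonzero()[0]:
            k = int((cty == ci).sum())
            pixels = county_flat[fips[ci]]
            if pixels.size == 0:
                continue
            picks = pixels[rng.integers(pixels.size, size=k)]
            p = flat_prob[picks]
            y = rng.uniform(size=k) < p
            for pick, yi in zip(picks, y):
                row = (int(pick), fips[ci])
                (pres_rows if yi else abs_rows).append(row)
    pres_rows = pres_rows[:want_pres]
    abs_rows = abs_rows[:want_abs]
    rows = pres_rows + abs_rows
    labels = np.array([1] * len(pres_rows) + [0] * len(abs_rows))
    order = rng.permutation(len(rows))
    nc = surf.shape[1]
    data = {"y": labels[order]}
    picks = np.array([rows[i][0] for i in order])
    rr, ccol = np.divmod(picks, nc)
    for name, grid in landscape.covariates.items():
        data[name] = grid[rr, ccol]
    data["county"] = [rows[i][1] for i in order]
    return pd.DataFrame(data)
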