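"""Missing-data model: hierarchical iterative proportional fitting (raking).

Redacted population cells are seeded at bin midpoints (farm count × midpoint
farm size), redacted totals as the sum of their seeded cells.  Each parent
unit then defines a two-way matrix — rows are its children, columns the seven
size bins — whose marginals are the child population totals (Q_i) and the
parent's bin subtotals (Q_j).  Alternating row/column rescaling adjusts the
seeded cells until the marginal discrepancies vanish; published cells are hard
constraints, re-pinned on every pass, so the discrepancy is absorbed
proportionally by the seeded cells alone.  The hierarchy is handled in two
steps: states are completed against the national distribution, then counties
against the completed states.  Imputation is deterministic.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np

from . import census as cs
from ._util import distribute_integer, scale_to_sum

__all__ = ["IpfMatrix", "seed_cell", "ipf_fit", "impute_level", "impute_all"]

log = logging.getLogger(__name__)

#: iteration cap for the raking loop
M_MAX = 2000
#: convergence tolerance on marginal discrepancies, in animals
DEFAULT_TOL = 0.5


def seed_cell(rec: cs.UnitRecord, b: int, cap: Optional[int] = None) -> float:
    """Midpoint seed for redacted bin ``b`` of ``rec``.

    ``n_b × (lower + upper)/2`` for the bounded bins; the unbounded top bin is
    seeded at the midpoint of [1000·n_b, cap] and clamped into its feasible
    range.  An empty bin is forced to 0.
    """
    n = rec.farm_counts[b - 1]
    if n == 0:
        return 0.0
    lo, hi = cs.BIN_BOUNDS[b - 1]
    if hi is not None:
        return n * (lo + hi) / 2.0
    bmin, bmax = cs.cell_bounds(rec, b, cap)
    return float(min(max((bmin + bmax) / 2.0, bmin), bmax))


def seed_total(rec: cs.UnitRecord, cap: Optional[int] = None) -> float:
    """Seed for a redacted population total: sum of published or seeded cells."""
    s = 0.0
    for b in range(1, cs.N_BINS + 1):
        c = rec.pop_cells[b - 1]
        s += seed_cell(rec, b, cap) if c is cs.REDACTED else c
    return s


@dataclass
class IpfMatrix:
    """Two-way raking problem for one parent unit.

    ``seeded`` marks cells free to move; ``seeded_rows`` marks row marginals
    that were themselves imputed.  ``lo``/``hi`` are the per-cell feasibility
    bounds derived from the published farm counts.
    """

    p: np.ndarray
    Q_i: np.ndarray
    Q_j: np.ndarray
    seeded: np.ndarray
    lo: np.ndarray
    hi: np.ndarray
    seeded_rows: np.ndarray | None = None
    row_ids: list[str] = field(default_factory=list)
    m_max: int = M_MAX
    k: int = 0
    converged: bool = False

    def discrepancy(self) -> float:
        """Max absolute marginal mismatch (the convergence statistic)."""
        dr = np.abs(self.p.sum(axis=1) - self.Q_i).max() if self.p.size else 0.0
        dc = np.abs(self.p.sum(axis=0) - self.Q_j).max() if self.p.size else 0.0
        return float(max(dr, dc))


class IpfInfeasibleError(ValueError):
    """Marginals cannot be met: inconsistent totals or no seeded cell to move."""


def ipf_fit(M: IpfMatrix, tol: float = DEFAULT_TOL) -> IpfMatrix:
    """Rake ``M`` until every marginal discrepancy is ≤ ``tol`` or ``m_max``.

    Each iteration rescales rows to Q_i then columns to Q_j.  Published cells
    never move; after each multiplicative pass they are restored and the
    residual re-absorbed by the row's (or column's) seeded cells, clamped to
    their bounds.  With every cell seeded and infinite bounds this reduces to
    classical iterative proportional fitting.
    """
    if abs(M.Q_i.sum() - M.Q_j.sum()) > max(tol, 1e-6 * max(M.Q_j.sum(), 1.0)):
        raise IpfInfeasibleError(
            "marginals inconsistent: sum(Q_i)=%s != sum(Q_j)=%s"
            % (M.Q_i.sum(), M.Q_j.sum())
        )
    p = M.p.astype(float).copy()
    nr, nc = p.shape
    for i in range(nr):
        if not M.seeded[i].any() and abs(p[i].sum() - M.Q_i[i]) > tol:
            raise IpfInfeasibleError(
                "row %s discrepant but fully published"
                % (M.row_ids[i] if M.row_ids else i)
            )
    k = 0
    converged = False
    # stop early when the discrepancy plateaus (pinned integer marginals can
    # leave an irreducible 1-2 animal mismatch that no iteration removes)
    best = np.inf
    stall = 0
    eps = max(1e-12 * float(M.Q_j.sum()), 1e-12)
    while k < M.m_max:
        k += 1
        for i in range(nr):
            p[i] = scale_to_sum(p[i], M.seeded[i], M.Q_i[i], M.lo[i], M.hi[i])
        for j in range(nc):
            p[:, j] = scale_to_sum(
                p[:, j], M.seeded[:, j], M.Q_j[j], M.lo[:, j], M.hi[:, j]
            )
        disc = replace(M, p=p, k=k).discrepancy()
        if disc <= tol:
            converged = True
            break
        if disc < best - eps:
            best = disc
            stall = 0
        else:
            stall += 1
            if stall >= 50:
                break
    return replace(M, p=p, k=k, converged=converged)


def _build_matrix(
    table: cs.CensusTable, parent: cs.UnitRecord, children: list[cs.UnitRecord]
) -> IpfMatrix:
    if not parent.complete:
        raise IpfInfeasibleError("parent %s is not complete" % parent.unit_id)
    nr, nc = len(children), cs.N_BINS
    p = np.zeros((nr, nc))
    seeded = np.zeros((nr, nc), dtype=bool)
    lo = np.zeros((nr, nc))
    hi = np.zeros((nr, nc))
    Q_i = np.zeros(nr)
    seeded_rows = np.zeros(nr, dtype=bool)
    for i, ch in enumerate(children):
        cap = ch.pop_total if ch.pop_total is not cs.REDACTED else parent.pop_total
        for b in range(1, nc + 1):
            bmin, bmax = cs.cell_bounds(ch, b, cap)
            lo[i, b - 1], hi[i, b - 1] = bmin, bmax
            cell = ch.pop_cells[b - 1]
            if cell is cs.REDACTED:
                p[i, b - 1] = seed_cell(ch, b, cap)
                seeded[i, b - 1] = ch.farm_counts[b - 1] > 0
            else:
                p[i, b - 1] = cell
                lo[i, b - 1] = hi[i, b - 1] = cell
        if ch.pop_total is cs.REDACTED:
            Q_i[i] = p[i].sum()
            seeded_rows[i] = True
        else:
            Q_i[i] = ch.pop_total
    Q_j = np.array(parent.pop_cells, dtype=float)
    # reconcile seeded row totals so the hierarchy identity holds exactly
    target = float(parent.pop_total)
    pub_sum = Q_i[~seeded_rows].sum()
    if pub_sum > target + 1e-9:
        raise IpfInfeasibleError(
            "published children of %s exceed the parent total" % parent.unit_id
        )
    if seeded_rows.any():
        row_lo = lo.sum(axis=1)
        row_hi = hi.sum(axis=1)
        Q_i = scale_to_sum(Q_i, seeded_rows, target, row_lo, row_hi)
        Q_i = distribute_integer(
            Q_i, int(round(target)), row_lo.astype(np.int64),
            row_hi.astype(np.int64), adjustable=seeded_rows,
        ).astype(float)
    elif abs(Q_i.sum() - target) > 1e-9:
        raise IpfInfeasibleError(
            "children of %s are fully published but do not sum to its total"
            % parent.unit_id
        )
    return IpfMatrix(
        p=p, Q_i=Q_i, Q_j=Q_j, seeded=seeded, lo=lo, hi=hi,
        seeded_rows=seeded_rows, row_ids=[c.unit_id for c in children],
    )


def impute_level(
    table: cs.CensusTable, child_level: cs.Level, tol: float = DEFAULT_TOL
) -> cs.CensusTable:
    """Complete every unit at ``child_level`` against its (complete) parent.

    Builds one raking matrix per parent, fits it, clamps imputed cells into
    their feasibility bounds, and writes back integers that reproduce each
    child's total exactly (largest-remainder rounding confined to seeded
    cells).  Fully published families pass through unchanged.
    """
    parent_level = {cs.Level.STATE: cs.Level.NATIONAL, cs.Level.COUNTY: cs.Level.STATE}[
        child_level
    ]
    new_units: list[cs.UnitRecord] = []
    for parent in table.at_level(parent_level):
        children = table.children(parent.unit_id)
        if not children:
            continue
        if all(ch.complete for ch in children):
            continue
        M = _build_matrix(table, parent, children)
        M = ipf_fit(M, tol=tol)
        if not M.converged:
            # a few animals of column mismatch is the expected rounding floor;
            # anything larger deserves attention
            emit = log.warning if M.discrepancy() > 5 else log.debug
            emit(
                "parent %s: raking stopped at k=%d with discrepancy %.3g",
                parent.unit_id, M.k, M.discrepancy(),
            )
        for i, ch in enumerate(children):
            if ch.complete:
                continue
            row = distribute_integer(
                M.p[i], int(round(M.Q_i[i])),
                M.lo[i].astype(np.int64), M.hi[i].astype(np.int64),
                adjustable=M.seeded[i],
            )
            new_units.append(
                replace(
                    ch,
                    pop_cells=tuple(int(v) for v in row),
                    pop_total=int(round(M.Q_i[i])),
                )
            )
        log.info("parent %s: k=%d discrepancy=%.3g", parent.unit_id, M.k,
                 M.discrepancy())
    return table.with_units(new_units)


def impute_all(table: cs.CensusTable, tol: float = DEFAULT_TOL) -> cs.CensusTable:
    """Two-step hierarchical imputation: states first, then counties.

    Requires published national totals.  The result has no redacted entries
    and satisfies every structural invariant of :func:`flaps.census.validate`.
    """
    nat = table.national
    if not nat.complete:
        raise IpfInfeasibleError("national totals must be published")
    out = impute_level(table, cs.Level.STATE, tol=tol)
    out = impute_level(out, cs.Level.COUNTY, tol=tol)
    return out
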