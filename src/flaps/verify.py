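"""Verification analyses: reaggregation, substitution, absolute percent difference.

Spatial microsimulation output rarely has external validation data, so the
model is verified internally: re-sum the fine-grained output and compare it to
the aggregate inputs it was derived from (reaggregation), and re-impute under
freshly randomized redaction patterns to show the imputation does not depend
on which cells happen to be missing (substitution).  Both use the absolute
percent difference, APD = 100·|estimate − reference|/reference.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional

import numpy as np
import pandas as pd

from . import census as cs
from .impute import impute_all

__all__ = ["apd", "VerificationReport", "reaggregation_check", "substitution_check"]


def apd(estimate: float, reference: float) -> float:
    """Absolute percent difference; 0/0 is 0 by convention, x/0 is NaN (undefined)."""
    if estimate < 0 or reference < 0:
        raise ValueError("APD is defined for non-negative quantities")
    if reference == 0:
        return 0.0 if estimate == 0 else float("nan")
    return 100.0 * abs(estimate - reference) / reference


@dataclass
class VerificationReport:
    """Per-unit APD values with per-level/iteration summaries."""

    per_unit: pd.DataFrame  # columns: unit_id, level, apd (NaN = undefined)
    iterations: int = 1
    seed: Optional[int] = None
    iteration_means: list[float] = field(default_factory=list)

    @property
    def n_undefined(self) -> int:
        return int(self.per_unit["apd"].isna().sum())

    @property
    def mean_apd(self) -> float:
        """Mean APD over defined units (single run) or over iterations."""
        if self.iteration_means:
            return float(np.mean(self.iteration_means))
        return float(self.per_unit["apd"].mean())

    @property
    def se_apd(self) -> float:
        """Standard error over iterations (NaN for a single run)."""
        if len(self.iteration_means) > 1:
            return float(
                np.std(self.iteration_means, ddof=1) / np.sqrt(len(self.iteration_means))
            )
        return float("nan")

    def summary(self) -> str:
        lines = [
            "units: %d (undefined APD: %d)" % (len(self.per_unit), self.n_undefined),
            "mean APD: %.4f%%" % self.mean_apd,
        ]
        if len(self.iteration_means) > 1:
            lines.append(
                "iterations: %d, SE: %.4f%%" % (self.iterations, self.se_apd)
            )
        return "\n".join(lines)

    def to_csv(self, path) -> None:
        self.per_unit.to_csv(path, index=False)


def reaggregation_check(
    fine: Mapping[str, float],
    coarse: Mapping[str, float],
    grouping: Mapping[str, str],
    level: str = "",
) -> VerificationReport:
    """Sum fine-level values into their groups and APD them against references.

    ``grouping`` maps every fine unit id to a coarse unit id; an unmapped fine
    unit is an error.
    """
    sums: dict[str, float] = {k: 0.0 for k in coarse}
    for unit, value in fine.items():
        if unit not in grouping:
            raise KeyError("fine unit %s has no group" % unit)
        g = grouping[unit]
        if g not in sums:
            raise KeyError("group %s of unit %s has no reference total" % (g, unit))
        sums[g] += value
    rows = [
        {"unit_id": g, "level": level, "apd": apd(sums[g], coarse[g])} for g in coarse
    ]
    return VerificationReport(per_unit=pd.DataFrame(rows))


def _redactable_cells(table: cs.CensusTable) -> list[tuple[str, int]]:
    """(unit_id, slot) pairs eligible for substitution redaction.

    Slots 1..7 are population bin cells, 0 the population total; national
    values are never redacted.  Empty bins are excluded (their zero is forced
    by the farm count, so redacting them carries no information).
    """
    out = []
    for u in table.units:
        if u.level is cs.Level.NATIONAL:
            continue
        out.append((u.unit_id, 0))
        out.extend(
            (u.unit_id, b) for b in range(1, cs.N_BINS + 1) if u.farm_counts[b - 1] > 0
        )
    return out


def _redact(table: cs.CensusTable, picks: list[tuple[str, int]]) -> cs.CensusTable:
    from dataclasses import replace

    by_unit: dict[str, set[int]] = {}
    for uid, slot in picks:
        by_unit.setdefault(uid, set()).add(slot)
    new_units = []
    for uid, slots in by_unit.items():
        u = table[uid]
        cells = list(u.pop_cells)
        for s in slots:
            if s > 0:
                cells[s - 1] = cs.REDACTED
        total = cs.REDACTED if 0 in slots else u.pop_total
        new_units.append(replace(u, pop_cells=tuple(cells), pop_total=total))
    return table.with_units(new_units)


def substitution_check(
    completed: cs.CensusTable,
    k: int,
    iters: int = 100,
    seed: int = 0,
    max_redraws: int = 20,
) -> VerificationReport:
    """Re-impute under ``iters`` random redaction patterns of ``k`` cells each.

    Each iteration redacts ``k`` randomly chosen published population values
    (bin cells or totals, never national), re-runs the full imputation, and
    measures the APD of the recovered state totals against the originals.  An
    infeasible pattern is redrawn with a logged retry.  Similar mean APD
    across patterns shows the imputation is insensitive to which cells are
    missing.
    """
    if any(not u.complete for u in completed.units):
        raise ValueError("substitution requires a fully published table")
    rng = np.random.default_rng(seed)
    cells = _redactable_cells(completed)
    originals = {
        u.unit_id: u.pop_total for u in completed.at_level(cs.Level.STATE)
    }
    rows = []
    iter_means = []
    for it in range(iters):
        for _ in range(max_redraws):
            idx = rng.choice(len(cells), size=min(k, len(cells)), replace=False)
            picks = [cells[i] for i in idx]
            try:
                recovered = impute_all(_redact(completed, picks))
                break
            except Exception:
                continue
        else:
            raise RuntimeError("iteration %d: no feasible redaction draw" % it)
        vals = []
        for sid, ref in originals.items():
            a = apd(float(recovered[sid].pop_total), float(ref))
            rows.append({"unit_id": sid, "level": "state", "apd": a, "iteration": it})
            if not np.isnan(a):
                vals.append(a)
        iter_means.append(float(np.mean(vals)) if vals else 0.0)
    return VerificationReport(
        per_unit=pd.DataFrame(rows),
        iterations=iters,
        seed=seed,
        iteration_means=iter_means,
    )
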