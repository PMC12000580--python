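"""Centriole inheritance through spermatogonial cyst divisions.

A goniablast carrying one engaged centriole pair undergoes four symmetric
mitoses, producing a 16-cell spermatogonial cyst.  In each division the
centrioles duplicate (count doubles) and are then segregated as evenly as
possible between the daughters.  If duplication fails from some stage of
the cyst onward ("failure onset"), the remaining divisions merely dilute
the existing centrioles.  The model predicts the per-cell centriole-count
distribution in the final cyst and fits, by maximum multinomial
likelihood, the fraction ``f`` of final cells descending from cells that
already failed at the 4-cell stage (the rest failing at the 8-cell
stage) from an observed 0C/1C count table.

With even segregation the two informative scenarios are exact:
failure from the 8-cell stage gives 16 cells with one centriole each
(all 1C); a 4-cell-stage failure gives, among the 4 descendants of each
failing cell, two with one centriole and two with none.  Hence the
mixture distribution is ``P(0C) = f/2`` and ``P(1C) = 1 - f/2``.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Dict, List, Mapping, Tuple

import numpy as np
from scipy.optimize import minimize_scalar

logger = logging.getLogger(__name__)

__all__ = [
    "CellState",
    "LineageOutcome",
    "MixtureFit",
    "divide",
    "simulate_cyst",
    "predict_distribution",
    "fit_failure_mixture",
]

CLASSES = ("0C", "1C", "2C", "3C", "4C")
FAILURE_ONSETS = ("none", "stage4", "stage8")

# generation g holds 2**g cells: 0 = goniablast, 2 = 4-cell stage,
# 3 = 8-cell stage, 4 = 16-cell cyst
_ONSET_GENERATION = {"none": math.inf, "stage4": 2, "stage8": 3}


@dataclass(frozen=True)
class CellState:
    """A germ cell with its centriole count and cyst generation."""

    centriole_count: int
    generation: int = 0

    def __post_init__(self) -> None:
        if self.centriole_count < 0:
            raise ValueError("centriole_count must be >= 0")


@dataclass
class LineageOutcome:
    """Centriole-count distribution across the final cells of one cyst."""

    counts: Dict[str, int]
    scenario: str
    premeiotic_duplication: bool
    n_cells: int

    def __post_init__(self) -> None:
        if sum(self.counts.values()) != self.n_cells:
            raise ValueError("class counts must sum to the number of final cells")


@dataclass
class MixtureFit:
    """Maximum-likelihood fit of the 4-cell-stage failure fraction."""

    f_hat: float
    f_closed_form: float
    loglik: float
    predicted: Dict[str, float]
    observed: Dict[str, int]
    n_excluded: int = 0


def divide(cell: CellState, duplication_active: bool) -> Tuple[CellState, CellState]:
    """One mitosis: optional duplication, then even segregation.

    If duplication is active the centriole count doubles before
    segregation; segregation splits the count as evenly as possible
    (ceil(n/2), floor(n/2)).
    """
    n = cell.centriole_count * (2 if duplication_active else 1)
    g = cell.generation + 1
    return CellState(math.ceil(n / 2), g), CellState(n // 2, g)


def simulate_cyst(
    failure_onset: str = "none", premeiotic_duplication: bool = True
) -> LineageOutcome:
    """Deterministic cyst outcome under a duplication-failure scenario.

    Starts from one goniablast with 2 centrioles and applies four rounds
    of :func:`divide`; duplication is active for divisions of cells in
    generations before the failure onset (stage4 = 4-cell stage =
    generation 2) and inactive from it onward.  If there is no failure and
    ``premeiotic_duplication`` is set, each final cell duplicates its
    centrioles once more (pre-meiotic S phase, the spermatocyte state).
    """
    if failure_onset not in FAILURE_ONSETS:
        raise ValueError(f"unknown failure onset {failure_onset!r}")
    onset_gen = _ONSET_GENERATION[failure_onset]
    cells: List[CellState] = [CellState(2, generation=0)]
    for _ in range(4):
        next_gen: List[CellState] = []
        for cell in cells:
            active = cell.generation < onset_gen
            next_gen.extend(divide(cell, duplication_active=active))
        cells = next_gen
    counts = [c.centriole_count for c in cells]
    if premeiotic_duplication and failure_onset == "none":
        counts = [2 * c for c in counts]
    table = {cls: 0 for cls in CLASSES}
    for c in counts:
        key = f"{c}C"
        if key not in table:
            raise RuntimeError(f"unexpected centriole count {c}")
        table[key] += 1
    return LineageOutcome(
        counts=table,
        scenario=failure_onset,
        premeiotic_duplication=premeiotic_duplication,
        n_cells=len(counts),
    )


def predict_distribution(f: float) -> Dict[str, float]:
    """Mixture distribution of per-cell counts for failure fraction ``f``.

    A fraction ``f`` of final cells descends from 4-cell-stage failures
    (half 0C, half 1C among their descendants) and ``1 - f`` from
    8-cell-stage failures (all 1C): ``P(0C) = f/2``, ``P(1C) = 1 - f/2``.
    """
    if not 0 <= f <= 1:
        raise ValueError("f must be in [0, 1]")
    return {"0C": f / 2.0, "1C": 1.0 - f / 2.0}


def _loglik(f: float, n0: int, n1: int) -> float:
    p0 = f / 2.0
    p1 = 1.0 - p0
    ll = 0.0
    if n0:
        ll += n0 * (math.log(p0) if p0 > 0 else -math.inf)
    if n1:
        ll += n1 * (math.log(p1) if p1 > 0 else -math.inf)
    return ll


def fit_failure_mixture(observed: Mapping[str, int]) -> MixtureFit:
    """Fit the 4-cell-stage failure fraction to an observed count table.

    Only the 0C and 1C classes enter the likelihood; other classes are
    logged and excluded (a tolerated residual, e.g. escaper pairs).  The
    maximizer is located by a coarse grid over [0, 1] followed by
    bounded golden-section refinement; the closed form
    ``f_hat = 2 * n0 / (n0 + n1)`` is reported alongside as a check.
    """
    if not observed:
        raise ValueError("observed table is empty")
    clean = {k: int(v) for k, v in observed.items()}
    if any(v < 0 for v in clean.values()):
        raise ValueError("counts must be non-negative")
    n0 = clean.get("0C", 0)
    n1 = clean.get("1C", 0)
    excluded = sum(v for k, v in clean.items() if k not in ("0C", "1C"))
    if excluded:
        logger.warning("excluding %d cells outside the 0C/1C classes", excluded)
    if n0 + n1 == 0:
        raise ValueError("no cells in the 0C/1C classes")

    grid = np.linspace(0.0, 1.0, 201)
    lls = np.array([_loglik(f, n0, n1) for f in grid])
    i = int(np.argmax(lls))
    lo = grid[max(i - 1, 0)]
    hi = grid[min(i + 1, grid.size - 1)]
    if lo == hi:
        f_hat = float(grid[i])
    else:
        res = minimize_scalar(
            lambda f: -_loglik(f, n0, n1), bounds=(lo, hi), method="bounded",
            options={"xatol": 1e-10},
        )
        f_hat = float(np.clip(res.x, 0.0, 1.0))
        if _loglik(f_hat, n0, n1) < lls[i]:
            f_hat = float(grid[i])
    f_closed = min(1.0, 2.0 * n0 / (n0 + n1))
    return MixtureFit(
        f_hat=f_hat,
        f_closed_form=f_closed,
        loglik=_loglik(f_hat, n0, n1),
        predicted=predict_distribution(f_hat),
        observed={"0C": n0, "1C": n1},
        n_excluded=excluded,
    )
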