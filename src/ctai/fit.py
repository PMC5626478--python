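"""Fitting wobble pairing penalties against construct expression data.

Construct expression (relative mRNA level, reference = 1) is regressed on the
region ctAI of each construct by simple ordinary least squares; goodness of
fit is the coefficient of determination R². The pairing penalties s are fitted
by exhaustive grid search: for each candidate penalty vector the adaptiveness
table and every construct's region ctAI are recomputed and R² evaluated; the
argmax (lexicographically smallest vector on ties) is returned with the full
evaluation trace.

``WobbleConstraintModel`` / ``WobbleConstraintResults`` wrap this in a
model-object interface: build the model from data, call ``fit()``, inspect the
results object (estimates, R², trace) or print ``summary()``.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Iterable, Literal, Mapping

import numpy as np
import statsmodels.api as sm

from .adaptiveness import ConstraintTable, adaptiveness_from_map
from .errors import DegenerateFitError, InsufficientDataError
from .pool import PairingClass, TRNAPool, build_decoding_map
from .scoring import OrfSequence, Region, score_region

__all__ = [
    "ExpressionTable",
    "FitResult",
    "r_squared",
    "fit_constraints",
    "WobbleConstraintModel",
    "WobbleConstraintResults",
]

GRID_POINT_CAP = 10**6


@dataclass(frozen=True)
class ExpressionTable:
    """construct id → relative expression level (positive, reference = 1)."""

    records: dict[str, float]

    def __post_init__(self) -> None:
        for cid, value in self.records.items():
            if not value > 0:
                raise ValueError(f"{cid}: expression must be positive, got {value}")

    @classmethod
    def from_tsv(cls, text: str) -> "ExpressionTable":
        records: dict[str, float] = {}
        lines = [
            ln for ln in text.splitlines() if ln.strip() and not ln.lstrip().startswith("#")
        ]
        start = 1 if lines and lines[0].split("\t")[0].lower() == "construct_id" else 0
        for ln in lines[start:]:
            cid, value = ln.split("\t")[:2]
            if cid in records:
                raise ValueError(f"duplicate construct id {cid}")
            records[cid] = float(value)
        return cls(records)

    def __getitem__(self, cid: str) -> float:
        return self.records[cid]

    def __len__(self) -> int:
        return len(self.records)


def r_squared(
    scores: Mapping[str, float],
    expression: ExpressionTable,
    fit_scale: Literal["linear", "log"] = "linear",
) -> float:
    """R² of a simple OLS regression of expression (or log expression) on ctAI.

    Computed over the constructs shared between the two inputs; at least three
    are required, with non-degenerate variance on both sides.
    """
    shared = sorted(set(scores) & set(expression.records))
    if len(shared) < 3:
        raise InsufficientDataError(
            f"only {len(shared)} constructs shared between scores and expression"
        )
    x = np.array([scores[c] for c in shared])
    y = np.array([expression[c] for c in shared])
    if fit_scale == "log":
        y = np.log(y)
    if np.ptp(x) == 0:
        raise DegenerateFitError("zero variance in ctAI scores")
    if np.allclose(y, y[0]):
        raise DegenerateFitError("zero variance in expression (SS_tot = 0)")
    model = sm.OLS(y, sm.add_constant(x))
    return float(model.fit().rsquared)


@dataclass(frozen=True)
class FitResult:
    """Outcome of a penalty grid search."""

    s_fitted: dict[PairingClass, float]
    r_squared: float
    grid_trace: tuple[tuple[dict[PairingClass, float], float], ...]
    fit_scale: str

    def __post_init__(self) -> None:
        if not 0.0 <= self.r_squared <= 1.0:
            raise ValueError(f"R² {self.r_squared} outside [0, 1]")


def fit_constraints(
    construct_seqs: Mapping[str, OrfSequence],
    region: Region,
    expression: ExpressionTable,
    pool: TRNAPool,
    free_classes: Iterable[PairingClass],
    grid: Mapping[PairingClass, Iterable[float]],
    base_constraints: ConstraintTable | None = None,
    fit_scale: Literal["linear", "log"] = "linear",
    inosine_rule: bool = True,
) -> FitResult:
    """Exhaustive grid search over penalty vectors, maximizing expression R².

    Classes not in *free_classes* keep their *base_constraints* (default
    table) values. Deterministic: grid points are evaluated in lexicographic
    order and ties in R² resolve to the lexicographically smallest vector.
    """
    free = sorted(free_classes, key=lambda c: c.name)
    if not free:
        raise ValueError("no free classes to fit")
    axes = []
    for cls in free:
        values = sorted(grid[cls])
        if not values:
            raise ValueError(f"empty grid for class {cls.value}")
        axes.append(values)
    n_points = math.prod(len(a) for a in axes)
    if n_points > GRID_POINT_CAP:
        raise ValueError(
            f"grid has {n_points} points (cap {GRID_POINT_CAP}); use a coarser grid"
        )
    base = base_constraints or ConstraintTable()
    decoding_map = build_decoding_map(pool, inosine_rule=inosine_rule)
    trace = []
    best: tuple[float, tuple[float, ...]] | None = None
    for point in itertools.product(*axes):
        s = dict(base.s)
        s.update(dict(zip(free, point)))
        constraints = ConstraintTable(s=s, read_cap=base.read_cap)
        table = adaptiveness_from_map(decoding_map, constraints)
        scores = {
            cid: score_region(orf, region, table) for cid, orf in construct_seqs.items()
        }
        r2 = r_squared(scores, expression, fit_scale)
        trace.append(({cls: v for cls, v in zip(free, point)}, r2))
        if best is None or r2 > best[0]:
            best = (r2, point)
    assert best is not None
    return FitResult(
        s_fitted={cls: v for cls, v in zip(free, best[1])},
        r_squared=best[0],
        grid_trace=tuple(trace),
        fit_scale=fit_scale,
    )


@dataclass
class WobbleConstraintModel:
    """Model object tying construct sequences, a region, expression data and a
    tRNA pool together for penalty fitting.

    Parameters
    ----------
    construct_seqs : mapping of construct id to in-frame ORF
    region : codon span whose ctAI is the predictor
    expression : relative expression per construct
    pool : measured tRNA pool
    free_classes : pairing classes whose penalty is fitted
    grid : candidate penalty values per free class; by default 0 to 0.95 in
        steps of 0.05 with 0.9999 appended as a near-forbidden sentinel
    """

    construct_seqs: Mapping[str, OrfSequence]
    region: Region
    expression: ExpressionTable
    pool: TRNAPool
    free_classes: tuple[PairingClass, ...] = (PairingClass.UG,)
    grid: Mapping[PairingClass, tuple[float, ...]] | None = None
    base_constraints: ConstraintTable | None = None
    fit_scale: Literal["linear", "log"] = "linear"

    @staticmethod
    def default_grid() -> tuple[float, ...]:
        return tuple(round(0.05 * k, 2) for k in range(20)) + (0.9999,)

    def fit(self) -> "WobbleConstraintResults":
        grid = self.grid or {cls: self.default_grid() for cls in self.free_classes}
        result = fit_constraints(
            self.construct_seqs,
            self.region,
            self.expression,
            self.pool,
            self.free_classes,
            grid,
            base_constraints=self.base_constraints,
            fit_scale=self.fit_scale,
        )
        return WobbleConstraintResults(model=self, result=result)


@dataclass(frozen=True)
class WobbleConstraintResults:
    """Fitted penalties with their goodness of fit and search trace."""

    model: WobbleConstraintModel
    result: FitResult

    @property
    def s_fitted(self) -> dict[PairingClass, float]:
        return self.result.s_fitted

    @property
    def rsquared(self) -> float:
        return self.result.r_squared

    def summary(self) -> str:
        lines = [
            "Wobble constraint fit",
            "=" * 44,
            f"constructs:       {len(self.model.construct_seqs)}",
            f"region:           codons {self.model.region.start}-{self.model.region.end}",
            f"fit scale:        {self.result.fit_scale}",
            f"grid points:      {len(self.result.grid_trace)}",
            f"R-squared:        {self.rsquared:.4f}",
            "-" * 44,
            f"{'class':<10}{'s fitted':>10}",
        ]
        for cls, value in sorted(self.s_fitted.items(), key=lambda kv: kv[0].name):
            lines.append(f"{cls.value:<10}{value:>10.4f}")
        lines.append("=" * 44)
        return "\n".join(lines)
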