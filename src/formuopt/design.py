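"""Experimental design generation: Plackett-Burman screening and central
composite designs, with coded/actual level transforms.

The central composite design used throughout is the 3-factor, 5-level,
2-block layout: 8 cube points plus cube centers in block 1, 6 axial points
at distance ``alpha`` plus axial centers in block 2.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from enum import Enum
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "FactorSpec",
    "DesignPoint",
    "DesignMatrix",
    "ResponseTable",
    "PointType",
    "coded_to_actual",
    "actual_to_coded",
    "generate_plackett_burman",
    "generate_ccd",
]

# Cyclic generator row of the canonical 12-run Plackett-Burman design.
_PB12_GENERATOR = np.array([+1, +1, -1, +1, +1, +1, -1, -1, -1, +1, -1])


class PointType(str, Enum):
    CUBE = "cube"
    AXIAL = "axial"
    CENTER = "center"


@dataclass(frozen=True)
class FactorSpec:
    """A factor with an affine map between coded and actual units.

    ``center`` is the actual value at coded 0 and ``half_range`` the actual
    change per coded unit, so coded -1/+1 sit at ``low_actual``/``high_actual``.
    """

    name: str
    center: float
    half_range: float

    def __post_init__(self) -> None:
        if not self.half_range > 0:
            raise ValueError(f"half_range must be > 0, got {self.half_range}")

    @property
    def low_actual(self) -> float:
        return self.center - self.half_range

    @property
    def high_actual(self) -> float:
        return self.center + self.half_range

    def coded_to_actual(self, coded: float) -> float:
        return self.center + coded * self.half_range

    def actual_to_coded(self, actual: float) -> float:
        return (actual - self.center) / self.half_range


def coded_to_actual(f: FactorSpec, coded: float) -> float:
    """Map a coded level to actual units for factor ``f``."""
    return f.coded_to_actual(coded)


def actual_to_coded(f: FactorSpec, actual: float) -> float:
    """Map an actual level to coded units for factor ``f``."""
    return f.actual_to_coded(actual)


@dataclass(frozen=True)
class DesignPoint:
    run_order: int
    code: str
    coded_levels: tuple[float, ...]
    actual_levels: tuple[float, ...]
    block: int
    point_type: PointType


@dataclass
class DesignMatrix:
    """A realized experimental design: factor specs plus ordered run points."""

    factors: list[FactorSpec]
    points: list[DesignPoint]
    alpha: float
    design_kind: str  # "plackett_burman" or "ccd"

    @property
    def n_runs(self) -> int:
        return len(self.points)

    @property
    def factor_names(self) -> list[str]:
        return [f.name for f in self.factors]

    def coded_array(self) -> np.ndarray:
        return np.array([p.coded_levels for p in self.points], dtype=float)

    def actual_array(self) -> np.ndarray:
        return np.array([p.actual_levels for p in self.points], dtype=float)

    def point_type_counts(self) -> dict[str, int]:
        counts: dict[str, int] = {}
        for p in self.points:
            counts[p.point_type.value] = counts.get(p.point_type.value, 0) + 1
        return counts

    def to_frame(self, include_coded: bool = True) -> pd.DataFrame:
        rows = []
        for p in self.points:
            row: dict = {
                "run_order": p.run_order,
                "code": p.code,
                "block": p.block,
                "point_type": p.point_type.value,
            }
            for f, a in zip(self.factors, p.actual_levels):
                row[f.name] = a
            if include_coded:
                for f, c in zip(self.factors, p.coded_levels):
                    row[f"coded_{f.name}"] = c
            rows.append(row)
        return pd.DataFrame(rows)

    def write_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False, float_format="%.12g")


@dataclass
class ResponseTable:
    """Responses keyed by run code; columns are response names (Y1, Y2, ...)."""

    frame: pd.DataFrame  # indexed by run code

    def __post_init__(self) -> None:
        values = self.frame.to_numpy(dtype=float)
        if not np.all(np.isfinite(values)):
            raise ValueError("response values must be finite")

    @classmethod
    def from_arrays(cls, codes: Sequence[str], **responses: Sequence[float]) -> "ResponseTable":
        frame = pd.DataFrame(responses, index=pd.Index(codes, name="code"))
        return cls(frame)

    def aligned_values(self, design: DesignMatrix, response_name: str) -> np.ndarray:
        """Response vector in design run order; raises if any code is missing."""
        if response_name not in self.frame.columns:
            raise KeyError(f"unknown response {response_name!r}")
        codes = [p.code for p in design.points]
        missing = [c for c in codes if c not in self.frame.index]
        if missing:
            raise ValueError(f"responses missing for runs: {missing}")
        return self.frame.loc[codes, response_name].to_numpy(dtype=float)


def design_from_frame(frame: pd.DataFrame) -> DesignMatrix:
    """Rebuild a DesignMatrix from the CSV dialect written by ``to_frame``.

    Factor specs are recovered from the coded/actual column pairs by an
    affine least-squares fit; without coded columns the actual levels are
    assumed to already be coded (center 0, half-range 1).
    """
    meta = {"run_order", "code", "block", "point_type"}
    missing = meta - set(frame.columns)
    if missing:
        raise ValueError(f"design table missing columns: {sorted(missing)}")
    factor_names = [
        c for c in frame.columns if c not in meta and not c.startswith("coded_")
    ]
    factors = []
    coded_cols = {}
    for name in factor_names:
        actual = frame[name].to_numpy(dtype=float)
        coded_name = f"coded_{name}"
        if coded_name in frame.columns:
            coded = frame[coded_name].to_numpy(dtype=float)
            A = np.column_stack([np.ones(len(coded)), coded])
            (center, half), *_ = np.linalg.lstsq(A, actual, rcond=None)
        else:
            coded, center, half = actual, 0.0, 1.0
        coded_cols[name] = coded
        factors.append(FactorSpec(name, float(center), float(half)))
    points = []
    for i, row in frame.iterrows():
        coded = tuple(float(coded_cols[n][i]) for n in factor_names)
        actual = tuple(float(row[n]) for n in factor_names)
        points.append(
            DesignPoint(
                run_order=int(row["run_order"]),
                code=str(row["code"]),
                coded_levels=coded,
                actual_levels=actual,
                block=int(row["block"]),
                point_type=PointType(str(row["point_type"])),
            )
        )
    axial = [p for p in points if p.point_type is PointType.AXIAL]
    alpha = max((max(abs(c) for c in p.coded_levels) for p in axial), default=1.0)
    kind = "plackett_burman" if not axial and len(points) == 12 else "ccd"
    return DesignMatrix(factors=factors, points=points, alpha=float(alpha), design_kind=kind)


def generate_plackett_burman(n_factors: int, seed: int | None = None) -> DesignMatrix:
    """12-run Plackett-Burman design for up to 11 two-level factors.

    The first ``n_factors`` columns are real factors; the remaining columns
    are retained as dummy columns for error estimation.  Rows are the 11
    cyclic shifts of the generator row plus an all-minus row.  A seed, if
    given, shuffles the run order only.
    """
    if not 2 <= n_factors <= 11:
        raise ValueError(f"n_factors must be in [2, 11], got {n_factors}")
    rows = [np.roll(_PB12_GENERATOR, i) for i in range(11)]
    rows.append(-np.ones(11, dtype=int))
    matrix = np.array(rows, dtype=float)
    order = np.arange(12)
    if seed is not None:
        order = np.random.default_rng(seed).permutation(12)

    factors = [FactorSpec(f"F{i + 1}", 0.0, 1.0) for i in range(n_factors)]
    factors += [FactorSpec(f"D{i + 1}", 0.0, 1.0) for i in range(11 - n_factors)]
    points = []
    for run, idx in enumerate(order, start=1):
        coded = tuple(matrix[idx])
        actual = tuple(f.coded_to_actual(c) for f, c in zip(factors, coded))
        points.append(
            DesignPoint(
                run_order=run,
                code=f"PB{run:02d}",
                coded_levels=coded,
                actual_levels=actual,
                block=1,
                point_type=PointType.CUBE,
            )
        )
    return DesignMatrix(factors=factors, points=points, alpha=1.0, design_kind="plackett_burman")


def generate_ccd(
    factors: Sequence[FactorSpec],
    alpha: float = 1.633,
    n_center_cube: int = 4,
    n_center_axial: int = 2,
    seed: int | None = None,
) -> DesignMatrix:
    """Two-block central composite design for exactly three factors.

    Block 1: the 2^3 factorial cube plus ``n_center_cube`` center replicates.
    Block 2: six axial points at +/- ``alpha`` plus ``n_center_axial`` center
    replicates.  Run codes CC01... are assigned deterministically; a seed, if
    given, shuffles run order within each block (codes follow the new order).
    """
    factors = list(factors)
    if len(factors) != 3:
        raise ValueError(f"generate_ccd requires exactly 3 factors, got {len(factors)}")
    if not alpha > 0:
        raise ValueError("alpha must be > 0")
    if n_center_cube < 0 or n_center_axial < 0:
        raise ValueError("center counts must be >= 0")

    coded_rows: list[tuple[tuple[float, ...], int, PointType]] = []
    for combo in itertools.product((-1.0, 1.0), repeat=3):
        coded_rows.append((combo, 1, PointType.CUBE))
    coded_rows += [((0.0, 0.0, 0.0), 1, PointType.CENTER)] * n_center_cube
    for axis in range(3):
        for sign in (-1.0, 1.0):
            coded = [0.0, 0.0, 0.0]
            coded[axis] = sign * alpha
            coded_rows.append((tuple(coded), 2, PointType.AXIAL))
    coded_rows += [((0.0, 0.0, 0.0), 2, PointType.CENTER)] * n_center_axial

    if seed is not None:
        rng = np.random.default_rng(seed)
        block1 = [r for r in coded_rows if r[1] == 1]
        block2 = [r for r in coded_rows if r[1] == 2]
        coded_rows = [block1[i] for i in rng.permutation(len(block1))]
        coded_rows += [block2[i] for i in rng.permutation(len(block2))]

    points = []
    for run, (coded, block, ptype) in enumerate(coded_rows, start=1):
        actual = tuple(f.coded_to_actual(c) for f, c in zip(factors, coded))
        points.append(
            DesignPoint(
                run_order=run,
                code=f"CC{run:02d}",
                coded_levels=coded,
                actual_levels=actual,
                block=block,
                point_type=ptype,
            )
        )
    return DesignMatrix(factors=factors, points=points, alpha=alpha, design_kind="ccd")
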