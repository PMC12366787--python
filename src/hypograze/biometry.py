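"""Cell geometry and mean-cell-volume (MCV) computations.

Planktonic cells sized under the microscope are approximated as prolate
spheroids: a cell of length L and width W has volume V = (π/6)·L·W².
Because volume is convex in width, the mean of per-cell volumes exceeds the
volume of the mean-dimension cell; MCV is therefore always computed per cell
first and averaged afterwards.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "CellDimension",
    "BiovolumeStats",
    "prolate_spheroid_volume",
    "mcv_from_dims",
    "mixture_mcv",
    "read_dimensions",
]


@dataclass(frozen=True)
class CellDimension:
    """Length and width of one cell, in μm. Length must be >= width > 0."""

    length: float
    width: float

    def __post_init__(self) -> None:
        if not (math.isfinite(self.length) and math.isfinite(self.width)):
            raise ValueError("cell dimensions must be finite")
        if self.width <= 0 or self.length <= 0:
            raise ValueError(
                f"cell dimensions must be positive, got {self.length} x {self.width}"
            )
        if self.length < self.width:
            raise ValueError(
                f"length ({self.length}) must be >= width ({self.width})"
            )


@dataclass
class BiovolumeStats:
    """Summary of per-cell biovolumes (μm³)."""

    mean: float
    sd: float
    n: int
    per_cell: list[float] = field(repr=False)

    def __post_init__(self) -> None:
        if self.n != len(self.per_cell):
            raise ValueError("n must equal the number of per-cell volumes")


def prolate_spheroid_volume(dim: CellDimension) -> float:
    """Volume (μm³) of a prolate spheroid with the cell's length and width.

    V = (π/6)·L·W², i.e. an ellipsoid of revolution with semi-axes
    L/2, W/2, W/2. A cell with L == W reduces to a sphere of diameter L.
    """
    return math.pi / 6.0 * dim.length * dim.width**2


def mcv_from_dims(dims: list[CellDimension]) -> BiovolumeStats:
    """Mean cell volume from a list of measured dimensions.

    Volumes are computed per cell and then averaged (the order matters: for
    cells of varying width the result exceeds the volume of the
    mean-dimension cell because E[W²] = E[W]² + Var(W)). The SD is the
    sample SD (n − 1 denominator); for a single cell it is reported as 0
    with a warning.
    """
    if not dims:
        raise ValueError("at least one cell dimension is required")
    per_cell = [prolate_spheroid_volume(d) for d in dims]
    n = len(per_cell)
    mean = float(np.mean(per_cell))
    if n == 1:
        warnings.warn("sample SD undefined for n=1; reporting 0", stacklevel=2)
        sd = 0.0
    else:
        sd = float(np.std(per_cell, ddof=1))
    return BiovolumeStats(mean=mean, sd=sd, n=n, per_cell=per_cell)


def mixture_mcv(volumes: list[float], proportions: list[float]) -> float:
    """Number-weighted mean cell volume of a mixture of strains.

    ``proportions`` are numerical fractions of cells and must sum to 1.
    Note this is the arithmetic expectation for the mixed suspension; a
    stock's measured MCV can differ (e.g. cell shrinkage on labeling or
    freezing) and should then be used directly as a measured input.
    """
    if len(volumes) != len(proportions):
        raise ValueError("volumes and proportions must have the same length")
    if not volumes:
        raise ValueError("at least one component is required")
    if abs(sum(proportions) - 1.0) > 1e-9:
        raise ValueError(f"proportions must sum to 1, got {sum(proportions)}")
    if any(v <= 0 for v in volumes) or any(p < 0 for p in proportions):
        raise ValueError("volumes must be positive and proportions non-negative")
    return float(np.dot(volumes, proportions))


def read_dimensions(path: str | Path) -> list[CellDimension]:
    """Read a two-column (length, width) delimited text file; units are μm."""
    df = pd.read_csv(path, sep=None, engine="python")
    if df.shape[1] < 2:
        raise ValueError(f"{path}: expected two columns (length, width)")
    out = []
    for i, row in enumerate(df.itertuples(index=False)):
        try:
            out.append(CellDimension(float(row[0]), float(row[1])))
        except (TypeError, ValueError) as exc:
            raise ValueError(f"{path}: row {i + 2}: {exc}") from exc
    return out
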