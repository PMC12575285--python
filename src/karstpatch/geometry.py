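"""Soil-patch delineation and patch morphometrics on depth rasters.

A plot is a rectangular raster of soil-depth readings (cm) on a square
lattice; a depth of 0 marks exposed rock. Soil patches are maximal connected
components of depth > 0 cells. Per patch we compute area ``PA`` (m²),
perimeter ``PM`` (m, exposed-edge convention) and the perimeter–area fractal
dimension ``PFD = 2·ln(PM/4)/ln(PA)``.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

logger = logging.getLogger(__name__)

__all__ = [
    "SoilGrid",
    "PatchMap",
    "SummaryRow",
    "delineate_patches",
    "patch_area",
    "patch_perimeter",
    "fractal_dimension",
    "patch_metrics",
    "summarize_patch_properties",
    "cv_from_moments",
]


def cv_from_moments(sd: float, mean: float) -> float:
    """Coefficient of variation CV = SD/mean from pre-computed moments."""
    if sd < 0:
        raise ValueError("sd must be >= 0")
    if mean == 0:
        raise ValueError("CV undefined for zero mean")
    return sd / mean


@dataclass(frozen=True)
class SoilGrid:
    """Rectangular raster of soil depths (cm) with a physical cell side (m).

    Depth 0 encodes exposed rock. Origin is the top-left corner, rows are
    stored row-major with 0-based indices.
    """

    depths: np.ndarray
    cell_side: float

    def __post_init__(self) -> None:
        depths = np.asarray(self.depths, dtype=float)
        if depths.ndim != 2 or depths.size == 0:
            raise ValueError("depths must be a non-empty 2-D raster")
        if np.any(depths < 0) or not np.all(np.isfinite(depths)):
            raise ValueError("depths must be finite and >= 0 (0 = rock)")
        if not self.cell_side > 0:
            raise ValueError("cell_side must be > 0")
        object.__setattr__(self, "depths", depths)

    @property
    def shape(self) -> tuple[int, int]:
        return self.depths.shape

    @property
    def soil_mask(self) -> np.ndarray:
        return self.depths > 0

    @classmethod
    def from_csv(cls, path, cell_side: float) -> "SoilGrid":
        """Read a plain rectangular numeric grid (no header, 0 = rock)."""
        depths = np.atleast_2d(np.loadtxt(path, delimiter=","))
        return cls(depths=depths, cell_side=cell_side)

    def to_csv(self, path) -> None:
        np.savetxt(path, self.depths, delimiter=",", fmt="%.6g")


@dataclass(frozen=True)
class PatchMap:
    """Labeled connected soil regions; label 0 is rock."""

    labels: np.ndarray
    cell_side: float
    connectivity: int = 4

    @property
    def n_patches(self) -> int:
        return int(self.labels.max())

    @property
    def patch_ids(self) -> list[int]:
        return list(range(1, self.n_patches + 1))

    def cells(self, patch_id: int) -> np.ndarray:
        return self.labels == patch_id

    def to_csv(self, path) -> None:
        np.savetxt(path, self.labels, delimiter=",", fmt="%d")

    @classmethod
    def from_csv(cls, path, cell_side: float, connectivity: int = 4) -> "PatchMap":
        labels = np.atleast_2d(np.loadtxt(path, delimiter=",")).astype(int)
        return cls(labels=labels, cell_side=cell_side, connectivity=connectivity)


@dataclass(frozen=True)
class SummaryRow:
    """Min/max/mean/SD/CV summary of one patch property.

    ``sd`` is the sample standard deviation (n−1 denominator) unless
    computed otherwise; ``cv = sd/mean`` and is NaN when the mean is 0.
    ``n_excluded`` counts NaN inputs that were skipped.
    """

    minimum: float
    maximum: float
    mean: float
    sd: float
    cv: float
    n: int = 0
    n_excluded: int = 0

    def rounded(self, ndigits: int = 2) -> "SummaryRow":
        return SummaryRow(
            minimum=round(self.minimum, ndigits),
            maximum=round(self.maximum, ndigits),
            mean=round(self.mean, ndigits),
            sd=round(self.sd, ndigits),
            cv=round(self.cv, ndigits),
            n=self.n,
            n_excluded=self.n_excluded,
        )

    def as_dict(self) -> dict:
        return {
            "min": self.minimum,
            "max": self.maximum,
            "mean": self.mean,
            "sd": self.sd,
            "cv": self.cv,
            "n": self.n,
            "n_excluded": self.n_excluded,
        }


_STRUCTURES = {
    4: ndimage.generate_binary_structure(2, 1),
    8: ndimage.generate_binary_structure(2, 2),
}


def delineate_patches(grid: SoilGrid, connectivity: int = 4) -> PatchMap:
    """Partition depth > 0 cells into maximal connected components.

    Parameters
    ----------
    grid : SoilGrid
    connectivity : {4, 8}
        4 = edge-sharing adjacency (default), 8 = edges + corners.

    Returns
    -------
    PatchMap
        Labels 1..n_patches assigned in raster-scan order of each patch's
        first cell; rock cells keep label 0. An all-rock grid yields
        ``n_patches == 0``.
    """
    if connectivity not in _STRUCTURES:
        raise ValueError(f"connectivity must be 4 or 8, got {connectivity!r}")
    raw, n = ndimage.label(grid.soil_mask, structure=_STRUCTURES[connectivity])
    labels = _relabel_scan_order(raw, n)
    return PatchMap(labels=labels, cell_side=grid.cell_side, connectivity=connectivity)


def _relabel_scan_order(raw: np.ndarray, n: int) -> np.ndarray:
    """Renumber labels 1..n by the flat index of each component's first cell."""
    if n == 0:
        return raw.astype(int)
    flat = raw.ravel()
    first = np.full(n + 1, flat.size, dtype=int)
    idx = np.flatnonzero(flat)
    # reversed so earlier indices overwrite later ones
    first[flat[idx[::-1]]] = idx[::-1]
    order = np.argsort(first[1:], kind="stable") + 1
    remap = np.zeros(n + 1, dtype=int)
    remap[order] = np.arange(1, n + 1)
    return remap[raw]


def patch_area(n_cells: int, cell_side: float) -> float:
    """Patch area PA = n_cells · cell_side² (m²)."""
    if n_cells < 1:
        raise ValueError("patch must contain at least one cell")
    if not cell_side > 0:
        raise ValueError("cell_side must be > 0")
    return n_cells * cell_side**2


def patch_perimeter(mask: np.ndarray, cell_side: float) -> float:
    """Patch perimeter PM (m) by the exposed-edge raster convention.

    Every cell edge adjacent to rock, to another patch, or to the raster
    boundary contributes one cell side to the perimeter.
    """
    mask = np.asarray(mask, dtype=bool)
    n = int(mask.sum())
    if n == 0:
        raise ValueError("patch mask is empty")
    adj = int((mask[:, 1:] & mask[:, :-1]).sum()) + int((mask[1:, :] & mask[:-1, :]).sum())
    return (4 * n - 2 * adj) * cell_side


def fractal_dimension(pa: float, pm: float) -> float:
    """Perimeter–area fractal dimension PFD = 2·ln(PM/4)/ln(PA).

    Undefined (NaN, with a warning) when PA = 1 m² exactly since
    ln(PA) = 0. Square raster patches with PA ≠ 1 give exactly 1.
    """
    if not (pa > 0 and pm > 0):
        raise ValueError("PA and PM must be > 0")
    log_pa = math.log(pa)
    if abs(log_pa) < 1e-15:
        logger.warning("PFD undefined for PA = 1 m^2 (ln PA = 0); returning NaN")
        return math.nan
    return 2.0 * math.log(pm / 4.0) / log_pa


def patch_metrics(patch_map: PatchMap) -> pd.DataFrame:
    """Per-patch geometry table: patch_id, n_cells, PA_m2, PM_m, PFD."""
    rows = []
    side = patch_map.cell_side
    for pid in patch_map.patch_ids:
        mask = patch_map.cells(pid)
        n = int(mask.sum())
        pa = patch_area(n, side)
        pm = patch_perimeter(mask, side)
        rows.append(
            {
                "patch_id": pid,
                "n_cells": n,
                "PA_m2": pa,
                "PM_m": pm,
                "PFD": fractal_dimension(pa, pm),
            }
        )
    return pd.DataFrame(
        rows, columns=["patch_id", "n_cells", "PA_m2", "PM_m", "PFD"]
    )


def summarize_patch_properties(
    values, ddof: int = 1, skipna: bool = True
) -> SummaryRow:
    """Summary statistics (min, max, mean, sample SD, CV = SD/mean).

    NaNs are skipped when ``skipna`` and counted in ``n_excluded``. At least
    two finite values are required for the SD. CV is NaN when the mean is 0.
    """
    arr = np.asarray(values, dtype=float).ravel()
    nan_mask = np.isnan(arr)
    n_excluded = int(nan_mask.sum())
    if n_excluded:
        if not skipna:
            raise ValueError("values contain NaN and skipna is False")
        arr = arr[~nan_mask]
    if not np.all(np.isfinite(arr)):
        raise ValueError("values must be finite")
    if arr.size < 2:
        raise ValueError("need at least 2 finite values for the SD")
    mean = float(arr.mean())
    sd = float(arr.std(ddof=ddof))
    if mean == 0:
        logger.warning("CV undefined for zero mean; returning NaN")
        cv = math.nan
    else:
        cv = sd / mean
    return SummaryRow(
        minimum=float(arr.min()),
        maximum=float(arr.max()),
        mean=mean,
        sd=sd,
        cv=cv,
        n=int(arr.size),
        n_excluded=n_excluded,
    )
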