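"""Taxonomic diversity of patch communities: richness, Shannon-Wiener, Pielou.

The Shannon-Wiener index uses the base-2 logarithm. Pielou's evenness by
default divides that base-2 entropy by ln(S) — a mixed-base quotient that can
exceed 1 (uniform communities reach 1/ln 2 ≈ 1.4427); pass
``consistent_base=True`` to divide by log2(S) instead, which caps evenness
at exactly 1.
"""

from __future__ import annotations

import logging
import math

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "richness",
    "shannon",
    "pielou",
    "load_community_matrix",
    "diversity_table",
    "community_members",
]


def _abundances(community) -> np.ndarray:
    if isinstance(community, dict):
        arr = np.asarray(list(community.values()), dtype=float)
    else:
        arr = np.asarray(community, dtype=float)
    if arr.size and (np.any(arr < 0) or not np.all(np.isfinite(arr))):
        raise ValueError("abundances must be finite and >= 0")
    return arr


def richness(community) -> int:
    """Number of species with abundance > 0; 0 for an empty community."""
    return int((_abundances(community) > 0).sum())


def shannon(community) -> float:
    """Shannon-Wiener index H' = −Σ (N_i/N)·log2(N_i/N), in bits.

    NaN (with a warning) for an empty community.
    """
    arr = _abundances(community)
    arr = arr[arr > 0]
    if arr.size == 0:
        logger.warning("Shannon index undefined for an empty community")
        return math.nan
    p = arr / arr.sum()
    return float(-(p * np.log2(p)).sum())


def pielou(community, consistent_base: bool = False) -> float:
    """Pielou evenness E = H'/ln(S) (default) or H'/log2(S).

    NaN (with a warning) when S < 2, since the denominator vanishes.
    """
    s = richness(community)
    if s < 2:
        logger.warning("Pielou evenness undefined for S < 2")
        return math.nan
    denom = math.log2(s) if consistent_base else math.log(s)
    return shannon(community) / denom


def load_community_matrix(path) -> pd.DataFrame:
    """Read a patch × species abundance CSV (index column ``patch_id``)."""
    table = pd.read_csv(path, index_col=0)
    if table.columns.duplicated().any():
        raise ValueError("species names must be unique")
    if (table.to_numpy() < 0).any():
        raise ValueError("abundances must be >= 0")
    return table


def community_members(matrix: pd.DataFrame, patch_id) -> list[str]:
    """Species present (abundance > 0) in one patch row."""
    row = matrix.loc[patch_id]
    return list(row.index[row > 0])


def diversity_table(matrix: pd.DataFrame, consistent_base: bool = False) -> pd.DataFrame:
    """Per-patch R, H' and E for every row of a community matrix."""
    rows = []
    for pid, row in matrix.iterrows():
        arr = row.to_numpy(dtype=float)
        rows.append(
            {
                "patch_id": pid,
                "R": richness(arr),
                "Hprime": shannon(arr),
                "E": pielou(arr, consistent_base=consistent_base),
            }
        )
    return pd.DataFrame(rows)
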