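"""Tip-shuffle null models and the standardized effect sizes NRI and NTI.

The null model permutes tip labels of the phylogeny uniformly at random and
recomputes MPD or MNTD for the focal community — equivalent to evaluating the
metric on a uniform random k-subset of tips, holding community richness
fixed. NRI = −1·(MPD_obs − null mean)/null SD; NTI likewise with MNTD. An
exhaustive enumeration over all k-subsets provides exact null moments for
small trees and serves as the test oracle for the Monte-Carlo null.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd

from karstpatch.phylo import DistanceMatrix, PhyloTree, mntd, mpd

logger = logging.getLogger(__name__)

__all__ = [
    "NullDistribution",
    "StructureCall",
    "tip_shuffle_null",
    "exhaustive_null",
    "nri",
    "nti",
    "interpret_structure",
    "phylostructure_table",
]

#: null SDs below this are treated as degenerate (SES undefined)
SD_TOLERANCE = 1e-12

#: two-sided 5% normal critical value used for the individual-significance flag
Z_CRITICAL = 1.96

_EXHAUSTIVE_LIMIT = 10**6


@dataclass(frozen=True)
class NullDistribution:
    """Permutation replicates of MPD or MNTD with their moments."""

    metric: str
    replicates: np.ndarray
    null_mean: float
    null_sd: float

    @property
    def n_perm(self) -> int:
        return len(self.replicates)


@dataclass(frozen=True)
class StructureCall:
    """Phylogenetic-structure label with an individual-significance flag."""

    label: str  # clustered | dispersed | random | undefined
    significant: bool


def _metric_values(values: np.ndarray, subsets: np.ndarray, metric: str) -> np.ndarray:
    """Evaluate MPD or MNTD on each row of a (m, k) tip-index array."""
    k = subsets.shape[1]
    sub = values[subsets[:, :, None], subsets[:, None, :]]  # (m, k, k)
    if metric == "mpd":
        return sub.sum(axis=(1, 2)) / (k * (k - 1))
    if metric == "mntd":
        eye = np.eye(k, dtype=bool)
        sub = np.where(eye, np.inf, sub)
        return sub.min(axis=2).mean(axis=1)
    raise ValueError(f"metric must be 'mpd' or 'mntd', got {metric!r}")


def tip_shuffle_null(
    dist: DistanceMatrix,
    k: int,
    n_perm: int = 999,
    seed=None,
    metric: str = "mpd",
    ddof: int = 1,
) -> NullDistribution:
    """Null distribution of a metric for community size ``k`` under tip shuffling.

    Each replicate relabels the tree's tips by a uniform random permutation,
    which maps the focal community to a uniform random k-subset of tips.

    Parameters
    ----------
    dist : DistanceMatrix
        Cophenetic distances of the full phylogeny.
    k : int
        Community richness, ``2 <= k <= n_tips``.
    n_perm : int
        Number of permutations (default 999).
    seed : int | numpy.random.Generator | None
        Randomness source; a fixed integer gives identical replicates.
    metric : {"mpd", "mntd"}
    ddof : int
        1 (default) for sample SD of the replicates, 0 for population SD.
    """
    n = dist.n
    if not 2 <= k <= n:
        raise ValueError(f"k must be in [2, {n}], got {k}")
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    if metric not in ("mpd", "mntd"):
        raise ValueError(f"metric must be 'mpd' or 'mntd', got {metric!r}")
    rng = np.random.default_rng(seed)
    keys = rng.random((n_perm, n))
    subsets = np.argpartition(keys, k - 1, axis=1)[:, :k]
    reps = _metric_values(dist.values, subsets, metric)
    sd = float(reps.std(ddof=ddof)) if n_perm > ddof else 0.0
    return NullDistribution(
        metric=metric,
        replicates=reps,
        null_mean=float(reps.mean()),
        null_sd=sd,
    )


def exhaustive_null(
    dist: DistanceMatrix, k: int, metric: str = "mpd", ddof: int = 1
) -> tuple[float, float]:
    """Exact null moments: metric evaluated on every k-subset of tips.

    Refuses when C(n_tips, k) exceeds 10^6.
    """
    n = dist.n
    if not 2 <= k <= n:
        raise ValueError(f"k must be in [2, {n}], got {k}")
    n_subsets = math.comb(n, k)
    if n_subsets > _EXHAUSTIVE_LIMIT:
        raise ValueError(
            f"C({n}, {k}) = {n_subsets} subsets exceeds the "
            f"exhaustive-enumeration bound of {_EXHAUSTIVE_LIMIT}"
        )
    values = np.empty(n_subsets, dtype=float)
    chunk: list[tuple[int, ...]] = []
    start = 0
    for combo in combinations(range(n), k):
        chunk.append(combo)
        if len(chunk) == 20000:
            values[start : start + len(chunk)] = _metric_values(
                dist.values, np.asarray(chunk), metric
            )
            start += len(chunk)
            chunk = []
    if chunk:
        values[start : start + len(chunk)] = _metric_values(
            dist.values, np.asarray(chunk), metric
        )
    sd = float(values.std(ddof=ddof)) if n_subsets > ddof else 0.0
    return float(values.mean()), sd


def _ses(obs: float, null_mean: float, null_sd: float) -> float:
    if null_sd < SD_TOLERANCE:
        logger.warning("null SD below tolerance (%g); SES undefined", SD_TOLERANCE)
        return math.nan
    return -1.0 * (obs - null_mean) / null_sd


def nri(
    dist: DistanceMatrix,
    taxa,
    n_perm: int = 999,
    seed=None,
    exact: bool = False,
    ddof: int = 1,
) -> float:
    """Net relatedness index: −1 × (MPD_obs − null mean)/null SD.

    Positive values indicate phylogenetic clustering, negative values
    dispersion. ``exact=True`` replaces the Monte-Carlo null with exhaustive
    enumeration (small trees only). NaN when the null SD is degenerate.
    """
    taxa = list(taxa)
    if len(taxa) < 2:
        logger.warning("NRI undefined for fewer than 2 taxa")
        return math.nan
    obs = mpd(dist, taxa)
    if exact:
        mean, sd = exhaustive_null(dist, len(taxa), metric="mpd", ddof=ddof)
    else:
        null = tip_shuffle_null(dist, len(taxa), n_perm, seed, metric="mpd", ddof=ddof)
        mean, sd = null.null_mean, null.null_sd
    return _ses(obs, mean, sd)


def nti(
    dist: DistanceMatrix,
    taxa,
    n_perm: int = 999,
    seed=None,
    exact: bool = False,
    ddof: int = 1,
) -> float:
    """Nearest taxon index: −1 × (MNTD_obs − null mean)/null SD."""
    taxa = list(taxa)
    if len(taxa) < 2:
        logger.warning("NTI undefined for fewer than 2 taxa")
        return math.nan
    obs = mntd(dist, taxa)
    if exact:
        mean, sd = exhaustive_null(dist, len(taxa), metric="mntd", ddof=ddof)
    else:
        null = tip_shuffle_null(dist, len(taxa), n_perm, seed, metric="mntd", ddof=ddof)
        mean, sd = null.null_mean, null.null_sd
    return _ses(obs, mean, sd)


def interpret_structure(nri_value: float, nti_value: float) -> StructureCall:
    """Label community assembly from the signs of NRI and NTI.

    clustered when both > 0, dispersed when both < 0, random otherwise;
    undefined when either input is not finite. ``significant`` flags
    |z| >= 1.96 for both indices.
    """
    if not (math.isfinite(nri_value) and math.isfinite(nti_value)):
        return StructureCall(label="undefined", significant=False)
    if nri_value > 0 and nti_value > 0:
        label = "clustered"
    elif nri_value < 0 and nti_value < 0:
        label = "dispersed"
    else:
        label = "random"
    significant = abs(nri_value) >= Z_CRITICAL and abs(nti_value) >= Z_CRITICAL
    return StructureCall(label=label, significant=significant)


def phylostructure_table(
    tree: PhyloTree,
    communities: pd.DataFrame,
    n_perm: int = 999,
    seed=None,
    ddof: int = 1,
) -> pd.DataFrame:
    """Per-patch observed MPD/MNTD, NRI, NTI and assembly label.

    ``communities`` is a patch × species abundance matrix whose columns are
    tip labels of ``tree``. Null moments are computed once per distinct
    richness value and shared across patches of that richness. Output
    columns: ``patch_id,R,MPD_obs,MNTD_obs,NRI,NTI,label``.
    """
    unknown = [c for c in communities.columns if c not in set(tree.tip_labels)]
    if unknown:
        raise KeyError(f"species absent from the phylogeny: {unknown}")
    dist = tree.cophenetic()
    seeds = np.random.SeedSequence(seed).spawn(2)
    null_cache: dict[tuple[str, int], tuple[float, float]] = {}

    def null_moments(metric: str, k: int, seq) -> tuple[float, float]:
        key = (metric, k)
        if key not in null_cache:
            null = tip_shuffle_null(
                dist, k, n_perm, np.random.default_rng(seq), metric=metric, ddof=ddof
            )
            null_cache[key] = (null.null_mean, null.null_sd)
        return null_cache[key]

    rows = []
    for pid, row in communities.iterrows():
        taxa = list(row.index[row > 0])
        k = len(taxa)
        if k < 2:
            rows.append(
                {
                    "patch_id": pid,
                    "R": k,
                    "MPD_obs": math.nan,
                    "MNTD_obs": math.nan,
                    "NRI": math.nan,
                    "NTI": math.nan,
                    "label": "undefined",
                }
            )
            continue
        mpd_obs = mpd(dist, taxa)
        mntd_obs = mntd(dist, taxa)
        nri_value = _ses(mpd_obs, *null_moments("mpd", k, seeds[0]))
        nti_value = _ses(mntd_obs, *null_moments("mntd", k, seeds[1]))
        rows.append(
            {
                "patch_id": pid,
                "R": k,
                "MPD_obs": mpd_obs,
                "MNTD_obs": mntd_obs,
                "NRI": nri_value,
                "NTI": nti_value,
                "label": interpret_structure(nri_value, nti_value).label,
            }
        )
    return pd.DataFrame(
        rows, columns=["patch_id", "R", "MPD_obs", "MNTD_obs", "NRI", "NTI", "label"]
    )
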