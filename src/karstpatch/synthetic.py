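"""Synthetic phylogenies, soil grids, resource samples and communities.

Stand-ins for field data: every generator is a pure function of its
configuration and seed, so downstream stages are testable without any
download. Defaults emulate 10 m × 10 m plots sampled on a 26 × 26 lattice of
0.39 m cells with fragmented soil patches, strong depth/moisture
heterogeneity, and communities whose richness rises with log10 patch area
and whose phylogenetic structure can be random, clustered (environmental
filtering toward one clade) or overdispersed.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage

from karstpatch.geometry import PatchMap, SoilGrid
from karstpatch.phylo import PhyloTree

logger = logging.getLogger(__name__)

__all__ = [
    "SynthConfig",
    "gen_tree",
    "gen_soil_grid",
    "gen_resource_samples",
    "gen_communities",
    "gen_patch_areas",
]

ASSEMBLY_MODES = ("random", "filtered", "overdispersed")


@dataclass(frozen=True)
class SynthConfig:
    """Configuration for all synthetic generators.

    Resource targets default to the magnitudes typical of shallow karst
    soils: mean depth ~24 cm with CV ~0.53, moisture ~17% with CV ~0.37,
    and weakly varying carbon/nitrogen content.
    """

    n_rows: int = 26
    n_cols: int = 26
    cell_side: float = 0.39
    rock_fraction: float = 0.5
    clumping: float = 1.0
    depth_mean: float = 24.27
    depth_cv: float = 0.53
    swc_mean: float = 17.17
    swc_cv: float = 0.37
    tc_mean: float = 1.82
    tc_cv: float = 0.18
    tn_mean: float = 0.23
    tn_cv: float = 0.14
    samples_per_patch: int = 3
    n_taxa: int = 98
    richness_intercept: float = 5.0
    richness_slope: float = 8.0
    richness_noise_sd: float = 0.0
    abundance_mean: float = 5.0
    assembly_mode: str = "random"
    filter_strength: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_rows < 1 or self.n_cols < 1:
            raise ValueError("grid dimensions must be >= 1")
        if not self.cell_side > 0:
            raise ValueError("cell_side must be > 0")
        if not 0.0 <= self.rock_fraction <= 1.0:
            raise ValueError("rock_fraction must be in [0, 1]")
        if self.clumping < 0:
            raise ValueError("clumping must be >= 0")
        if not self.depth_mean > 0:
            raise ValueError("depth_mean must be > 0")
        for name in ("depth_cv", "swc_cv", "tc_cv", "tn_cv", "richness_noise_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.samples_per_patch < 1:
            raise ValueError("samples_per_patch must be >= 1")
        if self.n_taxa < 2:
            raise ValueError("n_taxa must be >= 2")
        if self.assembly_mode not in ASSEMBLY_MODES:
            raise ValueError(
                f"assembly_mode must be one of {ASSEMBLY_MODES}, got {self.assembly_mode!r}"
            )
        if self.filter_strength < 0:
            raise ValueError("filter_strength must be >= 0")

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=2, sort_keys=True)
            fh.write("\n")

    @classmethod
    def from_json(cls, path) -> "SynthConfig":
        with open(path) as fh:
            return cls(**json.load(fh))


def _lognormal_params(mean: float, cv: float) -> tuple[float, float]:
    """(mu, sigma) of a lognormal with the given arithmetic mean and CV."""
    sigma2 = np.log1p(cv**2)
    return np.log(mean) - sigma2 / 2.0, np.sqrt(sigma2)


def _lognormal(rng: np.random.Generator, mean: float, cv: float, size) -> np.ndarray:
    if cv == 0:
        return np.full(size, float(mean))
    mu, sigma = _lognormal_params(mean, cv)
    return rng.lognormal(mu, sigma, size)


def gen_tree(n_taxa: int, seed: int) -> PhyloTree:
    """Random ultrametric bifurcating tree with ``n_taxa`` labeled tips.

    Built coalescent-style: lineages are merged pairwise at strictly
    increasing heights, so all branch lengths are strictly positive and all
    root-to-tip distances are equal. The Newick serialization is a pure
    function of ``(n_taxa, seed)``.
    """
    if n_taxa < 2:
        raise ValueError("n_taxa must be >= 2")
    rng = np.random.default_rng(seed)
    width = len(str(n_taxa))
    clades = [f"t{i + 1:0{width}d}" for i in range(n_taxa)]
    heights = [0.0] * n_taxa
    height = 0.0
    while len(clades) > 1:
        height += float(rng.exponential(1.0))
        i, j = sorted(rng.choice(len(clades), size=2, replace=False))
        left, right = clades[i], clades[j]
        merged = (
            f"({left}:{height - heights[i]:.10f},{right}:{height - heights[j]:.10f})"
        )
        clades[i] = merged
        heights[i] = height
        del clades[j], heights[j]
    return PhyloTree.from_newick(clades[0] + ";")


def gen_soil_grid(config: SynthConfig) -> SoilGrid:
    """Soil-depth raster with a target rock fraction and depth distribution.

    Rock placement thresholds a smoothed uniform noise field at the empirical
    quantile matching ``rock_fraction`` (exact cell count), so clumping > 0
    aggregates rock into fewer, larger masses without changing the fraction.
    Depths on soil cells are lognormal with mean ``depth_mean`` and CV
    ``depth_cv``.
    """
    rng = np.random.default_rng(config.seed)
    shape = (config.n_rows, config.n_cols)
    size = config.n_rows * config.n_cols
    noise = rng.random(shape)
    field = (
        ndimage.gaussian_filter(noise, sigma=config.clumping, mode="nearest")
        if config.clumping > 0
        else noise
    )
    n_rock = int(round(config.rock_fraction * size))
    order = np.argsort(field.ravel(), kind="stable")
    rock = np.zeros(size, dtype=bool)
    rock[order[:n_rock]] = True
    rock = rock.reshape(shape)
    depths = _lognormal(rng, config.depth_mean, config.depth_cv, shape)
    depths[rock] = 0.0
    return SoilGrid(depths=depths, cell_side=config.cell_side)


def gen_resource_samples(
    patch_map: PatchMap, config: SynthConfig, seed: int
) -> pd.DataFrame:
    """Per-patch quadrat records of Sd, SWC, TC and TN.

    Each patch receives ``config.samples_per_patch`` records (>= 1) drawn
    independently from lognormal distributions with the configured means and
    CVs; CV = 0 collapses a variable to its exact mean.
    """
    if patch_map.n_patches < 1:
        raise ValueError("patch map has no patches")
    rng = np.random.default_rng(seed)
    n_q = config.samples_per_patch
    rows = []
    for pid in patch_map.patch_ids:
        frame = pd.DataFrame(
            {
                "patch_id": pid,
                "Sd_cm": _lognormal(rng, config.depth_mean, config.depth_cv, n_q),
                "SWC_pct": _lognormal(rng, config.swc_mean, config.swc_cv, n_q),
                "TC_gkg": _lognormal(rng, config.tc_mean, config.tc_cv, n_q),
                "TN_gkg": _lognormal(rng, config.tn_mean, config.tn_cv, n_q),
            }
        )
        rows.append(frame)
    return pd.concat(rows, ignore_index=True)


def _patch_areas(patches) -> pd.DataFrame:
    """Normalize a patch collection to a (patch_id, PA_m2) frame."""
    if isinstance(patches, pd.DataFrame):
        if not {"patch_id", "PA_m2"} <= set(patches.columns):
            raise ValueError("patches frame needs 'patch_id' and 'PA_m2' columns")
        frame = patches[["patch_id", "PA_m2"]].copy()
    elif isinstance(patches, dict):
        frame = pd.DataFrame(
            {"patch_id": list(patches.keys()), "PA_m2": list(patches.values())}
        )
    else:
        raise TypeError("patches must be a DataFrame or a {patch_id: area} mapping")
    if frame.empty:
        raise ValueError("patch collection is empty")
    if (frame["PA_m2"] <= 0).any():
        raise ValueError("patch areas must be > 0")
    return frame


def _pick_filtered(
    rng: np.random.Generator, dist: np.ndarray, k: int, strength: float
) -> np.ndarray:
    """k tips biased toward one clade: weights exp(−strength·d(tip, seed tip))."""
    n = dist.shape[0]
    seed_tip = int(rng.integers(n))
    # scale distances so strength is comparable across trees of any depth
    scale = dist[dist > 0].mean() if np.any(dist > 0) else 1.0
    weights = np.exp(-strength * dist[seed_tip] / scale)
    weights /= weights.sum()
    return rng.choice(n, size=k, replace=False, p=weights)


def _pick_overdispersed(rng: np.random.Generator, dist: np.ndarray, k: int) -> np.ndarray:
    """Greedy maximin: add the tip farthest from the current selection."""
    n = dist.shape[0]
    chosen = [int(rng.integers(n))]
    min_d = dist[chosen[0]].copy()
    for _ in range(k - 1):
        min_d[chosen] = -np.inf
        nxt = int(np.argmax(min_d))
        chosen.append(nxt)
        min_d = np.minimum(min_d, dist[nxt])
    return np.asarray(chosen)


def gen_communities(
    patches, tree: PhyloTree, config: SynthConfig, seed: int
) -> pd.DataFrame:
    """Patch × species abundance matrix with a log-area richness gradient.

    Expected richness is ``richness_intercept + richness_slope·log10(PA)``
    plus optional Gaussian noise, rounded and clipped to [1, n_tips] (with a
    log entry when clipping occurs). Species are drawn without replacement:
    uniformly (``random``), biased toward one clade (``filtered``, weight
    decaying with cophenetic distance from a seed tip at rate
    ``filter_strength``), or greedily toward maximal pairwise distance
    (``overdispersed``). Abundances are positive integers.
    """
    frame = _patch_areas(patches)
    rng = np.random.default_rng(seed)
    tips = np.asarray(tree.tip_labels)
    n_tips = len(tips)
    dist = (
        tree.cophenetic().values
        if config.assembly_mode in ("filtered", "overdispersed")
        else None
    )
    matrix = pd.DataFrame(
        0, index=pd.Index(frame["patch_id"], name="patch_id"), columns=tips, dtype=int
    )
    n_clipped = 0
    for pid, pa in zip(frame["patch_id"], frame["PA_m2"]):
        target = config.richness_intercept + config.richness_slope * np.log10(pa)
        if config.richness_noise_sd > 0:
            target += rng.normal(0.0, config.richness_noise_sd)
        k = int(round(target))
        if k < 1 or k > n_tips:
            n_clipped += 1
            k = min(max(k, 1), n_tips)
        if config.assembly_mode == "filtered":
            idx = _pick_filtered(rng, dist, k, config.filter_strength)
        elif config.assembly_mode == "overdispersed":
            idx = _pick_overdispersed(rng, dist, k)
        else:
            idx = rng.choice(n_tips, size=k, replace=False)
        abundance = 1 + rng.poisson(max(config.abundance_mean - 1, 0.0), size=k)
        matrix.loc[pid, tips[idx]] = abundance
    if n_clipped:
        logger.info(
            "richness target clipped to [1, %d] for %d patch(es)", n_tips, n_clipped
        )
    return matrix


def gen_patch_areas(
    n_patches: int,
    seed: int,
    median_area: float = 6.0,
    sigma: float = 1.1,
    min_area: float = 0.15,
    max_area: float = 67.19,
) -> pd.DataFrame:
    """Lognormal patch-area spectrum for recovery experiments.

    Returns exactly ``n_patches`` areas (m²) clipped to the karst patch-size
    range, as a (patch_id, PA_m2) frame; a convenience when an experiment
    needs a fixed patch count rather than a delineated raster.
    """
    if n_patches < 1:
        raise ValueError("n_patches must be >= 1")
    rng = np.random.default_rng(seed)
    areas = np.clip(
        rng.lognormal(np.log(median_area), sigma, n_patches), min_area, max_area
    )
    return pd.DataFrame({"patch_id": np.arange(1, n_patches + 1), "PA_m2": areas})
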