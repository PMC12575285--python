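"""Assemble the per-patch analysis table and its statistical summaries.

Joins patch geometry, soil resources, taxonomic diversity and phylogenetic
structure into one table keyed by patch id, computes pairwise Pearson
correlations (pairwise-complete, with unadjusted and Holm-adjusted p-values)
and ordinary least-squares fits of each diversity metric on log10 patch
area, and writes everything to CSV together with a JSON run manifest.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass
from datetime import datetime, timezone
from pathlib import Path

import numpy as np
import pandas as pd
import scipy
from scipy import stats

import karstpatch
from karstpatch import diversity, geometry, nulls, phylo, resources

logger = logging.getLogger(__name__)

__all__ = [
    "FitResult",
    "PearsonResult",
    "pearson_matrix",
    "fit_loglinear",
    "build_patch_table",
    "build_report",
]

#: diversity/structure metrics regressed on log10(PA) in the report
FIT_METRICS = ["R", "Hprime", "E", "PD", "NRI", "NTI"]


@dataclass(frozen=True)
class FitResult:
    """OLS fit of y on log10(PA)."""

    slope: float
    intercept: float
    r_squared: float
    p_value: float
    n: int


@dataclass(frozen=True)
class PearsonResult:
    """Pairwise-complete Pearson correlations with p-values."""

    r: pd.DataFrame
    p: pd.DataFrame
    p_holm: pd.DataFrame  # Holm step-down adjustment (extension, not in Tables 1-2)


def pearson_matrix(table: pd.DataFrame, variables=None) -> PearsonResult:
    """Pearson r and two-sided p for every variable pair, pairwise-complete.

    Pairs with fewer than 3 complete rows or a constant column get NaN.
    The diagonal is 1 and the matrix is symmetric by construction.
    """
    if variables is None:
        variables = [c for c in table.columns if table[c].dtype.kind in "fi"]
    m = len(variables)
    r = np.full((m, m), np.nan)
    p = np.full((m, m), np.nan)
    np.fill_diagonal(r, 1.0)
    np.fill_diagonal(p, 0.0)
    for i in range(m):
        for j in range(i + 1, m):
            x = table[variables[i]].to_numpy(dtype=float)
            y = table[variables[j]].to_numpy(dtype=float)
            ok = np.isfinite(x) & np.isfinite(y)
            if ok.sum() < 3 or np.std(x[ok]) == 0 or np.std(y[ok]) == 0:
                continue
            res = stats.pearsonr(x[ok], y[ok])
            r[i, j] = r[j, i] = res.statistic
            p[i, j] = p[j, i] = res.pvalue
    p_holm = _holm_adjust(p)
    idx = pd.Index(variables)
    return PearsonResult(
        r=pd.DataFrame(r, index=idx, columns=idx),
        p=pd.DataFrame(p, index=idx, columns=idx),
        p_holm=pd.DataFrame(p_holm, index=idx, columns=idx),
    )


def _holm_adjust(p: np.ndarray) -> np.ndarray:
    """Holm step-down adjustment over the off-diagonal upper triangle."""
    m = p.shape[0]
    iu = np.triu_indices(m, k=1)
    raw = p[iu]
    finite = np.isfinite(raw)
    adjusted = np.full_like(raw, np.nan)
    if finite.any():
        vals = raw[finite]
        n_tests = len(vals)
        order = np.argsort(vals)
        stepped = vals[order] * (n_tests - np.arange(n_tests))
        stepped = np.minimum(np.maximum.accumulate(stepped), 1.0)
        unsorted = np.empty(n_tests)
        unsorted[order] = stepped
        adjusted[finite] = unsorted
    out = np.full_like(p, np.nan)
    np.fill_diagonal(out, 0.0)
    out[iu] = adjusted
    out[(iu[1], iu[0])] = adjusted
    return out


def fit_loglinear(pa, y) -> FitResult:
    """Ordinary least squares of ``y`` on log10(PA).

    Requires positive areas and at least 3 finite points; a constant design
    (all areas equal) yields a NaN fit with a warning, and a constant
    response fits slope 0 with R² = 0.
    """
    pa = np.asarray(pa, dtype=float)
    y = np.asarray(y, dtype=float)
    if pa.shape != y.shape:
        raise ValueError("PA and y must have the same length")
    if np.any(pa[np.isfinite(pa)] <= 0):
        raise ValueError("patch areas must be > 0")
    ok = np.isfinite(pa) & np.isfinite(y)
    if ok.sum() < 3:
        raise ValueError("need at least 3 complete (PA, y) points")
    x = np.log10(pa[ok])
    y = y[ok]
    n = int(ok.sum())
    if np.std(x) == 0:
        logger.warning("constant PA: log-linear fit undefined")
        return FitResult(math.nan, math.nan, math.nan, math.nan, n)
    if np.std(y) == 0:
        return FitResult(0.0, float(y[0]), 0.0, 1.0, n)
    res = stats.linregress(x, y)
    return FitResult(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r_squared=float(res.rvalue**2),
        p_value=float(res.pvalue),
        n=n,
    )


def build_patch_table(
    patch_metrics: pd.DataFrame,
    resource_table: pd.DataFrame | None = None,
    diversity_table: pd.DataFrame | None = None,
    pd_values: pd.Series | None = None,
    structure_table: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """One row per patch: geometry, resources, diversity and structure.

    Patch ids present in an auxiliary table but absent from the geometry
    table are orphans and raise an error listing them. Missing metrics are
    NaN, never 0. Adds the perimeter-to-area ratio column ``PA_ratio``.
    """
    table = patch_metrics.copy()
    table["PA_ratio"] = table["PM_m"] / table["PA_m2"]
    known = set(table["patch_id"])
    for name, aux in (
        ("resources", resource_table),
        ("diversity", diversity_table),
        ("structure", structure_table),
    ):
        if aux is None:
            continue
        orphans = sorted(set(aux["patch_id"]) - known)
        if orphans:
            raise ValueError(f"{name} table has unknown patch ids: {orphans}")
        drop = [
            c
            for c in aux.columns
            if c.startswith("class_") or (c != "patch_id" and c in table.columns)
        ]
        table = table.merge(aux.drop(columns=drop), on="patch_id", how="left")
    if pd_values is not None:
        orphans = sorted(set(pd_values.index) - known)
        if orphans:
            raise ValueError(f"PD series has unknown patch ids: {orphans}")
        table = table.merge(
            pd_values.rename("PD").rename_axis("patch_id").reset_index(),
            on="patch_id",
            how="left",
        )
    return table


def build_report(
    grid: geometry.SoilGrid,
    samples: pd.DataFrame,
    communities: pd.DataFrame,
    tree: phylo.PhyloTree,
    out_dir,
    connectivity: int = 4,
    n_perm: int = 999,
    seed: int | None = None,
    consistent_base: bool = False,
    meta: dict | None = None,
) -> dict[str, Path]:
    """Run the full pipeline and write all report artifacts to ``out_dir``.

    Outputs: patch_map.csv, patch_metrics.csv, patch_resources.csv,
    diversity.csv, phylostructure.csv, patch_table.csv, summary.csv,
    correlations_{r,p,p_holm}.csv, fits.csv and manifest.json. Returns a
    name → path mapping.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    patch_map = geometry.delineate_patches(grid, connectivity=connectivity)
    metrics = geometry.patch_metrics(patch_map)

    resource_table = resources.patch_resources_table(samples)
    div_table = diversity.diversity_table(communities, consistent_base=consistent_base)
    pd_values = pd.Series(
        {
            pid: tree.faith_pd(taxa) if (taxa := diversity.community_members(communities, pid)) else math.nan
            for pid in communities.index
        },
        name="PD",
    )
    structure = nulls.phylostructure_table(tree, communities, n_perm=n_perm, seed=seed)

    table = build_patch_table(
        metrics,
        resource_table=resource_table,
        diversity_table=div_table,
        pd_values=pd_values,
        structure_table=structure,
    )

    numeric = [
        c
        for c in table.columns
        if c != "patch_id" and table[c].dtype.kind in "fi"
    ]
    summary_rows = []
    for col in numeric:
        vals = table[col].to_numpy(dtype=float)
        if np.isfinite(vals).sum() < 2:
            continue
        row = geometry.summarize_patch_properties(vals).as_dict()
        row["variable"] = col
        summary_rows.append(row)
    summary = pd.DataFrame(summary_rows)[
        ["variable", "min", "max", "mean", "sd", "cv", "n", "n_excluded"]
    ]

    corr = pearson_matrix(table, [c for c in numeric if not c.startswith("n_")])

    fit_rows = []
    for metric in FIT_METRICS:
        if metric not in table.columns:
            continue
        try:
            fit = fit_loglinear(table["PA_m2"], table[metric])
        except ValueError as exc:
            logger.warning("skipping fit of %s on log10(PA): %s", metric, exc)
            continue
        fit_rows.append(
            {
                "metric": metric,
                "slope": fit.slope,
                "intercept": fit.intercept,
                "r_squared": fit.r_squared,
                "p_value": fit.p_value,
                "n": fit.n,
            }
        )
    fits = pd.DataFrame(fit_rows)

    paths: dict[str, Path] = {}

    def _write(name: str, writer) -> None:
        path = out / name
        writer(path)
        paths[name] = path

    _write("patch_map.csv", patch_map.to_csv)
    _write("patch_metrics.csv", lambda p: metrics.to_csv(p, index=False))
    _write("patch_resources.csv", lambda p: resource_table.to_csv(p, index=False))
    _write("diversity.csv", lambda p: div_table.to_csv(p, index=False))
    _write("phylostructure.csv", lambda p: structure.to_csv(p, index=False))
    _write("patch_table.csv", lambda p: table.to_csv(p, index=False))
    _write("summary.csv", lambda p: summary.to_csv(p, index=False))
    _write("correlations_r.csv", corr.r.to_csv)
    _write("correlations_p.csv", corr.p.to_csv)
    _write("correlations_p_holm.csv", corr.p_holm.to_csv)
    _write("fits.csv", lambda p: fits.to_csv(p, index=False))

    manifest = {
        "karstpatch_version": karstpatch.__version__,
        "numpy_version": np.__version__,
        "pandas_version": pd.__version__,
        "scipy_version": scipy.__version__,
        "connectivity": connectivity,
        "n_perm": n_perm,
        "seed": seed,
        "consistent_base": consistent_base,
        "n_patches": int(patch_map.n_patches),
        "timestamp": datetime.now(timezone.utc).isoformat(),
    }
    if meta:
        manifest.update(meta)
    _write(
        "manifest.json",
        lambda p: p.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n"),
    )
    return paths
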