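"""Driver attribution for per-unit flux patterns.

Summarizes flux means/trends and habitat, disturbance, and water indicators
per management unit, explores their joint structure with a PCA on the
correlation matrix (with iterative pruning of weakly loading variables), and
quantifies hypothesized causal pathways with a recursive observed-variable
path model (equation-wise least squares on standardized variables, which for
recursive systems coincides with maximum likelihood).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
import statsmodels.api as sm

from .synth import HABITATS, PIXEL_SIZE_M, HabitatMap

SIGNIFICANCE_LEVELS = ((0.0001, "***"), (0.005, "**"), (0.05, "*"))


def significance_stars(p: float) -> str:
    for level, stars in SIGNIFICANCE_LEVELS:
        if p < level:
            return stars
    return ""


@dataclass
class PCAResult:
    eigenvalues: np.ndarray
    percent_variance: np.ndarray
    loadings: pd.DataFrame   # variables x components
    scores: pd.DataFrame     # units x components
    variables: list


@dataclass
class PathModel:
    edges: pd.DataFrame          # from, to, coef, se, p, stars
    r2: dict                     # endogenous variable -> R^2
    indirect: pd.DataFrame       # source, target, effect (sum over paths)
    spec: list = field(default_factory=list)


def build_unit_summaries(unit_map: np.ndarray, hab_map: HabitatMap,
                         annual_mass: dict, indicator_rasters: dict | None = None,
                         trend_per_unit: dict | None = None) -> pd.DataFrame:
    """Zonal summary table: one row per management unit.

    ``annual_mass`` maps gas -> {year: (y, x) pixel mass grid}; means over the
    window are reported per unit together with habitat percent areas,
    optional indicator-raster means and optional precomputed trends.
    Units with zero pixels are omitted; missing indicators stay NaN.
    """
    rows = []
    for unit in np.unique(unit_map):
        sel = unit_map == unit
        n_pix = int(sel.sum())
        if n_pix == 0:
            continue
        row: dict = {"unit_id": int(unit), "n_pixels": n_pix}
        for hab in HABITATS:
            row[f"pct_{hab}"] = 100.0 * float((hab_map.mask(hab) & sel).sum()) / n_pix
        # distance of the unit centroid to the western shore (col 0), km
        cols = np.nonzero(sel)[1]
        row["dist_to_shore"] = float(cols.mean()) * PIXEL_SIZE_M / 1000.0
        for gas, per_year in annual_mass.items():
            vals = [np.nansum(np.where(sel, g, np.nan)) for g in per_year.values()]
            row[f"mean_{gas.lower()}"] = float(np.mean(vals)) if vals else np.nan
        if indicator_rasters:
            for name, raster in indicator_rasters.items():
                row[name] = float(np.asarray(raster, dtype=float)[sel].mean())
        if trend_per_unit:
            for name, per_unit in trend_per_unit.items():
                row[name] = per_unit.get(int(unit), np.nan)
        rows.append(row)
    return pd.DataFrame(rows)


def _standardize(df: pd.DataFrame, variables: list) -> np.ndarray:
    X = df[variables].to_numpy(dtype=float)
    if np.isnan(X).any():
        bad = [v for v in variables if df[v].isna().any()]
        raise ValueError(f"missing values in variables: {bad}")
    sd = X.std(axis=0, ddof=1)
    if (sd == 0).any():
        bad = [v for v, s in zip(variables, sd) if s == 0]
        raise ValueError(f"constant variable(s): {bad}")
    return (X - X.mean(axis=0)) / sd


def pca(summaries: pd.DataFrame, variables: list, standardize: bool = True) -> PCAResult:
    """PCA via eigendecomposition of the correlation (or covariance) matrix.

    Components are ordered by descending eigenvalue; each loading column is
    unit-norm with its largest-|loading| element made positive.
    """
    if len(summaries) < 3:
        raise ValueError("need at least 3 units")
    if len(variables) < 2:
        raise ValueError("need at least 2 variables")
    if standardize:
        Z = _standardize(summaries, variables)
    else:
        X = summaries[variables].to_numpy(dtype=float)
        Z = X - X.mean(axis=0)
    C = (Z.T @ Z) / (len(Z) - 1)
    eigvals, eigvecs = np.linalg.eigh(C)
    order = np.argsort(eigvals)[::-1]
    eigvals = np.clip(eigvals[order], 0.0, None)
    eigvecs = eigvecs[:, order]
    for j in range(eigvecs.shape[1]):
        k = np.argmax(np.abs(eigvecs[:, j]))
        if eigvecs[k, j] < 0:
            eigvecs[:, j] = -eigvecs[:, j]
    pct = 100.0 * eigvals / eigvals.sum()
    comp_names = [f"PC{i + 1}" for i in range(len(eigvals))]
    loadings = pd.DataFrame(eigvecs, index=variables, columns=comp_names)
    scores = pd.DataFrame(Z @ eigvecs, columns=comp_names)
    return PCAResult(eigenvalues=eigvals, percent_variance=pct,
                     loadings=loadings, scores=scores, variables=list(variables))


def prune_variables(summaries: pd.DataFrame, variables: list,
                    threshold: float = 0.3, protect: tuple = (),
                    cum_variance: float = 0.7) -> tuple[list, PCAResult]:
    """Iteratively drop the weakest-loading variable until all load >= threshold.

    At each step the PCA is refit; the retained components are the leading
    ones that together explain ``cum_variance`` of the variance (so a pure
    noise variable cannot shelter in its own trailing component), and the
    variable with the smallest maximum |loading| across them is removed if
    that maximum is below the threshold.  Variables in ``protect`` (e.g. the
    flux responses) are never dropped.
    """
    kept = list(variables)
    while True:
        if len([v for v in kept if v not in protect]) == 0 or len(kept) < 2:
            raise ValueError("pruning removed all prunable variables")
        result = pca(summaries, kept)
        cum = np.cumsum(result.percent_variance) / 100.0
        n_keep = max(int(np.searchsorted(cum, cum_variance) + 1), 1)
        max_load = result.loadings.iloc[:, :n_keep].abs().max(axis=1)
        candidates = max_load.drop(labels=[v for v in protect if v in max_load.index])
        weakest = candidates.idxmin()
        if candidates[weakest] >= threshold:
            return kept, result
        kept.remove(weakest)


def fit_path_model(spec: list, summaries: pd.DataFrame) -> PathModel:
    """Recursive path model on standardized observed variables.

    ``spec`` is a list of (source, target) directed edges; the graph must be
    acyclic.  Each endogenous variable is regressed on its parents by OLS on
    standardized variables, giving standardized coefficients, SEs, two-sided
    p-values, and per-equation R^2.  Indirect effects are sums over directed
    paths of the products of path coefficients.
    """
    g = nx.DiGraph(spec)
    if not nx.is_directed_acyclic_graph(g):
        raise ValueError("path specification contains a cycle")
    variables = sorted(g.nodes)
    Z = pd.DataFrame(_standardize(summaries, variables), columns=variables)
    edge_rows = []
    r2 = {}
    coefs: dict[tuple, float] = {}
    for target in variables:
        parents = sorted(g.predecessors(target))
        if not parents:
            continue
        X = Z[parents].to_numpy()
        cond = np.linalg.cond(X.T @ X)
        if cond > 1e8:
            raise ValueError(f"collinear predictors for {target!r}: {parents} "
                             f"(condition number {cond:.2g})")
        fit = sm.OLS(Z[target].to_numpy(), X).fit()
        r2[target] = float(fit.rsquared)
        for i, parent in enumerate(parents):
            p_val = float(fit.pvalues[i])
            coefs[(parent, target)] = float(fit.params[i])
            edge_rows.append({"from": parent, "to": target,
                              "coef": float(fit.params[i]), "se": float(fit.bse[i]),
                              "p": p_val, "stars": significance_stars(p_val)})
    indirect_rows = []
    for source in variables:
        for target in variables:
            if source == target:
                continue
            total = 0.0
            found = False
            for path in nx.all_simple_paths(g, source, target):
                if len(path) < 3:
                    continue  # direct edges are not indirect effects
                found = True
                prod = 1.0
                for u, v in zip(path[:-1], path[1:]):
                    prod *= coefs[(u, v)]
                total += prod
            if found:
                indirect_rows.append({"source": source, "target": target, "effect": total})
    return PathModel(edges=pd.DataFrame(edge_rows), r2=r2,
                     indirect=pd.DataFrame(indirect_rows,
                                           columns=["source", "target", "effect"]),
                     spec=list(spec))


def hurricane_damage_ratio(ghost_forest_mask: np.ndarray,
                           mangrove_mask: np.ndarray) -> float:
    """Ratio of post-storm ghost-forest area to pre-storm mangrove area."""
    mangrove_area = float(np.asarray(mangrove_mask, dtype=bool).sum())
    if mangrove_area == 0:
        return float("nan")
    return float(np.asarray(ghost_forest_mask, dtype=bool).sum()) / mangrove_area
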