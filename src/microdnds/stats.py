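"""Cross-species statistics of pathway constraint.

Taylor's-law mean-variance scaling across pathways (with the slope-vs-2
t-test), the coefficient-of-variation summary, and the decay of between-
species pathway-correlation with phylogenetic distance (Mantel-style
significance).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import dendropy
import numpy as np
import pandas as pd
from scipy import stats as sps

from .pathways import PathwayMatrix, matrix_summaries

logger = logging.getLogger(__name__)


@dataclass
class ScalingFit:
    """OLS of log10(variance) on log10(mean) across pathways; H0: slope = 2."""

    slope: float
    intercept: float
    slope_se: float
    t_vs_2: float
    p_one_sided: float
    p_two_sided: float
    n_pathways: int

    def to_dict(self) -> dict:
        return self.__dict__.copy()


@dataclass
class PhyloSignalFit:
    """Slope of pair correlation on phylogenetic distance with Mantel p."""

    beta: float
    intercept: float
    p_mantel: float
    p_ols: float
    n_pairs: int
    n_mantel: int
    seed: int | None

    def to_dict(self) -> dict:
        return self.__dict__.copy()


def taylor_regression(matrix: PathwayMatrix, min_species_per_pathway: int = 3) -> ScalingFit:
    """Mean-variance power-law fit across pathways on log-log axes.

    Slope 2 means constant coefficient of variation. Pathways with zero
    variance (log undefined) are excluded with a log line; one-sided P is
    the upper tail P(T >= t_vs_2).
    """
    summ = matrix_summaries(matrix, min_presence=min_species_per_pathway)["pathway"]
    usable = summ[(summ["mean"] > 0) & (summ["variance"] > 0)]
    dropped = len(summ) - len(usable)
    if dropped:
        logger.warning("taylor_regression: %d pathways with zero variance or mean excluded", dropped)
    n = len(usable)
    if n < 3:
        raise ValueError(f"need >= 3 usable pathways, got {n}")
    x = np.log10(usable["mean"].to_numpy())
    y = np.log10(usable["variance"].to_numpy())
    xm, ym = x.mean(), y.mean()
    sxx = float(np.sum((x - xm) ** 2))
    if sxx == 0:
        raise ValueError("all pathway means identical; slope undefined")
    slope = float(np.sum((x - xm) * (y - ym)) / sxx)
    intercept = float(ym - slope * xm)
    resid = y - (intercept + slope * x)
    df = n - 2
    s2 = float(np.sum(resid**2) / df)
    if s2 < 1e-20:  # numerically perfect fit: t is rounding noise
        s2 = 0.0
    se = float(np.sqrt(s2 / sxx))
    t = (slope - 2.0) / se if se > 0 else 0.0
    return ScalingFit(
        slope=slope,
        intercept=intercept,
        slope_se=se,
        t_vs_2=t,
        p_one_sided=float(sps.t.sf(t, df)),
        p_two_sided=float(2 * sps.t.sf(abs(t), df)),
        n_pathways=n,
    )


def cv_summary(
    matrix: PathwayMatrix,
    min_species_per_pathway: int = 3,
    n_boot: int = 2000,
    seed: int = 0,
) -> dict:
    """Per-pathway CV of dN/dS across species plus a bootstrap CI on the median."""
    summ = matrix_summaries(matrix, min_presence=min_species_per_pathway)["pathway"]
    cvs = summ["cv"].dropna()
    if cvs.empty:
        raise ValueError("no pathway has a defined CV")
    rng = np.random.default_rng(seed)
    arr = cvs.to_numpy()
    boots = np.median(arr[rng.integers(0, arr.size, size=(n_boot, arr.size))], axis=1)
    lo, hi = np.percentile(boots, [2.5, 97.5])
    return {
        "per_pathway": cvs,
        "median_cv": float(np.median(arr)),
        "median_ci": (float(lo), float(hi)),
        "n_pathways": int(arr.size),
    }


def pairwise_pathway_correlation(
    matrix: PathwayMatrix,
    min_shared_pathways: int = 5,
    method: str = "pearson",
    log_scale: bool = True,
) -> pd.DataFrame:
    """Correlation of two species' pathway dN/dS vectors, per species pair.

    Pearson (default) on log10 values over the pathways both species have
    unmasked; pairs sharing fewer than ``min_shared_pathways`` are dropped,
    as are pairs where either shared vector has zero variance.
    """
    frame = matrix.to_frame()
    if log_scale:
        with np.errstate(divide="ignore"):
            frame = np.log10(frame)
        frame = frame.replace(-np.inf, np.nan)
    species = list(frame.index)
    rows = []
    n_dropped = 0
    for a_idx in range(len(species)):
        for b_idx in range(a_idx + 1, len(species)):
            a, b = species[a_idx], species[b_idx]
            sub = frame.loc[[a, b]].dropna(axis=1)
            if sub.shape[1] < min_shared_pathways:
                n_dropped += 1
                continue
            u, v = sub.loc[a].to_numpy(), sub.loc[b].to_numpy()
            if np.std(u) == 0 or np.std(v) == 0:
                n_dropped += 1
                continue
            if method == "pearson":
                r = float(sps.pearsonr(u, v).statistic)
            elif method == "spearman":
                r = float(sps.spearmanr(u, v).statistic)
            else:
                raise ValueError(f"unknown correlation method {method!r}")
            rows.append({"species_a": a, "species_b": b, "r": r, "n_shared": sub.shape[1]})
    if n_dropped:
        logger.info("pairwise_pathway_correlation: %d pairs dropped (overlap/variance)", n_dropped)
    return pd.DataFrame(rows, columns=["species_a", "species_b", "r", "n_shared"])


def _pair_slope(corr: np.ndarray, dist: np.ndarray) -> tuple[float, float]:
    dm, cm = dist.mean(), corr.mean()
    sxx = float(np.sum((dist - dm) ** 2))
    if sxx == 0:
        raise ValueError("constant distances; slope undefined")
    beta = float(np.sum((dist - dm) * (corr - cm)) / sxx)
    return beta, float(cm - beta * dm)


def phylo_distance_regression(
    correlations: pd.DataFrame,
    distances: pd.DataFrame,
    n_mantel: int = 999,
    seed: int = 0,
    exact: bool = False,
) -> PhyloSignalFit:
    """Slope of pair correlation on phylogenetic distance, Mantel significance.

    Pairs share species, so OLS p-values overstate significance; the default
    test permutes species labels of the distance matrix (``n_mantel`` draws,
    two-sided on |beta|). ``exact=True`` enumerates all label permutations
    (small species sets only). The analytic OLS p is reported for comparison.
    """
    if correlations.empty:
        raise ValueError("no species-pair correlations supplied")
    d = distances
    if not d.index.equals(d.columns):
        raise ValueError("distance matrix must have identical row/column labels")
    arr = d.to_numpy(dtype=float)
    if not np.allclose(arr, arr.T):
        raise ValueError("distance matrix must be symmetric")
    if np.any(np.diag(arr) != 0):
        raise ValueError("distance matrix must have a zero diagonal")
    if np.any(arr < 0):
        raise ValueError("distances must be non-negative")

    species = sorted(set(correlations["species_a"]) | set(correlations["species_b"]))
    missing = [s for s in species if s not in d.index]
    if missing:
        raise ValueError(f"species without distances: {missing}")
    loc = {s: d.index.get_loc(s) for s in species}
    ia = correlations["species_a"].map(loc).to_numpy()
    ib = correlations["species_b"].map(loc).to_numpy()
    corr = correlations["r"].to_numpy(dtype=float)
    dist = arr[ia, ib]

    beta, intercept = _pair_slope(corr, dist)

    # analytic OLS p (reported but not the headline test)
    n = corr.size
    if n > 2:
        resid = corr - (intercept + beta * dist)
        s2 = float(np.sum(resid**2) / (n - 2))
        se = np.sqrt(s2 / np.sum((dist - dist.mean()) ** 2))
        p_ols = float(2 * sps.t.sf(abs(beta) / se, n - 2)) if se > 0 else 1.0
    else:
        p_ols = 1.0

    idx = np.arange(len(d.index))
    sub = arr  # full matrix; labels permuted below
    if exact:
        import itertools
        import math

        if math.factorial(len(idx)) > 50_000:
            raise ValueError("too many species for exact Mantel enumeration")
        betas = []
        for perm in itertools.permutations(idx):
            perm = np.asarray(perm)
            betas.append(_pair_slope(corr, sub[perm[ia], perm[ib]])[0])
        betas = np.asarray(betas)
        p_mantel = float(np.mean(np.abs(betas) >= abs(beta) - 1e-12))
        n_draws = betas.size
        used_seed = None
    else:
        rng = np.random.default_rng(seed)
        count = 0
        for _ in range(n_mantel):
            perm = rng.permutation(idx)
            b = _pair_slope(corr, sub[perm[ia], perm[ib]])[0]
            if abs(b) >= abs(beta) - 1e-12:
                count += 1
        p_mantel = (1 + count) / (n_mantel + 1)
        n_draws = n_mantel
        used_seed = seed
    return PhyloSignalFit(
        beta=beta,
        intercept=intercept,
        p_mantel=float(p_mantel),
        p_ols=p_ols,
        n_pairs=int(n),
        n_mantel=int(n_draws),
        seed=used_seed,
    )


def cophenetic_distances(tree: dendropy.Tree | str) -> pd.DataFrame:
    """Tip-to-tip path-length matrix from a newick tree.

    Accepts a dendropy tree, a newick string, or a path to a newick file.
    Errors on missing branch lengths or duplicate tip labels.
    """
    if isinstance(tree, str):
        try:
            if "(" in tree:
                tree = dendropy.Tree.get(data=tree, schema="newick")
            else:
                tree = dendropy.Tree.get(path=tree, schema="newick")
        except Exception as exc:
            if "uplicate" in str(exc):
                raise ValueError(f"tip labels are not unique: {exc}") from exc
            raise ValueError(f"failed to parse newick tree: {exc}") from exc
    labels = [leaf.taxon.label for leaf in tree.leaf_node_iter()]
    if len(set(labels)) != len(labels):
        raise ValueError("tip labels are not unique")
    for edge in tree.preorder_edge_iter():
        if edge.head_node is tree.seed_node:
            continue
        if edge.length is None:
            raise ValueError(
                f"missing branch length above node {edge.head_node.taxon.label if edge.head_node.taxon else '<internal>'}"
            )
    pdm = tree.phylogenetic_distance_matrix()
    labels = sorted(labels)
    taxa = {t.label: t for t in tree.taxon_namespace}
    out = pd.DataFrame(0.0, index=labels, columns=labels)
    for i, a in enumerate(labels):
        for b in labels[i + 1 :]:
            dist = pdm.patristic_distance(taxa[a], taxa[b])
            out.loc[a, b] = dist
            out.loc[b, a] = dist
    return out
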