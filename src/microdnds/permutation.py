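"""Paired permutation tests on the species x pathway matrix.

Exceptional species are found by shuffling values among species within every
pathway column; exceptional pathways by the mirrored scheme (shuffle within
each species row). A unit is flagged when its observed statistic falls
outside the 2.5-97.5% band of its permutation null.
"""

from __future__ import annotations

import itertools
import logging
import math
import warnings

import numpy as np
import pandas as pd

from .pathways import PathwayMatrix

logger = logging.getLogger(__name__)

_EXHAUSTIVE_LIMIT = 200_000


def empirical_pvalue(observed: float, null_values: np.ndarray, exact: bool = False) -> float:
    """Two-sided empirical p: deviation from the null median, add-one corrected.

    With ``exact=True`` the null is a full enumeration that includes the
    identity assignment, so the plain fraction is returned (no add-one).
    """
    nulls = np.asarray(null_values, dtype=float)
    if nulls.size == 0:
        raise ValueError("null_values must be non-empty")
    med = np.median(nulls)
    dev = abs(observed - med)
    tol = 1e-12 * max(1.0, dev)
    count = int(np.sum(np.abs(nulls - med) >= dev - tol))
    if exact:
        return count / nulls.size
    return (1 + count) / (nulls.size + 1)


def bh_adjust(p_values: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values (monotone, q >= p, capped at 1)."""
    p = np.asarray(p_values, dtype=float)
    if np.any((p <= 0) | (p > 1)):
        raise ValueError("p-values must lie in (0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    q_sorted = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(q_sorted[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


def _row_statistic(values: np.ndarray, statistic: str) -> np.ndarray:
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN rows
        if statistic == "mean":
            return np.nanmean(values, axis=-1)
        if statistic == "median":
            return np.nanmedian(values, axis=-1)
    raise ValueError(f"unknown statistic {statistic!r}")


def _null_row_stats(
    values: np.ndarray, mask: np.ndarray, B: int, rng: np.random.Generator, statistic: str
) -> np.ndarray:
    """(B, n_rows) row statistics under independent within-column shuffles.

    Only unmasked values move; the mask geometry is fixed, so every unit keeps
    its support structure and every column keeps its value multiset.
    """
    n_rows, n_cols = values.shape
    if statistic == "mean":
        row_sums = np.zeros((B, n_rows))
        counts = np.zeros(n_rows)
        for j in range(n_cols):
            rows_j = np.nonzero(mask[:, j])[0]
            k = rows_j.size
            if k == 0:
                continue
            vals_j = values[rows_j, j]
            perm = np.argsort(rng.random((B, k)), axis=1)
            row_sums[:, rows_j] += vals_j[perm]
            counts[rows_j] += 1
        with np.errstate(invalid="ignore", divide="ignore"):
            return row_sums / counts
    # generic path (median): materialize the permuted matrices
    permuted = np.full((B, n_rows, n_cols), np.nan)
    for j in range(n_cols):
        rows_j = np.nonzero(mask[:, j])[0]
        k = rows_j.size
        if k == 0:
            continue
        vals_j = values[rows_j, j]
        perm = np.argsort(rng.random((B, k)), axis=1)
        permuted[:, rows_j, j] = vals_j[perm]
    return _row_statistic(permuted, statistic)


def _exhaustive_row_stats(values: np.ndarray, mask: np.ndarray, statistic: str) -> np.ndarray:
    """Row statistics over ALL within-column assignments (small matrices only)."""
    n_rows, n_cols = values.shape
    col_rows, col_perms = [], []
    total = 1
    for j in range(n_cols):
        rows_j = np.nonzero(mask[:, j])[0]
        col_rows.append(rows_j)
        perms = [np.array(p) for p in itertools.permutations(values[rows_j, j])]
        col_perms.append(perms)
        total *= math.factorial(rows_j.size) if rows_j.size else 1
        if total > _EXHAUSTIVE_LIMIT:
            raise ValueError(
                f"exhaustive enumeration needs {total}+ assignments; use sampled permutations"
            )
    out = np.empty((total, n_rows))
    template = np.full((n_rows, n_cols), np.nan)
    for b, combo in enumerate(itertools.product(*col_perms)):
        m = template.copy()
        for j in range(n_cols):
            m[col_rows[j], j] = combo[j]
        out[b] = _row_statistic(m, statistic)
    return out


def test_species(
    matrix: PathwayMatrix,
    B: int = 10_000,
    seed: int = 0,
    statistic: str = "mean",
    exhaustive: bool = False,
) -> pd.DataFrame:
    """Permutation test for species with exceptional dN/dS.

    Statistic per species = ``statistic`` over its unmasked pathway cells;
    the null shuffles values among species independently within every pathway
    column. Returns one row per species with observed value, null 95% band,
    add-one two-sided empirical p, BH q-value and flag
    (``stronger`` = below the band, ``weaker`` = above it).
    """
    values, mask = matrix.values, matrix.mask
    n_rows = values.shape[0]
    if n_rows < 2 or np.sum(mask.any(axis=0)) < 2:
        raise ValueError("need >= 2 units and >= 2 columns with unmasked cells")
    if B < 100 and not exhaustive:
        warnings.warn(f"B={B} permutations is too few for stable 95% intervals")

    keep = mask.any(axis=1)
    if not keep.all():
        omitted = [matrix.species_ids[i] for i in np.nonzero(~keep)[0]]
        logger.info("test_species: fully masked units omitted: %s", omitted)

    observed = _row_statistic(np.where(mask, values, np.nan), statistic)
    rng = np.random.default_rng(seed)
    if exhaustive:
        nulls = _exhaustive_row_stats(values, mask, statistic)
        n_perm = nulls.shape[0]
    else:
        nulls = _null_row_stats(values, mask, B, rng, statistic)
        n_perm = B

    rows = []
    for i in np.nonzero(keep)[0]:
        null_i = nulls[:, i]
        null_i = null_i[~np.isnan(null_i)]
        lo, hi = np.percentile(null_i, [2.5, 97.5])
        obs = observed[i]
        p = empirical_pvalue(obs, null_i, exact=exhaustive)
        tol = 1e-12 * max(1.0, abs(obs))
        if obs < lo - tol:
            flag = "stronger"
        elif obs > hi + tol:
            flag = "weaker"
        else:
            flag = ""
        rows.append(
            {
                "unit_id": matrix.species_ids[i],
                "observed": float(obs),
                "null_lo": float(lo),
                "null_hi": float(hi),
                "empirical_p": float(p),
                "n_cells": int(mask[i].sum()),
                "n_perm": int(n_perm),
                "seed": seed,
                "flag": flag,
            }
        )
    out = pd.DataFrame(rows)
    out["q_value"] = bh_adjust(out["empirical_p"].to_numpy())
    return out


def test_pathways(
    matrix: PathwayMatrix,
    B: int = 10_000,
    seed: int = 0,
    statistic: str = "mean",
    exhaustive: bool = False,
) -> pd.DataFrame:
    """Mirrored test for pathways: shuffle within each species row.

    Implemented as :func:`test_species` on the transposed matrix (duality),
    so the statistic per pathway is taken over species.
    """
    return test_species(
        matrix.transpose(), B=B, seed=seed, statistic=statistic, exhaustive=exhaustive
    )
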