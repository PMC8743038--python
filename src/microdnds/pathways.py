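"""Coarse-graining: gene -> pathway mapping and the species x pathway matrix.

Each matrix cell holds the pooled dN/dS of all genes of one pathway across
all lineage pairs of one species; cells with too few pooled synonymous
differences are masked rather than reported as noisy ratios.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .records import compute_dnds

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class PathwayMap:
    """Single-level gene -> pathway assignment (one pathway per gene)."""

    entries: dict[str, str]
    pathway_names: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.entries:
            raise ValueError("pathway map is empty")

    @classmethod
    def from_frame(cls, table: pd.DataFrame) -> "PathwayMap":
        """Build from a table with gene_id / pathway_id (/ pathway_name) columns."""
        dup = table["gene_id"][table["gene_id"].duplicated()]
        if len(dup):
            raise ValueError(
                "genes mapped to more than one pathway (one pathway per gene "
                f"is required): {sorted(set(dup))[:10]}"
            )
        names = {}
        if "pathway_name" in table.columns:
            names = (
                table.dropna(subset=["pathway_name"])
                .drop_duplicates("pathway_id")
                .set_index("pathway_id")["pathway_name"]
                .to_dict()
            )
        return cls(entries=dict(zip(table["gene_id"], table["pathway_id"])), pathway_names=names)


@dataclass
class PathwayMatrix:
    """Species x pathway matrix of pooled dN/dS with missingness.

    ``values`` is NaN where masked; ``support`` holds the pooled synonymous
    difference count per cell (0 where no data at all).
    """

    species_ids: list[str]
    pathway_ids: list[str]
    values: np.ndarray  # float, NaN = masked
    support: np.ndarray  # int

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.support = np.asarray(self.support, dtype=int)
        expected = (len(self.species_ids), len(self.pathway_ids))
        if self.values.shape != expected or self.support.shape != expected:
            raise ValueError("matrix shape does not match axis labels")
        present = self.values[~np.isnan(self.values)]
        if np.any(present < 0):
            raise ValueError("dN/dS values must be non-negative")

    @property
    def mask(self) -> np.ndarray:
        """True where an estimate is present."""
        return ~np.isnan(self.values)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.species_ids, columns=self.pathway_ids)

    def support_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.support, index=self.species_ids, columns=self.pathway_ids)

    @classmethod
    def from_frame(cls, values: pd.DataFrame, support: pd.DataFrame | None = None) -> "PathwayMatrix":
        if support is None:
            support = pd.DataFrame(0, index=values.index, columns=values.columns)
        support = support.reindex(index=values.index, columns=values.columns).fillna(0)
        return cls(
            species_ids=list(values.index),
            pathway_ids=list(values.columns),
            values=values.to_numpy(dtype=float),
            support=support.to_numpy(dtype=int),
        )

    def transpose(self) -> "PathwayMatrix":
        return PathwayMatrix(
            species_ids=list(self.pathway_ids),
            pathway_ids=list(self.species_ids),
            values=self.values.T.copy(),
            support=self.support.T.copy(),
        )


def aggregate_by_pathway(
    table: pd.DataFrame,
    pathway_map: PathwayMap | None = None,
    min_support: int = 10,
) -> tuple[PathwayMatrix, dict]:
    """Pool counts per (species, pathway) across genes and lineage pairs.

    If ``pathway_map`` is None the table's own ``pathway_id`` column is used.
    Cells whose pooled synonymous difference count is below ``min_support``,
    and cells with pooled dS == 0 (undefined ratio), are masked. Rows and
    columns are sorted lexicographically so output is order-independent.
    """
    work = table.copy()
    if pathway_map is not None:
        work["pathway_id"] = work["gene_id"].map(pathway_map.entries)
    unmapped = work["pathway_id"].isna() | (work["pathway_id"] == "")
    n_unmapped = int(unmapped.sum())
    if n_unmapped:
        logger.info("aggregate_by_pathway: %d records without a pathway excluded", n_unmapped)
    work = work[~unmapped]
    if work.empty:
        raise ValueError("no records carry a pathway assignment")

    pooled = (
        work.groupby(["species_id", "pathway_id"], sort=True)[
            ["n_diff", "n_opp", "s_diff", "s_opp"]
        ]
        .sum()
        .reset_index()
    )
    species_ids = sorted(work["species_id"].unique())
    pathway_ids = sorted(work["pathway_id"].unique())
    s_index = {s: i for i, s in enumerate(species_ids)}
    p_index = {p: j for j, p in enumerate(pathway_ids)}

    values = np.full((len(species_ids), len(pathway_ids)), np.nan)
    support = np.zeros((len(species_ids), len(pathway_ids)), dtype=int)
    n_undefined = 0
    n_low_support = 0
    for row in pooled.itertuples(index=False):
        i, j = s_index[row.species_id], p_index[row.pathway_id]
        support[i, j] = int(row.s_diff)
        if row.s_diff < min_support:
            n_low_support += 1
            continue
        est = compute_dnds((int(row.n_diff), int(row.n_opp), int(row.s_diff), int(row.s_opp)))
        if est.ratio is None:
            n_undefined += 1
            continue
        values[i, j] = est.ratio

    if np.all(np.isnan(values)):
        raise ValueError(
            f"no (species, pathway) cell passed min_support={min_support}; "
            "lower the threshold or provide more data"
        )
    report = {
        "n_records_unmapped": n_unmapped,
        "n_cells_low_support": n_low_support,
        "n_cells_undefined_ratio": n_undefined,
        "n_cells_present": int(np.sum(~np.isnan(values))),
        "min_support": min_support,
    }
    matrix = PathwayMatrix(species_ids, pathway_ids, values, support)
    return matrix, report


def matrix_summaries(matrix: PathwayMatrix, min_presence: int = 3) -> dict[str, pd.DataFrame]:
    """Row/column summaries of the pathway matrix.

    Per pathway (over species): mean, unbiased variance, CV; pathways present
    in fewer than ``min_presence`` species are omitted. Per species: mean over
    its unmasked pathways. A pathway with mean 0 gets CV = NaN and is flagged.
    """
    frame = matrix.to_frame()
    counts = frame.notna().sum(axis=0)
    keep = counts[counts >= min_presence].index
    dropped = sorted(set(frame.columns) - set(keep))
    if dropped:
        logger.info("matrix_summaries: %d pathways below presence threshold omitted: %s",
                    len(dropped), dropped)
    sub = frame[keep]
    mean = sub.mean(axis=0)
    var = sub.var(axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        cv = np.sqrt(var) / mean
    cv[mean == 0] = np.nan
    pathway = pd.DataFrame(
        {
            "n_species": counts[keep],
            "mean": mean,
            "variance": var,
            "cv": cv,
            "cv_undefined": mean == 0,
        }
    )
    species = pd.DataFrame(
        {
            "n_pathways": frame.notna().sum(axis=1),
            "mean": frame.mean(axis=1),
        }
    )
    return {"pathway": pathway, "species": species}
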