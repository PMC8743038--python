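"""Per-gene divergence records and dN/dS arithmetic.

The currency of the package is a table of per-gene substitution counts for
one lineage pair of one species: nonsynonymous differences over
nonsynonymous opportunities (sites), and likewise for synonymous sites.
Group-level dN/dS is always a ratio of pooled counts, never a mean of
per-gene ratios.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

RECORD_COLUMNS = [
    "species_id",
    "pair_id",
    "gene_id",
    "pathway_id",
    "n_diff",
    "n_opp",
    "s_diff",
    "s_opp",
]

COUNT_COLUMNS = ["n_diff", "n_opp", "s_diff", "s_opp"]

#: Proportions at or above this value have no Jukes-Cantor correction.
JC_SINGULARITY = 0.75


class RecordValidationError(ValueError):
    """Raised when a divergence record violates its count invariants."""


@dataclass(frozen=True)
class GeneDivergenceRecord:
    """Substitution counts for one gene of one lineage pair of one species."""

    species_id: str
    pair_id: str
    gene_id: str
    n_diff: int
    n_opp: int
    s_diff: int
    s_opp: int
    pathway_id: str = ""

    def __post_init__(self) -> None:
        for name in COUNT_COLUMNS:
            value = getattr(self, name)
            if value != int(value) or value < 0:
                raise RecordValidationError(
                    f"{self.gene_id}: {name}={value!r} must be a non-negative integer"
                )
        if self.n_opp <= 0 or self.s_opp <= 0:
            raise RecordValidationError(
                f"{self.gene_id}: opportunities must be strictly positive "
                f"(n_opp={self.n_opp}, s_opp={self.s_opp})"
            )
        if self.n_diff > self.n_opp:
            raise RecordValidationError(
                f"{self.gene_id}: n_diff={self.n_diff} exceeds n_opp={self.n_opp}"
            )
        if self.s_diff > self.s_opp:
            raise RecordValidationError(
                f"{self.gene_id}: s_diff={self.s_diff} exceeds s_opp={self.s_opp}"
            )


@dataclass(frozen=True)
class DivergenceEstimate:
    """dN, dS and their ratio for one record or one pooled group.

    ``ratio`` is ``None`` (undefined) when dS == 0; it is never coerced to
    zero or infinity so downstream code must handle missingness explicitly.
    """

    dN: float
    dS: float
    ratio: float | None
    corrected: bool = False

    @property
    def defined(self) -> bool:
        return self.ratio is not None


def jukes_cantor(p: float | np.ndarray) -> float | np.ndarray:
    """Multiple-hit corrected distance -(3/4)ln(1 - 4p/3) for proportion p."""
    p = np.asarray(p, dtype=float)
    if np.any(p < 0) or np.any(p >= JC_SINGULARITY):
        raise ValueError(f"proportion outside [0, {JC_SINGULARITY}) cannot be JC-corrected")
    out = -0.75 * np.log1p(-(4.0 / 3.0) * p)
    return float(out) if out.ndim == 0 else out


def compute_dnds(
    counts: GeneDivergenceRecord | tuple[int, int, int, int],
    correction: str = "none",
) -> DivergenceEstimate:
    """dN, dS and dN/dS from substitution counts.

    Parameters
    ----------
    counts
        A :class:`GeneDivergenceRecord` or a ``(n_diff, n_opp, s_diff, s_opp)``
        tuple of pooled counts.
    correction
        ``"none"`` (raw proportions) or ``"jukes_cantor"``.

    Raises
    ------
    ValueError
        If a proportion is >= 3/4 under Jukes-Cantor correction, naming the
        offending record.
    """
    if isinstance(counts, GeneDivergenceRecord):
        label = counts.gene_id
        n_diff, n_opp, s_diff, s_opp = counts.n_diff, counts.n_opp, counts.s_diff, counts.s_opp
    else:
        label = "<pooled>"
        n_diff, n_opp, s_diff, s_opp = counts
    if n_opp <= 0 or s_opp <= 0:
        raise ValueError(f"{label}: opportunities must be strictly positive")
    pn = n_diff / n_opp
    ps = s_diff / s_opp
    if correction == "none":
        dn, ds = pn, ps
        corrected = False
    elif correction == "jukes_cantor":
        try:
            dn = jukes_cantor(pn)
            ds = jukes_cantor(ps)
        except ValueError as exc:
            raise ValueError(f"{label}: {exc}") from None
        corrected = True
    else:
        raise ValueError(f"unknown correction {correction!r}")
    ratio = dn / ds if ds > 0 else None
    return DivergenceEstimate(dN=dn, dS=ds, ratio=ratio, corrected=corrected)


def pool_counts(
    records: Iterable[GeneDivergenceRecord] | pd.DataFrame,
) -> tuple[int, int, int, int]:
    """Field-wise sums (n_diff, n_opp, s_diff, s_opp) over a non-empty record set."""
    if isinstance(records, pd.DataFrame):
        if records.empty:
            raise ValueError("cannot pool an empty record set")
        sums = records[COUNT_COLUMNS].sum()
        return tuple(int(sums[c]) for c in COUNT_COLUMNS)
    records = list(records)
    if not records:
        raise ValueError("cannot pool an empty record set")
    return (
        sum(r.n_diff for r in records),
        sum(r.n_opp for r in records),
        sum(r.s_diff for r in records),
        sum(r.s_opp for r in records),
    )


def records_to_frame(records: Sequence[GeneDivergenceRecord]) -> pd.DataFrame:
    """Materialize records into the canonical column layout."""
    return pd.DataFrame(
        [
            (r.species_id, r.pair_id, r.gene_id, r.pathway_id, r.n_diff, r.n_opp, r.s_diff, r.s_opp)
            for r in records
        ],
        columns=RECORD_COLUMNS,
    )


def frame_to_records(table: pd.DataFrame) -> list[GeneDivergenceRecord]:
    return [
        GeneDivergenceRecord(
            species_id=row.species_id,
            pair_id=row.pair_id,
            gene_id=row.gene_id,
            pathway_id=getattr(row, "pathway_id", "") or "",
            n_diff=int(row.n_diff),
            n_opp=int(row.n_opp),
            s_diff=int(row.s_diff),
            s_opp=int(row.s_opp),
        )
        for row in table.itertuples(index=False)
    ]


def filter_records(
    table: pd.DataFrame,
    min_s_opp: int = 10,
    min_pair_dS: float = 0.0,
    max_pair_dS: float = 0.3,
) -> tuple[pd.DataFrame, dict]:
    """Drop unreliable genes and out-of-range lineage pairs.

    Rules applied in order:

    1. genes with ``s_opp < min_s_opp`` are dropped;
    2. whole (species, pair) groups whose genome-wide pooled dS falls
       outside ``[min_pair_dS, max_pair_dS]`` are dropped.

    Returns the surviving table and a report with counts dropped per rule.
    """
    if min_s_opp < 0 or min_pair_dS < 0:
        raise ValueError("thresholds must be non-negative")
    if not min_pair_dS < max_pair_dS:
        raise ValueError("min_pair_dS must be < max_pair_dS")
    n_input = len(table)
    kept = table[table["s_opp"] >= min_s_opp]
    n_low_s_opp = n_input - len(kept)

    n_pair_out = 0
    dropped_pairs: list[list[str]] = []
    if not kept.empty:
        pooled = kept.groupby(["species_id", "pair_id"], sort=False)[["s_diff", "s_opp"]].sum()
        pair_ds = pooled["s_diff"] / pooled["s_opp"]
        bad = pair_ds[(pair_ds < min_pair_dS) | (pair_ds > max_pair_dS)].index
        if len(bad):
            key = pd.MultiIndex.from_frame(kept[["species_id", "pair_id"]])
            drop_mask = key.isin(bad)
            n_pair_out = int(drop_mask.sum())
            dropped_pairs = sorted([list(t) for t in bad])
            kept = kept[~drop_mask]
    report = {
        "n_input": n_input,
        "n_dropped_low_s_opp": n_low_s_opp,
        "n_dropped_pair_dS": n_pair_out,
        "dropped_pairs": dropped_pairs,
        "n_kept": len(kept),
        "thresholds": {
            "min_s_opp": min_s_opp,
            "min_pair_dS": min_pair_dS,
            "max_pair_dS": max_pair_dS,
        },
    }
    if kept.empty:
        raise ValueError(
            "all records were filtered out; review min_s_opp / pair dS thresholds "
            f"(report: {report})"
        )
    return kept.reset_index(drop=True), report
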