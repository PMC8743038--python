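"""File formats: TSV tables, newick trees, JSON results, YAML config.

All tables are tab-separated, UTF-8, '.' decimals, LF endings. Every file
written by the pipeline carries provenance (tool version, config hash, seed)
either as ``#`` comment header lines (TSV) or a ``meta`` field (JSON).
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .pathways import PathwayMap, PathwayMatrix
from .records import RECORD_COLUMNS, COUNT_COLUMNS, RecordValidationError

PATHWAY_MAP_COLUMNS = ["gene_id", "pathway_id", "pathway_name"]


@dataclass
class PipelineConfig:
    """Configuration of the full pipeline run (flags > file > defaults)."""

    records: str = ""
    pathway_map: str = ""
    tree: str = ""
    distances: str = ""
    out_dir: str = "results"
    min_s_opp: int = 10
    min_pair_ds: float = 0.0
    max_pair_ds: float = 0.3
    min_support: int = 10
    min_species_per_pathway: int = 3
    min_shared_pathways: int = 5
    permutations: int = 10_000
    n_mantel: int = 999
    statistic: str = "mean"
    correlation: str = "pearson"
    correction: str = "none"
    seed: int = 0

    @classmethod
    def from_file(cls, path: str | Path, **overrides) -> "PipelineConfig":
        with open(path, encoding="utf-8") as fh:
            data = yaml.safe_load(fh) or {}
        unknown = set(data) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        data.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**data)

    def to_dict(self) -> dict:
        return asdict(self)

    #: filesystem locations, excluded from the config digest so that the same
    #: analysis run from different directories yields identical artifacts
    PATH_FIELDS = ("records", "pathway_map", "tree", "distances", "out_dir")

    def digest(self) -> str:
        params = {k: v for k, v in self.to_dict().items() if k not in self.PATH_FIELDS}
        raw = json.dumps(params, sort_keys=True).encode()
        return hashlib.sha256(raw).hexdigest()[:16]


def provenance(config_hash: str = "", seed: int | None = None) -> dict:
    meta = {"tool": "microdnds", "version": __version__}
    if config_hash:
        meta["config_hash"] = config_hash
    if seed is not None:
        meta["seed"] = seed
    return meta


def _header_lines(meta: dict) -> str:
    return "".join(f"# {k}={v}\n" for k, v in meta.items())


def write_tsv(table: pd.DataFrame, path: str | Path, meta: dict | None = None,
              index: bool = False) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        if meta:
            fh.write(_header_lines(meta))
        table.to_csv(fh, sep="\t", index=index, lineterminator="\n")


def read_tsv(path: str | Path, **kwargs) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#", **kwargs)


def write_json(obj: dict, path: str | Path, meta: dict | None = None) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    payload = dict(obj)
    if meta:
        payload["meta"] = meta
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True, default=str)
        fh.write("\n")


def read_records(path: str | Path) -> pd.DataFrame:
    """Read and validate a gene-divergence table.

    Expects the exact header ``species_id pair_id gene_id pathway_id n_diff
    n_opp s_diff s_opp`` (tab-separated). Rows violating the count invariants
    are collected and reported together with 1-based line numbers.
    """
    table = pd.read_csv(path, sep="\t", comment="#", dtype={
        "species_id": str, "pair_id": str, "gene_id": str, "pathway_id": str,
    })
    missing = [c for c in RECORD_COLUMNS if c not in table.columns]
    if missing:
        raise RecordValidationError(f"{path}: missing required columns: {missing}")
    table = table[RECORD_COLUMNS]
    table["pathway_id"] = table["pathway_id"].fillna("")

    problems = []
    counts = table[COUNT_COLUMNS]
    if not all(pd.api.types.is_integer_dtype(counts[c]) for c in COUNT_COLUMNS):
        bad = counts.apply(lambda col: col != col.round()).any(axis=1)
        for i in table.index[bad]:
            problems.append(f"line {i + 2}: non-integer count")
        table[COUNT_COLUMNS] = counts.round().astype("int64", errors="ignore")
    checks = [
        (table["n_diff"] < 0, "n_diff < 0"),
        (table["s_diff"] < 0, "s_diff < 0"),
        (table["n_opp"] <= 0, "n_opp <= 0"),
        (table["s_opp"] <= 0, "s_opp <= 0"),
        (table["n_diff"] > table["n_opp"], "n_diff > n_opp"),
        (table["s_diff"] > table["s_opp"], "s_diff > s_opp"),
    ]
    for mask, label in checks:
        for i in table.index[mask]:
            problems.append(f"line {i + 2}: {label} ({table.loc[i, 'gene_id']})")
    if problems:
        raise RecordValidationError(
            f"{path}: {len(problems)} invalid rows:\n" + "\n".join(problems[:20])
        )
    table[COUNT_COLUMNS] = table[COUNT_COLUMNS].astype("int64")
    return table


def write_records(table: pd.DataFrame, path: str | Path, meta: dict | None = None) -> None:
    write_tsv(table[RECORD_COLUMNS], path, meta=meta)


def read_pathway_map(path: str | Path) -> PathwayMap:
    table = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    missing = [c for c in PATHWAY_MAP_COLUMNS[:2] if c not in table.columns]
    if missing:
        raise ValueError(f"{path}: pathway map missing columns {missing}")
    return PathwayMap.from_frame(table)


def write_pathway_map(pmap: PathwayMap, path: str | Path, meta: dict | None = None) -> None:
    table = pd.DataFrame(
        [(g, p, pmap.pathway_names.get(p, "")) for g, p in sorted(pmap.entries.items())],
        columns=PATHWAY_MAP_COLUMNS,
    )
    write_tsv(table, path, meta=meta)


def write_matrix(matrix: PathwayMatrix, path: str | Path, meta: dict | None = None) -> None:
    """Species rows x pathway columns; empty cell = masked. Support counts go
    to a sidecar ``<path>.support.json``."""
    frame = matrix.to_frame()
    frame.index.name = "species_id"
    write_tsv(frame, path, meta=meta, index=True)
    support = {
        s: {p: int(v) for p, v in row.items()}
        for s, row in matrix.support_frame().iterrows()
    }
    write_json({"support": support}, Path(str(path) + ".support.json"), meta=meta)


def read_matrix(path: str | Path) -> PathwayMatrix:
    frame = pd.read_csv(path, sep="\t", comment="#", index_col=0)
    frame.index = frame.index.astype(str)
    frame.columns = frame.columns.astype(str)
    support_path = Path(str(path) + ".support.json")
    support = None
    if support_path.exists():
        with open(support_path, encoding="utf-8") as fh:
            support = pd.DataFrame(json.load(fh)["support"]).T
            support = support.reindex(index=frame.index, columns=frame.columns).fillna(0)
    return PathwayMatrix.from_frame(frame, support)


def read_distances(path: str | Path) -> pd.DataFrame:
    """Square species-pair distance matrix from TSV (labels in row/col headers)."""
    frame = pd.read_csv(path, sep="\t", comment="#", index_col=0)
    frame.index = frame.index.astype(str)
    frame.columns = frame.columns.astype(str)
    if list(frame.index) != list(frame.columns):
        raise ValueError(f"{path}: distance matrix rows/columns differ")
    return frame


def write_distances(frame: pd.DataFrame, path: str | Path, meta: dict | None = None) -> None:
    out = frame.copy()
    out.index.name = "species_id"
    write_tsv(out, path, meta=meta, index=True)


def sha256_file(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()
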