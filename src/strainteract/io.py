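"""Table IO: FastANI parsing, role-typed TSV/CSV readers and writers.

Canonical on-disk dialect is TSV; CSV is accepted on read by sniffing the
delimiter of the first data line.  Lines starting with ``#`` are comment
headers (writers can record the seed and a config hash there).  Parsers
reject malformed input rather than coercing it; writers sort rows by the
role's key columns so output is deterministic.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .classify import ANITable

logger = logging.getLogger("strainteract")

__all__ = [
    "parse_fastani",
    "read_table",
    "write_table",
    "read_matrix",
    "write_matrix",
    "RunConfig",
    "ROLE_SCHEMAS",
]


@dataclass(frozen=True)
class TableSchema:
    required: tuple[str, ...]
    optional: tuple[str, ...]
    key: tuple[str, ...]
    numeric: tuple[str, ...]
    integer: tuple[str, ...] = ()


#: Documented schemas for each table role the pipeline consumes.
ROLE_SCHEMAS: dict[str, TableSchema] = {
    "design": TableSchema(
        required=("trial_id", "layout", "focal", "members"),
        optional=(),
        key=("trial_id",),
        numeric=(),
    ),
    "biomass": TableSchema(
        required=("trial_id", "isolate", "replicate", "day"),
        optional=("ct", "log10_copies"),
        key=("trial_id", "replicate", "day"),
        numeric=("ct", "log10_copies"),
        integer=("replicate", "day"),
    ),
    "amino": TableSchema(
        required=("focal_group", "medium_source", "amino_acid", "day", "replicate", "concentration"),
        optional=(),
        key=("focal_group", "medium_source", "amino_acid", "day", "replicate"),
        numeric=("concentration",),
        integer=("day", "replicate"),
    ),
    "transcription": TableSchema(
        required=("isolate", "gene", "condition", "log2_fold_change"),
        optional=("p_raw", "p_adjusted", "cog_category"),
        key=("isolate", "gene", "condition"),
        numeric=("log2_fold_change", "p_raw", "p_adjusted"),
    ),
    "pathway": TableSchema(
        required=("isolate", "amino_acid", "gene"),
        optional=(),
        key=("isolate", "amino_acid"),
        numeric=(),
    ),
}


def _sniff_sep(path: Path) -> str:
    with open(path) as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            return "\t" if "\t" in line else ","
    return "\t"


def read_table(path: str | Path, role: str) -> pd.DataFrame:
    """Read a role-typed table, validating schema, dtypes and key uniqueness."""
    if role not in ROLE_SCHEMAS:
        raise ValueError(f"unknown table role {role!r}; expected one of {sorted(ROLE_SCHEMAS)}")
    schema = ROLE_SCHEMAS[role]
    path = Path(path)
    df = pd.read_csv(path, sep=_sniff_sep(path), comment="#", dtype=str)
    missing = [c for c in schema.required if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required column(s) {missing} for role {role!r}")
    unknown = [c for c in df.columns if c not in schema.required + schema.optional]
    if unknown:
        raise ValueError(f"{path}: unknown column(s) {unknown} for role {role!r}")
    if role == "biomass" and not ({"ct", "log10_copies"} & set(df.columns)):
        raise ValueError(f"{path}: biomass table needs a 'ct' or 'log10_copies' column")
    for col in schema.numeric:
        if col in df.columns:
            try:
                df[col] = pd.to_numeric(df[col], errors="raise")
            except (ValueError, TypeError) as exc:
                bad = df.index[pd.to_numeric(df[col], errors="coerce").isna() & df[col].notna()]
                row = int(bad[0]) + 2 if len(bad) else "?"
                raise ValueError(f"{path}: non-numeric value in column {col!r} (row {row})") from exc
    for col in schema.integer:
        df[col] = pd.to_numeric(df[col], errors="raise").astype(int)
    if schema.key:
        dup = df.duplicated(subset=list(schema.key))
        if dup.any():
            first = df.loc[dup, list(schema.key)].iloc[0].to_dict()
            raise ValueError(f"{path}: duplicate key {first} for role {role!r}")
    return df.reset_index(drop=True)


def write_table(
    df: pd.DataFrame,
    path: str | Path,
    role: str,
    header_meta: Mapping[str, object] | None = None,
) -> None:
    """Write a role-typed table as TSV with deterministic row order."""
    schema = ROLE_SCHEMAS[role]
    cols = [c for c in schema.required + schema.optional if c in df.columns]
    out = df[cols].sort_values(list(schema.key), kind="stable")
    path = Path(path)
    with open(path, "w") as fh:
        if header_meta:
            meta = " ".join(f"{k}={v}" for k, v in header_meta.items())
            fh.write(f"# strainteract {role} table | {meta}\n")
        out.to_csv(fh, sep="\t", index=False, lineterminator="\n")


def read_matrix(path: str | Path) -> pd.DataFrame:
    """Read a wide matrix table (first column = row identifiers)."""
    path = Path(path)
    return pd.read_csv(path, sep=_sniff_sep(path), comment="#", index_col=0)


def write_matrix(df: pd.DataFrame, path: str | Path, header_meta: Mapping[str, object] | None = None) -> None:
    with open(path, "w") as fh:
        if header_meta:
            meta = " ".join(f"{k}={v}" for k, v in header_meta.items())
            fh.write(f"# strainteract matrix | {meta}\n")
        df.to_csv(fh, sep="\t", lineterminator="\n")


def parse_fastani(path: str | Path) -> ANITable:
    """Parse raw FastANI output into a symmetric ANI table.

    Expects the default 5-column layout per line: query, reference, ANI,
    mapped fragments, total fragments (tab or whitespace separated; a
    3-column file without the fragment counts is also accepted).  The two
    directed values of each unordered pair are harmonised by arithmetic
    mean; self-pairs are forced to 100.  Pairs observed in only one
    direction and isolates never seen as query (or reference) are retained
    with a logged warning; missing pairs are left as NaN and flagged.
    """
    path = Path(path)
    sums: dict[tuple[str, str], float] = {}
    counts: dict[tuple[str, str], int] = {}
    queries: set[str] = set()
    references: set[str] = set()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.split("\t") if "\t" in line else line.split()
            if len(parts) < 3:
                raise ValueError(f"{path}:{lineno}: expected >=3 fields, got {len(parts)}")
            q, r = parts[0].strip(), parts[1].strip()
            try:
                ani = float(parts[2])
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: non-numeric ANI {parts[2]!r}") from exc
            if not 0 < ani <= 100:
                raise ValueError(f"{path}:{lineno}: ANI {ani} outside (0, 100]")
            queries.add(q)
            references.add(r)
            if q == r:
                continue
            key = (q, r) if q < r else (r, q)
            sums[key] = sums.get(key, 0.0) + ani
            counts[key] = counts.get(key, 0) + 1

    isolates = sorted(queries | references)
    one_sided = queries.symmetric_difference(references)
    if one_sided:
        logger.warning("isolates seen only as query or only as reference: %s", sorted(one_sided))
    n = len(isolates)
    idx = {iso: i for i, iso in enumerate(isolates)}
    values = np.full((n, n), np.nan)
    np.fill_diagonal(values, 100.0)
    for (a, b), s in sums.items():
        c = counts[(a, b)]
        if c == 1:
            logger.warning("pair (%s, %s) observed in one direction only", a, b)
        v = s / c
        values[idx[a], idx[b]] = values[idx[b], idx[a]] = v
    missing = [
        (isolates[i], isolates[j])
        for i in range(n)
        for j in range(i + 1, n)
        if np.isnan(values[i, j])
    ]
    if missing:
        logger.warning("missing ANI pairs after harmonisation: %s", missing)
    table = ANITable(tuple(isolates), values)
    table.validate(require_complete=False)
    return table


@dataclass
class RunConfig:
    """Run-level configuration shared by the CLI subcommands.

    ``inputs`` maps table roles (design, biomass, amino, transcription,
    pathway, ani, gene_families, assignment) to file paths.  Threshold
    conventions: ``alpha`` applies to every hypothesis test,
    ``log2fc_cutoff`` to differential-expression and terminal-gene gates.
    """

    inputs: dict[str, str] = field(default_factory=dict)
    ani_threshold_grid: list[float] = field(default_factory=list)
    ani_threshold: float = 99.5
    alpha: float = 0.05
    log2fc_cutoff: float = 1.0
    final_day: int = 8
    outdir: str = "."
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must lie in (0, 1)")
        grid = sorted(self.ani_threshold_grid)
        if grid != list(self.ani_threshold_grid):
            raise ValueError("ani_threshold_grid must be sorted ascending")
        if any(not 0 < t <= 100 for t in grid):
            raise ValueError("grid thresholds must lie in (0, 100]")

    @classmethod
    def from_json(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            data = json.load(fh)
        return cls(**data)

    def digest(self) -> str:
        payload = json.dumps(self.__dict__, sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]
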