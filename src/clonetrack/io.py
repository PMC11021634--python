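"""Reading and writing clonotype tables and sample metadata.

A *clonotype* is one TCR sequence variant observed in one sample, identified
by default by its CDR3 nucleotide sequence together with the V segment call
(allele suffixes stripped).  Abundance is measured in UMIs where available,
otherwise in reads; the downstream statistics treat the two identically.

Supported table dialects:

``airr``
    AIRR Rearrangement TSV: ``junction``, ``junction_aa``, ``v_call``,
    ``j_call``, ``duplicate_count``.
``mixcr``
    MiXCR-style clone export: ``nSeqCDR3`` (or ``targetSequences``),
    ``aaSeqCDR3``, ``bestVHit`` (or ``allVHitsWithScore``), ``bestJHit``
    (or ``allJHitsWithScore``), ``cloneCount``.
``canonical``
    This package's own output (``key``, ``cdr3_nt``, ``cdr3_aa``, ``v``,
    ``j``, ``count``), round-trippable.
``generic``
    Any delimited table plus a user-supplied column map, either as a dict or
    a TOML config file with a ``[columns]`` section.
"""

from __future__ import annotations

import logging
import tomllib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import pandas as pd

logger = logging.getLogger(__name__)

#: identity modes -> fields entering the clonotype key, in order
IDENTITY_FIELDS: dict[str, tuple[str, ...]] = {
    "nt": ("cdr3_nt",),
    "aa": ("cdr3_aa",),
    "nt+V": ("cdr3_nt", "v"),
    "aa+V": ("cdr3_aa", "v"),
    "nt+V+J": ("cdr3_nt", "v", "j"),
}

DEFAULT_IDENTITY = "nt+V"

#: canonical internal column order
CANONICAL_COLUMNS = ["key", "cdr3_nt", "cdr3_aa", "v", "j", "count"]

_DIALECT_MAPS: dict[str, dict[str, str]] = {
    "airr": {
        "cdr3_nt": "junction",
        "cdr3_aa": "junction_aa",
        "v": "v_call",
        "j": "j_call",
        "count": "duplicate_count",
    },
    "mixcr": {
        "cdr3_nt": "nSeqCDR3",
        "cdr3_aa": "aaSeqCDR3",
        "v": "bestVHit",
        "j": "bestJHit",
        "count": "cloneCount",
    },
    "canonical": {
        "cdr3_nt": "cdr3_nt",
        "cdr3_aa": "cdr3_aa",
        "v": "v",
        "j": "j",
        "count": "count",
    },
}

# alternative source columns accepted per dialect, tried in order
_FALLBACKS: dict[tuple[str, str], tuple[str, ...]] = {
    ("mixcr", "cdr3_nt"): ("targetSequences",),
    ("mixcr", "v"): ("allVHitsWithScore",),
    ("mixcr", "j"): ("allJHitsWithScore",),
}


def normalize_gene(call: str | None) -> str | None:
    """Strip allele suffix (``*01``), alignment scores and extra hits.

    ``"TRBV9*01"`` and ``"TRBV9"`` normalise to the same symbol; MiXCR
    ``allVHitsWithScore`` entries like ``"TRBV9*00(1234.5),TRBV5-1*00(...)"``
    keep only the best hit.
    """
    if call is None or (isinstance(call, float) and pd.isna(call)):
        return None
    first = str(call).split(",")[0]
    for sep in ("*", "("):
        first = first.split(sep)[0]
    first = first.strip()
    return first or None


@dataclass(frozen=True)
class Clonotype:
    """One TCR sequence variant with its abundance in one sample."""

    cdr3_nt: str
    count: int
    cdr3_aa: str | None = None
    v_call: str | None = None
    d_call: str | None = None
    j_call: str | None = None

    def __post_init__(self) -> None:
        if not self.cdr3_nt:
            raise ValueError("cdr3_nt must be nonempty")
        if int(self.count) < 1:
            raise ValueError(f"count must be >= 1, got {self.count}")


def make_clonotype_key(clonotype: Clonotype, mode: str = DEFAULT_IDENTITY) -> str:
    """Build the canonical identity key for a clonotype.

    Keys are equal iff the fields selected by ``mode`` are equal after
    normalization (sequences uppercased, gene calls truncated at the allele
    separator ``*``).

    Parameters
    ----------
    clonotype : Clonotype
    mode : str
        One of ``nt``, ``aa``, ``nt+V`` (default), ``aa+V``, ``nt+V+J``.
    """
    if mode not in IDENTITY_FIELDS:
        raise ValueError(f"unknown identity mode {mode!r}; choose from {sorted(IDENTITY_FIELDS)}")
    parts = []
    values = {
        "cdr3_nt": clonotype.cdr3_nt,
        "cdr3_aa": clonotype.cdr3_aa,
        "v": normalize_gene(clonotype.v_call),
        "j": normalize_gene(clonotype.j_call),
    }
    for fld in IDENTITY_FIELDS[mode]:
        value = values[fld]
        if value is None or value == "":
            raise ValueError(f"identity mode {mode!r} requires field {fld!r}, which is missing")
        if fld in ("cdr3_nt", "cdr3_aa"):
            value = str(value).upper()
        parts.append(str(value))
    return "|".join(parts)


@dataclass
class RepertoireSample:
    """One sample's clonotype table plus its metadata.

    ``table`` holds one row per unique clonotype identity with columns
    ``key, cdr3_nt, cdr3_aa, v, j, count``; duplicates are merged on
    construction by summing counts.
    """

    sample_id: str
    table: pd.DataFrame
    identity_mode: str = DEFAULT_IDENTITY
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        df = self.table
        missing = [c for c in CANONICAL_COLUMNS if c not in df.columns]
        if missing:
            raise ValueError(f"sample table missing columns {missing}")
        if (df["count"] < 1).any():
            raise ValueError("sample table contains counts < 1")
        if df["key"].duplicated().any():
            df = (
                df.groupby("key", sort=False, as_index=False)
                .agg(
                    cdr3_nt=("cdr3_nt", "first"),
                    cdr3_aa=("cdr3_aa", "first"),
                    v=("v", "first"),
                    j=("j", "first"),
                    count=("count", "sum"),
                )
            )
            df = df[CANONICAL_COLUMNS]
        self.table = df.reset_index(drop=True)

    @property
    def richness(self) -> int:
        """Number of unique clonotype identities."""
        return int(len(self.table))

    @property
    def total_umi(self) -> int:
        """Total number of UMIs (or reads) across clonotypes."""
        return int(self.table["count"].sum())

    def counts(self) -> pd.Series:
        """Counts indexed by clonotype key."""
        return self.table.set_index("key")["count"]

    def key_set(self) -> set[str]:
        return set(self.table["key"])


def _rows_to_sample(
    rows: pd.DataFrame,
    source_cols: Mapping[str, str],
    sample_id: str,
    identity_mode: str,
    metadata: dict | None = None,
) -> RepertoireSample:
    count_col = source_cols["count"]
    raw_counts = rows[count_col]
    counts = pd.to_numeric(raw_counts, errors="coerce")
    bad = counts.isna() | (counts <= 0) | (counts != counts.round())
    if bad.any():
        row_no = int(bad.idxmax()) + 2  # header is line 1
        raise ValueError(
            f"non-integer or non-positive count {raw_counts[bad.idxmax()]!r} "
            f"in column {count_col!r} at line {row_no}"
        )

    def col(name: str) -> pd.Series:
        src = source_cols.get(name)
        if src is not None and src in rows.columns:
            return rows[src]
        return pd.Series([None] * len(rows), index=rows.index, dtype=object)

    df = pd.DataFrame(
        {
            "cdr3_nt": col("cdr3_nt").astype(object).where(col("cdr3_nt").notna(), None),
            "cdr3_aa": col("cdr3_aa").astype(object).where(col("cdr3_aa").notna(), None),
            "v": col("v").map(normalize_gene),
            "j": col("j").map(normalize_gene),
            "count": counts.astype(int),
        }
    )
    df["cdr3_nt"] = df["cdr3_nt"].map(lambda s: str(s).upper() if s is not None else None)
    df["cdr3_aa"] = df["cdr3_aa"].map(lambda s: str(s).upper() if s is not None else None)

    fields = IDENTITY_FIELDS[identity_mode]
    for fld in fields:
        if fld not in df.columns or df[fld].isna().any():
            raise ValueError(
                f"identity mode {identity_mode!r} requires field {fld!r}, "
                f"which is missing for some rows"
            )
    if len(df):
        df["key"] = df[list(fields)].astype(str).agg("|".join, axis=1)
    else:
        df["key"] = pd.Series(dtype=object)
    df = df[CANONICAL_COLUMNS]
    return RepertoireSample(
        sample_id=sample_id,
        table=df,
        identity_mode=identity_mode,
        metadata=dict(metadata or {}),
    )


def _resolve_columns(dialect: str, header: list[str], column_map: Mapping[str, str] | None) -> dict[str, str]:
    if dialect == "generic":
        if not column_map:
            raise ValueError("dialect 'generic' requires a column map")
        cols = dict(column_map)
    elif dialect in _DIALECT_MAPS:
        cols = dict(_DIALECT_MAPS[dialect])
        for (dia, fld), alts in _FALLBACKS.items():
            if dia == dialect and cols[fld] not in header:
                for alt in alts:
                    if alt in header:
                        cols[fld] = alt
                        break
    else:
        raise ValueError(f"unknown dialect {dialect!r}")
    # optional fields simply absent from the file are tolerated
    hard_missing = [cols[f] for f in ("cdr3_nt", "count") if f in cols and cols[f] not in header]
    if hard_missing:
        raise ValueError(
            f"table lacks required column(s) {hard_missing} for dialect {dialect!r}; header: {header}"
        )
    return cols


def read_column_map(path: str | Path) -> dict[str, str]:
    """Read a generic-dialect column map from a TOML file.

    The file must contain a ``[columns]`` table mapping canonical field names
    (``cdr3_nt``, ``cdr3_aa``, ``v``, ``j``, ``count``) to column headers.
    """
    with open(path, "rb") as fh:
        cfg = tomllib.load(fh)
    if "columns" not in cfg:
        raise ValueError(f"{path}: missing [columns] section")
    return {str(k): str(v) for k, v in cfg["columns"].items()}


def read_clonotype_table(
    path: str | Path,
    dialect: str = "airr",
    identity_mode: str = DEFAULT_IDENTITY,
    column_map: Mapping[str, str] | str | Path | None = None,
    sample_id: str | None = None,
    sep: str = "\t",
    metadata: dict | None = None,
) -> RepertoireSample:
    """Load one clonotype table into a :class:`RepertoireSample`.

    Rows sharing a clonotype key are merged by summing counts; rows with
    non-integer or non-positive counts raise with the offending line number.
    """
    path = Path(path)
    if identity_mode not in IDENTITY_FIELDS:
        raise ValueError(f"unknown identity mode {identity_mode!r}")
    if isinstance(column_map, (str, Path)):
        column_map = read_column_map(column_map)
    rows = pd.read_csv(path, sep=sep, dtype=str)
    cols = _resolve_columns(dialect, list(rows.columns), column_map)
    if "umi" not in cols["count"].lower() and cols["count"] != "duplicate_count":
        # downstream statistics do not distinguish UMIs from reads
        logger.info("column %r used as abundance; treated as read counts unless upstream used UMIs", cols["count"])
    sample = _rows_to_sample(
        rows,
        cols,
        sample_id=sample_id or path.stem,
        identity_mode=identity_mode,
        metadata=metadata,
    )
    return sample


def write_clonotype_table(sample: RepertoireSample, path: str | Path) -> None:
    """Write the canonical internal table (TSV, fixed column order)."""
    sample.table.to_csv(path, sep="\t", index=False)


def write_airr(sample: RepertoireSample, path: str | Path) -> None:
    """Write a minimal AIRR Rearrangement TSV view of a sample."""
    out = pd.DataFrame(
        {
            "junction": sample.table["cdr3_nt"],
            "junction_aa": sample.table["cdr3_aa"],
            "v_call": sample.table["v"],
            "j_call": sample.table["j"],
            "duplicate_count": sample.table["count"],
        }
    )
    out.to_csv(path, sep="\t", index=False)


def read_metadata(path: str | Path, file_column: str = "file", require_files: bool = True) -> pd.DataFrame:
    """Read a sample metadata table (TSV).

    Must contain ``sample_id`` and a file column; every other column is
    preserved verbatim as a modelling factor.  File paths are resolved
    relative to the metadata file's directory.
    """
    path = Path(path)
    meta = pd.read_csv(path, sep="\t", dtype=str)
    if "sample_id" not in meta.columns or file_column not in meta.columns:
        raise ValueError(f"metadata must contain 'sample_id' and {file_column!r} columns")
    dup = meta["sample_id"][meta["sample_id"].duplicated()]
    if len(dup):
        raise ValueError(f"duplicate sample_id in metadata: {sorted(set(dup))}")
    meta = meta.copy()
    meta[file_column] = [str(path.parent / f) for f in meta[file_column]]
    if require_files:
        missing = [f for f in meta[file_column] if not Path(f).exists()]
        if missing:
            raise FileNotFoundError(f"metadata references missing file(s): {missing}")
    return meta


def load_samples(
    metadata: pd.DataFrame,
    dialect: str = "airr",
    identity_mode: str = DEFAULT_IDENTITY,
    file_column: str = "file",
    **read_kwargs,
) -> dict[str, RepertoireSample]:
    """Load every sample listed in a metadata table.

    Factor columns of the metadata row are attached to each sample's
    ``metadata`` mapping and travel with it into tracking and modelling.
    """
    samples: dict[str, RepertoireSample] = {}
    for _, row in metadata.iterrows():
        factors = {k: row[k] for k in metadata.columns if k not in (file_column,)}
        samples[row["sample_id"]] = read_clonotype_table(
            row[file_column],
            dialect=dialect,
            identity_mode=identity_mode,
            sample_id=row["sample_id"],
            metadata=factors,
            **read_kwargs,
        )
    return samples
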