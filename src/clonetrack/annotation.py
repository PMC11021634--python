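"""Antigen-specificity annotation by CDR3 lookup in a reference database.

Clonotypes are flagged "specific" when their CDR3 amino-acid sequence is
within a small Hamming distance (default 1) of a database entry with known
specificity, e.g. a VDJdb export.  Hamming distance is only defined for
equal-length sequences; unequal lengths never match.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .io import RepertoireSample, normalize_gene

NO_MATCH = None


def hamming_distance(a: str, b: str) -> int | None:
    """Positionwise mismatch count, or ``None`` when lengths differ."""
    if len(a) != len(b):
        return NO_MATCH
    return sum(x != y for x, y in zip(a, b))


@dataclass(frozen=True)
class SpecificityRecord:
    """One reference TCR with known antigen specificity."""

    cdr3_aa: str
    epitope: str
    v_call: str | None = None
    mhc: str | None = None
    species: str | None = None

    def __post_init__(self) -> None:
        if not self.cdr3_aa:
            raise ValueError("cdr3_aa must be nonempty")


def read_specificity_table(path: str | Path) -> list[SpecificityRecord]:
    """Read a specificity database TSV.

    Accepts a VDJdb export (columns ``cdr3``, ``v.segm`` or ``v.gene``,
    ``antigen.epitope``, ``mhc.a``) or a minimal two-column table
    (``cdr3_aa``, ``epitope``).
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    cols = set(df.columns)
    if {"cdr3", "antigen.epitope"} <= cols:
        v_col = "v.segm" if "v.segm" in cols else ("v.gene" if "v.gene" in cols else None)
        return [
            SpecificityRecord(
                cdr3_aa=row["cdr3"],
                epitope=row["antigen.epitope"],
                v_call=row[v_col] if v_col else None,
                mhc=row.get("mhc.a"),
                species=row.get("species"),
            )
            for _, row in df.iterrows()
        ]
    if {"cdr3_aa", "epitope"} <= cols:
        return [
            SpecificityRecord(cdr3_aa=row["cdr3_aa"], epitope=row["epitope"],
                              v_call=row.get("v_call"))
            for _, row in df.iterrows()
        ]
    raise ValueError(
        f"{path}: unrecognised specificity table columns {sorted(cols)}; "
        "expected VDJdb export or (cdr3_aa, epitope)"
    )


def annotate_specificity(
    sample: RepertoireSample,
    db: list[SpecificityRecord],
    max_mismatch: int = 1,
    match_v: bool = False,
    use_nt: bool = False,
) -> pd.DataFrame:
    """Flag clonotypes matching a specificity database within ``max_mismatch``.

    Returns a DataFrame with one row per clonotype key: ``specific`` flag,
    semicolon-joined matched ``epitopes``, and ``min_distance`` (the minimal
    Hamming distance to any same-length database entry; NaN when no entry
    shares the sequence length).  A clonotype is specific iff
    ``min_distance <= max_mismatch`` (restricted to matching V genes when
    ``match_v``).

    The scan is vectorised per sequence length and equals a naive all-pairs
    comparison.
    """
    if not db:
        raise ValueError("specificity database is empty")
    if max_mismatch < 0:
        raise ValueError("max_mismatch must be >= 0")
    seq_col = "cdr3_nt" if use_nt else "cdr3_aa"
    seqs = sample.table[seq_col]
    if seqs.isna().any():
        raise ValueError(f"sample {sample.sample_id!r} lacks {seq_col} for some clonotypes")

    db_attr = "cdr3_aa"  # databases store amino-acid CDR3s
    by_len: dict[int, tuple[np.ndarray, list[SpecificityRecord]]] = {}
    for length in {len(getattr(r, db_attr)) for r in db}:
        recs = [r for r in db if len(getattr(r, db_attr)) == length]
        mat = np.array([list(getattr(r, db_attr).upper()) for r in recs], dtype="U1")
        by_len[length] = (mat, recs)

    rows = []
    for key, seq, v in zip(sample.table["key"], seqs, sample.table["v"]):
        seq = str(seq).upper()
        entry = by_len.get(len(seq))
        min_d: float = np.nan
        epitopes: list[str] = []
        if entry is not None:
            mat, recs = entry
            dists = (mat != np.array(list(seq), dtype="U1")).sum(axis=1)
            if match_v:
                ok = np.array(
                    [normalize_gene(r.v_call) == normalize_gene(v) if r.v_call else False
                     for r in recs]
                )
                dists = np.where(ok, dists, np.iinfo(np.int64).max)
            finite = dists < np.iinfo(np.int64).max
            if finite.any():
                min_d = float(dists[finite].min())
                hit = [r.epitope for r, d in zip(recs, dists) if d <= max_mismatch]
                epitopes = sorted(set(hit))
        specific = (not np.isnan(min_d)) and min_d <= max_mismatch
        rows.append(
            {
                "key": key,
                "specific": bool(specific),
                "epitopes": ";".join(epitopes),
                "min_distance": min_d,
            }
        )
    return pd.DataFrame(rows)
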