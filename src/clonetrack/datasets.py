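"""Cohort-level helpers: metadata-driven pairing and record pooling.

A cohort directory is expected to contain

``metadata.tsv``
    one row per sample: ``sample_id``, ``file`` (clonotype table relative to
    the directory) and arbitrary factor columns (donor, time point,
    condition, subset).
``pairs.tsv``
    one row per pre/post comparison: ``pair_id``, ``pre_sample_id``,
    ``post_sample_id`` and optional pair-level factor columns (e.g. ``DLI``).

These helpers load every sample, track each pair and pool the capture
records into one table ready for :class:`clonetrack.model.CaptureModel`.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

from .io import DEFAULT_IDENTITY, RepertoireSample, load_samples, read_metadata
from .tracking import DEFAULT_BINS, SizeBins, concat_records, summarize_capture, track_pair


def read_pairs(path: str | Path) -> pd.DataFrame:
    pairs = pd.read_csv(path, sep="\t", dtype=str)
    required = {"pair_id", "pre_sample_id", "post_sample_id"}
    if not required <= set(pairs.columns):
        raise ValueError(f"pairs table must contain columns {sorted(required)}")
    if pairs["pair_id"].duplicated().any():
        raise ValueError("duplicate pair_id in pairs table")
    return pairs


def records_from_pairs(
    samples: dict[str, RepertoireSample],
    pairs: pd.DataFrame,
    bins: SizeBins = DEFAULT_BINS,
    group_by: tuple[str, ...] = (),
    labels: dict | None = None,
) -> pd.DataFrame:
    """Track every pair and pool capture records.

    Pair-level factor columns of ``pairs`` are attached to that pair's
    records.  ``labels`` optionally maps label name -> per-key values
    (attached to every tracking result before summarising).
    """
    all_records = []
    for _, row in pairs.iterrows():
        for sid in (row["pre_sample_id"], row["post_sample_id"]):
            if sid not in samples:
                raise KeyError(f"pairs table references unknown sample_id {sid!r}")
        tracked = track_pair(
            samples[row["pre_sample_id"]],
            samples[row["post_sample_id"]],
            bins=bins,
            pair_id=row["pair_id"],
        )
        for name, values in (labels or {}).items():
            tracked.add_label(name, values)
        recs = summarize_capture(tracked, group_by=group_by)
        for col in pairs.columns:
            if col not in ("pair_id", "pre_sample_id", "post_sample_id") and col not in recs:
                recs[col] = row[col]
        all_records.append(recs)
    return concat_records(all_records)


def cohort_capture_records(
    data_dir: str | Path,
    dialect: str = "airr",
    identity_mode: str = DEFAULT_IDENTITY,
    bins: SizeBins = DEFAULT_BINS,
    group_by: tuple[str, ...] = (),
) -> pd.DataFrame:
    """Load a cohort directory and return its pooled capture records."""
    data_dir = Path(data_dir)
    meta_path = data_dir / "metadata.tsv"
    pairs_path = data_dir / "pairs.tsv"
    for p in (meta_path, pairs_path):
        if not p.exists():
            raise FileNotFoundError(
                f"{p} not found: cohort directories need metadata.tsv and pairs.tsv "
                "(see clonetrack.datasets module docstring for the layout)"
            )
    metadata = read_metadata(meta_path)
    samples = load_samples(metadata, dialect=dialect, identity_mode=identity_mode)
    pairs = read_pairs(pairs_path)
    return records_from_pairs(samples, pairs, bins=bins, group_by=group_by)
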