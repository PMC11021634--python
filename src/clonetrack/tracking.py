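"""Pairing samples across time points and building capture records.

The central object is a :class:`TrackingResult`: the union of clonotype keys
of a "pre" and a "post" sample, each key carrying both counts, both size
groups, and a found/not-found flag.  ``summarize_capture`` collapses a
tracking result into capture records — one row per size group (optionally
crossed with user labels such as antigen specificity) with the number of
pre clonotypes ``N`` in the cell and the number ``n`` recaptured in the post
sample, alongside the pair's richness covariates ``N_pre`` and ``N_post``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import RepertoireSample

MISSING = "missing"

_WIDTH1_NAMES = {1: "singleton", 2: "doubleton", 3: "tripleton"}


@dataclass(frozen=True)
class SizeBins:
    """Contiguous abundance bins starting at count 1, plus ``missing`` = 0.

    ``lowers`` are the lower bounds of each bin; the last bin is open-ended.
    The default ``(1, 2, 3, 4)`` yields singleton / doubleton / tripleton /
    large (4+).  ``(1, 2, 3)`` merges tripletons into "large" (3+), as used
    for shallow sorted-subset samples.
    """

    lowers: tuple[int, ...] = (1, 2, 3, 4)

    def __post_init__(self) -> None:
        if not self.lowers or self.lowers[0] != 1:
            raise ValueError("bins must start at count 1")
        if list(self.lowers) != sorted(set(self.lowers)):
            raise ValueError("bin lower bounds must be strictly increasing")

    @classmethod
    def from_spec(cls, spec: str) -> "SizeBins":
        """Parse a spec like ``"1,2,3,4+"`` or ``"1,2,3+"``."""
        lowers = tuple(int(tok.rstrip("+")) for tok in spec.split(",") if tok.strip())
        return cls(lowers)

    @property
    def labels(self) -> tuple[str, ...]:
        """Bin labels: width-1 bins at counts 1-3 get their classical names,
        everything else is ``large``."""
        out = []
        for i, lo in enumerate(self.lowers):
            hi = self.lowers[i + 1] - 1 if i + 1 < len(self.lowers) else None
            if hi == lo and lo in _WIDTH1_NAMES:
                out.append(_WIDTH1_NAMES[lo])
            else:
                out.append("large")
        return tuple(out)

    @property
    def levels(self) -> tuple[str, ...]:
        """Ordered category levels, smallest first, with ``missing`` lowest."""
        return (MISSING,) + self.labels

    def assign(self, count: int) -> str:
        """Map a nonnegative count to its size-group label."""
        if count < 0:
            raise ValueError(f"count must be >= 0, got {count}")
        if count == 0:
            return MISSING
        idx = int(np.searchsorted(self.lowers, count, side="right")) - 1
        return self.labels[idx]

    def assign_array(self, counts) -> pd.Categorical:
        counts = np.asarray(counts)
        if (counts < 0).any():
            raise ValueError("counts must be >= 0")
        labels = np.empty(len(counts), dtype=object)
        labels[counts == 0] = MISSING
        pos = counts > 0
        idx = np.searchsorted(self.lowers, counts[pos], side="right") - 1
        labels[pos] = np.asarray(self.labels, dtype=object)[idx]
        # duplicates in self.labels (merged bins) are fine for Categorical levels
        levels = list(dict.fromkeys(self.levels))
        return pd.Categorical(labels, categories=levels, ordered=True)


DEFAULT_BINS = SizeBins()


def assign_size_group(count: int, bins: SizeBins = DEFAULT_BINS) -> str:
    """Size-group label for one count (0 -> ``missing``)."""
    return bins.assign(count)


@dataclass
class TrackingResult:
    """Tracked clonotypes of one pre/post sample pair.

    ``df`` has one row per clonotype key in the union of both samples with
    columns ``key, count_pre, count_post, size_group_pre, size_group_post,
    found_in_post`` plus any label columns added via :meth:`add_label`.
    """

    pair_id: str
    pre_sample_id: str
    post_sample_id: str
    df: pd.DataFrame
    bins: SizeBins = field(default_factory=SizeBins)
    factors: dict = field(default_factory=dict)

    @property
    def n_pre(self) -> int:
        """Richness of the pre sample (number of keys with count_pre >= 1)."""
        return int((self.df["count_pre"] >= 1).sum())

    @property
    def n_post(self) -> int:
        return int((self.df["count_post"] >= 1).sum())

    def add_label(self, name: str, values, default=False) -> "TrackingResult":
        """Attach a per-clonotype label column.

        ``values`` may be a set of keys (boolean label), a mapping/Series
        keyed by clonotype key, or a DataFrame with ``key`` + value column.
        Keys absent from ``values`` receive ``default``.
        """
        if isinstance(values, (set, frozenset)):
            col = self.df["key"].isin(values)
        else:
            if isinstance(values, pd.DataFrame):
                if "key" not in values.columns:
                    raise ValueError("label DataFrame needs a 'key' column")
                value_col = [c for c in values.columns if c != "key"][0]
                values = values.set_index("key")[value_col]
            mapping = pd.Series(values)
            col = self.df["key"].map(mapping)
            col = col.where(col.notna(), default)
        self.df[name] = col.values
        return self


def track_pair(
    pre: RepertoireSample,
    post: RepertoireSample,
    bins: SizeBins = DEFAULT_BINS,
    pair_id: str | None = None,
) -> TrackingResult:
    """Track clonotypes from a "pre" sample into a "post" sample.

    Both samples must use the same clonotype identity mode.  Size groups are
    assigned from each side's count; clonotypes absent pre-side ("novel")
    get size group ``missing`` pre.
    """
    if pre.identity_mode != post.identity_mode:
        raise ValueError(
            f"identity-mode mismatch: pre={pre.identity_mode!r} post={post.identity_mode!r}"
        )
    merged = pd.merge(
        pre.table[["key", "count"]].rename(columns={"count": "count_pre"}),
        post.table[["key", "count"]].rename(columns={"count": "count_post"}),
        on="key",
        how="outer",
    )
    merged = merged.sort_values("key", kind="stable").reset_index(drop=True)
    merged["count_pre"] = merged["count_pre"].fillna(0).astype(int)
    merged["count_post"] = merged["count_post"].fillna(0).astype(int)
    merged["size_group_pre"] = bins.assign_array(merged["count_pre"])
    merged["size_group_post"] = bins.assign_array(merged["count_post"])
    merged["found_in_post"] = merged["count_post"] >= 1
    pair = pair_id or f"{pre.sample_id}->{post.sample_id}"
    factors = {
        k: v
        for k, v in {**pre.metadata, **post.metadata}.items()
        if pre.metadata.get(k) == post.metadata.get(k)
    }
    return TrackingResult(
        pair_id=pair,
        pre_sample_id=pre.sample_id,
        post_sample_id=post.sample_id,
        df=merged,
        bins=bins,
        factors=factors,
    )


def flag_emerging(baseline: RepertoireSample, followup: RepertoireSample) -> pd.Series:
    """Boolean per-key label: present in the follow-up but absent at baseline.

    Typical use: clonotypes present on day 7 post-vaccination but not on
    day 0 are "emerging"; the returned Series (indexed by clonotype key over
    the union of the two samples) can be attached to any later
    :class:`TrackingResult` via ``add_label``.
    """
    if baseline.identity_mode != followup.identity_mode:
        raise ValueError("identity-mode mismatch between baseline and follow-up")
    base = baseline.key_set()
    follow = followup.key_set()
    keys = sorted(base | follow)
    return pd.Series([k in follow and k not in base for k in keys], index=keys, name="emerging")


def summarize_capture(
    result: TrackingResult,
    group_by: list[str] | tuple[str, ...] = (),
) -> pd.DataFrame:
    """Collapse a tracking result into capture records.

    One record per (pre size group x ``group_by`` labels) cell among
    clonotypes present in the pre sample: ``N`` clonotypes in the cell, of
    which ``n`` were found in the post sample, with the pair richness
    covariates ``N_pre``/``N_post`` and the capture probability ``P = n/N``.
    Cells with ``N = 0`` are omitted; "novel" clonotypes (absent pre-side)
    never enter a record.
    """
    group_by = list(group_by)
    for g in group_by:
        if g not in result.df.columns:
            raise KeyError(f"unknown grouping factor {g!r}; available: {list(result.df.columns)}")
    pre_side = result.df[result.df["count_pre"] >= 1].copy()
    pre_side["size_group"] = pre_side["size_group_pre"].astype(str)
    grouped = pre_side.groupby(["size_group"] + group_by, dropna=False, observed=True)
    records = grouped.agg(n=("found_in_post", "sum"), N=("found_in_post", "size")).reset_index()
    records = records[records["N"] > 0]
    records.insert(0, "pair_id", result.pair_id)
    records["N_pre"] = result.n_pre
    records["N_post"] = result.n_post
    records["n"] = records["n"].astype(int)
    records["N"] = records["N"].astype(int)
    records["P"] = records["n"] / records["N"]
    for name, value in result.factors.items():
        if name not in records.columns:
            records[name] = value
    order = list(dict.fromkeys(result.bins.labels))
    records["size_group"] = pd.Categorical(records["size_group"], categories=order, ordered=True)
    return records.sort_values(["size_group"] + group_by, kind="stable").reset_index(drop=True)


def concat_records(records_list) -> pd.DataFrame:
    """Concatenate capture-record tables from several pairs."""
    frames = [r for r in records_list if len(r)]
    out = pd.concat(frames, ignore_index=True)
    first = frames[0]["size_group"]
    if isinstance(first.dtype, pd.CategoricalDtype):
        out["size_group"] = pd.Categorical(
            out["size_group"], categories=first.cat.categories, ordered=True
        )
    return out
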