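"""Depth-normalised diversity and population-frequency estimation.

Repertoire samples differ enormously in sequencing depth, so raw richness
is not comparable across samples.  Two standard remedies are used here:

* rarefaction — hypergeometric downsampling of UMIs to a common depth,
  with the Chao1 abundance-based richness estimator applied to the
  downsampled table and averaged over replicates;
* the Poisson capture model — a size group with recapture probability ``P``
  sampled at depth ``R`` implies a per-clone population frequency
  ``phi = -ln(1 - P) / R``, and the clonotype-fraction-weighted average of
  ``phi`` over size groups estimates the frequency of a typical clone.
  Multiplying by the body-wide T-cell count gives a rough cells-per-clone
  figure.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import gammaln

from .io import RepertoireSample


def downsample(sample: RepertoireSample, depth: int, seed: int | np.random.Generator = 0) -> RepertoireSample:
    """Subsample ``depth`` UMIs without replacement (multivariate
    hypergeometric); deterministic under a fixed seed."""
    if depth > sample.total_umi:
        raise ValueError(f"depth {depth} exceeds sample total_umi {sample.total_umi}")
    if depth < 0:
        raise ValueError("depth must be >= 0")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    counts = sample.table["count"].to_numpy()
    new_counts = rng.multivariate_hypergeometric(counts, depth)
    table = sample.table.copy()
    table["count"] = new_counts
    table = table[table["count"] >= 1].reset_index(drop=True)
    return RepertoireSample(
        sample_id=sample.sample_id,
        table=table,
        identity_mode=sample.identity_mode,
        metadata=dict(sample.metadata),
    )


def chao1(sample: RepertoireSample | pd.Series | np.ndarray, bias_corrected: bool = True) -> float:
    """Chao1 estimate of clonotype richness.

    The default bias-corrected form ``S_obs + f1 (f1 - 1) / (2 (f2 + 1))``
    is finite for ``f2 = 0``; ``bias_corrected=False`` gives the classical
    ``S_obs + f1^2 / (2 f2)``.  An empty sample yields 0.
    """
    from skbio.diversity.alpha import chao1 as _skbio_chao1

    counts = sample.table["count"] if isinstance(sample, RepertoireSample) else sample
    counts = np.asarray(counts, dtype=int)
    if counts.size == 0 or counts.sum() == 0:
        return 0.0
    return float(_skbio_chao1(counts, bias_corrected=bias_corrected))


def expected_rarefied_richness(sample: RepertoireSample, depth: int) -> float:
    """Closed-form expected richness after downsampling to ``depth``:
    ``sum_i 1 - C(T - c_i, d) / C(T, d)`` (hypergeometric rarefaction)."""
    counts = sample.table["count"].to_numpy()
    T = counts.sum()
    if depth > T:
        raise ValueError("depth exceeds total_umi")

    def log_choose(n, k):
        return gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1)

    with np.errstate(invalid="ignore"):
        log_p_absent = log_choose(T - counts, depth) - log_choose(T, depth)
    p_absent = np.where(T - counts >= depth, np.exp(log_p_absent), 0.0)
    return float(np.sum(1.0 - p_absent))


@dataclass
class DiversityEstimate:
    """Depth-normalised Chao1 diversity of one sample."""

    sample_id: str
    observed_richness: int
    depth: int
    replicates: int
    values: np.ndarray

    @property
    def chao1(self) -> float:
        """Mean Chao1 over downsampling replicates."""
        return float(np.mean(self.values))

    @property
    def spread(self) -> float:
        return float(np.std(self.values))


def normalized_diversity(
    sample: RepertoireSample,
    depth: int,
    replicates: int = 100,
    seed: int = 0,
    bias_corrected: bool = True,
) -> DiversityEstimate:
    """Chao1 richness normalised to analysis depth.

    Downsamples the UMI table to ``depth`` ``replicates`` times (seeded)
    and averages the Chao1 estimate over replicates.
    """
    if replicates < 1:
        raise ValueError("replicates must be >= 1")
    ss = np.random.SeedSequence(seed)
    values = np.array(
        [
            chao1(downsample(sample, depth, np.random.default_rng(child)), bias_corrected)
            for child in ss.spawn(replicates)
        ]
    )
    return DiversityEstimate(
        sample_id=sample.sample_id,
        observed_richness=sample.richness,
        depth=depth,
        replicates=replicates,
        values=values,
    )


@dataclass
class FrequencyEstimate:
    """Population frequency inferred from group capture probabilities."""

    R: int
    per_group: pd.DataFrame  # size_group, n, N, P, weight, phi
    phi: float  # weighted per-cell population frequency

    def cells_per_clone(self, body_t_cells: float = 1e11) -> float:
        return estimate_clone_cell_count(self.phi, body_t_cells)


def infer_population_frequency(records: pd.DataFrame, R: int) -> FrequencyEstimate:
    """Invert the Poisson capture law ``P = 1 - exp(-phi R)`` per size group.

    ``records`` are capture records (columns ``size_group, n, N``); records
    sharing a size group are pooled by summing ``n`` and ``N``.  The overall
    ``phi`` is the weighted mean of the per-group ``phi_s`` with weights
    ``w_s = N_s / sum(N)``, the fractions of clonotypes per size group.
    """
    if R < 1:
        raise ValueError("R must be >= 1")
    pooled = (
        records.groupby("size_group", observed=True)[["n", "N"]]
        .sum()
        .reset_index()
    )
    pooled["P"] = pooled["n"] / pooled["N"]
    if (pooled["P"] >= 1).any():
        groups = pooled.loc[pooled["P"] >= 1, "size_group"].tolist()
        raise ValueError(f"capture probability is 1 in group(s) {groups}; phi is infinite")
    pooled["weight"] = pooled["N"] / pooled["N"].sum()
    pooled["phi"] = -np.log1p(-pooled["P"]) / R
    phi = float((pooled["weight"] * pooled["phi"]).sum())
    return FrequencyEstimate(R=R, per_group=pooled, phi=phi)


def estimate_clone_cell_count(phi: float, body_t_cells: float = 1e11) -> float:
    """Rough clone size in cells: ``phi`` x body-wide T-cell count."""
    if phi < 0:
        raise ValueError("phi must be >= 0")
    return float(phi * body_t_cells)
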