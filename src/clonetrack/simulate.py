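"""Synthetic longitudinal repertoires with known ground truth.

The generator draws a fixed catalogue of clones with power-law (default,
rank-frequency exponent alpha = 2) or log-normal frequencies, equips each
clone with a synthetic but format-valid TCR identity (random non-stop CDR3
nucleotide sequence starting at a cysteine codon, translated amino-acid
sequence, V/J gene labels), and multinomially samples UMIs at a "pre" and a
"post" time point.  Optional perturbations applied before the post draw:

* *expansion* — a labeled fraction of clones has its frequency multiplied
  by a factor (then all frequencies renormalise, so non-expanded clones are
  slightly diluted — intended clonal competition);
* *death* — a labeled fraction of clones is set to frequency 0.

All randomness flows from the single scenario seed through a documented
splitting rule (``numpy.random.SeedSequence(seed).spawn``: child 0 builds
identities and labels, child 1 draws the pre sample, child 2 the post), so
every output is bit-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from Bio.Seq import Seq

from .io import CANONICAL_COLUMNS, RepertoireSample

_V_GENES = (
    "TRBV2", "TRBV4-1", "TRBV5-1", "TRBV6-2", "TRBV7-2", "TRBV9",
    "TRBV11-2", "TRBV12-3", "TRBV15", "TRBV19", "TRBV20-1", "TRBV25-1",
    "TRBV27", "TRBV28", "TRBV29-1", "TRBV30",
)
_J_GENES = ("TRBJ1-1", "TRBJ1-2", "TRBJ1-5", "TRBJ2-1", "TRBJ2-3", "TRBJ2-7")

_BASES = np.array(list("ACGT"))
_STOPS = {"TAA", "TAG", "TGA"}
_CODONS = np.array(
    [a + b + c for a in "ACGT" for b in "ACGT" for c in "ACGT" if a + b + c not in _STOPS]
)


@dataclass(frozen=True)
class SimulationScenario:
    """Parameters of one synthetic two-time-point repertoire.

    Defaults describe an unperturbed (neutral) repertoire: 10^4 clones with
    power-law rank frequencies (alpha = 2), 5x10^4 UMIs sampled at each time
    point.
    """

    n_clones: int = 10_000
    law: str = "power_law"  # or "lognormal"
    alpha: float = 2.0
    lognorm_mu: float = 0.0
    lognorm_sigma: float = 2.0
    depth_pre: int = 50_000
    depth_post: int = 50_000
    expanded_fraction: float = 0.0
    expansion_factor: float = 1.0
    death_fraction: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_clones < 1:
            raise ValueError("n_clones must be >= 1")
        if self.depth_pre < 1 or self.depth_post < 1:
            raise ValueError("depths must be >= 1")
        if self.expansion_factor <= 0:
            raise ValueError("expansion_factor must be > 0")
        if not 0 <= self.expanded_fraction <= 1 or not 0 <= self.death_fraction <= 1:
            raise ValueError("fractions must be in [0, 1]")
        if self.law not in ("power_law", "lognormal"):
            raise ValueError(f"unknown clone-frequency law {self.law!r}")


def _base_frequencies(scenario: SimulationScenario, rng: np.random.Generator) -> np.ndarray:
    n = scenario.n_clones
    if scenario.law == "power_law":
        freqs = np.arange(1, n + 1, dtype=float) ** (-scenario.alpha)
    else:
        freqs = rng.lognormal(scenario.lognorm_mu, scenario.lognorm_sigma, size=n)
    return freqs / freqs.sum()


def _synth_identities(n: int, rng: np.random.Generator) -> pd.DataFrame:
    """Unique synthetic clonotype identities with valid-format sequences."""
    seen: set[tuple[str, str]] = set()
    cdr3_nt, cdr3_aa, v, j = [], [], [], []
    while len(cdr3_nt) < n:
        n_codons = int(rng.integers(8, 17))
        middle = "".join(rng.choice(_CODONS, size=n_codons))
        nt = "TGT" + middle + "TTC"
        vg = str(rng.choice(_V_GENES))
        if (nt, vg) in seen:
            continue
        seen.add((nt, vg))
        cdr3_nt.append(nt)
        cdr3_aa.append(str(Seq(nt).translate()))
        v.append(vg)
        j.append(str(rng.choice(_J_GENES)))
    return pd.DataFrame({"cdr3_nt": cdr3_nt, "cdr3_aa": cdr3_aa, "v": v, "j": j})


@dataclass
class SyntheticTruth:
    """Ground-truth clone table: identities, frequencies, labels."""

    clones: pd.DataFrame  # key, cdr3_nt, cdr3_aa, v, j, freq_pre, freq_post, expanded, dead
    scenario: SimulationScenario

    def keys_where(self, column: str) -> set[str]:
        return set(self.clones.loc[self.clones[column], "key"])


def _draw_sample(
    truth_clones: pd.DataFrame,
    freq_column: str,
    depth: int,
    rng: np.random.Generator,
    sample_id: str,
) -> RepertoireSample:
    freqs = truth_clones[freq_column].to_numpy()
    total = freqs.sum()
    if total <= 0:
        table = pd.DataFrame({c: [] for c in CANONICAL_COLUMNS})
        table["count"] = table["count"].astype(int)
        return RepertoireSample(sample_id=sample_id, table=table)
    counts = rng.multinomial(depth, freqs / total)
    picked = counts > 0
    table = truth_clones.loc[picked, ["key", "cdr3_nt", "cdr3_aa", "v", "j"]].copy()
    table["count"] = counts[picked]
    return RepertoireSample(sample_id=sample_id, table=table.reset_index(drop=True))


def sample_repertoire(
    truth: SyntheticTruth,
    time_point: str,
    depth: int,
    seed: int | np.random.Generator,
    sample_id: str | None = None,
) -> RepertoireSample:
    """Multinomial draw of ``depth`` UMIs from a truth table.

    ``time_point`` selects the frequency column (``pre`` or ``post``).
    """
    if time_point not in ("pre", "post"):
        raise ValueError("time_point must be 'pre' or 'post'")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    return _draw_sample(
        truth.clones, f"freq_{time_point}", depth, rng, sample_id or f"sim_{time_point}"
    )


def simulate_timecourse(
    scenario: SimulationScenario,
) -> tuple[RepertoireSample, RepertoireSample, SyntheticTruth]:
    """Generate a (pre, post, truth) triple for one scenario."""
    ss = np.random.SeedSequence(scenario.seed)
    rng_truth, rng_pre, rng_post = (np.random.default_rng(c) for c in ss.spawn(3))

    clones = _synth_identities(scenario.n_clones, rng_truth)
    clones["key"] = clones["cdr3_nt"] + "|" + clones["v"]
    clones["freq_pre"] = _base_frequencies(scenario, rng_truth)

    n = scenario.n_clones
    expanded = np.zeros(n, dtype=bool)
    if scenario.expanded_fraction > 0:
        k = int(round(scenario.expanded_fraction * n))
        expanded[rng_truth.choice(n, size=k, replace=False)] = True
    dead = np.zeros(n, dtype=bool)
    if scenario.death_fraction > 0:
        k = int(round(scenario.death_fraction * n))
        dead[rng_truth.choice(n, size=k, replace=False)] = True
    clones["expanded"] = expanded
    clones["dead"] = dead

    post = clones["freq_pre"].to_numpy().copy()
    post[expanded] *= scenario.expansion_factor
    post[dead] = 0.0
    total = post.sum()
    clones["freq_post"] = post / total if total > 0 else post
    truth = SyntheticTruth(clones=clones, scenario=scenario)

    pre_sample = _draw_sample(clones, "freq_pre", scenario.depth_pre, rng_pre, "sim_pre")
    post_sample = _draw_sample(clones, "freq_post", scenario.depth_post, rng_post, "sim_post")
    return pre_sample, post_sample, truth


def simulate_pairs(scenario: SimulationScenario, n_pairs: int):
    """Independent replicate (pre, post, truth) triples, seeds split from
    the scenario seed."""
    rng = np.random.default_rng(scenario.seed)
    out = []
    for _ in range(n_pairs):
        child = int(rng.integers(0, 2**31 - 1))
        out.append(simulate_timecourse(replace(scenario, seed=child)))
    return out
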