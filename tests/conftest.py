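import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

import clonetrack as ct

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("ci")


def make_sample(counts: dict[str, int], sample_id: str = "s", **metadata) -> ct.RepertoireSample:
    """Sample from a {key: count} mapping; keys double as CDR3nt|V strings."""
    rows = []
    for key, count in counts.items():
        nt, _, v = key.partition("|")
        rows.append(
            {"key": key, "cdr3_nt": nt, "cdr3_aa": None, "v": v or None, "j": None, "count": count}
        )
    table = pd.DataFrame(rows, columns=ct.io.CANONICAL_COLUMNS)
    return ct.RepertoireSample(sample_id=sample_id, table=table, metadata=metadata)


@pytest.fixture
def toy_pair():
    """The canonical toy pair: pre={A:1,B:2,C:5}, post={B:1,D:4}."""
    pre = make_sample({"AAA|TRBV9": 1, "CCC|TRBV9": 2, "GGG|TRBV9": 5}, "pre")
    post = make_sample({"CCC|TRBV9": 1, "TTT|TRBV9": 4}, "post")
    return pre, post


@pytest.fixture
def noiseless_records():
    """Capture records generated exactly from a known log-linear law.

    log P = -2 + 0.9 log N_post - 0.9 log N_pre + {0, 0.8, 1.5, 2.7}[size]
    """
    rng = np.random.default_rng(1234)
    size_effect = {"singleton": 0.0, "doubleton": 0.8, "tripleton": 1.5, "large": 2.7}
    rows = []
    for i in range(50):
        n_pre = int(rng.integers(5_000, 50_000))
        n_post = int(rng.integers(max(100, n_pre // 20), n_pre // 3))
        for size, eff in size_effect.items():
            log_p = -2.0 + eff + 0.9 * np.log(n_post) - 0.9 * np.log(n_pre)
            assert log_p < 0
            rows.append(
                {
                    "pair_id": f"pair{i}",
                    "size_group": size,
                    "N_pre": n_pre,
                    "N_post": n_post,
                    "P": np.exp(log_p),
                    "n": 1,
                    "N": 1,
                }
            )
    df = pd.DataFrame(rows)
    df["size_group"] = pd.Categorical(
        df["size_group"], categories=["singleton", "doubleton", "tripleton", "large"], ordered=True
    )
    truth = {
        "Intercept": -2.0,
        "log_N_pre": -0.9,
        "log_N_post": 0.9,
        "size_group[T.doubleton]": 0.8,
        "size_group[T.tripleton]": 1.5,
        "size_group[T.large]": 2.7,
    }
    return df, truth


@pytest.fixture(scope="session")
def neutral_pairs():
    """Six replicate neutral (no expansion/death) pre-post pairs, pooled.

    Equal depths, power-law clone sizes; used by the monotonicity checks.
    """
    scenario = ct.SimulationScenario(
        n_clones=20_000, depth_pre=100_000, depth_post=100_000, seed=11
    )
    return ct.simulate_pairs(scenario, 6)


@pytest.fixture(scope="session")
def capture_curve(neutral_pairs):
    """Pooled capture probability per exact pre-sample count (1..10).

    Uses a deep scenario with post/pre depth ratio 0.3, emulating
    longitudinal repertoires whose diversity shrinks between samplings.
    """
    scenario = ct.SimulationScenario(
        n_clones=30_000, depth_pre=300_000, depth_post=90_000, seed=7
    )
    rows = []
    for pre, post, _ in ct.simulate_pairs(scenario, 4):
        df = ct.track_pair(pre, post).df
        pre_side = df[df["count_pre"] >= 1]
        for c in range(1, 11):
            grp = pre_side[pre_side["count_pre"] == c]
            rows.append((c, int(grp["found_in_post"].sum()), len(grp)))
    pooled = pd.DataFrame(rows, columns=["count", "n", "N"]).groupby("count").sum()
    pooled["P"] = pooled["n"] / pooled["N"]
    return pooled


@pytest.fixture(scope="session")
def neutral_records(neutral_pairs):
    recs = [
        ct.summarize_capture(ct.track_pair(pre, post, pair_id=f"pair{i}"))
        for i, (pre, post, _) in enumerate(neutral_pairs)
    ]
    return ct.concat_records(recs)
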