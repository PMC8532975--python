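import numpy as np
import pandas as pd
import pytest

import refstab as rs


@pytest.fixture(scope="session")
def planted_dataset():
    """4 stable + 2 unstable genes, 5 stages x 3 replicates, fixed seed."""
    ct, truth = rs.generate_ct_dataset(4, 2, seed=7)
    return ct, truth


@pytest.fixture(scope="session")
def planted_quantities(planted_dataset):
    ct, truth = planted_dataset
    return rs.ct_to_quantity(ct), truth


@pytest.fixture()
def small_quantities():
    """A tiny hand-written quantity matrix (3 genes x 6 samples)."""
    rng = np.random.default_rng(11)
    base = rng.uniform(0.2, 1.0, 6)
    values = pd.DataFrame(
        {
            "A": base,
            "B": base * 0.5,                       # proportional to A
            "C": rng.uniform(0.05, 1.0, 6),        # noisy
        }
    ).T
    values.columns = [f"s{i}" for i in range(6)]
    group_of = {f"s{i}": ("G1" if i < 3 else "G2") for i in range(6)}
    return rs.QuantityMatrix(values / values.max(axis=1).to_numpy()[:, None],
                             {g: 1.0 for g in "ABC"}, group_of)


def naive_pairwise_sd(qj, qk):
    """Loop-computed SD of per-sample log2 ratios (independent of numpy paths)."""
    import math
    import statistics

    ratios = [math.log2(a / b) for a, b in zip(qj, qk)]
    return statistics.stdev(ratios)


def naive_genorm_order(values):
    """Brute-force stepwise geNorm on a dict gene -> list of quantities.

    Pure-python loops; recomputes every pairwise SD at each step.  Returns
    (exclusion order, final pair sorted, m at exclusion).
    """
    import statistics

    remaining = sorted(values)
    excluded = []
    m_at = {}
    while len(remaining) > 2:
        m = {}
        for j in remaining:
            vs = [naive_pairwise_sd(values[j], values[k])
                  for k in remaining if k != j]
            m[j] = statistics.mean(vs) if len(vs) > 1 else vs[0]
        worst_m = max(m.values())
        worst = sorted(g for g in m if m[g] == worst_m)[0]
        m_at[worst] = worst_m
        excluded.append(worst)
        remaining.remove(worst)
    pair = sorted(remaining)
    v = naive_pairwise_sd(values[pair[0]], values[pair[1]])
    m_at[pair[0]] = m_at[pair[1]] = v
    return excluded, pair, m_at
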