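import numpy as np
import pandas as pd
import pytest

import synstress as ss


def make_blocks(n_samples: int, block_sizes, within_r: float,
                n_background: int = 0, seed: int = 0):
    """Block-correlated expression with planted module activities.

    Each block gene is sqrt(r) * activity + sqrt(1 - r) * noise so the
    expected within-block Pearson correlation is ``within_r``.  Block
    activities are mutually orthogonalized (QR) so the planted between-block
    correlation is exactly zero; background genes are white noise.
    Returns (expr, truth_labels, activities).
    """
    rng = np.random.default_rng(seed)
    raw = rng.normal(0, 1, (n_samples, len(block_sizes)))
    raw -= raw.mean(axis=0)
    q, _ = np.linalg.qr(raw)
    activities = q * np.sqrt(n_samples)        # unit-variance, orthogonal
    rows, labels, acts = [], [], {}
    for b, size in enumerate(block_sizes):
        name = f"B{b + 1}"
        activity = activities[:, b]
        acts[name] = activity
        noise = rng.normal(0, 1, (size, n_samples))
        rows.append(np.sqrt(within_r) * activity + np.sqrt(1 - within_r) * noise)
        labels += [name] * size
    if n_background:
        rows.append(rng.normal(0, 1, (n_background, n_samples)))
        labels += ["background"] * n_background
    x = np.vstack(rows)
    genes = [f"g{i:04d}" for i in range(x.shape[0])]
    expr = pd.DataFrame(x, index=genes, columns=[f"s{j:03d}" for j in range(n_samples)])
    return expr, pd.Series(labels, index=genes), pd.DataFrame(acts, index=expr.columns)


@pytest.fixture(scope="session")
def blocks():
    return make_blocks


@pytest.fixture(scope="session")
def small_sim():
    cfg = ss.SimulationConfig(n_genes=600, module_sizes=(120, 80, 50), seed=3)
    counts, meta, traits, truth = ss.simulate_experiment(cfg)
    return cfg, counts, meta, traits, truth


@pytest.fixture(scope="session")
def small_prep(small_sim):
    _, counts, meta, _, _ = small_sim
    return ss.preprocess(counts, meta)


@pytest.fixture(scope="session")
def small_network(small_prep):
    return ss.CoexpressionNetwork(small_prep.expr).fit()
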