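import numpy as np
import pytest

from emscore import synthdata


def make_labeled_catalog(seed: int, n_genes: int = 50, n_individuals: int = 50,
                         m_variants: int = 200, causal_fraction: float = 0.1,
                         unlabeled_fraction: float = 0.05):
    """Catalog with fine-mapping-style PIP columns synthesized from the truth.

    Causal pairs get PIPs above the positive-label threshold, non-causal
    pairs get PIPs below the negative threshold, and a small fraction is
    left at intermediate PIP (unlabeled), mimicking a confident two-method
    fine-mapping run without paying for one.
    """
    cat = synthdata.simulate_catalog(
        n_genes=n_genes, n_individuals=n_individuals, m_variants=m_variants,
        causal_fraction=causal_fraction, seed=seed)
    rng = np.random.default_rng(seed + 1)
    n = len(cat.pairs)
    pip = np.where(cat.truth, rng.uniform(0.92, 1.0, n), rng.uniform(0.0, 5e-5, n))
    mid = rng.uniform(size=n) < unlabeled_fraction
    pip[mid] = rng.uniform(0.1, 0.8, mid.sum())
    cat.pairs["pip_a"] = pip
    cat.pairs["pip_b"] = pip
    return cat


@pytest.fixture(scope="session")
def labeled_catalog():
    return make_labeled_catalog(seed=11)


@pytest.fixture(scope="session")
def fresh_catalog():
    return make_labeled_catalog(seed=77)
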