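import itertools

import numpy as np
import pytest

from owlserr import GeneratorConfig, PARAMETERS, default_parameter_table, generate_dataset


@pytest.fixture(scope="session")
def default_config() -> GeneratorConfig:
    return default_parameter_table()


@pytest.fixture(scope="session")
def dataset_seed1(default_config):
    """One full synthetic study (7 species x 4 positions x 25 serrations)."""
    return generate_dataset(default_config, seed=1)


@pytest.fixture(scope="session")
def zero_noise_config(default_config) -> GeneratorConfig:
    zeros = {p: 0.0 for p in PARAMETERS}
    return default_config.with_overrides(sigma_feather=zeros, sigma_serration=zeros)


def mann_whitney_oracle(a, b) -> float:
    """Independent brute-force exact two-sided Mann-Whitney p-value.

    Pure-Python enumeration of all C(n_a+n_b, n_a) group assignments of the
    pooled values, with manually computed midranks.
    """
    pooled = [float(x) for x in a] + [float(x) for x in b]
    n_a, n_b = len(a), len(b)
    n = n_a + n_b
    order = sorted(range(n), key=lambda i: pooled[i])
    ranks = [0.0] * n
    i = 0
    while i < n:
        j = i
        while j + 1 < n and pooled[order[j + 1]] == pooled[order[i]]:
            j += 1
        midrank = (i + j + 2) / 2.0  # ranks are 1-based
        for k in range(i, j + 1):
            ranks[order[k]] = midrank
        i = j + 1
    center = n_a * n_b / 2.0
    offset = n_a * (n_a + 1) / 2.0

    def stat(idx) -> float:
        return abs(sum(ranks[i] for i in idx) - offset - center)

    observed = stat(range(n_a))
    assignments = list(itertools.combinations(range(n), n_a))
    hits = sum(1 for c in assignments if stat(c) >= observed - 1e-12)
    return hits / len(assignments)


@pytest.fixture(scope="session")
def mw_oracle():
    return mann_whitney_oracle
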