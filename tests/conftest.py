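"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

import numpy as np
import pytest

from paraloci import hybrid_detection as hd
from paraloci import synthetic_data as sd

GAP_OPEN = -4
GAP_EXTEND = -1
MATCH = 1
MISMATCH = -1


def gotoh_score(a: str, b: str) -> float:
    """Brute-force affine-gap global alignment score (independent oracle).

    Straight Gotoh dynamic programming with the package's fixed scoring;
    used only on short sequences.
    """
    neg = float("-inf")
    n, m = len(a), len(b)
    M = np.full((n + 1, m + 1), neg)
    X = np.full((n + 1, m + 1), neg)  # gap in b (consuming a)
    Y = np.full((n + 1, m + 1), neg)  # gap in a (consuming b)
    M[0, 0] = 0.0
    for i in range(1, n + 1):
        X[i, 0] = GAP_OPEN + GAP_EXTEND * (i - 1)
    for j in range(1, m + 1):
        Y[0, j] = GAP_OPEN + GAP_EXTEND * (j - 1)
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            s = MATCH if a[i - 1] == b[j - 1] else MISMATCH
            M[i, j] = max(M[i - 1, j - 1], X[i - 1, j - 1], Y[i - 1, j - 1]) + s
            X[i, j] = max(M[i - 1, j] + GAP_OPEN, X[i - 1, j] + GAP_EXTEND,
                          Y[i - 1, j] + GAP_OPEN)
            Y[i, j] = max(M[i, j - 1] + GAP_OPEN, Y[i, j - 1] + GAP_EXTEND,
                          X[i, j - 1] + GAP_OPEN)
    return max(M[n, m], X[n, m], Y[n, m])


def random_dna(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(list("ACGT"), length))


@pytest.fixture(scope="session")
def family() -> sd.Family:
    return sd.simulate_family(sd.FamilyConfig(seed=1))


@pytest.fixture(scope="session")
def cohort(family) -> sd.Cohort:
    return sd.simulate_cohort(family, sd.default_cohort_spec(seed=3))


@pytest.fixture(scope="session")
def masked_sites(family):
    sites = hd.find_diagnostic_sites(family.acceptor_gene, family.donor_gene)
    return hd.mask_confounded_sites(sites, family.donor_variants)
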