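"""Shared fixtures and independent oracles for the test suite."""

import math
from collections import Counter

import numpy as np
import pytest

from cmf import Alignment
from cmf.synthetic import SyntheticSpec, generate_msa, random_coupled_pairs


def brute_force_u(rows, i, j):
    """Direct-summation normalized mutual information of columns i and j.

    Pure-python oracle: builds the joint and marginal distributions with
    dictionaries and sums entropies term by term.  Deliberately shares no
    code with the package implementation.
    """
    pairs = [(r[i], r[j]) for r in rows if r[i] != "-" and r[j] != "-"]
    if not pairs:
        return 0.0
    n = len(pairs)

    def entropy(counter):
        h = 0.0
        for c in counter.values():
            p = c / n
            if p > 0:
                h -= p * math.log2(p)
        return h

    hi = entropy(Counter(a for a, _ in pairs))
    hj = entropy(Counter(b for _, b in pairs))
    hij = entropy(Counter(pairs))
    if hi + hj == 0:
        return 0.0
    return 2.0 * (hi + hj - hij) / (hi + hj)


def make_alignment(columns, ids=None):
    """Build an Alignment from a list of column strings."""
    n = len(columns[0])
    rows = ["".join(col[r] for col in columns) for r in range(n)]
    return Alignment(ids=ids or [f"s{k}" for k in range(n)], rows=rows)


@pytest.fixture(scope="session")
def small_synthetic():
    """A 140x80 alignment with 6 planted pairs at rho=0.9 plus ground truth."""
    rng = np.random.default_rng(42)
    pairs = random_coupled_pairs(6, 80, 0.9, rng)
    spec = SyntheticSpec(n_seqs=140, n_cols=80, coupled_pairs=pairs, seed=42)
    return generate_msa(spec)


@pytest.fixture(scope="session")
def random_dcm():
    """A non-trivial doubly stochastic 400x400 matrix (Sinkhorn of noise)."""
    from cmf import DoublyStochasticMatrix
    from cmf.dcm import sinkhorn_normalize

    rng = np.random.default_rng(7)
    raw = rng.random((400, 400)) + 1e-3
    raw = 0.5 * (raw + raw.T)
    d = sinkhorn_normalize(raw, tol=1e-10, max_iter=5000)
    d = 0.5 * (d + d.T)
    return DoublyStochasticMatrix(values=d, tolerance=1e-8).validate()
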