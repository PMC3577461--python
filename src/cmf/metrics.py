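"""Column-pair coupling metrics: normalized mutual information and its
dissimilarity-upscaled variant.

For a pair of alignment columns *i*, *j* the coupling score is

    U(i,j) = 2 * (H_i + H_j - H_ij) / (H_i + H_j),

a mutual information normalized into [0, 1], where H_i and H_j are the
Shannon entropies of the column marginals and H_ij the entropy of the joint
residue-pair distribution.  U = 1 for perfect covariation and 0 for sampled
independence (and by convention when both columns are constant).

The UD(alpha) variant first pushes the 400-state empirical pair distribution
through the doubly stochastic matrix D(alpha) = (1-alpha)*I + alpha*D, where
D is a trained matrix concentrating mass on BLOSUM62-dissimilar compensatory
exchanges, and then takes the U-value of the transform (marginals recomputed
from the transformed joint).  Because a doubly stochastic transform can only
increase entropy, pairs whose statistics do not match the trained
compensatory pattern are penalized, while matching pairs keep their signal.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Optional

import numpy as np

from .msa_io import Alignment

N_STATES = 400  # ordered amino-acid pairs, index = 20*idx(a) + idx(b)


@dataclass
class PairDistribution:
    """Empirical distribution over the 400 ordered residue-pair states."""

    probs: np.ndarray
    support_count: int

    def __post_init__(self):
        self.probs = np.asarray(self.probs, dtype=float)
        if self.probs.shape != (N_STATES,):
            raise ValueError("pair distribution must have 400 states")


@dataclass
class PairScoreTable:
    """Scores for every unordered pair of retained columns of one MSA."""

    metric_name: str  # "U" or "UD"
    entries: dict  # (i, j) with i < j (filtered-column indices) -> score
    alpha: Optional[float] = None

    def pairs(self):
        return list(self.entries.keys())

    def scores(self) -> np.ndarray:
        return np.asarray(list(self.entries.values()), dtype=float)

    def to_tsv(self, aln: Alignment, path) -> None:
        """Write all pair scores with original-column and reference-residue
        coordinates."""
        with open(path, "w") as fh:
            fh.write("col_i\tcol_j\tref_res_i\tref_res_j\tscore\n")
            for (i, j), score in self.entries.items():
                ri = aln.ref_residue[i]
                rj = aln.ref_residue[j]
                fh.write(
                    f"{aln.col_map[i]}\t{aln.col_map[j]}\t"
                    f"{'' if ri is None else ri}\t{'' if rj is None else rj}\t"
                    f"{score:.6f}\n"
                )


def _entropy_bits(p: np.ndarray) -> float:
    p = p[p > 0]
    return float(-(p * np.log2(p)).sum())


def column_entropy(counts) -> float:
    """Shannon entropy (bits) of a residue count vector; 0*log 0 := 0."""
    counts = np.asarray(counts, dtype=float)
    if counts.min() < 0:
        raise ValueError("counts must be non-negative")
    total = counts.sum()
    if total <= 0:
        raise ValueError("all-zero count vector has no entropy")
    return _entropy_bits(counts / total)


def joint_distribution(msa: Alignment, i: int, j: int) -> PairDistribution:
    """Empirical 400-state pair distribution of columns *i* and *j*.

    Sequences with a gap at either column are excluded; the number of
    remaining sequences is recorded as ``support_count``.
    """
    if i == j:
        raise ValueError("column indices must differ")
    codes = msa.codes()
    ci, cj = codes[:, i], codes[:, j]
    mask = (ci >= 0) & (cj >= 0)
    n = int(mask.sum())
    probs = np.zeros(N_STATES)
    if n > 0:
        states = 20 * ci[mask] + cj[mask]
        probs = np.bincount(states, minlength=N_STATES).astype(float) / n
    return PairDistribution(probs=probs, support_count=n)


def _check_normalized(p: PairDistribution):
    if p.probs.min() < -1e-12:
        raise ValueError("pair distribution has negative entries")
    if abs(p.probs.sum() - 1.0) > 1e-9:
        raise ValueError("pair distribution is not normalized")


def u_metric(p: PairDistribution) -> float:
    """Normalized mutual information of a pair distribution, in [0, 1].

    Marginals are taken from the same 400-vector as the joint, which
    guarantees H_ij <= H_i + H_j and hence U >= 0.  Returns 0 when
    H_i + H_j = 0 (both columns constant on the shared support).
    """
    if p.support_count < 1:
        raise ValueError("empty support: no gap-free sequence at this pair")
    _check_normalized(p)
    return _u_of_vector(p.probs)


def _u_of_vector(probs: np.ndarray) -> float:
    square = probs.reshape(20, 20)
    hi = _entropy_bits(square.sum(axis=1))
    hj = _entropy_bits(square.sum(axis=0))
    hij = _entropy_bits(probs)
    denom = hi + hj
    if denom <= 0:
        return 0.0
    u = 2.0 * (denom - hij) / denom
    return float(min(1.0, max(0.0, u)))


def _dcm_values(dcm) -> np.ndarray:
    values = getattr(dcm, "values", dcm)
    values = np.asarray(values, dtype=float)
    if values.shape != (N_STATES, N_STATES):
        raise ValueError("doubly stochastic matrix must be 400x400")
    return values


def transform_distribution(p: PairDistribution, dcm, alpha: float) -> PairDistribution:
    """Apply q = D(alpha) @ p with D(alpha) = (1-alpha)*I + alpha*D."""
    if not (0 < alpha <= 1):
        raise ValueError("alpha must lie in (0, 1]")
    _check_normalized(p)
    d = _dcm_values(dcm)
    # written as p + alpha*(D p - p) so that D = I is a bitwise no-op
    q = p.probs + alpha * (d @ p.probs - p.probs)
    q = np.clip(q, 0.0, None)
    total = q.sum()
    if abs(total - 1.0) > 1e-12:
        q = q / total
    return PairDistribution(probs=q, support_count=p.support_count)


def ud_metric(p: PairDistribution, dcm, alpha: float = 1.0) -> float:
    """U-value of the D(alpha)-transformed pair distribution."""
    if p.support_count < 1:
        raise ValueError("empty support: no gap-free sequence at this pair")
    return u_metric(transform_distribution(p, dcm, alpha))


def all_pair_scores(
    msa: Alignment,
    metric: str = "U",
    dcm=None,
    alpha: float = 1.0,
) -> PairScoreTable:
    """Score every unordered pair of retained columns.

    Pairs with empty gap-free support score 0.  Deterministic in the input;
    invariant under permutation of the sequences.
    """
    if metric not in ("U", "UD"):
        raise ValueError(f"unknown metric {metric!r}")
    if metric == "UD":
        if dcm is None:
            raise ValueError("metric 'UD' requires a doubly stochastic matrix")
        if not (0 < alpha <= 1):
            raise ValueError("alpha must lie in (0, 1]")
        d = _dcm_values(dcm)

    codes = msa.codes()
    valid = codes >= 0
    pairs = list(combinations(range(msa.n_cols), 2))
    n_pairs = len(pairs)
    dists = np.zeros((n_pairs, N_STATES))
    support = np.zeros(n_pairs, dtype=int)
    for k, (i, j) in enumerate(pairs):
        mask = valid[:, i] & valid[:, j]
        n = int(mask.sum())
        support[k] = n
        if n:
            states = 20 * codes[mask, i] + codes[mask, j]
            dists[k] = np.bincount(states, minlength=N_STATES)
    with np.errstate(invalid="ignore"):
        dists /= np.where(support > 0, support, 1)[:, None]

    if metric == "UD":
        dists = dists + alpha * (dists @ d.T - dists)
        np.clip(dists, 0.0, None, out=dists)
        sums = dists.sum(axis=1)
        bad = np.abs(sums - 1.0) > 1e-12
        if bad.any():
            dists[bad] /= np.where(sums[bad] > 0, sums[bad], 1)[:, None]

    scores = _u_rows(dists)
    scores[support == 0] = 0.0
    entries = {pair: float(s) for pair, s in zip(pairs, scores)}
    return PairScoreTable(
        metric_name=metric,
        entries=entries,
        alpha=alpha if metric == "UD" else None,
    )


def score_from_codes(ci, cj, metric: str = "U", dcm=None, alpha: float = 1.0) -> float:
    """Score one column pair given integer-coded columns (gap = -1).

    Used by the shuffle-based null-variance estimator, where one column is a
    permuted copy and no Alignment object exists for the pair.
    """
    ci = np.asarray(ci)
    cj = np.asarray(cj)
    mask = (ci >= 0) & (cj >= 0)
    n = int(mask.sum())
    if n == 0:
        return 0.0
    states = 20 * ci[mask] + cj[mask]
    probs = np.bincount(states, minlength=N_STATES).astype(float) / n
    if metric == "UD":
        d = _dcm_values(dcm)
        probs = probs + alpha * (d @ probs - probs)
        np.clip(probs, 0.0, None, out=probs)
        total = probs.sum()
        if abs(total - 1.0) > 1e-12:
            probs = probs / total
    return _u_of_vector(probs)


def _u_rows(dists: np.ndarray) -> np.ndarray:
    """Vectorized U over rows of a (n_pairs, 400) distribution matrix."""

    def h(mat):
        with np.errstate(divide="ignore", invalid="ignore"):
            terms = np.where(mat > 0, mat * np.log2(np.where(mat > 0, mat, 1)), 0.0)
        return -terms.sum(axis=-1)

    cube = dists.reshape(-1, 20, 20)
    hi = h(cube.sum(axis=2))
    hj = h(cube.sum(axis=1))
    hij = h(dists)
    denom = hi + hj
    with np.errstate(invalid="ignore", divide="ignore"):
        u = np.where(denom > 0, 2.0 * (denom - hij) / np.where(denom > 0, denom, 1), 0.0)
    return np.clip(u, 0.0, 1.0)
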