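"""Training of the 400x400 doubly stochastic compensatory-exchange matrix.

The matrix D models how often pairs of residue-pair states replace one
another at coevolving column pairs, restricted to *formal dissimilar
compensatory* exchanges: a pair of pair-states ((a_i, a_j), (a_k, a_l)) is
dissimilar-compensatory when both positional BLOSUM62 scores, B(a_i, a_k)
and B(a_j, a_l), are negative.

Training runs in five phases over a corpus of filtered MSAs:

1. Count residue-pair substitutions (BLOSUM-style, lifted from single
   columns to column pairs) separately over a signal set (the significant
   column pairs of every MSA) and a null set (random column pairs) to give
   the symmetric count matrices C_alt and C_null.
2. Keep an entry of C_alt iff it is diagonal or its relative frequency
   strictly exceeds that in C_null (matrix C_sig).
3. Zero off-diagonal entries that are not formal dissimilar compensatory
   exchanges; normalize to a probability matrix P.
4. Form the log-odds matrix S = log P / (Pb x Pb), Pb the first-index
   marginal of P.
5. Zero negative entries of S and run iterated row/column (Sinkhorn)
   normalization to a doubly stochastic matrix, symmetrized on exit.
"""

from __future__ import annotations

import hashlib
import logging
import time
from dataclasses import dataclass, field
from itertools import combinations
from pathlib import Path

import numpy as np
from Bio.Align import substitution_matrices

from .msa_io import AMINO_ACIDS, AA_INDEX, Alignment, filter_alignment, read_msa
from .metrics import N_STATES, all_pair_scores

logger = logging.getLogger(__name__)

_BLOSUM62 = None


def _blosum62_array() -> np.ndarray:
    """BLOSUM62 as a 20x20 integer array in alphabetical residue order."""
    global _BLOSUM62
    if _BLOSUM62 is None:
        mat = substitution_matrices.load("BLOSUM62")
        arr = np.zeros((20, 20), dtype=int)
        for a, i in AA_INDEX.items():
            for b, j in AA_INDEX.items():
                arr[i, j] = int(mat[a, b])
        _BLOSUM62 = arr
    return _BLOSUM62


def blosum62_score(a: str, b: str) -> int:
    """Standard BLOSUM62 substitution score for two standard residues."""
    if a not in AA_INDEX or b not in AA_INDEX:
        raise ValueError(f"non-standard residue in pair ({a!r}, {b!r})")
    return int(_blosum62_array()[AA_INDEX[a], AA_INDEX[b]])


def dissimilar_mask() -> np.ndarray:
    """Boolean 400x400 mask of formal dissimilar compensatory exchanges.

    Entry (20*i + j, 20*k + l) is True iff B(i,k) < 0 and B(j,l) < 0.
    """
    neg = _blosum62_array() < 0
    return np.kron(neg, neg).astype(bool)


def is_formal_dissimilar_compensatory(p1, p2) -> bool:
    """True iff both positional substitutions of the two pair-states score
    negatively under BLOSUM62."""
    (ai, aj), (ak, al) = p1, p2
    return blosum62_score(ai, ak) < 0 and blosum62_score(aj, al) < 0


@dataclass
class PairPairMatrix:
    """A 400x400 matrix over (pair-state, pair-state)."""

    values: np.ndarray
    role: str = ""

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (N_STATES, N_STATES):
            raise ValueError("pair-pair matrix must be 400x400")

    def check_symmetric(self, tol: float = 1e-9):
        finite = np.nan_to_num(self.values, neginf=-1.0)
        if np.abs(finite - finite.T).max() > tol:
            raise ValueError(f"{self.role or 'matrix'} is not symmetric")


@dataclass
class DoublyStochasticMatrix:
    """Non-negative 400x400 matrix with unit row and column sums."""

    values: np.ndarray
    tolerance: float = 1e-8
    provenance: dict = field(default_factory=dict)

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (N_STATES, N_STATES):
            raise ValueError("doubly stochastic matrix must be 400x400")

    def validate(self):
        v = self.values
        if v.min() < 0:
            raise ValueError("doubly stochastic matrix has negative entries")
        dev = max(
            np.abs(v.sum(axis=0) - 1).max(), np.abs(v.sum(axis=1) - 1).max()
        )
        if dev > self.tolerance:
            raise ValueError(
                f"row/column sums deviate from 1 by {dev:.3g} "
                f"(tolerance {self.tolerance:.3g})"
            )
        return self

    @classmethod
    def identity(cls) -> "DoublyStochasticMatrix":
        return cls(values=np.eye(N_STATES), provenance={"kind": "identity"})


# ---------------------------------------------------------------------------
# Phase 1: substitution counting
# ---------------------------------------------------------------------------

def count_pair_substitutions(
    column_pairs,
    max_rows: int = 300,
    rng=None,
) -> PairPairMatrix:
    """Count residue-pair substitutions over a set of column pairs.

    ``column_pairs`` iterates over ``(alignment, i, j)``.  For each column
    pair, every unordered pair of sequences without gaps at either column
    contributes one count to both ordered entries (so the matrix is symmetric
    by construction, diagonal included).  MSAs deeper than ``max_rows``
    are subsampled (seeded) for tractability; pass ``max_rows=None`` to
    disable.
    """
    if rng is None:
        rng = np.random.default_rng(0)
    total = np.zeros((N_STATES, N_STATES))
    n_pairs = 0
    for aln, i, j in column_pairs:
        codes = aln.codes()
        ci, cj = codes[:, i], codes[:, j]
        mask = (ci >= 0) & (cj >= 0)
        states = 20 * ci[mask] + cj[mask]
        if max_rows is not None and states.size > max_rows:
            states = states[rng.choice(states.size, size=max_rows, replace=False)]
        if states.size < 2:
            continue
        counts = np.bincount(states, minlength=N_STATES).astype(float)
        # outer(c, c) - diag(c): off-diagonal (u,v) gets c_u*c_v per ordered
        # entry; diagonal (u,u) gets c_u*(c_u-1) = 2*C(c_u, 2).
        total += np.outer(counts, counts)
        total[np.diag_indices(N_STATES)] -= counts
        n_pairs += 1
    if n_pairs == 0:
        raise ValueError("no usable column pairs to count substitutions from")
    return PairPairMatrix(values=total, role="counts")


# ---------------------------------------------------------------------------
# Phases 2-4
# ---------------------------------------------------------------------------

def phase2_signal_counts(
    c_alt: PairPairMatrix, c_null: PairPairMatrix
) -> PairPairMatrix:
    """Keep entries of C_alt that are diagonal or relatively enriched over
    the null counts (strict inequality of relative frequencies)."""
    alt, null = c_alt.values, c_null.values
    alt_total, null_total = alt.sum(), null.sum()
    if alt_total <= 0 or null_total <= 0:
        raise ValueError("phase 2 requires non-empty count matrices")
    keep = (alt / alt_total) > (null / null_total)
    keep[np.diag_indices(N_STATES)] = True
    return PairPairMatrix(values=np.where(keep, alt, 0.0), role="C_sig")


def phase3_compmut(c_sig: PairPairMatrix):
    """Mask non-compensatory off-diagonal entries and normalize."""
    mask = dissimilar_mask()
    mask[np.diag_indices(N_STATES)] = True
    c_compmut = np.where(mask, c_sig.values, 0.0)
    total = c_compmut.sum()
    if total <= 0:
        raise ValueError("no compensatory signal in corpus")
    return (
        PairPairMatrix(values=c_compmut, role="C_CompMut"),
        PairPairMatrix(values=c_compmut / total, role="P_CompMut"),
    )


def phase4_log_odds(p: PairPairMatrix) -> PairPairMatrix:
    """Log-odds of P against the product of its first-index marginals.

    Entries with zero probability get -inf, which phase 5 zeroes along with
    every other negative entry.
    """
    values = p.values
    marginal = values.sum(axis=1)
    expected = np.outer(marginal, marginal)
    with np.errstate(divide="ignore", invalid="ignore"):
        s = np.where(
            (values > 0) & (expected > 0),
            np.log(np.where(values > 0, values, 1.0))
            - np.log(np.where(expected > 0, expected, 1.0)),
            -np.inf,
        )
    return PairPairMatrix(values=s, role="S_CompMut")


# ---------------------------------------------------------------------------
# Phase 5: Sinkhorn scaling
# ---------------------------------------------------------------------------

def sinkhorn_normalize(
    matrix: np.ndarray, tol: float = 1e-8, max_iter: int = 10000
) -> np.ndarray:
    """Iterated row/column normalization of a non-negative matrix.

    Alternates row and column normalization until every row and column sum
    is within ``tol`` of 1.  Raises on non-convergence, reporting the
    achieved deviation.
    """
    a = np.asarray(matrix, dtype=float).copy()
    if a.min() < 0:
        raise ValueError("Sinkhorn scaling requires a non-negative matrix")
    if (a.sum(axis=1) == 0).any() or (a.sum(axis=0) == 0).any():
        raise ValueError("Sinkhorn scaling requires support in every row and column")
    for _ in range(max_iter):
        rows = a.sum(axis=1)
        cols = a.sum(axis=0)
        dev = max(np.abs(rows - 1).max(), np.abs(cols - 1).max())
        if dev <= tol:
            return a
        a /= rows[:, None]
        a /= a.sum(axis=0)[None, :]
    rows = a.sum(axis=1)
    dev = max(np.abs(rows - 1).max(), np.abs(a.sum(axis=0) - 1).max())
    raise RuntimeError(
        f"Sinkhorn scaling did not converge in {max_iter} iterations "
        f"(achieved deviation {dev:.3g}, tolerance {tol:.3g})"
    )


def phase5_sinkhorn(
    s: PairPairMatrix, tol: float = 1e-8, max_iter: int = 10000
) -> DoublyStochasticMatrix:
    """Zero negative log-odds, repair the diagonal, scale to doubly stochastic.

    Zero diagonal entries are set to 1 before scaling: an identity
    substitution is always admissible, and for a symmetric matrix a fully
    positive diagonal guarantees total support, hence geometric Sinkhorn
    convergence (this also repairs rows/columns left empty by the
    negative-zeroing).  The converged matrix is symmetrized as (D + D^T)/2
    and re-validated.
    """
    a = np.where(np.isfinite(s.values) & (s.values > 0), s.values, 0.0)
    zero_diag = np.diag(a) == 0
    if zero_diag.any():
        logger.info("phase 5: injecting %d zero diagonal entries", zero_diag.sum())
        idx = np.where(zero_diag)[0]
        a[idx, idx] = 1.0
    d = sinkhorn_normalize(a, tol=tol, max_iter=max_iter)
    d = 0.5 * (d + d.T)
    return DoublyStochasticMatrix(values=d, tolerance=tol).validate()


# ---------------------------------------------------------------------------
# Orchestration
# ---------------------------------------------------------------------------

def train_dcm(
    corpus,
    fdr: float = 0.01,
    seed: int = 0,
    filter_kwargs: dict | None = None,
    significance_kwargs: dict | None = None,
    null_min: int = 50,
    max_rows: int = 300,
    sinkhorn_tol: float = 1e-8,
    sinkhorn_max_iter: int = 10000,
    iterations: int = 1,
) -> DoublyStochasticMatrix:
    """Train D from a corpus of MSAs (directory of FASTA files or a list of
    Alignments).

    Per MSA: filter, score all column pairs with U, call significant pairs
    at ``fdr`` (the signal set), and draw a seeded null set of random
    non-significant column pairs (size = max(#signal, ``null_min``)).
    Phases 1-5 are then run on the pooled counts.  Deterministic given the
    corpus and ``seed``.

    ``iterations > 1`` re-runs the significance scan with the UD(1) metric of
    the previously trained matrix and retrains (an optional refinement loop;
    the default single pass is the standard training).
    """
    from . import significance as sig  # deferred: avoids an import cycle

    filter_kwargs = dict(filter_kwargs or {})
    significance_kwargs = dict(significance_kwargs or {})

    if isinstance(corpus, (str, Path)):
        paths = sorted(Path(corpus).glob("*.fasta")) + sorted(
            Path(corpus).glob("*.fa")
        )
        if not paths:
            raise ValueError(f"no FASTA files found in {corpus}")
        alignments = [read_msa(p) for p in paths]
        names = [p.name for p in paths]
    else:
        alignments = list(corpus)
        names = [f"msa{k}" for k in range(len(alignments))]
    if not alignments:
        raise ValueError("empty training corpus")

    root = np.random.SeedSequence(seed)
    msa_seeds = root.spawn(len(alignments) + 1)
    count_rng = np.random.default_rng(msa_seeds[-1])

    filtered = []
    for name, aln in zip(names, alignments):
        try:
            faln, rep = filter_alignment(aln, **filter_kwargs)
        except Exception as exc:  # noqa: BLE001 - skip unusable MSAs
            logger.warning("skipping %s: %s", name, exc)
            continue
        if not rep.depth_ok:
            logger.warning("skipping %s: insufficient depth", name)
            continue
        filtered.append((name, faln))
    if not filtered:
        raise ValueError("no MSA in the corpus survives pre-processing")

    dcm = None
    for it in range(iterations):
        signal, null = [], []
        for (name, faln), ss in zip(filtered, msa_seeds):
            rng = np.random.default_rng(ss)
            if it == 0 or dcm is None:
                table = all_pair_scores(faln, metric="U")
                score_kwargs = {}
            else:
                table = all_pair_scores(faln, metric="UD", dcm=dcm, alpha=1.0)
                score_kwargs = {"dcm": dcm, "alpha": 1.0}
            result = sig.analyze(
                faln,
                table,
                target_fdr=fdr,
                seed=int(rng.integers(2**31)),
                **significance_kwargs,
                **score_kwargs,
            )
            sig_pairs = sorted(result.significant_pairs)
            signal.extend((faln, i, j) for i, j in sig_pairs)
            candidates = [p for p in table.entries if p not in result.significant_pairs]
            n_null = min(len(candidates), max(len(sig_pairs), null_min))
            if n_null:
                chosen = rng.choice(len(candidates), size=n_null, replace=False)
                null.extend((faln, *candidates[c]) for c in sorted(chosen))
        if not signal:
            raise ValueError("no significant pairs anywhere in the corpus")
        c_alt = count_pair_substitutions(signal, max_rows=max_rows, rng=count_rng)
        c_alt.role = "C_alt"
        c_null = count_pair_substitutions(null, max_rows=max_rows, rng=count_rng)
        c_null.role = "C_null"
        c_sig = phase2_signal_counts(c_alt, c_null)
        _, p_compmut = phase3_compmut(c_sig)
        s_compmut = phase4_log_odds(p_compmut)
        dcm = phase5_sinkhorn(s_compmut, tol=sinkhorn_tol, max_iter=sinkhorn_max_iter)

    dcm.provenance = {
        "kind": "trained",
        "corpus_hash": _corpus_hash(filtered),
        "seed": seed,
        "fdr": fdr,
        "n_msas": len(filtered),
        "iterations": iterations,
    }
    return dcm


def _corpus_hash(filtered) -> str:
    h = hashlib.sha256()
    for name, aln in filtered:
        h.update(name.encode())
        for row in aln.rows:
            h.update(row.encode())
    return h.hexdigest()[:16]


# ---------------------------------------------------------------------------
# Persistence
# ---------------------------------------------------------------------------

_PAIR_CONVENTION = "index = 20*idx(a) + idx(b), alphabetical order"


def write_dcm(d: DoublyStochasticMatrix, path) -> None:
    """Write a doubly stochastic matrix as headered whitespace TSV.

    Header lines are ``# key=value``; values use full repr precision so that
    write -> read round-trips exactly.
    """
    with open(path, "w") as fh:
        fh.write(f"# alphabet={AMINO_ACIDS}\n")
        fh.write(f"# pair_index={_PAIR_CONVENTION}\n")
        fh.write(f"# tolerance={d.tolerance!r}\n")
        for key, value in sorted(d.provenance.items()):
            fh.write(f"# {key}={value}\n")
        for row in d.values:
            fh.write(" ".join(np.format_float_scientific(x, unique=True) for x in row))
            fh.write("\n")


def read_dcm(path) -> DoublyStochasticMatrix:
    header, rows = {}, []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                key, _, value = line[1:].strip().partition("=")
                header[key.strip()] = value.strip()
            else:
                rows.append([float(x) for x in line.split()])
    if header.get("alphabet") not in (None, AMINO_ACIDS):
        raise ValueError("matrix file uses an unexpected residue alphabet")
    values = np.asarray(rows, dtype=float)
    if values.shape != (N_STATES, N_STATES):
        raise ValueError(
            f"matrix file has shape {values.shape}, expected (400, 400)"
        )
    tolerance = float(header.get("tolerance", 1e-8))
    provenance = {
        k: v
        for k, v in header.items()
        if k not in ("alphabet", "pair_index", "tolerance")
    }
    return DoublyStochasticMatrix(
        values=values, tolerance=tolerance, provenance=provenance
    ).validate()
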