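"""Seeded synthetic alignments with known coevolving column pairs.

The generator emulates the three ingredients a coupling detector has to
separate: independent background columns, genuinely coupled column pairs,
and phylogenetic redundancy (rows that are near-copies of other rows).

Background columns use a consensus-mixture model: each column draws a
consensus residue from the background frequency vector, and each ancestral
sequence carries the consensus with probability ``1 - divergence`` and an
independent draw from the background otherwise.  This keeps columns mutually
independent while giving sequences a realistic pairwise identity (about 39%
at the default divergence of 0.40), so that generated alignments survive the
20-90% identity filter.  A planted coupled pair (i, j, rho, state_set)
replaces the two column values jointly, with probability ``rho``, by a
pair-state drawn uniformly from ``state_set``.

Phylogenetic redundancy is modelled by duplication: a fraction of rows are
copies of earlier rows with independent per-site point mutations.  Gaps are
injected uniformly at a small rate; the reference row (first) stays
gap-free so every column keeps a reference residue number.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .msa_io import AMINO_ACIDS, AA_INDEX, Alignment, write_msa

_UNIFORM = np.full(20, 1 / 20)


@dataclass
class CoupledPair:
    """A planted coevolving column pair."""

    col_i: int
    col_j: int
    rho: float  # coupling strength in [0, 1]
    state_set: list  # [(aa, aa), ...] joint pair states


@dataclass
class SyntheticSpec:
    """Study conditions for one synthetic alignment."""

    n_seqs: int = 150
    n_cols: int = 120
    coupled_pairs: list = field(default_factory=list)
    background: np.ndarray = None  # 20-vector, default uniform
    divergence: float = 0.40  # per-site non-consensus probability
    duplication_rate: float = 0.15
    point_mutation_rate: float = 0.12
    gap_rate: float = 0.01
    seed: int = 0

    def __post_init__(self):
        if self.background is None:
            self.background = _UNIFORM.copy()
        self.background = np.asarray(self.background, dtype=float)
        if self.background.shape != (20,) or abs(self.background.sum() - 1) > 1e-9:
            raise ValueError("background must be a 20-vector summing to 1")
        used = set()
        for cp in self.coupled_pairs:
            if not isinstance(cp, CoupledPair):
                raise TypeError("coupled_pairs must contain CoupledPair items")
            if cp.col_i == cp.col_j:
                raise ValueError("coupled columns must be distinct")
            for c in (cp.col_i, cp.col_j):
                if not (0 <= c < self.n_cols):
                    raise ValueError(f"coupled column {c} out of range")
                if c in used:
                    raise ValueError(f"column {c} used by more than one coupled pair")
                used.add(c)
            if not (0 <= cp.rho <= 1):
                raise ValueError("coupling strength rho must lie in [0, 1]")
            if not cp.state_set:
                raise ValueError("state_set must be non-empty")
            for a, b in cp.state_set:
                if a not in AA_INDEX or b not in AA_INDEX:
                    raise ValueError(f"non-standard residue in state ({a}, {b})")


def blosum62_background() -> np.ndarray:
    """Residue frequencies matching the BLOSUM62 marginal (a rough preset
    of natural amino-acid abundances)."""
    from .dcm import _blosum62_array  # local import to avoid a hard cycle

    # Marginal of the implied target frequencies ~ softmax of row scores;
    # a simple robust proxy: normalized exp(score/2) diagonal weighting.
    diag = np.exp(np.diag(_blosum62_array()) / -2.0)
    return diag / diag.sum()


@dataclass
class GroundTruth:
    """What was planted where."""

    coupled_pairs: set  # {(col_i, col_j)} with i < j, original coordinates
    column_family: dict  # col -> "background" | "coupled"
    duplicated_from: dict  # row index -> parent row index


def generate_msa(spec: SyntheticSpec):
    """Generate one alignment and its ground truth, reproducibly from
    ``spec.seed``."""
    rng = np.random.default_rng(spec.seed)
    n_dup = int(round(spec.duplication_rate * spec.n_seqs))
    n_base = spec.n_seqs - n_dup
    if n_base < 2:
        raise ValueError("duplication_rate leaves fewer than 2 ancestral rows")

    coupled_cols = {}
    for cp in spec.coupled_pairs:
        coupled_cols[cp.col_i] = cp
        coupled_cols[cp.col_j] = cp

    codes = np.empty((spec.n_seqs, spec.n_cols), dtype=np.int16)

    # Ancestral rows, column by column.
    consensus = rng.choice(20, size=spec.n_cols, p=spec.background)
    for c in range(spec.n_cols):
        if c in coupled_cols:
            continue
        noise = rng.random(n_base) < spec.divergence
        col = np.full(n_base, consensus[c], dtype=np.int16)
        col[noise] = rng.choice(20, size=int(noise.sum()), p=spec.background)
        codes[:n_base, c] = col
    for cp in spec.coupled_pairs:
        states = np.array(
            [[AA_INDEX[a], AA_INDEX[b]] for a, b in cp.state_set], dtype=np.int16
        )
        joint = rng.random(n_base) < cp.rho
        pick = rng.integers(len(cp.state_set), size=n_base)
        for c, k in ((cp.col_i, 0), (cp.col_j, 1)):
            noise = rng.random(n_base) < spec.divergence
            col = np.full(n_base, consensus[c], dtype=np.int16)
            col[noise] = rng.choice(20, size=int(noise.sum()), p=spec.background)
            col[joint] = states[pick[joint], k]
            codes[:n_base, c] = col

    # Duplicated rows: copy an earlier row and add point mutations.
    duplicated_from = {}
    for r in range(n_base, spec.n_seqs):
        parent = int(rng.integers(r))
        duplicated_from[r] = parent
        row = codes[parent].copy()
        hits = rng.random(spec.n_cols) < spec.point_mutation_rate
        row[hits] = rng.choice(20, size=int(hits.sum()), p=spec.background)
        codes[r] = row

    # Gaps (code -1); the reference row stays gap-free.
    if spec.gap_rate > 0:
        gaps = rng.random(codes.shape) < spec.gap_rate
        gaps[0] = False
        codes[gaps] = -1

    rows = ["".join(AMINO_ACIDS[x] if x >= 0 else "-" for x in row) for row in codes]
    ids = ["ref"] + [f"seq{k:04d}" for k in range(1, spec.n_seqs)]
    aln = Alignment(ids=ids, rows=rows)
    truth = GroundTruth(
        coupled_pairs={
            (min(cp.col_i, cp.col_j), max(cp.col_i, cp.col_j))
            for cp in spec.coupled_pairs
        },
        column_family={
            c: ("coupled" if c in coupled_cols else "background")
            for c in range(spec.n_cols)
        },
        duplicated_from=duplicated_from,
    )
    return aln, truth


def random_coupled_pairs(
    n_pairs: int,
    n_cols: int,
    rho: float,
    rng,
    state_sets=None,
) -> list:
    """Place ``n_pairs`` coupled pairs on distinct random columns.

    ``state_sets`` is a list to cycle through (default:
    :data:`DEFAULT_STATE_SETS`, four-state compensatory alphabets whose
    column entropies are comparable to background columns).
    """
    if state_sets is None:
        state_sets = DEFAULT_STATE_SETS
    cols = rng.choice(n_cols, size=2 * n_pairs, replace=False)
    out = []
    for k in range(n_pairs):
        out.append(
            CoupledPair(
                col_i=int(cols[2 * k]),
                col_j=int(cols[2 * k + 1]),
                rho=rho,
                state_set=state_sets[k % len(state_sets)],
            )
        )
    return out


#: Default planted alphabets: four pair-states per coupled pair (two
#: compensatory exchange classes).  A real coevolving site pair admits
#: several residue combinations, so its columns have entropies comparable to
#: other non-conserved columns; a two-state toggle would make the planted
#: columns much lower-entropy than the background and distort the MSA-wide
#: score distribution that the null model is fitted to.
DEFAULT_STATE_SETS = [
    [("D", "R"), ("R", "D"), ("E", "K"), ("K", "E")],
    [("G", "G"), ("F", "F"), ("S", "S"), ("W", "W")],
    [("K", "W"), ("W", "K"), ("R", "F"), ("F", "R")],
    [("P", "N"), ("N", "P"), ("A", "Q"), ("Q", "A")],
]

#: Couplings in which every exchange between two states is a formal
#: dissimilar compensatory mutation: at each position the four residues come
#: from a group that is pairwise BLOSUM62-negative ({D,G,W,P}, {K,C,F,D},
#: {E,W,G,C}, {N,F,P,A}), so all 12 ordered within-set transitions have both
#: positional scores < 0.  Four states keep the planted columns
#: entropy-matched to background columns.
DISSIMILAR_STATE_SETS = [
    [("D", "W"), ("G", "P"), ("W", "D"), ("P", "G")],
    [("K", "D"), ("C", "F"), ("F", "C"), ("D", "K")],
    [("E", "C"), ("W", "G"), ("G", "W"), ("C", "E")],
    [("N", "A"), ("F", "P"), ("P", "F"), ("A", "N")],
]

#: Control couplings in which every exchange is BLOSUM62-similar (both
#: positional scores >= 0; residue groups {I,L,V,M}, {K,R,Q,E}, {D,E,N,Q})
#: -- covariation signal that is free of dissimilar compensatory exchanges.
SIMILAR_STATE_SETS = [
    [("I", "K"), ("L", "R"), ("V", "Q"), ("M", "E")],
    [("K", "I"), ("R", "L"), ("Q", "V"), ("E", "M")],
    [("D", "Q"), ("E", "N"), ("N", "E"), ("Q", "D")],
    [("M", "D"), ("V", "E"), ("L", "N"), ("I", "Q")],
]


def generate_corpus(
    n_msas: int,
    spec_template: SyntheticSpec,
    seed: int = 0,
    out_dir=None,
    n_coupled: int = 8,
    rho: float = 0.9,
    state_sets=None,
):
    """Generate a family of MSAs with varied coupled-pair placements.

    Returns ``(alignments, truths)``; when ``out_dir`` is given the MSAs are
    also written as FASTA together with a ``truth.tsv`` manifest mapping each
    file to its planted pairs.
    """
    if n_msas < 1:
        raise ValueError("need at least one MSA")
    root = np.random.default_rng(seed)
    alignments, truths, names = [], [], []
    for k in range(n_msas):
        msa_seed = int(root.integers(2**31))
        place_rng = np.random.default_rng(msa_seed)
        pairs = random_coupled_pairs(
            n_coupled, spec_template.n_cols, rho, place_rng, state_sets=state_sets
        )
        spec = SyntheticSpec(
            n_seqs=spec_template.n_seqs,
            n_cols=spec_template.n_cols,
            coupled_pairs=pairs,
            background=spec_template.background.copy(),
            divergence=spec_template.divergence,
            duplication_rate=spec_template.duplication_rate,
            point_mutation_rate=spec_template.point_mutation_rate,
            gap_rate=spec_template.gap_rate,
            seed=msa_seed,
        )
        aln, truth = generate_msa(spec)
        alignments.append(aln)
        truths.append(truth)
        names.append(f"msa{k:03d}.fasta")
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        for name, aln in zip(names, alignments):
            write_msa(aln, out_dir / name)
        with open(out_dir / "truth.tsv", "w") as fh:
            fh.write("file\tcol_i\tcol_j\n")
            for name, truth in zip(names, truths):
                for i, j in sorted(truth.coupled_pairs):
                    fh.write(f"{name}\t{i}\t{j}\n")
    return alignments, truths
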