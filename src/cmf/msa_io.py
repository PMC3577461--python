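"""Reading, writing and pre-processing of protein multiple sequence alignments.

An alignment enters the pipeline as plain multiple-FASTA (aligned rows, gap
character ``-``).  Before any coupling statistic is computed it passes a
four-stage filter: redundant / unrelated sequences are removed so that every
kept pair of sequences has an identity within a target band, near-invariant
columns and gap-rich columns are discarded, and the remaining depth is checked
against a minimum.  Coordinate maps (original column index and 1-based residue
number in the ungapped reference sequence) are maintained through every stage
so that results can always be reported in reference coordinates.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

#: The 20 standard amino acids in alphabetical one-letter order.  This order
#: fixes the 400-state pair-space indexing used throughout the package.
AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
AA_INDEX = {aa: i for i, aa in enumerate(AMINO_ACIDS)}
GAP = "-"

# Ambiguity / non-standard codes are outside the 20-letter alphabet that the
# 400-state pair space is built on; they are treated as gaps everywhere.
_NON_STANDARD = set("BZXUOJ*.")


class AlignmentError(ValueError):
    """Raised for malformed or inconsistent alignments."""


class InsufficientDepthError(AlignmentError):
    """Raised in strict mode when a filtered MSA has too few sequences."""


def _normalize_row(seq: str) -> str:
    out = []
    for ch in seq.upper():
        if ch in AA_INDEX or ch == GAP:
            out.append(ch)
        elif ch in _NON_STANDARD:
            out.append(GAP)
        else:
            raise AlignmentError(f"unrecognized residue code {ch!r}")
    return "".join(out)


@dataclass
class Alignment:
    """A rectangular protein alignment with coordinate bookkeeping.

    Attributes
    ----------
    ids : list of str
        Unique sequence identifiers, in file order.
    rows : list of str
        Aligned sequences over the 20 standard residues plus ``-``.
    ref_index : int
        Row index of the reference sequence (default: first record).
    col_map : list of int
        For each retained column, its 0-based index in the original alignment.
    ref_residue : list of int or None
        For each retained column, the 1-based residue number in the ungapped
        reference sequence, or ``None`` where the reference is gapped.
    """

    ids: list
    rows: list
    ref_index: int = 0
    col_map: list = field(default=None)
    ref_residue: list = field(default=None)

    def __post_init__(self):
        if not self.rows:
            raise AlignmentError("alignment has no sequences")
        length = len(self.rows[0])
        if length < 1:
            raise AlignmentError("alignment has zero columns")
        if any(len(r) != length for r in self.rows):
            raise AlignmentError("not aligned: rows have unequal lengths")
        if len(set(self.ids)) != len(self.ids):
            raise AlignmentError("sequence identifiers are not unique")
        if not (0 <= self.ref_index < len(self.rows)):
            raise AlignmentError("ref_index out of range")
        if self.col_map is None:
            self.col_map = list(range(length))
        if self.ref_residue is None:
            self.ref_residue = _reference_numbering(self.rows[self.ref_index])
        self._codes = None

    @property
    def n_seqs(self) -> int:
        return len(self.rows)

    @property
    def n_cols(self) -> int:
        return len(self.rows[0])

    def codes(self) -> np.ndarray:
        """Integer encoding, shape (n_seqs, n_cols); residues 0..19, gap -1."""
        if self._codes is None:
            lut = np.full(128, -1, dtype=np.int16)
            for aa, i in AA_INDEX.items():
                lut[ord(aa)] = i
            mat = np.frombuffer(
                "".join(self.rows).encode("ascii"), dtype=np.uint8
            ).reshape(self.n_seqs, self.n_cols)
            self._codes = lut[mat]
        return self._codes


def _reference_numbering(ref_row: str) -> list:
    numbering, res = [], 0
    for ch in ref_row:
        if ch == GAP:
            numbering.append(None)
        else:
            res += 1
            numbering.append(res)
    return numbering


@dataclass
class FilterReport:
    """Record of everything removed by :func:`filter_alignment`."""

    removed_sequences: list = field(default_factory=list)  # (id, reason, stat)
    removed_columns: list = field(default_factory=list)  # (orig_idx, reason, stat)
    depth_ok: bool = True
    n_kept_sequences: int = 0
    n_kept_columns: int = 0
    thresholds: dict = field(default_factory=dict)

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("item\treason\tstatistic\n")
            for sid, reason, stat in self.removed_sequences:
                fh.write(f"{sid}\t{reason}\t{stat:.4f}\n")
            for col, reason, stat in self.removed_columns:
                fh.write(f"col:{col}\t{reason}\t{stat:.4f}\n")


def read_msa(path) -> Alignment:
    """Read a multiple-FASTA alignment.

    Rows are upper-cased and non-standard residue codes (B, Z, X, U, O, J, *)
    are mapped to gaps.  Raises :class:`AlignmentError` for an empty file or
    rows of unequal length.
    """
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise AlignmentError(f"{path}: no FASTA records found")
    ids = [r.id for r in records]
    rows = [_normalize_row(str(r.seq)) for r in records]
    return Alignment(ids=ids, rows=rows)


def write_msa(aln: Alignment, path) -> None:
    records = [
        SeqRecord(Seq(row), id=sid, description="")
        for sid, row in zip(aln.ids, aln.rows)
    ]
    SeqIO.write(records, str(path), "fasta")


def pairwise_identity(a, b) -> float:
    """Fraction of identical residues among columns where neither has a gap.

    Returns 0.0 when no gap-free shared column exists.
    """
    if isinstance(a, str):
        if len(a) != len(b):
            raise AlignmentError("sequences have unequal lengths")
        pairs = [(x, y) for x, y in zip(a, b) if x != GAP and y != GAP]
        if not pairs:
            return 0.0
        return sum(x == y for x, y in pairs) / len(pairs)
    # integer-coded fast path
    if a.shape != b.shape:
        raise AlignmentError("sequences have unequal lengths")
    mask = (a >= 0) & (b >= 0)
    n = int(mask.sum())
    if n == 0:
        return 0.0
    return float((a[mask] == b[mask]).sum()) / n


def filter_alignment(
    msa: Alignment,
    min_id: float = 0.20,
    max_id: float = 0.90,
    max_cons: float = 0.95,
    max_gap: float = 0.25,
    min_depth: int = 125,
    strict_depth: bool = False,
):
    """Apply the four pre-processing filters, in order.

    1. Greedy sequence filtering (file order, reference first and never
       dropped): a sequence is removed if its identity to any already-kept
       sequence exceeds ``max_id`` (too-similar) or falls below ``min_id``
       (too-dissimilar).  Every kept pair therefore has identity in
       [min_id, max_id].
    2. Columns whose most frequent residue exceeds ``max_cons`` of the
       non-gap rows are removed (conserved).
    3. Columns with a gap fraction above ``max_gap`` are removed (gapped).
    4. If fewer than ``min_depth`` sequences remain the report flags
       ``depth_ok=False`` (an error when ``strict_depth``).

    Returns ``(filtered_alignment, FilterReport)``.
    """
    report = FilterReport(
        thresholds=dict(
            min_id=min_id,
            max_id=max_id,
            max_cons=max_cons,
            max_gap=max_gap,
            min_depth=min_depth,
        )
    )
    codes = msa.codes()

    # --- sequences -------------------------------------------------------
    order = [msa.ref_index] + [i for i in range(msa.n_seqs) if i != msa.ref_index]
    kept: list = []
    for idx in order:
        if idx == msa.ref_index:
            kept.append(idx)
            continue
        row = codes[idx]
        verdict = None
        for k in kept:
            ident = pairwise_identity(row, codes[k])
            if ident > max_id:
                verdict = ("too-similar", ident)
                break
            if ident < min_id:
                verdict = ("too-dissimilar", ident)
                break
        if verdict is None:
            kept.append(idx)
        else:
            report.removed_sequences.append((msa.ids[idx], *verdict))
    kept.sort()
    sub = codes[kept]

    # --- conserved columns ----------------------------------------------
    n_rows = sub.shape[0]
    kept_cols = []
    for c in range(msa.n_cols):
        col = sub[:, c]
        residues = col[col >= 0]
        if residues.size > 0:
            top = np.bincount(residues, minlength=20).max()
            frac = top / residues.size
            if frac > max_cons:
                report.removed_columns.append((msa.col_map[c], "conserved", frac))
                continue
        kept_cols.append(c)

    # --- gapped columns --------------------------------------------------
    final_cols = []
    for c in kept_cols:
        gap_frac = float((sub[:, c] < 0).sum()) / n_rows
        if gap_frac > max_gap:
            report.removed_columns.append((msa.col_map[c], "gapped", gap_frac))
        else:
            final_cols.append(c)

    # --- depth -----------------------------------------------------------
    report.depth_ok = len(kept) >= min_depth
    if not report.depth_ok and strict_depth:
        raise InsufficientDepthError(
            f"insufficient depth: {len(kept)} sequences after filtering "
            f"(minimum {min_depth})"
        )

    if not final_cols:
        raise AlignmentError("no columns survive filtering")

    new_ref = kept.index(msa.ref_index)
    filtered = Alignment(
        ids=[msa.ids[i] for i in kept],
        rows=["".join(msa.rows[i][c] for c in final_cols) for i in kept],
        ref_index=new_ref,
        col_map=[msa.col_map[c] for c in final_cols],
        ref_residue=[msa.ref_residue[c] for c in final_cols],
    )
    report.n_kept_sequences = len(kept)
    report.n_kept_columns = len(final_cols)
    return filtered, report
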