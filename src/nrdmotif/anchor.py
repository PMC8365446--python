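"""Apical-loop anchoring and motif extraction.

The phosphate-binding site of a ribonucleotide reductase comprises two
loops; the *apical* loop carries the 4–5 residue motif (e.g. P-N-S-P vs
P-A-G-R) that determines whether the enzyme reduces ribonucleoside
di- or triphosphates.  This module locates that loop in a query protein
by global alignment to an annotated reference sequence and extracts the
motif, or reads it straight out of designated columns of a multiple
sequence alignment.

Coordinates are 1-based and spans are inclusive throughout, matching the
residue-numbering convention of the mutagenesis literature (e.g. "G68").
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from Bio import SeqIO
from Bio.Align import PairwiseAligner, substitution_matrices
from sklearn.base import BaseEstimator, TransformerMixin

__all__ = [
    "ReferenceAnchor",
    "MotifCall",
    "AlignmentResult",
    "global_align",
    "extract_motif_pairwise",
    "extract_motif_msa",
    "PairwiseMotifExtractor",
    "MsaMotifExtractor",
    "read_fasta",
    "motif_calls_to_frame",
]

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
_ALLOWED = set(AMINO_ACIDS) | {"X"}

GAP_CHARS = frozenset("-.")

#: default affine-gap penalties (BLAST protein defaults)
DEFAULT_GAP_OPEN = 11.0
DEFAULT_GAP_EXTEND = 1.0

#: alignments scoring below this fraction of the reference self-score are
#: reported as UNMAPPED rather than trusted for motif extraction
DEFAULT_SCORE_FLOOR = 0.25


def _blosum62_x_neutral():
    """BLOSUM62 with the ambiguity residue X scored 0 against everything."""
    m = substitution_matrices.load("BLOSUM62")
    for a in m.alphabet:
        m["X", a] = 0.0
        m[a, "X"] = 0.0
    return m


_MATRIX = _blosum62_x_neutral()


def _validate_protein(seq: str, name: str) -> str:
    seq = str(seq).upper()
    if not seq:
        raise ValueError(f"{name}: empty sequence")
    for i, c in enumerate(seq):
        if c not in _ALLOWED:
            raise ValueError(
                f"{name}: illegal residue {c!r} at position {i + 1} "
                f"(allowed: 20 amino acids + X)"
            )
    return seq


@dataclass(frozen=True)
class ReferenceAnchor:
    """An annotated reference sequence fixing the loop coordinate system.

    Parameters
    ----------
    reference_id : str
        Identifier of the reference enzyme.
    sequence : str
        Amino-acid sequence (20-letter alphabet, X tolerated).
    apical_span : tuple[int, int]
        1-based inclusive residue interval of the apical loop; length 4 or 5.
    distal_span : tuple[int, int]
        1-based inclusive interval of the distal loop.  Carried as
        annotation only: the distal loop is conserved across phosphate
        specificities and plays no part in classification.
    """

    reference_id: str
    sequence: str
    apical_span: tuple[int, int]
    distal_span: tuple[int, int]

    def __post_init__(self):
        object.__setattr__(
            self, "sequence", _validate_protein(self.sequence, "reference")
        )
        n = len(self.sequence)
        for nm, (lo, hi) in (("apical_span", self.apical_span),
                             ("distal_span", self.distal_span)):
            if not (1 <= lo <= hi <= n):
                raise ValueError(f"{nm} {lo}:{hi} outside sequence of length {n}")
        alen = self.apical_span[1] - self.apical_span[0] + 1
        if alen not in (4, 5):
            raise ValueError(f"apical span length must be 4 or 5, got {alen}")
        a, d = sorted([self.apical_span, self.distal_span])
        if a[1] >= d[0]:
            raise ValueError("apical and distal spans overlap")

    @property
    def apical_motif(self) -> str:
        lo, hi = self.apical_span
        return self.sequence[lo - 1:hi]


@dataclass(frozen=True)
class MotifCall:
    """Result of extracting the apical-loop motif from one query.

    ``coverage_flag`` is FULL when every span column aligned to a query
    residue, PARTIAL when some column aligned to a gap, and UNMAPPED when
    the query could not be anchored at all (score below the floor).
    """

    query_id: str
    motif: str
    query_span: tuple[int, int] | None = None
    alignment_score: float | None = None
    coverage_flag: str = "FULL"

    def __post_init__(self):
        if self.coverage_flag not in ("FULL", "PARTIAL", "UNMAPPED"):
            raise ValueError(f"bad coverage flag {self.coverage_flag!r}")
        if self.coverage_flag == "UNMAPPED" and self.motif:
            raise ValueError("UNMAPPED call must carry an empty motif")


@dataclass(frozen=True)
class AlignmentResult:
    aligned_a: str
    aligned_b: str
    score: float


def _make_aligner(gap_open: float, gap_extend: float) -> PairwiseAligner:
    aligner = PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = _MATRIX
    # a gap of length L costs gap_open + (L - 1) * gap_extend
    aligner.open_gap_score = -float(gap_open)
    aligner.extend_gap_score = -float(gap_extend)
    return aligner


def global_align(
    a: str,
    b: str,
    gap_open: float = DEFAULT_GAP_OPEN,
    gap_extend: float = DEFAULT_GAP_EXTEND,
) -> AlignmentResult:
    """Optimal global alignment of two protein sequences.

    Needleman–Wunsch with affine gaps under BLOSUM62 (X scored 0).  The
    score is the dynamic-programming optimum; among co-optimal tracebacks
    the first alignment reported by the engine is returned, which is
    deterministic for fixed inputs.
    """
    a = _validate_protein(a, "sequence a")
    b = _validate_protein(b, "sequence b")
    aligner = _make_aligner(gap_open, gap_extend)
    aln = aligner.align(a, b)[0]
    return AlignmentResult(aligned_a=str(aln[0]), aligned_b=str(aln[1]),
                           score=float(aln.score))


def _reference_self_score(ref: ReferenceAnchor) -> float:
    return float(sum(_MATRIX[c, c] for c in ref.sequence))


def extract_motif_pairwise(
    query: str,
    ref: ReferenceAnchor,
    query_id: str = "query",
    gap_open: float = DEFAULT_GAP_OPEN,
    gap_extend: float = DEFAULT_GAP_EXTEND,
    score_floor: float = DEFAULT_SCORE_FLOOR,
) -> MotifCall:
    """Anchor ``query`` to the reference and extract its apical-loop motif.

    The query is globally aligned to the reference; the motif is read from
    the loop window — all query residues in alignment columns strictly
    between the reference residues flanking the apical span.  That window
    equals the span columns when the alignment is gapless there, and
    additionally captures residues inserted within the loop, which is how a
    5-residue P-Q-G-S-P maps onto a 4-residue reference span regardless of
    which side of the span the aligner attaches the insertion column to.

    Queries whose alignment score falls below ``score_floor`` times the
    reference self-score are reported UNMAPPED with an empty motif.
    """
    query = _validate_protein(query, f"query {query_id}")
    aligner = _make_aligner(gap_open, gap_extend)
    aln = aligner.align(ref.sequence, query)[0]
    score = float(aln.score)
    if score < score_floor * _reference_self_score(ref):
        return MotifCall(query_id=query_id, motif="", query_span=None,
                         alignment_score=score, coverage_flag="UNMAPPED")

    lo, hi = ref.apical_span  # 1-based inclusive
    inv_ref = aln.inverse_indices[0]   # residue index -> alignment column
    col_q = aln.indices[1]             # alignment column -> query index or -1
    n_cols = col_q.shape[0]

    # loop window: open interval between the flanking reference residues
    left = inv_ref[lo - 2] + 1 if lo >= 2 else 0
    right = inv_ref[hi] - 1 if hi < len(ref.sequence) else n_cols - 1

    q_idx = [int(col_q[c]) for c in range(left, right + 1) if col_q[c] >= 0]
    motif = "".join(query[i] for i in q_idx)

    span_cols = [int(inv_ref[p - 1]) for p in range(lo, hi + 1)]
    partial = any(col_q[c] < 0 for c in span_cols)
    flag = "PARTIAL" if partial else "FULL"
    qspan = (q_idx[0] + 1, q_idx[-1] + 1) if q_idx else None
    if not q_idx:
        flag = "PARTIAL"
    return MotifCall(query_id=query_id, motif=motif, query_span=qspan,
                     alignment_score=score, coverage_flag=flag)


def extract_motif_msa(
    msa: Sequence[tuple[str, str]],
    apical_columns: Sequence[int],
) -> list[MotifCall]:
    """Read apical-loop motifs straight out of designated MSA columns.

    Parameters
    ----------
    msa : sequence of (id, aligned sequence) pairs
        All rows must have equal aligned length.
    apical_columns : sequence of int
        1-based alignment-column indices of the loop positions.

    Per sequence, the characters at the designated columns are taken and
    gap characters removed; calls with any gapped designated column are
    flagged PARTIAL.
    """
    rows = [(str(i), str(s).upper()) for i, s in msa]
    if not rows:
        return []
    width = len(rows[0][1])
    for rid, seq in rows:
        if len(seq) != width:
            raise ValueError(
                f"ragged alignment: row {rid!r} has length {len(seq)}, "
                f"expected {width}"
            )
    cols = [int(c) for c in apical_columns]
    for c in cols:
        if not (1 <= c <= width):
            raise ValueError(f"column {c} outside alignment of width {width}")

    calls = []
    for rid, seq in rows:
        chars = [seq[c - 1] for c in cols]
        motif = "".join(ch for ch in chars if ch not in GAP_CHARS)
        partial = any(ch in GAP_CHARS for ch in chars)
        calls.append(MotifCall(
            query_id=rid, motif=motif, query_span=None, alignment_score=None,
            coverage_flag="PARTIAL" if partial else "FULL"))
    return calls


class PairwiseMotifExtractor(BaseEstimator, TransformerMixin):
    """Transformer extracting apical-loop motifs by pairwise anchoring.

    Parameters
    ----------
    reference : ReferenceAnchor
    gap_open, gap_extend : float
        Affine gap penalties (positive costs).
    score_floor : float
        Fraction of the reference self-score below which a query is
        reported UNMAPPED.
    """

    def __init__(self, reference: ReferenceAnchor,
                 gap_open: float = DEFAULT_GAP_OPEN,
                 gap_extend: float = DEFAULT_GAP_EXTEND,
                 score_floor: float = DEFAULT_SCORE_FLOOR):
        self.reference = reference
        self.gap_open = gap_open
        self.gap_extend = gap_extend
        self.score_floor = score_floor

    def fit(self, X=None, y=None):
        self.reference_self_score_ = _reference_self_score(self.reference)
        return self

    def transform(self, X: Iterable) -> list[MotifCall]:
        """Extract one :class:`MotifCall` per input sequence.

        ``X`` is an iterable of ``(id, sequence)`` pairs, Biopython
        ``SeqRecord`` objects, or bare sequences (ids auto-numbered).
        """
        calls = []
        for k, item in enumerate(X):
            if hasattr(item, "seq"):
                sid, seq = item.id, str(item.seq)
            elif isinstance(item, str):
                sid, seq = f"seq{k}", item
            else:
                sid, seq = item
            calls.append(extract_motif_pairwise(
                seq, self.reference, query_id=str(sid),
                gap_open=self.gap_open, gap_extend=self.gap_extend,
                score_floor=self.score_floor))
        return calls


class MsaMotifExtractor(BaseEstimator, TransformerMixin):
    """Transformer reading motifs from fixed MSA columns."""

    def __init__(self, apical_columns: Sequence[int]):
        self.apical_columns = apical_columns

    def fit(self, X=None, y=None):
        return self

    def transform(self, X) -> list[MotifCall]:
        rows = []
        for k, item in enumerate(X):
            if hasattr(item, "seq"):
                rows.append((item.id, str(item.seq)))
            elif isinstance(item, str):
                rows.append((f"seq{k}", item))
            else:
                rows.append(item)
        return extract_motif_msa(rows, self.apical_columns)


def read_fasta(path) -> list[tuple[str, str]]:
    """Read a (possibly aligned) FASTA file into (id, sequence) pairs."""
    return [(rec.id, str(rec.seq)) for rec in SeqIO.parse(str(path), "fasta")]


def motif_calls_to_frame(calls: Sequence[MotifCall]):
    """Tabulate motif calls (query_id, motif, start, end, flag, score)."""
    import pandas as pd

    return pd.DataFrame({
        "query_id": [c.query_id for c in calls],
        "motif": [c.motif for c in calls],
        "start": [c.query_span[0] if c.query_span else None for c in calls],
        "end": [c.query_span[1] if c.query_span else None for c in calls],
        "flag": [c.coverage_flag for c in calls],
        "score": [c.alignment_score for c in calls],
    })
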