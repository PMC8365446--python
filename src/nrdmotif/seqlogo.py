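"""Sequence-logo matrices: per-column residue frequencies and information
content for motif-class sub-alignments.

These are observed-frequency logos in the classic Shannon sense: for a
column with residue distribution *p*, the information content is
``IC = log2(20) - H(p)`` bits, partitioned into letter heights
``h_a = p_a * IC * occupancy``.  Gaps reduce the column's occupancy
(the WebLogo convention) rather than acting as a 21st symbol, and an
optional uniform pseudocount regularises sparse columns.  No
posterior/profile-HMM letter weighting is applied.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np

from .anchor import AMINO_ACIDS, GAP_CHARS

__all__ = [
    "MAX_IC_BITS",
    "LogoColumn",
    "LogoMatrix",
    "column_frequencies",
    "information_content",
    "build_logo",
]

#: maximum per-column information content for a 20-letter alphabet
MAX_IC_BITS = math.log2(20)


def column_frequencies(
    msa: Sequence[str],
    column: int,
    pseudocount: float = 0.0,
) -> dict[str, float]:
    """Residue probability vector for one alignment column.

    Parameters
    ----------
    msa : sequence of aligned strings (equal length)
    column : int
        1-based column index.
    pseudocount : float
        Added uniformly to every residue count.  Gaps are excluded from
        the denominator.

    Returns a dict over the 20 amino acids summing to 1.
    """
    if not msa:
        raise ValueError("empty alignment")
    width = len(msa[0])
    if not (1 <= column <= width):
        raise ValueError(f"column {column} outside alignment of width {width}")
    counts = {a: float(pseudocount) for a in AMINO_ACIDS}
    n = 20.0 * pseudocount
    for row in msa:
        if len(row) != width:
            raise ValueError("ragged alignment")
        c = row[column - 1].upper()
        if c in GAP_CHARS:
            continue
        if c == "X":  # ambiguity: spread over all residues
            for a in AMINO_ACIDS:
                counts[a] += 1.0 / 20.0
            n += 1.0
            continue
        if c not in counts:
            raise ValueError(f"illegal residue {c!r} in column {column}")
        counts[c] += 1.0
        n += 1.0
    if n == 0:
        raise ValueError(
            f"column {column} is all gaps and pseudocount is 0; "
            "no distribution is defined"
        )
    return {a: counts[a] / n for a in AMINO_ACIDS}


def information_content(p: Mapping[str, float] | Sequence[float]) -> float:
    """Shannon information content of a residue distribution, in bits.

    ``IC = log2(20) - H(p)``, clipped at 0.  ``p`` must sum to 1.
    """
    if isinstance(p, Mapping):
        vec = np.asarray(list(p.values()), dtype=float)
    else:
        vec = np.asarray(p, dtype=float)
    if vec.size == 0 or not np.isclose(vec.sum(), 1.0, atol=1e-6):
        raise ValueError("probability vector must sum to 1")
    nz = vec[vec > 0]
    entropy = float(-(nz * np.log2(nz)).sum())
    return max(0.0, MAX_IC_BITS - entropy)


@dataclass(frozen=True)
class LogoColumn:
    column: int
    heights: dict[str, float]
    occupancy: float
    ic: float


@dataclass(frozen=True)
class LogoMatrix:
    """Per-column letter heights for a motif-class sub-alignment.

    Heights are in bits and sum to ``IC * occupancy`` per column.
    """

    columns: tuple[LogoColumn, ...]

    def to_frame(self):
        import pandas as pd

        rows = []
        for col in self.columns:
            row = {"column": col.column, "occupancy": col.occupancy,
                   "ic_bits": col.ic}
            row.update({a: col.heights.get(a, 0.0) for a in AMINO_ACIDS})
            rows.append(row)
        return pd.DataFrame(rows)

    def as_dict(self) -> dict:
        return {
            "columns": [
                {"column": c.column, "occupancy": c.occupancy, "ic_bits": c.ic,
                 "heights": {a: h for a, h in c.heights.items() if h > 0}}
                for c in self.columns
            ]
        }


def build_logo(
    msa: Sequence[str] | Sequence[tuple[str, str]],
    columns: Iterable[int],
    pseudocount: float = 0.0,
    small_sample_correction: bool = False,
) -> LogoMatrix:
    """Build a logo matrix over the designated columns of a sub-alignment.

    ``msa`` holds aligned strings (or ``(id, string)`` pairs, ids
    ignored); rows are typically the subset of an alignment sharing one
    motif class.  ``small_sample_correction`` subtracts the standard
    ``(20-1) / (2 ln2 n)`` bias term from each column's IC (clipped at 0);
    it is off by default since class subsets here are large.
    """
    rows = [r[1] if isinstance(r, tuple) else r for r in msa]
    if not rows:
        raise ValueError("empty sub-alignment")
    out = []
    for col in columns:
        p = column_frequencies(rows, col, pseudocount=pseudocount)
        n_res = sum(1 for r in rows if r[col - 1].upper() not in GAP_CHARS)
        occupancy = n_res / len(rows)
        ic = information_content(p)
        if small_sample_correction and n_res > 0:
            ic = max(0.0, ic - 19.0 / (2.0 * math.log(2) * n_res))
        heights = {a: p[a] * ic * occupancy for a in AMINO_ACIDS if p[a] > 0}
        out.append(LogoColumn(column=int(col), heights=heights,
                              occupancy=occupancy, ic=ic))
    return LogoMatrix(columns=tuple(out))
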