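"""Cyclotide sequence analytics: cystine-loop decomposition,
Moebius/bracelet subtype assignment, identity-scored homology ranking
and frequency matrices for sequence logos.

Cyclotides carry six conserved cysteines; the residues between
consecutive cysteines form intercysteine loops 1-6, numbered from the
native ligation site onward (the sequence as written starts in loop 6,
immediately after the ligation Asn/Asp).  The Moebius subfamily carries
a cis-Pro in loop 5; bracelets do not.  At the sequence level the
presence of any Pro in loop 5 is the usable proxy — cis/trans geometry
is not inferable from sequence, and classification output carries that
caveat.

Pairwise homology is scored as the maximum number of identities in an
alignment with match 1, mismatch 0 and no gap penalties; with free gaps
this optimum equals the longest-common-subsequence (LCS) length,
computed here by dynamic programming.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import CyclopeptError

__all__ = [
    "LoopDecomposition",
    "HomologyHit",
    "SUBTYPE_CAVEAT",
    "loop_decompose",
    "classify_subtype",
    "identity_alignment_score",
    "rank_homologs",
    "frequency_matrix",
]

SUBTYPE_CAVEAT = (
    "sequence-level proxy: Pro presence in loop 5 stands in for the "
    "cis-Pro geometry, which cannot be read from sequence alone"
)


@dataclass(frozen=True)
class LoopDecomposition:
    """Six cysteine positions (1-based) and the six intercysteine loops.

    Loop i holds the residues strictly between Cys i and Cys i+1; loop 6
    wraps from Cys VI around the ligation site to Cys I.
    """

    sequence: str
    cys_positions: tuple[int, int, int, int, int, int]
    loops: dict[int, str]


def loop_decompose(cyclic_sequence: str) -> LoopDecomposition:
    """Decompose a cyclic six-Cys sequence into intercysteine loops.

    The sequence is taken as written per the cyclotide convention,
    beginning in loop 6 immediately after the ligation site, so the
    first cysteine encountered is Cys I.
    """
    seq = cyclic_sequence
    cys = [i for i, aa in enumerate(seq) if aa == "C"]
    if len(cys) != 6:
        raise CyclopeptError(
            f"loop decomposition needs exactly 6 cysteines, found {len(cys)}"
        )
    loops: dict[int, str] = {}
    for k in range(5):
        loops[k + 1] = seq[cys[k] + 1 : cys[k + 1]]
    loops[6] = seq[cys[5] + 1 :] + seq[: cys[0]]  # wraps through the ligation site
    return LoopDecomposition(
        sequence=seq,
        cys_positions=tuple(c + 1 for c in cys),
        loops=loops,
    )


def classify_subtype(d: LoopDecomposition) -> str:
    """``"moebius"`` if loop 5 contains a Pro, else ``"bracelet"``.

    See :data:`SUBTYPE_CAVEAT` for the sequence-proxy caveat.
    """
    return "moebius" if "P" in d.loops[5] else "bracelet"


def identity_alignment_score(a: str, b: str, mode: str = "global") -> int:
    """Maximum identities over alignments with match=1, no gap penalties.

    With free gaps and zero mismatch cost this equals the
    longest-common-subsequence length; computed by O(len(a)*len(b))
    dynamic programming.  ``mode="local"`` maximizes over substrings,
    which under this scoring coincides with the global optimum and is
    kept for interface symmetry with gap-penalized scoring schemes.
    """
    if not a or not b:
        raise CyclopeptError("sequences must be nonempty")
    if mode not in ("global", "local"):
        raise CyclopeptError(f"unknown mode {mode!r}")
    na, nb = len(a), len(b)
    prev = np.zeros(nb + 1, dtype=np.int32)
    cur = np.zeros(nb + 1, dtype=np.int32)
    for i in range(1, na + 1):
        ai = a[i - 1]
        for j in range(1, nb + 1):
            if ai == b[j - 1]:
                cur[j] = prev[j - 1] + 1
            else:
                cur[j] = max(prev[j], cur[j - 1])
        prev, cur = cur, prev
    return int(prev[nb])


@dataclass(frozen=True)
class HomologyHit:
    id: str
    score: int
    normalized: float


def _rotations(s: str) -> list[str]:
    return [s[k:] + s[:k] for k in range(len(s))]


def rank_homologs(
    query: str,
    library: Sequence[tuple[str, str]],
    best_over_rotations: bool = False,
) -> list[HomologyHit]:
    """Rank library sequences by identity score against the query.

    Descending by score, ties broken by id.  ``best_over_rotations``
    scores the best cyclic rotation of the query against each subject
    (useful when library sequences follow a different opening
    convention).
    """
    if not library:
        raise CyclopeptError("library must be nonempty")
    queries = _rotations(query) if best_over_rotations else [query]
    hits = []
    for sid, seq in library:
        score = max(identity_alignment_score(q, seq) for q in queries)
        hits.append(
            HomologyHit(
                id=sid,
                score=score,
                normalized=score / min(len(query), len(seq)),
            )
        )
    hits.sort(key=lambda h: (-h.score, h.id))
    return hits


def frequency_matrix(
    aligned: Sequence[str], gap_char: str = "-"
) -> tuple[pd.DataFrame, pd.Series]:
    """Per-column residue frequencies of an alignment.

    Returns a (positions x residues) DataFrame whose rows sum to 1 over
    non-gap characters (all-gap columns are all-zero), plus the per-column
    gap fraction as a separate Series.  The matrix orientation matches
    what logo-rendering tools expect.
    """
    if not aligned:
        raise CyclopeptError("alignment must be nonempty")
    width = len(aligned[0])
    if any(len(row) != width for row in aligned):
        raise CyclopeptError("ragged alignment: rows differ in length")
    residues = sorted({c for row in aligned for c in row if c != gap_char})
    mat = pd.DataFrame(
        0.0, index=pd.RangeIndex(1, width + 1, name="position"), columns=residues
    )
    gap_frac = pd.Series(0.0, index=mat.index, name="gap_fraction")
    nrows = len(aligned)
    for j in range(width):
        col = [row[j] for row in aligned]
        non_gap = [c for c in col if c != gap_char]
        gap_frac.iloc[j] = (nrows - len(non_gap)) / nrows
        if non_gap:
            counts = pd.Series(non_gap).value_counts()
            for c, cnt in counts.items():
                mat.iloc[j, mat.columns.get_loc(c)] = cnt / len(non_gap)
    return mat, gap_frac


def plot_logo(matrix: pd.DataFrame, ax=None):
    """Minimal frequency-logo rendering as stacked bars (optional layer;
    the analysis artifact is the matrix itself)."""
    import matplotlib.pyplot as plt  # deferred; plotting is optional

    if ax is None:
        _, ax = plt.subplots(figsize=(max(4, 0.3 * len(matrix)), 2.5))
    bottoms = np.zeros(len(matrix))
    for res in matrix.columns:
        vals = matrix[res].to_numpy()
        ax.bar(matrix.index, vals, bottom=bottoms, label=res, width=0.85)
        bottoms += vals
    ax.set_xlabel("alignment position")
    ax.set_ylabel("frequency")
    ax.set_ylim(0, 1)
    return ax
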