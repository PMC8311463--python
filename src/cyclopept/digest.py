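"""In-silico site-specific proteolysis of cyclic and linear peptides.

A cyclic peptide with *k* cleavage sites yields *k* complete-digest
fragments, each running from the successor of one site to the next site
around the ring; partial products span up to ``max_missed`` internal
sites.  The full-length single-cut ("ring-opened") linear forms — the
species used as MS/MS precursors — are emitted for every site regardless
of the missed-cleavage cap.  Every fragment mass is computed as a linear
peptide (each cut adds one water).

Enzyme specificities used for cyclotide sequencing:

* GluC cleaves after Glu; a single Glu in a cyclic peptide gives exactly
  one linearized product (+18 Da), the diagnostic cyclotide signature.
* Trypsin cleaves after Lys/Arg, blocked by a following Pro.
* Chymotrypsin cleaves after Phe/Tyr/Trp/Leu/Met but is sterically
  hindered by Ile — the property exploited to tell isobaric Ile from Leu.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .errors import CyclopeptError
from .masses import CAM_DELTA, PROTON, RESIDUE_MASS, WATER, Peptide, mz
from .peaks import PeakList

__all__ = [
    "CleavageRule",
    "DigestFragment",
    "ENZYMES",
    "GLUC",
    "TRYPSIN",
    "CHYMOTRYPSIN",
    "CHYMOTRYPSIN_STRICT",
    "cleavage_sites",
    "digest_peptide",
    "match_fragment_table",
]


@dataclass(frozen=True)
class CleavageRule:
    name: str
    cleave_after: frozenset[str]
    blocked_by_next: frozenset[str] = frozenset()
    max_missed: int = 2

    def __post_init__(self) -> None:
        if not self.cleave_after:
            raise CyclopeptError("cleave_after must be nonempty")
        bad = (self.cleave_after | self.blocked_by_next) - set(RESIDUE_MASS)
        if bad:
            raise CyclopeptError(f"invalid residues in cleavage rule: {sorted(bad)}")
        if self.max_missed < 0:
            raise CyclopeptError("max_missed must be >= 0")


GLUC = CleavageRule("gluc", frozenset("E"))
TRYPSIN = CleavageRule("trypsin", frozenset("KR"), frozenset("P"))
CHYMOTRYPSIN = CleavageRule("chymotrypsin", frozenset("FYWLM"))
#: High-specificity chymotrypsin variant (aromatic residues only).
CHYMOTRYPSIN_STRICT = CleavageRule("chymotrypsin_strict", frozenset("FYW"))

ENZYMES = {r.name: r for r in (GLUC, TRYPSIN, CHYMOTRYPSIN, CHYMOTRYPSIN_STRICT)}


@dataclass(frozen=True)
class DigestFragment:
    """A linear proteolysis product of a (possibly cyclic) parent.

    ``start`` is a 0-based index into the parent sequence as written
    (cyclic parents wrap modulo their length).  ``full_length`` marks the
    single-cut ring-opened form of a cyclic parent, which is reported
    even when its internal site count exceeds the missed-cleavage cap.
    """

    sequence: str
    start: int
    length: int
    missed: int
    neutral_mass: float
    mz1: float
    full_length: bool = False

    @property
    def start1(self) -> int:
        """1-based start position for reports."""
        return self.start + 1


def cleavage_sites(p: Peptide, rule: CleavageRule) -> list[int]:
    """0-based indices i such that the bond after residue i is cleaved."""
    seq, n = p.sequence, len(p.sequence)
    sites = []
    for i, aa in enumerate(seq):
        if aa not in rule.cleave_after:
            continue
        if p.topology == "cyclic":
            nxt = seq[(i + 1) % n]
        else:
            nxt = seq[i + 1] if i + 1 < n else None
        if nxt is not None and nxt in rule.blocked_by_next:
            continue
        sites.append(i)
    return sites


def _fragment_mass(sequence: str, cys_state: str) -> float:
    m = sum(RESIDUE_MASS[aa] for aa in sequence) + WATER
    if cys_state == "carbamidomethylated":
        m += CAM_DELTA * sequence.count("C")
    return m


def _arc(seq: str, start: int, length: int) -> str:
    n = len(seq)
    return "".join(seq[(start + k) % n] for k in range(length))


def digest_peptide(
    p: Peptide, rule: CleavageRule, max_missed: int | None = None
) -> list[DigestFragment]:
    """Enumerate digestion products of a cyclic or linear parent.

    Fragment masses are reported with the parent's cysteine state
    (carbamidomethylated parents add +57.0215 Da per Cys; oxidized
    parents are priced as free thiols, since the disulfide pairing of a
    fragment is not defined).
    """
    if max_missed is None:
        max_missed = rule.max_missed
    sites = cleavage_sites(p, rule)
    n = len(p.sequence)
    frags: list[DigestFragment] = []

    def emit(start: int, length: int, missed: int, full: bool = False) -> None:
        seq = _arc(p.sequence, start, length)
        m = _fragment_mass(seq, p.cys_state)
        frags.append(
            DigestFragment(
                sequence=seq,
                start=start % n,
                length=length,
                missed=missed,
                neutral_mass=m,
                mz1=mz(m, 1),
                full_length=full,
            )
        )

    if p.topology == "cyclic":
        k = len(sites)
        if k == 0:
            return []
        if k == 1:
            emit(sites[0] + 1, n, 0, full=True)
            return frags
        # arcs from one site's successor spanning m internal sites
        for j in range(k):
            start = sites[j] + 1
            for m_int in range(min(max_missed, k - 2) + 1):
                end_site = sites[(j + 1 + m_int) % k]
                length = (end_site - start) % n + 1
                emit(start, length, m_int)
        # full-length ring-opened forms, one per site (k-1 internal sites)
        for s in sites:
            emit(s + 1, n, k - 1, full=True)
    else:
        cuts = [-1] + sites + ([n - 1] if (not sites or sites[-1] != n - 1) else [])
        for a in range(len(cuts) - 1):
            for b in range(a + 1, min(a + 2 + max_missed, len(cuts))):
                start, end = cuts[a] + 1, cuts[b]
                emit(start, end - start + 1, b - a - 1)
    return frags


def match_fragment_table(
    fragments: list[DigestFragment],
    observed: PeakList,
    tolerance: float = 0.2,
    tolerance_mode: str = "dalton",
) -> pd.DataFrame:
    """Annotate observed singly-charged peaks with the best fragment.

    Each peak gets the in-tolerance fragment with the smallest absolute
    m/z error, or ``unassigned``; a fragment is consumed by at most one
    peak (singly-charged MALDI context).
    """
    rows = []
    pairs = []
    for pi in range(len(observed)):
        omz = float(observed.mz[pi])
        for fi, f in enumerate(fragments):
            err = omz - f.mz1
            lim = tolerance if tolerance_mode == "dalton" else tolerance * 1e-6 * f.mz1
            if abs(err) <= lim:
                pairs.append((abs(err), pi, fi, err))
    pairs.sort()
    used_p: set[int] = set()
    used_f: set[int] = set()
    assign: dict[int, tuple[int, float]] = {}
    for aerr, pi, fi, err in pairs:
        if pi in used_p or fi in used_f:
            continue
        used_p.add(pi)
        used_f.add(fi)
        assign[pi] = (fi, err)
    for pi in range(len(observed)):
        omz = float(observed.mz[pi])
        if pi in assign:
            fi, err = assign[pi]
            f = fragments[fi]
            rows.append(
                {
                    "observed_mz": omz,
                    "intensity": float(observed.intensity[pi]),
                    "sequence": f.sequence,
                    "start1": f.start1,
                    "missed": f.missed,
                    "theoretical_mz1": f.mz1,
                    "error": err,
                    "assigned": True,
                }
            )
        else:
            rows.append(
                {
                    "observed_mz": omz,
                    "intensity": float(observed.intensity[pi]),
                    "sequence": "unassigned",
                    "start1": pd.NA,
                    "missed": pd.NA,
                    "theoretical_mz1": pd.NA,
                    "error": pd.NA,
                    "assigned": False,
                }
            )
    return pd.DataFrame(
        rows,
        columns=[
            "observed_mz",
            "intensity",
            "sequence",
            "start1",
            "missed",
            "theoretical_mz1",
            "error",
            "assigned",
        ],
    )
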