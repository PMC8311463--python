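"""Theoretical b/y ion ladders, spectrum annotation and Ile/Leu resolution.

MALDI post-source-decay spectra of ring-opened cyclotide precursors are
annotated against candidate sequences with singly charged b and y ions
plus their -17 Da (NH3) and -18 Da (H2O) neutral-loss satellites.  A
residue counts as verified when at least one matched ion places a
backbone-bond boundary adjacent to it, in either series.  Because the
parent is cyclic, evidence from differently opened linear forms (GluC
vs. trypsin precursors) is merged in cyclic coordinates.

Isobaric Ile/Leu cannot be told apart by mass; ``resolve_ile_leu``
exploits chymotrypsin, which cleaves after Leu but is sterically
hindered by Ile: an observed fragment boundary right after an ambiguous
position argues Leu, while fragments spanning the position uncut argue
Ile.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Optional, Sequence

import numpy as np

from .errors import CyclopeptError
from .masses import CAM_DELTA, PROTON, RESIDUE_MASS, WATER, Peptide
from .peaks import PeakList

__all__ = [
    "LOSS_NH3",
    "LOSS_H2O",
    "FragmentIon",
    "AnnotationResult",
    "AmbiguousSequence",
    "theoretical_ions",
    "annotate_spectrum",
    "combine_evidence",
    "resolve_ile_leu",
]

LOSS_NH3 = 17.026549
LOSS_H2O = 18.010565
_LOSSES = {"none": 0.0, "NH3": LOSS_NH3, "H2O": LOSS_H2O}

#: Mass used for the Ile/Leu placeholder J (both are 113.08406 Da).
_J_MASS = RESIDUE_MASS["L"]


@dataclass(frozen=True)
class FragmentIon:
    series: Literal["b", "y"]
    index: int
    loss: Literal["none", "NH3", "H2O"]
    mz1: float
    matched_peak_mz: Optional[float] = None


def _residue_mass(aa: str, cys_state: str) -> float:
    m = _J_MASS if aa == "J" else RESIDUE_MASS[aa]
    if aa == "C" and cys_state == "carbamidomethylated":
        m += CAM_DELTA
    return m


def theoretical_ions(
    linear_sequence: str,
    cys_state: str = "carbamidomethylated",
    losses: bool = True,
) -> list[FragmentIon]:
    """Singly charged b/y ladder of a linear peptide.

    ``b_i`` is the N-terminal prefix of i residues plus a proton;
    ``y_i`` is the C-terminal suffix of i residues plus water and a
    proton.  With ``losses`` each ion also gets -17.026549 (NH3) and
    -18.010565 (H2O) variants.
    """
    n = len(linear_sequence)
    if n < 2:
        raise CyclopeptError("need at least 2 residues for a fragment ladder")
    masses = [_residue_mass(aa, cys_state) for aa in linear_sequence]
    prefix = np.cumsum(masses)
    loss_names = ["none", "NH3", "H2O"] if losses else ["none"]
    ions = []
    for i in range(1, n):
        b = prefix[i - 1] + PROTON
        y = (prefix[n - 1] - prefix[n - i - 1]) + WATER + PROTON
        for ln in loss_names:
            ions.append(FragmentIon("b", i, ln, b - _LOSSES[ln]))
            ions.append(FragmentIon("y", i, ln, y - _LOSSES[ln]))
    return ions


@dataclass
class AnnotationResult:
    """Per-residue b/y evidence for a candidate sequence.

    ``parent_offset``/``parent_length`` locate this linear form on its
    cyclic parent (0-based index of residue 1 in cyclic coordinates) so
    that evidence from differently opened precursors can be merged.
    """

    sequence: str
    matched_ions: list[FragmentIon]
    residue_support: np.ndarray
    coverage: float
    unsupported_positions: list[int]
    parent_offset: int = 0
    parent_length: Optional[int] = None

    def to_dict(self) -> dict:
        return {
            "sequence": self.sequence,
            "coverage": self.coverage,
            "residue_support": [bool(x) for x in self.residue_support],
            "unsupported_positions": self.unsupported_positions,
            "matched_ions": [
                {
                    "series": i.series,
                    "index": i.index,
                    "loss": i.loss,
                    "mz1": i.mz1,
                    "matched_peak_mz": i.matched_peak_mz,
                }
                for i in self.matched_ions
            ],
        }


def annotate_spectrum(
    spectrum: PeakList,
    candidate: str,
    cys_state: str = "carbamidomethylated",
    tolerance: float = 0.3,
    losses: bool = True,
    parent_offset: int = 0,
    parent_length: Optional[int] = None,
) -> AnnotationResult:
    """Match the theoretical ladder of ``candidate`` against a spectrum.

    Greedy nearest-match by absolute error; each (series, index) pair is
    matched to at most one peak across its loss states.  Residue j is
    supported when the bond boundary before or after it is verified by a
    matched b or y ion; the ladder termini are taken as given (the
    precursor mass is known), so a full single-series ladder yields
    coverage 1.0 while an empty spectrum yields 0.0.
    """
    n = len(candidate)
    ions = theoretical_ions(candidate, cys_state, losses)
    matches = []
    if len(spectrum) > 0:
        for ion in ions:
            _, peak_mz = spectrum.nearest(ion.mz1)
            err = abs(peak_mz - ion.mz1)
            if err <= tolerance:
                matches.append((err, ion, peak_mz))
    matches.sort(key=lambda t: t[0])
    seen: set[tuple[str, int]] = set()
    matched_ions: list[FragmentIon] = []
    boundary = np.zeros(n + 1, dtype=bool)  # boundary[i]: bond after residue i
    for err, ion, peak_mz in matches:
        key = (ion.series, ion.index)
        if key in seen:
            continue
        seen.add(key)
        matched_ions.append(
            FragmentIon(ion.series, ion.index, ion.loss, ion.mz1, peak_mz)
        )
        boundary[ion.index if ion.series == "b" else n - ion.index] = True
    if matched_ions:
        boundary[0] = boundary[n] = True  # termini of a known-mass precursor
    support = boundary[:-1] | boundary[1:]
    coverage = float(support.mean()) if n else 0.0
    unsupported = [j + 1 for j in range(n) if not support[j]]
    return AnnotationResult(
        sequence=candidate,
        matched_ions=matched_ions,
        residue_support=support,
        coverage=coverage,
        unsupported_positions=unsupported,
        parent_offset=parent_offset,
        parent_length=parent_length if parent_length is not None else n,
    )


def combine_evidence(results: Sequence[AnnotationResult]) -> AnnotationResult:
    """OR per-position support from several opened forms of one cyclic parent.

    Each result's linear positions are mapped back to cyclic coordinates
    via its ``parent_offset`` before merging.
    """
    if not results:
        raise CyclopeptError("no annotation results to combine")
    lengths = {r.parent_length for r in results}
    if len(lengths) != 1:
        raise CyclopeptError(f"inconsistent parent lengths: {sorted(lengths)}")
    n = lengths.pop()
    support = np.zeros(n, dtype=bool)
    ions: list[FragmentIon] = []
    for r in results:
        if len(r.sequence) != n:
            raise CyclopeptError(
                "linearized form length differs from parent length"
            )
        for j in range(n):
            if r.residue_support[j]:
                support[(r.parent_offset + j) % n] = True
        ions.extend(r.matched_ions)
    coverage = float(support.mean())
    return AnnotationResult(
        sequence=results[0].sequence,
        matched_ions=ions,
        residue_support=support,
        coverage=coverage,
        unsupported_positions=[j + 1 for j in range(n) if not support[j]],
        parent_offset=0,
        parent_length=n,
    )


@dataclass
class AmbiguousSequence:
    """A sequence with ``J`` at unresolved Ile/Leu positions.

    ``resolved`` maps 1-based written positions to an (assignment,
    evidence) pair; evidence is one of ``chymotryptic_cleavage``,
    ``homology`` (caller-supplied) or ``none``.
    """

    sequence: str
    resolved: dict[int, tuple[str, str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for pos, (aa, _) in self.resolved.items():
            if aa not in ("I", "L", "J"):
                raise CyclopeptError(f"invalid assignment {aa!r} at {pos}")
            if self.sequence[pos - 1] not in ("J", "I", "L"):
                raise CyclopeptError(
                    f"position {pos} is {self.sequence[pos - 1]!r}, not Ile/Leu"
                )

    @property
    def j_positions(self) -> list[int]:
        return [i + 1 for i, aa in enumerate(self.sequence) if aa == "J"]

    def apply(self) -> str:
        """Sequence with resolved positions substituted."""
        out = list(self.sequence)
        for pos, (aa, _) in self.resolved.items():
            if aa in ("I", "L"):
                out[pos - 1] = aa
        return "".join(out)


def resolve_ile_leu(
    candidate: AmbiguousSequence,
    chymo_fragments_observed: PeakList,
    parent: Peptide,
    tolerance: float = 0.3,
) -> AmbiguousSequence:
    """Assign I/L at J positions from observed chymotryptic fragment masses.

    Candidate cleavage boundaries are the definite chymotryptic sites
    (F/Y/W/L/M) plus every J position.  All arcs of the cyclic parent
    bounded by such sites are priced; arcs matching an observed mass
    provide evidence: a J at a matched arc's C-terminal boundary must
    have been cleaved after (=> Leu), a J strictly inside a matched arc
    was spanned uncut (=> Ile).  Leu evidence wins over spanning evidence
    (incomplete digestion can span a genuine Leu); positions with no
    evidence stay unresolved.
    """
    seq = candidate.sequence
    n = len(seq)
    cyclic = parent.topology == "cyclic"
    sites = [
        i for i, aa in enumerate(seq) if aa in "FYWLM" or aa == "J"
    ]
    if not cyclic:
        sites = sorted(set(sites) | {n - 1})

    leu_evidence: set[int] = set()
    spanned: set[int] = set()
    observed = chymo_fragments_observed

    def arc_positions(start: int, length: int) -> list[int]:
        return [(start + k) % n for k in range(length)]

    for si in sites:  # arc starts after site si
        start = (si + 1) % n
        for sj in sites:
            if cyclic:
                length = (sj - start) % n + 1
                if length == n:
                    # the ring-opened full-length mass is identical for
                    # every cut position, so it localizes nothing
                    continue
            else:
                if sj < start:
                    continue
                length = sj - start + 1
            if length < 1 or length > n:
                continue
            arc = arc_positions(start, length)
            frag = "".join(seq[k] for k in arc)
            m = sum(_residue_mass(aa, parent.cys_state) for aa in frag)
            frag_mz = m + WATER + PROTON
            if len(observed) == 0:
                continue
            _, peak = observed.nearest(frag_mz)
            if abs(peak - frag_mz) > tolerance:
                continue
            end_pos = arc[-1]
            if seq[end_pos] == "J":
                leu_evidence.add(end_pos + 1)
            if seq[si] == "J":
                leu_evidence.add(si + 1)  # cleavage after the start boundary
            for k in arc[:-1]:
                if seq[k] == "J":
                    spanned.add(k + 1)

    resolved = dict(candidate.resolved)
    for pos in candidate.j_positions:
        if pos in leu_evidence:
            resolved[pos] = ("L", "chymotryptic_cleavage")
        elif pos in spanned:
            resolved[pos] = ("I", "chymotryptic_cleavage")
        elif pos not in resolved:
            resolved[pos] = ("J", "none")
    return AmbiguousSequence(sequence=seq, resolved=resolved)
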