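"""Monoisotopic mass arithmetic for cyclic and linear cystine-rich peptides.

Cyclotides are head-to-tail cyclized peptides (~30 residues) with six
conserved cysteines forming three disulfide bonds.  All screening and
digestion logic in this package reduces to careful bookkeeping of a few
mass deltas on top of the standard residue masses:

* cyclization removes one water relative to the linear chain,
* each disulfide bond removes two hydrogen atoms,
* reduction of a disulfide restores them (+1.007825 Da per Cys),
* S-carbamidomethylation (iodoacetamide) adds +57.021464 Da per reduced
  Cys, i.e. +58.029289 Da per Cys relative to the oxidized (native) form,
* proteolytic ring opening adds one water (+18.010565 Da).

Residue masses come from :data:`pyteomics.mass.std_aa_mass`, restricted to
the 20 canonical one-letter codes.  Only monoisotopic masses are handled;
MALDI context means singly (occasionally doubly) protonated ions.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal

from pyteomics import mass as _ptmass

from .errors import SequenceError, CyclopeptError

__all__ = [
    "WATER",
    "PROTON",
    "H_ATOM",
    "CAM_DELTA",
    "REDUCTION_DELTA_PER_CYS",
    "ALKYLATION_FROM_NATIVE_PER_CYS",
    "RING_OPEN_DELTA",
    "RESIDUE_MASS",
    "CANONICAL_RESIDUES",
    "Peptide",
    "peptide_neutral_mass",
    "mz",
    "derivatization_delta",
    "extinction_coefficient_280",
    "ppm_error",
]

WATER = 18.010565
PROTON = 1.007276
H_ATOM = 1.007825

#: S-carbamidomethyl on a reduced cysteine thiol (iodoacetamide adduct).
CAM_DELTA = 57.021464
#: Reduction of a disulfide adds one H atom per cysteine.
REDUCTION_DELTA_PER_CYS = H_ATOM
#: Net shift per cysteine going native (disulfide) -> reduced -> CAM.
ALKYLATION_FROM_NATIVE_PER_CYS = REDUCTION_DELTA_PER_CYS + CAM_DELTA
#: Single proteolytic cut of a cyclic backbone adds one water.
RING_OPEN_DELTA = WATER

CANONICAL_RESIDUES = "ACDEFGHIKLMNPQRSTVWY"

#: Monoisotopic residue (internal) masses, Da.
RESIDUE_MASS: dict[str, float] = {
    aa: _ptmass.std_aa_mass[aa] for aa in CANONICAL_RESIDUES
}

Topology = Literal["cyclic", "linear"]
CysState = Literal["oxidized", "reduced", "carbamidomethylated"]

_CYS_STATES = ("oxidized", "reduced", "carbamidomethylated")
_TOPOLOGIES = ("cyclic", "linear")


def _validate_sequence(sequence: str) -> None:
    for i, aa in enumerate(sequence):
        if aa not in RESIDUE_MASS:
            raise SequenceError(
                f"unknown residue {aa!r} at position {i + 1} "
                f"(only the 20 canonical one-letter codes are accepted)"
            )


@dataclass(frozen=True)
class Peptide:
    """A peptide sequence with backbone topology and cysteine chemistry.

    Parameters
    ----------
    sequence : str
        Uppercase one-letter codes.  For a cyclic peptide the sequence is
        written starting at the residue immediately after the native
        ligation site (cyclotide convention).
    topology : {"cyclic", "linear"}
    cys_state : {"oxidized", "reduced", "carbamidomethylated"}
        ``oxidized`` means disulfide-bonded cysteines (native cyclotide);
        ``carbamidomethylated`` means every Cys carries the +57.0215 Da
        acetamide adduct.
    n_disulfides : int
        Number of disulfide bonds; only meaningful when oxidized.
    """

    sequence: str
    topology: Topology = "linear"
    cys_state: CysState = "reduced"
    n_disulfides: int = 0

    def __post_init__(self) -> None:
        _validate_sequence(self.sequence)
        if self.topology not in _TOPOLOGIES:
            raise SequenceError(f"unknown topology {self.topology!r}")
        if self.cys_state not in _CYS_STATES:
            raise SequenceError(f"unknown cys_state {self.cys_state!r}")
        if self.topology == "cyclic" and len(self.sequence) < 3:
            raise SequenceError("a cyclic peptide needs at least 3 residues")
        if self.n_disulfides < 0:
            raise SequenceError("n_disulfides must be >= 0")
        if self.cys_state == "oxidized":
            if 2 * self.n_disulfides > self.n_cys:
                raise SequenceError(
                    f"{self.n_disulfides} disulfides require "
                    f"{2 * self.n_disulfides} cysteines, sequence has {self.n_cys}"
                )
        elif self.n_disulfides != 0:
            raise SequenceError(
                "n_disulfides must be 0 unless cys_state='oxidized'"
            )

    @property
    def n_cys(self) -> int:
        return self.sequence.count("C")

    def __len__(self) -> int:
        return len(self.sequence)


def peptide_neutral_mass(p: Peptide) -> float:
    """Monoisotopic neutral mass of a peptide in Da.

    Linear chains carry one water (H at the N terminus, OH at the C
    terminus); head-to-tail cyclization removes it.  Each disulfide bond
    subtracts two hydrogen atoms; carbamidomethylation adds
    :data:`CAM_DELTA` per cysteine on top of the reduced form.
    """
    m = sum(RESIDUE_MASS[aa] for aa in p.sequence)
    if p.topology == "linear":
        m += WATER
    if p.cys_state == "oxidized":
        m -= 2.0 * H_ATOM * p.n_disulfides
    elif p.cys_state == "carbamidomethylated":
        m += CAM_DELTA * p.n_cys
    return m


def mz(neutral_mass: float, charge: int = 1) -> float:
    """m/z of the ``[M + charge*H]^charge+`` ion."""
    if not isinstance(charge, int) or charge < 1:
        raise CyclopeptError(f"charge must be a positive integer, got {charge!r}")
    return (neutral_mass + charge * PROTON) / charge


def derivatization_delta(
    n_cys: int, step: Literal["reduce", "alkylate_from_native", "ring_open"]
) -> float:
    """Expected mass shift for one step of the derivatization workflow.

    ``reduce``: +1.007825 Da per Cys (disulfide -> thiol).
    ``alkylate_from_native``: +58.029289 Da per Cys (native -> CAM).
    ``ring_open``: +18.010565 Da for the single GluC cut, independent of
    the cysteine count.
    """
    if n_cys < 0:
        raise CyclopeptError(f"n_cys must be >= 0, got {n_cys}")
    if step == "reduce":
        return n_cys * REDUCTION_DELTA_PER_CYS
    if step == "alkylate_from_native":
        return n_cys * ALKYLATION_FROM_NATIVE_PER_CYS
    if step == "ring_open":
        return RING_OPEN_DELTA
    raise CyclopeptError(f"unknown derivatization step {step!r}")


def extinction_coefficient_280(sequence: str, n_cystine: int = 0) -> int:
    """Molar absorption coefficient at 280 nm (M^-1 cm^-1).

    Standard composition rule: 1490 per Tyr, 5500 per Trp, 125 per
    cystine (disulfide-bonded cysteine pair).
    """
    _validate_sequence(sequence)
    if n_cystine < 0 or 2 * n_cystine > sequence.count("C"):
        raise CyclopeptError(
            f"{n_cystine} cystines inconsistent with "
            f"{sequence.count('C')} cysteines"
        )
    return (
        1490 * sequence.count("Y")
        + 5500 * sequence.count("W")
        + 125 * n_cystine
    )


def ppm_error(observed: float, theoretical: float) -> float:
    """Signed relative mass error in parts per million."""
    if theoretical <= 0:
        raise CyclopeptError(f"theoretical m/z must be > 0, got {theoretical}")
    return 1e6 * (observed - theoretical) / theoretical
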