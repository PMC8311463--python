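"""Seeded generators emulating every input the pipeline consumes.

The generators mirror the structure of the real experiments:

* ``generate_cyclotide_like`` draws cyclic ~28-34-mers with exactly six
  cysteines, a single Glu in loop 1 (so GluC opens the ring at one site)
  and an Asn/Asp ligation residue closing loop 6, with native masses in
  the 2,900-3,550 Da MALDI screening window.
* ``simulate_derivatization_peaklists`` produces the four screening peak
  lists (native / reduced / alkylated / GluC-linearized) with exact
  shifts, Gaussian ppm mass error, uniform decoy peaks kept clear of the
  true peaks, and optional per-peak dropout.
* ``simulate_msms`` samples b/y ions (with optional -17/-18 losses),
  m/z jitter and noise peaks for a linear precursor.
* ``simulate_dose_response`` draws 4PL-shaped inhibition data with
  multiplicative plate-reader-like noise.

Every generator returns machine-readable ground truth and is fully
deterministic for a fixed config/seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .errors import CyclopeptError
from .masses import (
    CAM_DELTA,
    PROTON,
    REDUCTION_DELTA_PER_CYS,
    RING_OPEN_DELTA,
    Peptide,
    mz,
    peptide_neutral_mass,
)
from .msms import LOSS_H2O, LOSS_NH3, theoretical_ions
from .assay import four_pl
from .peaks import PeakList

__all__ = [
    "GeneratorConfig",
    "generate_cyclotide_like",
    "simulate_derivatization_peaklists",
    "simulate_msms",
    "simulate_dose_response",
]

# cyclotide-like inter-cysteine alphabet (no Cys outside the scaffold, no
# extra Glu so GluC stays single-cut); weights loosely follow the residue
# usage of Violaceae cyclotide mature domains
_ALPHABET = np.array(list("GASTVILPNDKRFYQH"))
_WEIGHTS = np.array([14, 8, 10, 8, 8, 7, 5, 7, 6, 4, 6, 5, 3, 4, 3, 2], dtype=float)
_WEIGHTS /= _WEIGHTS.sum()


@dataclass(frozen=True)
class GeneratorConfig:
    """Study-design parameters for all synthetic inputs."""

    seed: int = 0
    n_peptides: int = 18
    #: inclusive length ranges for intercysteine loops 1-6; loop 1 length
    #: includes its single Glu, loop 6 its terminal Asn/Asp ligation residue
    loop_len_ranges: dict = field(
        default_factory=lambda: {1: (3, 4), 2: (3, 4), 3: (4, 6), 4: (1, 1), 5: (4, 5), 6: (6, 8)}
    )
    mass_window: tuple[float, float] = (2900.0, 3550.0)
    ppm_noise_sd: float = 10.0
    decoys_per_list: int = 10
    dropout_prob: float = 0.0
    dropout_labels: tuple[str, ...] = ("linearized",)
    msms_ion_prob: float = 0.8
    msms_loss_prob: float = 0.2
    msms_noise_peaks: int = 10
    msms_mz_jitter_sd: float = 0.05
    dr_bottom: float = 0.0
    dr_top: float = 100.0
    dr_ic50: float = 4.4  # µM, alca-2-like truth
    dr_hill: float = -2.8
    dr_noise_cv: float = 0.05
    dr_doses: tuple[float, ...] = tuple(np.geomspace(0.1, 60.0, 10).round(4))
    dr_replicates: int = 6

    def __post_init__(self) -> None:
        for p in (self.dropout_prob, self.msms_ion_prob, self.msms_loss_prob):
            if not 0.0 <= p <= 1.0:
                raise CyclopeptError("probabilities must lie in [0, 1]")
        for k, (lo, hi) in self.loop_len_ranges.items():
            if lo > hi or lo < (1 if k in (1, 6) else 0):
                raise CyclopeptError(f"infeasible length range for loop {k}")


def _rng(cfg: GeneratorConfig, rng: Optional[np.random.Generator]) -> np.random.Generator:
    return rng if rng is not None else np.random.default_rng(cfg.seed)


def _draw_loop(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(_ALPHABET, size=length, p=_WEIGHTS))


def generate_cyclotide_like(
    cfg: GeneratorConfig, rng: Optional[np.random.Generator] = None
) -> tuple[list[Peptide], pd.DataFrame]:
    """Draw cyclic six-Cys peptides with cyclotide-like architecture.

    The sequence is written starting at Cys I (the residue after the
    ligation site), so loop 6 — ending in the Asn/Asp ligation residue —
    closes the written string.  Each draw is rejected until the native
    oxidized [M+H]+ falls inside ``cfg.mass_window``.
    """
    rng = _rng(cfg, rng)
    peptides: list[Peptide] = []
    rows = []
    for idx in range(cfg.n_peptides):
        for _ in range(200):
            lens = {
                k: int(rng.integers(lo, hi + 1))
                for k, (lo, hi) in cfg.loop_len_ranges.items()
            }
            loop1 = list(_draw_loop(rng, lens[1] - 1))
            loop1.insert(int(rng.integers(0, len(loop1) + 1)), "E")
            loop6 = _draw_loop(rng, lens[6] - 1) + str(rng.choice(["N", "D"]))
            seq = (
                "C" + "".join(loop1)
                + "C" + _draw_loop(rng, lens[2])
                + "C" + _draw_loop(rng, lens[3])
                + "C" + _draw_loop(rng, lens[4])
                + "C" + _draw_loop(rng, lens[5])
                + "C" + loop6
            )
            p = Peptide(seq, topology="cyclic", cys_state="oxidized", n_disulfides=3)
            native_mh = mz(peptide_neutral_mass(p))
            if cfg.mass_window[0] <= native_mh <= cfg.mass_window[1]:
                break
        else:
            raise CyclopeptError(
                "could not draw a peptide inside the mass window; "
                "loop length ranges are infeasible"
            )
        peptides.append(p)
        rows.append(
            {
                "id": f"syn{idx:03d}",
                "sequence": seq,
                "length": len(seq),
                "n_cys": seq.count("C"),
                "n_glu": seq.count("E"),
                "native_mh": native_mh,
            }
        )
    return peptides, pd.DataFrame(rows)


def simulate_derivatization_peaklists(
    peptides: Sequence[Peptide],
    cfg: GeneratorConfig,
    rng: Optional[np.random.Generator] = None,
) -> tuple[dict[str, PeakList], pd.DataFrame]:
    """Simulate the four screening peak lists for cyclic six-Cys peptides.

    Mass error is modelled as per-measurement calibration drift relative
    to the previous derivatization state: each observed peak deviates by
    N(0, ppm_noise_sd) from the position predicted by the previously
    observed peak plus the exact chemical shift, so errors accumulate
    along the native -> reduced -> alkylated -> linearized chain.  Decoy
    peaks are uniform over each list's mass window, redrawn if within
    3 x 25 ppm of any true peak; dropout removes peaks from the lists
    named in ``cfg.dropout_labels``.
    """
    rng = _rng(cfg, rng)
    truth_rows = []
    true_peaks: dict[str, list[float]] = {
        "native": [], "reduced": [], "alkylated": [], "linearized": []
    }
    for i, p in enumerate(peptides):
        if p.topology != "cyclic" or p.n_cys != 6:
            raise CyclopeptError("derivatization simulation expects cyclic six-Cys peptides")
        native_theory = mz(peptide_neutral_mass(p))
        shifts = {
            "reduced": 6 * REDUCTION_DELTA_PER_CYS,
            "alkylated": 6 * CAM_DELTA,
            "linearized": RING_OPEN_DELTA,
        }
        obs = native_theory * (1.0 + rng.normal(0.0, cfg.ppm_noise_sd) * 1e-6)
        chain = {"native": obs}
        for label, delta in shifts.items():
            pred = chain[list(chain)[-1]] + delta
            chain[label] = pred * (1.0 + rng.normal(0.0, cfg.ppm_noise_sd) * 1e-6)
        row = {"id": i, "native_theory": native_theory}
        for label, val in chain.items():
            dropped = (
                label in cfg.dropout_labels and rng.random() < cfg.dropout_prob
            )
            row[f"{label}_mz"] = val
            row[f"{label}_dropped"] = dropped
            if not dropped:
                true_peaks[label].append(val)
        truth_rows.append(row)

    lists: dict[str, PeakList] = {}
    all_true = np.array(sorted(m for v in true_peaks.values() for m in v))
    for label, peaks in true_peaks.items():
        peaks = list(peaks)
        lo = min(peaks) - 30.0 if peaks else cfg.mass_window[0]
        hi = max(peaks) + 30.0 if peaks else cfg.mass_window[1]
        n_decoys = 0
        attempts = 0
        while n_decoys < cfg.decoys_per_list and attempts < 100 * (cfg.decoys_per_list + 1):
            attempts += 1
            d = rng.uniform(lo, hi)
            if all_true.size and np.min(np.abs(all_true - d)) < 3 * 25e-6 * d:
                continue
            peaks.append(d)
            n_decoys += 1
        mzs = np.array(sorted(peaks))
        keep = np.ones(len(mzs), dtype=bool)
        keep[1:] = np.diff(mzs) >= 1e-6  # merge coincidental duplicates
        lists[label] = PeakList(
            mz=mzs[keep], intensity=np.ones(int(keep.sum())), label=label
        )
    return lists, pd.DataFrame(truth_rows)


def simulate_msms(
    linear_sequence: str,
    cfg: GeneratorConfig,
    rng: Optional[np.random.Generator] = None,
    cys_state: str = "carbamidomethylated",
) -> tuple[PeakList, pd.DataFrame]:
    """Simulate a centroided MS/MS spectrum of a linear precursor.

    Each base b/y ion is emitted with probability ``msms_ion_prob``; each
    -17/-18 loss satellite independently with ``msms_loss_prob``.  Peaks
    get Gaussian m/z jitter and uniform noise peaks are added below the
    precursor.
    """
    rng = _rng(cfg, rng)
    ions = theoretical_ions(linear_sequence, cys_state, losses=True)
    peaks: list[float] = []
    rows = []
    for ion in ions:
        prob = cfg.msms_ion_prob if ion.loss == "none" else cfg.msms_loss_prob
        emitted = rng.random() < prob
        jittered = ion.mz1 + rng.normal(0.0, cfg.msms_mz_jitter_sd)
        if emitted:
            peaks.append(jittered)
        rows.append(
            {
                "series": ion.series,
                "index": ion.index,
                "loss": ion.loss,
                "mz1": ion.mz1,
                "emitted": emitted,
            }
        )
    precursor = max(i.mz1 for i in ions) + 150.0
    for _ in range(cfg.msms_noise_peaks):
        peaks.append(rng.uniform(100.0, precursor))
    mzs = np.array(sorted(peaks))
    if mzs.size:
        keep = np.ones(len(mzs), dtype=bool)
        keep[1:] = np.diff(mzs) >= 1e-6
        mzs = mzs[keep]
    spectrum = PeakList(
        mz=mzs,
        intensity=np.ones(len(mzs)),
        label="msms",
        metadata={"sequence": linear_sequence, "seed": cfg.seed},
    )
    return spectrum, pd.DataFrame(rows)


def simulate_dose_response(
    cfg: GeneratorConfig, rng: Optional[np.random.Generator] = None
) -> tuple[pd.DataFrame, dict]:
    """Simulate a 4PL-shaped inhibition experiment.

    Responses follow the 4PL at the configured truth parameters with
    multiplicative Gaussian noise of coefficient of variation
    ``dr_noise_cv``, replicated ``dr_replicates`` times per dose.
    Concentrations are in µM.
    """
    rng = _rng(cfg, rng)
    log_ic50 = float(np.log10(cfg.dr_ic50))
    rows = []
    for dose in cfg.dr_doses:
        y0 = four_pl(np.log10(dose), cfg.dr_bottom, cfg.dr_top, log_ic50, cfg.dr_hill)
        for rep in range(cfg.dr_replicates):
            y = float(y0) * (1.0 + rng.normal(0.0, cfg.dr_noise_cv))
            rows.append(
                {
                    "concentration": dose,
                    "unit": "uM",
                    "response": y,
                    "replicate": rep + 1,
                }
            )
    truth = {
        "bottom": cfg.dr_bottom,
        "top": cfg.dr_top,
        "ic50": cfg.dr_ic50,
        "log_ic50": log_ic50,
        "hill_slope": cfg.dr_hill,
        "noise_cv": cfg.dr_noise_cv,
        "seed": cfg.seed,
    }
    return pd.DataFrame(rows), truth
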