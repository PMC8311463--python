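"""Derivatization-series screening for cyclic cystine-rich peptides.

The wet-lab workflow records four MALDI peak lists of the same extract:
native, disulfide-reduced (DTT), S-carbamidomethylated (iodoacetamide)
and GluC ring-opened.  A peptide with *n* cysteines and a cyclic backbone
appears as a quadruple of peaks separated by

    +n x 1.007825 Da  (reduction),
    +n x 57.021464 Da (alkylation of the reduced thiols),
    +18.010565 Da     (single-site ring opening).

``match_series`` chains these shifts across the four lists, infers the
cysteine count, and classifies each native peak; cyclotide-like peptides
are the six-cysteine series whose ring-opened product is observed.
"""

from __future__ import annotations

import heapq
from dataclasses import dataclass, field
from typing import Literal, Optional, Sequence

import numpy as np

from .errors import CyclopeptError, FormatError
from .masses import (
    CAM_DELTA,
    PROTON,
    REDUCTION_DELTA_PER_CYS,
    RING_OPEN_DELTA,
    WATER,
    ppm_error,
)
from .peaks import SCREEN_LABELS, PeakList

__all__ = ["ScreenParams", "DerivatizationSeries", "match_series", "screen_report"]

Classification = Literal["six_cys_cyclic", "cys_rich_other", "incomplete"]


@dataclass(frozen=True)
class ScreenParams:
    """Matching parameters for the derivatization screen.

    ``tolerance_mode`` selects how step deviations are measured: relative
    (``"ppm"``, the instrument-accuracy reading) or absolute
    (``"dalton"``, needed when peak lists are rounded to one decimal).
    ``chaining`` controls the anchor of each step prediction: the matched
    peak of the previous step (default) or always the native peak.
    """

    tolerance_mode: Literal["ppm", "dalton"] = "ppm"
    tolerance_value: float = 25.0
    cys_candidates: frozenset[int] = frozenset(range(1, 11))
    require_linearized: bool = True
    chaining: Literal["from_previous_observed", "from_native"] = "from_previous_observed"

    def __post_init__(self) -> None:
        if self.tolerance_value <= 0:
            raise CyclopeptError("tolerance_value must be > 0")
        if not self.cys_candidates:
            raise CyclopeptError("cys_candidates must be nonempty")
        if self.tolerance_mode not in ("ppm", "dalton"):
            raise CyclopeptError(f"unknown tolerance_mode {self.tolerance_mode!r}")

    def deviation(self, observed: float, predicted: float) -> float:
        """Signed step deviation in the active tolerance unit."""
        if self.tolerance_mode == "ppm":
            return ppm_error(observed, predicted)
        return observed - predicted

    def within(self, observed: float, predicted: float) -> bool:
        return abs(self.deviation(observed, predicted)) <= self.tolerance_value


@dataclass
class DerivatizationSeries:
    """A matched native/reduced/alkylated(/linearized) peak quadruple."""

    native_mz: float
    reduced_mz: float
    alkylated_mz: float
    linearized_mz: Optional[float]
    inferred_n_cys: int
    step_deviations: tuple[float, float, Optional[float]]
    classification: Classification
    internal_fragment_flag: bool = False

    @property
    def total_abs_deviation(self) -> float:
        return sum(abs(d) for d in self.step_deviations if d is not None)

    def to_dict(self) -> dict:
        return {
            "native_mz": self.native_mz,
            "reduced_mz": self.reduced_mz,
            "alkylated_mz": self.alkylated_mz,
            "linearized_mz": self.linearized_mz,
            "inferred_n_cys": self.inferred_n_cys,
            "step_deviations": list(self.step_deviations),
            "classification": self.classification,
            "internal_fragment_flag": self.internal_fragment_flag,
        }


def _check_labels(lists: Sequence[Optional[PeakList]]) -> None:
    for pl, expected in zip(lists, SCREEN_LABELS):
        if pl is not None and pl.label != expected:
            raise FormatError(
                f"peak list labelled {pl.label!r} passed where {expected!r} expected"
            )


def _find(pl: Optional[PeakList], predicted: float, params: ScreenParams):
    """Nearest in-tolerance peak, or None.  Ties break toward lower m/z."""
    if pl is None or len(pl) == 0:
        return None
    idx, observed = pl.nearest(predicted)
    if params.within(observed, predicted):
        return idx, observed
    return None


def _chain(native_mz: float, n: int, lists, params: ScreenParams):
    """Try to chain the three derivatization steps for cysteine count n.

    Returns (claims, series fields) or None.  ``claims`` are
    (list_index, peak_index) pairs used for injectivity bookkeeping.
    """
    reduced, alkylated, linearized = lists
    pred_r = native_mz + n * REDUCTION_DELTA_PER_CYS
    hit_r = _find(reduced, pred_r, params)
    if hit_r is None:
        return None
    anchor = hit_r[1] if params.chaining == "from_previous_observed" else native_mz
    pred_a = (
        anchor + n * CAM_DELTA
        if params.chaining == "from_previous_observed"
        else native_mz + n * (REDUCTION_DELTA_PER_CYS + CAM_DELTA)
    )
    hit_a = _find(alkylated, pred_a, params)
    if hit_a is None:
        return None
    anchor = hit_a[1] if params.chaining == "from_previous_observed" else native_mz
    pred_l = (
        anchor + RING_OPEN_DELTA
        if params.chaining == "from_previous_observed"
        else native_mz
        + n * (REDUCTION_DELTA_PER_CYS + CAM_DELTA)
        + RING_OPEN_DELTA
    )
    hit_l = _find(linearized, pred_l, params)

    dev_r = params.deviation(hit_r[1], pred_r)
    dev_a = params.deviation(hit_a[1], pred_a)
    dev_l = params.deviation(hit_l[1], pred_l) if hit_l is not None else None
    claims = [(1, hit_r[0]), (2, hit_a[0])]
    if hit_l is not None:
        claims.append((3, hit_l[0]))
    return claims, (
        hit_r[1],
        hit_a[1],
        hit_l[1] if hit_l is not None else None,
        (dev_r, dev_a, dev_l),
    )


def match_series(
    native: PeakList,
    reduced: PeakList,
    alkylated: PeakList,
    linearized: Optional[PeakList],
    params: ScreenParams = ScreenParams(),
) -> list[DerivatizationSeries]:
    """Match each native peak to a derivatization series.

    For every native peak, each candidate cysteine count is chained
    through the reduced, alkylated and (optionally) linearized lists; the
    count minimizing the total absolute step deviation wins.  No
    companion peak is claimed by two series: conflicts are resolved in
    favor of the series with the smaller total deviation, then the lower
    native m/z.  Each native peak yields at most one series.
    """
    _check_labels([native, reduced, alkylated, linearized])
    if linearized is None and params.require_linearized:
        # permissible: series can still be emitted, classified incomplete
        pass
    lists = (reduced, alkylated, linearized)

    # candidate series per native peak, all viable n, best n first
    per_native: dict[int, list[tuple[float, float, int, int, tuple, list]]] = {}
    for ni in range(len(native)):
        nat_mz = float(native.mz[ni])
        cands = []
        for n in sorted(params.cys_candidates):
            got = _chain(nat_mz, n, lists, params)
            if got is None:
                continue
            claims, (r_mz, a_mz, l_mz, devs) = got
            total = sum(abs(d) for d in devs if d is not None)
            cands.append((total, nat_mz, n, ni, (r_mz, a_mz, l_mz, devs), claims))
        if cands:
            cands.sort(key=lambda c: (c[0], c[2]))
            per_native[ni] = cands

    # global greedy by (total deviation, native m/z, n) over each native's
    # current best candidate; a native whose chain is blocked by an
    # already-claimed companion peak falls back to its next-best n
    heap: list[tuple[float, float, int, int, int]] = []
    for ni, cands in per_native.items():
        total, nat_mz, n, _, _, _ = cands[0]
        heapq.heappush(heap, (total, nat_mz, n, ni, 0))
    claimed: set[tuple[int, int]] = set()
    accepted: list[DerivatizationSeries] = []
    while heap:
        total, nat_mz, n, ni, idx = heapq.heappop(heap)
        _, _, _, _, (r_mz, a_mz, l_mz, devs), claims = per_native[ni][idx]
        if any(c in claimed for c in claims):
            if idx + 1 < len(per_native[ni]):
                nxt = per_native[ni][idx + 1]
                heapq.heappush(heap, (nxt[0], nxt[1], nxt[2], ni, idx + 1))
            continue
        claimed.update(claims)
        if n == 6 and l_mz is not None:
            cls: Classification = "six_cys_cyclic"
        elif n == 6:
            cls = "incomplete"
        else:
            cls = "cys_rich_other"
        accepted.append(
            DerivatizationSeries(
                native_mz=nat_mz,
                reduced_mz=r_mz,
                alkylated_mz=a_mz,
                linearized_mz=l_mz,
                inferred_n_cys=n,
                step_deviations=devs,
                classification=cls,
            )
        )
    accepted.sort(key=lambda s: s.native_mz)
    if linearized is not None:
        _flag_internal_fragments(accepted, linearized, params, claimed)
    return accepted


def _flag_internal_fragments(
    series_list: list[DerivatizationSeries],
    linearized: PeakList,
    params: ScreenParams,
    claimed: set[tuple[int, int]],
) -> None:
    """Flag series whose linearized list holds extra peaks explainable as
    two-cut internal GluC fragments of the alkylated mass.

    A single conserved Glu yields only the +18 Da ring-opened product; a
    pair of unclaimed peaks whose masses reassemble the alkylated peptide
    (sum of neutral masses = alkylated neutral mass + 2 waters, i.e. two
    hydrolysis events) points at additional cleavage sites.
    """
    unclaimed = [
        float(linearized.mz[i])
        for i in range(len(linearized))
        if (3, i) not in claimed
    ]
    if not unclaimed:
        return
    for s in series_list:
        target = s.alkylated_mz + PROTON + 2.0 * WATER  # a+b in [M+H]+ space
        tol = (
            params.tolerance_value
            if params.tolerance_mode == "dalton"
            else params.tolerance_value * 1e-6 * target
        )
        for i, a in enumerate(unclaimed):
            for b in unclaimed[i:]:
                if abs((a + b) - target) <= 2 * tol:
                    s.internal_fragment_flag = True
                    break
            if s.internal_fragment_flag:
                break


def screen_report(
    series_list: Sequence[DerivatizationSeries],
    params: ScreenParams = ScreenParams(),
) -> dict:
    """Machine-readable summary of a screening run."""
    counts = {"six_cys_cyclic": 0, "cys_rich_other": 0, "incomplete": 0}
    for s in series_list:
        counts[s.classification] += 1
    ordered = sorted(series_list, key=lambda s: s.native_mz)
    return {
        "n_series": len(ordered),
        "counts": counts,
        "params": {
            "tolerance_mode": params.tolerance_mode,
            "tolerance_value": params.tolerance_value,
            "cys_candidates": sorted(params.cys_candidates),
            "require_linearized": params.require_linearized,
            "chaining": params.chaining,
        },
        "series": [s.to_dict() for s in ordered],
    }
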