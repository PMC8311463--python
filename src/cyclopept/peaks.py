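"""A thin centroided peak-list container shared by screening, digestion
matching and MS/MS annotation."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .errors import FormatError

__all__ = ["PeakList", "SCREEN_LABELS"]

#: The four derivatization states matched by the screening workflow.
SCREEN_LABELS = ("native", "reduced", "alkylated", "linearized")


@dataclass
class PeakList:
    """Centroided (m/z, intensity) peaks, sorted ascending by m/z.

    ``label`` names the sample state: one of :data:`SCREEN_LABELS` for the
    derivatization screen, or any descriptive string (e.g. ``"msms"``).
    Duplicate m/z values (within 1e-6) are rejected.
    """

    mz: np.ndarray
    intensity: np.ndarray
    label: str = "peaks"
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.mz = np.asarray(self.mz, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.mz.ndim != 1 or self.mz.shape != self.intensity.shape:
            raise FormatError("mz and intensity must be 1-D arrays of equal length")
        if np.any(self.mz <= 0):
            raise FormatError("all m/z values must be > 0")
        if np.any(self.intensity < 0):
            raise FormatError("intensities must be >= 0")
        order = np.argsort(self.mz, kind="stable")
        self.mz = self.mz[order]
        self.intensity = self.intensity[order]
        if self.mz.size > 1 and np.any(np.diff(self.mz) < 1e-6):
            raise FormatError("duplicate m/z values (within 1e-6) in peak list")

    @classmethod
    def from_pairs(
        cls,
        pairs: Iterable[tuple[float, float]] | Sequence[float],
        label: str = "peaks",
    ) -> "PeakList":
        """Build from (m/z, intensity) pairs or bare m/z values
        (intensity defaults to 1.0)."""
        pairs = list(pairs)
        if pairs and not isinstance(pairs[0], (tuple, list, np.ndarray)):
            mz = np.asarray(pairs, dtype=float)
            inten = np.ones_like(mz)
        else:
            mz = np.array([p[0] for p in pairs], dtype=float)
            inten = np.array([p[1] for p in pairs], dtype=float)
        return cls(mz=mz, intensity=inten, label=label)

    def __len__(self) -> int:
        return int(self.mz.size)

    def nearest(self, target: float) -> tuple[int, float]:
        """Index and m/z of the peak closest to ``target``.

        Exact distance ties break toward the lower m/z peak.
        """
        if len(self) == 0:
            raise FormatError("empty peak list has no nearest peak")
        i = int(np.searchsorted(self.mz, target))
        best = None
        for j in (i - 1, i):
            if 0 <= j < len(self):
                d = abs(self.mz[j] - target)
                if best is None or d < best[0] - 1e-12:
                    best = (d, j)
        return best[1], float(self.mz[best[1]])
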