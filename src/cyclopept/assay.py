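"""Enzyme-activity analytics: percent-activity normalization,
Michaelis-Menten kinetics and four-parameter logistic (4PL)
concentration-response fits.

The inhibition readout is percent remaining protease activity,
``I = 100 * vi / vo`` (initial velocity with sample over enzyme-alone
velocity, both background-corrected).  Concentration-response curves are
fitted with the 4PL model

    Y = Bottom + (Top - Bottom) / (1 + 10**((LogIC50 - X) * HillSlope))

with X the log10 concentration and Y the response; remaining-activity
curves have negative Hill slopes under this parameterization.  Fits use
:func:`scipy.optimize.curve_fit` (Levenberg-Marquardt / trust region
least squares) on replicate means by default.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from .errors import FitError

__all__ = [
    "ActivityMeasurement",
    "KineticsFit",
    "DoseResponseFit",
    "percent_activity",
    "michaelis_menten",
    "four_pl",
    "fit_michaelis_menten",
    "fit_4pl",
    "normalize_responses",
]


@dataclass(frozen=True)
class ActivityMeasurement:
    """Initial velocities with sample (vi) and enzyme alone (vo), plus an
    optional substrate-only background subtracted from both."""

    vi: float
    vo: float
    background: float = 0.0


def percent_activity(m: ActivityMeasurement) -> float:
    """Percent remaining enzyme activity, I = 100 * vi / vo."""
    vi = m.vi - m.background
    vo = m.vo - m.background
    if vo <= 0:
        raise FitError("enzyme-alone velocity must be > 0 after background correction")
    return 100.0 * vi / vo


def michaelis_menten(S, Vmax: float, Km: float):
    """v = Vmax * S / (Km + S)."""
    S = np.asarray(S, dtype=float)
    return Vmax * S / (Km + S)


def four_pl(X, bottom: float, top: float, log_ic50: float, hill: float):
    """Y = Bottom + (Top - Bottom) / (1 + 10**((LogIC50 - X) * Hill))."""
    X = np.asarray(X, dtype=float)
    return bottom + (top - bottom) / (1.0 + 10.0 ** ((log_ic50 - X) * hill))


@dataclass
class KineticsFit:
    Km: float
    Vmax: float
    se_Km: float
    se_Vmax: float
    residuals: np.ndarray
    converged: bool


@dataclass
class DoseResponseFit:
    log_ic50: float
    ic50: float
    hill_slope: float
    top: float
    bottom: float
    se: dict = field(default_factory=dict)
    residuals: np.ndarray = field(default_factory=lambda: np.empty(0))
    converged: bool = True

    def to_dict(self) -> dict:
        return {
            "log_ic50": self.log_ic50,
            "ic50": self.ic50,
            "hill_slope": self.hill_slope,
            "top": self.top,
            "bottom": self.bottom,
            "se": self.se,
            "converged": self.converged,
        }


def fit_michaelis_menten(S: Sequence[float], v: Sequence[float]) -> KineticsFit:
    """Least-squares Michaelis-Menten fit of velocity vs. substrate."""
    S = np.asarray(S, dtype=float)
    v = np.asarray(v, dtype=float)
    if S.shape != v.shape or S.ndim != 1:
        raise FitError("S and v must be 1-D arrays of equal length")
    if len(np.unique(S)) < 4:
        raise FitError("need at least 4 distinct substrate concentrations")
    if np.any(v < 0) or np.any(S < 0) or np.any(~np.isfinite(S)) or np.any(~np.isfinite(v)):
        raise FitError("S and v must be finite and nonnegative")
    if np.all(v == 0):
        raise FitError("all velocities are zero")
    # rescale velocities to O(1) so curve_fit's stopping criteria behave
    # for raw-signal units that may be ~1e-4
    scale = float(v.max())
    vs = v / scale
    km0 = float(S[np.argmin(np.abs(vs - vs.max() / 2.0))])
    p0 = [1.2, km0]
    converged = True
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            popt, pcov = curve_fit(
                michaelis_menten, S, vs, p0=p0, bounds=([0, 0], [np.inf, np.inf]),
                maxfev=10000,
            )
    except RuntimeError:
        popt, pcov = np.array(p0), np.full((2, 2), np.inf)
        converged = False
    popt = np.array([popt[0] * scale, popt[1]])
    pcov = np.array(pcov) * np.array([[scale**2, scale], [scale, 1.0]])
    se = np.sqrt(np.diag(pcov))
    if not np.all(np.isfinite(se)):
        converged = False
    resid = v - michaelis_menten(S, *popt)
    return KineticsFit(
        Km=float(popt[1]),
        Vmax=float(popt[0]),
        se_Km=float(se[1]),
        se_Vmax=float(se[0]),
        residuals=resid,
        converged=converged,
    )


def fit_4pl(
    X: Sequence[float],
    Y: Sequence[float],
    replicate_means: bool = True,
) -> DoseResponseFit:
    """Four-parameter logistic fit of response vs. log10 concentration.

    ``X`` may contain repeated values (replicates); by default the fit is
    ordinary least squares on replicate means.  Initial values: Top =
    max(Y), Bottom = min(Y), LogIC50 = X nearest the half response,
    Hill = -1; the Hill slope is bounded to [-10, 10].  The returned fit
    is normalized so bottom <= top (the 4PL is invariant under swapping
    top/bottom with a sign flip of the Hill slope).
    """
    X = np.asarray(X, dtype=float)
    Y = np.asarray(Y, dtype=float)
    if X.shape != Y.shape or X.ndim != 1:
        raise FitError("X and Y must be 1-D arrays of equal length")
    if np.any(~np.isfinite(X)) or np.any(~np.isfinite(Y)):
        raise FitError("NaN/inf in dose-response input")
    if replicate_means:
        df = pd.DataFrame({"X": X, "Y": Y}).groupby("X", as_index=False).mean()
        X, Y = df["X"].to_numpy(), df["Y"].to_numpy()
    if len(np.unique(X)) < 5:
        raise FitError("need at least 5 distinct concentrations")

    top0, bot0 = float(Y.max()), float(Y.min())
    mid = (top0 + bot0) / 2.0
    log_ic50_0 = float(X[np.argmin(np.abs(Y - mid))])
    p0 = [bot0, top0, log_ic50_0, -1.0]
    lb = [-np.inf, -np.inf, -np.inf, -10.0]
    ub = [np.inf, np.inf, np.inf, 10.0]
    converged = True
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            popt, pcov = curve_fit(
                four_pl, X, Y, p0=p0, bounds=(lb, ub), maxfev=20000
            )
    except RuntimeError:
        popt, pcov = np.array(p0), np.full((4, 4), np.inf)
        converged = False
    bottom, top, log_ic50, hill = (float(x) for x in popt)
    se_vec = np.sqrt(np.diag(pcov))
    if bottom > top:  # canonical orientation
        bottom, top, hill = top, bottom, -hill
        se_vec = se_vec[[1, 0, 2, 3]]
    if not np.all(np.isfinite(se_vec)):
        converged = False
    # degenerate designs: a flat fitted curve, or a transition the dosed
    # range never brackets, carry no information about the IC50
    if abs(top - bottom) < 1e-9 * max(1.0, abs(top), abs(bottom)):
        converged = False
    if not (X.min() <= log_ic50 <= X.max()):
        converged = False
    resid = Y - four_pl(X, bottom, top, log_ic50, hill)
    se = {
        "bottom": float(se_vec[0]),
        "top": float(se_vec[1]),
        "log_ic50": float(se_vec[2]),
        "hill_slope": float(se_vec[3]),
    }
    return DoseResponseFit(
        log_ic50=log_ic50,
        ic50=float(10.0 ** log_ic50),
        hill_slope=hill,
        top=top,
        bottom=bottom,
        se=se,
        residuals=resid,
        converged=converged,
    )


def normalize_responses(
    raw: pd.DataFrame,
    mode: str = "to_max_response",
    control: Optional[str] = "control",
) -> pd.DataFrame:
    """Rescale a response table to percent.

    ``to_enzyme_control`` divides by the mean of the ``control`` column
    (enzyme-alone signal) times 100; ``to_max_response`` rescales so the
    maximum normalized response is 100.  The mode is recorded in
    ``DataFrame.attrs['normalization']``.
    """
    if "response" not in raw.columns:
        raise FitError("table must have a 'response' column")
    out = raw.copy()
    if mode == "to_enzyme_control":
        if control not in raw.columns:
            raise FitError(f"mode 'to_enzyme_control' needs a {control!r} column")
        c = float(raw[control].mean())
        if c <= 0:
            raise FitError("nonpositive enzyme control mean")
        out["response_norm"] = raw["response"] / c * 100.0
    elif mode == "to_max_response":
        m = float(raw["response"].max())
        if m <= 0:
            raise FitError("nonpositive maximum response")
        out["response_norm"] = raw["response"] / m * 100.0
    else:
        raise FitError(f"unknown normalization mode {mode!r}")
    out.attrs["normalization"] = mode
    return out
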