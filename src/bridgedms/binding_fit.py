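"""One-site saturation binding analysis for whole-cell radioligand data.

The model is the single-site hyperbola

    y(L) = Bmax * L / (Kd + L)

with ``L`` the free ligand concentration (nM), ``Kd`` the equilibrium
dissociation constant (nM) and ``Bmax`` the maximal specific binding in
the response units of the instrument (counts per minute for a
scintillation counter).  Specific signal is the raw signal minus a
matched empty-vector negative control measured at the same
concentrations.

Fitting is weighted nonlinear least squares.  "Instrumental" weighting
uses ``w_i = 1 / max(y_i, eps)^2`` — i.e. a per-point standard deviation
proportional to the signal — which matches the counting-statistics
behaviour of scintillation measurements; explicit per-point standard
deviations take precedence when supplied.  Standard errors come from the
curvature (covariance) of the weighted fit.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import curve_fit

__all__ = [
    "BindingDataset",
    "BindingFit",
    "one_site",
    "specific_signal",
    "fit_one_site",
    "fold_change",
]


def one_site(L, bmax, kd):
    """Specific binding of the one-site model, y = Bmax*L/(Kd+L)."""
    L = np.asarray(L, dtype=float)
    return bmax * L / (kd + L)


@dataclass(frozen=True)
class BindingDataset:
    """Raw saturation-binding measurements with their negative control.

    ``signal`` and ``background`` are arrays over concentrations; a
    second axis, if present, holds replicates.
    """

    concentrations: np.ndarray
    signal: np.ndarray
    background: np.ndarray

    def __post_init__(self) -> None:
        conc = np.asarray(self.concentrations, dtype=float)
        if np.any(conc < 0):
            raise ValueError("ligand concentrations must be non-negative")
        if len(np.unique(conc)) < 4:
            raise ValueError("need at least 4 distinct concentrations")
        sig = np.asarray(self.signal, dtype=float)
        bg = np.asarray(self.background, dtype=float)
        if sig.shape != bg.shape or sig.shape[0] != conc.shape[0]:
            raise ValueError("signal and background must match the concentrations")
        object.__setattr__(self, "concentrations", conc)
        object.__setattr__(self, "signal", sig)
        object.__setattr__(self, "background", bg)


@dataclass(frozen=True, slots=True)
class BindingFit:
    """Fitted one-site parameters with curvature standard errors."""

    kd: float
    bmax: float
    kd_se: float
    bmax_se: float
    weighting: str

    def predict(self, L):
        return one_site(L, self.bmax, self.kd)


def specific_signal(ds: BindingDataset) -> tuple[np.ndarray, np.ndarray]:
    """Background-subtracted responses plus a negative-value flag mask.

    Negative values are retained, not clipped — clipping would bias the
    low-concentration tail upward — but flagged for inspection.
    """
    net = ds.signal - ds.background
    return net, net < 0


def fit_one_site(
    concentrations,
    responses,
    sigma=None,
    weighting: str = "instrumental",
) -> BindingFit:
    """Weighted least-squares fit of the one-site saturation model.

    ``sigma`` (per-point standard deviations) switches to explicit
    weighting when given; otherwise ``weighting`` selects
    ``"instrumental"`` (sd proportional to signal) or ``"none"``
    (unweighted).  At least 4 points are required and the response must
    not be identically zero.
    """
    L = np.asarray(concentrations, dtype=float).ravel()
    y = np.asarray(responses, dtype=float).ravel()
    if L.shape != y.shape:
        raise ValueError("concentrations and responses differ in length")
    if L.size < 4:
        raise ValueError(f"under-determined fit: {L.size} points (need >= 4)")
    if not np.any(y > 0):
        raise ValueError("all responses are <= 0; nothing to fit")

    if sigma is not None:
        sd = np.asarray(sigma, dtype=float).ravel()
        mode = "explicit"
    elif weighting == "instrumental":
        eps = float(np.min(y[y > 0]))
        sd = np.maximum(y, eps)
        mode = "instrumental"
    elif weighting == "none":
        sd = None
        mode = "none"
    else:
        raise ValueError(f"unknown weighting {weighting!r}")

    bmax0 = float(np.max(y))
    kd0 = float(L[np.argmin(np.abs(y - bmax0 / 2.0))])
    if kd0 <= 0:
        kd0 = float(np.median(L[L > 0]))
    try:
        popt, pcov = curve_fit(
            one_site,
            L,
            y,
            p0=[bmax0, kd0],
            sigma=sd,
            absolute_sigma=False,
            bounds=([0.0, 0.0], [np.inf, np.inf]),
            maxfev=10000,
        )
    except RuntimeError as exc:
        raise RuntimeError(f"one-site fit did not converge: {exc}") from exc
    bmax, kd = popt
    if not (kd > 0 and bmax > 0) or not np.all(np.isfinite(popt)):
        raise RuntimeError(f"degenerate fit: Kd={kd}, Bmax={bmax}")
    se = np.sqrt(np.diag(pcov))
    return BindingFit(
        kd=float(kd),
        bmax=float(bmax),
        kd_se=float(se[1]),
        bmax_se=float(se[0]),
        weighting=mode,
    )


def fold_change(a: float, b: float, decimals: int = 1) -> float:
    """Ratio a/b rounded to the requested number of decimals."""
    if b == 0:
        raise ZeroDivisionError("fold change against zero is undefined")
    return round(a / b, decimals)
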