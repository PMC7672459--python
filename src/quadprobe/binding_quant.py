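"""Binding quantitation: two-population EMSA isotherm, ddCt, pull-down.

The EMSA model assumes two G4 subpopulations, each binding the probe
with 1:1 stoichiometry:

    Y = F1 * X / (Kd1 + X) + (1 - F1) * X / (Kd2 + X)

with Y the fractional bound DNA, X the free probe concentration (molar),
F1 the fraction of the subpopulation governed by Kd1. Fits are reported
with Kd1 <= Kd2; when the two constants coincide (or Kd2 exceeds 1 M)
the fit collapses to a single-Kd one-site model and is flagged
degenerate.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy.optimize import least_squares

KD_BOUNDS = (1e-12, 10.0)  # molar
DEGENERACY_LOG10_TOL = 0.05
DEGENERACY_KD2_CAP = 1.0  # molar: "or the other is > 1 M"


@dataclass
class BindingSeries:
    """An EMSA titration: free probe concentrations X and bound fractions Y.

    X must be non-negative and strictly ascending with at least 4 points;
    Y values outside [0, 1] are clipped on load and flagged.
    """

    X: np.ndarray
    Y: np.ndarray
    clipped: bool = False

    @classmethod
    def from_arrays(cls, X, Y) -> "BindingSeries":
        X = np.asarray(X, dtype=float)
        Y = np.asarray(Y, dtype=float)
        if X.shape != Y.shape or X.ndim != 1:
            raise ValueError("X and Y must be 1-D arrays of equal length")
        if len(X) < 4:
            raise ValueError("a titration needs at least 4 points")
        if (X < 0).any():
            raise ValueError("concentrations must be non-negative")
        if (np.diff(X) <= 0).any():
            raise ValueError("concentrations must be strictly ascending")
        clipped = bool((Y < 0).any() or (Y > 1).any())
        return cls(X, np.clip(Y, 0.0, 1.0), clipped)


@dataclass
class BindingFit:
    """Fitted two-population parameters with canonical ordering Kd1 <= Kd2."""

    Kd1: float
    Kd2: float
    F1: float
    rss: float
    degenerate: bool

    @property
    def Kd(self) -> float:
        """The single reported Kd for a degenerate (one-site) fit."""
        return self.Kd1


def predict_bound(fit, X) -> np.ndarray:
    """Fractional bound DNA at free probe concentration X (scalar or array)."""
    X = np.asarray(X, dtype=float)
    if (X < 0).any():
        raise ValueError("concentrations must be non-negative")
    kd1, kd2, f1 = fit.Kd1, fit.Kd2, fit.F1
    with np.errstate(invalid="ignore"):
        y = f1 * X / (kd1 + X) + (1.0 - f1) * X / (kd2 + X)
    return y


def _fit_once(X, Y, f1_0, k1_0, k2_0):
    """One bounded least-squares run in (F1, log10 Kd1, log10 Kd2) space."""
    lo, hi = math.log10(KD_BOUNDS[0]), math.log10(KD_BOUNDS[1])

    def residuals(p):
        f1, lk1, lk2 = p
        y = f1 * X / (10.0 ** lk1 + X) + (1 - f1) * X / (10.0 ** lk2 + X)
        return y - Y

    res = least_squares(
        residuals,
        x0=[f1_0, math.log10(k1_0), math.log10(k2_0)],
        bounds=([0.0, lo, lo], [1.0, hi, hi]),
        method="trf",
    )
    return res.x, float(np.sum(res.fun**2))


def _fit_one_site(X, Y):
    lo, hi = math.log10(KD_BOUNDS[0]), math.log10(KD_BOUNDS[1])

    def residuals(p):
        return X / (10.0 ** p[0] + X) - Y

    best = None
    for k0 in np.geomspace(max(X[X > 0].min(), KD_BOUNDS[0]), X.max(), 7):
        res = least_squares(residuals, x0=[math.log10(k0)], bounds=([lo], [hi]), method="trf")
        rss = float(np.sum(res.fun**2))
        if best is None or rss < best[1]:
            best = (10.0 ** res.x[0], rss)
    return best


def fit_two_site(
    series: BindingSeries,
    starts: Optional[Sequence] = None,
    degeneracy_log10_tol: float = DEGENERACY_LOG10_TOL,
) -> BindingFit:
    """Fit the two-population isotherm by multi-start nonlinear least squares.

    Starts default to a grid of F1 in {0.25, 0.5, 0.75} crossed with Kd
    pairs log-spaced over the observed concentration range; the best-RSS
    solution is kept and canonically ordered (Kd1 <= Kd2). If the two
    constants agree within ``degeneracy_log10_tol`` in log10, or Kd2
    exceeds 1 M, the fit is refit as a one-site model and flagged
    degenerate (the single-Kd reporting rule).
    """
    X, Y = series.X, series.Y
    if not (Y > 0).any():
        raise ValueError("all-zero bound fractions cannot be fitted")
    if starts is None:
        pos = X[X > 0]
        kgrid = np.geomspace(max(pos.min() / 10, KD_BOUNDS[0]), pos.max() * 10, 5)
        starts = [
            (f1, k1, k2)
            for f1 in (0.25, 0.5, 0.75)
            for i, k1 in enumerate(kgrid)
            for k2 in kgrid[i:]
        ]
    best = None
    for f1_0, k1_0, k2_0 in starts:
        params, rss = _fit_once(X, Y, f1_0, k1_0, k2_0)
        if best is None or rss < best[1]:
            best = (params, rss)
    (f1, lk1, lk2), rss = best
    kd1, kd2 = 10.0 ** lk1, 10.0 ** lk2
    if kd1 > kd2:
        kd1, kd2 = kd2, kd1
        f1 = 1.0 - f1
    if abs(math.log10(kd2) - math.log10(kd1)) < degeneracy_log10_tol or kd2 > DEGENERACY_KD2_CAP:
        kd, rss1 = _fit_one_site(X, Y)
        return BindingFit(Kd1=kd, Kd2=kd, F1=1.0, rss=rss1, degenerate=True)
    return BindingFit(Kd1=kd1, Kd2=kd2, F1=f1, rss=rss, degenerate=False)


@dataclass(frozen=True)
class CtQuad:
    """The four qPCR cycle numbers of one ddCt measurement.

    The reference amplicon is a PQS-negative region; "chip" denotes the
    pulled-down sample and "input" the pre-pulldown chromatin.
    """

    ct_chip_target: float
    ct_chip_ref: float
    ct_input_target: float
    ct_input_ref: float

    def __post_init__(self) -> None:
        for v in (self.ct_chip_target, self.ct_chip_ref, self.ct_input_target, self.ct_input_ref):
            if not np.isfinite(v) or v <= 0:
                raise ValueError("Ct values must be finite and positive")


def ddct_enrichment(q: CtQuad, efficiency: float = 2.0) -> float:
    """Fold enrichment by the double-delta-Ct method.

    fold = E ** -[(Ct_chip_target - Ct_chip_ref) - (Ct_input_target - Ct_input_ref)]

    with amplification efficiency E (2.0 = perfect doubling per cycle).
    """
    if not (1.0 < efficiency <= 2.0):
        raise ValueError("efficiency must be in (1, 2]")
    ddct = (q.ct_chip_target - q.ct_chip_ref) - (q.ct_input_target - q.ct_input_ref)
    return float(efficiency ** -ddct)


def pulldown_enrichment(
    q_target_pulldown: float,
    q_ref_pulldown: float,
    q_target_input: float,
    q_ref_input: float,
    normalizer: float,
) -> float:
    """Internal-control-calibrated pull-down fold enrichment.

    The target quantity is first calibrated against the co-precipitated
    reference plasmid, then referenced to the same ratio in the input,
    and finally normalized to the identical ratio measured for the
    mutant-motif control (``normalizer``).
    """
    for name, v in {
        "q_ref_pulldown": q_ref_pulldown,
        "q_target_input": q_target_input,
        "q_ref_input": q_ref_input,
        "normalizer": normalizer,
    }.items():
        if v == 0:
            raise ZeroDivisionError(f"{name} must be non-zero")
    return ((q_target_pulldown / q_ref_pulldown) / (q_target_input / q_ref_input)) / normalizer
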