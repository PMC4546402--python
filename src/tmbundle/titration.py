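"""FRET titration Kd fitting and DOSY hydrodynamic radius.

Binding is modelled as a 1:1 association with the exact quadratic
isotherm (no weak-binding approximation): at total donor and acceptor
concentrations D and A with dissociation constant Kd, the complex
concentration is the smaller root of

    [DA]^2 - (D + A + Kd) [DA] + D A = 0.

The observable is a donor/acceptor emission ratio, linear in the bound
donor fraction between ``r_free`` (no complex) and ``r_bound``
(saturation).  Homo-dimer titrations reuse the same functional form on
the labelled/unlabelled pools.

DOSY: the hydrodynamic radius follows from the translational diffusion
coefficient via Stokes-Einstein, R_h = k_B T / (6 pi eta D_tr).  The
default viscosity is that of water at 298 K (0.890 mPa s) — NOT of an
SDS/D2O micelle buffer; always supply the solvent viscosity actually
used when accuracy matters.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import least_squares
from sklearn.base import BaseEstimator, RegressorMixin

BOLTZMANN = 1.380649e-23  # J/K
WATER_VISCOSITY_298K = 0.890e-3  # Pa s


class NonIdentifiableFitError(ValueError):
    """The titration data do not constrain the binding parameters."""


def binding_model(kd: float, d_total, a_total, r_free: float, r_bound: float):
    """Predicted emission ratio(s) for a 1:1 binding titration.

    ``a_total`` may be scalar or array (same units as ``d_total`` and
    ``kd``, conventionally uM).  The ratio interpolates linearly between
    ``r_free`` and ``r_bound`` with the bound donor fraction.
    """
    a_total = np.asarray(a_total, float)
    if kd <= 0:
        raise ValueError("Kd must be positive")
    if d_total <= 0:
        raise ValueError("donor concentration must be positive")
    if np.any(a_total < 0):
        raise ValueError("concentrations must be non-negative")
    b = d_total + a_total + kd
    complex_conc = (b - np.sqrt(b * b - 4.0 * d_total * a_total)) / 2.0
    frac_bound = complex_conc / d_total
    out = r_free + (r_bound - r_free) * frac_bound
    return out if out.ndim else float(out)


@dataclass
class BindingFit:
    """Fitted 1:1 binding parameters with standard errors."""

    kd: float
    r_free: float
    r_bound: float
    kd_stderr: float
    r_free_stderr: float
    r_bound_stderr: float
    covariance: np.ndarray
    residual_norm: float

    def predict(self, d_total, a_total):
        return binding_model(self.kd, d_total, a_total, self.r_free, self.r_bound)


class KdFit(RegressorMixin, BaseEstimator):
    """sklearn-style estimator for the 1:1 titration isotherm.

    ``fit(X, y)`` takes titrant concentrations ``X`` (shape (n,) or
    (n, 1)) and observed emission ratios ``y`` at a fixed partner
    concentration ``d_total``.  Nonlinear least squares over
    (Kd, r_free, r_bound), multi-started over Kd decades to avoid local
    minima.  Fitted attributes: ``kd_``, ``r_free_``, ``r_bound_``,
    ``stderr_``, ``fit_``.
    """

    def __init__(self, d_total: float = 50.0, kd_starts=(1.0, 10.0, 100.0, 1000.0)):
        self.d_total = d_total
        self.kd_starts = kd_starts

    def fit(self, X, y, sample_weight=None):
        conc = np.asarray(X, float).reshape(-1)
        ratio = np.asarray(y, float).reshape(-1)
        if conc.shape != ratio.shape:
            raise ValueError("concentration and ratio arrays differ in length")
        if len(conc) < 4:
            raise ValueError("Kd fitting needs at least 4 titration points")
        if np.any(conc < 0):
            raise ValueError("concentrations must be non-negative")
        if np.ptp(ratio) < 1e-12:
            raise NonIdentifiableFitError(
                "titration response is flat; binding parameters are not identifiable"
            )
        err = None
        if sample_weight is not None:
            err = 1.0 / np.sqrt(np.asarray(sample_weight, float))

        def residuals(x):
            pred = binding_model(x[0], self.d_total, conc, x[1], x[2])
            res = pred - ratio
            return res / err if err is not None else res

        r_lo, r_hi = float(ratio.min()), float(ratio.max())
        span = r_hi - r_lo
        best = None
        for kd0 in self.kd_starts:
            x0 = np.array([kd0, ratio[np.argmin(conc)], ratio[np.argmax(conc)]])
            sol = least_squares(
                residuals, x0,
                bounds=([1e-9, r_lo - 10 * span - 1.0, r_lo - 10 * span - 1.0],
                        [1e9, r_hi + 10 * span + 1.0, r_hi + 10 * span + 1.0]),
                xtol=1e-14, ftol=1e-14,
            )
            if best is None or sol.cost < best.cost:
                best = sol
        cov, stderr = _covariance(best, n_obs=len(conc))
        self.kd_, self.r_free_, self.r_bound_ = (float(v) for v in best.x)
        self.stderr_ = stderr
        self.fit_ = BindingFit(
            self.kd_, self.r_free_, self.r_bound_,
            stderr[0], stderr[1], stderr[2], cov,
            float(np.linalg.norm(best.fun)),
        )
        return self

    def predict(self, X):
        conc = np.asarray(X, float).reshape(-1)
        return binding_model(self.kd_, self.d_total, conc, self.r_free_, self.r_bound_)


def fit_kd(dataset: pd.DataFrame, d_total: float = 50.0) -> BindingFit:
    """Fit a 1:1 binding isotherm to a titration table.

    ``dataset`` needs columns ``conc_uM`` and ``ratio`` (optional
    ``err``); point order is irrelevant.
    """
    for col in ("conc_uM", "ratio"):
        if col not in dataset.columns:
            raise ValueError(f"titration table missing column {col!r}")
    weights = None
    if "err" in dataset.columns and (dataset["err"] > 0).all():
        weights = 1.0 / dataset["err"].to_numpy(float) ** 2
    est = KdFit(d_total=d_total).fit(
        dataset["conc_uM"].to_numpy(float), dataset["ratio"].to_numpy(float),
        sample_weight=weights,
    )
    return est.fit_


def _covariance(sol, n_obs: int):
    """Gauss-Newton covariance of a least_squares solution."""
    n_par = len(sol.x)
    dof = max(n_obs - n_par, 1)
    s_sq = 2.0 * sol.cost / dof
    jtj = sol.jac.T @ sol.jac
    try:
        cov = np.linalg.inv(jtj) * s_sq
        stderr = np.sqrt(np.clip(np.diag(cov), 0.0, None))
    except np.linalg.LinAlgError:
        cov = np.full((n_par, n_par), np.nan)
        stderr = np.full(n_par, np.nan)
    return cov, stderr


def hydrodynamic_radius(d_tr: float, temperature: float = 303.0,
                        viscosity: float | None = None) -> float:
    """Stokes-Einstein hydrodynamic radius (meters).

    Parameters: translational diffusion coefficient ``d_tr`` (m^2/s),
    ``temperature`` (K) and the solvent ``viscosity`` (Pa s).  When the
    viscosity is omitted the water value at 298 K is used and a warning
    is emitted — micellar D2O buffers are substantially more viscous.
    """
    if viscosity is None:
        warnings.warn(
            "no viscosity given; using water at 298 K (0.890 mPa s), which "
            "underestimates R_h in D2O/SDS buffers",
            stacklevel=2,
        )
        viscosity = WATER_VISCOSITY_298K
    if d_tr <= 0 or temperature <= 0 or viscosity <= 0:
        raise ValueError("d_tr, temperature and viscosity must be positive")
    return BOLTZMANN * temperature / (6.0 * np.pi * viscosity * d_tr)
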