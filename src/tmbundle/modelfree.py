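"""Isotropic Lipari-Szabo model-free analysis of 15N backbone relaxation.

The spectral density of an N-H bond vector under isotropic overall
tumbling (correlation time tau_m) with fast internal motion (order
parameter S^2, internal correlation time tau_e) is

    J(w) = (2/5) [ S^2 tau_m / (1 + (w tau_m)^2)
                   + (1 - S^2) tau / (1 + (w tau)^2) ],
    1/tau = 1/tau_m + 1/tau_e.

R1, R2 and the steady-state {1H}-15N NOE follow from the standard
dipolar + CSA expressions.  The overall correlation time is extracted
from R2/R1 ratios (which are insensitive to S^2 for fast internal
motion) and then refined jointly with the per-residue (S^2, tau_e) by
least squares.  No conformational-exchange (R_ex) term is included.

Physical constants (r_NH = 1.02 A, 15N CSA = -160 ppm, standard
gyromagnetic ratios) are module-level and may be overridden per call
via an :class:`NMRConstants` instance.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import brentq, least_squares
from sklearn.base import BaseEstimator


@dataclass(frozen=True)
class NMRConstants:
    """Physical constants of the 15N relaxation expressions (SI units)."""

    gamma_h: float = 2.6752218744e8  # rad/s/T
    gamma_n: float = -2.7126189e7  # rad/s/T (negative for 15N)
    r_nh: float = 1.02e-10  # m
    csa_n: float = -160e-6  # 15N chemical shift anisotropy
    hbar: float = 1.054571817e-34  # J s
    mu0_4pi: float = 1e-7  # T m / A

    @property
    def d_dipolar(self) -> float:
        """Dipolar coupling constant d (rad/s)."""
        return self.mu0_4pi * self.hbar * self.gamma_h * abs(self.gamma_n) \
            / self.r_nh ** 3

    def omega(self, field: float):
        """Angular frequencies (wH, wN) at a field in Tesla (rad/s)."""
        return self.gamma_h * field, self.gamma_n * field


CONSTANTS = NMRConstants()


@dataclass(frozen=True)
class ModelFreeParams:
    """One residue's dynamics parameters."""

    s2: float  # order parameter, [0, 1]
    tau_e: float  # internal correlation time, s
    tau_m: float  # overall rotational correlation time, s

    def __post_init__(self):
        if not 0.0 <= self.s2 <= 1.0:
            raise ValueError("S^2 must be in [0, 1]")
        if self.tau_m <= 0 or self.tau_e < 0:
            raise ValueError("correlation times must be positive")


def spectral_density(s2: float, tau_e: float, tau_m: float, omega) -> np.ndarray:
    """Model-free spectral density J(omega) in s/rad (isotropic tumbling).

    ``omega`` may be scalar or array (rad/s); J is even in omega.
    """
    omega = np.asarray(omega, float)
    j = s2 * tau_m / (1.0 + (omega * tau_m) ** 2)
    if tau_e > 0 and s2 < 1.0:
        tau = 1.0 / (1.0 / tau_m + 1.0 / tau_e)
        j = j + (1.0 - s2) * tau / (1.0 + (omega * tau) ** 2)
    return 0.4 * j


def predict_rates(s2: float, tau_e: float, tau_m: float, field: float = 18.8,
                  constants: NMRConstants = CONSTANTS):
    """Predicted (R1, R2, NOE) for one residue at a given field (Tesla)."""
    if not 0.0 <= s2 <= 1.0:
        raise ValueError("S^2 must be in [0, 1]")
    if tau_m <= 0 or tau_e < 0:
        raise ValueError("correlation times must be positive")
    if field <= 0:
        raise ValueError("field must be positive")
    w_h, w_n = constants.omega(field)
    d2_4 = constants.d_dipolar ** 2 / 4.0
    c2 = (w_n * constants.csa_n) ** 2 / 3.0

    def j(w):
        return spectral_density(s2, tau_e, tau_m, w)

    j0 = j(0.0)
    j_n = j(w_n)
    j_h = j(w_h)
    j_diff = j(w_h - w_n)
    j_sum = j(w_h + w_n)

    r1 = d2_4 * (j_diff + 3.0 * j_n + 6.0 * j_sum) + c2 * j_n
    r2 = (d2_4 / 2.0) * (4.0 * j0 + j_diff + 3.0 * j_n + 6.0 * j_h + 6.0 * j_sum) \
        + (c2 / 6.0) * (4.0 * j0 + 3.0 * j_n)
    noe = 1.0 + d2_4 * (constants.gamma_h / constants.gamma_n) \
        * (6.0 * j_sum - j_diff) / r1
    return float(r1), float(r2), float(noe)


def tau_m_from_ratio(r1: float, r2: float, field: float = 18.8,
                     bounds=(0.5e-9, 50e-9),
                     constants: NMRConstants = CONSTANTS) -> float:
    """Overall correlation time from an R2/R1 ratio (seconds).

    Solves predicted R2/R1 (rigid limit: S^2 = 1, tau_e -> 0) equal to
    the observed ratio on ``bounds``; raises ValueError when the ratio
    is outside the achievable range.
    """
    if r1 <= 0 or r2 <= 0:
        raise ValueError("R1 and R2 must be positive")
    target = r2 / r1

    def f(tau_m):
        p1, p2, _ = predict_rates(1.0, 0.0, tau_m, field, constants)
        return p2 / p1 - target

    lo, hi = bounds
    f_lo, f_hi = f(lo), f(hi)
    if f_lo * f_hi > 0:
        raise ValueError(
            f"R2/R1 = {target:.3f} unreachable for tau_m in "
            f"[{lo * 1e9:.2f}, {hi * 1e9:.2f}] ns"
        )
    return float(brentq(f, lo, hi, xtol=1e-15))


# ---------------------------------------------------------------------------
# Fitting
# ---------------------------------------------------------------------------

REQUIRED_COLUMNS = ("residue", "R1", "R2", "NOE")


@dataclass
class ModelFreeResult:
    """Shared tau_m plus per-residue parameters and fit residuals."""

    tau_m: float  # s
    tau_m_initial: float  # s, from R2/R1 ratios alone
    params: pd.DataFrame  # residue, S2, tau_e
    residuals: pd.DataFrame
    field: float


class ModelFreeFit(BaseEstimator):
    """sklearn-style estimator for isotropic model-free fitting.

    ``fit(X)`` takes a per-residue relaxation table (DataFrame with
    columns residue, R1, R2, NOE and optional ``*_err``), estimates one
    shared overall correlation time from the R2/R1 ratios, then refines
    (tau_m, {S2_i, tau_e_i}) jointly by bounded least squares.  Fitted
    attributes: ``tau_m_``, ``params_``, ``residuals_``.
    """

    def __init__(self, field: float = 18.8, refine: bool = True,
                 constants: NMRConstants = CONSTANTS):
        self.field = field
        self.refine = refine
        self.constants = constants

    def fit(self, X: pd.DataFrame, y=None):
        df = _validate_dataset(X)
        n = len(df)
        tau_estimates = []
        for _, row in df.iterrows():
            try:
                tau_estimates.append(
                    tau_m_from_ratio(row.R1, row.R2, self.field,
                                     constants=self.constants)
                )
            except ValueError:
                continue
        if not tau_estimates:
            raise ValueError("no residue yields a usable R2/R1 ratio")
        tau_m0 = float(np.mean(tau_estimates))

        obs = df[["R1", "R2", "NOE"]].to_numpy()
        weights = _weights(df)

        def unpack(x):
            tau_m = x[0] * 1e-9
            s2 = x[1:1 + n]
            tau_e = x[1 + n:] * 1e-12
            return tau_m, s2, tau_e

        def residuals(x):
            tau_m, s2, tau_e = unpack(x)
            pred = np.array([
                predict_rates(s2[i], tau_e[i], tau_m, self.field, self.constants)
                for i in range(n)
            ])
            return ((pred - obs) / weights).ravel()

        x0 = np.concatenate([[tau_m0 * 1e9], np.full(n, 0.8), np.full(n, 50.0)])
        lower = np.concatenate([[0.5], np.zeros(n), np.full(n, 1e-3)])
        upper = np.concatenate([[50.0], np.ones(n), np.full(n, 2000.0)])
        if not self.refine:
            # Hold tau_m at the ratio-derived estimate; fit only (S2, tau_e).
            lower[0] = upper[0] = x0[0] = tau_m0 * 1e9
            lower[0] -= 1e-12
            upper[0] += 1e-12
        sol = least_squares(residuals, x0, bounds=(lower, upper),
                            xtol=1e-14, ftol=1e-14, gtol=1e-14)
        tau_m, s2, tau_e = unpack(sol.x)
        pred = np.array([
            predict_rates(s2[i], tau_e[i], tau_m, self.field, self.constants)
            for i in range(n)
        ])
        self.tau_m_ = float(tau_m)
        self.tau_m_initial_ = tau_m0
        self.params_ = pd.DataFrame({
            "residue": df["residue"].to_numpy(),
            "S2": np.clip(s2, 0.0, 1.0),
            "tau_e": tau_e,
        })
        self.residuals_ = pd.DataFrame(
            pred - obs, columns=["R1", "R2", "NOE"]
        ).assign(residue=df["residue"].to_numpy())
        return self

    def result(self) -> ModelFreeResult:
        return ModelFreeResult(self.tau_m_, self.tau_m_initial_, self.params_,
                               self.residuals_, self.field)


def fit_model_free(dataset: pd.DataFrame, field: float = 18.8,
                   refine: bool = True,
                   constants: NMRConstants = CONSTANTS) -> ModelFreeResult:
    """Fit shared tau_m and per-residue (S^2, tau_e) to a relaxation table."""
    est = ModelFreeFit(field=field, refine=refine, constants=constants).fit(dataset)
    return est.result()


def _validate_dataset(df: pd.DataFrame) -> pd.DataFrame:
    if not isinstance(df, pd.DataFrame):
        raise TypeError("dataset must be a pandas DataFrame")
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"dataset missing columns: {missing}")
    if len(df) < 1:
        raise ValueError("dataset needs at least one residue")
    if (df["R1"] <= 0).any() or (df["R2"] <= 0).any():
        raise ValueError("R1 and R2 must be positive")
    return df.reset_index(drop=True)


def _weights(df: pd.DataFrame) -> np.ndarray:
    """Residual scales: experimental errors when present, else unit."""
    cols = []
    for name in ("R1", "R2", "NOE"):
        err = f"{name}_err"
        if err in df.columns and (df[err] > 0).all():
            cols.append(df[err].to_numpy(float))
        else:
            cols.append(np.ones(len(df)))
    return np.column_stack(cols)
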