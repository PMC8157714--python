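"""Stokes-Einstein prediction, fractional-exponent fitting, and
quantification of diffusion/viscosity decoupling.

The SE relation D = C k_B T / (eta a) is evaluated with a configurable
boundary-condition constant (stick 1/(6 pi) by default).  Divergence is
reported in orders of magnitude, log10(D_measured / D_SE).  All
regression happens in log10 space because the data span many decades.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .constants import KB, WATER_RADIUS_M
from .droplet_fickian import DiffusivityParameterization

__all__ = [
    "SEParams",
    "DiffusionViscosityTable",
    "FractionalSEFit",
    "ViscosityParameterization",
    "se_predict",
    "divergence_orders",
    "fit_fractional_exponent",
    "build_table",
]

C_STICK = 1.0 / (6.0 * np.pi)
C_SLIP = 1.0 / (4.0 * np.pi)


@dataclass
class SEParams:
    """Constants of the SE relation D = C k_B T / (eta a)."""

    C: float = C_STICK
    a: float = WATER_RADIUS_M  # hydrodynamic radius, m
    T: float = 298.0

    def __post_init__(self) -> None:
        if self.C <= 0 or self.a <= 0 or self.T <= 0:
            raise ValueError("C, a and T must be positive")


@dataclass
class DiffusionViscosityTable:
    """Matched rows of (a_w, D, eta) with per-row provenance labels."""

    a_w: np.ndarray
    d: np.ndarray  # m^2 s^-1
    eta: np.ndarray  # Pa s
    labels: list[str] = field(default_factory=list)
    valid: np.ndarray | None = None  # per-row: inside both validity ranges

    def __post_init__(self) -> None:
        self.a_w = np.atleast_1d(np.asarray(self.a_w, dtype=float))
        self.d = np.atleast_1d(np.asarray(self.d, dtype=float))
        self.eta = np.atleast_1d(np.asarray(self.eta, dtype=float))
        n = len(self.a_w)
        if len(self.d) != n or len(self.eta) != n:
            raise ValueError("column length mismatch")
        if np.any(self.d <= 0) or np.any(self.eta <= 0):
            raise ValueError("D and eta must be positive")
        if np.any((self.a_w < 0) | (self.a_w > 1)):
            raise ValueError("a_w must lie in [0, 1]")
        if not self.labels:
            self.labels = [""] * n
        if self.valid is None:
            self.valid = np.ones(n, dtype=bool)

    def __len__(self) -> int:
        return len(self.a_w)


@dataclass
class FractionalSEFit:
    """Power-law fit D = 10^b * eta^-alpha over a viscosity window."""

    alpha: float
    prefactor_log10: float
    window: tuple[float, float]
    residual_rms: float
    alpha_sd: float | None = None

    @property
    def is_se(self) -> bool:
        return abs(self.alpha - 1.0) < 1e-12

    def predict_log10_d(self, eta) -> np.ndarray:
        return self.prefactor_log10 - self.alpha * np.log10(np.asarray(eta))


@dataclass
class ViscosityParameterization:
    """log10 eta(a_w) = sum_k c_k a_w^k, eta in Pa s."""

    coefficients: np.ndarray
    validity: tuple[float, float] = (0.0, 1.0)
    label: str = ""

    def __post_init__(self) -> None:
        self.coefficients = np.atleast_1d(np.asarray(self.coefficients, dtype=float))

    def log10_eta(self, a_w):
        return np.polyval(self.coefficients[::-1], np.asarray(a_w, dtype=float))

    def eta(self, a_w):
        return 10.0 ** self.log10_eta(a_w)

    def in_validity(self, a_w) -> np.ndarray:
        lo, hi = self.validity
        a_w = np.asarray(a_w, dtype=float)
        return (a_w >= lo) & (a_w <= hi)


def se_predict(eta, params: SEParams | None = None):
    """SE diffusion coefficient D = C k_B T / (eta a), m^2 s^-1."""
    if params is None:
        params = SEParams()
    eta = np.asarray(eta, dtype=float)
    if np.any(eta <= 0):
        raise ValueError("viscosity must be positive")
    return params.C * KB * params.T / (eta * params.a)


def divergence_orders(d_measured, d_se):
    """Orders of magnitude by which measured D exceeds the SE estimate."""
    d_measured = np.asarray(d_measured, dtype=float)
    d_se = np.asarray(d_se, dtype=float)
    if np.any(d_measured <= 0) or np.any(d_se <= 0):
        raise ValueError("diffusion coefficients must be positive")
    return np.log10(d_measured / d_se)


def fit_fractional_exponent(
    table: DiffusionViscosityTable,
    window: tuple[float, float] | None = None,
    n_bootstrap: int = 200,
    seed: int = 0,
) -> FractionalSEFit:
    """Fit D ~ eta^-alpha by least squares in (log10 eta, log10 D).

    Requires >= 3 rows inside the window spanning >= 2 decades of eta.
    ``alpha_sd`` comes from a residual bootstrap.
    """
    if window is None:
        window = (float(table.eta.min()), float(table.eta.max()))
    lo, hi = window
    mask = (table.eta >= lo) & (table.eta <= hi)
    eta = table.eta[mask]
    d = table.d[mask]
    if len(eta) < 3:
        raise ValueError(f"only {len(eta)} rows inside window; need >= 3")
    span = np.log10(eta.max() / eta.min())
    if span < 2.0:
        raise ValueError(
            f"window spans {span:.2f} decades of viscosity; the exponent is "
            "unidentifiable below 2 decades"
        )
    x = np.log10(eta)
    y = np.log10(d)
    slope, intercept = np.polyfit(x, y, 1)
    resid = y - (slope * x + intercept)
    rms = float(np.sqrt(np.mean(resid**2)))

    alpha_sd = None
    if n_bootstrap > 0 and len(x) > 2:
        rng = np.random.default_rng(seed)
        alphas = np.empty(n_bootstrap)
        fitted = slope * x + intercept
        for b in range(n_bootstrap):
            yb = fitted + rng.choice(resid, size=len(resid), replace=True)
            alphas[b] = -np.polyfit(x, yb, 1)[0]
        alpha_sd = float(np.std(alphas, ddof=1))

    return FractionalSEFit(
        alpha=float(-slope),
        prefactor_log10=float(intercept),
        window=(float(lo), float(hi)),
        residual_rms=rms,
        alpha_sd=alpha_sd,
    )


def build_table(
    d_param: DiffusivityParameterization,
    eta_param: ViscosityParameterization,
    a_w_grid,
    label: str = "",
) -> DiffusionViscosityTable:
    """Join independently parameterized D(a_w) and eta(a_w) on one grid.

    Rows outside either parameterization's validity range are flagged in
    ``table.valid`` (never silently extrapolated away).
    """
    a_w = np.atleast_1d(np.asarray(a_w_grid, dtype=float))
    valid = d_param.in_validity(a_w) & eta_param.in_validity(a_w)
    return DiffusionViscosityTable(
        a_w=a_w,
        d=d_param.d(a_w),
        eta=eta_param.eta(a_w),
        labels=[label] * len(a_w),
        valid=valid,
    )
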