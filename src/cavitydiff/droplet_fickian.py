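"""Spherical-shell Fickian water transport in aqueous-organic droplets.

Forward model: radial diffusion of water between concentric shells that
carry a fixed solute load each (equal solute mass per shell, so shells
never vanish on drying).  The droplet surface is held in instantaneous
equilibrium with the gas phase (surface water activity = RH/100); shells
are re-sized every step from composition via ideal volume additivity.

Inverse tools: stretched-exponential (KWW) characterization of response
functions, and simultaneous multi-curve fitting of a polynomial
log10 D_w(a_w) parameterization.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from numba import njit
from scipy.optimize import curve_fit, least_squares

from .constants import DENSITY_WATER, SOLUTE_DENSITY

__all__ = [
    "ResponseFunction",
    "KWWFit",
    "DiffusivityParameterization",
    "ActivityModel",
    "DropletState",
    "SolverError",
    "initial_state",
    "solve_shell_diffusion",
    "fit_kww",
    "fit_diffusivity",
]


class SolverError(RuntimeError):
    """Shell solver failed to produce a stable, conservative solution."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass
class ResponseFunction:
    """Normalized droplet-size time series for one RH step.

    ``normalized_size`` is total radius divided by the initial radius, so
    it starts at 1 and relaxes toward the new equilibrium value.
    """

    times: np.ndarray
    normalized_size: np.ndarray
    rh_initial: float
    rh_final: float
    temperature: float = 298.0
    droplet_radius_initial: float = 4e-6
    solute_label: str = "generic"
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.normalized_size = np.asarray(self.normalized_size, dtype=float)
        if len(self.times) != len(self.normalized_size):
            raise ValueError("times / normalized_size length mismatch")
        if len(self.times) and self.times[0] != 0.0:
            raise ValueError("times must start at 0")
        if len(self.times) > 1 and np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")

    @property
    def total_change(self) -> float:
        return float(self.normalized_size[-1] - self.normalized_size[0])


@dataclass
class KWWFit:
    """Stretched-exponential fit y(t) = c + (1 - c) exp[-(t/tau)^beta]."""

    tau: float
    beta: float
    asymptote: float
    residual_rms: float
    span_fraction: float = 1.0
    warning: str | None = None

    def __post_init__(self) -> None:
        if self.tau <= 0:
            raise ValueError("tau must be positive")
        if not (0 < self.beta <= 1.5):
            raise ValueError("beta must lie in (0, 1.5]")

    def evaluate(self, t: np.ndarray) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        return self.asymptote + (1.0 - self.asymptote) * np.exp(
            -((t / self.tau) ** self.beta)
        )


@dataclass
class DiffusivityParameterization:
    """log10 D_w(a_w) = sum_k c_k a_w^k, D in m^2 s^-1.

    ``coefficients`` are in ascending powers; the intercept ``c_0`` fixes
    the dry-matrix limit D_w_org = 10**c_0 exactly.
    """

    coefficients: np.ndarray
    validity: tuple[float, float] = (0.0, 1.0)
    label: str = ""

    def __post_init__(self) -> None:
        self.coefficients = np.atleast_1d(np.asarray(self.coefficients, dtype=float))
        if not np.all(np.isfinite(self.coefficients)):
            raise ValueError("coefficients must be finite")

    @property
    def order(self) -> int:
        return len(self.coefficients) - 1

    @property
    def d_w_org(self) -> float:
        """Dry-matrix diffusion coefficient, 10**c_0 (a_w = 0), m^2 s^-1."""
        return float(10.0 ** self.coefficients[0])

    def log10_d(self, a_w):
        a_w = np.asarray(a_w, dtype=float)
        return np.polyval(self.coefficients[::-1], a_w)

    def d(self, a_w):
        """Diffusion coefficient in m^2 s^-1."""
        return 10.0 ** self.log10_d(a_w)

    def in_validity(self, a_w) -> np.ndarray:
        lo, hi = self.validity
        a_w = np.asarray(a_w, dtype=float)
        return (a_w >= lo) & (a_w <= hi)

    def to_dict(self) -> dict:
        return {
            "coefficients": self.coefficients.tolist(),
            "validity": list(self.validity),
            "label": self.label,
            "d_w_org": self.d_w_org,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "DiffusivityParameterization":
        return cls(
            coefficients=np.asarray(d["coefficients"], dtype=float),
            validity=tuple(d.get("validity", (0.0, 1.0))),
            label=d.get("label", ""),
        )


@dataclass
class ActivityModel:
    """Parametric map between water mass fraction w and water activity.

    a_w(w) = w * exp(A (1 - w)^2), which satisfies a_w(0) = 0 and
    a_w(1) = 1 and is strictly increasing for A < 2.  Densities mix by
    ideal volume additivity.
    """

    A: float = 0.5
    density_water: float = DENSITY_WATER
    density_solute: float = SOLUTE_DENSITY["sucrose"]

    _grid_w: np.ndarray = field(init=False, repr=False)
    _grid_a: np.ndarray = field(init=False, repr=False)

    def __post_init__(self) -> None:
        if self.A >= 2.0:
            raise ValueError("A >= 2 makes a_w(w) non-monotone")
        self._grid_w = np.linspace(0.0, 1.0, 8193)
        self._grid_a = self.activity(self._grid_w)
        if np.any(np.diff(self._grid_a) <= 0):
            raise ValueError("activity map is not strictly increasing")

    def activity(self, w):
        w = np.asarray(w, dtype=float)
        return w * np.exp(self.A * (1.0 - w) ** 2)

    def mass_fraction(self, a_w):
        """Inverse map a_w -> w (monotone interpolation on a dense grid)."""
        a_w = np.asarray(a_w, dtype=float)
        if np.any(a_w < 0) or np.any(a_w > 1):
            raise ValueError("water activity must lie in [0, 1]")
        return np.interp(a_w, self._grid_a, self._grid_w)

    def density(self, w):
        """Mixture density, kg m^-3, ideal volume additivity."""
        w = np.asarray(w, dtype=float)
        return 1.0 / (w / self.density_water + (1.0 - w) / self.density_solute)


@dataclass
class DropletState:
    """Radially resolved droplet composition on equal-solute-mass shells."""

    shell_boundaries: np.ndarray  # (n+1,) outer radii incl. 0, m
    water_mass_fraction: np.ndarray  # (n,)
    water_activity: np.ndarray  # (n,)
    total_radius: float  # m
    temperature: float  # K
    solute_mass: np.ndarray = None  # (n,), kg
    water_mass: np.ndarray = None  # (n,), kg

    @property
    def n_shells(self) -> int:
        return len(self.water_mass_fraction)


def initial_state(
    radius: float,
    rh_initial: float,
    activity: ActivityModel,
    n_shells: int = 50,
    temperature: float = 298.0,
) -> DropletState:
    """Uniform droplet equilibrated at ``rh_initial`` (%), radius in m."""
    if not 0.0 <= rh_initial <= 100.0:
        raise ValueError("RH must lie in [0, 100]")
    if n_shells < 10:
        raise ValueError("need at least 10 shells")
    w0 = float(activity.mass_fraction(rh_initial / 100.0))
    rho = float(activity.density(w0))
    total_mass = rho * 4.0 / 3.0 * np.pi * radius**3
    m_s = np.full(n_shells, total_mass * (1.0 - w0) / n_shells)
    m_w = np.full(n_shells, total_mass * w0 / n_shells)
    bounds = _shell_boundaries(m_s, m_w, activity)
    return DropletState(
        shell_boundaries=bounds,
        water_mass_fraction=np.full(n_shells, w0),
        water_activity=np.full(n_shells, rh_initial / 100.0),
        total_radius=float(bounds[-1]),
        temperature=temperature,
        solute_mass=m_s,
        water_mass=m_w,
    )


def _shell_boundaries(m_s, m_w, activity: ActivityModel) -> np.ndarray:
    w = m_w / (m_w + m_s)
    vol = (m_w + m_s) / activity.density(w)
    return np.concatenate(([0.0], np.cbrt(np.cumsum(vol) * 3.0 / (4.0 * np.pi))))


# ---------------------------------------------------------------------------
# forward solver (numba kernel)
# ---------------------------------------------------------------------------


@njit(cache=True)
def _step_kernel(
    m_s,
    m_w,
    coeffs,
    act_a,
    rho_w,
    rho_s,
    a_b,
    c_b,
    t_out,
    safety,
    max_steps,
):
    """Explicit conservative integration; returns radii and water masses at t_out.

    Energy/units: masses kg, radii m, D m^2/s.  a_w(w) = w*exp(act_a*(1-w)^2).
    Returns (radii, water_totals, flux_residual, status); status 0 = ok,
    1 = negative mass (instability), 2 = step budget exhausted.
    """
    n = m_s.shape[0]
    n_out = t_out.shape[0]
    radii = np.empty(n_out)
    water_totals = np.empty(n_out)
    boundary_in = 0.0  # cumulative water mass through the surface, kg
    m_w = m_w.copy()
    m_w0_total = m_w.sum()

    t = 0.0
    steps = 0
    four_pi = 4.0 * np.pi

    w = np.empty(n)
    a = np.empty(n)
    c = np.empty(n)
    vol = np.empty(n)
    r_out = np.empty(n)
    r_c = np.empty(n)
    flux = np.empty(n)  # net dm_w/dt per shell

    for k_out in range(n_out):
        t_target = t_out[k_out]
        while True:
            # --- geometry & thermodynamics ---------------------------------
            acc = 0.0
            for i in range(n):
                tot = m_w[i] + m_s[i]
                w[i] = m_w[i] / tot
                vol[i] = m_w[i] / rho_w + m_s[i] / rho_s
                acc += vol[i]
                r_out[i] = (acc * 3.0 / four_pi) ** (1.0 / 3.0)
                omw = 1.0 - w[i]
                a[i] = w[i] * np.exp(act_a * omw * omw)
                c[i] = m_w[i] / vol[i]
            r_prev = 0.0
            for i in range(n):
                r_c[i] = 0.5 * (r_prev + r_out[i])
                r_prev = r_out[i]

            if t >= t_target:
                break

            # --- fluxes -----------------------------------------------------
            for i in range(n):
                flux[i] = 0.0
            max_rate = 0.0
            for j in range(n - 1):
                a_face = 0.5 * (a[j] + a[j + 1])
                # log10 D = polynomial in a_w
                ld = 0.0
                for p in range(coeffs.shape[0] - 1, -1, -1):
                    ld = ld * a_face + coeffs[p]
                d_face = 10.0**ld
                area = four_pi * r_out[j] * r_out[j]
                dr = r_c[j + 1] - r_c[j]
                g = d_face * area / dr  # m^3/s
                f = g * (c[j + 1] - c[j])  # kg/s into shell j
                flux[j] += f
                flux[j + 1] -= f
                rate = g / min(vol[j], vol[j + 1])
                if rate > max_rate:
                    max_rate = rate
            # surface face: Dirichlet a_w = a_b at r = R
            a_face = 0.5 * (a[n - 1] + a_b)
            ld = 0.0
            for p in range(coeffs.shape[0] - 1, -1, -1):
                ld = ld * a_face + coeffs[p]
            d_face = 10.0**ld
            area = four_pi * r_out[n - 1] * r_out[n - 1]
            dr = r_out[n - 1] - r_c[n - 1]
            g = d_face * area / dr
            f_surface = g * (c_b - c[n - 1])
            flux[n - 1] += f_surface
            rate = g / vol[n - 1]
            if rate > max_rate:
                max_rate = rate

            if max_rate <= 0.0:
                dt = t_target - t
            else:
                dt = safety / max_rate
                if t + dt > t_target:
                    dt = t_target - t

            for i in range(n):
                m_w[i] += dt * flux[i]
            boundary_in += dt * f_surface
            t += dt
            steps += 1

            for i in range(n):
                if m_w[i] < 0.0:
                    if m_w[i] > -1e-16 * m_w0_total:
                        m_w[i] = 0.0
                    else:
                        return radii, water_totals, 0.0, 1
            if steps > max_steps:
                return radii, water_totals, 0.0, 2

        radii[k_out] = r_out[n - 1]
        water_totals[k_out] = m_w.sum()

    residual = (m_w.sum() - m_w0_total) - boundary_in
    scale = max(abs(boundary_in), m_w0_total)
    rel_residual = abs(residual) / scale if scale > 0 else 0.0
    return radii, water_totals, rel_residual, 0


def solve_shell_diffusion(
    initial: DropletState,
    D: DiffusivityParameterization,
    activity: ActivityModel,
    rh_final: float,
    output_times: np.ndarray,
    safety: float = 0.2,
    max_steps: int = 50_000_000,
    return_diagnostics: bool = False,
):
    """Forward-simulate an RH step and return the size response function.

    The outermost face is held at instantaneous equilibrium with the gas
    phase (water activity = rh_final / 100); water moves between shells
    down the radial concentration gradient with D evaluated at the
    interface activity.  Water mass is conserved to machine precision
    (interior change equals integrated boundary flux).
    """
    if not 0.0 <= rh_final <= 100.0:
        raise ValueError("rh_final must lie in [0, 100]")
    if initial.n_shells < 10:
        raise ValueError("need at least 10 shells")
    output_times = np.asarray(output_times, dtype=float)
    if output_times[0] != 0.0:
        raise ValueError("output_times must start at 0")

    a_b = rh_final / 100.0
    w_b = float(activity.mass_fraction(a_b))
    c_b = w_b * float(activity.density(w_b))

    attempt_safety = safety
    for _ in range(6):
        radii, water, residual, status = _step_kernel(
            np.ascontiguousarray(initial.solute_mass),
            np.ascontiguousarray(initial.water_mass),
            np.ascontiguousarray(D.coefficients),
            float(activity.A),
            float(activity.density_water),
            float(activity.density_solute),
            a_b,
            c_b,
            output_times,
            attempt_safety,
            max_steps,
        )
        if status == 0:
            break
        if status == 2:
            raise SolverError(
                f"step budget {max_steps} exhausted (safety={attempt_safety:g}); "
                "reduce the output horizon or coarsen shells"
            )
        attempt_safety /= 2.0
    else:
        raise SolverError(
            f"negative mass fraction persisted down to safety={attempt_safety:g}"
        )

    if residual > 1e-10:
        raise SolverError(f"conservation violated: relative residual {residual:.2e}")

    rf = ResponseFunction(
        times=output_times,
        normalized_size=radii / radii[0],
        rh_initial=float(initial.water_activity[0] * 100.0),
        rh_final=rh_final,
        temperature=initial.temperature,
        droplet_radius_initial=float(radii[0]),
        meta={"safety": attempt_safety},
    )
    if return_diagnostics:
        diag = {
            "water_mass": water,
            "radii_m": radii,
            "conservation_residual": residual,
            "initial_water_mass": float(np.sum(initial.water_mass)),
        }
        return rf, diag
    return rf


# ---------------------------------------------------------------------------
# KWW characterization
# ---------------------------------------------------------------------------


def fit_kww(rf: ResponseFunction, beta_grid=(0.3, 0.5, 0.7, 1.0, 1.3)) -> KWWFit:
    """Fit y(t) = c + (1-c) exp[-(t/tau)^beta], multi-start over beta.

    Raises ``ValueError`` on a flat curve; returns a flagged fit when the
    curve spans less than 80 % of its fitted total change (relaxation not
    complete over the observed window).
    """
    t = rf.times
    y = rf.normalized_size
    if len(t) < 20:
        raise ValueError("need at least 20 samples for a KWW fit")
    change = y[-1] - y[0]
    noise_scale = np.std(np.diff(y)) / np.sqrt(2.0) if len(y) > 2 else 0.0
    if abs(change) < max(5.0 * noise_scale, 1e-12):
        raise ValueError("no decay to fit: curve is constant within noise")

    def model(tt, tau, beta, c):
        return c + (1.0 - c) * np.exp(-((tt / tau) ** beta))

    # tau init: first crossing of 1 - (1 - y_end)/e
    y_e = 1.0 + (y[-1] - 1.0) * (1.0 - 1.0 / np.e)
    idx = np.nonzero((y - y_e) * np.sign(change) >= 0)[0]
    tau0 = t[idx[0]] if len(idx) and t[idx[0]] > 0 else t[-1] / 3.0

    best = None
    for beta0 in beta_grid:
        try:
            popt, _ = curve_fit(
                model,
                t,
                y,
                p0=(tau0, beta0, y[-1]),
                bounds=([t[1] * 1e-6, 0.05, -np.inf], [np.inf, 1.5, np.inf]),
                maxfev=20000,
            )
        except RuntimeError:
            continue
        resid = y - model(t, *popt)
        rms = float(np.sqrt(np.mean(resid**2)))
        if best is None or rms < best[1]:
            best = (popt, rms)
    if best is None:
        raise ValueError("KWW fit failed for every beta start")

    (tau, beta, c), rms = best
    denom = y[0] - c
    span = float((y[0] - y[-1]) / denom) if denom != 0 else 1.0
    warning = None
    if span < 0.8:
        warning = (
            f"curve spans only {span:.0%} of its fitted change; "
            "relaxation not complete over the observed window"
        )
        warnings.warn(warning, stacklevel=2)
    return KWWFit(
        tau=float(tau),
        beta=float(beta),
        asymptote=float(c),
        residual_rms=rms,
        span_fraction=span,
        warning=warning,
    )


# ---------------------------------------------------------------------------
# inverse fitting of D_w(a_w)
# ---------------------------------------------------------------------------


def _curve_aw_midpoint(rf: ResponseFunction) -> float:
    return 0.5 * (rf.rh_initial + rf.rh_final) / 100.0


def _initial_coefficients(curves, activity, order) -> np.ndarray:
    """KWW-based initializer: D_eff ~ r0^2 / (pi^2 tau) at the step midpoint."""
    mids, logd = [], []
    for rf in curves:
        try:
            kww = fit_kww(rf)
        except ValueError:
            continue
        d_eff = rf.droplet_radius_initial**2 / (np.pi**2 * kww.tau)
        mids.append(_curve_aw_midpoint(rf))
        logd.append(np.log10(d_eff))
    if not mids:
        return np.full(order + 1, -12.0)
    fit_order = min(order, max(len(mids) - 1, 0))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        coef = np.polyfit(mids, logd, fit_order)[::-1]
    out = np.zeros(order + 1)
    out[: len(coef)] = coef
    return out


def fit_diffusivity(
    curves: list[ResponseFunction],
    activity: ActivityModel,
    order: int = 3,
    init: DiffusivityParameterization | None = None,
    n_shells: int = 50,
    n_bootstrap: int = 0,
    seed: int = 0,
    verbose: bool = False,
):
    """Recover a polynomial log10 D_w(a_w) from one or more RH-step curves.

    Minimizes the summed squared residual between shell-model forecasts
    and every observed curve simultaneously.  Returns
    ``(DiffusivityParameterization, coefficient_sd or None)``; coefficient
    uncertainty comes from a bootstrap over curves when
    ``n_bootstrap > 0``.
    """
    if len(curves) < 1:
        raise ValueError("need at least one response curve")
    if order > 0 and len(curves) < 2:
        raise ValueError("order > 0 requires at least 2 curves")

    a_lo = min(min(rf.rh_initial, rf.rh_final) for rf in curves) / 100.0
    a_hi = max(max(rf.rh_initial, rf.rh_final) for rf in curves) / 100.0
    mids = np.array([_curve_aw_midpoint(rf) for rf in curves])
    if order >= 1 and (mids.max() - mids.min()) < 0.05:
        raise ValueError(
            f"coefficients c_1..c_{order} unconstrained: all curves probe a "
            f"narrow a_w band [{a_lo:.2f}, {a_hi:.2f}]"
        )

    states = [
        initial_state(
            rf.droplet_radius_initial,
            rf.rh_initial,
            activity,
            n_shells=n_shells,
            temperature=rf.temperature,
        )
        for rf in curves
    ]

    def residuals(coeffs):
        out = []
        param = DiffusivityParameterization(coeffs)
        for rf, st in zip(curves, states):
            try:
                pred = solve_shell_diffusion(st, param, activity, rf.rh_final, rf.times)
                out.append(pred.normalized_size - rf.normalized_size)
            except SolverError:
                out.append(np.full(len(rf.times), 1.0))
        return np.concatenate(out)

    if init is not None:
        x0 = np.zeros(order + 1)
        k = min(order + 1, len(init.coefficients))
        x0[:k] = init.coefficients[:k]
    else:
        x0 = _initial_coefficients(curves, activity, order)

    result = least_squares(
        residuals,
        x0,
        method="trf",
        diff_step=1e-3,
        xtol=1e-10,
        ftol=1e-10,
        verbose=2 if verbose else 0,
    )
    coeffs = result.x

    extrapolation_note = None
    if a_lo > 0.0:
        extrapolation_note = (
            f"D below a_w={a_lo:.2f} (incl. the intercept D_w_org) is an "
            "extrapolation outside the probed range"
        )

    param = DiffusivityParameterization(coeffs, validity=(a_lo, a_hi))

    coeff_sd = None
    if n_bootstrap > 0:
        rng = np.random.default_rng(seed)
        samples = []
        for _ in range(n_bootstrap):
            pick = rng.integers(0, len(curves), size=len(curves))
            if len(np.unique([round(mids[i], 6) for i in pick])) < (
                2 if order >= 1 else 1
            ):
                continue
            try:
                boot, _ = fit_diffusivity(
                    [curves[i] for i in pick],
                    activity,
                    order=order,
                    init=param,
                    n_shells=n_shells,
                    n_bootstrap=0,
                )
            except ValueError:
                continue
            samples.append(boot.coefficients)
        if len(samples) >= 2:
            coeff_sd = np.std(np.asarray(samples), axis=0, ddof=1)

    if extrapolation_note:
        param.label = extrapolation_note
    return param, coeff_sd


def sphere_sorption_series(t, D, radius, n_terms: int = 200):
    """Analytic fractional uptake for a fixed sphere with constant D.

    M(t)/M_inf = 1 - (6/pi^2) sum n^-2 exp(-n^2 pi^2 D t / r^2).
    Independent oracle for the shell solver in the dilute, fixed-boundary
    limit.
    """
    t = np.atleast_1d(np.asarray(t, dtype=float))
    n = np.arange(1, n_terms + 1)
    expo = np.exp(-np.outer(t, n**2) * (np.pi**2 * D / radius**2))
    return 1.0 - (6.0 / np.pi**2) * (expo / n**2).sum(axis=1)
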