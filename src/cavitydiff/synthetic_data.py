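"""Synthetic input generators with known ground truth.

Every input class the pipeline consumes can be generated here at desk
scale: shell-model response curves from a known D_w(a_w), overdamped
Langevin trajectories in multi-well potentials (emulating cavity
hopping with optional slow matrix fluctuation), exact two-state jump
processes with Gaussian position emissions, and random sphere packings.

All generators are deterministic given a seed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from numba import njit
from scipy.linalg import expm

from .droplet_fickian import (
    ActivityModel,
    DiffusivityParameterization,
    ResponseFunction,
    initial_state,
    solve_shell_diffusion,
)
from .trajectory import Trajectory

__all__ = [
    "SyntheticSpec",
    "MultiWellPotential",
    "PackedConfiguration",
    "gen_response_curve",
    "gen_langevin_trajectory",
    "gen_two_state_jump",
    "gen_sphere_packing",
]

GENERATOR_KINDS = {
    "response_curve",
    "langevin_trajectory",
    "two_state_jump",
    "sphere_packing",
}


@dataclass
class SyntheticSpec:
    """Declarative description of one synthetic dataset."""

    seed: int
    kind: str
    parameters: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.kind not in GENERATOR_KINDS:
            raise ValueError(f"unknown generator kind {self.kind!r}")

    def generate(self):
        fn = {
            "response_curve": gen_response_curve,
            "langevin_trajectory": gen_langevin_trajectory,
            "two_state_jump": gen_two_state_jump,
            "sphere_packing": gen_sphere_packing,
        }[self.kind]
        return fn(seed=self.seed, **self.parameters)


@dataclass
class PackedConfiguration:
    """Sphere centers + radii in a periodic box (nm)."""

    centers: np.ndarray  # (n, 3)
    radii: np.ndarray  # (n,)
    box: np.ndarray  # (3,)
    label: str = ""

    def __post_init__(self) -> None:
        self.centers = np.asarray(self.centers, dtype=float).reshape(-1, 3)
        self.radii = np.atleast_1d(np.asarray(self.radii, dtype=float))
        self.box = np.asarray(self.box, dtype=float)
        if len(self.centers) != len(self.radii):
            raise ValueError("centers / radii length mismatch")
        if len(self.radii) and self.radii.min() <= 0:
            raise ValueError("radii must be positive")
        self.centers = np.mod(self.centers, self.box)

    @property
    def n_spheres(self) -> int:
        return len(self.radii)


# ---------------------------------------------------------------------------
# response curves
# ---------------------------------------------------------------------------


def gen_response_curve(
    truth: DiffusivityParameterization,
    rh_step: tuple[float, float],
    initial_radius: float = 4e-6,
    solute_label: str = "generic",
    activity: ActivityModel | None = None,
    noise_sd: float = 0.0,
    n_points: int = 200,
    n_shells: int = 100,
    span_time_constants: float = 5.0,
    temperature: float = 298.0,
    seed: int = 0,
) -> ResponseFunction:
    """Forward-simulate an RH step from a known D_w(a_w) and add noise.

    Output times span ``span_time_constants`` nominal time constants
    tau_nom = r0^2 / (pi^2 D_min), with D_min the smallest diffusivity
    on the traversed activity interval.  Noise is multiplicative
    Gaussian on the normalized size.
    """
    rh_i, rh_f = rh_step
    for rh in (rh_i, rh_f):
        if not 0.0 <= rh <= 100.0:
            raise ValueError("RH must lie in [0, 100]")
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    if activity is None:
        activity = ActivityModel()

    a_grid = np.linspace(min(rh_i, rh_f), max(rh_i, rh_f), 64) / 100.0
    d_min = float(np.min(truth.d(a_grid)))
    tau_nom = initial_radius**2 / (np.pi**2 * d_min)
    t_end = span_time_constants * tau_nom
    times = np.concatenate(([0.0], np.geomspace(t_end * 2e-4, t_end, n_points - 1)))

    state = initial_state(
        initial_radius, rh_i, activity, n_shells=n_shells, temperature=temperature
    )
    rf = solve_shell_diffusion(state, truth, activity, rh_f, times)
    y = rf.normalized_size.copy()
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        y = y * (1.0 + noise_sd * rng.standard_normal(len(y)))
    return ResponseFunction(
        times=times,
        normalized_size=y,
        rh_initial=rh_i,
        rh_final=rh_f,
        temperature=temperature,
        droplet_radius_initial=initial_radius,
        solute_label=solute_label,
        meta={"noise_sd": noise_sd, "seed": seed, "truth": truth.to_dict()},
    )


# ---------------------------------------------------------------------------
# multi-well Langevin trajectories
# ---------------------------------------------------------------------------


@dataclass
class MultiWellPotential:
    """Sum of inverted Gaussian wells with optional slow depth modulation.

    U(x, t) = -sum_i depth_i(t) exp(-|x - x_i|_mi^2 / (2 width_i^2)), in
    units of k_B*T, with minimum-image displacements in a periodic box.
    Depth modulation: depth_i(t) = depth_i + amp * sin(2 pi t / tau + phi_i)
    with per-well phases, emulating slow matrix reorganisation.
    """

    centers: np.ndarray  # (k, 3) nm
    depths: np.ndarray  # (k,) kBT
    widths: np.ndarray  # (k,) nm
    box: np.ndarray  # (3,) nm
    fluctuation_amplitude: float = 0.0  # kBT
    fluctuation_timescale: float = 1000.0  # ps (default 1 ns)
    phases: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.centers = np.asarray(self.centers, dtype=float).reshape(-1, 3)
        self.depths = np.atleast_1d(np.asarray(self.depths, dtype=float))
        self.widths = np.atleast_1d(np.asarray(self.widths, dtype=float))
        self.box = np.asarray(self.box, dtype=float)
        if self.phases is None:
            self.phases = np.zeros(len(self.depths))
        self.phases = np.atleast_1d(np.asarray(self.phases, dtype=float))
        if np.any(self.centers < 0) or np.any(self.centers > self.box):
            raise ValueError("well centers must lie inside the box")

    def depths_at(self, t_ps: float) -> np.ndarray:
        if self.fluctuation_amplitude == 0.0:
            return self.depths
        return self.depths + self.fluctuation_amplitude * np.sin(
            2.0 * np.pi * t_ps / self.fluctuation_timescale + self.phases
        )

    def frozen(self, t_ps: float) -> "MultiWellPotential":
        """Static copy with depths frozen at modulation phase ``t_ps``."""
        return MultiWellPotential(
            centers=self.centers.copy(),
            depths=self.depths_at(t_ps).copy(),
            widths=self.widths.copy(),
            box=self.box.copy(),
            fluctuation_amplitude=0.0,
        )

    def energy(self, x: np.ndarray, t_ps: float = 0.0) -> np.ndarray:
        """Potential in kBT at positions x (..., 3)."""
        x = np.asarray(x, dtype=float)
        disp = x[..., None, :] - self.centers  # (..., k, 3)
        disp -= self.box * np.round(disp / self.box)
        r2 = (disp**2).sum(axis=-1)
        d = self.depths_at(t_ps)
        return -(d * np.exp(-r2 / (2.0 * self.widths**2))).sum(axis=-1)

    def max_curvature(self) -> float:
        """Upper bound on |U''|, kBT nm^-2 (for step-size guards)."""
        return float(np.max(self.depths_abs_max() / self.widths**2))

    def depths_abs_max(self) -> np.ndarray:
        return np.abs(self.depths) + abs(self.fluctuation_amplitude)


@njit(cache=True)
def _langevin_kernel(
    x0,
    centers,
    depths,
    widths,
    phases,
    amp,
    tau_mod,
    box,
    d0,
    dt,
    n_steps,
    stride,
    noise,
    noise_on,
):
    """Overdamped Euler-Maruyama in the multi-well potential.

    Positions in nm, time in ps, energies in kBT; drift = D0 * F with
    F in kBT/nm.  Returns unwrapped positions sampled every ``stride``
    steps (step 0 included) and a status (1 = blow-up).
    """
    k = centers.shape[0]
    n_out = n_steps // stride + 1
    out = np.empty((n_out, 3))
    x = x0.copy()
    out[0] = x
    amp_noise = np.sqrt(2.0 * d0 * dt)
    half_box = min(box[0], min(box[1], box[2])) / 2.0
    i_out = 1
    for step in range(1, n_steps + 1):
        t = step * dt
        f0 = 0.0
        f1 = 0.0
        f2 = 0.0
        for i in range(k):
            dx0 = x[0] - centers[i, 0]
            dx1 = x[1] - centers[i, 1]
            dx2 = x[2] - centers[i, 2]
            dx0 -= box[0] * np.round(dx0 / box[0])
            dx1 -= box[1] * np.round(dx1 / box[1])
            dx2 -= box[2] * np.round(dx2 / box[2])
            w2 = widths[i] * widths[i]
            r2 = dx0 * dx0 + dx1 * dx1 + dx2 * dx2
            depth = depths[i]
            if amp != 0.0:
                depth = depth + amp * np.sin(2.0 * np.pi * t / tau_mod + phases[i])
            # F = -dU/dx ; U = -depth exp(-r2/2w2)  =>  F = -depth * exp * dx / w2
            e = depth * np.exp(-r2 / (2.0 * w2)) / w2
            f0 -= e * dx0
            f1 -= e * dx1
            f2 -= e * dx2
        s0 = d0 * f0 * dt
        s1 = d0 * f1 * dt
        s2 = d0 * f2 * dt
        if noise_on:
            s0 += amp_noise * noise[step - 1, 0]
            s1 += amp_noise * noise[step - 1, 1]
            s2 += amp_noise * noise[step - 1, 2]
        if (
            abs(s0) > half_box
            or abs(s1) > half_box
            or abs(s2) > half_box
        ):
            return out, 1
        x[0] += s0
        x[1] += s1
        x[2] += s2
        if step % stride == 0:
            out[i_out] = x
            i_out += 1
    return out, 0


def gen_langevin_trajectory(
    wells: list[tuple] | MultiWellPotential,
    box: tuple[float, float, float] = (4.0, 4.0, 4.0),
    barrier_fluctuation: tuple[float, float] = (0.0, 1000.0),
    friction: float = 10.0,
    temperature: float = 300.0,
    dt: float = 0.01,
    n_steps: int = 100_000,
    sample_stride: int = 1,
    x0: np.ndarray | None = None,
    noise_on: bool = True,
    seed: int = 0,
) -> Trajectory:
    """Overdamped Langevin trajectory of a tracer in a multi-well potential.

    Parameters
    ----------
    wells
        Either a :class:`MultiWellPotential` or a list of
        ``(center_3vec_nm, depth_kBT, width_nm)`` tuples.
    barrier_fluctuation
        ``(amplitude_kBT, timescale_ps)`` sinusoidal modulation of well
        depths (per-well phases drawn from the seed); amplitude 0 gives a
        static potential.
    friction
        Friction coefficient gamma in ps^-1; the free diffusion
        coefficient is D0 = 1/gamma nm^2 ps^-1 (thermal length 1 nm).
    noise_on
        Disable for the zero-temperature (gradient descent) limit.

    Time unit ps, positions nm.  Wrapped and unwrapped positions are
    both retained on the returned :class:`Trajectory`.
    """
    rng = np.random.default_rng(seed)
    box = np.asarray(box, dtype=float)
    amp, tau_mod = barrier_fluctuation
    if isinstance(wells, MultiWellPotential):
        pot = wells
    else:
        centers = np.array([w[0] for w in wells], dtype=float)
        depths = np.array([w[1] for w in wells], dtype=float)
        widths = np.array([w[2] for w in wells], dtype=float)
        phases = rng.uniform(0.0, 2.0 * np.pi, size=len(wells)) if amp else None
        pot = MultiWellPotential(
            centers=centers,
            depths=depths,
            widths=widths,
            box=box,
            fluctuation_amplitude=amp,
            fluctuation_timescale=tau_mod,
            phases=phases,
        )
    d0 = 1.0 / friction
    curv = pot.max_curvature()
    if dt * curv * d0 >= 0.1:
        raise ValueError(
            f"dt too large: dt * max_curvature * D0 = {dt * curv * d0:.3f} >= 0.1"
        )
    if x0 is None:
        x0 = pot.centers[int(rng.integers(len(pot.centers)))].copy()
    x0 = np.asarray(x0, dtype=float)

    noise = (
        rng.standard_normal((n_steps, 3))
        if noise_on
        else np.zeros((1, 3))
    )
    unwrapped, status = _langevin_kernel(
        x0,
        pot.centers,
        pot.depths,
        pot.widths,
        pot.phases,
        float(pot.fluctuation_amplitude),
        float(pot.fluctuation_timescale),
        pot.box,
        d0,
        dt,
        n_steps,
        sample_stride,
        noise,
        noise_on,
    )
    if status == 1:
        raise RuntimeError(
            "integrator instability: single-step displacement exceeded box/2"
        )
    times = np.arange(unwrapped.shape[0]) * dt * sample_stride
    return Trajectory(
        times=times,
        positions=np.mod(unwrapped, box),
        unwrapped=unwrapped,
        box=box,
        periodic=True,
        meta={
            "potential": pot,
            "friction": friction,
            "temperature": temperature,
            "d0_nm2_ps": d0,
            "seed": seed,
        },
    )


# ---------------------------------------------------------------------------
# exact two-state jump process
# ---------------------------------------------------------------------------


def gen_two_state_jump(
    k12: float,
    k21: float,
    emission_sd: float = 0.1,
    centers: np.ndarray | None = None,
    dt: float = 1.0,
    n_steps: int = 10_000,
    box: tuple[float, float, float] | None = None,
    seed: int = 0,
) -> tuple[Trajectory, np.ndarray]:
    """Two-state continuous-time Markov chain sampled at interval dt.

    Rates in ns^-1, dt in ps.  States emit isotropic Gaussian positions
    around their centers.  Returns the trajectory and the ground-truth
    state sequence (0/1).
    """
    if k12 <= 0 or k21 <= 0:
        raise ValueError("rates must be positive")
    dt_ns = dt * 1e-3
    if dt_ns * (k12 + k21) >= 0.1:
        raise ValueError("dt * (k12 + k21) must be < 0.1 (oversampling needed)")
    rng = np.random.default_rng(seed)
    if centers is None:
        centers = np.array([[1.0, 1.0, 1.0], [2.0, 1.0, 1.0]])
    centers = np.asarray(centers, dtype=float).reshape(2, 3)
    sep = np.linalg.norm(centers[1] - centers[0])
    if sep < 3.0 * emission_sd:
        warnings.warn(
            f"state centers separated by {sep:.3g} nm < 3 emission_sd: "
            "states may be unresolvable",
            stacklevel=2,
        )

    q = np.array([[-k12, k12], [k21, -k21]])
    p = expm(q * dt_ns)
    pi0 = np.array([k21, k12]) / (k12 + k21)

    states = np.empty(n_steps, dtype=np.int64)
    states[0] = rng.choice(2, p=pi0)
    u = rng.random(n_steps - 1) if n_steps > 1 else np.empty(0)
    for i in range(1, n_steps):
        states[i] = 0 if u[i - 1] < p[states[i - 1], 0] else 1

    positions = centers[states] + emission_sd * rng.standard_normal((n_steps, 3))
    if box is None:
        lo = centers.min(axis=0) - 10.0 * emission_sd
        hi = centers.max(axis=0) + 10.0 * emission_sd
        box = hi - lo
        positions = positions - lo
        centers_shifted = centers - lo
    else:
        box = np.asarray(box, dtype=float)
        centers_shifted = centers
    traj = Trajectory(
        times=np.arange(n_steps) * dt,
        positions=np.mod(positions, box),
        unwrapped=positions,
        box=np.asarray(box, dtype=float),
        periodic=True,
        meta={
            "k12": k12,
            "k21": k21,
            "emission_sd": emission_sd,
            "centers": centers_shifted,
            "propagator": p,
            "seed": seed,
        },
    )
    return traj, states


# ---------------------------------------------------------------------------
# sphere packings
# ---------------------------------------------------------------------------


def gen_sphere_packing(
    n_spheres: int,
    radius: float | tuple[float, float] = 0.15,
    box: tuple[float, float, float] = (4.0, 4.0, 4.0),
    mode: str = "poisson",
    max_attempts: int = 200_000,
    label: str = "",
    seed: int = 0,
) -> PackedConfiguration:
    """Random sphere packing in a periodic box.

    ``radius`` is a single value or a ``(low, high)`` uniform range, nm.
    ``poisson`` places centers uniformly (overlaps allowed);
    ``non_overlapping`` uses random sequential addition with periodic
    minimum-image overlap checks (feasible up to ~0.35 packing fraction).
    """
    if mode not in {"poisson", "non_overlapping"}:
        raise ValueError(f"unknown mode {mode!r}")
    rng = np.random.default_rng(seed)
    box = np.asarray(box, dtype=float)
    if n_spheres == 0:
        return PackedConfiguration(
            centers=np.empty((0, 3)), radii=np.empty(0), box=box, label=label
        )

    def draw_radius():
        if np.isscalar(radius):
            return float(radius)
        lo, hi = radius
        return float(rng.uniform(lo, hi))

    radii = np.array([draw_radius() for _ in range(n_spheres)])
    vbox = float(np.prod(box))
    if mode == "poisson":
        centers = rng.uniform(0.0, 1.0, size=(n_spheres, 3)) * box
        return PackedConfiguration(centers=centers, radii=radii, box=box, label=label)

    target_fraction = (4.0 / 3.0) * np.pi * np.sum(radii**3) / vbox
    if target_fraction > 0.35:
        raise ValueError(
            f"requested packing fraction {target_fraction:.3f} > 0.35: "
            "random sequential addition is unreliable above this"
        )
    centers = np.empty((n_spheres, 3))
    placed = 0
    attempts = 0
    while placed < n_spheres:
        if attempts >= max_attempts:
            achieved = (4.0 / 3.0) * np.pi * np.sum(radii[:placed] ** 3) / vbox
            raise RuntimeError(
                f"RSA failed after {max_attempts} attempts: placed {placed}/"
                f"{n_spheres} spheres (achieved fraction {achieved:.3f})"
            )
        cand = rng.uniform(0.0, 1.0, size=3) * box
        attempts += 1
        if placed:
            disp = centers[:placed] - cand
            disp -= box * np.round(disp / box)
            d2 = (disp**2).sum(axis=1)
            min_sep = radii[:placed] + radii[placed]
            if np.any(d2 < min_sep**2):
                continue
        centers[placed] = cand
        placed += 1
    return PackedConfiguration(centers=centers, radii=radii, box=box, label=label)
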