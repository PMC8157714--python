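"""Tracer-trajectory analysis of the cavity-hopping transport mechanism.

Provides the full chain used to characterize hopping: MSD diffusion
coefficients (Einstein relation), metastable-state detection with
Gaussian-emission hidden Markov models, relaxation timescales with
bootstrap credibility intervals, Boltzmann-inversion PMF maps,
transition-state-theory barrier/rate conversion, hop statistics, matrix
autocorrelation times, and per-slice kinetic modelling.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from hmmlearn.hmm import GaussianHMM

logging.getLogger("hmmlearn.base").setLevel(logging.ERROR)

from .constants import NM2_PER_PS_TO_M2_PER_S, kt_over_h_per_ns
from .trajectory import Trajectory

__all__ = [
    "Trajectory",
    "MarkovModel",
    "PMFGrid",
    "BarrierEstimate",
    "HopStatistics",
    "MSDResult",
    "AutocorrelationResult",
    "msd_diffusion",
    "fit_hmm",
    "select_n_states",
    "compute_pmf",
    "frozen_matrix_probe",
    "tst_barrier",
    "tst_rate",
    "hop_statistics",
    "position_autocorrelation",
    "slice_and_model",
]


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass
class MarkovModel:
    """Gaussian-emission HMM of cavity hopping at a fixed lag time."""

    n_states: int
    means: np.ndarray  # (n, 3) nm
    sds: np.ndarray  # (n,) nm, isotropic
    transmat: np.ndarray  # (n, n), row-stochastic, at lag tau_lag
    lag_ps: float
    stationary: np.ndarray  # (n,)
    state_sequence: np.ndarray  # most-likely path on the lagged frames
    timescales_ns: np.ndarray  # sorted descending
    timescale_ci_ns: np.ndarray | None = None  # (2, k) 95 % interval
    log_likelihood: float = np.nan
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        rows = self.transmat.sum(axis=1)
        if not np.allclose(rows, 1.0, atol=1e-8):
            raise ValueError("transition matrix rows must sum to 1")

    def to_dict(self) -> dict:
        d = {
            "n_states": self.n_states,
            "means_nm": self.means.tolist(),
            "sds_nm": self.sds.tolist(),
            "transmat": self.transmat.tolist(),
            "lag_ps": self.lag_ps,
            "stationary": self.stationary.tolist(),
            "timescales_ns": self.timescales_ns.tolist(),
            "log_likelihood": self.log_likelihood,
        }
        if self.timescale_ci_ns is not None:
            d["timescale_ci_ns"] = self.timescale_ci_ns.tolist()
        return d


@dataclass
class PMFGrid:
    """2-D potential of mean force, -ln P in kBT, gauge min = 0."""

    edges_x: np.ndarray  # nm
    edges_y: np.ndarray  # nm
    values: np.ndarray  # (nx, ny) kBT; masked bins are nan
    mask: np.ndarray  # True where unsampled
    plane: tuple[int, int] = (1, 2)

    @property
    def sampled_fraction(self) -> float:
        return float(1.0 - self.mask.mean())


@dataclass
class BarrierEstimate:
    """A TST barrier with the rate and prefactor it was derived from."""

    delta_g: float  # kBT
    rate: float  # ns^-1
    prefactor: float  # ns^-1
    method: str = "rate-inversion"

    def __post_init__(self) -> None:
        if self.method == "rate-inversion":
            assert np.isclose(self.rate, self.prefactor * np.exp(-self.delta_g))


@dataclass
class HopStatistics:
    hops_per_ns: float
    n_hops: int
    dwell_times_ns: dict  # state -> array of dwell times, ns
    return_trip_fraction: float
    min_dwell_ps: float

    def __post_init__(self) -> None:
        if self.n_hops and not 0.0 <= self.return_trip_fraction <= 1.0:
            raise ValueError("return-trip fraction must lie in [0, 1]")


@dataclass
class MSDResult:
    d: float  # m^2 s^-1
    d_sd: float  # m^2 s^-1, block estimate
    lags_ps: np.ndarray
    msd_nm2: np.ndarray
    fit_window_ps: tuple[float, float]
    loglog_slope: float
    diffusive: bool


@dataclass
class AutocorrelationResult:
    lags_ps: np.ndarray
    correlation: np.ndarray
    decorrelation_time_ns: float
    censored: bool  # True when C never fell below 1/e (lower bound)


# ---------------------------------------------------------------------------
# MSD
# ---------------------------------------------------------------------------


def _msd_fft(x: np.ndarray) -> np.ndarray:
    """Time-averaged MSD over all sliding origins, O(n log n) via FFT."""
    n = len(x)
    nfft = 1 << (2 * n - 1).bit_length()
    s1 = np.zeros(n)
    s2 = np.zeros(n)
    sq = (x**2).sum(axis=1)
    for dim in range(x.shape[1]):
        f = np.fft.rfft(x[:, dim], nfft)
        acf = np.fft.irfft(f * np.conj(f), nfft)[:n]
        s2 += acf
    # S1(m) = sum_{k} (sq[k] + sq[k+m]) over valid origins
    cum = np.concatenate(([0.0], np.cumsum(sq)))
    total = cum[-1]
    m = np.arange(n)
    s1 = 2.0 * total - cum[m] - (cum[n] - cum[n - m])
    counts = n - m
    return (s1 - 2.0 * s2) / counts


def msd_diffusion(
    traj: Trajectory,
    fit_window: tuple[float, float] | None = None,
    n_blocks: int = 3,
) -> MSDResult:
    """Diffusion coefficient from the Einstein relation, D = slope/6.

    Uses the time-averaged MSD over all sliding origins and a linear fit
    inside ``fit_window`` (ps).  The trajectory must carry unwrapped
    positions -- computing an MSD on wrapped coordinates silently caps
    displacements at the box size, so it is refused.
    Uncertainty comes from block averaging over trajectory thirds.  A
    log-log MSD slope below 0.8 across the window flags the estimate as
    non-diffusive (still reported).
    """
    if traj.unwrapped is None:
        raise ValueError(
            "trajectory has no unwrapped positions; an MSD on wrapped "
            "coordinates would corrupt D -- unwrap first"
        )
    dt = traj.dt
    n = traj.n_frames
    if n < 10:
        raise ValueError("trajectory too short for an MSD")
    if fit_window is None:
        fit_window = (dt * max(2, n // 100), dt * n // 5)
    lo, hi = fit_window
    if hi > traj.times[-1]:
        raise ValueError("fit window extends beyond sampled lags")

    lags = np.arange(n) * dt
    msd = _msd_fft(traj.unwrapped)
    sel = (lags >= lo) & (lags <= hi) & (lags > 0)
    if sel.sum() < 2:
        raise ValueError("fewer than 2 MSD points inside the fit window")

    # weight ~ number of origins contributing at each lag
    w = (n - np.arange(n))[sel].astype(float)
    slope, intercept = np.polyfit(lags[sel], msd[sel], 1, w=np.sqrt(w))
    d = max(slope, 0.0) / 6.0 * NM2_PER_PS_TO_M2_PER_S

    with np.errstate(divide="ignore", invalid="ignore"):
        pos = msd[sel] > 0
        ll_slope = (
            np.polyfit(np.log(lags[sel][pos]), np.log(msd[sel][pos]), 1)[0]
            if pos.sum() >= 2
            else 0.0
        )
    diffusive = bool(ll_slope >= 0.8)
    if not diffusive:
        warnings.warn(
            f"MSD log-log slope {ll_slope:.2f} < 0.8 across the fit window: "
            "motion is sub-diffusive; D reported anyway",
            stacklevel=2,
        )

    block_ds = []
    size = n // n_blocks
    for b in range(n_blocks):
        x = traj.unwrapped[b * size : (b + 1) * size]
        if len(x) < 10:
            continue
        bl = np.arange(len(x)) * dt
        bm = _msd_fft(x)
        bsel = (bl >= lo) & (bl <= min(hi, bl[-1])) & (bl > 0)
        if bsel.sum() >= 2:
            bw = (len(x) - np.arange(len(x)))[bsel].astype(float)
            bs = np.polyfit(bl[bsel], bm[bsel], 1, w=np.sqrt(bw))[0]
            block_ds.append(max(bs, 0.0) / 6.0 * NM2_PER_PS_TO_M2_PER_S)
    d_sd = (
        float(np.std(block_ds, ddof=1) / np.sqrt(len(block_ds)))
        if len(block_ds) > 1
        else np.nan
    )
    return MSDResult(
        d=float(d),
        d_sd=d_sd,
        lags_ps=lags,
        msd_nm2=msd,
        fit_window_ps=(float(lo), float(hi)),
        loglog_slope=float(ll_slope),
        diffusive=diffusive,
    )


# ---------------------------------------------------------------------------
# hidden Markov modelling
# ---------------------------------------------------------------------------


def _hmm_fit_raw(
    obs: np.ndarray,
    n_states: int,
    seed: int,
    n_iter: int = 200,
    tol: float = 1e-4,
) -> GaussianHMM:
    model = GaussianHMM(
        n_components=n_states,
        covariance_type="spherical",
        n_iter=n_iter,
        tol=tol,
        random_state=seed,
        min_covar=1e-6,
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model.fit(obs)
    if not model.monitor_.converged and n_iter >= 100:
        history = list(model.monitor_.history)
        raise RuntimeError(
            f"EM did not converge after {n_iter} iterations; "
            f"log-likelihood trace tail: {history}"
        )
    return model


def _stationary(transmat: np.ndarray) -> np.ndarray:
    vals, vecs = np.linalg.eig(transmat.T)
    i = int(np.argmin(np.abs(vals - 1.0)))
    pi = np.real(vecs[:, i])
    pi = np.abs(pi)
    return pi / pi.sum()


def _timescales(transmat: np.ndarray, lag_ps: float) -> np.ndarray:
    """Implied relaxation timescales t_i = -lag / ln lambda_i, ns."""
    vals = np.linalg.eigvals(transmat)
    vals = np.sort(np.abs(np.real(vals)))[::-1]
    out = []
    for lam in vals[1:]:  # skip the stationary eigenvalue
        if 1e-12 < lam < 1.0 - 1e-12:
            out.append(-lag_ps / np.log(lam) * 1e-3)
    return np.array(sorted(out, reverse=True))


def fit_hmm(
    traj: Trajectory,
    n_states: int,
    lag: float = 10.0,
    n_bootstrap: int = 25,
    seed: int = 0,
    ci: float = 0.95,
) -> MarkovModel:
    """Fit a Gaussian-emission HMM to tracer positions at lag ``lag`` (ps).

    Positions are subsampled to the lag interval, the HMM is trained by
    expectation-maximization (k-means initialization), the most-likely
    state path comes from the Viterbi decoder, and relaxation timescales
    from the transition-matrix eigenvalues.  Credibility intervals are a
    parametric bootstrap: synthetic trajectories are resampled from the
    fitted model and refit.
    """
    dt = traj.dt
    stride = max(1, int(round(lag / dt)))
    lag_ps = stride * dt
    obs = traj.positions[::stride]
    if len(obs) < 50:
        raise ValueError(
            f"trajectory has {len(obs)} lagged frames; need >= 50 x lag"
        )
    if n_states < 1:
        raise ValueError("n_states must be >= 1")

    while True:
        model = _hmm_fit_raw(obs, n_states, seed)
        path = model.predict(obs)
        used = np.unique(path)
        if len(used) == n_states or n_states == 1:
            break
        warnings.warn(
            f"{n_states - len(used)} state(s) empty after fitting; "
            f"refitting with n_states={len(used)}",
            stacklevel=2,
        )
        n_states = len(used)

    transmat = model.transmat_
    sds = np.sqrt(model.covars_[:, 0, 0])
    ts = _timescales(transmat, lag_ps)

    ci_arr = None
    if n_bootstrap > 0 and n_states > 1 and len(ts):
        rng = np.random.default_rng(seed + 1)
        boot = []
        for _ in range(n_bootstrap):
            bseed = int(rng.integers(2**31 - 1))
            bx, _ = model.sample(len(obs), random_state=bseed)
            try:
                bmodel = _hmm_fit_raw(bx, n_states, bseed, n_iter=100)
            except RuntimeError:
                continue
            bts = _timescales(bmodel.transmat_, lag_ps)
            if len(bts) == len(ts):
                boot.append(bts)
        if len(boot) >= 5:
            boot = np.asarray(boot)
            alpha = (1.0 - ci) / 2.0
            ci_arr = np.quantile(boot, [alpha, 1.0 - alpha], axis=0)

    return MarkovModel(
        n_states=n_states,
        means=model.means_.copy(),
        sds=sds,
        transmat=transmat.copy(),
        lag_ps=lag_ps,
        stationary=_stationary(transmat),
        state_sequence=path,
        timescales_ns=ts,
        timescale_ci_ns=ci_arr,
        log_likelihood=float(model.score(obs)),
        meta={"stride": stride, "n_bootstrap": n_bootstrap, "seed": seed},
    )


def _n_hmm_params(n: int) -> int:
    # transitions n(n-1) + start (n-1) + means 3n + spherical variances n
    return n * (n - 1) + (n - 1) + 4 * n


def select_n_states(
    traj: Trajectory,
    lag: float = 10.0,
    candidates=(1, 2, 3, 4),
    train_fraction: float = 0.7,
    tie_tolerance: float = 2.0,
    seed: int = 0,
):
    """Choose the number of metastable states by held-out likelihood.

    Fits each candidate on the first 70 % of the (lagged) trajectory and
    scores the final 30 %, penalizing parameters BIC-style on the
    held-out size.  Candidates within ``tie_tolerance`` score units of
    the best are treated as ties and the smallest wins (flagged).

    Returns ``(n_states, diagnostics)`` where diagnostics maps candidate
    -> penalized score, plus a ``tie`` flag.
    """
    candidates = sorted(set(int(c) for c in candidates))
    if any(c < 1 or c > 8 for c in candidates):
        raise ValueError("candidates must lie in 1..8")
    dt = traj.dt
    stride = max(1, int(round(lag / dt)))
    obs = traj.positions[::stride]
    split = int(len(obs) * train_fraction)
    train, test = obs[:split], obs[split:]
    if len(train) < 20 or len(test) < 10:
        raise ValueError("trajectory too short to split for state selection")

    scores: dict[int, float] = {}
    for n in candidates:
        try:
            model = _hmm_fit_raw(train, n, seed)
            ll = model.score(test)
        except (RuntimeError, ValueError):
            scores[n] = -np.inf
            continue
        scores[n] = float(ll - 0.5 * _n_hmm_params(n) * np.log(len(test)))

    best_score = max(scores.values())
    tied = [n for n, s in scores.items() if best_score - s <= tie_tolerance]
    chosen = min(tied)
    diagnostics = {
        "scores": scores,
        "tie": len(tied) > 1,
        "tied_candidates": tied,
        "lag_ps": stride * dt,
    }
    if len(tied) > 1:
        warnings.warn(
            f"state-count candidates {tied} tie within {tie_tolerance}; "
            f"choosing the smallest ({chosen})",
            stacklevel=2,
        )
    return chosen, diagnostics


# ---------------------------------------------------------------------------
# PMF
# ---------------------------------------------------------------------------


def compute_pmf(
    positions: np.ndarray | Trajectory,
    plane: tuple[int, int] = (1, 2),
    bin_width: float = 0.05,
    box: np.ndarray | None = None,
    min_samples: int = 10_000,
) -> PMFGrid:
    """Boltzmann-inversion PMF on a 2-D projection: PMF = -ln P, kBT.

    ``positions`` is an (n, 3) sample or a Trajectory (wrapped positions
    are used).  The gauge is fixed so the minimum over sampled bins is
    zero; unsampled bins are masked (nan), never zero-filled.
    """
    if isinstance(positions, Trajectory):
        if box is None:
            box = positions.box
        positions = positions.positions
    positions = np.asarray(positions, dtype=float)
    if bin_width <= 0:
        raise ValueError("bin width must be positive")
    if len(positions) < min_samples:
        raise ValueError(
            f"{len(positions)} samples < {min_samples}; PMF would be noise"
        )
    i, j = plane
    xy = positions[:, [i, j]]
    if box is not None:
        lo = np.zeros(2)
        hi = np.array([box[i], box[j]], dtype=float)
    else:
        lo = xy.min(axis=0)
        hi = xy.max(axis=0) + 1e-12
    nx = max(1, int(np.ceil((hi[0] - lo[0]) / bin_width)))
    ny = max(1, int(np.ceil((hi[1] - lo[1]) / bin_width)))
    edges_x = np.linspace(lo[0], hi[0], nx + 1)
    edges_y = np.linspace(lo[1], hi[1], ny + 1)
    counts, _, _ = np.histogram2d(xy[:, 0], xy[:, 1], bins=[edges_x, edges_y])
    if counts.max() > 0.9 * len(xy):
        warnings.warn(
            "more than 90 % of samples fall in one bin: bin width too large",
            stacklevel=2,
        )
    p = counts / counts.sum()
    mask = counts == 0
    with np.errstate(divide="ignore"):
        pmf = -np.log(np.where(mask, np.nan, p))
    pmf -= np.nanmin(pmf)
    return PMFGrid(
        edges_x=edges_x, edges_y=edges_y, values=pmf, mask=mask, plane=plane
    )


def pmf_change_metric(a: PMFGrid, b: PMFGrid, min_overlap: float = 0.05):
    """Mean |delta PMF| over co-sampled bins; returns (metric, coverage)."""
    if a.values.shape != b.values.shape:
        raise ValueError("PMF grids have different shapes")
    both = ~(a.mask | b.mask)
    coverage = float(both.mean())
    if coverage < min_overlap:
        raise ValueError(
            f"only {coverage:.1%} of bins sampled in both PMFs; "
            "comparison is meaningless"
        )
    return float(np.mean(np.abs(a.values[both] - b.values[both]))), coverage


def frozen_matrix_probe(
    potential,
    phase_times_ps,
    n_steps: int = 200_000,
    dt: float = 0.01,
    friction: float = 10.0,
    plane: tuple[int, int] = (1, 2),
    bin_width: float = 0.05,
    sample_stride: int = 10,
    seed: int = 0,
    per_slice_seeds: bool = True,
):
    """Probe cavity evolution by sampling in potentials frozen in time.

    The fluctuating multi-well potential is frozen at each phase time
    (default protocol: slices 1 ns apart), a tracer is equilibrated in
    each frozen landscape, and sequential PMFs are compared.  Returns
    ``(pmfs, change_metrics, coverages)`` where change metric k compares
    slices k and k+1 (mean |delta PMF| over co-sampled bins).

    With ``per_slice_seeds=False`` every slice reuses the same noise
    stream, so a static potential yields exactly zero change; the default
    draws fresh noise per slice, so the static change metric measures the
    sampling-noise floor (the right control for fluctuation detection).
    """
    from .synthetic_data import gen_langevin_trajectory

    if not hasattr(potential, "frozen"):
        raise TypeError("potential must support frozen(t) snapshots")
    pmfs = []
    for k, t_phase in enumerate(phase_times_ps):
        frozen = potential.frozen(float(t_phase))
        traj = gen_langevin_trajectory(
            frozen,
            box=tuple(frozen.box),
            friction=friction,
            dt=dt,
            n_steps=n_steps,
            sample_stride=sample_stride,
            x0=frozen.centers[0],
            seed=seed + k if per_slice_seeds else seed,
        )
        pmfs.append(
            compute_pmf(traj, plane=plane, bin_width=bin_width, box=frozen.box)
        )
    metrics, coverages = [], []
    for a, b in zip(pmfs[:-1], pmfs[1:]):
        m, c = pmf_change_metric(a, b)
        metrics.append(m)
        coverages.append(c)
    return pmfs, np.array(metrics), np.array(coverages)


# ---------------------------------------------------------------------------
# transition state theory
# ---------------------------------------------------------------------------


def tst_barrier(
    rate: float, prefactor: float | None = None, temperature: float = 300.0
) -> BarrierEstimate:
    """Free-energy barrier (kBT) from a rate: delta_g = ln(prefactor/rate).

    Default prefactor is the thermal attempt frequency k_B T / h in
    ns^-1 (~6.25e3 ns^-1 at 300 K).
    """
    if prefactor is None:
        prefactor = kt_over_h_per_ns(temperature)
    if rate <= 0 or prefactor <= 0:
        raise ValueError("rate and prefactor must be positive")
    if rate > prefactor:
        raise ValueError("rate exceeds prefactor: barrier would be negative")
    return BarrierEstimate(
        delta_g=float(np.log(prefactor / rate)),
        rate=float(rate),
        prefactor=float(prefactor),
    )


def tst_rate(
    delta_g: float, prefactor: float | None = None, temperature: float = 300.0
) -> float:
    """Rate (ns^-1) from a barrier: k = prefactor * exp(-delta_g)."""
    if prefactor is None:
        prefactor = kt_over_h_per_ns(temperature)
    if prefactor <= 0:
        raise ValueError("prefactor must be positive")
    if delta_g < 0:
        raise ValueError("barrier must be non-negative")
    return float(prefactor * np.exp(-delta_g))


# ---------------------------------------------------------------------------
# hop statistics
# ---------------------------------------------------------------------------


def _dwell_filter(states: np.ndarray, min_frames: int) -> np.ndarray:
    """Merge excursions shorter than ``min_frames`` into the prior state."""
    if min_frames <= 1 or len(states) == 0:
        return states.copy()
    out = states.copy()
    i = 0
    n = len(out)
    while i < n:
        j = i
        while j < n and out[j] == out[i]:
            j += 1
        if (j - i) < min_frames and i > 0:
            out[i:j] = out[i - 1]
        else:
            i = j
            continue
        i = j
    return out


def hop_statistics(model: MarkovModel, min_dwell: float | None = None) -> HopStatistics:
    """Hop counts, dwell-time distributions and return-trip fraction.

    Excursions shorter than ``min_dwell`` (ps; default 2 frames) are
    merged into the surrounding state before counting, suppressing
    recrossing noise.  Return-trip fraction is the fraction of hops whose
    *next* hop goes back to the origin state.
    """
    seq = model.state_sequence
    frame_ps = model.lag_ps
    if min_dwell is None:
        min_dwell = 2.0 * frame_ps
    if min_dwell < frame_ps:
        raise ValueError("min_dwell must be >= the frame interval")
    min_frames = max(1, int(round(min_dwell / frame_ps)))
    filt = _dwell_filter(seq, min_frames)

    # run-length encode
    change = np.nonzero(np.diff(filt))[0]
    run_starts = np.concatenate(([0], change + 1))
    run_states = filt[run_starts]
    run_lengths = np.diff(np.concatenate((run_starts, [len(filt)])))

    n_hops = len(run_states) - 1
    duration_ns = (len(seq) - 1) * frame_ps * 1e-3
    hops_per_ns = n_hops / duration_ns if duration_ns > 0 else 0.0

    dwells: dict[int, np.ndarray] = {}
    for s in range(model.n_states):
        sel = run_states == s
        dwells[s] = run_lengths[sel] * frame_ps * 1e-3

    if n_hops >= 2:
        origins = run_states[:-2]
        nexts = run_states[2:]
        rt = float(np.mean(origins == nexts))
    else:
        rt = 0.0
    return HopStatistics(
        hops_per_ns=float(hops_per_ns),
        n_hops=int(n_hops),
        dwell_times_ns=dwells,
        return_trip_fraction=rt,
        min_dwell_ps=float(min_frames * frame_ps),
    )


# ---------------------------------------------------------------------------
# autocorrelation
# ---------------------------------------------------------------------------


def position_autocorrelation(
    traj: Trajectory, max_lag_fraction: float = 0.5
) -> AutocorrelationResult:
    """Normalized position-position autocovariance and decorrelation time.

    C(tau) = <dx(t) . dx(t+tau)> / <|dx|^2> with dx the displacement from
    the mean position.  The decorrelation time is the first lag where
    C < 1/e (linearly interpolated).  The result is censored (reported
    value is a lower bound) when C never falls below 1/e within the
    sampled lags, or when the crossing happens so late (beyond a quarter
    of the trajectory) that it cannot be distinguished from
    non-stationary drift.
    """
    if traj.n_frames < 100:
        raise ValueError("need at least 100 frames")
    x = traj.unwrapped if traj.unwrapped is not None else traj.positions
    dx = x - x.mean(axis=0)
    n = len(dx)
    max_lag = int(n * max_lag_fraction)
    nfft = 1 << (2 * n - 1).bit_length()
    acf = np.zeros(n)
    for dim in range(3):
        f = np.fft.rfft(dx[:, dim], nfft)
        acf += np.fft.irfft(f * np.conj(f), nfft)[:n]
    acf /= n - np.arange(n)
    c = acf[:max_lag] / acf[0]
    lags = np.arange(max_lag) * traj.dt

    thresh = 1.0 / np.e
    below = np.nonzero(c < thresh)[0]
    if len(below) == 0:
        return AutocorrelationResult(
            lags_ps=lags,
            correlation=c,
            decorrelation_time_ns=float(lags[-1]) * 1e-3,
            censored=True,
        )
    k = below[0]
    if k == 0:
        t_dec = lags[0] if lags[0] > 0 else traj.dt
    else:
        # linear interpolation between lags k-1 and k
        frac = (c[k - 1] - thresh) / (c[k - 1] - c[k])
        t_dec = lags[k - 1] + frac * (lags[k] - lags[k - 1])
    censored = bool(t_dec > 0.25 * (traj.times[-1] - traj.times[0]))
    return AutocorrelationResult(
        lags_ps=lags,
        correlation=c,
        decorrelation_time_ns=float(t_dec) * 1e-3,
        censored=censored,
    )


# ---------------------------------------------------------------------------
# slicing
# ---------------------------------------------------------------------------


def slice_and_model(
    traj: Trajectory,
    slice_length_ns: float = 1.0,
    lag: float = 10.0,
    candidates=(1, 2, 3, 4),
    n_bootstrap: int = 0,
    seed: int = 0,
):
    """Split a trajectory into fixed-length slices and model each one.

    For each slice, the state count is selected by held-out likelihood
    and an HMM fitted; slices too short for the lag are skipped with a
    warning.  Returns a list of ``(slice_index, MarkovModel or None)``.
    The default slice length of 1 ns matches the matrix reorganisation
    bound from the position autocorrelation analysis.
    """
    n_slice = max(1, int(round(slice_length_ns * 1e3 / traj.dt)))
    n_slices = max(1, traj.n_frames // n_slice)
    if n_slices == 1:
        n_slice = traj.n_frames
    out = []
    for k in range(n_slices):
        sub = traj.slice_frames(k * n_slice, (k + 1) * n_slice)
        stride = max(1, int(round(lag / traj.dt)))
        if sub.n_frames // stride < 50:
            warnings.warn(
                f"slice {k} too short for lag {lag} ps; skipped", stacklevel=2
            )
            out.append((k, None))
            continue
        try:
            n, _ = select_n_states(sub, lag=lag, candidates=candidates, seed=seed + k)
            model = fit_hmm(
                sub, n_states=n, lag=lag, n_bootstrap=n_bootstrap, seed=seed + k
            )
        except (ValueError, RuntimeError) as exc:
            warnings.warn(f"slice {k} modelling failed: {exc}", stacklevel=2)
            out.append((k, None))
            continue
        out.append((k, model))
    return out
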