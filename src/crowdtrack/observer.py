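"""Synthetic tracking observers.

No generative observer accompanies the analysis chain in the experimental
literature this package models, so one is defined here with exactly the
statistical structure the estimators assume:

* **motor latency** -- the response follows the stimulus with a pure delay;
* **pursuit lag** -- a first-order time constant, entering as its
  steady-state error ``-omega * tau`` under the current rotation;
* **hinged heteroscedastic percept noise** -- wrapped-normal report noise
  whose SD grows linearly as the flanker intrudes below the observer's
  crowding extent (the hinge), and is flat at baseline beyond it;
* **post-jump recovery** -- for one latency period after a jump the
  response continues the pre-jump trajectory (so the error jumps by the
  stimulus reassignment); re-acquisition is then modeled as inflated
  report noise relaxing exponentially at a condition-specific rate.

The recovery enters as *variance inflation* calibrated on the wrapped
scale: the per-frame noise SD is chosen so that the expected absolute
(wrapped) error after a jump is exactly ``|e0| * exp(-b t) + floor`` --
the same exponential-plus-floor form the decay-fitting analysis assumes.
A signed decaying offset would instead approach the noise floor
quadratically in its own amplitude and bias the fitted rate upward by
tens of percent; the calibrated variance-inflation form keeps the
estimator correctly specified at any noise level. Percept
noise is AR(1)-smoothed at the pursuit time constant to mimic the smooth
error autocorrelation of real tracking data.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Optional

import numpy as np
from scipy.optimize import brentq
from scipy.signal import lfilter
from scipy.special import i0e, i1e
from scipy.stats import vonmises

from .angles import signed_diff_deg, wrap_deg
from .paradigm import (FLANKED, ConfigError, ParadigmConfig, StimulusTrace,
                       TrialSpec, build_block_schedule,
                       build_trial_based_schedule, generate_continuous_trial)

_SEED_MAX = 2**31 - 1


@dataclass
class ObserverConfig:
    """Generative parameters of a synthetic observer.

    ``crowding_extent_deg`` is the true hinge e_c: below it, report-noise SD
    rises by ``crowding_slope_deg_per_deg`` per degree of flanker intrusion.
    Recovery rates are the exponential decay constants of post-jump error,
    per condition. ``trial_based_kappa_fn`` maps target-flanker distance to
    a Von Mises concentration; the default inverts circular SD so that the
    trial-based report distribution shares the continuous hinge exactly.
    """

    motor_latency_ms: float = 280.0
    tracking_time_constant_ms: float = 150.0
    baseline_noise_sd_deg: float = 10.0
    crowding_extent_deg: float = 5.0
    crowding_slope_deg_per_deg: float = 8.0
    recovery_rate_flanked_per_s: float = 2.0
    recovery_rate_isolated_per_s: float = 3.5
    trial_based_kappa_fn: Optional[Callable[[float], float]] = None
    predictive: bool = True
    seed: int = 0
    observer_id: str = "obs"

    def __post_init__(self):
        for name in ("motor_latency_ms", "tracking_time_constant_ms",
                     "baseline_noise_sd_deg", "crowding_extent_deg",
                     "crowding_slope_deg_per_deg", "recovery_rate_flanked_per_s",
                     "recovery_rate_isolated_per_s"):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be >= 0")


@dataclass
class TrackingTrace:
    """Paired stimulus/response orientation series of one continuous trial."""

    trial_id: str
    time_s: np.ndarray
    theta_stimulus_deg: np.ndarray
    theta_response_deg: np.ndarray
    condition: str
    distance_trend: str
    jump_indices: np.ndarray
    flanker_distance_deg: np.ndarray
    gap_mask: np.ndarray = field(default=None)  # True = frame excluded upstream

    def __post_init__(self):
        if self.gap_mask is None:
            self.gap_mask = np.zeros(self.time_s.size, dtype=bool)


@dataclass
class TrialBasedReport:
    trial_id: str
    condition: str
    distance_deg: Optional[float]
    target_ori_deg: float
    report_ori_deg: float


_WN_GRID_SD = None
_WN_GRID_ABS = None
_WN_ABS_CAP = 88.0  # below the uniform-limit mean |error| of 90 deg


def wrapped_abs_mean(sd_deg):
    """E|error| for error ~ wrapped normal(0, sd) on (-180, 180], degrees."""
    sd = np.atleast_1d(np.asarray(sd_deg, dtype=float))
    u = np.linspace(-180.0, 180.0, 1441)
    out = np.empty(sd.shape)
    for i, s in enumerate(sd.ravel()):
        if s == 0:
            out.ravel()[i] = 0.0
            continue
        k = np.arange(-int(np.ceil(3 * s / 360.0)) - 1, int(np.ceil(3 * s / 360.0)) + 2)
        dens = np.exp(-((u[:, None] + 360.0 * k[None, :]) ** 2) / (2 * s * s)).sum(axis=1)
        dens /= s * np.sqrt(2 * np.pi)
        out.ravel()[i] = np.trapezoid(np.abs(u) * dens, u)
    return out if np.ndim(sd_deg) else float(out[0])


def _wn_tables():
    global _WN_GRID_SD, _WN_GRID_ABS
    if _WN_GRID_SD is None:
        _WN_GRID_SD = np.concatenate([np.linspace(0.0, 100.0, 501),
                                      np.linspace(101.0, 400.0, 300)])
        _WN_GRID_ABS = wrapped_abs_mean(_WN_GRID_SD)
    return _WN_GRID_SD, _WN_GRID_ABS


def sd_for_wrapped_abs_mean(target_abs_deg):
    """Inverse of :func:`wrapped_abs_mean` (targets capped below saturation)."""
    grid_sd, grid_abs = _wn_tables()
    target = np.minimum(np.asarray(target_abs_deg, dtype=float), _WN_ABS_CAP)
    return np.interp(target, grid_abs, grid_sd)


def _wrapped_abs_mean_interp(sd_deg):
    grid_sd, grid_abs = _wn_tables()
    return np.interp(np.asarray(sd_deg, dtype=float), grid_sd, grid_abs)


def perceived_noise_sd(distance_deg, observer: ObserverConfig):
    """Hinged report-noise SD: baseline + slope * max(0, e_c - d), in degrees."""
    d = np.asarray(distance_deg, dtype=float)
    return observer.baseline_noise_sd_deg + observer.crowding_slope_deg_per_deg * np.maximum(
        0.0, observer.crowding_extent_deg - d)


def _vm_mean_resultant(kappa: float) -> float:
    return i1e(kappa) / i0e(kappa)


def kappa_for_circular_sd(sd_deg: float) -> float:
    """Von Mises concentration whose circular SD equals ``sd_deg``.

    Circular SD is sqrt(-2 ln Rbar) with Rbar = I1(kappa)/I0(kappa); the
    inverse is found numerically. Returns inf for sd 0.
    """
    if sd_deg < 0:
        raise ValueError("sd_deg must be >= 0")
    if sd_deg == 0:
        return np.inf
    target_r = np.exp(-np.radians(sd_deg) ** 2 / 2.0)
    lo, hi = 1e-9, 1e9
    if _vm_mean_resultant(hi) < target_r:
        return hi
    if _vm_mean_resultant(lo) > target_r:
        return lo
    return brentq(lambda k: _vm_mean_resultant(k) - target_r, lo, hi, xtol=1e-12, rtol=1e-12)


def trial_based_kappa(distance_deg: Optional[float], observer: ObserverConfig) -> float:
    """Concentration of the trial-based report distribution at a distance.

    Isolated trials (distance None) use the concentration at/beyond the
    hinge, i.e. the baseline noise level.
    """
    if observer.trial_based_kappa_fn is not None:
        d = observer.crowding_extent_deg if distance_deg is None else distance_deg
        return observer.trial_based_kappa_fn(d)
    if distance_deg is None:
        sd = observer.baseline_noise_sd_deg
    else:
        sd = float(perceived_noise_sd(distance_deg, observer))
    return kappa_for_circular_sd(sd)


def simulate_tracking_response(stimulus: StimulusTrace, observer: ObserverConfig,
                               rng: np.random.Generator) -> TrackingTrace:
    """Simulate the observer's continuous orientation report for one trial.

    Two tracking regimes:

    * ``predictive=True`` (default): the observer anticipates the constant,
      predictable rotation, so steady-state tracking carries no phase lag
      (as in smooth pursuit of predictable motion). The motor latency shows
      only at the unpredictable jumps: for one latency period after a jump
      the response continues the pre-jump trajectory; the carried error then
      relaxes as exponentially decaying noise inflation at the condition's
      recovery rate (see module docstring).
    * ``predictive=False``: a pure-delay tracker -- the response is the
      stimulus delayed by the motor latency, offset by the steady-state
      first-order-lag error ``-omega * tau``, with a signed decaying error
      state injected at each jump.

    Both regimes add AR(1)-correlated wrapped-normal percept noise whose SD
    follows the crowding hinge at the flanker distance. All arithmetic is
    circular; the output is wrapped to [0, 360).
    """
    n = stimulus.n_frames
    dt = 1.0 / stimulus.sample_rate_hz
    t = stimulus.time_s
    lat_frames = int(round(observer.motor_latency_ms / 1000.0 * stimulus.sample_rate_hz))
    delayed = np.maximum(np.arange(n) - lat_frames, 0)

    theta = stimulus.target_orientation_deg
    tau_s = observer.tracking_time_constant_ms / 1000.0
    step = stimulus.rotation_speed_deg_s / stimulus.sample_rate_hz
    rate = (observer.recovery_rate_flanked_per_s if stimulus.condition == FLANKED
            else observer.recovery_rate_isolated_per_s)

    # percept-noise SD from the hinge (per frame)
    if stimulus.condition == FLANKED:
        sd = perceived_noise_sd(stimulus.flanker_distance_deg[delayed], observer)
    else:
        sd = np.full(n, observer.baseline_noise_sd_deg)

    e = np.zeros(n)
    if observer.predictive:
        s = theta.astype(float).copy()
        abs_target = np.zeros(n)
        for j in stimulus.jump_indices:
            if j <= 0:
                continue
            old_ori = theta[j - 1]
            old_dir = stimulus.rotation_direction[j - 1]
            i0 = min(j + lat_frames, n)
            # latency window: the response still follows the old trajectory
            idx = np.arange(j, i0)
            s[idx] = old_ori + old_dir * step * (idx - (j - 1))
            if i0 < n:
                carried = old_ori + old_dir * step * (i0 - (j - 1))
                e0 = abs(float(signed_diff_deg(carried, theta[i0])))
                # re-acquisition: the carried error relaxes as inflated report
                # noise; the target mean |error| decays exponentially from e0,
                # headroom-limited so the wrapped scale never saturates (a
                # high baseline thus shrinks the visible jump amplitude)
                floor_now = float(_wrapped_abs_mean_interp(sd[i0])) + abs_target[i0]
                e0 = max(0.0, min(e0, _WN_ABS_CAP - floor_now))
                abs_target[i0:] += e0 * np.exp(-rate * (t[i0:] - t[i0]))
        # per-frame noise SD chosen on the wrapped scale so the expected
        # |error| is exactly floor + sum of jump decays
        sd = sd_for_wrapped_abs_mean(_wrapped_abs_mean_interp(sd) + abs_target)
    else:
        s = theta[delayed]
        s = s + -stimulus.rotation_direction[delayed] * stimulus.rotation_speed_deg_s * tau_s
        for j in stimulus.jump_indices:
            if j <= 0:
                continue
            expected = theta[j - 1] + stimulus.rotation_direction[j - 1] * step
            delta = float(signed_diff_deg(theta[j], expected))
            i0 = j + lat_frames
            if i0 < n:
                e[i0:] += -delta * np.exp(-rate * (t[i0:] - t[i0]))

    # AR(1)-smoothed unit noise scaled by the total per-frame SD
    z = rng.standard_normal(n)
    phi = np.exp(-dt / tau_s) if tau_s > 0 else 0.0
    w = z * np.sqrt(1.0 - phi**2)
    w[0] = z[0]  # start in the stationary regime
    noise = sd * lfilter([1.0], [1.0, -phi], w)

    response = wrap_deg(s + e + noise)
    return TrackingTrace(
        trial_id=stimulus.trial_id,
        time_s=t,
        theta_stimulus_deg=theta,
        theta_response_deg=response,
        condition=stimulus.condition,
        distance_trend=stimulus.distance_trend,
        jump_indices=stimulus.jump_indices,
        flanker_distance_deg=stimulus.flanker_distance_deg,
    )


def simulate_trial_based_response(spec: TrialSpec, observer: ObserverConfig,
                                  rng: np.random.Generator) -> TrialBasedReport:
    """Simulate one trial-based report: Von Mises around the true orientation."""
    if spec.paradigm != "trial_based":
        raise ConfigError("simulate_trial_based_response needs a trial_based TrialSpec")
    target = float(rng.uniform(0.0, 360.0) % 360.0)
    d = spec.fixed_distance_deg if spec.condition == FLANKED else None
    kappa = trial_based_kappa(d, observer)
    if np.isinf(kappa):
        report = target
    else:
        err = np.degrees(vonmises.rvs(kappa, random_state=rng))
        report = float(wrap_deg(target + err))
    return TrialBasedReport(spec.trial_id, spec.condition, d, target, report)


@dataclass
class ContinuousTrial:
    spec: TrialSpec
    stimulus: StimulusTrace
    tracking: TrackingTrace


@dataclass
class ParticipantData:
    observer: ObserverConfig
    continuous_runs: list  # list of runs, each a list of ContinuousTrial
    trial_based: list  # list of TrialBasedReport


@dataclass
class Dataset:
    paradigm_config: ParadigmConfig
    participants: list
    seed: int = 0


def simulate_continuous_run(config: ParadigmConfig, observer: ObserverConfig,
                            run_seed: int) -> list:
    """Simulate one continuous block (schedule + stimulus + response)."""
    rng = np.random.default_rng(run_seed)
    trials = []
    for spec in build_block_schedule(config, rng):
        stim = generate_continuous_trial(spec, config, np.random.default_rng(spec.seed))
        track = simulate_tracking_response(stim, observer,
                                           np.random.default_rng([spec.seed, 17]))
        trials.append(ContinuousTrial(spec, stim, track))
    return trials


def simulate_trial_based_session(config: ParadigmConfig, observer: ObserverConfig,
                                 session_seed: int) -> list:
    rng = np.random.default_rng(session_seed)
    return [simulate_trial_based_response(spec, observer, np.random.default_rng([spec.seed, 29]))
            for spec in build_trial_based_schedule(config, rng)]


def generate_dataset(paradigm_config: ParadigmConfig, observer_configs: list,
                     n_runs: int = 2, seed: int = 0) -> Dataset:
    """Full synthetic study: per observer, ``n_runs`` continuous blocks plus
    one trial-based session, all reproducible from ``seed``."""
    if n_runs < 1:
        raise ConfigError("n_runs must be >= 1")
    master = np.random.default_rng(seed)
    participants = []
    for i, obs in enumerate(observer_configs):
        if not obs.observer_id or obs.observer_id == "obs":
            obs = ObserverConfig(**{**obs.__dict__, "observer_id": f"obs{i + 1:02d}"})
        run_seeds = [int(master.integers(0, _SEED_MAX)) for _ in range(n_runs + 1)]
        runs = [simulate_continuous_run(paradigm_config, obs, run_seeds[r])
                for r in range(n_runs)]
        tb = simulate_trial_based_session(paradigm_config, obs, run_seeds[-1])
        participants.append(ParticipantData(obs, runs, tb))
    return Dataset(paradigm_config, participants, seed=seed)
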