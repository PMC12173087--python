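"""Stimulus-side construction of the crowding paradigms.

Two paradigms are modeled. In the *continuous* paradigm a Landolt-C target
(optionally surrounded by a four-gap flanker ring) rotates at a constant
angular speed while the target-flanker distance sweeps slowly between its
bounds; whenever the sweep crosses one of a set of preselected distances,
all gap orientations are randomly reassigned (a "jump") and the rotation
direction is redrawn. In the *trial-based* paradigm the gap orientations
are static and each trial presents a single fixed target-flanker distance.

This module builds the per-frame stimulus channels (orientations, distance,
direction, jump annotations) and the block/trial schedules; it performs no
rendering. Geometry fields (eccentricity) are metadata only.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .angles import wrap_deg

FLANKED = "flanked"
ISOLATED = "isolated"
INCREASING = "increasing"
DECREASING = "decreasing"

_SEED_MAX = 2**31 - 1


class ConfigError(ValueError):
    """Raised when a configuration violates its invariants."""


@dataclass
class ParadigmConfig:
    """Parameters of the stimulus paradigms.

    Defaults reproduce the reference experimental conditions: 144 Hz
    display, 40 s trials, 72 deg/s gap rotation, a 0.13 deg/s distance
    sweep over [0, 5] deg, five preselected jump distances, flanker gap
    orientations drawn around the target with 45 deg SD, and block
    compositions of 8 flanked + 4 isolated continuous trials and
    (7 flanked distances + isolated) x 25 trial-based repetitions.
    """

    sample_rate_hz: float = 144.0
    trial_duration_s: float = 40.0
    rotation_speed_deg_s: float = 72.0
    distance_speed_deg_s: float = 0.13
    distance_min_deg: float = 0.0
    distance_max_deg: float = 5.0
    jump_distances_deg: tuple = (0.31, 0.35, 1.35, 2.20, 3.37)
    flanker_gap_sd_deg: float = 45.0
    eccentricity_deg: float = 10.0  # metadata only
    n_flanked_per_block: int = 8
    n_isolated_per_block: int = 4
    trial_based_distances_deg: tuple = (0.0, 0.31, 0.35, 1.35, 2.20, 3.37, 5.0)
    trial_based_reps: int = 25
    seed: int = 0

    def __post_init__(self):
        if self.sample_rate_hz <= 0:
            raise ConfigError("sample_rate_hz must be > 0")
        if self.trial_duration_s <= 0:
            raise ConfigError("trial_duration_s must be > 0")
        if self.rotation_speed_deg_s < 0:
            raise ConfigError("rotation_speed_deg_s must be >= 0")
        if self.distance_speed_deg_s < 0:
            raise ConfigError("distance_speed_deg_s must be >= 0")
        if self.distance_min_deg >= self.distance_max_deg:
            raise ConfigError("distance_min_deg must be < distance_max_deg")
        jd = tuple(float(d) for d in self.jump_distances_deg)
        if any(not (self.distance_min_deg < d < self.distance_max_deg) for d in jd):
            raise ConfigError(
                "jump_distances_deg must lie strictly inside "
                f"({self.distance_min_deg}, {self.distance_max_deg})"
            )
        if list(jd) != sorted(jd):
            raise ConfigError("jump_distances_deg must be sorted ascending")
        self.jump_distances_deg = jd
        if self.n_flanked_per_block % 2 != 0:
            raise ConfigError("n_flanked_per_block must be even (half per trend)")
        if self.n_flanked_per_block < 0 or self.n_isolated_per_block < 0:
            raise ConfigError("block trial counts must be >= 0")
        if self.trial_based_reps < 1:
            raise ConfigError("trial_based_reps must be >= 1")
        self.trial_based_distances_deg = tuple(float(d) for d in self.trial_based_distances_deg)

    @property
    def n_frames(self) -> int:
        return int(round(self.sample_rate_hz * self.trial_duration_s))

    @property
    def dt_s(self) -> float:
        return 1.0 / self.sample_rate_hz

    @property
    def step_deg_per_frame(self) -> float:
        return self.rotation_speed_deg_s / self.sample_rate_hz


@dataclass
class TrialSpec:
    """Schedule entry describing one trial (artifact plumbing)."""

    paradigm: str  # "continuous" | "trial_based"
    condition: str  # FLANKED | ISOLATED
    distance_trend: Optional[str] = None  # continuous trials
    fixed_distance_deg: Optional[float] = None  # trial-based flanked trials
    jump_times_s: Optional[tuple] = None
    seed: int = 0
    trial_id: str = ""

    def __post_init__(self):
        if self.paradigm == "continuous":
            if self.distance_trend not in (INCREASING, DECREASING):
                raise ConfigError("continuous trials need a distance trend")
        elif self.paradigm == "trial_based":
            if self.condition == FLANKED and self.fixed_distance_deg is None:
                raise ConfigError("trial-based flanked trials need fixed_distance_deg")
        else:
            raise ConfigError(f"unknown paradigm {self.paradigm!r}")


@dataclass
class StimulusTrace:
    """Per-frame stimulus channels of one continuous trial."""

    time_s: np.ndarray
    target_orientation_deg: np.ndarray  # wrapped to [0, 360)
    flanker_gap_orientations_deg: Optional[np.ndarray]  # (n, 4) or None when isolated
    flanker_distance_deg: np.ndarray  # isolated trials carry the matched "as-if" sweep
    rotation_direction: np.ndarray  # per-frame sign in {+1, -1}
    jump_indices: np.ndarray
    condition: str
    distance_trend: str
    sample_rate_hz: float
    rotation_speed_deg_s: float
    trial_id: str = ""

    @property
    def n_frames(self) -> int:
        return self.time_s.size


def draw_target_orientation(rng: np.random.Generator) -> float:
    """Draw a gap orientation from the uniform circular distribution, deg in [0, 360)."""
    return float(rng.uniform(0.0, 360.0) % 360.0)


def assign_flanker_gaps(target_orientation_deg: float, rng: np.random.Generator,
                        sd_deg: float = 45.0) -> np.ndarray:
    """Draw the four flanker gap orientations for a given target orientation.

    The first gap is a wrapped-normal draw centered on the target orientation
    (SD ``sd_deg``); the remaining three sit at fixed 90 deg intervals from it.
    """
    gap1 = rng.normal(target_orientation_deg, sd_deg)
    return wrap_deg(gap1 + 90.0 * np.arange(4))


def log_spaced_jump_distances(n: int = 5, inner_deg: float = 0.8,
                              outer_deg: float = 5.8) -> np.ndarray:
    """Log-spaced distances between two borders, shifted so the inner border is 0.

    Helper reproducing the construction described for the preselected jump
    distances; the package default uses the explicitly listed values instead.
    """
    return np.geomspace(inner_deg, outer_deg, n) - inner_deg


def distance_trajectory(config: ParadigmConfig, trend: str,
                        start_distance_deg: Optional[float] = None) -> np.ndarray:
    """Per-frame target-flanker distance for a continuous trial.

    Increasing trials start at the minimum distance, decreasing at the
    maximum; the sweep is clamped (held) at the range boundary.
    """
    if trend == INCREASING:
        start = config.distance_min_deg
        sign = 1.0
    elif trend == DECREASING:
        start = config.distance_max_deg
        sign = -1.0
    else:
        raise ConfigError(f"unknown trend {trend!r}")
    if start_distance_deg is not None and not math.isclose(start_distance_deg, start):
        raise ConfigError(
            f"start_distance_deg={start_distance_deg} inconsistent with trend {trend!r}"
        )
    t = np.arange(config.n_frames) * config.dt_s
    d = start + sign * config.distance_speed_deg_s * t
    return np.clip(d, config.distance_min_deg, config.distance_max_deg)


def jump_times_for_trend(config: ParadigmConfig, trend: str) -> np.ndarray:
    """First-crossing times (s) of each preselected jump distance, ascending in time."""
    speed = config.distance_speed_deg_s
    if speed == 0:
        return np.array([])
    jd = np.asarray(config.jump_distances_deg)
    if trend == INCREASING:
        times = (jd - config.distance_min_deg) / speed
    elif trend == DECREASING:
        times = (config.distance_max_deg - jd[::-1]) / speed
    else:
        raise ConfigError(f"unknown trend {trend!r}")
    return times[(times > 0) & (times < config.trial_duration_s)]


def jump_frames_for_times(config: ParadigmConfig, times_s: Sequence[float]) -> np.ndarray:
    """First frame index at which each jump time has been reached."""
    frames = []
    for t in times_s:
        f = int(math.ceil(t * config.sample_rate_hz - 1e-9))
        if 0 < f < config.n_frames and f not in frames:
            frames.append(f)
    return np.array(frames, dtype=int)


def generate_continuous_trial(spec: TrialSpec, config: ParadigmConfig,
                              rng: Optional[np.random.Generator] = None) -> StimulusTrace:
    """Construct the full per-frame stimulus trace for one continuous trial.

    Between jumps the target (and flanker gaps, when present) advance by
    exactly ``rotation_speed / sample_rate`` per frame in the current
    direction. On a jump frame the target orientation is redrawn uniformly,
    flanker gaps are reassigned around it, and the rotation direction is
    redrawn uniformly over {clockwise, counterclockwise}. Isolated trials
    share the jump schedule of the matched trend and retain the "as-if"
    distance sweep internally but expose no flanker orientation channels.
    """
    if spec.paradigm != "continuous":
        raise ConfigError("generate_continuous_trial needs a continuous TrialSpec")
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    n = config.n_frames
    step = config.step_deg_per_frame
    flanked = spec.condition == FLANKED

    times = spec.jump_times_s
    if times is None:
        times = jump_times_for_trend(config, spec.distance_trend)
    jump_idx = jump_frames_for_times(config, times)

    theta = np.empty(n)
    gaps = np.empty((n, 4)) if flanked else None
    direction = np.empty(n)

    # initial draws: orientation, gaps (flanked only), direction
    ori = draw_target_orientation(rng)
    gap1 = assign_flanker_gaps(ori, rng, config.flanker_gap_sd_deg)[0] if flanked else 0.0
    cur_dir = 1.0 if rng.uniform() < 0.5 else -1.0

    bounds = [0, *jump_idx.tolist(), n]
    for k in range(len(bounds) - 1):
        s, e = bounds[k], bounds[k + 1]
        if k > 0:  # reassignment on the jump frame, before "rendering"
            ori = draw_target_orientation(rng)
            if flanked:
                gap1 = assign_flanker_gaps(ori, rng, config.flanker_gap_sd_deg)[0]
            cur_dir = 1.0 if rng.uniform() < 0.5 else -1.0
        ramp = cur_dir * step * np.arange(e - s)
        theta[s:e] = ori + ramp
        if flanked:
            gaps[s:e] = (gap1 + ramp[:, None]) + 90.0 * np.arange(4)[None, :]
        direction[s:e] = cur_dir

    return StimulusTrace(
        time_s=np.arange(n) * config.dt_s,
        target_orientation_deg=wrap_deg(theta),
        flanker_gap_orientations_deg=wrap_deg(gaps) if flanked else None,
        flanker_distance_deg=distance_trajectory(config, spec.distance_trend),
        rotation_direction=direction,
        jump_indices=jump_idx,
        condition=spec.condition,
        distance_trend=spec.distance_trend,
        sample_rate_hz=config.sample_rate_hz,
        rotation_speed_deg_s=config.rotation_speed_deg_s,
        trial_id=spec.trial_id,
    )


def _draw_seed(rng: np.random.Generator) -> int:
    return int(rng.integers(0, _SEED_MAX))


def build_block_schedule(config: ParadigmConfig,
                         rng: Optional[np.random.Generator] = None) -> list[TrialSpec]:
    """One continuous block: 8 flanked (4 per trend) + 4 isolated trials.

    Half the isolated trials share the increasing-trend jump schedule, half
    the decreasing one. The presentation order is a random permutation.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    specs: list[TrialSpec] = []
    half_fl = config.n_flanked_per_block // 2
    half_iso = config.n_isolated_per_block - config.n_isolated_per_block // 2
    for trend, n_fl in ((INCREASING, half_fl), (DECREASING, config.n_flanked_per_block - half_fl)):
        times = tuple(jump_times_for_trend(config, trend))
        for _ in range(n_fl):
            specs.append(TrialSpec("continuous", FLANKED, distance_trend=trend,
                                   jump_times_s=times, seed=_draw_seed(rng)))
    for trend, n_iso in ((INCREASING, half_iso),
                         (DECREASING, config.n_isolated_per_block - half_iso)):
        times = tuple(jump_times_for_trend(config, trend))
        for _ in range(n_iso):
            specs.append(TrialSpec("continuous", ISOLATED, distance_trend=trend,
                                   jump_times_s=times, seed=_draw_seed(rng)))
    order = rng.permutation(len(specs))
    specs = [specs[i] for i in order]
    for i, s in enumerate(specs):
        s.trial_id = f"c{i:03d}_{s.condition}_{s.distance_trend}"
    return specs


def build_trial_based_schedule(config: ParadigmConfig,
                               rng: Optional[np.random.Generator] = None) -> list[TrialSpec]:
    """Trial-based session: (flanked distances + isolated) x repetitions, permuted."""
    if rng is None:
        rng = np.random.default_rng(config.seed)
    specs: list[TrialSpec] = []
    for _ in range(config.trial_based_reps):
        for d in config.trial_based_distances_deg:
            specs.append(TrialSpec("trial_based", FLANKED, fixed_distance_deg=float(d),
                                   seed=_draw_seed(rng)))
        specs.append(TrialSpec("trial_based", ISOLATED, seed=_draw_seed(rng)))
    order = rng.permutation(len(specs))
    specs = [specs[i] for i in order]
    for i, s in enumerate(specs):
        tag = "iso" if s.condition == ISOLATED else f"d{s.fixed_distance_deg:.2f}"
        s.trial_id = f"t{i:03d}_{tag}"
    return specs
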