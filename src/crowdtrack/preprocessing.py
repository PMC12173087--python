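"""Raw tracking traces to cleaned, condition-averaged error series.

Implements the report-error definition (wrapped difference in [-180, 180)),
the flip-and-average of increasing/decreasing sweeps onto a common
increasing-distance axis, artifact cleaning keyed to the isolated
condition's error statistics, and post-jump window extraction for the
recovery analyses.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .angles import signed_diff_deg
from .observer import TrackingTrace
from .paradigm import ISOLATED


def report_error(theta_stimulus_deg, theta_response_deg):
    """Signed report error (response - stimulus), wrapped to [-180, 180)."""
    return signed_diff_deg(theta_response_deg, theta_stimulus_deg)


def _nanmean_cols(stack: np.ndarray) -> np.ndarray:
    """Column-wise mean ignoring NaN; all-NaN columns give NaN, silently."""
    finite = np.isfinite(stack)
    count = finite.sum(axis=0)
    total = np.where(finite, stack, 0.0).sum(axis=0)
    return np.where(count > 0, total / np.maximum(count, 1), np.nan)


@dataclass
class ErrorSeries:
    """Per-frame report error of one trial (or a condition average)."""

    time_s: np.ndarray
    signed_error_deg: Optional[np.ndarray]
    abs_error_deg: np.ndarray
    condition: str
    distance_trend: Optional[str] = None
    n_trials_averaged: int = 1
    deletion_mask: np.ndarray = field(default=None)  # True = deleted
    jump_indices: np.ndarray = field(default_factory=lambda: np.array([], dtype=int))

    def __post_init__(self):
        if self.deletion_mask is None:
            self.deletion_mask = np.zeros(self.time_s.size, dtype=bool)

    @property
    def n_frames(self) -> int:
        return self.time_s.size


def error_series_from_trace(trace: TrackingTrace) -> ErrorSeries:
    signed = report_error(trace.theta_stimulus_deg, trace.theta_response_deg)
    signed = signed.copy()
    signed[trace.gap_mask] = np.nan
    return ErrorSeries(
        time_s=trace.time_s,
        signed_error_deg=signed,
        abs_error_deg=np.abs(signed),
        condition=trace.condition,
        distance_trend=trace.distance_trend,
        deletion_mask=trace.gap_mask.copy(),
        jump_indices=np.asarray(trace.jump_indices, dtype=int),
    )


def artifact_mask(isolated_signed_error: np.ndarray) -> np.ndarray:
    """Deletion mask from an isolated-condition signed report-error series.

    Thresholds come from the signed report errors (the series' mean and
    SD): a *peak* is a frame whose error magnitude exceeds twice the SD;
    around each peak, the maximal contiguous run of frames whose error
    exceeds mean + 1 SD in magnitude is marked for deletion (the peak
    frame itself is always marked). A constant series (SD = 0) yields an
    empty mask.
    """
    x = np.asarray(isolated_signed_error, dtype=float)
    finite = np.isfinite(x)
    if finite.sum() == 0:
        return np.zeros(x.size, dtype=bool)
    sd = float(np.nanstd(x))
    if sd == 0:
        return np.zeros(x.size, dtype=bool)
    mean = float(np.nanmean(x))
    mag = np.abs(x)
    peaks = finite & (mag > 2.0 * sd)
    if not peaks.any():
        return np.zeros(x.size, dtype=bool)
    above = finite & (mag > abs(mean) + sd)
    mask = peaks.copy()
    # label contiguous runs of `above`; keep runs containing a peak
    padded = np.concatenate(([False], above, [False]))
    edges = np.flatnonzero(np.diff(padded.astype(int)))
    for start, stop in zip(edges[::2], edges[1::2]):
        if peaks[start:stop].any():
            mask[start:stop] = True
    return mask


def apply_deletion_mask(series: ErrorSeries, mask: np.ndarray) -> ErrorSeries:
    """Return a copy with masked frames set to NaN and recorded as deleted."""
    signed = None if series.signed_error_deg is None else series.signed_error_deg.copy()
    if signed is not None:
        signed[mask] = np.nan
    abs_err = series.abs_error_deg.copy()
    abs_err[mask] = np.nan
    return ErrorSeries(series.time_s, signed, abs_err, series.condition,
                       series.distance_trend, series.n_trials_averaged,
                       deletion_mask=series.deletion_mask | mask,
                       jump_indices=series.jump_indices)


def clean_artifacts(isolated: ErrorSeries, flanked: ErrorSeries):
    """Remove artifactual error segments from a matched trial pair.

    Peaks are detected in the isolated series only; the resulting deletion
    mask is applied to *both* series so the two conditions keep identical
    frame availability. Returns (isolated_clean, flanked_clean, mask).
    """
    if isolated.n_frames != flanked.n_frames:
        raise ValueError("isolated and flanked series must have equal length")
    if isolated.signed_error_deg is None:
        raise ValueError("cleaning needs the isolated signed error series")
    mask = artifact_mask(isolated.signed_error_deg)
    return apply_deletion_mask(isolated, mask), apply_deletion_mask(flanked, mask), mask


def flip_and_average(trials: Sequence[ErrorSeries]) -> ErrorSeries:
    """Average absolute errors over trials on a common increasing-distance axis.

    Decreasing-trend trials are reversed in time so that every series runs
    from minimum to maximum flanker distance; the per-frame mean ignores
    deleted (NaN) frames.
    """
    if not trials:
        raise ValueError("no trials to average")
    n = trials[0].n_frames
    if any(t.n_frames != n for t in trials):
        raise ValueError("all trials must have the same length")
    rows = []
    for t in trials:
        x = t.abs_error_deg
        rows.append(x[::-1] if t.distance_trend == "decreasing" else x)
    stack = np.vstack(rows)
    mean = _nanmean_cols(stack)
    return ErrorSeries(trials[0].time_s, None, mean, trials[0].condition,
                       distance_trend="increasing", n_trials_averaged=len(trials),
                       deletion_mask=~np.isfinite(mean))


@dataclass
class PostJumpWindows:
    """Absolute report errors aligned to jump onsets (jumps x samples)."""

    window_matrix: np.ndarray
    window_samples: int
    skip_samples: int
    dt_s: float

    @property
    def time_from_jump_s(self) -> np.ndarray:
        """Time of each retained column, measured from jump onset."""
        return (self.skip_samples + np.arange(self.window_matrix.shape[1])) * self.dt_s

    @property
    def mean_error(self) -> np.ndarray:
        return _nanmean_cols(self.window_matrix)


def extract_post_jump_windows(errors: ErrorSeries,
                              jump_indices: Optional[Sequence[int]] = None,
                              window_samples: int = 300,
                              skip_samples: int = 0) -> PostJumpWindows:
    """Cut absolute-error windows after each jump.

    Each row covers ``window_samples`` frames from the jump onset, with the
    first ``skip_samples`` columns dropped (motor-latency correction).
    Frames beyond the next jump or the trial end are left as NaN rather
    than read across the boundary; deleted frames stay NaN.
    """
    if jump_indices is None:
        jump_indices = errors.jump_indices
    jumps = np.asarray(jump_indices, dtype=int)
    if jumps.size == 0:
        raise ValueError("empty jump list")
    if not 0 <= skip_samples < window_samples:
        raise ValueError("skip_samples must be in [0, window_samples)")
    n = errors.n_frames
    dt = float(errors.time_s[1] - errors.time_s[0]) if n > 1 else 1.0
    width = window_samples - skip_samples
    mat = np.full((jumps.size, width), np.nan)
    order = np.argsort(jumps)
    for row, k in enumerate(order):
        j = jumps[k]
        nxt = jumps[order[row + 1]] if row + 1 < jumps.size else n
        stop = min(j + window_samples, nxt, n)
        start = j + skip_samples
        if stop > start:
            mat[k, : stop - start] = errors.abs_error_deg[start:stop]
    return PostJumpWindows(mat, window_samples, skip_samples, dt)


def clean_run_trials(trials: Sequence[ErrorSeries]) -> tuple[list, dict]:
    """Artifact-clean all trials of one continuous run, per trend.

    For each distance trend, the deletion masks derived from that trend's
    isolated trials (each from its own error statistics) are unioned and
    applied to every trial of the trend, keeping frame availability
    consistent across conditions. Returns (cleaned trials in input order,
    report dict with the removed fraction per trial).
    """
    cleaned: list = []
    report = {"per_trial_removed_fraction": {}, "per_trend_mask_fraction": {}}
    masks = {}
    for trend in ("increasing", "decreasing"):
        iso = [t for t in trials if t.condition == ISOLATED and t.distance_trend == trend]
        mask = np.zeros(trials[0].n_frames, dtype=bool)
        for t in iso:
            mask |= artifact_mask(t.signed_error_deg)
        masks[trend] = mask
        report["per_trend_mask_fraction"][trend] = float(mask.mean())
    for i, t in enumerate(trials):
        mask = masks.get(t.distance_trend, np.zeros(t.n_frames, dtype=bool))
        ct = apply_deletion_mask(t, mask)
        cleaned.append(ct)
        key = f"trial{i:02d}_{t.condition}_{t.distance_trend}"
        report["per_trial_removed_fraction"][key] = float(mask.mean())
    return cleaned, report
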