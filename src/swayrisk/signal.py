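"""Pre-processing of raw sway trials: zero-phase low-pass filtering,
demeaning, and validation.

Filtering follows standard stabilometry practice: a fourth-order
Butterworth low-pass at 5 Hz applied forward and backward (zero net
phase; effective magnitude response is the square of the single-pass
response).  Distance measures downstream are defined about the mean
point, so trials are demeaned after filtering.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

from .cohort import CohortSpec, SwayTrial


@dataclass(frozen=True)
class FilterConfig:
    order: int = 4
    cutoff: float = 5.0  # Hz
    # edge transients suppressed by odd-reflection padding of this many
    # multiples of the filter order
    pad_factor: int = 3

    def __post_init__(self) -> None:
        if self.order < 1:
            raise ValueError("filter order must be >= 1")
        if self.cutoff <= 0:
            raise ValueError("cutoff must be positive")


def sampling_rate_of(trial: SwayTrial) -> float:
    """Infer the (uniform) sampling rate from the trial's time vector."""
    dt = np.diff(trial.t)
    if len(dt) == 0:
        raise ValueError("trial has fewer than 2 samples")
    return 1.0 / float(np.median(dt))


def lowpass_zero_phase(trial: SwayTrial, cfg: FilterConfig = FilterConfig()) -> SwayTrial:
    """Apply the zero-phase Butterworth low-pass to both axes identically."""
    fs = sampling_rate_of(trial)
    if cfg.cutoff >= fs / 2:
        raise ValueError(
            f"cutoff {cfg.cutoff} Hz is not below the Nyquist rate {fs / 2} Hz"
        )
    padlen = cfg.pad_factor * cfg.order
    if len(trial.t) <= padlen:
        raise ValueError(
            f"series of length {len(trial.t)} too short for padding length {padlen}"
        )
    b, a = sps.butter(cfg.order, cfg.cutoff, btype="low", fs=fs)
    ml = sps.filtfilt(b, a, trial.ml, padtype="odd", padlen=padlen)
    ap = sps.filtfilt(b, a, trial.ap, padtype="odd", padlen=padlen)
    return dataclasses.replace(trial, ml=ml, ap=ap)


def demean(trial: SwayTrial) -> SwayTrial:
    """Remove the per-axis mean so positions are measured about the mean point."""
    return dataclasses.replace(
        trial, ml=trial.ml - trial.ml.mean(), ap=trial.ap - trial.ap.mean()
    )


def preprocess(trial: SwayTrial, cfg: FilterConfig = FilterConfig()) -> SwayTrial:
    """Filter then demean — the canonical preparation before feature extraction."""
    return demean(lowpass_zero_phase(trial, cfg))


def validate_trial(trial: SwayTrial, spec: CohortSpec) -> list[str]:
    """Report contract violations; an empty list means the trial is valid."""
    violations: list[str] = []
    n = len(trial.t)
    if n < 2:
        return ["series has fewer than 2 samples"]
    for name, series in (("ml", trial.ml), ("ap", trial.ap), ("t", trial.t)):
        if not np.all(np.isfinite(series)):
            violations.append(f"non-finite values in {name}")
    dt = np.diff(trial.t)
    expected_dt = 1.0 / spec.sampling_rate
    if np.any(np.abs(dt - expected_dt) > 1e-6 * max(expected_dt, 1.0)):
        violations.append("non-uniform sampling or wrong sampling rate")
    duration = n / spec.sampling_rate
    if abs(duration - spec.duration) > 1.5 * expected_dt:
        violations.append(
            f"duration {duration:.3f} s differs from spec {spec.duration:.3f} s"
        )
    return violations
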