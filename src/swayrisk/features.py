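"""Stabilogram feature extraction: 31 posturographic parameters per trial.

The parameter set follows the classical center-of-pressure analysis
literature, applied here to lumbar-tracker trunk displacement.  Per
trial the extractor computes, on the demeaned and filtered M-L / A-P
series and the resultant radius r[i] = sqrt(ml[i]^2 + ap[i]^2):

time-domain distance (x5 measures x3 directions = 15)
    mean distance, maximal distance, RMS distance, range, mean velocity
time-domain area (1)
    95% confidence ellipse area
hybrid (5)
    sway area per second, mean frequency (M-L, A-P, radius),
    fractal dimension
frequency domain (x5 measures x2 axes = 10)
    total power, 50% power frequency, 95% power frequency,
    centroid frequency, frequency dispersion

Power spectra are Welch estimates (~5 s Hann segments, 50% overlap,
linear detrend) and spectral moments are integrated over a band matched
to the analysis filter, 0.15-5 Hz by default.

Per participant the two trials of each stance condition are averaged,
yielding 31 x 4 = 124 posturographic columns, to which personal metrics
(age, sex, height, weight, BMI) and the two risk labels are appended.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import signal as sps
from scipy.spatial import ConvexHull, QhullError

from .cohort import CONDITIONS, Participant, SwayTrial

_DIRECTIONS = ("ml", "ap", "r")
_DISTANCE_MEASURES = ("mean_dist", "max_dist", "rms_dist", "range", "mean_velocity")
_SPECTRAL_MEASURES = ("total_power", "f50", "f95", "centroid_freq", "freq_dispersion")

#: Canonical order of the 31 per-trial parameter names.
PARAMETER_NAMES: tuple[str, ...] = tuple(
    [f"{m}_{d}" for m in _DISTANCE_MEASURES for d in _DIRECTIONS]
    + ["ellipse_area_95"]
    + ["sway_area_per_sec", "mean_freq_ml", "mean_freq_ap", "mean_freq_r", "fractal_dim"]
    + [f"{m}_{d}" for m in _SPECTRAL_MEASURES for d in ("ml", "ap")]
)

PERSONAL_COLUMNS: tuple[str, ...] = ("age", "sex", "height", "weight", "bmi")
LABEL_COLUMNS: tuple[str, ...] = ("criteria_I", "criteria_II")


def posturographic_columns(
    conditions: Sequence[str] = CONDITIONS,
) -> list[str]:
    """The 124 feature-table column names, ``<condition>__<parameter>``."""
    return [f"{c}__{p}" for c in conditions for p in PARAMETER_NAMES]


@dataclass(frozen=True)
class FeatureConfig:
    """Numerical conventions of the extractor."""

    #: multiplier in the 95% confidence ellipse area; the large-sample
    #: value of F(0.05; 2, n-2).
    ellipse_f: float = 3.00
    #: Welch segment length in seconds and fractional overlap.
    psd_segment_seconds: float = 5.0
    psd_overlap: float = 0.5
    #: band (Hz) over which spectral moments are integrated.
    band: tuple[float, float] = (0.15, 5.0)
    #: planar diameter convention for the fractal dimension:
    #: "max_radius" (max distance from the mean point) or "farthest_pair".
    fd_diameter: str = "max_radius"

    def __post_init__(self) -> None:
        if self.fd_diameter not in ("max_radius", "farthest_pair"):
            raise ValueError("fd_diameter must be 'max_radius' or 'farthest_pair'")


# --------------------------------------------------------------------------
# individual measures


def distance_measures(ml: np.ndarray, ap: np.ndarray, fs: float) -> dict[str, float]:
    """Time-domain distance measures for M-L, A-P, and the radius.

    Per axis: mean/max of |x|, RMS, range = max - min, and mean velocity
    = total excursion / duration.  For the radius: the same statistics of
    r[i] = sqrt(ml^2 + ap^2) with range reported as the maximal radial
    distance and mean velocity as planar path length / duration.
    """
    ml = np.asarray(ml, float)
    ap = np.asarray(ap, float)
    if len(ml) < 2:
        raise ValueError("distance measures require at least 2 samples")
    r = np.hypot(ml, ap)
    duration = (len(ml) - 1) / fs

    out: dict[str, float] = {}
    for name, series in (("ml", ml), ("ap", ap)):
        out[f"mean_dist_{name}"] = float(np.mean(np.abs(series)))
        out[f"max_dist_{name}"] = float(np.max(np.abs(series)))
        out[f"rms_dist_{name}"] = float(np.sqrt(np.mean(series**2)))
        out[f"range_{name}"] = float(np.max(series) - np.min(series))
        out[f"mean_velocity_{name}"] = float(
            np.sum(np.abs(np.diff(series))) / duration
        )
    out["mean_dist_r"] = float(np.mean(r))
    out["max_dist_r"] = float(np.max(r))
    out["rms_dist_r"] = float(np.sqrt(np.mean(r**2)))
    out["range_r"] = float(np.max(r))  # maximal radial distance about the mean
    out["mean_velocity_r"] = float(
        np.sum(np.hypot(np.diff(ml), np.diff(ap))) / duration
    )
    return out


def ellipse_area_95(ml: np.ndarray, ap: np.ndarray, f_value: float = 3.00) -> float:
    """Area of the 95% confidence ellipse of the (ml, ap) scatter, mm^2.

    2*pi*F * sqrt(s_ap^2 * s_ml^2 - s_apml^2) with sample (co)variances;
    a degenerate (singular) covariance yields 0.
    """
    ml = np.asarray(ml, float)
    ap = np.asarray(ap, float)
    if len(ml) < 3:
        return 0.0
    s_ml2 = np.var(ml, ddof=1)
    s_ap2 = np.var(ap, ddof=1)
    s_apml = np.cov(ml, ap, ddof=1)[0, 1]
    det = s_ap2 * s_ml2 - s_apml**2
    if det <= 0:
        return 0.0
    return float(2.0 * np.pi * f_value * np.sqrt(det))


def sway_area_per_second(ml: np.ndarray, ap: np.ndarray, duration: float) -> float:
    """Area swept per second by the position vector about the mean, mm^2/s.

    Sum of triangle areas |ap[i+1]*ml[i] - ap[i]*ml[i+1]| / 2, per unit time.
    """
    ml = np.asarray(ml, float)
    ap = np.asarray(ap, float)
    cross = np.abs(ap[1:] * ml[:-1] - ap[:-1] * ml[1:])
    return float(np.sum(cross) / (2.0 * duration))


def mean_frequency(mean_velocity: float, mean_dist: float) -> float:
    """Rotational mean frequency MVELO / (2*pi*MDIST), Hz.

    The frequency of a circular path of radius MDIST traversed at speed
    MVELO.  Undefined (NaN) when the mean distance is zero.
    """
    if mean_dist == 0:
        return float("nan")
    return float(mean_velocity / (2.0 * np.pi * mean_dist))


def _farthest_pair_distance(ml: np.ndarray, ap: np.ndarray) -> float:
    pts = np.column_stack([ml, ap])
    uniq = np.unique(pts, axis=0)
    if len(uniq) < 2:
        return 0.0
    if len(uniq) > 3:
        try:
            hull = ConvexHull(uniq)
            uniq = uniq[hull.vertices]
        except QhullError:
            pass  # collinear points: brute-force the (small) unique set
    d = uniq[:, None, :] - uniq[None, :, :]
    return float(np.sqrt((d**2).sum(-1)).max())


def fractal_dimension(
    ml: np.ndarray,
    ap: np.ndarray,
    diameter: str = "max_radius",
) -> float:
    """Curve fractal dimension FD = ln(N) / ln(N*d / L).

    N is the sample count, L the total planar path length, and d the
    planar diameter: by default the maximal distance from the mean point
    (the demeaned origin), or the farthest pair of samples when
    ``diameter="farthest_pair"``.  Undefined (NaN) for a degenerate path.
    """
    ml = np.asarray(ml, float)
    ap = np.asarray(ap, float)
    n = len(ml)
    length = float(np.sum(np.hypot(np.diff(ml), np.diff(ap))))
    if length == 0:
        return float("nan")
    if diameter == "max_radius":
        d = float(np.max(np.hypot(ml, ap)))
    elif diameter == "farthest_pair":
        d = _farthest_pair_distance(ml, ap)
    else:
        raise ValueError("diameter must be 'max_radius' or 'farthest_pair'")
    if d == 0:
        return float("nan")
    denom = np.log(n * d / length)
    if denom == 0:
        return float("nan")
    return float(np.log(n) / denom)


def spectral_features(
    series: np.ndarray,
    fs: float,
    cfg: FeatureConfig = FeatureConfig(),
) -> dict[str, float]:
    """Band-limited spectral measures of one axis.

    Welch PSD with Hann windows of ``psd_segment_seconds``, 50% overlap,
    linear detrend.  Over the analysis band: total power is the
    integrated PSD (~= band variance); f50/f95 are the smallest
    frequencies accumulating 50%/95% of band power; the centroid
    frequency is sqrt(mu2/mu0) and the frequency dispersion
    sqrt(1 - mu1^2/(mu0*mu2)), with mu_k the k-th spectral moment.
    """
    series = np.asarray(series, float)
    nperseg = min(int(round(cfg.psd_segment_seconds * fs)), len(series))
    noverlap = int(nperseg * cfg.psd_overlap)
    f, p = sps.welch(
        series,
        fs=fs,
        window="hann",
        nperseg=nperseg,
        noverlap=noverlap,
        detrend="linear",
    )
    lo, hi = cfg.band
    mask = (f >= lo) & (f <= hi)
    f, p = f[mask], p[mask]
    df = f[1] - f[0] if len(f) > 1 else 1.0

    mu0 = float(np.sum(p) * df)
    if mu0 <= 0 or len(f) == 0:
        return {
            "total_power": 0.0,
            "f50": float("nan"),
            "f95": float("nan"),
            "centroid_freq": float("nan"),
            "freq_dispersion": float("nan"),
        }
    mu1 = float(np.sum(f * p) * df)
    mu2 = float(np.sum(f**2 * p) * df)
    cum = np.cumsum(p) / np.sum(p)
    f50 = float(f[np.searchsorted(cum, 0.5)])
    f95 = float(f[np.searchsorted(cum, 0.95)])
    centroid = float(np.sqrt(mu2 / mu0))
    disp = float(np.sqrt(max(0.0, 1.0 - mu1**2 / (mu0 * mu2))))
    return {
        "total_power": mu0,
        "f50": f50,
        "f95": f95,
        "centroid_freq": centroid,
        "freq_dispersion": disp,
    }


# --------------------------------------------------------------------------
# per-trial assembly


def extract_trial_features(
    trial: SwayTrial,
    cfg: FeatureConfig = FeatureConfig(),
) -> dict[str, float]:
    """All 31 parameters of one (filtered, demeaned) trial, by name."""
    from .signal import sampling_rate_of  # local import to avoid a cycle

    fs = sampling_rate_of(trial)
    ml, ap = trial.ml, trial.ap
    duration = (len(ml) - 1) / fs

    values = distance_measures(ml, ap, fs)
    values["ellipse_area_95"] = ellipse_area_95(ml, ap, cfg.ellipse_f)
    values["sway_area_per_sec"] = sway_area_per_second(ml, ap, duration)
    for d in _DIRECTIONS:
        values[f"mean_freq_{d}"] = mean_frequency(
            values[f"mean_velocity_{d}"], values[f"mean_dist_{d}"]
        )
    values["fractal_dim"] = fractal_dimension(ml, ap, cfg.fd_diameter)
    for axis in ("ml", "ap"):
        spec = spectral_features(getattr(trial, axis), fs, cfg)
        for key, val in spec.items():
            values[f"{key}_{axis}"] = val

    assert set(values) == set(PARAMETER_NAMES)
    return {name: values[name] for name in PARAMETER_NAMES}


# --------------------------------------------------------------------------
# cohort-level feature table


@dataclass
class ExclusionLog:
    """Participants dropped from the feature table and why."""

    excluded: dict[str, str] = field(default_factory=dict)

    def add(self, participant_id: str, reason: str) -> None:
        self.excluded[participant_id] = reason


def build_feature_table(
    participants: Iterable[Participant],
    trials: Iterable[SwayTrial],
    cfg: FeatureConfig = FeatureConfig(),
    preprocess: bool = True,
) -> tuple[pd.DataFrame, ExclusionLog]:
    """Assemble the participants x (124 + personal + labels) table.

    The two trials of each stance condition are feature-extracted
    separately and averaged.  Participants missing any (condition, trial)
    slot are excluded and recorded in the returned :class:`ExclusionLog`.
    Duplicate (participant, condition, trial) keys are an error.
    Set ``preprocess=False`` if the trials are already filtered and
    demeaned.
    """
    from . import signal as _sig

    by_participant: dict[str, dict[tuple[str, int], SwayTrial]] = {}
    for tr in trials:
        key = (tr.condition, tr.trial_index)
        slot = by_participant.setdefault(tr.participant_id, {})
        if key in slot:
            raise ValueError(
                f"duplicate trial {key} for participant {tr.participant_id}"
            )
        slot[key] = tr

    expected_keys = set(itertools.product(CONDITIONS, (1, 2)))
    log = ExclusionLog()
    rows = []
    index = []
    for p in participants:
        slots = by_participant.get(p.id, {})
        missing = expected_keys - set(slots)
        if missing:
            conds = sorted({c for c, _ in missing})
            log.add(p.id, f"missing condition(s): {', '.join(conds)}")
            continue
        row: dict[str, float] = {}
        for condition in CONDITIONS:
            per_trial = []
            for idx in (1, 2):
                tr = slots[(condition, idx)]
                if preprocess:
                    tr = _sig.preprocess(tr)
                per_trial.append(extract_trial_features(tr, cfg))
            for name in PARAMETER_NAMES:
                row[f"{condition}__{name}"] = 0.5 * (
                    per_trial[0][name] + per_trial[1][name]
                )
        row["age"] = p.age
        row["sex"] = 1.0 if p.sex == "male" else 0.0
        row["height"] = p.height
        row["weight"] = p.weight
        row["bmi"] = p.bmi
        row["criteria_I"] = int(p.fell_last_year)
        row["criteria_II"] = int(p.slow_tug)
        rows.append(row)
        index.append(p.id)

    columns = posturographic_columns() + list(PERSONAL_COLUMNS) + list(LABEL_COLUMNS)
    table = pd.DataFrame(rows, index=pd.Index(index, name="participant_id"))
    table = table.reindex(columns=columns)
    return table, log
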