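"""Synthetic cohort generation for trunk-sway posturography.

The study population this emulates is community-dwelling older adults
standing quietly for 30 s under four stance conditions of increasing
difficulty — feet apart / feet together ("W"/"N") crossed with eyes
open / closed ("EO"/"EC") — while a lumbar tracker records trunk
displacement along the medial-lateral (M-L) and anterior-posterior
(A-P) axes.  Each participant carries two binary fall-risk labels: a
self-reported fall in the previous year, and a Timed-Up-and-Go (TUG)
time of 10 s or more.

A single latent "balance deficit" per participant drives both the sway
amplitude (multiplicatively, in every condition) and the labels.  The
TUG time is a noisy monotone function of the deficit, while the fall
label is deliberately degraded with independent label noise, so that
posturography carries more signal about the TUG label than about fall
history — the structure the downstream classifiers are expected to
exploit.

Sway itself is modelled as low-pass-shaped Gaussian noise: white noise
passed through a second-order Butterworth filter so that power
concentrates below ~1.5 Hz, then demeaned and scaled to the target RMS
amplitude.  No physiological model is claimed; the generator exists to
give the feature extractor and classifiers data with the right ordering
and correlation structure.
"""

from __future__ import annotations

import dataclasses
import io
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import signal as sps
from scipy import stats

#: Stance conditions in increasing order of difficulty.
CONDITIONS: tuple[str, ...] = ("W-EO", "W-EC", "N-EO", "N-EC")

_DEFAULT_CONDITION_GAIN: dict[str, float] = {
    "W-EO": 1.0,
    "W-EC": 1.3,
    "N-EO": 1.6,
    "N-EC": 2.1,
}

#: Baseline RMS sway amplitude (mm) per axis for a participant with zero
#: latent deficit in the easiest condition.  A-P sway exceeds M-L sway,
#: as is typical for quiet bipedal stance.
_BASE_RMS_MM = {"ml": 2.5, "ap": 3.5}

#: Cutoff (Hz) of the shaping filter applied to the white-noise innovations.
_SHAPING_CUTOFF_HZ = 1.5


class ConfigurationError(ValueError):
    """Raised when a cohort specification violates its invariants."""


@dataclass(frozen=True)
class CohortSpec:
    """Parameters of the synthetic cohort.

    Defaults emulate the study conditions: ~23% fallers, ~31% slow-TUG
    prevalence, four stance conditions with strictly increasing sway.
    """

    n_participants: int = 215
    seed: int = 0
    sampling_rate: float = 90.0  # Hz
    duration: float = 30.0  # seconds
    prevalence_slow_tug: float = 0.307
    prevalence_faller: float = 0.228
    #: log-ratio of sway amplitude per unit latent deficit; the amplitude
    #: multiplier is exp(balance_effect * deficit), ~(1 + effect * deficit)
    #: for small deficits and strictly positive for any draw.
    balance_effect: float = 0.35
    #: probability that the fall-history label is drawn independently of
    #: the latent deficit (pure prevalence coin).
    label_noise_fall: float = 0.35
    condition_gain: Mapping[str, float] = field(
        default_factory=lambda: dict(_DEFAULT_CONDITION_GAIN)
    )
    #: correlation between the M-L and A-P innovation noise.
    ap_ml_corr: float = 0.3
    #: fraction of participants missing the hardest condition (N-EC),
    #: to exercise downstream exclusion logic.
    missing_fraction: float = 0.0

    def __post_init__(self) -> None:
        if self.n_participants < 1:
            raise ConfigurationError("n_participants must be positive")
        if not 0.0 < self.prevalence_slow_tug < 1.0:
            raise ConfigurationError("prevalence_slow_tug must lie in (0, 1)")
        if not 0.0 < self.prevalence_faller < 1.0:
            raise ConfigurationError("prevalence_faller must lie in (0, 1)")
        if self.sampling_rate <= 10.0:
            raise ConfigurationError(
                "sampling_rate must exceed 10 Hz (Nyquist above the 5 Hz cutoff)"
            )
        if self.duration <= 0:
            raise ConfigurationError("duration must be positive")
        if not 0.0 <= self.label_noise_fall <= 1.0:
            raise ConfigurationError("label_noise_fall must lie in [0, 1]")
        if not -1.0 < self.ap_ml_corr < 1.0:
            raise ConfigurationError("ap_ml_corr must lie in (-1, 1)")
        if not 0.0 <= self.missing_fraction < 1.0:
            raise ConfigurationError("missing_fraction must lie in [0, 1)")
        if set(self.condition_gain) != set(CONDITIONS):
            raise ConfigurationError(
                f"condition_gain must define exactly the conditions {CONDITIONS}"
            )
        gains = [self.condition_gain[c] for c in CONDITIONS]
        if not all(g2 > g1 for g1, g2 in zip(gains, gains[1:])):
            raise ConfigurationError(
                "condition_gain must be strictly increasing along "
                "W-EO < W-EC < N-EO < N-EC"
            )


@dataclass(frozen=True)
class Participant:
    """Personal metrics, labels, and the hidden ground-truth deficit."""

    id: str
    age: float  # years
    sex: str  # "male" | "female"
    height: float  # cm
    weight: float  # kg
    bmi: float  # kg/m^2, derived
    uses_aid: bool
    tug_seconds: float
    fell_last_year: bool
    latent_deficit: float  # hidden; retained for ground-truth tests

    @property
    def slow_tug(self) -> bool:
        """Criteria-II label: TUG of 10 s or more."""
        return self.tug_seconds >= 10.0


@dataclass(frozen=True)
class SwayTrial:
    """One 30 s two-axis trunk-displacement recording."""

    participant_id: str
    condition: str
    trial_index: int  # 1 or 2
    t: np.ndarray  # seconds
    ml: np.ndarray  # mm
    ap: np.ndarray  # mm

    def __post_init__(self) -> None:
        if not (len(self.t) == len(self.ml) == len(self.ap)):
            raise ValueError("t, ml, ap must have equal length")
        if self.condition not in CONDITIONS:
            raise ValueError(f"unknown condition {self.condition!r}")


# --------------------------------------------------------------------------
# participants


def generate_participants(spec: CohortSpec) -> list[Participant]:
    """Draw the participant roster for a cohort specification.

    The latent deficit is standard normal.  TUG time is an affine function
    of a unit-variance blend of deficit (weight 0.85) and independent
    noise, centred so that the population fraction with TUG >= 10 s equals
    ``spec.prevalence_slow_tug``.  The fall label follows the deficit
    through a thresholded noisy copy, except that with probability
    ``label_noise_fall`` it is an independent prevalence coin — both
    branches share the same marginal rate.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n_participants

    deficit = rng.standard_normal(n)

    # personal metrics: normal marginals around typical values for a
    # community-dwelling cohort in its early 70s, ~1/3 male
    age = np.clip(rng.normal(72.0, 7.0, n) + 1.5 * deficit, 60.0, 100.0)
    sex_male = rng.random(n) < 1.0 / 3.0
    height = np.clip(
        rng.normal(157.0, 8.7, n) + 6.0 * sex_male - 1.0 * deficit, 130.0, 195.0
    )
    weight = np.clip(rng.normal(61.0, 12.5, n) + 4.0 * sex_male, 35.0, 130.0)
    bmi = weight / (height / 100.0) ** 2

    # TUG: blend of deficit and noise, calibrated so P(TUG >= 10) = prevalence
    w_def = 0.85
    w_noise = float(np.sqrt(1.0 - w_def**2))
    s = w_def * deficit + w_noise * rng.standard_normal(n)
    z_tug = stats.norm.ppf(1.0 - spec.prevalence_slow_tug)
    tug = np.clip(10.0 + 2.2 * (s - z_tug), 3.0, None)

    # fall history: deficit-linked threshold, degraded by label noise
    g = (deficit + 0.6 * rng.standard_normal(n)) / np.sqrt(1.36)
    z_fall = stats.norm.ppf(1.0 - spec.prevalence_faller)
    linked_fall = g > z_fall
    coin_fall = rng.random(n) < spec.prevalence_faller
    use_coin = rng.random(n) < spec.label_noise_fall
    fell = np.where(use_coin, coin_fall, linked_fall)

    uses_aid = (deficit > 1.2) & (rng.random(n) < 0.6)

    width = len(str(n))
    return [
        Participant(
            id=f"P{i + 1:0{width}d}",
            age=float(age[i]),
            sex="male" if sex_male[i] else "female",
            height=float(height[i]),
            weight=float(weight[i]),
            bmi=float(bmi[i]),
            uses_aid=bool(uses_aid[i]),
            tug_seconds=float(tug[i]),
            fell_last_year=bool(fell[i]),
            latent_deficit=float(deficit[i]),
        )
        for i in range(n)
    ]


# --------------------------------------------------------------------------
# sway trajectories


def _n_samples(spec: CohortSpec) -> int:
    return int(round(spec.duration * spec.sampling_rate))


def generate_sway_trial(
    participant: Participant,
    condition: str,
    trial_index: int,
    spec: CohortSpec,
    rng: np.random.Generator,
) -> SwayTrial:
    """Draw one two-axis sway trial for a participant.

    The two axes share correlated white-noise innovations (correlation
    ``spec.ap_ml_corr``), each shaped by a second-order Butterworth
    low-pass filter, demeaned, and scaled so the sample RMS equals
    base * condition_gain * exp(balance_effect * deficit).
    """
    if condition not in CONDITIONS:
        raise ValueError(f"unknown condition {condition!r}")
    n = _n_samples(spec)
    fs = spec.sampling_rate
    t = np.arange(n) / fs

    rho = spec.ap_ml_corr
    raw = rng.standard_normal((2, n))
    ml_raw = raw[0]
    ap_raw = rho * raw[0] + np.sqrt(1.0 - rho**2) * raw[1]

    sos = sps.butter(2, _SHAPING_CUTOFF_HZ, btype="low", fs=fs, output="sos")
    amp = spec.condition_gain[condition] * float(
        np.exp(spec.balance_effect * participant.latent_deficit)
    )

    axes = {}
    for name, series, base in (
        ("ml", ml_raw, _BASE_RMS_MM["ml"]),
        ("ap", ap_raw, _BASE_RMS_MM["ap"]),
    ):
        shaped = sps.sosfiltfilt(sos, series)
        shaped = shaped - shaped.mean()
        rms = float(np.sqrt(np.mean(shaped**2)))
        axes[name] = shaped * (base * amp / rms)

    return SwayTrial(
        participant_id=participant.id,
        condition=condition,
        trial_index=trial_index,
        t=t,
        ml=axes["ml"],
        ap=axes["ap"],
    )


def generate_cohort(spec: CohortSpec) -> tuple[list[Participant], list[SwayTrial]]:
    """Generate the full cohort: participants plus 4 conditions x 2 trials each.

    If ``spec.missing_fraction`` > 0, that fraction of participants (chosen
    by seeded Bernoulli draws) is missing the hardest condition (N-EC),
    emulating participants unable to complete the final task.
    """
    participants = generate_participants(spec)
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 1]))
    missing = rng.random(len(participants)) < spec.missing_fraction

    trials: list[SwayTrial] = []
    for p, is_missing in zip(participants, missing):
        for condition in CONDITIONS:
            if is_missing and condition == "N-EC":
                continue
            for trial_index in (1, 2):
                trials.append(
                    generate_sway_trial(p, condition, trial_index, spec, rng)
                )
    return participants, trials


# --------------------------------------------------------------------------
# CSV interchange


def participants_to_frame(participants: Iterable[Participant]) -> pd.DataFrame:
    rows = [dataclasses.asdict(p) for p in participants]
    return pd.DataFrame(rows)


def trials_to_frame(trials: Iterable[SwayTrial]) -> pd.DataFrame:
    """Long-form trajectory table: participant_id, condition, trial, t, ml_mm, ap_mm."""
    parts = []
    for tr in trials:
        parts.append(
            pd.DataFrame(
                {
                    "participant_id": tr.participant_id,
                    "condition": tr.condition,
                    "trial": tr.trial_index,
                    "t": tr.t,
                    "ml_mm": tr.ml,
                    "ap_mm": tr.ap,
                }
            )
        )
    return pd.concat(parts, ignore_index=True)


def write_cohort_csv(
    participants: Sequence[Participant],
    trials: Sequence[SwayTrial],
    participants_path,
    trajectories_path,
) -> None:
    participants_to_frame(participants).to_csv(participants_path, index=False)
    trials_to_frame(trials).to_csv(trajectories_path, index=False, float_format="%.6f")


def read_trials_csv(path) -> list[SwayTrial]:
    """Rebuild SwayTrial objects from a long-form trajectory CSV."""
    df = pd.read_csv(path)
    required = {"participant_id", "condition", "trial", "t", "ml_mm", "ap_mm"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"trajectory CSV missing columns: {sorted(missing)}")
    trials = []
    for (pid, condition, trial), g in df.groupby(
        ["participant_id", "condition", "trial"], sort=True
    ):
        g = g.sort_values("t")
        trials.append(
            SwayTrial(
                participant_id=str(pid),
                condition=str(condition),
                trial_index=int(trial),
                t=g["t"].to_numpy(float),
                ml=g["ml_mm"].to_numpy(float),
                ap=g["ap_mm"].to_numpy(float),
            )
        )
    return trials


def read_participants_csv(path) -> list[Participant]:
    df = pd.read_csv(path)
    return [
        Participant(
            id=str(r.id),
            age=float(r.age),
            sex=str(r.sex),
            height=float(r.height),
            weight=float(r.weight),
            bmi=float(r.bmi),
            uses_aid=bool(r.uses_aid),
            tug_seconds=float(r.tug_seconds),
            fell_last_year=bool(r.fell_last_year),
            latent_deficit=float(r.latent_deficit),
        )
        for r in df.itertuples()
    ]


# --------------------------------------------------------------------------
# planted-feature tables (ground truth for selection/recovery experiments)


def make_planted_table(
    n_samples: int = 300,
    n_informative: int = 5,
    n_noise: int = 119,
    effect_size: float = 1.0,
    prevalence: float = 0.307,
    seed: int = 0,
) -> tuple[pd.DataFrame, np.ndarray, np.ndarray]:
    """Feature table with a known informative subset, for recovery tests.

    Informative columns are shifted by ``effect_size`` standard deviations
    in the positive class; noise columns are independent of the label.
    Columns are min-max scaled to [0, 1] (the representation the wrapper
    fitness expects).  Returns ``(table, y, informative_mask)``; columns
    are named ``inf_**``/``noise_**`` but shuffled so informative features
    do not occupy a contiguous block.
    """
    rng = np.random.default_rng(seed)
    d = n_informative + n_noise
    y = (rng.random(n_samples) < prevalence).astype(int)
    X = rng.standard_normal((n_samples, d))
    X[:, :n_informative] += effect_size * y[:, None]

    names = [f"inf_{i:02d}" for i in range(n_informative)] + [
        f"noise_{i:03d}" for i in range(n_noise)
    ]
    order = rng.permutation(d)
    X = X[:, order]
    names = [names[j] for j in order]
    informative = np.array([nm.startswith("inf_") for nm in names])

    lo, hi = X.min(axis=0), X.max(axis=0)
    X = (X - lo) / np.where(hi - lo == 0, 1.0, hi - lo)
    return pd.DataFrame(X, columns=names), y, informative
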