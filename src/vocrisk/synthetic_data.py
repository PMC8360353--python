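"""Synthetic overnight cohort generator.

The sleep database this pipeline was designed around (overnight
polysomnograms of children with sickle-cell disease, with hospitalization
pain histories) is not publicly deposited, so this module generates
cohorts with the statistical structure the downstream analysis assumes:

- a roster of subjects with clinical and sleep covariates, split between a
  latent low- and high-severity class (default imbalance ~1:4.9);
- per-subject overnight beat-to-beat series (R-peak times, RRI, per-pulse
  PPG amplitude) containing transient vasoconstriction episodes — smooth
  raised-cosine PPGa drops with coupled negative RRI excursions — riding on
  baseline plus noise plus a respiratory-band oscillation;
- negative-binomial pain-episode histories whose expected rate increases
  log-linearly with the planted vasoconstriction severity (median event
  depth and event frequency), so that the association the classifier is
  meant to recover is present by construction;
- a ground-truth event log for detector validation.

All covariate ranges are plausible stand-ins, not estimates of the real
joint distribution; see the methods note for what they do and do not
emulate.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .preprocessing import BeatSeries

__all__ = [
    "CohortConfig",
    "SubjectProfile",
    "EventTruth",
    "CohortBundle",
    "ConfigurationError",
    "generate_cohort",
    "generate_subject_signals",
    "generate_pain_history",
]


class ConfigurationError(ValueError):
    """Invalid generator configuration; the message names the field."""


@dataclass(frozen=True)
class CohortConfig:
    """Cohort-level generator settings.

    Defaults reproduce the structure of the study population: 212
    subjects, 36 expected in the latent high-severity class, ~8 h nights,
    median event depths of ~13% (low) vs ~27% (high) matching the
    exemplar subjects, and a log-linear link from planted severity to the
    expected annual pain rate.
    """

    n_subjects: int = 212
    prevalence_high: float = 36 / 212
    sleep_hours: float = 8.0
    event_rate_low: float = 1.5   # events per hour, latent low-severity class
    event_rate_high: float = 2.5  # events per hour, latent high-severity class
    mvasoc_mean_low: float = 13.0   # percent PPGa drop
    mvasoc_mean_high: float = 27.0  # percent PPGa drop
    rri_coupling: float = 1.0
    noise_sd: float = 0.02           # fraction of baseline PPGa
    artifact_fraction: float = 0.02  # fraction of the night masked
    pain_link: tuple[float, float, float] = (-2.85, 0.12, 0.33)
    years_pre: float = 2.0
    years_post: float = 3.0
    nb_dispersion: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects < 1:
            raise ConfigurationError("n_subjects must be >= 1")
        if not 0.0 < self.prevalence_high < 1.0:
            raise ConfigurationError("prevalence_high must be in (0, 1)")
        if self.sleep_hours <= 0:
            raise ConfigurationError("sleep_hours must be positive")
        for name in ("event_rate_low", "event_rate_high"):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name} must be >= 0")
        if self.mvasoc_mean_high < self.mvasoc_mean_low:
            raise ConfigurationError(
                "mvasoc_mean_high must be >= mvasoc_mean_low"
            )
        if not 0.0 <= self.artifact_fraction < 1.0:
            raise ConfigurationError("artifact_fraction must be in [0, 1)")
        if self.noise_sd < 0:
            raise ConfigurationError("noise_sd must be >= 0")
        if self.years_pre <= 0 or self.years_post <= 0:
            raise ConfigurationError("years_pre and years_post must be positive")
        if self.nb_dispersion <= 0:
            raise ConfigurationError("nb_dispersion must be positive")


@dataclass(frozen=True)
class SubjectProfile:
    """Per-subject signal-generation settings."""

    subject_id: str
    mean_rri: float          # seconds, ~0.6-1.1
    baseline_ppga: float     # arbitrary amplitude units
    sleep_hours: float
    events: tuple[tuple[float, float, float], ...]  # (onset_s, duration_s, depth_pct)
    rri_coupling: float = 1.0
    noise_sd: float = 0.02
    resp_amplitude: float = 0.05  # fraction of baseline, respiratory band
    resp_freq: float = 0.25       # Hz, above the 0.18 Hz low-pass cutoff
    hrv_sd: float = 0.015         # fraction of mean RRI, beat-to-beat jitter


@dataclass(frozen=True)
class EventTruth:
    """Ground-truth record of one planted vasoconstriction episode."""

    subject_id: str
    onset_time: float
    duration: float
    depth: float

    def __post_init__(self) -> None:
        if self.duration <= 0:
            raise ValueError("duration must be positive")
        if not 0.0 < self.depth <= 100.0:
            raise ValueError("depth must be in (0, 100]")


@dataclass
class CohortBundle:
    """Everything the downstream pipeline consumes for one cohort.

    ``roster`` is a list of per-subject covariate dicts (one latent
    ``severity`` entry is logged for recovery tests but must not be used
    as a feature); ``signals`` maps subject id to its BeatSeries;
    ``artifact_intervals`` maps subject id to masked stretches; ``truth``
    is the planted-event log.
    """

    roster: list[dict]
    signals: dict[str, BeatSeries]
    artifact_intervals: dict[str, list[tuple[float, float]]]
    truth: list[EventTruth]
    config: CohortConfig = field(default=None)  # type: ignore[assignment]


# --- pain history -----------------------------------------------------------


def generate_pain_history(
    latent_rate: float,
    years: float,
    rng: np.random.Generator | int,
    dispersion: float = 2.0,
) -> int:
    """Draw a pain-episode count over ``years`` from a negative binomial.

    The count is overdispersed Poisson with mean ``latent_rate * years``
    and shape ``dispersion``; dividing by ``years`` yields the annual pain
    rate consumed by the category assignment. ``rng`` may be a Generator
    or an integer seed.
    """
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(rng)
    if latent_rate < 0:
        raise ConfigurationError("latent_rate must be >= 0")
    if years <= 0:
        raise ConfigurationError("years must be positive")
    mu = latent_rate * years
    if mu == 0:
        return 0
    k = dispersion
    p = k / (k + mu)
    return int(rng.negative_binomial(k, p))


# --- signal synthesis -------------------------------------------------------


def _raised_cosine_envelope(
    t: np.ndarray, onset: float, duration: float, ramp_on: float = 10.0, ramp_off: float = 20.0
) -> np.ndarray:
    """Smooth 0->1->0 envelope: raised-cosine onset/recovery around a plateau."""
    total_ramp = ramp_on + ramp_off
    if duration < total_ramp:  # shrink ramps proportionally for short events
        scale = duration / total_ramp
        ramp_on *= scale
        ramp_off *= scale
    env = np.zeros_like(t)
    rel = t - onset
    in_on = (rel >= 0) & (rel < ramp_on)
    env[in_on] = 0.5 * (1 - np.cos(np.pi * rel[in_on] / ramp_on))
    in_plateau = (rel >= ramp_on) & (rel < duration - ramp_off)
    env[in_plateau] = 1.0
    in_off = (rel >= duration - ramp_off) & (rel < duration)
    env[in_off] = 0.5 * (1 + np.cos(np.pi * (rel[in_off] - (duration - ramp_off)) / ramp_off))
    return env


def _event_sum(
    t: np.ndarray, events: tuple[tuple[float, float, float], ...]
) -> np.ndarray:
    """Sum of depth-weighted envelopes (fractional drop) at times ``t``."""
    total = np.zeros_like(t)
    for onset, duration, depth in events:
        lo, hi = np.searchsorted(t, [onset - 1.0, onset + duration + 1.0])
        if hi > lo:
            total[lo:hi] += (depth / 100.0) * _raised_cosine_envelope(
                t[lo:hi], onset, duration
            )
    return np.minimum(total, 0.95)


def generate_subject_signals(
    profile: SubjectProfile, seed: int
) -> BeatSeries:
    """Synthesize one night's beat-to-beat record for a subject.

    Beat times are the running sum of the RRI sequence. Each planted event
    is a smooth raised-cosine transient: PPGa drops by the specified depth
    while RRI shows a coupled negative excursion (heart-rate rise) scaled
    by ``rri_coupling``, followed by a small positive rebound. A
    respiratory-band oscillation and white noise ride on the PPGa baseline
    so the low-pass filter has work to do.

    The RRI envelope is evaluated at nominal beat times first, then beat
    times are re-derived from the realized RRIs (two fixed-point passes),
    which keeps the PPGa and RRI excursions aligned to within the slow
    drift of the heart-rate noise.
    """
    rng = np.random.default_rng(seed)
    night_s = profile.sleep_hours * 3600.0
    n_nominal = int(np.ceil(night_s / profile.mean_rri)) + 10

    hrv = rng.normal(0.0, profile.hrv_sd * profile.mean_rri, n_nominal)
    # slow autonomic drift in RRI (well below the low-pass cutoff)
    drift_t = np.arange(n_nominal) * profile.mean_rri
    drift = 0.02 * profile.mean_rri * np.sin(2 * np.pi * drift_t / 900.0)

    # RRI dip scale: fractional RRI drop = coupling * 0.4 * fractional PPGa drop
    t_nominal = drift_t
    for _ in range(2):
        env = _event_sum(t_nominal, profile.events)
        rebound = np.zeros_like(env)
        for onset, duration, depth in profile.events:
            rebound += (depth / 100.0) * 0.3 * _raised_cosine_envelope(
                t_nominal, onset + duration, 30.0
            )
        rri = profile.mean_rri * (
            1.0
            - profile.rri_coupling * 0.4 * env
            + profile.rri_coupling * 0.4 * rebound
        ) + hrv + drift
        rri = np.maximum(rri, 0.3)
        t_nominal = np.concatenate([[0.0], np.cumsum(rri[:-1])])

    beat_times = t_nominal
    keep = beat_times <= night_s
    beat_times, rri = beat_times[keep], rri[keep]

    env_p = _event_sum(beat_times, profile.events)
    resp = profile.resp_amplitude * np.sin(2 * np.pi * profile.resp_freq * beat_times)
    noise = rng.normal(0.0, profile.noise_sd, len(beat_times))
    ppga = profile.baseline_ppga * (1.0 - env_p) * (1.0 + resp) * (1.0 + noise)
    ppga = np.maximum(ppga, 0.0)
    return BeatSeries(beat_times=beat_times, rri=rri, ppga=ppga)


def _plant_events(
    rng: np.random.Generator,
    rate_per_hour: float,
    depth_mean: float,
    sleep_hours: float,
) -> list[tuple[float, float, float]]:
    """Draw event (onset, duration, depth) triples with enforced spacing."""
    n = rng.poisson(rate_per_hour * sleep_hours)
    if n == 0:
        return []
    night_s = sleep_hours * 3600.0
    margin = 220.0  # room for baseline + full segment at the night's edges
    events: list[tuple[float, float, float]] = []
    onsets: list[float] = []
    attempts = 0
    while len(events) < n and attempts < 50 * n:
        attempts += 1
        onset = rng.uniform(margin, night_s - margin)
        if any(abs(onset - o) < 240.0 for o in onsets):
            continue
        duration = float(np.clip(rng.normal(60.0, 15.0), 35.0, 130.0))
        depth = float(np.clip(rng.normal(depth_mean, 5.0), 6.0, 60.0))
        onsets.append(onset)
        events.append((onset, duration, depth))
    events.sort(key=lambda e: e[0])
    return events


# --- roster covariates ------------------------------------------------------

def _draw_covariates(rng: np.random.Generator, severe: bool) -> dict:
    """Clinical and sleep covariates from documented plausible ranges.

    Only hemoglobin differs by latent class (lower mean under high
    severity); everything else is class-independent, which gives the
    feature screen a signal to find without claiming the real joint
    distribution. Decoy covariates (class-independent by construction)
    pad the candidate pool.
    """
    cov = {
        "age": float(rng.uniform(8.0, 18.0)),
        "sex": int(rng.integers(0, 2)),
        "hemoglobin": float(rng.normal(7.8 if severe else 8.6, 1.0)),
        "white_blood_cell_count": float(np.clip(rng.normal(11.5, 3.0), 3.0, 25.0)),
        "reticulocyte_count": float(np.clip(rng.normal(9.0, 3.0), 1.0, 25.0)),
        "neutrophil_count": float(np.clip(rng.normal(5.5, 1.8), 1.0, 15.0)),
        "diastolic_bp": float(rng.normal(62.0, 8.0)),
        "systolic_bp": float(rng.normal(112.0, 10.0)),
        "bmi": float(np.clip(rng.normal(18.5, 3.0), 12.0, 35.0)),
        "hydroxyurea_use": int(rng.random() < 0.25),
        "arousal_index": float(rng.lognormal(np.log(9.0), 0.4)),
        "ahi": float(rng.lognormal(np.log(1.5), 0.8)),
        "limb_movements": float(np.clip(rng.normal(60.0, 30.0), 0.0, None)),
        # decoy clinical covariates (no planted class difference)
        "platelet_count": float(np.clip(rng.normal(380.0, 90.0), 100.0, 800.0)),
        "bilirubin": float(rng.lognormal(np.log(2.0), 0.4)),
        "ldh": float(np.clip(rng.normal(450.0, 120.0), 150.0, 1000.0)),
        "fetal_hemoglobin": float(np.clip(rng.normal(8.0, 5.0), 0.0, 30.0)),
        # decoy sleep covariates
        "sleep_efficiency": float(np.clip(rng.normal(88.0, 6.0), 50.0, 100.0)),
        "rem_fraction": float(np.clip(rng.normal(0.20, 0.05), 0.05, 0.40)),
        "sleep_latency": float(rng.lognormal(np.log(15.0), 0.5)),
    }
    cov["hemoglobin"] = float(np.clip(cov["hemoglobin"], 5.0, 12.0))
    return cov


def generate_cohort(config: CohortConfig) -> CohortBundle:
    """Generate a full cohort: roster, signals, artifact intervals, truth.

    Deterministic given ``config.seed``. Pain categories are *not* stored
    here — they are derived downstream from the pain rates; the latent
    severity class is logged separately for recovery tests only.
    """
    rng = np.random.default_rng(config.seed)
    b0, b_depth, b_rate = config.pain_link
    night_s = config.sleep_hours * 3600.0

    roster: list[dict] = []
    signals: dict[str, BeatSeries] = {}
    artifact_intervals: dict[str, list[tuple[float, float]]] = {}
    truth: list[EventTruth] = []

    for i in range(config.n_subjects):
        sid = f"S{i:04d}"
        severe = bool(rng.random() < config.prevalence_high)
        rate = config.event_rate_high if severe else config.event_rate_low
        depth_mean = config.mvasoc_mean_high if severe else config.mvasoc_mean_low
        events = _plant_events(rng, rate, depth_mean, config.sleep_hours)

        profile = SubjectProfile(
            subject_id=sid,
            mean_rri=float(rng.uniform(0.6, 1.1)),
            baseline_ppga=float(rng.uniform(0.8, 1.2)),
            sleep_hours=config.sleep_hours,
            events=tuple(events),
            rri_coupling=config.rri_coupling,
            noise_sd=config.noise_sd,
        )
        sig_seed = int(rng.integers(0, 2**31 - 1))
        signals[sid] = generate_subject_signals(profile, sig_seed)

        intervals: list[tuple[float, float]] = []
        masked = 0.0
        target = config.artifact_fraction * night_s
        guard = 0
        while masked < target and guard < 100:
            guard += 1
            length = float(rng.uniform(60.0, 180.0))
            start = float(rng.uniform(0.0, night_s - length))
            intervals.append((start, start + length))
            masked += length
        artifact_intervals[sid] = intervals

        for onset, duration, depth in events:
            truth.append(EventTruth(sid, onset, duration, depth))

        median_depth = float(np.median([e[2] for e in events])) if events else 6.0
        events_per_hour = len(events) / config.sleep_hours
        latent_rate = float(np.exp(b0 + b_depth * median_depth + b_rate * events_per_hour))

        pre_count = generate_pain_history(
            latent_rate, config.years_pre, rng, config.nb_dispersion
        )
        post_count = generate_pain_history(
            latent_rate, config.years_post, rng, config.nb_dispersion
        )

        record = {
            "id": sid,
            "severity": int(severe),  # latent class, logged for recovery tests only
            **_draw_covariates(rng, severe),
            "pre_pain_count": pre_count,
            "post_pain_count": post_count,
            "pre_pain_rate": pre_count / config.years_pre,
            "post_pain_rate": post_count / config.years_post,
        }
        roster.append(record)

    return CohortBundle(
        roster=roster,
        signals=signals,
        artifact_intervals=artifact_intervals,
        truth=truth,
        config=config,
    )
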