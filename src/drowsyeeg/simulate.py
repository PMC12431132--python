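"""Synthetic vigilance-EEG generator.

Emulates the structure of a sleep-deprivation PVT protocol: a cohort of
subjects, each recorded in three 10-minute sessions at 512 Hz over five
scalp channels (Fz, Cz, C3, C4, Pz), with a Karolinska Sleepiness Scale
(KSS) rating per session.  The alert/drowsy contrast is expressed
spectrally -- drowsiness elevates theta (4-7 Hz) power and attenuates the
posterior alpha (8-12 Hz) rhythm -- on top of a 1/f background, with
per-subject multiplicative band gains standing in for inter-subject
variability.

Signals are sums of band-limited oscillations (random frequencies and
phases within each canonical band, slowly amplitude-modulated) plus
spectrally shaped pink noise.  The homologous central electrodes C3 and
C4 share their oscillatory sources and differ only in noise, mimicking
the strong correlation of homologous sites; other channels draw
independent sources.  Everything is deterministic given the config seed.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .preprocess import EEGRecording

#: Canonical EEG frequency bands, Hz (lower edge inclusive).
BANDS: dict[str, tuple[float, float]] = {
    "delta": (0.5, 4.0),
    "theta": (4.0, 7.0),
    "alpha": (8.0, 12.0),
    "beta": (13.0, 30.0),
}

STATES = ("alert", "drowsy")

#: Mean band amplitudes (microvolt) per vigilance state.  Drowsiness is
#: expressed as elevated theta and attenuated alpha relative to alert
#: wakefulness; delta and beta barely move.
DEFAULT_BAND_POWERS: dict[str, dict[str, float]] = {
    "alert": {"delta": 10.0, "theta": 5.0, "alpha": 20.0, "beta": 5.0},
    "drowsy": {"delta": 12.0, "theta": 15.0, "alpha": 8.0, "beta": 4.0},
}

DEFAULT_CHANNELS = ("Fz", "Cz", "C3", "C4", "Pz")

_N_SINUSOIDS = 8  # oscillators per band
_ENV_DEPTH = 0.3  # slow amplitude-modulation depth


@dataclass(frozen=True)
class SimConfig:
    """Parameters of the synthetic cohort.

    Defaults reproduce the protocol geometry this package targets:
    14 subjects x 3 sessions x 600 s at 512 Hz, five channels, and a
    state schedule in which the final (most sleep-deprived) session is
    drowsy, giving a 2:1 alert:drowsy imbalance at the session level.
    """

    sampling_rate: float = 512.0
    session_duration: float = 600.0
    n_subjects: int = 14
    n_sessions_per_subject: int = 3
    channel_names: tuple[str, ...] = DEFAULT_CHANNELS
    band_powers: Mapping[str, Mapping[str, float]] = field(
        default_factory=lambda: {s: dict(v) for s, v in DEFAULT_BAND_POWERS.items()}
    )
    pink_noise_level: float = 5.0
    subject_effect_sd: float = 0.2
    kss_map: Mapping[str, int] = field(
        default_factory=lambda: {"alert": 3, "drowsy": 7}
    )
    state_schedule: tuple[str, ...] = ("alert", "alert", "drowsy")
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sampling_rate <= 0 or self.session_duration <= 0:
            raise ValueError("sampling_rate and session_duration must be positive")
        highest = max(hi for _, hi in BANDS.values())
        if self.sampling_rate <= 2 * highest:
            raise ValueError(
                f"sampling_rate {self.sampling_rate} violates Nyquist for "
                f"synthesized content up to {highest} Hz"
            )
        if self.pink_noise_level < 0 or self.subject_effect_sd < 0:
            raise ValueError("noise level and subject_effect_sd must be non-negative")
        for state, powers in self.band_powers.items():
            if state not in STATES:
                raise ValueError(f"unknown state {state!r}")
            for band, amp in powers.items():
                if band not in BANDS:
                    raise ValueError(f"unknown band {band!r}")
                if amp < 0:
                    raise ValueError("band amplitudes must be non-negative")
        if len(self.state_schedule) != self.n_sessions_per_subject:
            raise ValueError("state_schedule length must equal n_sessions_per_subject")
        for s in self.state_schedule:
            if s not in STATES:
                raise ValueError(f"invalid state {s!r} in schedule")

    @property
    def n_samples(self) -> int:
        return int(round(self.sampling_rate * self.session_duration))


@dataclass
class SyntheticRecording:
    """A simulated session: the recording plus its ground truth."""

    recording: EEGRecording
    state: str
    subject_gains: dict[str, float]


def _subject_gains(config: SimConfig, subject_id: int) -> dict[str, float]:
    """Per-subject multiplicative band gains, drawn once per subject.

    Log-normal so gains are positive and equal exactly 1 when
    ``subject_effect_sd`` is zero.
    """
    rng = np.random.default_rng(
        np.random.SeedSequence(config.seed, spawn_key=(0, subject_id))
    )
    z = rng.standard_normal(len(BANDS))
    return {
        band: float(np.exp(config.subject_effect_sd * z[i]))
        for i, band in enumerate(BANDS)
    }


def _band_oscillation(
    rng: np.random.Generator, t: np.ndarray, lo: float, hi: float, amplitude: float
) -> np.ndarray:
    """Sum of sinusoids within [lo, hi] Hz under a slow positive envelope."""
    if amplitude == 0:
        return np.zeros_like(t)
    freqs = rng.uniform(lo, hi, _N_SINUSOIDS)
    phases = rng.uniform(0, 2 * np.pi, _N_SINUSOIDS)
    x = np.zeros_like(t)
    for f, p in zip(freqs, phases):
        x += np.sin(2 * np.pi * f * t + p)
    # sum of N unit sinusoids has RMS sqrt(N/2); rescale so the band has
    # RMS equal to `amplitude`
    x *= amplitude / np.sqrt(_N_SINUSOIDS / 2.0)
    f_env = rng.uniform(0.02, 0.2)
    p_env = rng.uniform(0, 2 * np.pi)
    env = 1.0 + _ENV_DEPTH * np.sin(2 * np.pi * f_env * t + p_env)
    return x * env


def _pink_noise(rng: np.random.Generator, n: int, fs: float, level: float) -> np.ndarray:
    """Spectrally shaped white noise with power ~ 1/f for f >= 0.5 Hz."""
    if level == 0:
        return np.zeros(n)
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    freqs = np.fft.rfftfreq(n, 1.0 / fs)
    shape = 1.0 / np.sqrt(np.maximum(freqs, 0.5))  # amplitude ~ f^-1/2
    shape[0] = 0.0  # no DC
    x = np.fft.irfft(spec * shape, n=n)
    rms = np.sqrt(np.mean(x**2))
    return x * (level / rms) if rms > 0 else x


def simulate_session(
    config: SimConfig, subject_id: int, session_id: int, state: str
) -> SyntheticRecording:
    """Simulate one session of one subject in the given vigilance state.

    Deterministic given ``(config.seed, subject_id, session_id, state)``;
    the same call twice yields bit-identical samples.
    """
    if state not in STATES:
        raise ValueError(f"state must be one of {STATES}, got {state!r}")
    if not 0 <= subject_id < config.n_subjects:
        raise ValueError(f"subject_id {subject_id} out of range")
    if not 0 <= session_id < config.n_sessions_per_subject:
        raise ValueError(f"session_id {session_id} out of range")

    gains = _subject_gains(config, subject_id)
    n = config.n_samples
    t = np.arange(n) / config.sampling_rate
    powers = config.band_powers[state]

    state_idx = STATES.index(state)
    rng = np.random.default_rng(
        np.random.SeedSequence(
            config.seed, spawn_key=(1, subject_id, session_id, state_idx)
        )
    )

    # Homologous central electrodes share oscillatory sources.
    shared_pair = {"C3", "C4"}
    shared_source: np.ndarray | None = None
    signals = np.empty((len(config.channel_names), n))
    for ci, ch in enumerate(config.channel_names):
        if ch in shared_pair and shared_source is not None:
            osc = shared_source
        else:
            osc = np.zeros(n)
            for band, (lo, hi) in BANDS.items():
                amp = powers.get(band, 0.0) * gains[band]
                osc += _band_oscillation(rng, t, lo, hi, amp)
            if ch in shared_pair:
                shared_source = osc
        signals[ci] = osc + _pink_noise(rng, n, config.sampling_rate, config.pink_noise_level)

    rec = EEGRecording(
        subject_id=subject_id,
        session_id=session_id,
        sampling_rate=config.sampling_rate,
        channel_names=list(config.channel_names),
        samples=signals,
        kss=int(config.kss_map[state]),
    )
    return SyntheticRecording(recording=rec, state=state, subject_gains=gains)


def simulate_cohort(config: SimConfig) -> list[SyntheticRecording]:
    """Simulate the whole cohort under the configured state schedule."""
    if config.n_subjects < 1:
        raise ValueError("n_subjects must be >= 1")
    out = []
    for subj in range(config.n_subjects):
        for sess in range(config.n_sessions_per_subject):
            out.append(simulate_session(config, subj, sess, config.state_schedule[sess]))
    return out


class VigilanceEEGSimulator:
    """Thin object wrapper around :func:`simulate_cohort`.

    Mirrors the parameter-bag style of sklearn utilities: construct with a
    :class:`SimConfig` (or keyword overrides of the defaults) and call
    :meth:`simulate` / :meth:`simulate_session`.
    """

    def __init__(self, config: SimConfig | None = None, **overrides):
        base = config or SimConfig()
        self.config = replace(base, **overrides) if overrides else base

    def simulate(self) -> list[SyntheticRecording]:
        return simulate_cohort(self.config)

    def simulate_session(self, subject_id: int, session_id: int, state: str) -> SyntheticRecording:
        return simulate_session(self.config, subject_id, session_id, state)


def export_cohort_edf(
    recordings: Sequence[SyntheticRecording], out_dir: str | Path
) -> Path:
    """Write one EDF file per session plus a CSV manifest.

    Returns the manifest path.  File names are ``subj<S>_sess<K>.edf``.
    """
    from .edf import write_edf

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = out_dir / "manifest.csv"
    with open(manifest, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["path", "subject_id", "session_id", "state", "kss"])
        for sr in recordings:
            rec = sr.recording
            name = f"subj{rec.subject_id:02d}_sess{rec.session_id}.edf"
            write_edf(
                out_dir / name,
                rec.samples,
                rec.sampling_rate,
                rec.channel_names,
                subject=f"subj{rec.subject_id:02d}",
            )
            writer.writerow([name, rec.subject_id, rec.session_id, sr.state, rec.kss])
    return manifest
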