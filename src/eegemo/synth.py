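"""Seeded synthetic resting-state EEG cohorts.

Each recording is built, per channel, as

    x(t) = pink noise  +  sum over bands  A_band * e_band(t) * sin(2*pi*f_c*t + phi)
           (+ injected artifacts)

where ``A_band = base amplitude x condition multiplier x asymmetry factor x
participant multiplier`` and ``e_band(t)`` is a slow (~0.2 Hz) random envelope
normalized to unit RMS, so the expected band power of an oscillator is
``A_band**2 / 2``. The envelope is partly shared between the two electrodes of
a symmetric pair, which makes the per-epoch band-power series of a pair
positively correlated (the correlation-coefficient features would otherwise be
degenerate). Pink (1/f) background noise gives the canonical resting-EEG
spectral shape. Artifacts — frontal-dominant blink transients, 30–70 Hz muscle
bursts, single-sample spikes — are injected as Poisson event streams so the
rejection stage has realistic work to do.

Everything is a pure function of its parameters and an integer seed.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .bands import BAND_ORDER, CHANNELS, CONDITIONS, PAIRS
from .exceptions import ConfigurationError, InvalidLabelError, InvalidParameterError

#: Baseline oscillator amplitudes (uV), typical of eyes-open resting EEG.
BASE_AMPLITUDE_UV: dict[str, float] = {
    "delta": 20.0,
    "theta": 10.0,
    "alpha": 15.0,
    "beta": 5.0,
    "gamma": 3.0,
}

#: Oscillator carrier frequencies (Hz), band midpoints.
CARRIER_HZ: dict[str, float] = {
    "delta": 2.25,
    "theta": 6.0,
    "alpha": 10.0,
    "beta": 21.0,
    "gamma": 40.0,
}

#: RMS of the 1/f background noise (uV).
DEFAULT_NOISE_RMS_UV = 4.0

_ENVELOPE_CUTOFF_HZ = 0.2  # bandwidth of the slow amplitude envelope
_ENVELOPE_DEPTH = 0.4  # modulation depth before RMS normalization
_ENVELOPE_PAIR_WEIGHT = 0.6  # variance fraction of the pair-shared component

_CH_INDEX = {ch: i for i, ch in enumerate(CHANNELS)}


@dataclass(frozen=True)
class Recording:
    """A continuous 4-channel EEG recording in microvolts."""

    participant_id: str
    condition: str
    fs: float
    signal: np.ndarray  # (4, n_samples)
    channel_names: tuple[str, ...] = CHANNELS

    def __post_init__(self) -> None:
        if self.fs <= 0:
            raise InvalidParameterError(f"fs must be positive, got {self.fs}")
        if self.condition not in CONDITIONS:
            raise InvalidLabelError(f"unknown condition {self.condition!r}")
        sig = np.asarray(self.signal, dtype=float)
        if sig.ndim != 2 or sig.shape[0] != len(CHANNELS):
            raise InvalidParameterError(
                f"signal must be ({len(CHANNELS)}, n), got {sig.shape}"
            )
        if tuple(self.channel_names) != CHANNELS:
            raise InvalidParameterError(
                f"channels must be {CHANNELS} in order, got {self.channel_names}"
            )
        if not np.all(np.isfinite(sig)):
            raise InvalidParameterError("signal contains non-finite samples")
        object.__setattr__(self, "signal", sig)

    @property
    def n_samples(self) -> int:
        return self.signal.shape[1]

    @property
    def duration(self) -> float:
        return self.n_samples / self.fs


@dataclass(frozen=True)
class ConditionEffectProfile:
    """Multiplicative deviation of one condition from baseline.

    band_multipliers: amplitude multiplier per band (scalar, applied to every
        channel) — power scales as the square.
    asymmetry_offsets: per (band, pair) log-amplitude offsets; the right
        electrode of the pair is scaled by exp(+off/2) and the left by
        exp(-off/2), so the offset shifts asymmetry without changing the
        pair's total log-amplitude.
    """

    band_multipliers: dict[str, float] = field(default_factory=dict)
    asymmetry_offsets: dict[tuple[str, str], float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for band, m in self.band_multipliers.items():
            if band not in BAND_ORDER:
                raise InvalidParameterError(f"unknown band {band!r}")
            if m <= 0:
                raise InvalidParameterError(f"multiplier for {band} must be > 0")
        for (band, pair) in self.asymmetry_offsets:
            if band not in BAND_ORDER or pair not in PAIRS:
                raise InvalidParameterError(f"unknown (band, pair) ({band}, {pair})")

    def multiplier(self, band: str) -> float:
        return float(self.band_multipliers.get(band, 1.0))

    def channel_factor(self, band: str, channel: str) -> float:
        """Asymmetry factor for one channel (1.0 when no offset applies)."""
        f = 1.0
        for pair, (left, right) in PAIRS.items():
            off = self.asymmetry_offsets.get((band, pair), 0.0)
            if off and channel == right:
                f *= float(np.exp(off / 2.0))
            elif off and channel == left:
                f *= float(np.exp(-off / 2.0))
        return f


@dataclass(frozen=True)
class ArtifactSpec:
    """Poisson rates (events/minute) and amplitudes (uV) of injected artifacts."""

    blink_rate: float = 4.0
    blink_amplitude: float = 150.0
    muscle_burst_rate: float = 2.0
    muscle_band: tuple[float, float] = (30.0, 70.0)
    muscle_amplitude: float = 60.0  # RMS of the burst
    spike_rate: float = 1.0
    spike_amplitude: float = 300.0

    def __post_init__(self) -> None:
        for name in ("blink_rate", "muscle_burst_rate", "spike_rate"):
            if getattr(self, name) < 0:
                raise InvalidParameterError(f"{name} must be >= 0")
        for name in ("blink_amplitude", "muscle_amplitude", "spike_amplitude"):
            if getattr(self, name) < 0:
                raise InvalidParameterError(f"{name} must be >= 0")


NO_ARTIFACTS = ArtifactSpec(blink_rate=0.0, muscle_burst_rate=0.0, spike_rate=0.0)


def default_profiles() -> dict[str, ConditionEffectProfile]:
    """Default condition effect profiles.

    Directions follow the resting-EEG literature on arousal and anxiety:
    high arousal lowers alpha and raises beta/gamma; low arousal (calm)
    raises alpha; social anxiety raises theta and beta and shifts frontal
    asymmetry. Magnitudes are modelling assumptions, not measurements.
    """
    return {
        "baseline": ConditionEffectProfile(),
        "low_arousal": ConditionEffectProfile(band_multipliers={"alpha": 1.4}),
        "high_arousal": ConditionEffectProfile(
            band_multipliers={"alpha": 0.7, "beta": 1.6, "gamma": 1.5}
        ),
        "social_anxiety": ConditionEffectProfile(
            band_multipliers={"theta": 1.5, "beta": 1.5},
            asymmetry_offsets={("alpha", "AF"): 0.4},
        ),
    }


def _pink_noise(rng: np.random.Generator, n: int, fs: float, rms: float) -> np.ndarray:
    """1/f^1 power-shaped Gaussian noise, zero-mean, given RMS."""
    if rms == 0:
        return np.zeros(n)
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    spec = rng.standard_normal(len(freqs)) + 1j * rng.standard_normal(len(freqs))
    amp = np.zeros_like(freqs)
    amp[1:] = freqs[1:] ** -0.5  # power ~ 1/f
    x = np.fft.irfft(spec * amp, n=n)
    x -= x.mean()
    return x * (rms / np.sqrt(np.mean(x**2)))


def _slow_envelope_noise(rng: np.random.Generator, n: int, fs: float) -> np.ndarray:
    """Unit-variance Gaussian noise band-limited below the envelope cutoff."""
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    spec = rng.standard_normal(len(freqs)) + 1j * rng.standard_normal(len(freqs))
    mask = (freqs > 0) & (freqs <= _ENVELOPE_CUTOFF_HZ)
    x = np.fft.irfft(spec * mask, n=n)
    sd = x.std()
    if sd == 0:  # recording too short for any sub-cutoff bin
        return np.zeros(n)
    return (x - x.mean()) / sd


def make_recording(
    profile: ConditionEffectProfile,
    artifact: ArtifactSpec,
    participant_id: str,
    condition: str,
    fs: float = 256.0,
    duration: float = 300.0,
    seed: int = 0,
    *,
    participant_multipliers: dict[str, float] | None = None,
    noise_rms: float = DEFAULT_NOISE_RMS_UV,
) -> Recording:
    """Synthesize one participant-condition recording.

    Deterministic given identical arguments and seed. ``participant_multipliers``
    (per-band log-normal random effects) are supplied by :func:`make_cohort` so
    that one participant's four conditions share them.
    """
    if fs < 128:
        raise InvalidParameterError(f"fs must be >= 128 Hz, got {fs}")
    if duration < 4:
        raise InvalidParameterError(f"duration must be >= 4 s, got {duration}")
    if condition not in CONDITIONS:
        raise InvalidLabelError(f"unknown condition {condition!r}")

    pmult = participant_multipliers or {}
    n = int(round(fs * duration))
    t = np.arange(n) / fs
    rng = np.random.default_rng(seed)
    signal = np.empty((len(CHANNELS), n))

    # background noise, independent per channel
    for ci in range(len(CHANNELS)):
        signal[ci] = _pink_noise(rng, n, fs, noise_rms)

    # band oscillators: pair-shared + channel-specific envelope components
    for band in BAND_ORDER:
        fc = CARRIER_HZ[band]
        shared: dict[str, np.ndarray] = {
            pair: _slow_envelope_noise(rng, n, fs) for pair in PAIRS
        }
        for ch in CHANNELS:
            pair = next(p for p, (l, r) in PAIRS.items() if ch in (l, r))
            own = _slow_envelope_noise(rng, n, fs)
            w = _ENVELOPE_PAIR_WEIGHT
            mod = np.sqrt(w) * shared[pair] + np.sqrt(1 - w) * own
            env = 1.0 + _ENVELOPE_DEPTH * mod
            env /= np.sqrt(np.mean(env**2))  # unit RMS: power = A^2/2 exactly
            amp = (
                BASE_AMPLITUDE_UV[band]
                * profile.multiplier(band)
                * profile.channel_factor(band, ch)
                * float(pmult.get(band, 1.0))
            )
            phi = rng.uniform(0, 2 * np.pi)
            signal[_CH_INDEX[ch]] += amp * env * np.sin(2 * np.pi * fc * t + phi)

    _inject_artifacts(signal, fs, artifact, rng)

    return Recording(participant_id, condition, fs, signal)


def _inject_artifacts(
    signal: np.ndarray, fs: float, spec: ArtifactSpec, rng: np.random.Generator
) -> None:
    from scipy.signal import butter, sosfilt

    n = signal.shape[1]
    minutes = n / fs / 60.0

    # blinks: raised-cosine transients, frontal channels 3x temporoparietal
    n_blinks = rng.poisson(spec.blink_rate * minutes)
    for _ in range(n_blinks):
        width = rng.uniform(0.3, 0.5)
        w = max(int(round(width * fs)), 2)
        start = rng.integers(0, max(n - w, 1))
        u = np.arange(w) / (w - 1)
        shape = 0.5 * (1 - np.cos(2 * np.pi * u))
        for ch in CHANNELS:
            a = spec.blink_amplitude if ch.startswith("AF") else spec.blink_amplitude / 3
            signal[_CH_INDEX[ch], start : start + w] += a * shape

    # muscle bursts: band-limited noise on one random channel
    n_bursts = rng.poisson(spec.muscle_burst_rate * minutes)
    lo, hi = spec.muscle_band
    hi = min(hi, 0.99 * fs / 2)
    sos = butter(4, [lo, hi], btype="bandpass", fs=fs, output="sos")
    for _ in range(n_bursts):
        width = rng.uniform(0.2, 0.5)
        w = max(int(round(width * fs)), 8)
        start = rng.integers(0, max(n - w, 1))
        ch = rng.integers(0, len(CHANNELS))
        burst = sosfilt(sos, rng.standard_normal(w))
        burst_rms = np.sqrt(np.mean(burst**2))
        if burst_rms > 0:
            burst *= spec.muscle_amplitude / burst_rms
        signal[ch, start : start + w] += burst

    # spikes: single-sample outliers
    n_spikes = rng.poisson(spec.spike_rate * minutes)
    for _ in range(n_spikes):
        ch = rng.integers(0, len(CHANNELS))
        idx = rng.integers(0, n)
        signal[ch, idx] += spec.spike_amplitude * rng.choice([-1.0, 1.0])


def make_cohort(
    profiles: dict[str, ConditionEffectProfile],
    artifact: ArtifactSpec,
    n_participants: int = 15,
    fs: float = 256.0,
    duration: float = 300.0,
    seed: int = 0,
    *,
    participant_sigma: float = 0.2,
    noise_rms: float = DEFAULT_NOISE_RMS_UV,
) -> list[Recording]:
    """Generate ``n_participants x 4`` recordings.

    Each participant carries per-band log-normal amplitude multipliers
    (std of the log = ``participant_sigma``) shared across their four
    conditions, modelling stable between-subject differences.
    """
    if n_participants < 1:
        raise InvalidParameterError("n_participants must be >= 1")
    missing = [c for c in CONDITIONS if c not in profiles]
    if missing:
        raise ConfigurationError(f"missing effect profile for conditions: {missing}")

    ss = np.random.SeedSequence(seed)
    effect_seed, *rec_seeds = ss.spawn(1 + n_participants * len(CONDITIONS))
    effect_rng = np.random.default_rng(effect_seed)

    recordings: list[Recording] = []
    k = 0
    for p in range(n_participants):
        pid = f"P{p + 1:02d}"
        pmult = {
            band: float(np.exp(participant_sigma * effect_rng.standard_normal()))
            for band in BAND_ORDER
        }
        for condition in CONDITIONS:
            child_seed = int(rec_seeds[k].generate_state(1)[0] % (2**31))
            k += 1
            recordings.append(
                make_recording(
                    profiles[condition],
                    artifact,
                    pid,
                    condition,
                    fs=fs,
                    duration=duration,
                    seed=child_seed,
                    participant_multipliers=pmult,
                    noise_rms=noise_rms,
                )
            )
    return recordings


def write_recording_csv(recording: Recording, path: str | Path) -> None:
    """Write one recording as CSV: ``time_s,TP9,AF7,AF8,TP10``, uV, 6 decimals."""
    path = Path(path)
    t = np.arange(recording.n_samples) / recording.fs
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["time_s"] + list(CHANNELS))
        for i in range(recording.n_samples):
            writer.writerow(
                [f"{t[i]:.6f}"] + [f"{recording.signal[c, i]:.6f}" for c in range(4)]
            )


def read_recording_csv(
    path: str | Path, participant_id: str | None = None, condition: str | None = None
) -> Recording:
    """Read a recording CSV written by :func:`write_recording_csv`.

    ``participant_id`` and ``condition`` default to parsing the file stem as
    ``<participant>_<condition>``.
    """
    path = Path(path)
    data = np.loadtxt(path, delimiter=",", skiprows=1)
    if data.ndim != 2 or data.shape[1] != 1 + len(CHANNELS):
        raise InvalidParameterError(f"{path}: expected 5 columns, got {data.shape}")
    t = data[:, 0]
    dt = np.median(np.diff(t))
    fs = float(round(1.0 / dt))
    if participant_id is None or condition is None:
        stem = path.stem
        pid, _, cond = stem.partition("_")
        participant_id = participant_id or pid
        condition = condition or cond
    return Recording(participant_id, condition, fs, data[:, 1:].T.copy())
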