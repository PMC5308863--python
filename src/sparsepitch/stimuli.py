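"""Synthesis of calibrated acoustic stimuli.

All stimuli are pressure waveforms in pascals at a fixed sample rate
(default 100 kHz).  Levels are specified in dB SPL re 20 µPa: a component of
level L dB SPL is synthesised with peak amplitude 20e-6 * 10**(L/20) Pa, so a
single sine at L dB has the conventional SPL calibration of its amplitude.

Stimulus classes:

* harmonic / shifted-inharmonic complexes: sums of sinusoids at k*f0 + df,
* transposed tones: half-wave rectified low-frequency modulators, low-pass
  filtered and multiplied onto high-frequency carriers,
* iterated rippled noise (IRN): white noise through repeated delay-and-add
  (gain +1) or delay-and-subtract (gain -1) stages, then low-pass filtered,
* external audio (WAV / AIFF) for the framed musical-note pipeline.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import signal
from scipy.io import wavfile

DEFAULT_RATE = 100_000
P_REF = 20e-6  # threshold of hearing, Pa


def db_spl_to_pascal(level_db: float) -> float:
    """Peak pressure amplitude (Pa) of a component at ``level_db`` dB SPL."""
    if not np.isfinite(level_db):
        raise ValueError("level_db must be finite")
    return P_REF * 10.0 ** (level_db / 20.0)


@dataclass
class Waveform:
    """A calibrated pressure signal.

    Attributes
    ----------
    samples : np.ndarray
        Pressure in pascals, 1-D.
    rate : float
        Samples per second.
    """

    samples: np.ndarray
    rate: float = DEFAULT_RATE

    def __post_init__(self):
        self.samples = np.asarray(self.samples, dtype=float)
        if self.rate <= 0:
            raise ValueError("rate must be positive")
        if self.samples.ndim != 1:
            raise ValueError("samples must be one-dimensional")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("samples must be finite")

    @property
    def duration(self) -> float:
        return len(self.samples) / self.rate

    def time(self) -> np.ndarray:
        return np.arange(len(self.samples)) / self.rate


def _times(duration: float, rate: float) -> np.ndarray:
    n = int(round(duration * rate))
    return np.arange(n) / rate


@dataclass
class ComplexToneSpec:
    """A (possibly shifted) complex of sinusoids at frequencies k*f0 + shift.

    ``amplitude_weights`` optionally scales each component relative to the
    common calibrated amplitude (used e.g. for 1/k-weighted harmonic stacks).
    """

    f0: float
    harmonic_indices: tuple[int, ...]
    level_db: float = 30.0
    shift: float = 0.0
    phases: tuple[float, ...] | None = None
    amplitude_weights: tuple[float, ...] | None = None

    def __post_init__(self):
        self.harmonic_indices = tuple(int(k) for k in self.harmonic_indices)
        if self.f0 <= 0:
            raise ValueError("f0 must be positive")
        if any(k < 1 for k in self.harmonic_indices):
            raise ValueError("harmonic indices must be >= 1")
        for name in ("phases", "amplitude_weights"):
            v = getattr(self, name)
            if v is not None and len(v) != len(self.harmonic_indices):
                raise ValueError(f"{name} length must match harmonic_indices")

    @property
    def component_freqs(self) -> np.ndarray:
        return np.array([k * self.f0 + self.shift for k in self.harmonic_indices])


def make_harmonic_complex(
    spec: ComplexToneSpec, duration: float, rate: float = DEFAULT_RATE
) -> Waveform:
    """Sum of sinusoids at k*f0 + shift, each at the calibrated amplitude."""
    t = _times(duration, rate)
    freqs = spec.component_freqs
    if np.any(freqs >= rate / 2):
        raise ValueError("component frequency at or above Nyquist")
    amp = db_spl_to_pascal(spec.level_db)
    phases = spec.phases or (0.0,) * len(freqs)
    weights = spec.amplitude_weights or (1.0,) * len(freqs)
    x = np.zeros_like(t)
    for f, ph, w in zip(freqs, phases, weights):
        x += amp * w * np.sin(2 * np.pi * f * t + ph)
    return Waveform(x, rate)


def make_tone(
    freq: float,
    level_db: float,
    duration: float,
    rate: float = DEFAULT_RATE,
    phase: float = 0.0,
) -> Waveform:
    """Convenience: a single calibrated sine."""
    spec = ComplexToneSpec(f0=freq, harmonic_indices=(1,), level_db=level_db,
                           phases=(phase,))
    return make_harmonic_complex(spec, duration, rate)


@dataclass
class TransposedToneSpec:
    """Modulator frequency f0 carried on high-frequency carriers.

    Each carrier k is amplitude-modulated by a low-pass filtered (4th-order
    Butterworth, cutoff 0.2*f_c,k) half-wave rectified sine at f0.
    """

    f0: float
    carriers: tuple[float, ...] = (4000.0, 6350.0, 10080.0)
    level_db: float = 30.0

    def __post_init__(self):
        if self.f0 < 0:
            raise ValueError("f0 must be nonnegative")
        if self.f0 > 0 and self.f0 >= 0.2 * min(self.carriers):
            raise ValueError("modulator too fast relative to carriers")


def make_transposed_tone(
    spec: TransposedToneSpec, duration: float, rate: float = DEFAULT_RATE
) -> Waveform:
    if any(fc >= rate / 2 for fc in spec.carriers):
        raise ValueError("carrier at or above Nyquist")
    t = _times(duration, rate)
    amp = db_spl_to_pascal(spec.level_db)
    rect = np.maximum(0.0, np.sin(2 * np.pi * spec.f0 * t))
    x = np.zeros_like(t)
    for fc in spec.carriers:
        # causal (forward-only) filter, as a physical low-pass would act; the
        # DC of the rectified modulator passes through by design
        b, a = signal.butter(4, 0.2 * fc / (rate / 2), btype="low")
        env = signal.lfilter(b, a, rect)
        x += env * np.sin(2 * np.pi * fc * t)
    return Waveform(amp * x, rate)


@dataclass
class IRNSpec:
    """Iterated rippled noise: n_iterations delay-and-add/subtract stages."""

    delay: float
    gain: int = 1
    n_iterations: int = 1
    seed: int = 0
    lowpass_hz: float = 4000.0
    level_db: float = 70.0

    def __post_init__(self):
        if self.delay <= 0:
            raise ValueError("delay must be positive")
        if self.gain not in (1, -1):
            raise ValueError("gain must be +1 or -1")
        if self.n_iterations < 1:
            raise ValueError("n_iterations must be >= 1")


def make_irn(spec: IRNSpec, duration: float, rate: float = DEFAULT_RATE) -> Waveform:
    """Seed-deterministic IRN, low-pass filtered and RMS-calibrated.

    The level calibration matches the RMS of the noise to the RMS of a pure
    tone at ``level_db`` (amplitude/sqrt(2)), the usual broadband convention.
    """
    rng = np.random.default_rng(spec.seed)
    n = int(round(duration * rate))
    d = int(round(spec.delay * rate))
    if d == 0:
        raise ValueError("delay shorter than one sample")
    s = rng.standard_normal(n)
    for _ in range(spec.n_iterations):
        delayed = np.concatenate([np.zeros(d), s[:-d]]) if d < n else np.zeros(n)
        s = s + spec.gain * delayed
    b, a = signal.butter(4, spec.lowpass_hz / (rate / 2), btype="low")
    s = signal.lfilter(b, a, s)
    rms = np.sqrt(np.mean(s**2))
    target = db_spl_to_pascal(spec.level_db) / np.sqrt(2.0)
    if rms > 0:
        s = s * (target / rms)
    return Waveform(s, rate)


def _read_aiff(path: Path) -> tuple[int, np.ndarray]:
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", DeprecationWarning)
        import aifc
    with aifc.open(str(path), "rb") as f:
        rate = f.getframerate()
        sw = f.getsampwidth()
        nch = f.getnchannels()
        raw = f.readframes(f.getnframes())
    if sw == 2:
        data = np.frombuffer(raw, dtype=">i2").astype(float) / 2**15
    elif sw == 1:
        data = np.frombuffer(raw, dtype=np.int8).astype(float) / 2**7
    elif sw == 4:
        data = np.frombuffer(raw, dtype=">i4").astype(float) / 2**31
    else:
        raise ValueError(f"unsupported AIFF sample width: {sw}")
    return rate, data.reshape(-1, nch)


def _read_wav(path: Path) -> tuple[int, np.ndarray]:
    rate, data = wavfile.read(str(path))
    data = np.asarray(data)
    if data.dtype.kind == "i":
        data = data.astype(float) / float(2 ** (8 * data.dtype.itemsize - 1))
    elif data.dtype.kind == "u":  # 8-bit unsigned
        data = (data.astype(float) - 128.0) / 128.0
    else:
        data = data.astype(float)
    if data.ndim == 1:
        data = data[:, None]
    return rate, data


def load_audio(
    path: str | Path,
    rate: float = DEFAULT_RATE,
    level_db: float | None = None,
) -> Waveform:
    """Read a WAV or AIFF file as a mono Waveform at the pipeline rate.

    Stereo files are averaged to mono; the signal is polyphase-resampled to
    ``rate``; if ``level_db`` is given the RMS is rescaled to that SPL.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        if path.suffix.lower() in (".aif", ".aiff", ".aifc"):
            src_rate, data = _read_aiff(path)
        else:
            src_rate, data = _read_wav(path)
    except (FileNotFoundError, ValueError):
        raise
    except Exception as exc:  # corrupted container, truncated chunks, ...
        raise ValueError(f"could not read audio file {path}: {exc}") from exc
    if data.size == 0:
        raise ValueError(f"zero-length audio file: {path}")
    mono = data.mean(axis=1)
    if src_rate != rate:
        from math import gcd

        g = gcd(int(rate), int(src_rate))
        mono = signal.resample_poly(mono, int(rate) // g, int(src_rate) // g)
    if level_db is not None:
        rms = np.sqrt(np.mean(mono**2))
        if rms > 0:
            mono = mono * (db_spl_to_pascal(level_db) / np.sqrt(2.0) / rms)
    return Waveform(mono, rate)
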