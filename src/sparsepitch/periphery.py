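"""Simplified auditory periphery: waveform -> normalized AN rate matrix.

The stage structure per channel is

    4th-order gammatone at the channel CF (ERB bandwidth)
      -> optional memoryless compressive saturation ("saturating" mode)
      -> half-wave rectification (inner hair cell transduction)
      -> 1st-order low-pass at ``ihc_cutoff`` (loss of phase locking at
         high frequencies)

The final ``window_duration`` segment of the ``sim_duration`` simulation is
kept (the discarded prefix doubles as the filter settling window), optionally
decimated in time, and the whole matrix is divided by its maximum absolute
value so the peak entry is 1.

This periphery captures the three properties the downstream sparse-coding
model relies on: tonotopy, gradual loss of phase locking above ~1 kHz, and
(in saturating mode) the high-level saturation and spatial spread of the
response.  It is deliberately a compact, documented model with a stable
interface; external cochlear simulators can be dropped in behind the same
``simulate_an`` contract.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
from scipy import signal

from .stimuli import Waveform


# --- Glasberg & Moore ERB scale -------------------------------------------

def erb(f_hz):
    """Equivalent rectangular bandwidth (Hz) at frequency ``f_hz`` (Hz)."""
    return 24.7 * (4.37 * np.asarray(f_hz) / 1000.0 + 1.0)


def erb_number(f_hz):
    """ERB-number (cam) of a frequency in Hz."""
    return 21.4 * np.log10(4.37 * np.asarray(f_hz) / 1000.0 + 1.0)


def erb_number_to_hz(e):
    return (10.0 ** (np.asarray(e) / 21.4) - 1.0) * 1000.0 / 4.37


def erb_space(f_min: float, f_max: float, n: int) -> np.ndarray:
    """``n`` frequencies uniformly spaced on the ERB-number scale."""
    if n < 2:
        raise ValueError("need at least 2 points")
    return erb_number_to_hz(np.linspace(erb_number(f_min), erb_number(f_max), n))


@dataclass(frozen=True)
class PeripheryConfig:
    """Parameters of the peripheral model.

    ``sat_scale`` is the compression knee (Pa) of the saturating mode: BM
    signals well below it are passed linearly, signals above it are tanh
    compressed.  0.05 Pa (~68 dB SPL) keeps a 45 dB tone in the near-linear
    region while a 90 dB tone saturates.

    ``downsample`` decimates the windowed rate matrix in time (anti-aliased).
    The IHC low-pass leaves little energy at high rates, so moderate factors
    preserve the spatiotemporal structure while shrinking the sparse-coding
    problem; 1 reproduces the full-rate matrix.
    """

    n_channels: int = 200
    cf_min: float = 125.0
    cf_max: float = 20000.0
    mode: str = "linear"  # "linear" | "saturating"
    ihc_cutoff: float = 1000.0
    sim_duration: float = 0.015
    window_duration: float = 0.005
    downsample: int = 1
    sat_scale: float = 0.05

    def __post_init__(self):
        if not (0 < self.cf_min < self.cf_max):
            raise ValueError("need 0 < cf_min < cf_max")
        if self.window_duration > self.sim_duration:
            raise ValueError("window_duration must be <= sim_duration")
        if self.mode not in ("linear", "saturating"):
            raise ValueError(f"unknown mode: {self.mode}")
        if self.downsample < 1:
            raise ValueError("downsample must be >= 1")

    def key(self) -> tuple:
        return tuple(sorted(asdict(self).items()))


@dataclass
class ANResponse:
    """Time x channel matrix of normalized instantaneous AN rates."""

    rates: np.ndarray  # (T', N)
    cfs: np.ndarray  # (N,) strictly increasing
    rate: float  # effective sample rate of the time axis
    normalized: bool
    config: PeripheryConfig | None = None

    def __post_init__(self):
        if self.rates.shape[1] != len(self.cfs):
            raise ValueError("rates/cfs shape mismatch")
        if np.any(np.diff(self.cfs) <= 0):
            raise ValueError("cfs must be strictly increasing")


def cf_grid(config: PeripheryConfig) -> np.ndarray:
    """Characteristic frequencies, ERB-number spaced, ascending."""
    if config.n_channels < 2:
        raise ValueError("need at least 2 channels")
    return erb_space(config.cf_min, config.cf_max, config.n_channels)


def _gammatone_filterbank(x: np.ndarray, cfs: np.ndarray, fs: float) -> np.ndarray:
    """Filter ``x`` through a bank of 4th-order gammatone filters.

    Each channel is a cascade of four identical complex one-pole sections
    (impulse response envelope t^3 exp(-b t), i.e. the gammatone), realised
    as a single 4th-order complex IIR; the real part is taken and the gain
    at CF normalized to 1.
    """
    out = np.empty((len(x), len(cfs)))
    for j, cf in enumerate(cfs):
        b_rad = 2 * np.pi * 1.019 * float(erb(cf))
        pole = np.exp(-b_rad / fs) * np.exp(1j * 2 * np.pi * cf / fs)
        a = np.array(
            [1.0, -4 * pole, 6 * pole**2, -4 * pole**3, pole**4], dtype=complex
        )
        y = signal.lfilter([1.0], a, x.astype(complex))
        # analytic gain of the cascade at the CF; the real part of the
        # narrowband complex output carries half the amplitude
        z = np.exp(-1j * 2 * np.pi * cf / fs)
        gain = abs(1.0 / (1.0 - pole * z)) ** 4
        out[:, j] = y.real * (2.0 / gain)
    return out


def simulate_an(waveform: Waveform, config: PeripheryConfig) -> ANResponse:
    """Run the peripheral model on the trailing ``sim_duration`` of a waveform."""
    fs = waveform.rate
    n_sim = int(round(config.sim_duration * fs))
    if len(waveform.samples) < n_sim:
        raise ValueError("waveform shorter than sim_duration")
    if config.cf_max >= fs / 2:
        raise ValueError("cf_max at or above Nyquist")
    x = waveform.samples[-n_sim:]
    cfs = cf_grid(config)

    bm = _gammatone_filterbank(x, cfs, fs)
    if config.mode == "saturating":
        bm = config.sat_scale * np.tanh(bm / config.sat_scale)
    rect = np.maximum(bm, 0.0)
    # 1st-order IHC low-pass, same coefficients for every channel
    a1 = np.exp(-2 * np.pi * config.ihc_cutoff / fs)
    rates = signal.lfilter([1.0 - a1], [1.0, -a1], rect, axis=0)

    n_win = int(round(config.window_duration * fs))
    seg = rates[-n_win:, :]
    eff_rate = fs
    if config.downsample > 1:
        seg = signal.decimate(seg, config.downsample, axis=0, zero_phase=True)
        eff_rate = fs / config.downsample

    peak = np.max(np.abs(seg))
    if peak > 0:
        seg = seg / peak
        normalized = True
    else:
        normalized = False
    return ANResponse(rates=seg, cfs=cfs, rate=eff_rate, normalized=normalized,
                      config=config)


def vectorize(resp: ANResponse) -> np.ndarray:
    """Column-major stacking of the rate matrix (channel after channel)."""
    return resp.rates.flatten(order="F")


def unvectorize(v: np.ndarray, n_channels: int) -> np.ndarray:
    """Inverse of :func:`vectorize`."""
    return v.reshape((-1, n_channels), order="F")


def save_response(resp: ANResponse, path) -> None:
    """Round-trip an ANResponse to a portable .npz container."""
    import json

    meta = json.dumps(asdict(resp.config)) if resp.config else ""
    np.savez(path, rates=resp.rates, cfs=resp.cfs, rate=resp.rate,
             normalized=resp.normalized, config=meta)


def load_response(path) -> ANResponse:
    import json

    with np.load(path, allow_pickle=False) as z:
        cfg = PeripheryConfig(**json.loads(str(z["config"]))) if str(z["config"]) else None
        return ANResponse(rates=z["rates"], cfs=z["cfs"], rate=float(z["rate"]),
                          normalized=bool(z["normalized"]), config=cfg)
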