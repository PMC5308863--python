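"""Dictionaries of spatiotemporal auditory-nerve response atoms.

Each atom is the vectorized, peak-normalized AN population response to a
probe stimulus.  Two families are provided:

* ``sine``:  probes are pure tones at M frequencies, optionally in groups of
  g phase-shifted copies (phases 2*pi*k/g) so the decomposition can absorb
  unknown stimulus phase,
* ``stack``: probes are six-harmonic complexes with 1/k amplitude weighting,
  with atom frequencies capped at cf_max/6 to keep all partials in band.

Atom frequencies are spaced on the ERB-number scale so dictionary resolution
follows cochlear resolution.  Dictionaries can be cached on disk keyed by a
content hash of their build parameters; an in-process memo cache avoids
rebuilding within one session.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, asdict, field
from pathlib import Path

import numpy as np

from . import periphery as per
from .stimuli import ComplexToneSpec, make_harmonic_complex


@dataclass
class Dictionary:
    """Atom matrix with per-group frequency and phase structure.

    ``matrix`` is (T'*N) x (g*M); the g columns of one frequency group are
    contiguous, so column m*g + k is frequency ``freqs[m]`` at phase
    ``phases[k]``.
    """

    matrix: np.ndarray
    freqs: np.ndarray  # (M,) ascending
    n_groups: int
    phases: np.ndarray  # (g,)
    family: str
    periphery_config: per.PeripheryConfig
    levels_db: np.ndarray | None = None  # per-frequency probe level
    _gram: np.ndarray | None = field(default=None, repr=False)

    @property
    def n_atoms(self) -> int:
        return len(self.freqs)

    @property
    def gram(self) -> np.ndarray:
        """DᵀD, computed once and memoised (the ISTA inner loop runs on it)."""
        if self._gram is None:
            self._gram = self.matrix.T @ self.matrix
        return self._gram

    def project(self, v: np.ndarray) -> np.ndarray:
        """Dᵀv for a vectorized AN response."""
        return self.matrix.T @ v


def _atom_freqs(M: int, freq_range: tuple[float, float]) -> np.ndarray:
    lo, hi = freq_range
    if not (0 < lo < hi):
        raise ValueError("invalid frequency range")
    return per.erb_space(lo, hi, M)


def _atom_column(spec: ComplexToneSpec, config: per.PeripheryConfig) -> np.ndarray:
    wave = make_harmonic_complex(spec, config.sim_duration, rate=100_000)
    resp = per.simulate_an(wave, config)
    col = per.vectorize(resp)
    peak = np.max(np.abs(col))
    if peak == 0:
        raise ValueError(f"degenerate (all-zero) atom for probe at {spec.f0} Hz")
    return col / peak


def build_sine_dictionary(
    M: int,
    g: int = 1,
    level_db: float | tuple[float, float] = 30.0,
    freq_range: tuple[float, float] = (125.0, 20000.0),
    periphery_config: per.PeripheryConfig | None = None,
    seed: int = 0,
) -> Dictionary:
    """Tone-probe dictionary: M frequency groups x g phases.

    ``level_db`` is either a fixed probe level or a (lo, hi) interval from
    which per-frequency levels are drawn uniformly (seeded).
    """
    if M < 2:
        raise ValueError("M must be >= 2")
    if g < 1:
        raise ValueError("g must be >= 1")
    config = periphery_config or per.PeripheryConfig()
    if freq_range[1] >= 50_000:
        raise ValueError("atom frequency above Nyquist")
    freqs = _atom_freqs(M, freq_range)
    if np.isscalar(level_db):
        levels = np.full(M, float(level_db))
    else:
        lo, hi = level_db
        levels = np.random.default_rng(seed).uniform(lo, hi, size=M)
    phases = 2 * np.pi * np.arange(g) / g
    cols = []
    for f, lv in zip(freqs, levels):
        for ph in phases:
            spec = ComplexToneSpec(f0=f, harmonic_indices=(1,), level_db=lv,
                                   phases=(ph,))
            cols.append(_atom_column(spec, config))
    return Dictionary(
        matrix=np.column_stack(cols),
        freqs=freqs,
        n_groups=g,
        phases=phases,
        family="sine",
        periphery_config=config,
        levels_db=levels,
    )


def build_stack_dictionary(
    M: int,
    periphery_config: per.PeripheryConfig | None = None,
    level_db: float = 40.0,
    n_harmonics: int = 6,
) -> Dictionary:
    """Harmonic-stack dictionary: probes are n_harmonics partials with 1/k
    amplitudes; atom frequencies capped at cf_max / n_harmonics."""
    if M < 2:
        raise ValueError("M must be >= 2")
    config = periphery_config or per.PeripheryConfig()
    freqs = _atom_freqs(M, (config.cf_min, config.cf_max / n_harmonics))
    weights = tuple(1.0 / k for k in range(1, n_harmonics + 1))
    cols = []
    for f in freqs:
        spec = ComplexToneSpec(
            f0=f,
            harmonic_indices=tuple(range(1, n_harmonics + 1)),
            level_db=level_db,
            amplitude_weights=weights,
        )
        cols.append(_atom_column(spec, config))
    return Dictionary(
        matrix=np.column_stack(cols),
        freqs=freqs,
        n_groups=1,
        phases=np.zeros(1),
        family="stack",
        periphery_config=config,
        levels_db=np.full(M, level_db),
    )


# --- caching ---------------------------------------------------------------

_MEM_CACHE: dict[str, Dictionary] = {}


def _params_hash(params: dict) -> str:
    blob = json.dumps(params, sort_keys=True, default=str).encode()
    return hashlib.sha1(blob).hexdigest()[:16]


def load_or_build(
    family: str = "sine",
    cache_dir: str | Path | None = None,
    **kwargs,
) -> Dictionary:
    """Build a dictionary, reusing an in-memory or on-disk cached copy.

    The cache key is a content hash of (family, build parameters, periphery
    config), so a stale cache cannot be served for changed parameters.
    """
    config = kwargs.get("periphery_config") or per.PeripheryConfig()
    kwargs["periphery_config"] = config
    params = {k: v for k, v in kwargs.items() if k != "periphery_config"}
    params["family"] = family
    params["periphery"] = asdict(config)
    key = _params_hash(params)
    if key in _MEM_CACHE:
        return _MEM_CACHE[key]
    path = Path(cache_dir) / f"dict_{key}.npz" if cache_dir else None
    if path is not None and path.exists():
        d = _load(path, config)
    else:
        builder = {"sine": build_sine_dictionary, "stack": build_stack_dictionary}[family]
        d = builder(**kwargs)
        if path is not None:
            path.parent.mkdir(parents=True, exist_ok=True)
            _save(d, path)
    _MEM_CACHE[key] = d
    return d


def _save(d: Dictionary, path: Path) -> None:
    np.savez_compressed(
        path,
        matrix=d.matrix,
        freqs=d.freqs,
        phases=d.phases,
        n_groups=d.n_groups,
        family=d.family,
        levels_db=d.levels_db if d.levels_db is not None else np.array([]),
        periphery=json.dumps(asdict(d.periphery_config)),
    )


def _load(path: Path, config: per.PeripheryConfig) -> Dictionary:
    with np.load(path, allow_pickle=False) as z:
        return Dictionary(
            matrix=z["matrix"],
            freqs=z["freqs"],
            n_groups=int(z["n_groups"]),
            phases=z["phases"],
            family=str(z["family"]),
            periphery_config=config,
            levels_db=z["levels_db"] if z["levels_db"].size else None,
        )
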