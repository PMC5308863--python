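"""Experiment runners for the classic pitch phenomena.

Each runner synthesizes its stimulus battery, pushes it through the full
pipeline (periphery -> sparse coder -> harmonic sieve), and returns a tidy
``pandas.DataFrame`` plus a summary dict; with ``out_dir`` set it also writes
the results (CSV), the summary (JSON) and the full run configuration (JSON)
so a run is reproducible from its saved config and seeds.

Two scale presets are provided: ``full`` (N = 200 channels, M = 1000 atoms,
full-rate AN matrices), and ``desk``
(N = 100, M = 250, 2x decimated AN matrices) for interactive use and the
test battery.  The preset used is recorded in every run's metadata.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import dictionary as dict_mod
from . import periphery as per
from . import sieve as sieve_mod
from . import sparse_coder as sc
from . import stimuli as stim
from .sieve import GRID_OVERSAMPLE

log = logging.getLogger(__name__)

PRESETS: dict[str, dict] = {
    "desk": {"n_channels": 100, "M": 250, "downsample": 2},
    "full": {"n_channels": 200, "M": 1000, "downsample": 1},
}


@dataclass
class Pipeline:
    """A ready-to-run model instance: dictionary + sieve + solver settings."""

    dictionary: dict_mod.Dictionary
    sieve: sieve_mod.SieveMatrix
    solver: sc.SolverConfig
    stimulus_periphery: per.PeripheryConfig

    def analyze(self, waveform: stim.Waveform) -> tuple[sc.SparseCode, sieve_mod.PitchPDF]:
        resp = per.simulate_an(waveform, self.stimulus_periphery)
        v = per.vectorize(resp)
        code = sc.solve(v, self.dictionary, self.solver)
        ht = sieve_mod.interpolate_coefficients(
            code.h, self.dictionary.freqs, self.sieve.grid
        )
        return code, sieve_mod.compute_pdf(ht, self.sieve)

    def estimate(self, waveform: stim.Waveform,
                 restrict: tuple[float, float] | None = None) -> sieve_mod.PitchEstimate:
        _, pdf = self.analyze(waveform)
        return sieve_mod.estimate_pitch(pdf, restrict=restrict)


def make_pipeline(
    preset: str = "desk",
    g: int = 1,
    family: str = "sine",
    dict_level_db=30.0,
    stimulus_mode: str = "linear",
    lam: float = 0.01,
    dict_seed: int = 0,
    cache_dir=None,
    **overrides,
) -> Pipeline:
    """Assemble a Pipeline from a named scale preset.

    ``stimulus_mode`` selects the periphery nonlinearity applied to incoming
    stimuli ("linear" or "saturating"); dictionary probes are always run at
    moderate level through the linear periphery.
    """
    p = dict(PRESETS[preset])
    p.update(overrides)
    M = p.pop("M")
    dict_periphery = per.PeripheryConfig(mode="linear", **p)
    stim_periphery = per.PeripheryConfig(mode=stimulus_mode, **p)
    if family == "sine":
        d = dict_mod.load_or_build(
            "sine", cache_dir=cache_dir, M=M, g=g, level_db=dict_level_db,
            periphery_config=dict_periphery, seed=dict_seed,
        )
    else:
        d = dict_mod.load_or_build(
            "stack", cache_dir=cache_dir, M=M,
            periphery_config=dict_periphery,
        )
    sv = sieve_mod.sieve_for(GRID_OVERSAMPLE * M, dict_periphery.cf_min,
                             dict_periphery.cf_max)
    return Pipeline(
        dictionary=d,
        sieve=sv,
        solver=sc.SolverConfig(lam=lam),
        stimulus_periphery=stim_periphery,
    )


def _write_outputs(out_dir, name: str, config: dict, df: pd.DataFrame,
                   summary: dict) -> None:
    if out_dir is None:
        return
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    df.to_csv(out / f"{name}.csv", index=False)
    (out / f"{name}_summary.json").write_text(
        json.dumps(summary, indent=2, default=float))
    (out / f"{name}_config.json").write_text(
        json.dumps(config, indent=2, default=str))


# ---------------------------------------------------------------------------
# Level invariance (missing fundamental at 30 vs 90 dB, SC vs LS)
# ---------------------------------------------------------------------------

def run_level_invariance(
    f0: float = 225.0,
    harmonics: tuple[int, ...] = (3, 4, 5, 6, 7, 8),
    levels: tuple[float, ...] = (30.0, 90.0),
    lam_sc: float = 0.01,
    preset: str = "desk",
    out_dir=None,
    cache_dir=None,
) -> pd.DataFrame:
    """Missing-fundamental complex at several levels, sparse vs least squares.

    High levels (>= 60 dB SPL) are run through the saturating periphery; the
    flatness of each pdf is summarised by its peak-to-median ratio.
    """
    rows = []
    for level in levels:
        mode = "saturating" if level >= 60 else "linear"
        for lam, label in ((lam_sc, "SC"), (0.0, "LS")):
            pipe = make_pipeline(preset=preset, stimulus_mode=mode, lam=lam,
                                 cache_dir=cache_dir)
            wave = stim.make_harmonic_complex(
                stim.ComplexToneSpec(f0=f0, harmonic_indices=harmonics,
                                     level_db=level),
                duration=pipe.stimulus_periphery.sim_duration,
            )
            _, pdf = pipe.analyze(wave)
            est = sieve_mod.estimate_pitch(pdf)
            rows.append({
                "level_db": level, "solver_mode": label, "f_hat": est.f_hat,
                "peak_median_ratio": float(pdf.probs.max() / np.median(pdf.probs)),
            })
    df = pd.DataFrame(rows)
    summary = {
        f"{r.solver_mode}_{int(r.level_db)}dB": r.f_hat for r in df.itertuples()
    }
    cfg = dict(experiment="level_invariance", f0=f0, harmonics=harmonics,
               levels=levels, lam_sc=lam_sc, preset=preset)
    _write_outputs(out_dir, "level_invariance", cfg, df, summary)
    return df


# ---------------------------------------------------------------------------
# Resolved vs unresolved harmonics and salience
# ---------------------------------------------------------------------------

def run_resolved_unresolved(
    f0: float = 433.0,
    rs: tuple[int, ...] = (1, 6, 10, 17, 22),
    level_db: float = 45.0,
    family: str = "sine",
    dict_level_db: float = 60.0,
    M: int = 1000,
    preset: str = "desk",
    out_dir=None,
    cache_dir=None,
) -> pd.DataFrame:
    """Four-harmonic complexes starting at harmonic r; estimate and salience.

    Salience is the height ratio of the two tallest pdf peaks within one
    octave around the fundamental; it declines as the harmonics move from
    resolved (low r) to unresolved (high r) cochlear territory.  The
    dictionary defaults to M = 1000 atoms: resolving components around the
    20th harmonic requires atom spacing no coarser than the sieve template
    width there (~0.04 ERB), which the coarse desk dictionary does not reach.
    """
    pipe = make_pipeline(preset=preset, family=family,
                         dict_level_db=dict_level_db, M=M,
                         cache_dir=cache_dir)
    octave = sieve_mod.octave_interval(f0)
    rows = []
    for r in rs:
        wave = stim.make_harmonic_complex(
            stim.ComplexToneSpec(f0=f0, harmonic_indices=tuple(range(r, r + 4)),
                                 level_db=level_db),
            duration=pipe.stimulus_periphery.sim_duration,
        )
        _, pdf = pipe.analyze(wave)
        est_global = sieve_mod.estimate_pitch(pdf)
        est_oct = sieve_mod.estimate_pitch(pdf, restrict=octave)
        rows.append({
            "r": r,
            "f_hat": est_global.f_hat,
            "f_hat_octave": est_oct.f_hat,
            "salience": sieve_mod.salience(pdf, octave),
        })
    df = pd.DataFrame(rows)
    summary = {"f0": f0,
               "estimates": df["f_hat"].tolist(),
               "saliences": df["salience"].tolist()}
    cfg = dict(experiment="resolved_unresolved", f0=f0, rs=rs,
               level_db=level_db, family=family, dict_level_db=dict_level_db,
               preset=preset)
    _write_outputs(out_dir, "resolved_unresolved", cfg, df, summary)
    return df


# ---------------------------------------------------------------------------
# Pitch shift of equally spaced inharmonic complexes
# ---------------------------------------------------------------------------

def run_pitch_shift(
    f0: float = 200.0,
    harmonics: tuple[int, ...] = (4, 5, 6, 7),
    shifts: np.ndarray | None = None,
    level_db: float = 45.0,
    n_peaks: int = 4,
    M: int = 1000,
    preset: str = "desk",
    out_dir=None,
    cache_dir=None,
) -> tuple[pd.DataFrame, dict]:
    """Sweep the common shift of an equally spaced complex; track pdf peaks.

    For every shift the ``n_peaks`` tallest pdf peaks are recorded; the slope
    of the top peak against the lowest component frequency f_L (the "first
    effect of pitch shift") is fit by least squares over the sweep.  M
    defaults to the full 1000-atom dictionary (shifted components reach the
    8th harmonic and beyond, where coarse atom grids quantize away the shift).
    """
    if shifts is None:
        shifts = np.linspace(0.0, f0, 21)
    pipe = make_pipeline(preset=preset, M=M, cache_dir=cache_dir)
    rows = []
    for df_shift in np.atleast_1d(shifts):
        wave = stim.make_harmonic_complex(
            stim.ComplexToneSpec(f0=f0, harmonic_indices=harmonics,
                                 shift=float(df_shift), level_db=level_db),
            duration=pipe.stimulus_periphery.sim_duration,
        )
        _, pdf = pipe.analyze(wave)
        est = sieve_mod.estimate_pitch(pdf)
        f_low = min(harmonics) * f0 + df_shift
        top = est.peaks[:n_peaks]
        for rank, (freq, height) in enumerate(top, start=1):
            rows.append({"shift": float(df_shift), "f_low": float(f_low),
                         "rank": rank, "peak_freq": float(freq),
                         "peak_height": float(height),
                         "f_hat": est.f_hat})
    df = pd.DataFrame(rows)
    top_df = df[df["rank"] == 1]
    slope = float("nan")
    if len(top_df) > 1:
        # restrict to the main branch (estimates near f0) for the line fit
        branch = top_df[np.abs(np.log2(top_df["peak_freq"] / f0)) < 0.5]
        if len(branch) > 1:
            slope = float(np.polyfit(branch["f_low"], branch["peak_freq"], 1)[0])
    summary = {"f0": f0, "slope_vs_f_low": slope}
    cfg = dict(experiment="pitch_shift", f0=f0, harmonics=harmonics,
               shifts=list(np.atleast_1d(shifts)), level_db=level_db,
               preset=preset)
    _write_outputs(out_dir, "pitch_shift", cfg, df, summary)
    return df, summary


# ---------------------------------------------------------------------------
# Transposed tones vs pure tones
# ---------------------------------------------------------------------------

def fold_to_octave(ratio: float) -> float:
    """Fold a frequency ratio into [1/sqrt(2), sqrt(2)) by octave shifts."""
    if ratio <= 0:
        raise ValueError("ratio must be positive")
    frac = np.log2(ratio) - np.round(np.log2(ratio))
    return float(2.0 ** frac)


def run_transposed_tones(
    f0_values: np.ndarray | None = None,
    level_db: float = 30.0,
    hit_rtol: float = 0.02,
    preset: str = "desk",
    out_dir=None,
    cache_dir=None,
) -> tuple[pd.DataFrame, dict]:
    """Paired pure-tone / transposed-tone batches over an f0 grid.

    A "hit" is an estimate whose octave-folded ratio to f0 lies within
    ``hit_rtol``; octave folding follows the psychoacoustic convention of
    ignoring octave errors.  Pure tones are estimated accurately; transposed
    tones, whose low-frequency timing sits at high-CF places, are not.
    """
    if f0_values is None:
        f0_values = np.linspace(100.0, 500.0, 100)
    pipe = make_pipeline(preset=preset, cache_dir=cache_dir)
    dur = pipe.stimulus_periphery.sim_duration
    rows = []
    for f0 in np.atleast_1d(f0_values):
        pure = stim.make_tone(float(f0), level_db, dur)
        tt = stim.make_transposed_tone(
            stim.TransposedToneSpec(f0=float(f0), level_db=level_db), dur)
        for kind, wave in (("pure", pure), ("transposed", tt)):
            est = pipe.estimate(wave)
            folded = fold_to_octave(est.f_hat / f0)
            rows.append({
                "stimulus_type": kind, "f0": float(f0), "f_hat": est.f_hat,
                "folded_ratio": folded,
                "hit": bool(abs(np.log2(folded)) <= np.log2(1 + hit_rtol)),
            })
    df = pd.DataFrame(rows)
    summary = {
        "pure_hit_rate": float(df[df.stimulus_type == "pure"]["hit"].mean()),
        "transposed_hit_rate": float(
            df[df.stimulus_type == "transposed"]["hit"].mean()),
    }
    cfg = dict(experiment="transposed_tones",
               f0_values=list(np.atleast_1d(f0_values)), level_db=level_db,
               hit_rtol=hit_rtol, preset=preset)
    _write_outputs(out_dir, "transposed_tones", cfg, df, summary)
    return df, summary


# ---------------------------------------------------------------------------
# Iterated rippled noise
# ---------------------------------------------------------------------------

def run_irn(
    delays: tuple[float, ...] = (0.005,),
    gains: tuple[int, ...] = (1,),
    n_itrs: tuple[int, ...] = (10,),
    n_seeds: int = 50,
    level_db: float = 70.0,
    g: int = 4,
    dict_level_db: float = 45.0,
    duration: float = 0.05,
    seed: int = 0,
    preset: str = "desk",
    out_dir=None,
    cache_dir=None,
) -> tuple[pd.DataFrame, dict]:
    """Seeded IRN batteries; per condition the histogram of octave-restricted
    pitch estimates around 1/d and its mode.

    The stimulus periphery runs in saturating mode (70 dB SPL presentation);
    the dictionary uses ``g`` phase groups to absorb the random noise phase.
    """
    pipe = make_pipeline(preset=preset, g=g, dict_level_db=dict_level_db,
                         stimulus_mode="saturating", cache_dir=cache_dir)
    rows = []
    for d in delays:
        target = 1.0 / d
        interval = sieve_mod.octave_interval(target)
        for gain in gains:
            for n_itr in n_itrs:
                for rep in range(n_seeds):
                    spec = stim.IRNSpec(delay=d, gain=gain, n_iterations=n_itr,
                                        seed=seed * 100003 + rep,
                                        level_db=level_db)
                    wave = stim.make_irn(spec, duration)
                    est = pipe.estimate(wave, restrict=interval)
                    rows.append({"delay": d, "gain": gain, "n_itr": n_itr,
                                 "rep": rep, "f_hat": est.f_hat})
    df = pd.DataFrame(rows)
    summary = {}
    for (d, gain, n_itr), grp in df.groupby(["delay", "gain", "n_itr"]):
        vals, counts = np.unique(grp["f_hat"], return_counts=True)
        summary[f"mode_d{d * 1000:g}ms_g{gain:+d}_n{n_itr}"] = float(
            vals[np.argmax(counts)])  # argmax tie -> lower frequency
    cfg = dict(experiment="irn", delays=delays, gains=gains, n_itrs=n_itrs,
               n_seeds=n_seeds, level_db=level_db, g=g,
               dict_level_db=dict_level_db, duration=duration, seed=seed,
               preset=preset)
    _write_outputs(out_dir, "irn", cfg, df, summary)
    return df, summary


# ---------------------------------------------------------------------------
# Framed musical-note pipeline
# ---------------------------------------------------------------------------

NOTE_NAMES = ("A", "A#", "B", "C", "C#", "D", "D#", "E", "F", "F#", "G", "G#")


def note_name(freq: float, a4: float = 440.0) -> str:
    """Nearest equal-tempered note name (A4 = 440 Hz)."""
    if freq <= 0:
        raise ValueError("frequency must be positive")
    semis = int(np.round(12.0 * np.log2(freq / a4)))
    name = NOTE_NAMES[semis % 12]
    octave = 4 + (semis + 9) // 12
    return f"{name}{octave}"


@dataclass
class FramedResult:
    """Per-frame coefficients, per-frame pdfs, and their time average."""

    H_g: np.ndarray  # (M, T_steps)
    P_g: np.ndarray  # (P, T_steps), columns unit-sum
    mean_pdf: sieve_mod.PitchPDF
    f_hat: float
    note: str
    frame_starts: np.ndarray


def run_framed_note(
    waveform: stim.Waveform,
    t_steps: int = 100,
    g: int = 10,
    level_db: float | None = 60.0,
    preset: str = "desk",
    pipeline: Pipeline | None = None,
    out_dir=None,
    cache_dir=None,
) -> FramedResult:
    """Frame a recorded (or synthetic) note and aggregate per-frame pitch pdfs.

    The signal is divided into ``t_steps`` hops; each frame is the standard
    15 ms analysis window anchored at the frame start.  Frames whose window
    would overrun the signal are dropped (with a log note).  ``level_db``
    rescales the input RMS before analysis; pass None to keep the waveform's
    own calibration.
    """
    if level_db is not None:
        rms = np.sqrt(np.mean(waveform.samples**2))
        if rms > 0:
            scale = stim.db_spl_to_pascal(level_db) / np.sqrt(2.0) / rms
            waveform = stim.Waveform(waveform.samples * scale, waveform.rate)
    pipe = pipeline or make_pipeline(preset=preset, g=g, cache_dir=cache_dir)
    win = pipe.stimulus_periphery.sim_duration
    if waveform.duration < win:
        raise ValueError("waveform shorter than one analysis window")
    hop = waveform.duration / t_steps
    n_win = int(round(win * waveform.rate))
    starts, hs, ps = [], [], []
    for i in range(t_steps):
        s = int(round(i * hop * waveform.rate))
        if s + n_win > len(waveform.samples):
            break
        frame = stim.Waveform(waveform.samples[s:s + n_win], waveform.rate)
        code, pdf = pipe.analyze(frame)
        starts.append(s / waveform.rate)
        hs.append(code.h)
        ps.append(pdf.probs)
    if len(starts) < t_steps:
        log.info("kept %d of %d frames (window overruns signal end)",
                 len(starts), t_steps)
    H_g = np.column_stack(hs)
    P_g = np.column_stack(ps)
    mean_probs = P_g.mean(axis=1)
    mean_probs = mean_probs / mean_probs.sum()
    mean_pdf = sieve_mod.PitchPDF(pipe.sieve.grid, mean_probs)
    est = sieve_mod.estimate_pitch(mean_pdf)
    result = FramedResult(H_g=H_g, P_g=P_g, mean_pdf=mean_pdf,
                          f_hat=est.f_hat, note=note_name(est.f_hat),
                          frame_starts=np.asarray(starts))
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        pd.DataFrame({"grid_hz": mean_pdf.grid, "prob": mean_pdf.probs}).to_csv(
            out / "note_pdf.csv", index=False)
        (out / "note_summary.json").write_text(json.dumps(
            {"f_hat": result.f_hat, "note": result.note,
             "n_frames": len(starts)}, indent=2))
    return result
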