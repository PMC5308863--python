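"""Resolved vs unresolved harmonics: same pitch, declining salience.

Five complexes of four consecutive harmonics of 433 Hz, starting at harmonic
1, 6, 10, 17 and 22. All read out at 433 Hz within the +-0.5-octave interval,
but the pitch salience (ratio of the two tallest pdf peaks in that octave)
declines as the harmonics move into unresolved cochlear territory.

Uses the full 1000-atom dictionary; expect ~1 minute on first run.
"""

from sparsepitch import run_resolved_unresolved

df = run_resolved_unresolved(f0=433.0)
print(df.to_string(index=False))
# f_hat is the global pdf argmax (for high r it sits at the spectral locus,
# the alternative percept); f_hat_octave applies the psychoacoustic
# one-octave readout convention and recovers 433 Hz for every r.
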