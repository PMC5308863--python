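"""Transposed tones: low-frequency timing at high-frequency places carries no pitch.

Pairs pure tones with transposed tones (half-wave rectified modulator,
low-pass filtered, carried at 4/6.35/10.08 kHz) over a grid of modulation
frequencies and scores octave-folded hits within 2% of f0.
"""

import numpy as np

from sparsepitch import run_transposed_tones

df, summary = run_transposed_tones(f0_values=np.linspace(100, 500, 25))
print(df.groupby("stimulus_type")["hit"].mean().to_string())
print(f"\npure-tone hit rate:       {summary['pure_hit_rate']:.2f}")
print(f"transposed-tone hit rate: {summary['transposed_hit_rate']:.2f}")
# Pure tones are estimated almost perfectly; transposed tones are near
# chance. The dictionary's atoms bind temporal patterns to cochlear places,
# so temporal f0 cues presented at the wrong place do not map to a pitch --
# matching human listeners.
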