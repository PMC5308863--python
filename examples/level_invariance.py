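"""Level invariance: sparse coding keeps the pitch stable from 30 to 90 dB SPL.

Runs the same missing-fundamental complex at a quiet and a loud level (the
loud one through the saturating periphery) with both the sparse (lambda=0.01)
and the least-squares (lambda=0) decomposition.  The peak-to-median ratio
summarises how peaked each pitch density is.
"""

from sparsepitch import run_level_invariance

df = run_level_invariance(f0=225.0, levels=(30.0, 90.0))
print(df.to_string(index=False))
# The SC estimate is identical at both levels. At 90 dB the least-squares
# pdf is flatter (lower peak/median) than the sparse one: without the
# sparseness penalty the level-dependent distortions of the auditory-nerve
# response leak into the pitch readout.
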