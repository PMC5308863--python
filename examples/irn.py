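"""Iterated rippled noise: delay-and-add noise is heard at 1/delay.

Generates seeded IRN stimuli (delay 5 ms, gain +1) for increasing iteration
counts and reads the pitch within one octave of 1/d = 200 Hz through a
phase-grouped dictionary (4 phases per atom frequency).
"""

from sparsepitch import run_irn

df, summary = run_irn(delays=(0.005,), gains=(1,), n_itrs=(1, 10),
                      n_seeds=10, seed=0)
for cond, grp in df.groupby("n_itr"):
    print(f"n_itr={cond}: estimates {sorted(round(f, 1) for f in grp.f_hat)}")
print(summary)
# With 10 delay-add iterations the estimates concentrate tightly on 200 Hz;
# with a single iteration the spectral ripple is shallower and the
# estimates scatter more around the mode.
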