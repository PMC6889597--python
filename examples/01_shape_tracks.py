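"""Predict a per-base propeller-twist track from sequence.

Builds a small random sequence, slides the bundled pentamer table along it,
and prints the first defined values.  ProT is in degrees; more negative
values correspond to AT-rich contexts.
"""

import numpy as np

import protscape as ps

table = ps.load_reference_table()
rng = np.random.default_rng(1)
seq = ps.random_sequence(60, rng)
track = ps.predict_shape(seq, table)

print(f"sequence ({len(seq)} bp): {seq}")
print(f"defined positions: {track.n_defined}/{len(track)} "
      "(two bases at each end have no centred pentamer)")
print("first five defined ProT values (deg):",
      np.round(track.values[2:7], 2))
print("mean ProT (deg):", round(float(np.nanmean(track.values)), 3))
print("A more negative mean indicates a more AT-rich, strongly propeller-twisted duplex.")
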