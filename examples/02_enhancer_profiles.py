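"""Meta-profile of ProT around synthetic enhancer centres.

Generates an annotated genome whose positive regions carry two elevated-ProT
flanks mirrored about the region centre (the hallmark shape of ProT profiles
at active-enhancer peaks), then prints where the profile peaks.
"""

import numpy as np

import protscape as ps

table = ps.load_reference_table()
genome = ps.gen_enhancer_genome(ps.GeneratorConfig(seed=5), table)
tracks = ps.predict_tracks(genome.sequences, table)

prof = ps.center_profile(tracks, genome.positives, window=1001)
mean = prof.mean_profile()
off = prof.offsets
sm = np.convolve(mean, np.ones(25) / 25, mode="valid")
off_sm = off[12:-12]

left = off_sm[np.argmax(np.where(off_sm < 0, sm, -np.inf))]
right = off_sm[np.argmax(np.where(off_sm > 0, sm, -np.inf))]
print(f"{len(genome.positives)} enhancer regions, window +/-500 bp")
print(f"smoothed mean-ProT peaks at {left:+d} bp and {right:+d} bp from centre")
print("expected at +/-250 bp (the generator's flank offset); the two peaks are")
print("mirrored about the centre, as in ProT meta-profiles over enhancer peaks.")

pos_mean = np.nanmean(ps.aggregate_intervals(tracks, genome.positives, "mean"))
neg_mean = np.nanmean(ps.aggregate_intervals(tracks, genome.negatives, "mean"))
print(f"centre-window mean ProT: enhancers {pos_mean:.3f} deg "
      f"vs matched random {neg_mean:.3f} deg")
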