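"""Classify enhancers vs random loci from 2000-bp ProT profiles.

Trains a 9-model linear-SVM ensemble on single-nucleotide ProT windows from
a synthetic enhancer genome, and contrasts it with a zero-effect genome
where the classifier should sit at chance.
"""

import protscape as ps

table = ps.load_reference_table()

for effect in (1.0, 0.0):
    cfg = ps.GeneratorConfig(seed=5 if effect else 6, prot_effect_size=effect)
    genome = ps.gen_enhancer_genome(cfg, table)
    tracks = ps.predict_tracks(genome.sequences, table)
    result = ps.train_ensemble(
        ps.featurize(tracks, genome.positives, window=2000),
        ps.featurize(tracks, genome.negatives, window=2000),
        n_models=9, seed=0,
    )
    print(f"effect size {effect:.1f}: mAUC = {result.mauc:.3f} over "
          f"{result.n_models} models "
          f"(per-model {', '.join(f'{a:.2f}' for a in result.aucs)})")

print("mAUC near 1 with real profile structure, near 0.5 without: the ensemble")
print("reads the ProT flank peaks, not sample-size artefacts.")
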