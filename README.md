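# protscape

DNA shape tracks, regulatory-region profiling, and worm-like-chain
statistics for AFM contours.

## The problem

The propeller twist (ProT) of a base pair — the angle by which the two
paired bases rotate out of plane about their long axis — is a sequence-
determined biophysical feature of the double helix. Regions of high ProT
are more flexible and surface-accessible, and this biophysical state tracks
regulatory potential: ProT meta-profiles show characteristic twin peaks
around enhancer centres, 2-kb single-nucleotide ProT profiles suffice to
classify enhancers against random loci with a linear SVM, and mutation
density per kilobase is monotonically coupled to local ProT. At the single-
molecule level, AFM contours of DNA behave as a two-dimensional worm-like
chain (WLC): the mean-squared distance between contour points separated by
arc length *s* follows

    ⟨R²(s)⟩ = 4Ps · [1 − (2P/s)(1 − e^(−s/2P))]

with persistence length *P* ≈ 55 nm, while the bend-angle histogram at
5-nm separation yields an effective bending energy E(θ) = −ln p(θ) that is
harmonic, E(θ) = (P/2l)·θ², up to θ ≈ 1 rad and drops below the elastic
parabola beyond it (rare kinks).

`protscape` packages this whole analysis chain for people who want to run
it on their own sequences, interval sets and traced contours — or on fully
synthetic data with controlled ground truth:

- **shape**: pentamer sliding-window shape tracks (ProT/MGW/HelT/Roll) from
  FASTA, with RC-symmetric table handling and bedGraph/wiggle round-trips;
- **regions**: meta-profiles around interval midpoints, quantile grouping,
  track–track Pearson correlation, interval overlap classes, and
  mutation-density classes in 1-kb bins;
- **polymer**: 2D WLC simulation (with optional kinks), persistence-length
  fitting, bend-angle energy landscapes, large-bend fractions with
  √n/N counting errors, and the pooled two-proportion z-test;
- **classify**: linear-SVM ensembles on 2000-bp single-nucleotide ProT
  vectors, reported as per-model AUC and mAUC;
- **synth**: generators for all of the above (fixture tables,
  quantile-targeted sequences, enhancer genomes, coupled mutation
  catalogs).

The bundled pentamer table is **synthetic** (correct symmetry and AT/GC
trend, not published values); the engine is table-agnostic, so drop in any
`pentamer<TAB>value` TSV.

## Worked example

```python
import protscape as ps
from protscape.polymer import FractionResult

traces = ps.simulate_wlc_2d(persistence_length=55.0, contour_length=340.0,
                            spacing=2.5, n_molecules=600, seed=55)
curve = ps.msd_persistence(traces, max_separation=100.0)
sample = ps.bend_angles(traces, separation=5.0)
slope, _ = ps.energy_landscape(sample, p_ref=55.0).fit_quadratic(theta_max=1.0)
res = ps.compare_fractions(FractionResult(0.8, 182, 56874),
                           FractionResult(0.8, 157, 30294))
```

Running `python examples/03_afm_wlc.py` (which does exactly this) prints:

```
600 molecules, contour 340 nm
fitted persistence length P = 53.7 nm (generated at 55 nm; fit R^2 = 1.00000)
80400 bend angles at 5 nm separation
energy-landscape quadratic slope = 5.50 kT/rad^2 (elastic prediction P/2l = 5.50)
fraction of bends > 0.8 rad: 8.07e-03 +/- 3.2e-04
published AFM counts (control 182/56874 vs high-ProT 157/30294):
  two-proportion z = -4.48, two-sided p = 7.5e-06
```

Reading this: the mean-squared-separation fit recovers the generating
persistence length (53.7 nm vs 55 nm, within sampling error); the
−ln-histogram of bend angles is quadratic with exactly the elastic slope
P/2l = 5.5 kT/rad²; and on the published AFM large-bend counts the
two-proportion test reproduces p ≈ 7.5×10⁻⁶ — high-ProT molecules kink
significantly more often than controls.

The other example scripts each exercise one capability and say what their
numbers mean:

- `examples/01_shape_tracks.py` — per-base ProT from sequence;
- `examples/02_enhancer_profiles.py` — mirrored ±250-bp ProT peaks around
  synthetic enhancer centres;
- `examples/04_svm_classifier.py` — mAUC ≈ 1.0 with profile structure,
  ≈ 0.5 at zero effect;
- `examples/05_mutation_density.py` — eight mutation-density classes with
  strictly monotone class-median ProT, recovering the coupling sign.

A thin CLI mirrors the library (`protscape shape|profile|mutdensity|afm|
classify|simulate|compare-fractions`, see `--help`).

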