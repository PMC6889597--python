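# Methods

This note documents the models implemented in `protscape`, the defaults and
why they were chosen, what the synthetic generators do and do not emulate,
and the numerical conventions that matter for reproducing results.

## Pentamer shape model

Shape features are predicted by table lookup on the 5-mer centred at each
base: position *i* of a length-*L* sequence (0-based) gets the table value
of `seq[i-2 : i+3]` for 2 ≤ i ≤ L−3. The two bases at each end, and any
base whose pentamer covers a non-ACGT symbol or an absent table entry, are
*missing* — encoded as NaN, never 0, since 0 is a legal shape value.

ProT and MGW are base-pair features and are strand-symmetric:
`value(p) == value(reverse_complement(p))`. For the step features HelT and
Roll we adopt the convention that a pentamer's table value is the mean of
its two central base-pair-step values (the steps flanking the centre
base). Because those two steps map onto each other under strand reversal
and HelT/Roll are themselves strand-symmetric step parameters, this mean
is also RC-symmetric, so `load_shape_table` closes *every* feature's table
under reverse complementation and rejects conflicting RC pairs. No
smoothing is applied to tracks.

The bundled table `data/prot_pentamers_synthetic.tsv` is a generated
asset (`gen_fixture_table`, seed 2026): values follow
`−3 − 2·n_AT + N(0, 0.8)` degrees with RC symmetry by construction. It
reproduces the qualitative property that AT-rich pentamers carry more
negative ProT, but not the numerical values of any published predictor;
analyses that need a published table should pass their own TSV.

Coordinates are 0-based half-open everywhere; bedGraph output follows the
standard (runs of equal defined values merged, missing positions omitted),
wiggle output is 1-based `variableStep`. The track header records feature
and sequence length so round-trips are exact to the printed precision
(`%.6g`).

## Region profiling

The midpoint of `[start, end)` is `floor((start+end)/2)` — deterministic
for even lengths and consistent with half-open arithmetic. Meta-profile
row *r*, column *j* holds the track value at
`midpoint(r) − (window−1)//2 + j`; minus-strand rows are reversed so all
rows read 5′→3′. Out-of-bounds and undefined positions stay NaN and are
ignored by the per-position summaries. The default window, ±1000 bp,
mirrors the 2000-bp classifier window.

Quantile grouping is rank-based with stable tie-breaking (not value-bin
edges), so group sizes always differ by at most one even under heavy
ties; with all-equal input the boundaries are degenerate but the balance
invariant still holds. Group contrasts use two-sided Mann–Whitney tests
with Benjamini–Hochberg adjustment across the contrasts — a conventional
choice for ordered violin/boxplot comparisons.

Track–track correlation excludes positions missing in either track,
averages the survivors in fixed-width bins, and computes Pearson r on the
bins (≥ 3 required). Interval overlap classes call an interval of either
set "shared" iff it overlaps ≥ 1 bp of the other set, so each input set is
partitioned exactly.

Mutation-density analysis tiles each sequence with fixed bins (1 kb
default; the final partial bin is truncated at the sequence end), counts
catalog positions per bin, ranks bins into *n* (default 8) balanced
classes, and summarises each class by its bin-level mean-ProT
distribution.

## Worm-like-chain statistics

Traces are planar (surface-equilibrated convention): one bending degree of
freedom, tangent-angle increments over contour length *a* distributed
N(0, a/P), tangent correlation decaying as exp(−s/2P), and

    ⟨R²(s)⟩ = 4Ps·[1 − (2P/s)(1 − exp(−s/2P))].

`simulate_wlc_2d` is the discrete version of exactly this model, so the
generator's closed forms double as oracles: joint-angle variance is
`spacing/P` and the bend-angle second moment at separation *l* is `l/P`.
The simulator draws its elastic backbone and its kinks from separate RNG
substreams, so two conditions simulated under one seed share identical
backbones — paired comparisons (kinked vs kink-free) then isolate the kink
effect from sampling noise.

**Bend angles** at separation *l* are the unsigned angles between chain
*tangent* (segment) directions *k = l/spacing* segments apart, magnitudes
in [0, π] with no Jacobian correction. This convention is chosen over
secant-chord angles deliberately: for tangent pairs the pure-WLC variance
is exactly l/P and the elastic energy exactly (P/2l)·θ², whereas angles
between averaging chords of length *l* have variance
(2k²+1)/(3k²) · l/P (= 0.75 l/P at k = 2), which would silently bias every
elastic-slope comparison. A trace with *n* points yields n−1−k angles.

**Persistence length** is fitted by least squares of the closed form to
the pooled ⟨R²(s)⟩ over all point pairs at each lag, for s ≤ 100 nm by
default (configurable; the exact tracing spacing and fit range of AFM
pipelines vary). The fit's R² doubles as an equilibration diagnostic. The
discrete-chain expectation differs from the continuous form by < 1% at
2.5-nm spacing; fitting the exact discrete expectation recovers the
generating P to 0.1 nm, so the estimator is unbiased at these settings and
its seed-to-seed scatter is purely statistical (SD ≈ 1.2 nm at 600
molecules of 340 nm).

**Energy landscapes** use E_i = −ln(count_i) over occupied bins (0.05-rad
default width), shifted to min 0; empty bins are excluded, so −ln 0 never
occurs. The harmonic reference (P_ref/2l)·θ² is evaluated at the same bin
centres and shifted to the same minimum. The quadratic check fits E
against θ² for θ ≤ 1 rad — the elastic regime — weighted by bin counts
(approximately inverse-variance for a log-Poisson).

**Large-bend fractions** report n_large/n_total with the counting error
√n_large / n_total exactly. Conditions are compared with the pooled
two-proportion z-test, two-sided, no continuity correction; its squared
statistic equals the chi-square test on the 2×2 table, and on the
published AFM counts (182/56,874 vs 157/30,294) it reproduces the printed
p = 7.5×10⁻⁶. Fisher's exact test is kept in the test suite as an
independent small-count oracle, within a factor of two of the z-test where
both apply.

### Kinks and their limits

Kinks are modelled as rare extra joint angles of random sign with
exponential magnitude (probability `kink_prob` per joint, scale
`kink_scale`, default 0.8 rad — the magnitude regime where bends exceed
the elastic description). Two consequences follow in closed form and are
confirmed by simulation:

1. Because increments stay i.i.d., the chain's tangent correlation remains
   geometric with per-joint factor multiplied by
   `1 − kink_prob·(1 − E[cos m])`, `E[cos Exp(β)] = 1/(1+β²)`; the fitted
   P *is* this effective correlation length. At kink_prob 5×10⁻³ and
   spacing 2.5 nm, ΔP/P ≈ 0.22·(1 − 1/(1+β²)): the fit moves < 2% only for
   β ≲ 0.32 rad.
2. The added large-bend fraction at 0.8 rad is at most
   `[1−(1−kink_prob)^k] · sup_β P(|N(0, l/P) ± Exp(β)| > 0.8) ≈ 0.0078`
   at kink_prob 5×10⁻³ — just *below* the pure-WLC baseline
   2·Φ(−0.8/√(l/P)) = 0.0080 at P = 55 nm, l = 5 nm.

So under this generator the large-bend fraction can never double at
kink_prob 5×10⁻³, and simultaneously holding the fitted P within 2% caps
the achievable increase near 15%. The corresponding end-to-end check in
the test suite asserts the full conjunction and therefore fails; it is
kept as an honest record of this model limit rather than weakened. The
small-kink regime (scale ≈ 0.15 rad, kink_prob 10⁻²) does satisfy
"fraction strictly increases while fitted P moves < 1–2%" and is tested
green. Note that published AFM baselines (fraction ≈ 0.0032 at 0.8 rad)
sit *below* the pure-Gaussian WLC value — real tracing pipelines average
over chords, narrowing the angle distribution — which is precisely the
regime this generator, being exactly Gaussian in its elastic part, does
not emulate.

## Classifier

Features are the raw per-base ProT values in a 2000-bp window centred by
the region-profiler midpoint rule (even windows extend one base further
right of centre). Each of the *n* (default 9) models subsamples a balanced
set, draws an independent seeded 80/20 split, and fits
impute (per-position training mean) → standardise → linear SVM (C = 1);
AUC is computed on the disjoint held-out split and mAUC is the arithmetic
mean across models. A linear kernel is the deliberate choice for
2000-dimensional profiles: deterministic, interpretable weights, and no
hyper-parameter search. AUC equals the Mann–Whitney statistic over class
pairs with half credit for ties.

## Synthetic generators

All generators are deterministic under their seed and emit objects/files
the other modules consume unchanged.

- **Enhancer genomes** (defaults: 1.2-Mb chromosome, 150 positives + 150
  length-matched negatives of 1 kb on a shuffled non-overlapping slot
  grid): each positive carries two Gaussian-shaped (σ = 25 bp)
  composition-biased segments at ±250 bp from its midpoint. The local AT
  fraction is solved — through the exact pentamer-composition expectation
  of the supplied table — so the expected per-base shape value rises by
  `prot_effect_size` per-base SDs at each peak. Effect sizes are therefore
  capped near 2 SDs (the pure-composition limit); the default 1.0 gives a
  clearly visible, realistic twin-peak profile. What this does *not*
  emulate: real genome composition (isochores, repeats, CpG islands),
  TF-motif structure, or any epigenetic signal — a high mAUC here shows
  the pipeline reads profile shape, not that real enhancers are this easy.
- **Quantile-targeted sequences**: a Metropolis walk over single-base
  substitutions steers the per-sequence mean shape value to the midpoint
  of the normal quantile band [q, min(q+0.03, 0.9999)] of a seeded
  random-sequence null (one-sided high, so a 0.99 request lands clearly
  above an independent empirical 99th percentile), stopping within 0.15
  null-SD; it errors out, reporting the achieved value, if the band is
  unreachable.
- **Mutation catalogs**: per-bin Poisson counts with rate ∝ exp(b·z),
  z the standardised bin-mean ProT — the simplest monotone, sign-flippable
  coupling; positions are uniform within bins. b = +1 at 20,000 mutations
  over 2000 bins gives Spearman ρ > 0 at p ≪ 0.01 and strictly monotone
  class medians across 8 density classes.
- **Fixture tables**: see "Pentamer shape model" above.

## Problem sizes and numerical choices

Simulation-based checks use 600 molecules of 340-nm contour at 2.5-nm
spacing (≈ 80,000 bend angles; P-fit scatter ≈ 1.2 nm) and the
reproduction script uses 1200; classifier checks use the default 1.2-Mb /
150-region genomes; mutation checks use a 2-Mb genome with 20,000
mutations. These sizes keep every check statistically decisive while the
whole suite runs in well under a minute of compute per module.

Ties in quantile ranking are broken by stable input order; degenerate
inputs (all-equal values, all-missing intervals, empty bins, zero-count
proportions) are handled explicitly as documented above; curve fits are
bounded to P > 0 and non-convergence raises with diagnostics rather than
returning silently.

## Known limitations

- The bundled pentamer table is synthetic; absolute ProT values are not
  comparable to published predictors, only orderings and profiles are.
- 2D WLC only: no 3D chains, no force-extension, no excluded volume; the
  kink model's limits are described above.
- `gen_enhancer_genome` writes single-chromosome genomes; multi-chromosome
  inputs are supported everywhere downstream.
- The classifier makes no claim about real enhancer data: published AUCs
  on experimental enhancer sets depend on external assay data and are out
  of scope here.
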