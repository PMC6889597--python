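"""Synthetic inputs with controlled ground truth.

Every input the pipeline consumes can be generated here with a known
generative truth: a reverse-complement-symmetric pentamer ProT table with
the canonical AT/GC trend (AT-rich pentamers more negative), sequences
steered to a target ProT quantile, annotated "enhancer" genomes whose
positive regions carry two elevated-ProT flanks mirrored about the region
centre, and mutation catalogs whose per-kilobase density is exponentially
coupled to the local ProT level.  Polymer contours are generated by
:func:`protscape.polymer.simulate_wlc_2d`.

All generators are deterministic under their seed and emit objects (or
files) directly consumable by the other modules.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
from scipy import stats

from .regions import GenomicInterval, MutationCatalog, write_bed
from .seqio import write_fasta
from .shape import ShapeTable, ShapeTrack, all_pentamers, _POW4, _values_from_codes

__all__ = [
    "GeneratorConfig",
    "EnhancerGenome",
    "gen_fixture_table",
    "gen_sequence",
    "gen_enhancer_genome",
    "gen_mutation_catalog",
    "random_sequence",
    "table_composition_curve",
]

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass(frozen=True)
class GeneratorConfig:
    """Knobs of the synthetic study conditions (all deterministic under seed).

    seed               : master RNG seed.
    genome_length      : bp of the single synthetic chromosome.
    n_enhancers        : number of positive regions (equally many negatives).
    enhancer_length    : bp of each annotated region.
    flank_peak_offset  : bp from region centre to each elevated-ProT flank peak.
    flank_peak_width   : Gaussian sigma (bp) of each flank peak.
    prot_effect_size   : peak ProT elevation in units of the per-base ProT SD
                         of random sequence (composition bias caps this near 2).
    kink_prob          : per-joint kink probability for simulated contours.
    kink_scale         : exponential scale (rad) of kink magnitudes.
    """

    seed: int = 0
    genome_length: int = 1_200_000
    n_enhancers: int = 150
    enhancer_length: int = 1000
    flank_peak_offset: int = 250
    flank_peak_width: float = 25.0
    prot_effect_size: float = 1.0
    kink_prob: float = 0.0
    kink_scale: float = 0.8


def _decode(codes: np.ndarray) -> str:
    return _BASES[codes].tobytes().decode("ascii")


def random_sequence(length: int, rng: np.random.Generator) -> str:
    """Uniform-composition random sequence."""
    return _decode(rng.integers(0, 4, size=length))


# ---------------------------------------------------------------------------
# fixture table
# ---------------------------------------------------------------------------

def gen_fixture_table(seed: int = 0, feature: str = "ProT") -> ShapeTable:
    """Synthetic ProT-like pentamer table.

    Values follow ``-3 - 2 * n_AT + noise`` (degrees, noise sd 0.8), so
    AT-rich pentamers are more negative and GC-rich ones less negative —
    the qualitative trend of published propeller-twist tables — with
    reverse-complement symmetry enforced by construction (an RC pair shares
    its AT count and its noise draw).
    """
    rng = np.random.default_rng(seed)
    pentamers = all_pentamers()
    values = np.full(1024, np.nan)
    for i, pent in enumerate(pentamers):
        if np.isfinite(values[i]):
            continue  # already set via its reverse complement
        n_at = sum(b in "AT" for b in pent)
        val = -3.0 - 2.0 * n_at + rng.normal(0.0, 0.8)
        codes = np.array([{"A": 0, "C": 1, "G": 2, "T": 3}[b] for b in pent])
        rc_codes = 3 - codes[::-1]
        values[i] = val
        values[int(rc_codes @ _POW4)] = val
    return ShapeTable(feature=feature, values=values)


# ---------------------------------------------------------------------------
# composition calibration
# ---------------------------------------------------------------------------

def _at_counts() -> np.ndarray:
    pents = all_pentamers()
    return np.asarray([sum(b in "AT" for b in p) for p in pents], dtype=np.float64)


def table_composition_curve(
    table: ShapeTable, p_grid: np.ndarray | None = None
) -> tuple[np.ndarray, np.ndarray, float]:
    """Expected per-base shape value as a function of AT probability.

    For bases drawn iid with ``P(A) = P(T) = p/2``, the pentamer probability
    is ``(p/2)^n_AT ((1-p)/2)^(5-n_AT)``, so the expectation is an exact sum
    over the 1024 table entries.  Returns ``(p_grid, mean_curve, sigma)``
    where ``sigma`` is the per-base SD at uniform composition (p = 0.5),
    ignoring the short-range correlation of overlapping pentamers.
    """
    if p_grid is None:
        p_grid = np.linspace(0.02, 0.98, 97)
    v = table.values
    if not np.isfinite(v).all():
        raise ValueError("composition calibration needs a complete 1024-entry table")
    n_at = _at_counts()
    logw = (
        n_at[:, None] * np.log(p_grid[None, :] / 2.0)
        + (5.0 - n_at[:, None]) * np.log((1.0 - p_grid[None, :]) / 2.0)
    )
    w = np.exp(logw)  # columns sum to 1 exactly
    means = v @ w
    w_half = np.exp(n_at * np.log(0.25) + (5.0 - n_at) * np.log(0.25))
    mu = float(v @ w_half)
    sigma = float(np.sqrt((v - mu) ** 2 @ w_half))
    return p_grid, means, sigma


# ---------------------------------------------------------------------------
# quantile-targeted sequences (Metropolis over base flips)
# ---------------------------------------------------------------------------

def _mean_track(codes: np.ndarray, table: ShapeTable) -> np.ndarray:
    return _values_from_codes(codes.astype(np.int64), table)


def gen_sequence(
    length: int,
    target_prot_quantile: float,
    table: ShapeTable,
    seed: int = 0,
    n_null: int = 300,
    max_iter: int = 30000,
) -> str:
    """Sequence whose mean shape value sits in a requested quantile band of
    the random-sequence distribution.

    The null distribution of per-sequence mean shape is estimated from
    ``n_null`` seeded random sequences and summarised as a normal.  A
    Metropolis walk over single-base substitutions then steers the mean to
    the midpoint of the normal quantile band ``[q, min(q + 0.03, 0.9999)]``
    (one-sided high, so a q = 0.99 request lands clearly above an empirical
    99th percentile), stopping within 0.15 null-SD of that aim.
    """
    if length < 20:
        raise ValueError("sequence length must be >= 20")
    if not 0.0 < target_prot_quantile < 1.0:
        raise ValueError("target quantile must be in (0, 1)")
    rng = np.random.default_rng(seed)
    null = np.empty(n_null)
    for i in range(n_null):
        null[i] = np.nanmean(_mean_track(rng.integers(0, 4, size=length), table))
    mu, sd = float(null.mean()), float(null.std(ddof=1))
    q = min(max(target_prot_quantile, 1e-4), 0.999)
    z_lo = stats.norm.ppf(q)
    z_hi = stats.norm.ppf(min(q + 0.03, 0.9999))
    aim = mu + sd * 0.5 * (z_lo + z_hi)
    tol = 0.15 * sd
    temperature = 0.05 * sd

    codes = rng.integers(0, 4, size=length)
    vals = _mean_track(codes, table)
    total, count = np.nansum(vals), np.isfinite(vals).sum()
    mean = total / count
    for _ in range(max_iter):
        if abs(mean - aim) <= tol:
            return _decode(codes)
        pos = int(rng.integers(length))
        new = int(rng.integers(4))
        if new == codes[pos]:
            continue
        lo, hi = max(2, pos - 2), min(length - 2, pos + 3)
        old_base = codes[pos]
        old_vals = vals[lo:hi].copy()
        codes[pos] = new
        win = np.lib.stride_tricks.sliding_window_view(codes[lo - 2 : hi + 2], 5)
        new_vals = table.values[win @ _POW4]
        new_total = total - np.nansum(old_vals) + np.nansum(new_vals)
        new_count = count - np.isfinite(old_vals).sum() + np.isfinite(new_vals).sum()
        new_mean = new_total / new_count
        worse = abs(new_mean - aim) - abs(mean - aim)
        if worse <= 0 or rng.random() < np.exp(-worse / temperature):
            vals[lo:hi] = new_vals
            total, count, mean = new_total, new_count, new_mean
        else:
            codes[pos] = old_base
    raise ValueError(
        f"quantile {target_prot_quantile} unreachable in {max_iter} iterations: "
        f"achieved mean {mean:.4f}, aim {aim:.4f} (null {mu:.4f} +/- {sd:.4f})"
    )


# ---------------------------------------------------------------------------
# enhancer genomes
# ---------------------------------------------------------------------------

@dataclass
class EnhancerGenome:
    """Synthetic genome with annotated positive regions and matched negatives."""

    sequences: dict[str, str]
    positives: list[GenomicInterval]
    negatives: list[GenomicInterval]
    config: GeneratorConfig = field(default_factory=GeneratorConfig)

    def write(self, fasta_path, positives_bed, negatives_bed) -> None:
        write_fasta(self.sequences, fasta_path)
        write_bed(self.positives, positives_bed)
        write_bed(self.negatives, negatives_bed)


def gen_enhancer_genome(config: GeneratorConfig, table: ShapeTable) -> EnhancerGenome:
    """Genome whose positive regions carry two elevated-ProT flank peaks.

    Each positive region of length ``enhancer_length`` has Gaussian-shaped
    composition-biased segments centred ``flank_peak_offset`` bp either side
    of its midpoint: the local AT fraction is tuned (via the exact
    pentamer-composition expectation of the supplied table) so the expected
    per-base shape value rises by ``prot_effect_size`` per-base SDs at each
    peak.  Negatives are length-matched windows of untouched random sequence;
    regions are laid out on a shuffled slot grid so positives and negatives
    never overlap and 2-kb classifier windows stay disjoint.
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    span = 2 * (cfg.flank_peak_offset + int(4 * cfg.flank_peak_width)) + 1
    required = max(cfg.enhancer_length, span, 2100)
    slot = cfg.genome_length // (2 * cfg.n_enhancers)
    if slot < required:
        raise ValueError(
            f"genome_length {cfg.genome_length} too small for 2 x {cfg.n_enhancers} "
            f"slots of {required} bp"
        )
    p_grid, mean_curve, sigma = table_composition_curve(table)
    mu0 = float(np.interp(0.5, p_grid, mean_curve))
    d_peak = cfg.prot_effect_size * sigma
    # AT-rich pentamers may be more negative (usual) or more positive; map the
    # requested elevation through the monotone composition curve either way.
    increasing = mean_curve[-1] > mean_curve[0]
    if not increasing:
        p_grid_m, mean_m = p_grid[::-1], mean_curve[::-1]
    else:
        p_grid_m, mean_m = p_grid, mean_curve
    if mu0 + d_peak > mean_m[-1] + 1e-9:
        raise ValueError(
            f"prot_effect_size {cfg.prot_effect_size} unreachable by composition "
            f"bias (max ~{(mean_m[-1] - mu0) / sigma:.2f} per-base SDs)"
        )

    codes = rng.integers(0, 4, size=cfg.genome_length)
    order = rng.permutation(2 * cfg.n_enhancers)
    margin = (slot - required) // 2
    centers = []
    for s in order:
        jitter = int(rng.integers(-margin, margin + 1)) if margin > 0 else 0
        centers.append(s * slot + slot // 2 + jitter)
    pos_centers = centers[: cfg.n_enhancers]
    neg_centers = centers[cfg.n_enhancers :]

    reach = int(4 * cfg.flank_peak_width)
    for c in pos_centers:
        for side in (-1, 1):
            peak = c + side * cfg.flank_peak_offset
            j = np.arange(peak - reach, peak + reach + 1)
            d_j = d_peak * np.exp(-((j - peak) ** 2) / (2.0 * cfg.flank_peak_width**2))
            target_mean = np.minimum(mu0 + d_j, mean_m[-1])
            p_at = np.interp(target_mean, mean_m, p_grid_m)
            u = rng.random(len(j))
            # cumulative composition: A, T, C, G
            cum = np.column_stack([p_at / 2, p_at, p_at + (1 - p_at) / 2])
            drawn = (u[:, None] >= cum).sum(axis=1)
            codes[j] = np.array([0, 3, 1, 2])[drawn]

    half = cfg.enhancer_length // 2
    chrom = "chrS"

    def _iv(c: int, label: str) -> GenomicInterval:
        return GenomicInterval(chrom, c - half, c - half + cfg.enhancer_length, "+", None, label)

    return EnhancerGenome(
        sequences={chrom: _decode(codes)},
        positives=[_iv(c, "enhancer") for c in pos_centers],
        negatives=[_iv(c, "random") for c in neg_centers],
        config=cfg,
    )


# ---------------------------------------------------------------------------
# mutation catalogs
# ---------------------------------------------------------------------------

def gen_mutation_catalog(
    tracks: Mapping[str, ShapeTrack],
    n_mutations: int,
    coupling_slope: float,
    class_label: str = "random",
    seed: int = 0,
    bin: int = 1000,
) -> MutationCatalog:
    """Mutation catalog whose per-bin density follows ``exp(b * z)``.

    ``z`` is the standardised bin-level mean shape value; per-bin counts are
    Poisson with rates normalised so the expected total is ``n_mutations``.
    ``b > 0`` emulates the background ("random") mutation class enriched at
    high-ProT loci, ``b < 0`` the phenotype-associated class.
    """
    if n_mutations < 1:
        raise ValueError("n_mutations must be >= 1")
    rng = np.random.default_rng(seed)
    chrom_bins = []
    for name, track in tracks.items():
        L = len(track)
        n_bins = -(-L // bin)
        pad = n_bins * bin - L
        vals = np.concatenate([track.values, np.full(pad, np.nan)]) if pad else track.values
        import warnings as _warnings

        with _warnings.catch_warnings():
            _warnings.simplefilter("ignore", RuntimeWarning)
            prot = np.nanmean(vals.reshape(n_bins, bin), axis=1)
        chrom_bins.append((name, L, prot))
    all_prot = np.concatenate([p for _, _, p in chrom_bins])
    finite = np.isfinite(all_prot)
    if finite.sum() < 2:
        raise ValueError("tracks have too few defined bins")
    mu, sd = all_prot[finite].mean(), all_prot[finite].std()
    if sd == 0:
        sd = 1.0
    z = np.where(finite, (all_prot - mu) / sd, 0.0)
    weights = np.exp(coupling_slope * z)
    lam = n_mutations * weights / weights.sum()
    counts = rng.poisson(lam)
    records = []
    offset = 0
    for name, L, prot in chrom_bins:
        n_bins = len(prot)
        for b_idx in range(n_bins):
            c = counts[offset + b_idx]
            if c == 0:
                continue
            lo = b_idx * bin
            hi = min(lo + bin, L)
            for pos in rng.integers(lo, hi, size=c):
                records.append(GenomicInterval(name, int(pos), int(pos) + 1, ".", None, class_label))
        offset += n_bins
    if not records:
        raise ValueError("generator produced no mutations; increase n_mutations")
    return MutationCatalog(records=records)
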