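"""Aggregation of shape tracks over genomic intervals.

Meta-profiles around interval midpoints (the "density plot at peak centres"
view of a shape track), per-interval aggregates, balanced quantile grouping
of region scores, track-track correlation, interval-set overlap classes and
mutation-density binning.  Intervals are 0-based half-open throughout; the
midpoint of ``[start, end)`` is ``floor((start + end) / 2)``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from intervaltree import IntervalTree
from scipy import stats

from .shape import ShapeTrack

__all__ = [
    "GenomicInterval",
    "RegionProfile",
    "QuantileGrouping",
    "MutationCatalog",
    "OverlapClasses",
    "CorrelationResult",
    "MutationDensityResult",
    "read_bed",
    "write_bed",
    "midpoint",
    "center_profile",
    "aggregate_intervals",
    "quantile_groups",
    "correlate_tracks",
    "overlap_classes",
    "mutation_density_classes",
    "contrast_groups",
]


@dataclass(frozen=True)
class GenomicInterval:
    """0-based half-open genomic interval with optional strand/score/label."""

    chrom: str
    start: int
    end: int
    strand: str = "."
    score: float | None = None
    label: str | None = None

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(f"interval {self.chrom}:{self.start}-{self.end}: start must be < end")
        if self.strand not in ("+", "-", "."):
            raise ValueError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start


def midpoint(interval: GenomicInterval) -> int:
    """Deterministic midpoint, ``floor((start + end) / 2)``."""
    return (interval.start + interval.end) // 2


def read_bed(path) -> list[GenomicInterval]:
    """Read 3-6 column BED (name column stored as ``label``, col 5 as score)."""
    out: list[GenomicInterval] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            f = line.split("\t")
            if len(f) < 3:
                raise ValueError(f"{path}:{lineno}: BED needs >= 3 columns")
            label = f[3] if len(f) > 3 and f[3] != "." else None
            score = float(f[4]) if len(f) > 4 and f[4] != "." else None
            strand = f[5] if len(f) > 5 else "."
            out.append(GenomicInterval(f[0], int(f[1]), int(f[2]), strand, score, label))
    return out


def write_bed(intervals: Iterable[GenomicInterval], path) -> None:
    with open(path, "wt") as fh:
        for iv in intervals:
            score = "." if iv.score is None else f"{iv.score:g}"
            fh.write(
                f"{iv.chrom}\t{iv.start}\t{iv.end}\t{iv.label or '.'}\t{score}\t{iv.strand}\n"
            )


def _check_chroms(tracks: Mapping[str, ShapeTrack], intervals: Sequence[GenomicInterval]) -> None:
    unknown = sorted({iv.chrom for iv in intervals} - set(tracks))
    if unknown:
        raise ValueError(f"intervals on unknown sequences: {', '.join(unknown)}")


@dataclass
class RegionProfile:
    """Regions x positions matrix of shape values centred on interval midpoints.

    Row ``r``, column ``j`` holds the track value at
    ``midpoint(r) - (window-1)//2 + j`` on the plus strand; rows for
    minus-strand intervals are reversed so every row reads 5'->3'.
    Out-of-bounds or undefined positions are NaN.
    """

    window: int
    matrix: np.ndarray
    intervals: list[GenomicInterval] = field(default_factory=list)

    @property
    def offsets(self) -> np.ndarray:
        h = (self.window - 1) // 2
        return np.arange(self.window) - h

    def _summary(self, fn) -> np.ndarray:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN columns
            return fn(self.matrix, axis=0)

    def mean_profile(self) -> np.ndarray:
        return self._summary(np.nanmean)

    def median_profile(self) -> np.ndarray:
        return self._summary(np.nanmedian)

    def dispersion_profile(self) -> np.ndarray:
        return self._summary(np.nanstd)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.matrix, columns=self.offsets)


def center_profile(
    tracks: Mapping[str, ShapeTrack],
    intervals: Sequence[GenomicInterval],
    window: int = 2001,
) -> RegionProfile:
    """Collect track values in a fixed window around each interval midpoint."""
    if window % 2 != 1 or window < 1:
        raise ValueError(f"window must be a positive odd integer, got {window}")
    if not intervals:
        raise ValueError("no intervals supplied")
    _check_chroms(tracks, intervals)
    h = (window - 1) // 2
    matrix = np.full((len(intervals), window), np.nan)
    for r, iv in enumerate(intervals):
        vals = tracks[iv.chrom].values
        c = midpoint(iv)
        lo, hi = c - h, c + h + 1
        s, e = max(lo, 0), min(hi, len(vals))
        if s < e:
            matrix[r, s - lo : e - lo] = vals[s:e]
        if iv.strand == "-":
            matrix[r] = matrix[r, ::-1]
    return RegionProfile(window=window, matrix=matrix, intervals=list(intervals))


def aggregate_intervals(
    tracks: Mapping[str, ShapeTrack],
    intervals: Sequence[GenomicInterval],
    stat: str = "mean",
) -> np.ndarray:
    """Per-interval scalar aggregate over defined positions (NaN if none)."""
    if stat not in ("mean", "median"):
        raise ValueError(f"stat must be 'mean' or 'median', got {stat!r}")
    _check_chroms(tracks, intervals)
    fn = np.nanmean if stat == "mean" else np.nanmedian
    out = np.full(len(intervals), np.nan)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        for r, iv in enumerate(intervals):
            vals = tracks[iv.chrom].values[max(iv.start, 0) : iv.end]
            out[r] = fn(vals)
    return out


@dataclass
class QuantileGrouping:
    """Rank-based balanced grouping of a score vector.

    ``assignments[i]`` is the group index (0 = lowest scores) of input item
    ``i``; group sizes differ by at most one, ties broken by stable input
    order.  ``boundaries[k]`` is the smallest value assigned to group k+1
    (degenerate — possibly repeated — when the input carries heavy ties).
    """

    n_groups: int
    boundaries: np.ndarray
    assignments: np.ndarray

    @property
    def group_sizes(self) -> np.ndarray:
        return np.bincount(self.assignments, minlength=self.n_groups)

    def values_by_group(self, values: Sequence[float]) -> list[np.ndarray]:
        values = np.asarray(values, dtype=np.float64)
        return [values[self.assignments == k] for k in range(self.n_groups)]


def quantile_groups(values: Sequence[float], n_groups: int) -> QuantileGrouping:
    """Split values into ``n_groups`` balanced rank groups (0 = lowest)."""
    values = np.asarray(values, dtype=np.float64)
    if n_groups < 2:
        raise ValueError("n_groups must be >= 2")
    if not np.isfinite(values).all():
        raise ValueError("values must all be finite")
    n = len(values)
    if n < n_groups:
        raise ValueError(f"need at least {n_groups} values, got {n}")
    order = np.argsort(values, kind="stable")
    assignments = np.empty(n, dtype=np.int64)
    assignments[order] = np.arange(n) * n_groups // n
    sorted_vals = values[order]
    cuts = [-(-k * n // n_groups) for k in range(1, n_groups)]  # ceil(k*n/g)
    boundaries = sorted_vals[np.asarray(cuts)]
    return QuantileGrouping(n_groups=n_groups, boundaries=boundaries, assignments=assignments)


@dataclass(frozen=True)
class CorrelationResult:
    r: float
    pvalue: float
    n_bins: int


def correlate_tracks(
    track_a: ShapeTrack, track_b: ShapeTrack, bin: int = 1
) -> CorrelationResult:
    """Pearson correlation of two tracks on the same coordinate space.

    Positions missing in either track are excluded; remaining values are
    averaged within consecutive ``bin``-bp bins before correlating.
    """
    if len(track_a) != len(track_b):
        raise ValueError("tracks must cover the same coordinate space")
    if bin < 1:
        raise ValueError("bin must be >= 1")
    a = track_a.values.copy()
    b = track_b.values.copy()
    paired = np.isfinite(a) & np.isfinite(b)
    a[~paired] = np.nan
    b[~paired] = np.nan
    n_bins = -(-len(a) // bin)
    pad = n_bins * bin - len(a)
    if pad:
        a = np.concatenate([a, np.full(pad, np.nan)])
        b = np.concatenate([b, np.full(pad, np.nan)])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        a_bin = np.nanmean(a.reshape(n_bins, bin), axis=1)
        b_bin = np.nanmean(b.reshape(n_bins, bin), axis=1)
    ok = np.isfinite(a_bin) & np.isfinite(b_bin)
    if ok.sum() < 3:
        raise ValueError(f"only {int(ok.sum())} paired bins; need >= 3 to correlate")
    res = stats.pearsonr(a_bin[ok], b_bin[ok])
    return CorrelationResult(r=float(res.statistic), pvalue=float(res.pvalue), n_bins=int(ok.sum()))


@dataclass
class OverlapClasses:
    """Partition of two interval sets by >= 1 bp mutual overlap."""

    a_only: list[GenomicInterval]
    a_shared: list[GenomicInterval]
    b_shared: list[GenomicInterval]
    b_only: list[GenomicInterval]

    @property
    def shared(self) -> list[GenomicInterval]:
        return self.a_shared + self.b_shared


def _build_trees(intervals: Sequence[GenomicInterval]) -> dict[str, IntervalTree]:
    trees: dict[str, IntervalTree] = {}
    for iv in intervals:
        trees.setdefault(iv.chrom, IntervalTree()).addi(iv.start, iv.end)
    return trees


def overlap_classes(
    set_a: Sequence[GenomicInterval], set_b: Sequence[GenomicInterval]
) -> OverlapClasses:
    """Classify each interval of either set as set-specific or shared.

    An interval is shared iff it overlaps at least 1 bp of the other set, so
    ``len(a_only) + len(a_shared) == len(set_a)`` (and likewise for b).
    """
    trees_b = _build_trees(set_b)
    trees_a = _build_trees(set_a)
    a_only, a_shared, b_only, b_shared = [], [], [], []
    for iv in set_a:
        tree = trees_b.get(iv.chrom)
        (a_shared if tree is not None and tree.overlap(iv.start, iv.end) else a_only).append(iv)
    for iv in set_b:
        tree = trees_a.get(iv.chrom)
        (b_shared if tree is not None and tree.overlap(iv.start, iv.end) else b_only).append(iv)
    return OverlapClasses(a_only=a_only, a_shared=a_shared, b_shared=b_shared, b_only=b_only)


@dataclass
class MutationCatalog:
    """Width-1 mutation positions with a phenotype class per record.

    ``class_label`` is ``"phenotypic"`` (phenotype-associated mutations) or
    ``"random"`` (background mutations); it rides along in each record's
    ``label`` field.
    """

    records: list[GenomicInterval]

    def __post_init__(self) -> None:
        for iv in self.records:
            if len(iv) != 1:
                raise ValueError("mutation records must have width 1")

    def __len__(self) -> int:
        return len(self.records)

    def positions(self, chrom: str) -> np.ndarray:
        return np.asarray([iv.start for iv in self.records if iv.chrom == chrom], dtype=np.int64)


@dataclass
class MutationDensityResult:
    """Mutation counts per fixed-width bin, ranked into balanced density classes.

    ``class_prot[k]`` holds the bin-level mean-ProT values of density class k
    (0 = lowest mutation density); ``class_median`` is the per-class median of
    those values.
    """

    bin_size: int
    bin_chrom: np.ndarray
    bin_start: np.ndarray
    counts: np.ndarray
    prot: np.ndarray
    grouping: QuantileGrouping

    @property
    def n_classes(self) -> int:
        return self.grouping.n_groups

    @property
    def class_prot(self) -> list[np.ndarray]:
        out = self.grouping.values_by_group(self.prot)
        return [v[np.isfinite(v)] for v in out]

    @property
    def class_median(self) -> np.ndarray:
        return np.asarray([np.median(v) if len(v) else np.nan for v in self.class_prot])

    def contrasts(self) -> pd.DataFrame:
        finite = np.isfinite(self.prot)
        return contrast_groups(self.prot[finite], self.grouping.assignments[finite])


def mutation_density_classes(
    tracks: Mapping[str, ShapeTrack],
    catalog: MutationCatalog,
    bin: int = 1000,
    n_classes: int = 8,
) -> MutationDensityResult:
    """Bin the genome, rank bins by mutation count into balanced classes, and
    summarise the shape level of each class.

    The genome is tiled with ``bin``-bp bins per sequence (last bin truncated);
    bins are ranked by mutation count into ``n_classes`` balanced groups and
    each class is summarised by the distribution of its bin-level mean ProT.
    """
    if len(catalog) == 0:
        raise ValueError("no mutations in catalog")
    _check_chroms(tracks, catalog.records)
    chroms, starts, counts, prot = [], [], [], []
    for name, track in tracks.items():
        L = len(track)
        n_bins = -(-L // bin)
        pos = catalog.positions(name)
        if (pos >= L).any():
            raise ValueError(f"mutation beyond end of sequence {name}")
        c = np.bincount(pos // bin, minlength=n_bins)
        pad = n_bins * bin - L
        vals = np.concatenate([track.values, np.full(pad, np.nan)]) if pad else track.values
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            p = np.nanmean(vals.reshape(n_bins, bin), axis=1)
        chroms.append(np.full(n_bins, name, dtype=object))
        starts.append(np.arange(n_bins, dtype=np.int64) * bin)
        counts.append(c)
        prot.append(p)
    counts = np.concatenate(counts)
    grouping = quantile_groups(counts.astype(np.float64), n_classes)
    return MutationDensityResult(
        bin_size=bin,
        bin_chrom=np.concatenate(chroms),
        bin_start=np.concatenate(starts),
        counts=counts,
        prot=np.concatenate(prot),
        grouping=grouping,
    )


def contrast_groups(values: Sequence[float], assignments: Sequence[int]) -> pd.DataFrame:
    """Pairwise two-sided Mann-Whitney contrasts between groups, BH-adjusted.

    One row per group pair with the U statistic, raw p-value and
    Benjamini-Hochberg q-value across all contrasts.
    """
    values = np.asarray(values, dtype=np.float64)
    assignments = np.asarray(assignments, dtype=np.int64)
    groups = np.unique(assignments)
    rows = []
    for i, gi in enumerate(groups):
        for gj in groups[i + 1 :]:
            a, b = values[assignments == gi], values[assignments == gj]
            if len(a) == 0 or len(b) == 0:
                continue
            res = stats.mannwhitneyu(a, b, alternative="two-sided")
            rows.append((int(gi), int(gj), float(res.statistic), float(res.pvalue)))
    df = pd.DataFrame(rows, columns=["group_a", "group_b", "U", "pvalue"])
    if len(df):
        df["qvalue"] = stats.false_discovery_control(df["pvalue"], method="bh")
    else:
        df["qvalue"] = []
    return df
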