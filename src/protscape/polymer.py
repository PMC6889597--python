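"""Worm-like-chain statistics for surface-equilibrated DNA contours.

AFM imaging of DNA deposited on a surface yields planar molecule contours.
When deposition lets the molecule relax, the contour samples the thermal
ensemble of a two-dimensional worm-like chain (WLC): tangent-angle
increments over contour length ``a`` are Gaussian with variance ``a/P``,
where ``P`` is the bending persistence length, and the mean-squared
distance between two points separated by contour length ``s`` follows

    <R^2(s)> = 4 P s [1 - (2P/s) (1 - exp(-s / 2P))].

This module simulates such chains (optionally with rare kinks — large
localised bends beyond the elastic regime), estimates ``P`` from the
mean-squared-separation curve, extracts bend-angle samples at a fixed
contour separation, converts their histogram into an effective bending
energy ``E(theta) = -ln p(theta)`` (in units of kT), and compares
large-bend fractions between conditions with a two-proportion test.

Bend angles here are the unsigned angles between chain tangent (segment)
directions separated by contour length ``separation``; for the discrete
generator this makes the pure-WLC angle variance exactly
``separation / P`` and the elastic energy exactly
``(P / 2 separation) * theta^2``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

__all__ = [
    "PolymerTrace",
    "BendAngleSample",
    "MSDCurve",
    "EnergyLandscape",
    "FractionResult",
    "TwoProportionResult",
    "simulate_wlc_2d",
    "resample_contour",
    "msd_persistence",
    "wlc_msd",
    "bend_angles",
    "energy_landscape",
    "large_bend_fraction",
    "compare_fractions",
    "read_traces",
    "write_traces",
]


@dataclass
class PolymerTrace:
    """Ordered 2D contour coordinates (nm) of one traced molecule."""

    molecule_id: str
    points: np.ndarray
    spacing: float | None = None
    condition: str = "control"

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=np.float64)
        if self.points.ndim != 2 or self.points.shape[1] != 2:
            raise ValueError("points must be an (n, 2) array")
        if len(self.points) < 3:
            raise ValueError("a trace needs at least 3 points")

    @property
    def n_points(self) -> int:
        return len(self.points)

    @property
    def contour_length(self) -> float:
        return float(np.linalg.norm(np.diff(self.points, axis=0), axis=1).sum())

    @property
    def segment_lengths(self) -> np.ndarray:
        return np.linalg.norm(np.diff(self.points, axis=0), axis=1)


@dataclass
class BendAngleSample:
    """Unsigned bend-angle magnitudes at one contour separation.

    ``molecule_ids`` records, per angle, which molecule it came from.
    """

    separation: float
    angles: np.ndarray
    molecule_ids: np.ndarray
    condition: str = "control"

    def __post_init__(self) -> None:
        self.angles = np.asarray(self.angles, dtype=np.float64)
        self.molecule_ids = np.asarray(self.molecule_ids)
        if self.angles.shape != self.molecule_ids.shape:
            raise ValueError("angles and molecule_ids must align")
        if len(self.angles) and (self.angles.min() < 0 or self.angles.max() > np.pi + 1e-12):
            raise ValueError("bend angles must lie in [0, pi]")

    @property
    def n_angles(self) -> int:
        return len(self.angles)

    @property
    def n_molecules(self) -> int:
        return len(np.unique(self.molecule_ids))

    @classmethod
    def merge(cls, samples: Sequence["BendAngleSample"], condition: str = "pooled"):
        """Pool samples (e.g. different sequence preparations) into one."""
        seps = {s.separation for s in samples}
        if len(seps) != 1:
            raise ValueError(f"cannot merge samples at different separations: {sorted(seps)}")
        return cls(
            separation=samples[0].separation,
            angles=np.concatenate([s.angles for s in samples]),
            molecule_ids=np.concatenate(
                [
                    np.char.add(f"{s.condition}/", s.molecule_ids.astype(str))
                    for s in samples
                ]
            ),
            condition=condition,
        )


@dataclass
class MSDCurve:
    """Pooled mean-squared point separation versus contour distance, with the
    2D-WLC persistence-length fit."""

    separations: np.ndarray
    msd: np.ndarray
    n_pairs: np.ndarray
    persistence_length: float
    persistence_stderr: float
    fit_max_separation: float
    r_squared: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"s_nm": self.separations, "msd_nm2": self.msd, "n_pairs": self.n_pairs}
        )


@dataclass
class EnergyLandscape:
    """Effective bending energy E(theta) = -ln(histogram), shifted to min 0.

    ``reference_energy`` is the harmonic WLC expectation
    ``(P_ref / 2 l) theta^2`` evaluated at the occupied bin centres and
    shifted to the same minimum.
    """

    bin_centers: np.ndarray
    energy: np.ndarray
    counts: np.ndarray
    separation: float
    p_ref: float
    reference_energy: np.ndarray = field(default=None)

    def fit_quadratic(self, theta_max: float = 1.0) -> tuple[float, float]:
        """Weighted LS fit of E versus theta^2 for theta <= theta_max.

        Returns (slope, intercept); for a pure WLC the slope estimates
        P / (2 l).  Weights are bin counts (~inverse variance of -ln count).
        """
        sel = self.bin_centers <= theta_max
        if sel.sum() < 3:
            raise ValueError("too few occupied bins below theta_max for a quadratic fit")
        x = self.bin_centers[sel] ** 2
        w = self.counts[sel].astype(np.float64)
        coeffs = np.polynomial.polynomial.polyfit(x, self.energy[sel], 1, w=np.sqrt(w))
        return float(coeffs[1]), float(coeffs[0])


@dataclass(frozen=True)
class FractionResult:
    """Large-bend fraction with Poisson counting error sqrt(n)/total."""

    threshold: float
    n_large: int
    n_total: int

    def __post_init__(self) -> None:
        if not 0 <= self.n_large <= self.n_total:
            raise ValueError("need 0 <= n_large <= n_total")

    @property
    def fraction(self) -> float:
        return self.n_large / self.n_total

    @property
    def error(self) -> float:
        return float(np.sqrt(self.n_large) / self.n_total)


@dataclass(frozen=True)
class TwoProportionResult:
    z: float
    pvalue: float


# ---------------------------------------------------------------------------
# simulation
# ---------------------------------------------------------------------------

def simulate_wlc_2d(
    persistence_length: float,
    contour_length: float,
    spacing: float,
    n_molecules: int,
    seed: int | np.random.Generator = 0,
    kink_prob: float = 0.0,
    kink_scale: float = 0.0,
    condition: str = "control",
) -> list[PolymerTrace]:
    """Sample surface-equilibrated 2D worm-like chains.

    Successive tangent-angle increments are ``Normal(0, sqrt(spacing/P))``;
    with probability ``kink_prob`` per joint an extra angle of random sign
    and magnitude ``Exponential(kink_scale)`` is added, modelling localised
    bends beyond the elastic regime.  Reproducible under ``seed``.
    """
    if persistence_length <= 0 or contour_length <= 0 or spacing <= 0:
        raise ValueError("persistence_length, contour_length and spacing must be > 0")
    if n_molecules <= 0:
        raise ValueError("n_molecules must be > 0")
    if not 0 <= kink_prob <= 1:
        raise ValueError("kink_prob must be a probability")
    if kink_scale < 0:
        raise ValueError("kink_scale must be >= 0")
    # separate substreams for the elastic backbone and the kinks, so two
    # conditions simulated under one seed share identical backbones
    backbone_rng, kink_rng = np.random.default_rng(seed).spawn(2)
    n_steps = int(round(contour_length / spacing))
    if n_steps < 2:
        raise ValueError("contour_length must cover at least two spacings")
    sigma = np.sqrt(spacing / persistence_length)
    traces = []
    for m in range(n_molecules):
        increments = backbone_rng.normal(0.0, sigma, size=n_steps - 1)
        if kink_prob > 0 and kink_scale > 0:
            kinked = kink_rng.random(n_steps - 1) < kink_prob
            n_k = int(kinked.sum())
            if n_k:
                magnitudes = kink_rng.exponential(kink_scale, size=n_k)
                signs = kink_rng.choice((-1.0, 1.0), size=n_k)
                increments[kinked] += signs * magnitudes
        headings = np.concatenate(
            [[backbone_rng.uniform(0, 2 * np.pi)], increments]
        ).cumsum()
        steps = spacing * np.column_stack([np.cos(headings), np.sin(headings)])
        points = np.vstack([[0.0, 0.0], steps.cumsum(axis=0)])
        traces.append(
            PolymerTrace(
                molecule_id=f"mol{m:05d}",
                points=points,
                spacing=spacing,
                condition=condition,
            )
        )
    return traces


def resample_contour(trace: PolymerTrace, spacing: float = 2.5) -> PolymerTrace:
    """Resample a contour at fixed Euclidean point spacing.

    Walks along the polyline placing each next point exactly ``spacing`` nm
    (straight-line distance) from the previous one, on the polyline; this is
    the convention under which consecutive resampled points are chain
    segments of identical length.
    """
    if spacing <= 0:
        raise ValueError("spacing must be > 0")
    pts = trace.points
    if trace.contour_length < 2 * spacing:
        raise ValueError(
            f"trace {trace.molecule_id}: contour {trace.contour_length:.3g} nm "
            f"shorter than two spacings"
        )
    out = [pts[0]]
    seg = 0  # current polyline segment index
    t = 0.0  # parametric position within segment
    n_seg = len(pts) - 1
    while True:
        centre = out[-1]
        placed = False
        s, u = seg, t
        while s < n_seg:
            p0, p1 = pts[s], pts[s + 1]
            d = p1 - p0
            # solve |p0 + v d - centre| = spacing for v in (u, 1]
            a = d @ d
            if a == 0.0:
                s, u = s + 1, 0.0
                continue
            f = p0 - centre
            b = 2 * f @ d
            c = f @ f - spacing * spacing
            disc = b * b - 4 * a * c
            if disc >= 0:
                v = (-b + np.sqrt(disc)) / (2 * a)
                if u < v <= 1.0:
                    out.append(p0 + v * d)
                    seg, t = s, v
                    placed = True
                    break
            s, u = s + 1, 0.0
        if not placed:
            break
    if len(out) < 3:
        raise ValueError("resampling produced fewer than 3 points; spacing too large")
    return PolymerTrace(
        molecule_id=trace.molecule_id,
        points=np.asarray(out),
        spacing=spacing,
        condition=trace.condition,
    )


# ---------------------------------------------------------------------------
# persistence length from mean-squared separation
# ---------------------------------------------------------------------------

def wlc_msd(s, persistence_length):
    """Closed-form <R^2(s)> of an equilibrated 2D worm-like chain."""
    s = np.asarray(s, dtype=np.float64)
    p = persistence_length
    return 4.0 * p * s * (1.0 - (2.0 * p / s) * (1.0 - np.exp(-s / (2.0 * p))))


def msd_persistence(
    traces: Sequence[PolymerTrace],
    max_separation: float = 100.0,
    p0: float = 50.0,
) -> MSDCurve:
    """Fit the persistence length to the pooled mean-squared separation curve.

    ``<R^2(s)>`` is averaged over all point pairs at contour separation ``s``
    across molecules (traces must share one resampled spacing), then the 2D
    WLC closed form is least-squares fitted for ``s <= max_separation``.
    The fit's coefficient of determination doubles as an equilibration
    diagnostic: chains that did not equilibrate on the surface deviate from
    the closed form.
    """
    if not traces:
        raise ValueError("no traces supplied")
    spacings = {round(float(np.median(t.segment_lengths)), 6) for t in traces}
    if len(spacings) != 1:
        raise ValueError(f"traces have inconsistent spacings: {sorted(spacings)}")
    spacing = spacings.pop()
    max_lag = int(max_separation / spacing)
    max_lag = min(max_lag, max(t.n_points for t in traces) - 1)
    if max_lag < 3:
        raise ValueError("max_separation too small: fewer than 3 lags available")
    sums = np.zeros(max_lag)
    counts = np.zeros(max_lag, dtype=np.int64)
    for t in traces:
        pts = t.points
        for lag in range(1, min(max_lag, t.n_points - 1) + 1):
            d = pts[lag:] - pts[:-lag]
            sums[lag - 1] += np.einsum("ij,ij->", d, d)
            counts[lag - 1] += len(d)
    ok = counts > 0
    seps = (np.arange(1, max_lag + 1) * spacing)[ok]
    msd = sums[ok] / counts[ok]
    try:
        popt, pcov = optimize.curve_fit(
            wlc_msd, seps, msd, p0=[p0], bounds=(1e-6, np.inf), maxfev=10000
        )
    except RuntimeError as exc:
        raise ValueError(
            f"persistence-length fit failed to converge over s <= {max_separation} nm "
            f"({len(seps)} lags, {counts[ok].sum()} pairs): {exc}"
        ) from exc
    fitted = wlc_msd(seps, popt[0])
    ss_res = float(((msd - fitted) ** 2).sum())
    ss_tot = float(((msd - msd.mean()) ** 2).sum())
    return MSDCurve(
        separations=seps,
        msd=msd,
        n_pairs=counts[ok],
        persistence_length=float(popt[0]),
        persistence_stderr=float(np.sqrt(pcov[0, 0])),
        fit_max_separation=max_separation,
        r_squared=1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0,
    )


# ---------------------------------------------------------------------------
# bend angles and energy landscape
# ---------------------------------------------------------------------------

def bend_angles(traces: Sequence[PolymerTrace], separation: float = 5.0) -> BendAngleSample:
    """Unsigned bend angles between tangents separated by ``separation`` nm.

    For each molecule the tangent of segment ``i`` is compared with the
    tangent of segment ``i + k`` where ``k = separation / spacing`` (must be
    an integer multiple); the angle is the arccos of the normalised dot
    product, in [0, pi].  A trace with n points contributes ``n - 1 - k``
    angles.
    """
    if not traces:
        raise ValueError("no traces supplied")
    angles, ids = [], []
    condition = traces[0].condition
    for t in traces:
        spacing = t.spacing or float(np.median(t.segment_lengths))
        k = separation / spacing
        if abs(k - round(k)) > 1e-6:
            raise ValueError(
                f"separation {separation} nm is not an integer multiple of the "
                f"resampled spacing {spacing} nm (trace {t.molecule_id})"
            )
        k = int(round(k))
        if k < 1 or t.n_points - 1 - k < 1:
            continue
        tangents = np.diff(t.points, axis=0)
        a, b = tangents[:-k], tangents[k:]
        cosang = np.einsum("ij,ij->i", a, b) / (
            np.linalg.norm(a, axis=1) * np.linalg.norm(b, axis=1)
        )
        theta = np.arccos(np.clip(cosang, -1.0, 1.0))
        angles.append(theta)
        ids.append(np.full(len(theta), t.molecule_id, dtype=object))
    if not angles:
        raise ValueError("no trace long enough to yield a bend angle at this separation")
    return BendAngleSample(
        separation=separation,
        angles=np.concatenate(angles),
        molecule_ids=np.concatenate(ids),
        condition=condition,
    )


def energy_landscape(
    sample: BendAngleSample,
    bin_width: float = 0.05,
    p_ref: float = 55.0,
) -> EnergyLandscape:
    """Effective bending energy from the bend-angle histogram.

    ``E_i = -ln(count_i)`` over occupied bins, shifted so min(E) = 0; the
    harmonic WLC reference ``(P_ref / 2 l) theta^2`` is evaluated at the same
    bin centres and shifted to the same minimum (empty bins are excluded, so
    no ``-ln 0`` occurs).
    """
    if bin_width <= 0:
        raise ValueError("bin_width must be > 0")
    if sample.n_angles == 0:
        raise ValueError("empty bend-angle sample")
    edges = np.arange(0.0, np.pi + bin_width, bin_width)
    counts, _ = np.histogram(sample.angles, bins=edges)
    centers = 0.5 * (edges[:-1] + edges[1:])
    occupied = counts > 0
    energy = -np.log(counts[occupied].astype(np.float64))
    energy -= energy.min()
    ref = (p_ref / (2.0 * sample.separation)) * centers[occupied] ** 2
    ref -= ref.min()
    return EnergyLandscape(
        bin_centers=centers[occupied],
        energy=energy,
        counts=counts[occupied],
        separation=sample.separation,
        p_ref=p_ref,
        reference_energy=ref,
    )


def large_bend_fraction(sample: BendAngleSample, threshold: float) -> FractionResult:
    """Fraction of bend angles exceeding ``threshold`` rad, with counting error."""
    if threshold <= 0:
        raise ValueError("threshold must be > 0")
    if sample.n_angles == 0:
        raise ValueError("empty bend-angle sample")
    return FractionResult(
        threshold=threshold,
        n_large=int((sample.angles > threshold).sum()),
        n_total=sample.n_angles,
    )


def compare_fractions(a: FractionResult, b: FractionResult) -> TwoProportionResult:
    """Two-sided pooled two-proportion z-test (no continuity correction).

    Symmetric in its arguments; identical fractions give p = 1.  The squared
    statistic equals the chi-square test without continuity correction on the
    corresponding 2x2 table.
    """
    if a.n_total == 0 or b.n_total == 0:
        raise ValueError("both samples need a positive total count")
    p1, p2 = a.fraction, b.fraction
    pooled = (a.n_large + b.n_large) / (a.n_total + b.n_total)
    se = np.sqrt(pooled * (1.0 - pooled) * (1.0 / a.n_total + 1.0 / b.n_total))
    if se == 0.0:
        return TwoProportionResult(z=0.0, pvalue=1.0)
    z = (p1 - p2) / se
    return TwoProportionResult(z=float(z), pvalue=float(2.0 * stats.norm.sf(abs(z))))


# ---------------------------------------------------------------------------
# trace file format (TSV: molecule_id, x_nm, y_nm — one row per point)
# ---------------------------------------------------------------------------

def write_traces(traces: Sequence[PolymerTrace], path) -> None:
    frames = []
    for t in traces:
        frames.append(
            pd.DataFrame(
                {
                    "molecule_id": t.molecule_id,
                    "x_nm": t.points[:, 0],
                    "y_nm": t.points[:, 1],
                    "condition": t.condition,
                }
            )
        )
    pd.concat(frames, ignore_index=True).to_csv(path, sep="\t", index=False, float_format="%.6f")


def read_traces(path) -> list[PolymerTrace]:
    df = pd.read_csv(path, sep="\t")
    required = {"molecule_id", "x_nm", "y_nm"}
    if not required.issubset(df.columns):
        raise ValueError(f"{path}: trace TSV needs columns {sorted(required)}")
    traces = []
    for mol, grp in df.groupby("molecule_id", sort=False):
        condition = str(grp["condition"].iloc[0]) if "condition" in grp else "control"
        traces.append(
            PolymerTrace(
                molecule_id=str(mol),
                points=grp[["x_nm", "y_nm"]].to_numpy(),
                condition=condition,
            )
        )
    if not traces:
        raise ValueError(f"{path}: no molecules found")
    return traces
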