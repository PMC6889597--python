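"""Region profiler: meta-profiles, aggregates, quantile groups, overlaps."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

import protscape as ps
from protscape.regions import GenomicInterval


def _ramp_tracks(length=200, name="chrR"):
    return {name: ps.ShapeTrack(name, "ProT", np.arange(length, dtype=float))}


# ---------------------------------------------------------------------------
# center_profile
# ---------------------------------------------------------------------------

def test_profile_row_is_arithmetic_ramp():
    tracks = _ramp_tracks()
    iv = GenomicInterval("chrR", 90, 110)  # midpoint 100
    prof = ps.center_profile(tracks, [iv], window=11)
    np.testing.assert_array_equal(prof.matrix[0], np.arange(95, 106, dtype=float))


def test_profile_minus_strand_reads_reversed():
    tracks = _ramp_tracks()
    iv = GenomicInterval("chrR", 90, 110, strand="-")
    prof = ps.center_profile(tracks, [iv], window=11)
    np.testing.assert_array_equal(prof.matrix[0], np.arange(105, 94, -1, dtype=float))


def test_profile_at_sequence_edge_pads_with_missing():
    tracks = _ramp_tracks()
    prof = ps.center_profile(tracks, [GenomicInterval("chrR", 0, 4)], window=11)  # mid 2
    row = prof.matrix[0]
    assert np.isnan(row[:3]).all()
    np.testing.assert_array_equal(row[3:], np.arange(0, 8, dtype=float))


def test_profile_mean_matches_brute_force(ref_table):
    rng = np.random.default_rng(12)
    seq = ps.random_sequence(5000, rng)
    tracks = ps.predict_tracks({"chrR": seq}, ref_table)
    vals = tracks["chrR"].values
    intervals = [
        GenomicInterval("chrR", int(s), int(s) + int(w))
        for s, w in zip(rng.integers(0, 4800, 50), rng.integers(50, 200, 50))
    ]
    prof = ps.center_profile(tracks, intervals, window=101)
    # independent loop oracle
    expect = np.zeros(101)
    count = np.zeros(101)
    for iv in intervals:
        c = (iv.start + iv.end) // 2
        for j in range(101):
            p = c - 50 + j
            if 0 <= p < len(vals) and np.isfinite(vals[p]):
                expect[j] += vals[p]
                count[j] += 1
    np.testing.assert_allclose(prof.mean_profile(), expect / count, rtol=1e-12)


def test_profile_translation_equivariance(ref_table):
    rng = np.random.default_rng(13)
    seq = ps.random_sequence(800, rng)
    k = 37
    tracks_a = ps.predict_tracks({"c": seq}, ref_table)
    tracks_b = ps.predict_tracks({"c": "N" * k + seq}, ref_table)
    ivs_a = [GenomicInterval("c", 200, 300), GenomicInterval("c", 400, 451)]
    ivs_b = [GenomicInterval("c", iv.start + k, iv.end + k) for iv in ivs_a]
    pa = ps.center_profile(tracks_a, ivs_a, window=51).matrix
    pb = ps.center_profile(tracks_b, ivs_b, window=51).matrix
    np.testing.assert_array_equal(pa, pb)


def test_profile_unknown_sequence_lists_offenders():
    with pytest.raises(ValueError, match="chrZ"):
        ps.center_profile(_ramp_tracks(), [GenomicInterval("chrZ", 0, 10)], window=11)


def test_profile_requires_odd_window_and_intervals():
    tracks = _ramp_tracks()
    with pytest.raises(ValueError, match="odd"):
        ps.center_profile(tracks, [GenomicInterval("chrR", 0, 10)], window=10)
    with pytest.raises(ValueError, match="no intervals"):
        ps.center_profile(tracks, [], window=11)


# ---------------------------------------------------------------------------
# aggregates
# ---------------------------------------------------------------------------

def test_aggregate_constant_track_returns_constant():
    tracks = {"c": ps.ShapeTrack("c", "ProT", np.full(100, -7.5))}
    ivs = [GenomicInterval("c", 0, 10), GenomicInterval("c", 50, 99)]
    for stat in ("mean", "median"):
        np.testing.assert_allclose(ps.aggregate_intervals(tracks, ivs, stat), -7.5)


def test_aggregate_median_and_empty_interval():
    values = np.full(10, np.nan)
    values[2:5] = [1.0, 2.0, 100.0]
    tracks = {"c": ps.ShapeTrack("c", "ProT", values)}
    out = ps.aggregate_intervals(
        tracks, [GenomicInterval("c", 0, 10), GenomicInterval("c", 6, 9)], "median"
    )
    assert out[0] == 2.0
    assert np.isnan(out[1])  # no defined position -> missing


def test_aggregate_mean_matches_brute_force(ref_table):
    rng = np.random.default_rng(3)
    tracks = ps.predict_tracks({"c": ps.random_sequence(1000, rng)}, ref_table)
    ivs = [GenomicInterval("c", int(s), int(s) + 40) for s in rng.integers(0, 950, 20)]
    got = ps.aggregate_intervals(tracks, ivs, "mean")
    vals = tracks["c"].values
    for iv, g in zip(ivs, got):
        window = [v for v in vals[iv.start : iv.end] if np.isfinite(v)]
        assert g == pytest.approx(sum(window) / len(window), rel=1e-12)


# ---------------------------------------------------------------------------
# quantile groups
# ---------------------------------------------------------------------------

def test_quantile_groups_ranks_into_balanced_groups():
    grouping = ps.quantile_groups([5, 1, 7, 3, 8, 2, 6, 4], n_groups=4)
    np.testing.assert_array_equal(grouping.group_sizes, [2, 2, 2, 2])
    np.testing.assert_array_equal(grouping.assignments, [2, 0, 3, 1, 3, 0, 2, 1])


def test_quantile_groups_all_equal_stays_balanced():
    grouping = ps.quantile_groups([2.0] * 10, n_groups=4)
    assert grouping.group_sizes.max() - grouping.group_sizes.min() <= 1


def test_quantile_groups_means_strictly_increase():
    values = np.random.default_rng(7).uniform(size=1000)
    grouping = ps.quantile_groups(values, 4)
    means = [values[grouping.assignments == k].mean() for k in range(4)]
    assert all(a < b for a, b in zip(means, means[1:]))


def test_quantile_groups_validates_input():
    with pytest.raises(ValueError, match="finite"):
        ps.quantile_groups([1.0, np.nan, 2.0], 2)
    with pytest.raises(ValueError):
        ps.quantile_groups([1.0], 2)


@settings(derandomize=True, max_examples=30, deadline=None)
@given(
    st.lists(st.integers(min_value=-1000, max_value=1000), min_size=6, max_size=60, unique=True)
)
def test_quantile_groups_invariant_under_monotone_transform(values):
    base = ps.quantile_groups([float(v) for v in values], 3).assignments
    warped = ps.quantile_groups([np.arctan(v / 500.0) * 7 + 2 for v in values], 3).assignments
    np.testing.assert_array_equal(base, warped)


# ---------------------------------------------------------------------------
# track correlation
# ---------------------------------------------------------------------------

def test_correlation_of_track_with_itself_and_negation():
    rng = np.random.default_rng(5)
    vals = rng.normal(size=500)
    a = ps.ShapeTrack("c", "ProT", vals)
    b = ps.ShapeTrack("c", "ProT", -vals)
    assert ps.correlate_tracks(a, a).r == pytest.approx(1.0)
    assert ps.correlate_tracks(a, b).r == pytest.approx(-1.0)


def test_correlation_matches_direct_pearson_with_binning():
    rng = np.random.default_rng(6)
    latent = rng.normal(size=1000)
    va = latent + rng.normal(scale=0.5, size=1000)
    vb = latent + rng.normal(scale=0.5, size=1000)
    va[rng.random(1000) < 0.1] = np.nan
    vb[rng.random(1000) < 0.1] = np.nan
    res = ps.correlate_tracks(
        ps.ShapeTrack("c", "ProT", va), ps.ShapeTrack("c", "MGW", vb), bin=10
    )
    # brute-force recomputation of the binned Pearson r
    mask = np.isfinite(va) & np.isfinite(vb)
    xa, xb = np.where(mask, va, np.nan), np.where(mask, vb, np.nan)
    ba = np.nanmean(xa.reshape(100, 10), axis=1)
    bb = np.nanmean(xb.reshape(100, 10), axis=1)
    ok = np.isfinite(ba) & np.isfinite(bb)
    da, db = ba[ok] - ba[ok].mean(), bb[ok] - bb[ok].mean()
    expect = (da @ db) / np.sqrt((da @ da) * (db @ db))
    assert res.r == pytest.approx(expect, abs=1e-12)
    assert -1.0 <= res.r <= 1.0


def test_correlation_needs_three_bins():
    a = ps.ShapeTrack("c", "ProT", np.arange(10.0))
    with pytest.raises(ValueError, match="paired bins"):
        ps.correlate_tracks(a, a, bin=5)


# ---------------------------------------------------------------------------
# overlap classes
# ---------------------------------------------------------------------------

def _random_intervals(rng, n, chroms=("c1", "c2"), span=1000):
    out = []
    for _ in range(n):
        start = int(rng.integers(0, span))
        out.append(
            GenomicInterval(str(rng.choice(chroms)), start, start + int(rng.integers(1, 30)))
        )
    return out


def test_overlap_identical_and_disjoint_sets():
    ivs = [GenomicInterval("c", 0, 10), GenomicInterval("c", 20, 30)]
    res = ps.overlap_classes(ivs, ivs)
    assert not res.a_only and not res.b_only and len(res.a_shared) == 2
    far = [GenomicInterval("c", 100, 110)]
    res = ps.overlap_classes(ivs, far)
    assert len(res.a_only) == 2 and len(res.b_only) == 1 and not res.shared


def test_overlap_partition_matches_quadratic_brute_force():
    rng = np.random.default_rng(21)
    set_a = _random_intervals(rng, 60)
    set_b = _random_intervals(rng, 45)
    res = ps.overlap_classes(set_a, set_b)
    assert len(res.a_only) + len(res.a_shared) == len(set_a)
    assert len(res.b_only) + len(res.b_shared) == len(set_b)

    def hits(iv, others):
        return any(
            iv.chrom == o.chrom and iv.start < o.end and o.start < iv.end for o in others
        )

    for iv in set_a:
        assert (iv in res.a_shared) == hits(iv, set_b)
    for iv in set_b:
        assert (iv in res.b_shared) == hits(iv, set_a)


# ---------------------------------------------------------------------------
# mutation density classes
# ---------------------------------------------------------------------------

def test_uniform_catalog_gives_indistinguishable_classes(ref_table):
    rng = np.random.default_rng(30)
    tracks = ps.predict_tracks({"c": ps.random_sequence(500_000, rng)}, ref_table)
    catalog = ps.gen_mutation_catalog(tracks, 5000, 0.0, "random", seed=31)
    res = ps.mutation_density_classes(tracks, catalog, bin=1000, n_classes=8)
    stat = stats.kruskal(*res.class_prot)
    assert stat.pvalue > 1e-3  # no ProT/density coupling detectable
    assert res.grouping.group_sizes.max() - res.grouping.group_sizes.min() <= 1


def test_empty_catalog_rejected(ref_table):
    rng = np.random.default_rng(32)
    tracks = ps.predict_tracks({"c": ps.random_sequence(10_000, rng)}, ref_table)
    with pytest.raises(ValueError, match="no mutations"):
        ps.mutation_density_classes(tracks, ps.MutationCatalog(records=[]))


def test_contrast_groups_reports_bh_adjusted_pairs():
    rng = np.random.default_rng(33)
    values = np.concatenate([rng.normal(0, 1, 50), rng.normal(2, 1, 50)])
    assignments = np.repeat([0, 1], 50)
    df = ps.contrast_groups(values, assignments)
    assert len(df) == 1
    assert df["pvalue"].iloc[0] < 1e-6
    assert (df["qvalue"] >= df["pvalue"]).all()
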