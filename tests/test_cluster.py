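"""2D CCF histogram, smoothing-spline surface, peaks and assignment."""

import numpy as np
import pandas as pd
import pytest

from ccfevo import (
    CcfCluster,
    PipelineConfig,
    assign_mutations,
    build_histogram,
    cluster_pair,
    find_peaks,
    fit_surface,
)
from ccfevo.cluster import bin_centres, ccf_variance, merge_clusters, refine_clusters


def _pair(ccf1, ccf2, kind="shared", with_var=True, depth=120.0):
    df = pd.DataFrame({
        "ccf_1": np.asarray(ccf1, dtype=float),
        "ccf_2": np.asarray(ccf2, dtype=float),
        "kind": kind if isinstance(kind, str) else list(kind),
    }, index=[f"m{i}" for i in range(len(ccf1))])
    if with_var:
        df["var_1"] = ccf_variance(depth, np.clip(df["ccf_1"] * 0.42, 0.01, 0.95), 0.425)
        df["var_2"] = ccf_variance(depth, np.clip(df["ccf_2"] * 0.42, 0.01, 0.95), 0.425)
    return df


# ---- histogram -------------------------------------------------------------

def test_histogram_single_bin_and_conservation():
    grid = build_histogram(np.ones(100), np.ones(100))
    assert grid.sum() == 100
    assert (grid > 0).sum() == 1


def test_histogram_conserves_arbitrary_input():
    rng = np.random.default_rng(0)
    x, y = rng.uniform(0, 1.6, 500), rng.uniform(0, 1.6, 500)  # beyond range clipped in
    assert build_histogram(x, y).sum() == 500


def test_histogram_axis_accumulation_for_private_mutations():
    grid = build_histogram([0.0] * 10, [0.5] * 10)
    assert grid[0].sum() == 10


def test_histogram_rejects_empty_and_nonfinite():
    with pytest.raises(ValueError):
        build_histogram([], [])
    with pytest.raises(ValueError):
        build_histogram([np.nan], [0.5])


# ---- surface ---------------------------------------------------------------

def test_constant_grid_gives_constant_surface_no_spurious_peaks():
    surf = fit_surface(np.full((30, 30), 3.0))
    assert np.allclose(surf, 3.0, atol=1e-8)
    assert len(find_peaks(surf)) == 1  # argmax fallback only


def test_infinite_smoothing_flattens_to_trend_surface():
    rng = np.random.default_rng(2)
    grid = rng.poisson(3.0, size=(30, 30)).astype(float)
    surf = fit_surface(grid, smoothing=1e9)
    # all roughness is penalized away: only the smooth trend remains
    assert np.var(surf) < 0.05 * np.var(grid)
    assert len(find_peaks(surf)) <= 2  # at most corner extrema of the trend


def test_surface_input_validation():
    with pytest.raises(ValueError):
        fit_surface(np.ones((3, 3)))
    bad = np.ones((10, 10))
    bad[0, 0] = np.inf
    with pytest.raises(ValueError):
        fit_surface(bad)


def test_two_separated_clones_two_maxima_across_seeds():
    hits = 0
    for seed in range(20):
        rng = np.random.default_rng(seed)
        x = np.r_[rng.normal(1.0, 0.07, 200), rng.normal(0.4, 0.07, 100)]
        y = np.r_[rng.normal(1.0, 0.07, 200), rng.normal(0.45, 0.07, 100)]
        grid = build_histogram(np.clip(x, 0, 1.49), np.clip(y, 0, 1.49))
        peaks = find_peaks(fit_surface(grid), 0.05)
        hits += len(peaks) == 2
    assert hits >= 18


def test_peak_insensitive_to_poisson_jitter():
    """Surface maxima stay put when bin counts are re-jittered."""
    rng = np.random.default_rng(5)
    x = np.r_[rng.normal(1.0, 0.07, 300), rng.normal(0.4, 0.07, 150)]
    y = np.r_[rng.normal(1.0, 0.07, 300), rng.normal(0.4, 0.07, 150)]
    base = build_histogram(np.clip(x, 0, 1.49), np.clip(y, 0, 1.49))
    ref = sorted(find_peaks(fit_surface(base), 0.05))
    for seed in range(5):
        jig = np.random.default_rng(seed).poisson(np.maximum(base, 0.01))
        peaks = sorted(find_peaks(fit_surface(jig.astype(float)), 0.05))
        assert len(peaks) == len(ref)
        for (a, b), (c, d) in zip(peaks, ref):
            assert abs(a - c) <= 2 and abs(b - d) <= 2


# ---- assignment ------------------------------------------------------------

def test_tie_breaks_toward_larger_summed_ccf():
    centres = [CcfCluster("a", (1.0, 1.0), "shared"), CcfCluster("b", (0.5, 0.5), "shared")]
    muts = _pair([0.75] * 5, [0.75] * 5, with_var=False)
    clusters, assignment = assign_mutations(muts, centres, PipelineConfig(min_cluster=1))
    assert set(assignment) == {"a"}


def test_private_mutations_never_join_shared_clusters():
    centres = [CcfCluster("sh", (0.5, 0.5), "shared")]
    muts = _pair([0.5] * 6, [0.0] * 6, kind="private_s1", with_var=False)
    clusters, assignment = assign_mutations(muts, centres)
    # no private centre existed: a new axis centre is seeded at the median CCF
    kinds = {c.kind for c in clusters if c.size}
    assert kinds == {"private_s1"}
    assert clusters[-1].centre[1] == 0.0


def test_small_peaks_removed_and_counts_conserved():
    centres = [CcfCluster("a", (1.0, 1.0), "shared"), CcfCluster("b", (0.6, 0.6), "shared")]
    muts = _pair([1.0] * 20 + [0.62] * 3, [1.0] * 20 + [0.62] * 3, with_var=False)
    clusters, assignment = assign_mutations(muts, centres)
    assert len(clusters) == 1 and clusters[0].size == 23
    assert assignment.notna().all()


def test_orphan_private_below_minimum_excluded():
    centres = [CcfCluster("sh", (1.0, 1.0), "shared")]
    muts = pd.concat([
        _pair([1.0] * 10, [1.0] * 10, with_var=False),
        _pair([0.5] * 2, [0.0] * 2, kind="private_s1", with_var=False).rename(
            index=lambda s: s + "p"),
    ])
    clusters, assignment = assign_mutations(muts, centres)
    assert assignment.isna().sum() == 2


def test_cluster_pair_deterministic(class_e_bundle):
    from ccfevo import run_pair

    _gt, bundle = class_e_bundle
    r1 = run_pair(bundle, "S1", "S2")
    r2 = run_pair(bundle, "S1", "S2")
    assert [c.centre for c in r1.clusters] == [c.centre for c in r2.clusters]
    assert r1.assignment.equals(r2.assignment)


# ---- variance-aware refinement ---------------------------------------------

def test_refine_splits_merged_clones_and_spares_pure_ones():
    rng = np.random.default_rng(3)
    n1, n2 = 120, 80
    x = np.r_[rng.normal(1.0, 0.09, n1), rng.normal(0.7, 0.09, n2)]
    y = np.r_[rng.normal(1.0, 0.09, n1), rng.normal(0.72, 0.09, n2)]
    pair = _pair(np.clip(x, 0, 1.5), np.clip(y, 0, 1.5))
    merged = [CcfCluster("k", (0.9, 0.9), "shared", list(pair.index))]
    refined = refine_clusters(merged, pair, PipelineConfig())
    assert len(refined) == 2

    pure = pair.iloc[:n1]
    one = [CcfCluster("k", (1.0, 1.0), "shared", list(pure.index))]
    assert len(refine_clusters(one, pure, PipelineConfig())) == 1


def test_merge_rejoins_fragmented_clone():
    rng = np.random.default_rng(4)
    x = np.clip(rng.normal(1.0, 0.10, 150), 0, 1.5)
    y = np.clip(rng.normal(1.0, 0.10, 150), 0, 1.5)
    pair = _pair(x, y)
    halves = [
        CcfCluster("a", (0.93, 0.93), "shared", list(pair.index[x < 1.0])),
        CcfCluster("b", (1.07, 1.07), "shared", list(pair.index[x >= 1.0])),
    ]
    merged = merge_clusters(halves, pair, PipelineConfig())
    assert len(merged) == 1


# ---- recovery experiment (scaled-down unit version) ------------------------

def test_cluster_count_recovery_on_simulated_pairs(sim_conditions):
    from ccfevo import bundle_from_truth, emit_reads, run_pair, simulate_patient

    hits = 0
    for seed in range(15):
        gt = simulate_patient(3, 2, "C", seed=seed, sim=sim_conditions)
        reads = emit_reads(gt, mean_depth=120, sim=sim_conditions)
        res = run_pair(bundle_from_truth(gt, reads), "S1", "S2")
        hits += len(res.clusters) == 3
    assert hits >= 13
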