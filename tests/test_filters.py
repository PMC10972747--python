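"""Mutation filter battery: strand balance, power gates, LOH, trims, privacy."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ccfevo import (
    PipelineConfig,
    forward_reverse_score,
    low_af_power_gate,
    power_trim_mask,
    private_mutation_test,
    rescue_shared_lowaf,
    trim_quantile,
    unify_segmentation,
)
from ccfevo.filters import indel_proximity_fail, loh_conflict, positional_flags, strand_filter
from conftest import make_mutations


# ---- strand balance --------------------------------------------------------

@pytest.mark.parametrize("fwd,rev,score", [(5, 5, 1.0), (10, 0, 0.0), (8, 2, 0.4)])
def test_forward_reverse_score(fwd, rev, score):
    assert forward_reverse_score(fwd, rev) == pytest.approx(score)


def test_forward_reverse_score_undefined_without_alt_reads():
    assert np.isnan(forward_reverse_score(0, 0))


def test_strand_filter_applies_only_below_af_gate():
    # one-sided strand support fails at low AF but not at high AF
    assert strand_filter(0.1, 10, 0)
    assert not strand_filter(0.35, 10, 0)
    assert not strand_filter(0.1, 5, 5)


# ---- low-AF power gate -----------------------------------------------------

@pytest.mark.parametrize(
    "vaf,cov,fails",
    [(0.1, 50, True), (0.1, 200, False), (0.25, 10, False)],
)
def test_low_af_power_gate_threshold(vaf, cov, fails):
    assert low_af_power_gate(vaf, cov, cov, rc=10) == fails


def test_low_af_power_gate_uses_minimum_coverage():
    assert low_af_power_gate(0.1, 500, 50, rc=10)  # min coverage 50 decides


# ---- indel proximity -------------------------------------------------------

def test_indel_proximity_strict_window():
    rows = make_mutations(
        [
            ("snm_near", "S1", "chr1", 1005, 100, 30, 15),
            ("snm_edge", "S1", "chr1", 1010, 100, 30, 15),
            ("snm_far", "S1", "chr2", 1005, 100, 30, 15),
        ]
    )
    indel = make_mutations([("indel1", "S1", "chr1", 1000, 100, 20, 10)])
    indel["kind"] = "deletion"
    calls = pd.concat([rows, indel], ignore_index=True)
    fail = indel_proximity_fail(calls, window=10)
    by = dict(zip(calls["mutation_id"], fail))
    assert by["snm_near"] and not by["snm_edge"] and not by["snm_far"]
    assert not by["indel1"]  # indels themselves unaffected


def test_indel_proximity_all_pass_without_indels():
    rows = make_mutations([("a", "S1", "chr1", 1005, 100, 30, 15)])
    assert not indel_proximity_fail(rows).any()


# ---- positional flags ------------------------------------------------------

def test_positional_flags_tails_centromeres_mapq(config):
    L = 249_250_621
    rows = make_mutations(
        [
            ("tail", "S1", "chr1", int(0.01 * L), 100, 40, 20),
            ("mid", "S1", "chr1", int(0.5 * L) + 9_000_000, 100, 40, 20),
            ("cen", "S1", "chr1", 122_000_000, 100, 40, 20),
        ]
    ).set_index("mutation_id", drop=False)
    rows.loc["mid", "fraction_lowmapq"] = 0.12
    flags = positional_flags(rows, config=config)
    assert flags.loc["tail", "tail"]
    assert flags.loc["cen", "centromere"]
    assert flags.loc["mid", "lowmapq"] and not flags.loc["mid", "tail"]


def test_positional_flags_unknown_chromosome_named():
    rows = make_mutations([("a", "S1", "chrZ", 100, 100, 40, 20)])
    with pytest.raises(ValueError, match="chrZ"):
        positional_flags(rows)


# ---- unified segmentation --------------------------------------------------

def _segs(rows):
    return pd.DataFrame(
        [{"sample": s, "chrom": c, "start": a, "end": b, "major_cn": M, "minor_cn": m,
          "subclonal_cn": False} for s, c, a, b, M, m in rows]
    )


def test_unify_segmentation_breakpoint_union():
    segs = _segs([("S1", "chr1", 1, 100, 1, 1), ("S2", "chr1", 1, 50, 2, 1),
                  ("S2", "chr1", 51, 100, 1, 0)])
    uni = unify_segmentation(segs)
    spans = sorted(set(zip(uni["start"], uni["end"])))
    assert spans == [(1, 50), (51, 100)]
    s2 = uni[uni["sample"] == "S2"].sort_values("start")
    assert list(s2["minor_cn"]) == [1, 0]


def test_unify_segmentation_idempotent_on_identical_inputs():
    segs = _segs([("S1", "chr1", 1, 100, 1, 1), ("S2", "chr1", 1, 100, 1, 1)])
    uni = unify_segmentation(segs)
    assert sorted(set(zip(uni["start"], uni["end"]))) == [(1, 100)]


def test_unify_segmentation_rejects_overlaps():
    segs = _segs([("S1", "chr1", 1, 100, 1, 1), ("S1", "chr1", 90, 200, 2, 1),
                  ("S2", "chr1", 1, 200, 1, 1)])
    with pytest.raises(ValueError, match="overlap"):
        unify_segmentation(segs)


@settings(max_examples=25, derandomize=True)
@given(st.lists(st.integers(2, 99), min_size=1, max_size=6, unique=True))
def test_unify_segmentation_covers_every_base_once(breaks):
    # S1 one segment, S2 split at arbitrary breakpoints: union covers [1,100]
    bps = sorted(breaks)
    rows = [("S1", "chr1", 1, 100, 1, 1)]
    prev = 1
    for b in bps + [101]:
        rows.append(("S2", "chr1", prev, b - 1, 2, 1))
        prev = b
    uni = unify_segmentation(_segs(rows))
    per_sample = uni[uni["sample"] == "S1"].sort_values("start")
    covered = sum(e - s + 1 for s, e in zip(per_sample["start"], per_sample["end"]))
    assert covered == 100
    assert (per_sample["start"].to_numpy()[1:] > per_sample["end"].to_numpy()[:-1]).all()


# ---- LOH conflict ----------------------------------------------------------

def _loh_fixture(minor_s2, ccf_a, ccf_b, subclonal=False):
    uni = pd.DataFrame(
        [
            {"chrom": "chr1", "start": 1, "end": 1000, "sample": "S1",
             "major_cn": 1, "minor_cn": 1, "subclonal_cn": False},
            {"chrom": "chr1", "start": 1, "end": 1000, "sample": "S2",
             "major_cn": 1, "minor_cn": minor_s2, "subclonal_cn": subclonal},
        ]
    )
    pair = pd.DataFrame(
        {"chrom": ["chr1"], "pos": [500], "ccf_S1": [ccf_a], "ccf_S2": [ccf_b]},
        index=["m1"],
    )
    return pair, uni


def test_loh_conflict_excludes_private_to_non_loh_sample():
    pair, uni = _loh_fixture(minor_s2=0, ccf_a=0.9, ccf_b=0.0)
    assert loh_conflict(pair, uni).loc["m1"]


def test_loh_in_all_samples_is_retained():
    uni = pd.DataFrame(
        [
            {"chrom": "chr1", "start": 1, "end": 1000, "sample": s,
             "major_cn": 1, "minor_cn": 0, "subclonal_cn": False}
            for s in ("S1", "S2")
        ]
    )
    pair = pd.DataFrame({"chrom": ["chr1"], "pos": [500],
                         "ccf_S1": [0.9], "ccf_S2": [0.0]}, index=["m1"])
    assert not loh_conflict(pair, uni).loc["m1"]


def test_shared_mutation_without_loh_retained():
    pair, uni = _loh_fixture(minor_s2=1, ccf_a=0.8, ccf_b=0.7)
    assert not loh_conflict(pair, uni).loc["m1"]


def test_subclonal_cn_with_loh_clone_excluded_regardless_of_sharing():
    pair, uni = _loh_fixture(minor_s2=0, ccf_a=0.8, ccf_b=0.7, subclonal=True)
    assert loh_conflict(pair, uni).loc["m1"]


# ---- power trim ------------------------------------------------------------

def test_trim_quantile_matches_printed_z():
    assert round(trim_quantile(0.025), 2) == 1.96


def test_power_trim_degenerate_scores_trims_nothing():
    depth = pd.DataFrame({"S1": [100.0] * 20, "S2": [100.0] * 20})
    evaf = pd.DataFrame({"S1": [0.4] * 20, "S2": [0.4] * 20})
    assert not power_trim_mask(depth, evaf).any()


def test_power_trim_fraction_under_lognormal_model():
    rng = np.random.default_rng(7)
    score = np.exp(rng.normal(-3.0, 0.4, size=10_000))
    depth = pd.DataFrame({"S1": 1.0 / score})
    evaf = pd.DataFrame({"S1": np.ones(10_000)})
    frac = power_trim_mask(depth, evaf, z=1.96).mean()
    assert frac == pytest.approx(0.05, abs=0.01)


def test_power_trim_catches_depth_outlier():
    rng = np.random.default_rng(1)
    depths = rng.normal(120, 5, size=50)
    depths[0] = 5.0
    depth = pd.DataFrame({"S1": depths})
    evaf = pd.DataFrame({"S1": np.full(50, 0.425)})
    trimmed = power_trim_mask(depth, evaf)
    assert trimmed.iloc[0]
    assert trimmed.sum() <= 8  # the outlier plus at most the nominal tails


def test_power_trim_idempotent():
    rng = np.random.default_rng(11)
    score = np.exp(rng.normal(-3.0, 0.4, size=5000))
    depth = pd.DataFrame({"S1": 1.0 / score})
    evaf = pd.DataFrame({"S1": np.ones(5000)})
    first = power_trim_mask(depth, evaf)
    survivors = depth[~first]
    second = power_trim_mask(survivors, evaf[~first])
    assert second.mean() <= 0.025  # well under the nominal 5%: robust fit is near-stable


def test_power_trim_skips_small_samples_with_warning():
    depth = pd.DataFrame({"S1": [100.0] * 5})
    evaf = pd.DataFrame({"S1": [0.4] * 5})
    with pytest.warns(UserWarning, match="skipped"):
        assert not power_trim_mask(depth, evaf).any()


# ---- private-mutation test -------------------------------------------------

def test_private_test_closed_forms():
    res = private_mutation_test([0.5, 0.3], [1, 100])
    assert res.loc[0, "p_value"] == pytest.approx(0.5)
    assert res.loc[1, "p_value"] == pytest.approx(0.7**100, rel=1e-6)
    assert res.loc[1, "status"] == "truly_private"
    assert res.loc[0, "status"] == "excluded_ambiguous"


def test_private_test_zero_coverage_is_ambiguous():
    res = private_mutation_test([0.4], [0])
    assert res.loc[0, "status"] == "excluded_ambiguous"


def test_private_test_detection_threshold_k():
    # with k=3, two observed reads would still count as "not detected"
    res1 = private_mutation_test([0.1], [50], detection_k=1)
    res3 = private_mutation_test([0.1], [50], detection_k=3)
    assert res3.loc[0, "p_value"] > res1.loc[0, "p_value"]


# ---- rescue ----------------------------------------------------------------

def _rescue_fixture():
    calls = pd.DataFrame({"S1": [30, 0, 3], "S2": [3, 0, 0]},
                         index=["shared_lowaf", "absent", "only_weak"])
    stringent = pd.DataFrame({"S1": [True, False, False], "S2": [False, False, False]},
                             index=calls.index)
    return calls, stringent


def test_rescue_reintroduces_lowaf_calls_supported_elsewhere():
    calls, stringent = _rescue_fixture()
    present, provenance = rescue_shared_lowaf(calls, stringent)
    assert present.loc["shared_lowaf"].all()
    assert provenance.loc["shared_lowaf", "S2"] == "rescued"
    assert not present.loc["absent"].any()
    assert not present.loc["only_weak"].any()  # weak evidence nowhere stringent


def test_rescue_is_idempotent_and_never_removes():
    calls, stringent = _rescue_fixture()
    present1, _ = rescue_shared_lowaf(calls, stringent)
    present2, _ = rescue_shared_lowaf(calls, present1)
    assert (present2 >= present1).all().all()
    assert present2.equals(present1 | present1)
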