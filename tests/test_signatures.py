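"""SBS catalogue construction, NNLS refitting and selection rules."""

import numpy as np
import pandas as pd
import pytest

from ccfevo import (
    backward_select,
    build_catalogue,
    cohort_subset,
    eligibility,
    fit_exposures,
    radiation_ratios,
    synthetic_catalog,
)
from ccfevo.signatures import SBS96_CHANNELS, channel_of, sample_catalogue


def test_channel_of_pyrimidine_and_purine_folding():
    assert channel_of("ACA", "C", "A") == "A[C>A]A"
    # G>T at TGA folds onto the pyrimidine strand: reverse complement TCA, C>A
    assert channel_of("TGA", "G", "T") == "T[C>A]A"


def test_channel_of_rejects_mismatched_context():
    with pytest.raises(ValueError):
        channel_of("ACA", "G", "T")


def test_build_catalogue_conserves_and_skips_indels():
    mut = pd.DataFrame(
        [
            {"kind": "SNM", "trinucleotide": "ACA", "ref": "C", "alt": "A"},
            {"kind": "SNM", "trinucleotide": "TGA", "ref": "G", "alt": "T"},
            {"kind": "deletion", "trinucleotide": "", "ref": "AT", "alt": "A"},
        ]
    )
    counts, skipped = build_catalogue(mut)
    assert counts.sum() == 2 and skipped == 1
    assert counts["A[C>A]A"] == 1 and counts["T[C>A]A"] == 1


def test_synthetic_catalog_is_normalised_and_deterministic():
    cat1, cat2 = synthetic_catalog(), synthetic_catalog()
    assert list(cat1.index) == list(SBS96_CHANNELS)
    assert np.allclose(cat1.sum(axis=0), 1.0)
    assert cat1.equals(cat2)


def test_fit_exposures_exact_single_signature():
    cat = synthetic_catalog()
    catalogue = (300 * cat["SBS4"]).round().astype(int)
    fit = fit_exposures(catalogue, cat)
    assert fit.exposures["SBS4"] == pytest.approx(catalogue.sum(), rel=0.05)
    assert fit.exposures.drop("SBS4").sum() < 0.05 * catalogue.sum()
    assert (fit.exposures >= 0).all()
    assert fit.cost <= np.linalg.norm(catalogue)  # no worse than the zero fit


def test_fit_exposures_recovers_mixture_proportions():
    cat = synthetic_catalog()
    rng = np.random.default_rng(0)
    catalogue = sample_catalogue(cat, {"SBS4": 0.7, "SBS5": 0.3}, 2000, rng)
    rel = fit_exposures(catalogue, cat).relative
    assert rel["SBS4"] == pytest.approx(0.7, abs=0.05)
    assert rel["SBS5"] == pytest.approx(0.3, abs=0.05)


def test_fit_exposures_input_validation():
    cat = synthetic_catalog()
    empty = pd.Series(0, index=list(SBS96_CHANNELS))
    with pytest.raises(ValueError):
        fit_exposures(empty, cat)
    with pytest.raises(ValueError):
        fit_exposures(empty + 1, cat[[]])


def test_backward_select_keeps_cost_within_budget_and_true_signatures():
    cat = synthetic_catalog()
    rng = np.random.default_rng(1)
    hits = 0
    for seed in range(10):
        rng = np.random.default_rng(seed)
        catalogue = sample_catalogue(cat, {"SBS2": 0.6, "SBS24": 0.4}, 1000, rng)
        full = fit_exposures(catalogue, cat)
        sel = backward_select(catalogue, cat, cost_threshold=0.02)
        assert sel.cost <= full.cost * 1.02 + 1e-9
        kept = set(sel.exposures[sel.exposures > 0].index)
        hits += {"SBS2", "SBS24"} <= kept
    assert hits >= 9


def test_backward_select_zero_threshold_only_drops_redundant():
    cat = synthetic_catalog()
    catalogue = (500 * cat["SBS1"]).round()
    sel = backward_select(catalogue, cat, cost_threshold=0.0)
    kept = sel.exposures[sel.exposures > 0]
    assert "SBS1" in kept.index


def test_cohort_subset_prevalence_boundary_and_platinum_forcing():
    active4 = [pd.Series({"SBS1": 1.0, "SBS4": 0.0})] * 4 + [pd.Series({"SBS1": 0.0, "SBS4": 1.0})]
    assert "SBS1" not in cohort_subset(active4, min_cases=5)
    active5 = [pd.Series({"SBS1": 1.0, "SBS4": 0.0})] * 5
    assert "SBS1" in cohort_subset(active5, min_cases=5)
    forced = cohort_subset(active5, min_cases=5, force_platinum=True)
    assert "SBS31" in forced and "SBS35" in forced
    with pytest.raises(ValueError):
        cohort_subset([], min_cases=5)


def test_cohort_subset_monotone_in_min_cases():
    rng = np.random.default_rng(3)
    cases = [pd.Series(rng.integers(0, 2, 6).astype(float),
                       index=[f"S{i}" for i in range(6)]) for _ in range(12)]
    sizes = [len(cohort_subset(cases, min_cases=k)) for k in range(1, 8)]
    assert sizes == sorted(sizes, reverse=True)


@pytest.mark.parametrize(
    "n,kind,fit",
    [(20, "subclonal", False), (21, "subclonal", True),
     (300, "clonal", False), (301, "clonal", True), (1000, "clonal", True)],
)
def test_eligibility_strict_thresholds(n, kind, fit):
    assert eligibility(n, kind) == fit


def test_radiation_ratios_and_missing_denominators():
    mut = pd.DataFrame({"kind": ["SNM"] * 100 + ["deletion"] * 6 + ["insertion"] * 3})
    indel_sub, del_ins = radiation_ratios(mut)
    assert indel_sub == pytest.approx(9 / 100)
    assert del_ins == pytest.approx(2.0)
    only_del = pd.DataFrame({"kind": ["SNM", "deletion"]})
    assert radiation_ratios(only_del)[1] is None


def test_exposure_recovery_cosine_on_sampled_catalogues():
    cat = synthetic_catalog()
    sims = 15
    ok = 0
    for seed in range(sims):
        rng = np.random.default_rng(seed)
        names = list(rng.choice(cat.columns, 3, replace=False))
        weights = rng.dirichlet(np.ones(3))
        truth = pd.Series(0.0, index=cat.columns)
        truth[names] = weights
        catalogue = sample_catalogue(cat, dict(zip(names, weights)), 600, rng)
        rel = fit_exposures(catalogue, cat).relative
        cos = truth @ rel / (np.linalg.norm(truth) * np.linalg.norm(rel))
        ok += cos >= 0.9
    assert ok >= 14
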