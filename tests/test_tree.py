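"""Clone-tree reconstruction, classification and per-sample composition."""

import itertools

import numpy as np
import pandas as pd
import pytest

from ccfevo import (
    CcfCluster,
    CloneTree,
    NoAdmissibleTreeError,
    PipelineConfig,
    classify,
    clone_composition,
    downscale_pairs,
    reconstruct_tree,
    relapse_seed,
)


def clusters_from(centres, sizes=None, kinds=None):
    sizes = sizes or [10] * len(centres)
    kinds = kinds or ["shared"] * len(centres)
    return [
        CcfCluster(f"x{i}", tuple(c), k, [f"x{i}_{j}" for j in range(n)])
        for i, (c, n, k) in enumerate(zip(centres, sizes, kinds))
    ]


def tree_from(parent, ccf_rows, samples=("S1", "S2")):
    return CloneTree(parent, pd.DataFrame(ccf_rows, index=list(parent), columns=list(samples)))


# ---- brute-force oracle ----------------------------------------------------

def oracle_trees(centres, eps):
    """All admissible rooted trees (node 0 = root) by exhaustive enumeration."""
    n = len(centres)
    centres = np.asarray(centres, dtype=float)
    admissible = []
    cand = [
        [a for a in range(n) if a != b and np.all(centres[b] <= centres[a] + eps)]
        for b in range(1, n)
    ]
    if any(not c for c in cand):
        return []
    for combo in itertools.product(*cand):
        parent_of = {b + 1: combo[b] for b in range(n - 1)}
        # acyclicity
        ok = True
        for start in parent_of:
            seen, node = set(), start
            while node in parent_of:
                if node in seen:
                    ok = False
                    break
                seen.add(node)
                node = parent_of[node]
            if not ok:
                break
        if not ok:
            continue
        sums = {}
        for child, par in parent_of.items():
            sums.setdefault(par, np.zeros(centres.shape[1]))
            sums[par] += centres[child]
        if any(np.any(v > centres[p] + eps) for p, v in sums.items()):
            continue
        branchings = sum(1 for p in set(parent_of.values()) if list(parent_of.values()).count(p) >= 2)
        admissible.append((parent_of, branchings))
    return admissible


# ---- reconstruction --------------------------------------------------------

def test_two_clusters_give_linear_chain():
    tree = reconstruct_tree(clusters_from([(1, 1), (0.5, 0.5)]))
    assert tree.parent == {"C0": None, "C1": "C0"}
    assert classify(tree) == "B"


def test_incomparable_subclones_branch_from_c0():
    tree = reconstruct_tree(clusters_from([(1, 1), (0.6, 0.0), (0.0, 0.7)]))
    assert classify(tree) == "E"
    assert tree.parent["C1"] == "C0" and tree.parent["C2"] == "C0"


def test_parsimony_prefers_chain_over_branch():
    cfg = PipelineConfig(epsilon=0.05)
    tree = reconstruct_tree(clusters_from([(1, 1), (0.5, 0.5), (0.4, 0.5)]), cfg)
    assert tree.n_branching_events == 0
    assert classify(tree) == "C"


def test_near_clonal_clusters_merge_into_c0():
    tree = reconstruct_tree(clusters_from([(1.0, 1.0), (0.95, 1.02), (0.4, 0.4)]))
    assert len(tree.labels) == 2
    assert tree.mutation_counts["C0"] == 20


def test_c0_promoted_when_no_clonal_cluster():
    tree = reconstruct_tree(clusters_from([(0.7, 0.6), (0.3, 0.2)]))
    assert tree.c0_promoted
    assert tree.labels[0] == "C0"


def test_no_admissible_tree_lists_violations():
    # second cluster exceeds C0 beyond tolerance in sample 2
    with pytest.raises(NoAdmissibleTreeError, match="no admissible"):
        reconstruct_tree(clusters_from([(1, 1), (0.5, 1.4)]))


def test_sum_rule_blocks_flat_attachment():
    # both subclones fit under C0 individually but not jointly in sample 1
    cfg = PipelineConfig(epsilon=0.05)
    with pytest.raises(NoAdmissibleTreeError):
        reconstruct_tree(clusters_from([(1, 1), (0.7, 0.2), (0.6, 0.9)]), cfg)


def test_matches_bruteforce_minimal_branching_on_random_sets():
    """Reconstruction output is an admissible minimum-branching tree."""
    rng = np.random.default_rng(42)
    eps = 0.1
    checked = 0
    while checked < 50:
        k = int(rng.integers(2, 6))
        centres = [(1.0, 1.0)]
        for _ in range(k):
            centres.append(tuple(rng.uniform(0, 0.9, 2).round(2)))
        admissible = oracle_trees(centres, eps)
        try:
            tree = reconstruct_tree(clusters_from(centres))
        except NoAdmissibleTreeError:
            assert not admissible
            continue
        finally:
            checked += 1
        assert admissible, "implementation found a tree the oracle missed"
        assert tree.n_branching_events == min(b for _, b in admissible)
        tree.validate(eps)


# ---- classification --------------------------------------------------------

@pytest.mark.parametrize(
    "parent,expected",
    [
        ({"C0": None}, "A"),
        ({"C0": None, "C1": "C0"}, "B"),
        ({"C0": None, "C1": "C0", "C2": "C1"}, "C"),
        ({"C0": None, "C1": "C0", "C2": "C1", "C3": "C1"}, "D"),
        ({"C0": None, "C1": "C0", "C2": "C0"}, "E"),
        ({"C0": None, "C1": "C0", "C2": "C1", "C3": "C1", "C4": "C3", "C5": "C3"}, "F"),
    ],
)
def test_classify_topology_taxonomy(parent, expected):
    n = len(parent)
    ccf = np.linspace(1.0, 0.3, n)[:, None] * np.ones((1, 2))
    assert classify(tree_from(parent, ccf)) == expected


# ---- composition -----------------------------------------------------------

def test_clone_composition_terminal_fractions():
    tree = tree_from({"C0": None, "C1": "C0"}, [[1.0, 1.0], [0.6, 0.5]])
    comp = clone_composition(tree, "S1")
    assert comp.loc["C0", "terminal_fraction"] == pytest.approx(0.4)
    assert comp.loc["C1", "terminal_fraction"] == pytest.approx(0.6)


def test_clone_composition_single_clone():
    tree = tree_from({"C0": None}, [[1.0, 1.0]])
    assert clone_composition(tree, "S2").loc["C0", "terminal_fraction"] == 1.0


def test_composition_recovered_from_simulation(class_e_bundle):
    from ccfevo import run_patient

    gt, bundle = class_e_bundle
    res = run_patient(bundle)
    for s in gt.samples:
        truth = clone_composition(gt.tree(), s)["terminal_fraction"].sort_values()
        found = clone_composition(res.tree, s)["terminal_fraction"].sort_values()
        assert np.allclose(truth.to_numpy(), found.to_numpy(), atol=0.1)


# ---- relapse seeding -------------------------------------------------------

def test_relapse_seed_deep_ancestor():
    parent = {"C0": None, "C1": "C0", "C2": "C1", "C3": "C1"}
    ccf = [[1.0, 1.0], [0.9, 0.9], [0.5, 0.0], [0.0, 0.6]]
    tree = tree_from(parent, ccf)
    assert relapse_seed(tree, "S1", "S2") == "C1"


def test_relapse_seed_c0_for_lineages_branching_at_root():
    parent = {"C0": None, "C1": "C0", "C2": "C0"}
    ccf = [[1.0, 1.0], [0.7, 0.0], [0.0, 0.6]]
    tree = tree_from(parent, ccf)
    assert relapse_seed(tree, "S1", "S2") == "C0"


def test_relapse_seed_matches_simulated_class_e(sim_conditions):
    from ccfevo import bundle_from_truth, emit_reads, run_patient, simulate_patient

    hits = 0
    for seed in range(10):
        gt = simulate_patient(3, 2, "E", seed=seed, sim=sim_conditions)
        reads = emit_reads(gt, mean_depth=120, sim=sim_conditions)
        res = run_patient(bundle_from_truth(gt, reads))
        truth_seed = relapse_seed(gt.tree(), "S1", "S2")
        hits += relapse_seed(res.tree, "S1", "S2") == truth_seed
    assert hits == 10


# ---- pair downscaling ------------------------------------------------------

def test_downscale_two_samples_returns_that_pair():
    assert downscale_pairs({("S1", "S2"): (1, 30)}) == ("S1", "S2")


def test_downscale_argmax_by_complexity():
    stats = {("S1", "S2"): (1, 100), ("S1", "S3"): (3, 40), ("S2", "S3"): (3, 25)}
    assert downscale_pairs(stats) == ("S1", "S3")


def test_downscale_requires_a_pair():
    with pytest.raises(ValueError):
        downscale_pairs({})


def test_pairwise_downscaling_never_exceeds_class_e(sim_conditions):
    """Two-sample analyses cannot resolve two branchings: class stays <= E."""
    from ccfevo import bundle_from_truth, emit_reads, run_pair, simulate_patient

    for seed in range(6):
        gt = simulate_patient(5, 3, "F", seed=seed, sim=sim_conditions)
        reads = emit_reads(gt, mean_depth=120, sim=sim_conditions)
        bundle = bundle_from_truth(gt, reads)
        for s1, s2 in itertools.combinations(gt.samples, 2):
            try:
                res = run_pair(bundle, s1, s2)
            except NoAdmissibleTreeError:
                continue
            assert res.phylo_class in "ABCDE"


# ---- serialisation ---------------------------------------------------------

def test_newick_and_json_round_out_the_tree():
    tree = tree_from({"C0": None, "C1": "C0", "C2": "C0"},
                     [[1.0, 1.0], [0.6, 0.1], [0.2, 0.7]])
    nwk = tree.to_newick()
    assert nwk.endswith("C0[&ccf={1.000,1.000}];")
    import json

    payload = json.loads(tree.to_json())
    assert payload["class"] == "E"
    assert payload["parents"]["C1"] == "C0"
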