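"""Reproducible validation experiments run by the acceptance machinery.

Each function sets up the study conditions (exome-like depth, purity
0.85, the emulated mutation loads), runs the relevant part of the
pipeline from scratch and returns summary numbers.  They are shared by
the test suite and the acceptance script so both measure exactly the
same computation.
"""

from __future__ import annotations

import itertools

import numpy as np
import pandas as pd

from . import filters as flt
from .cluster import CcfCluster
from .config import PipelineConfig
from .io import bundle_from_truth
from .pipeline import run_patient
from .signatures import backward_select, fit_exposures, sample_catalogue, synthetic_catalog
from .simulate import SimConfig, emit_reads, simulate_patient
from .tree import NoAdmissibleTreeError, reconstruct_tree


def private_test_null_fdr(
    n_replicates: int = 500,
    n_mutations: int = 2000,
    mean_depth: float = 120.0,
    purity: float = 0.85,
    alpha: float = 0.05,
    seed: int = 0,
) -> float:
    """Replicate-level false-discovery proportion of the private test.

    Global null: every mutation is clonal, diploid (multiplicity 1) and
    shared between two samples, so any "truly private" verdict is a false
    discovery.  Mutations with zero variant reads in exactly one sample
    are the private candidates; the binomial non-detection p-values are
    BH-corrected at ``alpha`` per replicate.  Returns the percentage of
    replicates with at least one rejection.
    """
    rng = np.random.default_rng(seed)
    evaf = purity / 2.0  # m=1, CN=2, normal CN 2
    hits = 0
    for _ in range(n_replicates):
        depth = rng.poisson(mean_depth, size=(n_mutations, 2))
        alt = rng.binomial(depth, evaf)
        zero1, zero2 = alt[:, 0] == 0, alt[:, 1] == 0
        cand = zero1 ^ zero2
        if not cand.any():
            continue
        carrier = np.where(zero1[cand], 1, 0)
        idx = np.nonzero(cand)[0]
        vaf = alt[idx, carrier] / np.maximum(depth[idx, carrier], 1)
        d_other = depth[idx, 1 - carrier]
        res = flt.private_mutation_test(vaf, d_other, alpha=alpha)
        hits += int((res["status"] == "truly_private").any())
    return 100.0 * hits / n_replicates


def class_recovery(
    seeds_per_class: int = 50,
    mean_depth: float = 120.0,
    config: PipelineConfig | None = None,
    base_seed: int = 0,
) -> pd.DataFrame:
    """End-to-end phylogeny-class recovery across classes A-F.

    For every class, simulated bundles (depth ~Poisson(mean_depth),
    purity 0.85, clone separation >= 0.25, >= 50 mutations per clone;
    class F uses three samples, the others two) are pushed through the
    full pipeline; a seed counts as recovered when the reported class
    matches the truth, and centre accuracy is the largest Euclidean
    distance between matched true and recovered clone CCFs.
    """
    from scipy.optimize import linear_sum_assignment

    config = config or PipelineConfig()
    sim = SimConfig(mean_depth=mean_depth, subclonal_bounds=(50, 200))
    layout = {"A": (1, 2), "B": (2, 2), "C": (3, 2), "D": (4, 2), "E": (3, 2), "F": (5, 3)}
    rows = []
    for cls, (n_clones, n_samples) in layout.items():
        ok = centred = 0
        for k in range(seeds_per_class):
            seed = base_seed + 1000 * "ABCDEF".index(cls) + k
            try:
                gt = simulate_patient(n_clones, n_samples, cls, seed=seed, sim=sim)
                reads = emit_reads(gt, mean_depth=mean_depth, sim=sim)
                res = run_patient(bundle_from_truth(gt, reads), config)
            except Exception:
                continue
            if res.phylo_class == cls:
                ok += 1
            T, R = gt.clone_ccf.to_numpy(), res.tree.ccf.to_numpy()
            if T.shape == R.shape:
                D = np.linalg.norm(T[:, None, :] - R[None, :, :], axis=2)
                ri, ci = linear_sum_assignment(D)
                centred += bool(D[ri, ci].max() <= 0.1)
        rows.append({"class": cls, "n_seeds": seeds_per_class, "recovered": ok,
                     "recovery_pct": 100.0 * ok / seeds_per_class,
                     "centres_within_0.1": centred})
    return pd.DataFrame(rows).set_index("class")


def _oracle_admissible(centres: np.ndarray, eps: float):
    """Exhaustive enumeration of admissible rooted trees (node 0 = root)."""
    n = len(centres)
    cand = [
        [a for a in range(n) if a != b and np.all(centres[b] <= centres[a] + eps)]
        for b in range(1, n)
    ]
    if any(not c for c in cand):
        return []
    found = []
    for combo in itertools.product(*cand):
        parent_of = {b + 1: combo[b] for b in range(n - 1)}
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
        sums: dict[int, np.ndarray] = {}
        for child, par in parent_of.items():
            sums.setdefault(par, np.zeros(centres.shape[1]))
            sums[par] += centres[child]
        if any(np.any(v > centres[p] + eps) for p, v in sums.items()):
            continue
        branchings = sum(
            1 for p in set(parent_of.values()) if list(parent_of.values()).count(p) >= 2
        )
        found.append((parent_of, branchings))
    return found


def tree_oracle_agreement(n_configs: int = 200, seed: int = 0,
                          config: PipelineConfig | None = None) -> dict:
    """Reconstruction vs brute-force enumeration on random cluster sets.

    Random configurations of up to six clusters (a clonal cluster plus
    stick-broken subclone centres, plus occasional off-model noise
    centres) are reconstructed and compared against an independent
    exhaustive enumeration: the output must be admissible and attain the
    oracle's minimal branching count, and reconstruction may fail only
    when the oracle also finds no admissible tree.
    """
    config = config or PipelineConfig()
    rng = np.random.default_rng(seed)
    eps = config.epsilon
    agree = 0
    for _ in range(n_configs):
        k = int(rng.integers(1, 6))
        centres = [(1.0, 1.0)]
        for _ in range(k):
            if rng.random() < 0.6 and len(centres) > 1:
                base = centres[int(rng.integers(1, len(centres)))]
            else:
                base = centres[0]
            frac = rng.uniform(0.2, 0.9, 2)
            centres.append(tuple(np.round(np.asarray(base) * frac, 2)))
        arr = np.asarray(centres)
        clusters = [
            CcfCluster(f"x{i}", tuple(c), "shared", [f"x{i}_{j}" for j in range(8)])
            for i, c in enumerate(centres)
        ]
        admissible = _oracle_admissible(arr, eps)
        try:
            tree = reconstruct_tree(clusters, config)
        except NoAdmissibleTreeError:
            agree += int(not admissible)
            continue
        if not admissible:
            continue  # implementation found a tree the oracle missed: disagreement
        if len(tree.labels) != len(centres):
            continue  # C0 merge changed the problem; count as disagreement
        agree += int(tree.n_branching_events == min(b for _, b in admissible))
    return {"n_configs": n_configs, "agreement": agree,
            "agreement_pct": 100.0 * agree / n_configs}


def exposure_recovery(n_seeds: int = 50, n_mutations: int = 600, seed: int = 0) -> dict:
    """Signature-mixture recovery by NNLS refitting and backward selection.

    Catalogues are sampled from known 2-3 signature mixtures over the
    bundled synthetic catalogue; recovery is measured as the cosine
    similarity between true and fitted exposure vectors, and backward
    selection must retain every generating signature.
    """
    cat = synthetic_catalog()
    cos_ok = sel_ok = 0
    cosines = []
    for k in range(n_seeds):
        rng = np.random.default_rng(seed + k)
        names = list(rng.choice(cat.columns, 2, replace=False))
        w = float(rng.uniform(0.3, 0.7))
        mix = {names[0]: w, names[1]: 1.0 - w}
        catalogue = sample_catalogue(cat, mix, n_mutations, rng)
        truth = pd.Series(0.0, index=cat.columns)
        for nm, v in mix.items():
            truth[nm] = v
        rel = fit_exposures(catalogue, cat).relative
        cos = float(truth @ rel / (np.linalg.norm(truth) * np.linalg.norm(rel)))
        cosines.append(cos)
        cos_ok += cos >= 0.9
        sel = backward_select(catalogue, cat, cost_threshold=0.02)
        kept = set(sel.exposures[sel.exposures > 0].index)
        sel_ok += set(names) <= kept
    return {"n_seeds": n_seeds, "cosine_ok": cos_ok, "selection_ok": sel_ok,
            "mean_cosine": float(np.mean(cosines)),
            "cosine_ok_pct": 100.0 * cos_ok / n_seeds,
            "selection_ok_pct": 100.0 * sel_ok / n_seeds}
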