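"""Per-patient orchestration: filters -> CCFs -> clustering -> clone tree.

The stage order is fixed: (1) per-sample artifact filters (strand
balance, low-AF power gate, indel proximity, positional flags); (2)
unified candidate list across samples with rescue of low-AF calls
stringent elsewhere; (3) LOH-conflict and subclonal-copy-number
exclusions on the unified segmentation; (4) per-read power trim; (5)
binomial private-mutation test with BH control; (6) two-dimensional CCF
clustering of retained mutations; (7) clone-tree reconstruction and
classification.  Every decision lands in the filter report so totals are
auditable, and the whole run is deterministic for a fixed bundle and
configuration.

Patients with more than two samples are analysed pairwise; a
representative pair (highest subclonal complexity) supports interpatient
comparison, and a multi-sample clone tree is assembled by grouping
mutations that co-cluster in every pairwise analysis and re-running the
tree reconstruction on the per-sample median CCFs of those groups.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import ccf as ccfmod
from . import filters as flt
from .cluster import PRIVATE_S1, PRIVATE_S2, SHARED, CcfCluster, cluster_pair
from .config import PipelineConfig
from .io import PatientBundle
from .ploidy import PloidyCall, call_ploidy
from .tree import CloneTree, NoAdmissibleTreeError, classify, downscale_pairs, reconstruct_tree

log = logging.getLogger("ccfevo")


@dataclass
class PairResult:
    """Everything one sample-pair analysis produces."""

    samples: tuple[str, str]
    ccf_table: pd.DataFrame          # per mutation x sample CCF records
    report: pd.DataFrame             # per-mutation filter verdicts
    ccf_pair: pd.DataFrame           # retained mutations: ccf_1, ccf_2, kind
    ccf_wide: pd.DataFrame           # all mutations x both samples (0 = absent)
    var_wide: pd.DataFrame           # per-mutation CCF sampling variances
    clusters: list[CcfCluster]
    assignment: pd.Series
    tree: CloneTree
    phylo_class: str

    @property
    def n_subclones(self) -> int:
        return len(self.tree.labels) - 1

    @property
    def n_subclonal_mutations(self) -> int:
        return int(sum(v for k, v in self.tree.mutation_counts.items() if k != "C0"))


@dataclass
class PatientResult:
    patient_id: str
    pairs: dict[tuple[str, str], PairResult]
    representative: tuple[str, str]
    tree: CloneTree
    phylo_class: str
    ploidy_calls: dict[str, PloidyCall] = field(default_factory=dict)
    exposures: pd.DataFrame | None = None

    def summary_row(self) -> dict:
        rep = self.pairs[self.representative]
        return {
            "patient": self.patient_id,
            "representative_pair": "/".join(self.representative),
            "n_subclones": rep.n_subclones,
            "n_subclonal_mutations": rep.n_subclonal_mutations,
            "class_pairwise": rep.phylo_class,
            "class": self.phylo_class,
        }


def _per_sample_tables(mut: pd.DataFrame, samples: list[str], column: str) -> pd.DataFrame:
    wide = mut.pivot_table(index="mutation_id", columns="sample", values=column, aggfunc="first")
    return wide.reindex(columns=samples)


def _artifact_stringent(mut: pd.DataFrame, config: PipelineConfig) -> pd.Series:
    """Per (mutation, sample) row: passes all stringent artifact filters."""
    vaf = np.where(mut["depth"] > 0, mut["alt_reads"] / mut["depth"].replace(0, np.nan), 0.0)
    strand_fail = flt.strand_filter(vaf, mut["forward_alt"], mut["reverse_alt"], config)
    rc = mut["sample"].map(lambda s: config.rc_for(s)).to_numpy()
    power_fail = (vaf < config.af_gate) & (
        np.minimum(mut["depth"], mut["normal_depth"]).to_numpy() * vaf < rc
    )
    called = mut["alt_reads"].to_numpy() >= 1
    return pd.Series(called & ~np.asarray(strand_fail) & ~power_fail, index=mut.index)


def run_pair(
    bundle: PatientBundle,
    s1: str,
    s2: str,
    config: PipelineConfig | None = None,
    unified: pd.DataFrame | None = None,
    chrom_lengths: dict | None = None,
    centromeres: dict | None = None,
) -> PairResult:
    """Full two-sample analysis of one patient pair."""
    config = config or PipelineConfig()
    samples = [s1, s2]
    mut = bundle.mutations[bundle.mutations["sample"].isin(samples)].copy()
    if unified is None:
        segs = bundle.segments[bundle.segments["sample"].isin(samples)]
        unified = flt.unify_segmentation(segs)

    # ---- stage 1: artifact filters --------------------------------------
    stringent_rows = _artifact_stringent(mut, config)
    static = mut.drop_duplicates("mutation_id").set_index("mutation_id")
    indel_fail = flt.indel_proximity_fail(static.reset_index().rename(columns={"index": "mutation_id"}),
                                          config.indel_window)
    indel_fail.index = static.index
    pos_flags = flt.positional_flags(static, chrom_lengths, centromeres, config)
    pos_flags.index = static.index
    positional_bad = pos_flags.any(axis=1)
    artifact_ok = ~indel_fail & ~positional_bad

    stringent = _per_sample_tables(
        mut.assign(ok=stringent_rows.to_numpy()), samples, "ok"
    ).fillna(False).astype(bool)
    stringent = stringent.mul(artifact_ok.reindex(stringent.index, fill_value=False), axis=0)

    # ---- stage 2: unified list + rescue ----------------------------------
    alt_wide = _per_sample_tables(mut, samples, "alt_reads").fillna(0)
    present, provenance = flt.rescue_shared_lowaf(alt_wide, stringent)
    keep = present.any(axis=1)

    # ---- CCFs on the unified segmentation --------------------------------
    ccf_table = ccfmod.compute_ccf_table(mut, unified, bundle.purity(), config)
    ccf_wide = _per_sample_tables(ccf_table, samples, "ccf")
    evaf_wide = _per_sample_tables(ccf_table, samples, "expected_vaf")
    depth_wide = _per_sample_tables(ccf_table, samples, "depth")
    vaf_wide = _per_sample_tables(ccf_table, samples, "vaf")
    subclonal_cn = _per_sample_tables(ccf_table.assign(sc=ccf_table["subclonal_cn"].astype(float)),
                                      samples, "sc").fillna(0).astype(bool)
    ccf_wide = ccf_wide.where(present, 0.0).fillna(0.0)

    # ---- stage 3: LOH conflicts & subclonal-CN exclusions ----------------
    pair_df = pd.DataFrame({
        "chrom": static["chrom"], "pos": static["pos"],
        f"ccf_{s1}": ccf_wide[s1], f"ccf_{s2}": ccf_wide[s2],
    })
    loh_bad = flt.loh_conflict(pair_df, unified, config)
    clonal_any = (ccf_wide >= 1.0 - config.epsilon).any(axis=1)
    subclonal_cn_bad = clonal_any & subclonal_cn.any(axis=1)

    # ---- stage 4: power trim --------------------------------------------
    eligible = keep & artifact_ok.reindex(keep.index, fill_value=False) & ~loh_bad & ~subclonal_cn_bad
    trimmed = flt.power_trim_mask(depth_wide[eligible], evaf_wide[eligible].fillna(1.0),
                                  z=config.trim_z)
    trimmed = trimmed.reindex(keep.index, fill_value=False)

    # ---- stage 5: private-mutation test ----------------------------------
    retained = eligible & ~trimmed
    in1 = present[s1] & retained
    in2 = present[s2] & retained
    kind = pd.Series(index=keep.index, dtype=object)
    kind[in1 & in2] = SHARED
    private_status = pd.Series("", index=keep.index, dtype=object)
    cand1 = keep.index[in1 & ~in2]
    cand2 = keep.index[in2 & ~in1]
    for cands, carrier, other, label in ((cand1, s1, s2, PRIVATE_S1), (cand2, s2, s1, PRIVATE_S2)):
        if len(cands) == 0:
            continue
        res = flt.private_mutation_test(
            vaf_wide.loc[cands, carrier].fillna(0.0),
            depth_wide.loc[cands, other].fillna(0.0),
            alpha=config.alpha, detection_k=config.detection_k,
        )
        res.index = cands
        private_status.loc[cands] = res["status"]
        kind.loc[cands[res["status"] == "truly_private"]] = label
    retained &= kind.notna()

    # ---- filter report ----------------------------------------------------
    report = pd.DataFrame({
        "stringent_" + s1: stringent[s1], "stringent_" + s2: stringent[s2],
        "present_" + s1: present[s1], "present_" + s2: present[s2],
        "rescued_" + s1: provenance[s1] == "rescued",
        "rescued_" + s2: provenance[s2] == "rescued",
        "indel_proximity": indel_fail, "positional": positional_bad,
        "loh_conflict": loh_bad, "subclonal_cn": subclonal_cn_bad,
        "power_trim": trimmed, "private_status": private_status,
        "kind": kind, "retained": retained,
    })
    for col, n in (("indel_proximity", int(indel_fail.sum())),
                   ("positional", int(positional_bad.sum())),
                   ("loh_conflict", int(loh_bad.sum())),
                   ("power_trim", int(trimmed.sum()))):
        log.info("pair %s/%s: %s removed %d", s1, s2, col, n)

    # ---- stage 6-7: clustering and tree ----------------------------------
    from .cluster import ccf_variance

    ccf_pair = pd.DataFrame({
        "ccf_1": ccf_wide.loc[retained, s1],
        "ccf_2": ccf_wide.loc[retained, s2],
        "kind": kind[retained],
        "var_1": ccf_variance(depth_wide.loc[retained, s1], vaf_wide.loc[retained, s1],
                              evaf_wide.loc[retained, s1]),
        "var_2": ccf_variance(depth_wide.loc[retained, s2], vaf_wide.loc[retained, s2],
                              evaf_wide.loc[retained, s2]),
    })
    ccf_wide = ccf_wide[[s1, s2]]
    var_wide = pd.DataFrame({
        s: ccf_variance(depth_wide[s], vaf_wide[s], evaf_wide[s]) for s in (s1, s2)
    }, index=depth_wide.index)
    if ccf_pair.empty:
        raise ValueError(f"no mutations retained for pair {s1}/{s2}")
    clusters, assignment, _surface = cluster_pair(ccf_pair, config)
    tree = _tree_with_conflict_resolution(clusters, ccf_pair, config, (s1, s2))
    return PairResult((s1, s2), ccf_table, report, ccf_pair, ccf_wide, var_wide,
                      clusters, assignment, tree, classify(tree))


def _tree_with_conflict_resolution(clusters, ccf_pair, config, samples) -> CloneTree:
    """Reconstruct; on conflict, re-evaluate multiplicities and re-cluster.

    Clusters with a centre CCF well above 1 usually mean the clonality
    multiplicity was underestimated; their members' CCFs are halved (the
    next multiplicity solution) and clustering re-run once before giving
    up.
    """
    try:
        return reconstruct_tree(clusters, config, samples)
    except NoAdmissibleTreeError:
        adjusted = ccf_pair.copy()
        hot = [c for c in clusters if max(c.centre) > 1.0 + config.epsilon]
        if not hot:
            raise
        for c in hot:
            for col in ("ccf_1", "ccf_2"):
                adjusted.loc[adjusted.index.isin(c.members), col] /= 2.0
        clusters2, _assignment, _ = cluster_pair(adjusted, config)
        return reconstruct_tree(clusters2, config, samples)


def multi_sample_tree(
    bundle: PatientBundle,
    pairs: dict[tuple[str, str], PairResult],
    config: PipelineConfig | None = None,
) -> CloneTree:
    """Patient-level clone tree across all samples.

    Mutations are grouped by their tuple of pairwise cluster labels;
    absence from both samples of a pair is itself an informative token
    ("-": the clone simply does not live in those samples), whereas a
    mutation present somewhere but excluded by a filter in any pair is
    dropped outright.  Groups of at least the cluster minimum become
    clones whose per-sample CCF is the median over member mutations, and
    the tree is reconstructed over those centres.
    """
    config = config or PipelineConfig()
    samples = bundle.sample_ids
    keys = sorted(pairs)
    all_muts = sorted(set().union(*(pairs[k].report.index for k in keys)))
    signature: dict[str, tuple] = {}
    for m in all_muts:
        sig = []
        ok = True
        for k in keys:
            res = pairs[k]
            lab = res.assignment.get(m, np.nan)
            if isinstance(lab, str):
                sig.append(lab)
                continue
            a, b = res.samples
            present = bool(res.report.get(f"present_{a}", pd.Series(dtype=bool)).get(m, False)) or \
                bool(res.report.get(f"present_{b}", pd.Series(dtype=bool)).get(m, False))
            if present:
                ok = False  # seen but filtered: ambiguous, drop everywhere
                break
            sig.append("-")
        if ok:
            signature[m] = tuple(sig)
    groups: dict[tuple, list[str]] = {}
    for m, sig in signature.items():
        groups.setdefault(sig, []).append(m)
    # per-sample CCFs/variances from the first pair containing each sample
    ccf_by_sample: dict[str, pd.Series] = {}
    var_by_sample: dict[str, pd.Series] = {}
    for s in samples:
        for k in keys:
            res = pairs[k]
            if s in res.samples:
                ccf_by_sample[s] = res.ccf_wide[s]
                var_by_sample[s] = res.var_wide[s]
                break

    def centre_of(members: list[str]) -> tuple[float, ...]:
        return tuple(float(ccf_by_sample[s].reindex(members).median()) for s in samples)

    clusters = []
    for i, (sig, members) in enumerate(sorted(groups.items(), key=lambda kv: (-len(kv[1]), kv[0]))):
        if len(members) < config.min_cluster:
            continue
        centre = centre_of(members)
        if max(centre) < 0.15:
            continue  # below detectability in every sample: not a clone
        clusters.append(CcfCluster(f"g{i}", centre, "shared", members))

    # agglomerate boundary-slice shadows: merging two groups that belong to
    # one clone keeps the weighted residuals within their sampling variance
    from .cluster import _overdispersion_p

    def group_xv(members: list[str]):
        X = np.column_stack([ccf_by_sample[s].reindex(members).to_numpy() for s in samples])
        V = np.column_stack([var_by_sample[s].reindex(members).fillna(1.0).to_numpy() for s in samples])
        return X, V

    merged = True
    while merged and len(clusters) > 1:
        merged = False
        clusters.sort(key=lambda c: c.size)
        for small in list(clusters):
            others = [c for c in clusters if c is not small]
            near = min(others, key=lambda c: float(np.linalg.norm(np.subtract(c.centre, small.centre))))
            X, V = group_xv(small.members + near.members)
            if _overdispersion_p(X, V) >= config.split_alpha:
                clusters.remove(small)
                clusters.remove(near)
                both = near.members + small.members
                clusters.append(CcfCluster(near.label, centre_of(both), "shared", both))
                merged = True
                break
    return reconstruct_tree(clusters, config, tuple(samples))


def signature_exposures(
    tree: CloneTree,
    bundle: PatientBundle,
    catalog: pd.DataFrame,
    config: PipelineConfig | None = None,
) -> pd.DataFrame:
    """Clonal (C0) versus subclonal SBS exposures for one patient.

    Mutations are split by their clone assignment on the patient tree;
    each subset is refitted by backward selection against ``catalog``
    when it clears its eligibility threshold (> 300 clonal, > 20
    subclonal mutations).  Skipped subsets appear with a reason rather
    than being dropped.  Requires a ``trinucleotide`` column.
    """
    from . import signatures as sigs

    config = config or PipelineConfig()
    static = bundle.mutations.drop_duplicates("mutation_id").set_index("mutation_id")
    subsets = {"clonal_C0": tree.members.get("C0", [])}
    subsets["subclonal"] = [m for lab in tree.labels if lab != "C0"
                            for m in tree.members.get(lab, [])]
    rows = []
    for name, members in subsets.items():
        kind = "clonal" if name == "clonal_C0" else "subclonal"
        muts = static.loc[static.index.intersection(members)]
        muts = muts[(muts["kind"] == "SNM") & (muts["trinucleotide"].str.len() == 3)]
        if not sigs.eligibility(len(muts), kind, config):
            rows.append({"subset": name, "signature": None, "relative_exposure": np.nan,
                         "n_mutations": len(muts), "status": "skipped_below_threshold"})
            continue
        counts, _ = sigs.build_catalogue(muts, name)
        fit = sigs.backward_select(counts, catalog, config.sig_cost_threshold, subset=name)
        for sig_name, e in fit.relative.items():
            if e > 0:
                rows.append({"subset": name, "signature": sig_name, "relative_exposure": float(e),
                             "n_mutations": len(muts), "status": "fitted"})
    return pd.DataFrame(rows)


def run_patient(bundle: PatientBundle, config: PipelineConfig | None = None,
                catalog: pd.DataFrame | None = None) -> PatientResult:
    """Analyse every sample pair of a patient and assemble the clone tree.

    When a signature ``catalog`` (COSMIC-layout DataFrame) is given, the
    clonal/subclonal exposure table is fitted as well.
    """
    config = config or PipelineConfig()
    samples = bundle.sample_ids
    if len(samples) < 2:
        raise ValueError("a patient needs at least two samples")
    unified = flt.unify_segmentation(bundle.segments)
    pairs: dict[tuple[str, str], PairResult] = {}
    for s1, s2 in itertools.combinations(samples, 2):
        pairs[(s1, s2)] = run_pair(bundle, s1, s2, config, unified=unified)
    rep = downscale_pairs({k: (r.n_subclones, r.n_subclonal_mutations) for k, r in pairs.items()})
    if len(samples) == 2:
        tree = pairs[rep].tree
    else:
        tree = multi_sample_tree(bundle, pairs, config)
    ploidy_calls = {
        s: call_ploidy(bundle.segments, s, ploidy=bundle.ploidy().get(s), config=config)
        for s in samples
    }
    exposures = signature_exposures(tree, bundle, catalog, config) if catalog is not None else None
    return PatientResult(bundle.patient_id, pairs, rep, tree, classify(tree), ploidy_calls,
                         exposures)


def write_results(result: PatientResult, directory: str | Path) -> Path:
    """Persist every stage's output as plain-text tables."""
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    rows = []
    for (s1, s2), res in result.pairs.items():
        res.ccf_table.to_csv(d / f"ccf_{s1}_{s2}.tsv", sep="\t", index=False)
        res.report.to_csv(d / f"filters_{s1}_{s2}.tsv", sep="\t")
        out = res.ccf_pair.copy()
        out["cluster"] = res.assignment
        out.to_csv(d / f"clusters_{s1}_{s2}.tsv", sep="\t")
        rows.append({"pair": f"{s1}/{s2}", "class": res.phylo_class,
                     "n_subclones": res.n_subclones,
                     "n_subclonal_mutations": res.n_subclonal_mutations})
    (d / "tree.json").write_text(result.tree.to_json())
    (d / "tree.nwk").write_text(result.tree.to_newick() + "\n")
    pd.DataFrame(rows).to_csv(d / "pairs.tsv", sep="\t", index=False)
    pd.DataFrame([result.summary_row()]).to_csv(d / "summary.tsv", sep="\t", index=False)
    pd.DataFrame([
        {"sample": s, "ploidy": c.ploidy, "loh_fraction": c.loh_fraction,
         "high_ploidy": c.high_ploidy, "wgd": c.wgd}
        for s, c in result.ploidy_calls.items()
    ]).to_csv(d / "ploidy.tsv", sep="\t", index=False)
    if result.exposures is not None:
        result.exposures.to_csv(d / "exposures.tsv", sep="\t", index=False)
    return d
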