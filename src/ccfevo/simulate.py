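"""Synthetic multiregion/longitudinal tumour datasets with known truth.

Every downstream stage of the pipeline is testable without patient data:
the generator emits a clone tree whose per-sample CCFs obey the sum rule
by construction, assigns each mutation to exactly one clone (infinite
sites), places mutations on allele-specific copy-number segments, and
draws per-sample read counts from the sequencing-noise model the study
conditions imply — exome-like mean coverage (127x by default), high
purity (0.85), median ploidy ~2.5 reached through single-copy gains,
hundreds of clonal and tens-to-hundreds of subclonal mutations.

Optional artifact channels (off by default) emulate FFPE-like low-AF
strand-biased noise calls, indel calls adjacent to real SNMs, and
sample-specific LOH that deletes minor-allele mutations — the inputs the
filter battery exists for.

Fixing the seed fixes every emitted table byte for byte.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from . import signatures as sigs
from .config import PipelineConfig
from .genome import AUTOSOMES, HG19_CENTROMERES, HG19_CHROM_LENGTHS
from .tree import CloneTree, classify


class InfeasibleClassError(ValueError):
    """The requested phylogeny class cannot be realised at the given sizes."""


@dataclass
class SimConfig:
    """Study conditions of the generator (defaults = the emulated cohort)."""

    purity: float = 0.85
    mean_depth: float = 127.0
    ploidy_target: float = 2.5
    clonal_bounds: tuple[int, int] = (50, 500)
    subclonal_bounds: tuple[int, int] = (10, 200)
    min_separation: float = 0.25
    ffpe_noise_rate: float = 0.0    # artifact SNMs per real mutation
    indel_rate: float = 0.0         # real indels placed adjacent to SNMs
    loh_fraction: float = 0.0       # genome fraction under sample-2 LOH
    clonal_signature_mix: dict[str, float] = field(
        default_factory=lambda: {"SBS4": 0.6, "SBS5": 0.4}
    )
    subclonal_signature_mix: dict[str, float] = field(
        default_factory=lambda: {"SBS5": 0.7, "SBS1": 0.3}
    )


@dataclass
class GroundTruth:
    """Everything the pipeline is supposed to recover."""

    parent: dict[str, Optional[str]]
    clone_ccf: pd.DataFrame                 # clones x samples, C0 row all 1.0
    mutation_assignment: dict[str, str]     # mutation id -> clone label
    mutations: pd.DataFrame                 # per-mutation static info
    segments: pd.DataFrame                  # per-sample allele-specific CN
    purity: dict[str, float]
    ploidy: dict[str, float]
    seed: int

    @property
    def samples(self) -> list[str]:
        return list(self.clone_ccf.columns)

    def tree(self) -> CloneTree:
        counts: dict[str, int] = {}
        for clone in self.mutation_assignment.values():
            counts[clone] = counts.get(clone, 0) + 1
        return CloneTree(dict(self.parent), self.clone_ccf.copy(), counts)

    def phylogeny_class(self) -> str:
        return classify(self.tree())

    def to_json(self) -> str:
        return json.dumps(
            {
                "parent": self.parent,
                "clone_ccf": {c: self.clone_ccf.loc[c].to_dict() for c in self.clone_ccf.index},
                "mutation_assignment": self.mutation_assignment,
                "purity": self.purity,
                "ploidy": self.ploidy,
                "seed": self.seed,
                "class": self.phylogeny_class(),
            },
            indent=2,
        )


def _topology_for_class(target: str, n_clones: int) -> dict[str, Optional[str]]:
    minima = {"A": 1, "B": 2, "C": 3, "D": 4, "E": 3, "F": 5}
    if target not in minima:
        raise ValueError(f"unknown phylogeny class {target!r}")
    if n_clones < minima[target]:
        raise InfeasibleClassError(f"class {target} needs at least {minima[target]} clones, got {n_clones}")
    if target == "A" and n_clones > 1:
        raise InfeasibleClassError("class A admits exactly one clone (C0)")
    if target == "B" and n_clones != 2:
        raise InfeasibleClassError("class B admits exactly two clones")
    labels = [f"C{i}" for i in range(n_clones)]
    parent: dict[str, Optional[str]] = {"C0": None}
    if target in ("A",):
        pass
    elif target in ("B", "C"):
        for i in range(1, n_clones):
            parent[labels[i]] = labels[i - 1]
    elif target == "D":
        parent["C1"] = "C0"
        parent["C2"] = "C1"
        parent["C3"] = "C1"
        for i in range(4, n_clones):  # extras extend one branch linearly
            parent[labels[i]] = labels[i - 1]
    elif target == "E":
        parent["C1"] = "C0"
        parent["C2"] = "C0"
        for i in range(3, n_clones):
            parent[labels[i]] = labels[i - 1]
    elif target == "F":
        parent["C1"] = "C0"
        parent["C2"] = "C0"
        parent["C3"] = "C1"
        parent["C4"] = "C1"
        for i in range(5, n_clones):
            parent[labels[i]] = labels[i - 1]
    return parent


def _random_topology(n_clones: int, rng: np.random.Generator) -> dict[str, Optional[str]]:
    parent: dict[str, Optional[str]] = {"C0": None}
    for i in range(1, n_clones):
        parent[f"C{i}"] = f"C{int(rng.integers(0, i))}"
    return parent


def _children(parent: dict[str, Optional[str]]) -> dict[str, list[str]]:
    out: dict[str, list[str]] = {lab: [] for lab in parent}
    for c, p in parent.items():
        if p is not None:
            out[p].append(c)
    return out


def _draw_ccfs(
    parent: dict[str, Optional[str]],
    n_samples: int,
    rng: np.random.Generator,
    min_separation: float = 0.25,
    max_tries: int = 500,
    require_identifiable: bool = True,
) -> pd.DataFrame:
    """Clone x sample CCF matrix obeying the sum rule by construction.

    Children split their parent's CCF; at branch points each child is
    anchored to its own "home" sample (internal children keep presence in
    the other samples so their own descendants remain resolvable, leaf
    children become private).  Entries below 0.15 are snapped to zero and
    the draw is rejected unless all clones are pairwise separated by at
    least ``min_separation`` and every nonzero entry stays detectable
    (>= 0.2).
    """
    kids = _children(parent)
    labels = sorted(parent, key=lambda s: (len(s), s))
    for _ in range(max_tries):
        ccf = {"C0": np.ones(n_samples)}
        ok = True
        for node in labels:
            ch = kids[node]
            if not ch or not ok:
                continue
            base = ccf[node]
            if len(ch) == 1:
                frac = rng.uniform(0.4, 0.75) + rng.uniform(-0.08, 0.08, n_samples)
                ccf[ch[0]] = np.clip(base * np.clip(frac, 0.05, 0.9), 0.0, base)
                continue
            homes_avail = [s for s in range(n_samples) if base[s] >= 0.3]
            if len(homes_avail) < min(len(ch), n_samples):
                ok = False
                break
            perm = rng.permutation(homes_avail)
            for i, c in enumerate(ch):
                shares = np.zeros(n_samples)
                h = perm[i % len(perm)]
                shares[h] = rng.uniform(0.5, 0.7)
                if kids[c]:  # internal children stay visible everywhere
                    for s in range(n_samples):
                        if s != h:
                            shares[s] = rng.uniform(0.35, 0.55)
                ccf[c] = base * shares
            # rescale if siblings overflow the parent in any sample
            total = np.sum([ccf[c] for c in ch], axis=0)
            over = total > 0.95 * base
            if over.any():
                scale = np.where(over, 0.95 * base / np.maximum(total, 1e-12), 1.0)
                for c in ch:
                    ccf[c] = ccf[c] * scale
        if not ok:
            continue
        mat = pd.DataFrame({lab: ccf[lab] for lab in labels}).T
        mat.columns = [f"S{i+1}" for i in range(n_samples)]
        mat[mat < 0.15] = 0.0
        mat.loc["C0"] = 1.0
        if _valid_ccfs(mat, parent, min_separation) and (
            not require_identifiable or _identifiable(mat, parent)
        ):
            return mat
    raise InfeasibleClassError(
        f"could not draw a valid CCF matrix for {len(parent)} clones over {n_samples} samples"
    )


def _draw_ccfs_two_branchings(
    parent: dict[str, Optional[str]],
    n_samples: int,
    rng: np.random.Generator,
    min_separation: float = 0.25,
    max_tries: int = 200,
) -> pd.DataFrame:
    """Structured CCF draw for trees with two branch points (class F).

    Two branchings are only recoverable when flattening the lower branch
    onto C0 is blocked by the sum rule: the internal clone C1 must be
    near-fixated in the home samples of its children, so that C1 + child
    exceeds 1 there.  C1 is therefore drawn strong (~0.8) in two samples
    and weak (~0.25) in the rest; its sibling and its children are
    private to mutually distinct samples.  Needs >= 3 samples.
    """
    if n_samples < 3:
        raise InfeasibleClassError("two branching events need at least three samples")
    kids = _children(parent)
    c0_kids = kids["C0"]
    internal = [c for c in c0_kids if kids[c]]
    if len(c0_kids) != 2 or len(internal) != 1:
        raise InfeasibleClassError("structured two-branching draw expects C0 -> {internal, leaf}")
    c1 = internal[0]
    c2 = [c for c in c0_kids if c != c1][0]
    grand = kids[c1]
    labels = sorted(parent, key=lambda s: (len(s), s))
    for _ in range(max_tries):
        perm = rng.permutation(n_samples)
        strong = [int(perm[0]), int(perm[1])]
        weak = int(perm[2])
        ccf = {"C0": np.ones(n_samples)}
        v = np.full(n_samples, float(rng.uniform(0.2, 0.3)))
        v[strong[0]] = rng.uniform(0.75, 0.85)
        v[strong[1]] = rng.uniform(0.75, 0.85)
        ccf[c1] = v
        w = np.zeros(n_samples)
        w[weak] = rng.uniform(0.55, 0.65)
        ccf[c2] = w
        for g, s in zip(grand, strong):
            u = np.zeros(n_samples)
            u[s] = rng.uniform(0.45, 0.55)
            ccf[g] = u
        # extras chain below the last grandchild
        for lab in labels:
            if lab in ccf or not parent.get(lab):
                continue
            base = ccf[parent[lab]]
            ccf[lab] = np.clip(base * rng.uniform(0.45, 0.7), 0.0, base)
        mat = pd.DataFrame({lab: ccf[lab] for lab in labels}).T
        mat.columns = [f"S{i+1}" for i in range(n_samples)]
        mat[mat < 0.15] = 0.0
        mat.loc["C0"] = 1.0
        if _valid_ccfs(mat, parent, min_separation) and _identifiable(mat, parent):
            return mat
    raise InfeasibleClassError("could not draw an identifiable two-branching CCF matrix")


def _identifiable(mat: pd.DataFrame, parent: dict[str, Optional[str]]) -> bool:
    """True when exact centres reconstruct to the true topology.

    Maximum parsimony breaks ties toward linear evolution, so a CCF
    configuration whose true tree is *not* the minimum-branching
    admissible tree can never be recovered, even noise-free; such draws
    are rejected so that the emitted truth is identifiable in principle.
    """
    from .cluster import CcfCluster
    from .tree import NoAdmissibleTreeError, reconstruct_tree

    clusters = [
        CcfCluster(lab, tuple(float(v) for v in mat.loc[lab]), "shared", [f"{lab}_{i}" for i in range(10)])
        for lab in mat.index
    ]
    try:
        rec = reconstruct_tree(clusters, samples=tuple(mat.columns))
    except NoAdmissibleTreeError:
        return False
    if len(rec.labels) != len(mat.index):
        return False
    # map reconstructed labels onto truth labels via exact CCF vectors
    key_to_truth = {tuple(np.round(mat.loc[lab], 6)): lab for lab in mat.index}
    if len(key_to_truth) != len(mat.index):
        return False
    mapping = {}
    for lab in rec.labels:
        k = tuple(np.round(rec.ccf.loc[lab].to_numpy(), 6))
        if k not in key_to_truth:
            return False
        mapping[lab] = key_to_truth[k]
    for c in rec.labels:
        rec_parent = mapping[rec.parent[c]] if rec.parent[c] is not None else None
        if parent[mapping[c]] != rec_parent:
            return False
    return True


def _valid_ccfs(mat: pd.DataFrame, parent: dict[str, Optional[str]], min_sep: float) -> bool:
    kids = _children(parent)
    arr = mat.to_numpy()
    # detectability: entries are 0 or >= 0.2; subclones present somewhere
    vals = arr[arr > 0]
    if (vals < 0.2).any():
        return False
    if (arr.sum(axis=1) == 0).any():
        return False
    # monotonicity and exact sum rule
    for node, ch in kids.items():
        if not ch:
            continue
        p = mat.loc[node].to_numpy()
        tot = mat.loc[ch].to_numpy().sum(axis=0)
        if (tot > p + 1e-9).any():
            return False
        for c in ch:
            if (mat.loc[c].to_numpy() > p + 1e-9).any():
                return False
    # pairwise separation
    for i in range(arr.shape[0]):
        for j in range(i + 1, arr.shape[0]):
            if np.linalg.norm(arr[i] - arr[j]) < min_sep:
                return False
    return True


def sample_clone_tree(
    n_clones: int,
    n_samples: int,
    target_class: Optional[str] = None,
    seed: int = 0,
    min_separation: float = 0.25,
) -> tuple[dict[str, Optional[str]], pd.DataFrame]:
    """Clone topology and CCF matrix, optionally of a requested class.

    Returns (parent map, clone x sample CCF DataFrame); the emitted tree
    re-classifies as ``target_class`` whenever one is given, and the sum
    rule holds exactly in every sample.
    """
    if n_clones < 1 or n_samples < 1:
        raise ValueError("n_clones and n_samples must be positive")
    rng = np.random.default_rng(seed)
    if target_class is not None:
        parent = _topology_for_class(target_class, n_clones)
    else:
        parent = _random_topology(n_clones, rng)
    n_branch = sum(1 for lab in parent if len([c for c, p in parent.items() if p == lab]) >= 2)
    if n_clones == 1:
        ccf = pd.DataFrame([np.ones(n_samples)], index=["C0"],
                           columns=[f"S{i+1}" for i in range(n_samples)])
    elif n_branch >= 2 and target_class is not None:
        ccf = _draw_ccfs_two_branchings(parent, n_samples, rng, min_separation)
    else:
        ccf = _draw_ccfs(parent, n_samples, rng, min_separation,
                         require_identifiable=target_class is not None)
    if target_class is not None:
        emitted = classify(CloneTree(dict(parent), ccf))
        assert emitted == target_class, f"constructed class {emitted} != requested {target_class}"
    return parent, ccf


# --- genome / mutation placement -------------------------------------------

def _segment_layout(samples: list[str], ploidy_target: float, loh_fraction: float,
                    rng: np.random.Generator) -> pd.DataFrame:
    """One clonal segment per autosome; single-copy gains until the
    length-weighted mean copy number reaches the target; optional LOH on
    the last sample for a fraction of the genome."""
    chroms = list(AUTOSOMES)
    lengths = np.array([HG19_CHROM_LENGTHS[c] for c in chroms], dtype=float)
    states = {c: (1, 1) for c in chroms}
    order = rng.permutation(len(chroms))
    total = lengths.sum()
    for k in order:
        mean_cn = sum(lengths[i] * sum(states[chroms[i]]) for i in range(len(chroms))) / total
        if mean_cn >= ploidy_target:
            break
        states[chroms[k]] = (2, 1)
    loh_chroms: set[str] = set()
    if loh_fraction > 0:
        acc = 0.0
        for k in rng.permutation(len(chroms)):
            if acc / total >= loh_fraction:
                break
            if states[chroms[k]] == (1, 1):
                loh_chroms.add(chroms[k])
                acc += lengths[k]
    rows = []
    for sample in samples:
        is_loh_sample = sample == samples[-1] and len(samples) > 1
        for c in chroms:
            major, minor = states[c]
            if is_loh_sample and c in loh_chroms:
                major, minor = 1, 0
            rows.append({"sample": sample, "chrom": c, "start": 1,
                         "end": HG19_CHROM_LENGTHS[c], "major_cn": major,
                         "minor_cn": minor, "subclonal_cn": False})
    return pd.DataFrame(rows)


def _draw_position(rng: np.random.Generator) -> tuple[str, int]:
    chroms = list(AUTOSOMES)
    lengths = np.array([HG19_CHROM_LENGTHS[c] for c in chroms], dtype=float)
    p = lengths / lengths.sum()
    while True:
        c = chroms[int(rng.choice(len(chroms), p=p))]
        L = HG19_CHROM_LENGTHS[c]
        pos = int(rng.integers(int(0.02 * L), int(0.98 * L)))
        lo, hi = HG19_CENTROMERES[c]
        if not (lo - 1000 <= pos <= hi + 1000):
            return c, pos


_CHANNEL_PARSE = {
    ch: (ch[0] + ch[2] + ch[6], ch[2], ch[4]) for ch in sigs.SBS96_CHANNELS
}  # channel -> (trinucleotide, ref, alt)


def _draw_snm_identity(mix: dict[str, float], catalog: pd.DataFrame,
                       rng: np.random.Generator) -> tuple[str, str, str]:
    w = np.zeros(96)
    for name, e in mix.items():
        w += e * catalog[name].to_numpy()
    w /= w.sum()
    ch = sigs.SBS96_CHANNELS[int(rng.choice(96, p=w))]
    return _CHANNEL_PARSE[ch]


def _log_uniform_int(lo: int, hi: int, rng: np.random.Generator) -> int:
    return int(round(np.exp(rng.uniform(np.log(lo), np.log(hi)))))


def simulate_patient(
    n_clones: int,
    n_samples: int = 2,
    target_class: Optional[str] = None,
    seed: int = 0,
    sim: SimConfig | None = None,
) -> GroundTruth:
    """Full synthetic patient: tree, CCFs, segments and mutation identities.

    Mutation counts per clone are drawn log-uniformly (defaults 50-500
    for C0, 10-200 per subclone); SNM identities (trinucleotide context,
    ref, alt) are drawn from clone-specific signature mixtures over the
    synthetic catalogue so that signature refitting is testable end to
    end.
    """
    sim = sim or SimConfig()
    rng = np.random.default_rng(seed)
    parent, clone_ccf = sample_clone_tree(
        n_clones, n_samples, target_class, seed=int(rng.integers(2**31)),
        min_separation=sim.min_separation,
    )
    samples = list(clone_ccf.columns)
    segments = _segment_layout(samples, sim.ploidy_target, sim.loh_fraction, rng)
    catalog = sigs.synthetic_catalog()

    rows = []
    assignment: dict[str, str] = {}
    mid = 0
    for clone in clone_ccf.index:
        lo, hi = sim.clonal_bounds if clone == "C0" else sim.subclonal_bounds
        n_mut = _log_uniform_int(lo, hi, rng)
        mix = sim.clonal_signature_mix if clone == "C0" else sim.subclonal_signature_mix
        for _ in range(n_mut):
            mid += 1
            name = f"mut{mid:05d}"
            chrom, pos = _draw_position(rng)
            tri, ref, alt = _draw_snm_identity(mix, catalog, rng)
            seg = segments[(segments["sample"] == samples[0]) & (segments["chrom"] == chrom)].iloc[0]
            major = int(seg["major_cn"])
            allele = "major" if rng.random() < major / (major + int(seg["minor_cn"])) else "minor"
            mult = int(rng.integers(1, major + 1)) if (clone == "C0" and allele == "major") else 1
            rows.append({"mutation_id": name, "chrom": chrom, "pos": pos, "ref": ref,
                         "alt": alt, "kind": "SNM", "trinucleotide": tri, "clone": clone,
                         "allele": allele, "multiplicity": mult})
            assignment[name] = clone

    # real indels adjacent to SNMs (exercises the proximity filter)
    n_indel = int(round(sim.indel_rate * len(rows)))
    snm_rows = list(rows)
    for k in range(n_indel):
        mid += 1
        host = snm_rows[int(rng.integers(len(snm_rows)))]
        kind = "deletion" if rng.random() < 0.5 else "insertion"
        rows.append({"mutation_id": f"mut{mid:05d}", "chrom": host["chrom"],
                     "pos": host["pos"] + int(rng.integers(1, 9)),
                     "ref": "AT" if kind == "deletion" else "A",
                     "alt": "A" if kind == "deletion" else "AT",
                     "kind": kind, "trinucleotide": "", "clone": "C0",
                     "allele": "major", "multiplicity": 1})
        assignment[rows[-1]["mutation_id"]] = "C0"

    mutations = pd.DataFrame(rows)
    return GroundTruth(
        parent=parent,
        clone_ccf=clone_ccf,
        mutation_assignment=assignment,
        mutations=mutations,
        segments=segments,
        purity={s: sim.purity for s in samples},
        ploidy={s: float((segments[segments["sample"] == s].pipe(_seg_ploidy))) for s in samples},
        seed=seed,
    )


def _seg_ploidy(segs: pd.DataFrame) -> float:
    lengths = (segs["end"] - segs["start"] + 1).to_numpy(dtype=float)
    cn = (segs["major_cn"] + segs["minor_cn"]).to_numpy(dtype=float)
    return float((lengths * cn).sum() / lengths.sum())


def emit_reads(
    gt: GroundTruth,
    mean_depth: float | None = None,
    seed: int | None = None,
    sim: SimConfig | None = None,
    config: PipelineConfig | None = None,
) -> pd.DataFrame:
    """Per-sample read evidence for every mutation in the truth set.

    Depth is Poisson around the mean coverage; variant reads are binomial
    with success probability E[VAF] x true CCF, where the expected VAF
    uses the sample's purity and the mutation's local total copy number
    and multiplicity.  Strand counts split binomially at 1/2.  Mutations
    on the deleted allele of a sample-specific LOH segment are emitted
    with zero variant reads (multiplicity zero in that sample); placing a
    mutation on a zero-total-copy segment without LOH annotation is a
    validation error.  Optional FFPE-like noise calls are appended last.
    """
    sim = sim or SimConfig()
    config = config or PipelineConfig()
    depth_mean = mean_depth if mean_depth is not None else sim.mean_depth
    if depth_mean <= 0:
        raise ValueError("mean depth must be positive")
    rng = np.random.default_rng(gt.seed + 1 if seed is None else seed)
    samples = gt.samples
    seg_state = {
        (r["sample"], r["chrom"]): (int(r["major_cn"]), int(r["minor_cn"]))
        for _, r in gt.segments.iterrows()
    }
    out = []
    for _, m in gt.mutations.iterrows():
        for s in samples:
            major, minor = seg_state[(s, m["chrom"])]
            total_cn = major + minor
            if total_cn == 0:
                raise ValueError(
                    f"mutation {m['mutation_id']} lies on a zero-copy segment in {s} without LOH annotation"
                )
            deleted = m["allele"] == "minor" and minor == 0
            ccf = float(gt.clone_ccf.loc[m["clone"], s])
            depth = int(rng.poisson(depth_mean))
            normal_depth = int(rng.poisson(depth_mean))
            if deleted or ccf == 0.0 or depth == 0:
                alt = 0
            else:
                mult = min(int(m["multiplicity"]), major)
                p = gt.purity[s]
                evaf = mult * p / (p * total_cn + (1 - p) * config.normal_cn_for(m["chrom"]))
                alt = int(rng.binomial(depth, min(evaf * ccf, 1.0)))
            fwd = int(rng.binomial(alt, 0.5)) if alt else 0
            out.append({"mutation_id": m["mutation_id"], "chrom": m["chrom"], "pos": int(m["pos"]),
                        "ref": m["ref"], "alt": m["alt"], "kind": m["kind"],
                        "trinucleotide": m["trinucleotide"], "sample": s, "depth": depth,
                        "alt_reads": alt, "forward_alt": fwd, "reverse_alt": alt - fwd,
                        "normal_depth": normal_depth, "fraction_lowmapq": 0.0})

    n_noise = int(round(sim.ffpe_noise_rate * len(gt.mutations)))
    for k in range(n_noise):
        chrom, pos = _draw_position(rng)
        hit = samples[int(rng.integers(len(samples)))]
        vaf = float(rng.beta(1.5, 30.0))
        name = f"noise{k+1:04d}"
        for s in samples:
            depth = int(rng.poisson(depth_mean))
            alt = int(rng.binomial(depth, vaf)) if s == hit else 0
            out.append({"mutation_id": name, "chrom": chrom, "pos": pos, "ref": "C", "alt": "T",
                        "kind": "SNM", "trinucleotide": "ACA", "sample": s, "depth": depth,
                        "alt_reads": alt, "forward_alt": alt, "reverse_alt": 0,
                        "normal_depth": int(rng.poisson(depth_mean)), "fraction_lowmapq": 0.0})
    return pd.DataFrame(out)
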