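"""Clone-tree reconstruction under the infinite-sites / CCF sum rule.

Cluster centres are taken as clone CCFs.  Under infinite sites every
mutation arises once, so a clone's CCF can never exceed its parent's in
any sample (ancestry monotonicity) and sibling CCFs must sum to at most
the parent's CCF (the sum rule), both up to a tolerance ``epsilon`` that
absorbs estimation noise.  Among all admissible rooted trees the one with
the fewest branching events is returned (maximum parsimony: linear
evolution is preferred over branched evolution); remaining ties are
broken by attaching each clone to the admissible parent with the smallest
CCF (deepest attachment), then lexicographically.

Clones are labelled C0 (most recent common ancestor; CCF ~ 1 in every
sample), C1, C2, ... in depth-first order with larger-CCF children first.
Trees are classified into six topology classes:

    A  no subclones                     D  one branching below C0
    B  linear, one subclone             E  one branching at C0
    C  linear, two or more subclones    F  two or more branchings
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cluster import CcfCluster
from .config import PipelineConfig


class NoAdmissibleTreeError(ValueError):
    """No rooted tree satisfies ancestry monotonicity and the sum rule."""

    def __init__(self, violations: list[str]):
        super().__init__("no admissible clone tree; violated constraints: " + "; ".join(violations))
        self.violations = violations


@dataclass
class CloneTree:
    """Labelled clone hierarchy with per-sample clone CCFs.

    ``ccf`` is a DataFrame indexed by clone label (C0, C1, ...) with one
    column per sample; ``parent`` maps each non-root label to its parent.
    """

    parent: dict[str, str | None]
    ccf: pd.DataFrame
    mutation_counts: dict[str, int] = field(default_factory=dict)
    c0_promoted: bool = False
    members: dict[str, list] = field(default_factory=dict)

    @property
    def labels(self) -> list[str]:
        return list(self.ccf.index)

    @property
    def samples(self) -> list[str]:
        return list(self.ccf.columns)

    def children(self, label: str) -> list[str]:
        return [c for c, p in self.parent.items() if p == label]

    @property
    def n_branching_events(self) -> int:
        return sum(1 for lab in self.labels if len(self.children(lab)) >= 2)

    def depth(self, label: str) -> int:
        d = 0
        while self.parent[label] is not None:
            label = self.parent[label]
            d += 1
        return d

    def descends_from(self, label: str, ancestor: str) -> bool:
        while label is not None:
            if label == ancestor:
                return True
            label = self.parent[label]
        return False

    def validate(self, epsilon: float = 0.1) -> None:
        """Assert the invariants: single root C0 at CCF ~1, sum rule."""
        roots = [lab for lab, p in self.parent.items() if p is None]
        assert roots == ["C0"], f"root must be exactly C0, got {roots}"
        assert np.all(np.abs(self.ccf.loc["C0"].to_numpy() - 1.0) <= epsilon + 1e-9), \
            "C0 CCF must be ~1 in every sample"
        for lab in self.labels:
            kids = self.children(lab)
            if kids:
                total = self.ccf.loc[kids].sum(axis=0)
                assert np.all(total.to_numpy() <= self.ccf.loc[lab].to_numpy() + epsilon + 1e-9), \
                    f"sum rule violated at {lab}"

    def to_json(self) -> str:
        payload = {
            "nodes": self.labels,
            "parents": self.parent,
            "ccf": {lab: {s: float(self.ccf.loc[lab, s]) for s in self.samples} for lab in self.labels},
            "mutation_counts": {k: int(v) for k, v in self.mutation_counts.items()},
            "n_branching_events": self.n_branching_events,
            "class": classify(self),
            "c0_promoted": self.c0_promoted,
        }
        return json.dumps(payload, indent=2)

    def to_newick(self) -> str:
        def render(lab: str) -> str:
            kids = sorted(self.children(lab))
            ccfs = ",".join(f"{self.ccf.loc[lab, s]:.3f}" for s in self.samples)
            me = f"{lab}[&ccf={{{ccfs}}}]"
            if not kids:
                return me
            return "(" + ",".join(render(k) for k in kids) + ")" + me

        return render("C0") + ";"


def _admissible_parents(centres: np.ndarray, eps: float) -> list[list[int]]:
    """For each non-root node, indices of nodes it may descend from."""
    n = centres.shape[0]
    out = []
    for b in range(1, n):
        cands = [a for a in range(n) if a != b and np.all(centres[b] <= centres[a] + eps)]
        out.append(cands)
    return out


def _is_acyclic(parent_of: dict[int, int]) -> bool:
    for start in parent_of:
        seen = set()
        node = start
        while node in parent_of:
            if node in seen:
                return False
            seen.add(node)
            node = parent_of[node]
    return True


def _sum_rule_ok(parent_of: dict[int, int], centres: np.ndarray, eps: float) -> bool:
    sums: dict[int, np.ndarray] = {}
    for child, par in parent_of.items():
        sums.setdefault(par, np.zeros(centres.shape[1]))
        sums[par] = sums[par] + centres[child]
    return all(np.all(v <= centres[par] + eps) for par, v in sums.items())


def reconstruct_tree(
    clusters: list[CcfCluster],
    config: PipelineConfig | None = None,
    samples: tuple[str, ...] | None = None,
) -> CloneTree:
    """Most parsimonious admissible clone tree over CCF clusters.

    The cluster whose centre is within ``epsilon`` of 1 in every sample is
    the most recent common ancestor C0; multiple such clusters are merged
    (they are indistinguishable at tolerance), and if none qualifies the
    shared cluster with the highest summed CCF is promoted with a warning
    flag.  All rooted trees over the remaining clusters are enumerated
    under ancestry monotonicity and the sum rule; the minimum-branching
    tree wins, ties resolved by deepest admissible attachment then label
    order.

    Raises :class:`NoAdmissibleTreeError` listing the violated
    constraints when no tree exists (the caller may then re-evaluate
    mutation multiplicities and re-cluster).
    """
    config = config or PipelineConfig()
    eps = config.epsilon
    if not clusters:
        raise ValueError("no clusters to build a tree from")
    n_dim = len(clusters[0].centre)
    samples = samples or tuple(f"S{i+1}" for i in range(n_dim))

    # C0 detection / merge / promotion
    is_c0 = [all(c >= 1.0 - eps for c in cl.centre) for cl in clusters]
    c0_promoted = False
    if any(is_c0):
        c0_members = [cl for cl, f in zip(clusters, is_c0) if f]
        rest = [cl for cl, f in zip(clusters, is_c0) if not f]
        w = np.array([max(cl.size, 1) for cl in c0_members], dtype=float)
        centre = tuple(
            float(np.average([cl.centre[k] for cl in c0_members], weights=w)) for k in range(n_dim)
        )
        c0 = CcfCluster("C0", centre, "shared", sum((cl.members for cl in c0_members), []))
    else:
        shared = [cl for cl in clusters if cl.kind == "shared"] or list(clusters)
        c0 = max(shared, key=lambda cl: sum(cl.centre))
        rest = [cl for cl in clusters if cl is not c0]
        c0_promoted = True

    nodes = [c0] + sorted(rest, key=lambda cl: (-sum(cl.centre), cl.label))
    centres = np.array([cl.centre for cl in nodes], dtype=float)
    n = len(nodes)

    if n == 1:
        return CloneTree({"C0": None}, pd.DataFrame([centres[0]], index=["C0"], columns=list(samples)),
                         {"C0": c0.size}, c0_promoted, {"C0": list(c0.members)})

    cand = _admissible_parents(centres, eps)
    violations = [
        f"cluster {nodes[b + 1].label} at {tuple(np.round(centres[b + 1], 3))} has no admissible parent"
        for b, cs in enumerate(cand) if not cs
    ]
    if violations:
        raise NoAdmissibleTreeError(violations)

    space = float(np.prod([len(c) for c in cand]))
    if space > 2e5:
        # restrict parents to higher-CCF-sum nodes (nodes are sorted by
        # decreasing summed CCF, so admissible "backward" edges can only
        # link near-identical clusters and are safely dropped)
        cand = [[a for a in cs if a < b + 1] for b, cs in enumerate(cand)]
        violations = [
            f"cluster {nodes[b + 1].label} has no admissible parent after ordering restriction"
            for b, cs in enumerate(cand) if not cs
        ]
        if violations:
            raise NoAdmissibleTreeError(violations)
        if float(np.prod([len(c) for c in cand])) > 2e6:
            # degenerate many-cluster case: greedy deepest admissible attachment
            parent_of = {b + 1: min(cs, key=lambda a: (centres[a].sum(), nodes[a].label))
                         for b, cs in enumerate(cand)}
            if not _sum_rule_ok(parent_of, centres, eps):
                raise NoAdmissibleTreeError(
                    ["sum rule violated under greedy attachment of a large cluster set"]
                )
            cand = [[parent_of[b + 1]] for b in range(n - 1)]
    best = None
    for combo in itertools.product(*cand):
        parent_of = {b + 1: combo[b] for b in range(n - 1)}
        if not _is_acyclic(parent_of):
            continue
        if not _sum_rule_ok(parent_of, centres, eps):
            continue
        n_branch = sum(1 for _, grp in
                       itertools.groupby(sorted(parent_of.values()))
                       if len(list(grp)) >= 2)
        # deepest attachment: smaller parent CCF sums preferred, per node in label order
        tie = tuple(
            (float(centres[parent_of[b + 1]].sum()), nodes[parent_of[b + 1]].label)
            for b in range(n - 1)
        )
        key = (n_branch, tie)
        if best is None or key < best[0]:
            best = (key, parent_of)
    if best is None:
        raise NoAdmissibleTreeError(["sum rule admits no acyclic tree over the clusters"])

    parent_of = best[1]
    # relabel C0, C1, ... by DFS, larger-CCF children first
    order = {}
    counter = itertools.count()

    def dfs(i: int) -> None:
        order[i] = next(counter)
        kids = sorted((j for j, p in parent_of.items() if p == i),
                      key=lambda j: (-centres[j].sum(), nodes[j].label))
        for j in kids:
            dfs(j)

    dfs(0)
    label = {i: f"C{order[i]}" for i in order}
    parent = {label[i]: (label[parent_of[i]] if i in parent_of else None) for i in range(n)}
    ccf = pd.DataFrame(centres[[i for i in sorted(order, key=order.get)]],
                       index=[label[i] for i in sorted(order, key=order.get)],
                       columns=list(samples))
    counts = {label[i]: nodes[i].size for i in range(n)}
    members = {label[i]: list(nodes[i].members) for i in range(n)}
    return CloneTree(parent, ccf, counts, c0_promoted, members)


def classify(tree: CloneTree) -> str:
    """Topology class A-F of a clone tree (see module docstring)."""
    n = len(tree.labels)
    branch_points = [lab for lab in tree.labels if len(tree.children(lab)) >= 2]
    nb = len(branch_points)
    if nb == 0:
        if n == 1:
            return "A"
        return "B" if n == 2 else "C"
    if nb >= 2:
        return "F"
    return "E" if branch_points[0] == "C0" else "D"


def clone_composition(tree: CloneTree, sample: str) -> pd.DataFrame:
    """Per-clone CCF and terminal cell fraction in one sample.

    The terminal fraction of a clone is the fraction of tumour cells
    whose most derived clone is that node: its CCF minus the summed CCFs
    of its children, floored at zero.
    """
    rows = []
    for lab in tree.labels:
        ccf = float(tree.ccf.loc[lab, sample])
        kids = tree.children(lab)
        terminal = max(ccf - float(tree.ccf.loc[kids, sample].sum()) if kids else ccf, 0.0)
        rows.append({"clone": lab, "ccf": ccf, "terminal_fraction": terminal})
    return pd.DataFrame(rows).set_index("clone")


def relapse_seed(tree: CloneTree, pre_sample: str, post_sample: str,
                 epsilon: float = 0.1) -> str:
    """Deepest clone, present pre and post, from which every post clone descends.

    The post-sample's cell populations are the clones with a positive
    *terminal* fraction there (cells whose most derived clone is that
    node); the seed is the deepest clone, carried through treatment
    (CCF > epsilon pre and post), that is ancestral to all of them.  C0
    always qualifies, and is the answer when relapse branches directly
    from the common ancestor.
    """
    comp = clone_composition(tree, post_sample)
    post = [lab for lab in tree.labels if comp.loc[lab, "terminal_fraction"] > epsilon]
    both = [lab for lab in tree.labels
            if tree.ccf.loc[lab, pre_sample] > epsilon and tree.ccf.loc[lab, post_sample] > epsilon]
    cands = [a for a in both if all(tree.descends_from(p, a) for p in post)]
    return max(cands, key=tree.depth) if cands else "C0"


def downscale_pairs(pair_stats: dict[tuple[str, str], tuple[int, int]]) -> tuple[str, str]:
    """Representative sample pair of a multi-sample patient.

    ``pair_stats`` maps (sample1, sample2) -> (n_subclones,
    n_subclonal_mutations); the pair with the highest subclonal
    complexity wins, ties broken by sample-id order.
    """
    if not pair_stats:
        raise ValueError("at least two samples (one pair) required")
    return min(pair_stats, key=lambda k: (-pair_stats[k][0], -pair_stats[k][1], k))
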