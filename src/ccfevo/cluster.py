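"""Two-dimensional CCF clustering for a pair of samples.

Retained mutations, each with a CCF in both samples (0 when absent), are
binned into a 2D histogram; the histogram is modelled as a surface with a
tensor-product smoothing spline sharing one smoothing parameter across
both axes; strict local maxima of the surface are the cluster centres;
and mutations are assigned to their nearest centre by Euclidean distance
under a kind constraint — shared mutations join only shared clusters,
mutations private to one sample join only clusters on that sample's axis.
Peaks backing fewer than four mutations are disregarded and their members
re-assigned.

Centres are reported at bin centres; the histogram range extends above
CCF 1 (default 1.5) because sampling noise and multiplicity error push
real clonal mutations past 1 and that mass must stay visible.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from .config import PipelineConfig

SHARED, PRIVATE_S1, PRIVATE_S2 = "shared", "private_s1", "private_s2"


@dataclass
class CcfCluster:
    """A mutation cluster: a candidate tumour clone seen in a sample pair."""

    label: str
    centre: tuple[float, ...]
    kind: str  # shared / private_s1 / private_s2
    members: list[str] = field(default_factory=list)

    @property
    def size(self) -> int:
        return len(self.members)


def bin_centres(config: PipelineConfig) -> np.ndarray:
    n = int(round(config.ccf_max / config.bin_width))
    return (np.arange(n) + 0.5) * config.bin_width


def build_histogram(ccf1, ccf2, config: PipelineConfig | None = None) -> np.ndarray:
    """2D CCF count grid over [0, ccf_max]^2; counts sum to the input size.

    Values beyond the range are clipped into the outermost bin so that no
    mutation is lost; private mutations (CCF 0 in one sample) accumulate
    along the axes.
    """
    config = config or PipelineConfig()
    x = np.asarray(ccf1, dtype=float)
    y = np.asarray(ccf2, dtype=float)
    if x.size == 0:
        raise ValueError("no mutations to bin")
    if np.any(~np.isfinite(x)) or np.any(~np.isfinite(y)):
        raise ValueError("non-finite CCFs in clustering input")
    n = int(round(config.ccf_max / config.bin_width))
    eps = 1e-9
    xi = np.clip((x / config.bin_width).astype(int), 0, n - 1)
    yi = np.clip((y / config.bin_width).astype(int), 0, n - 1)
    # exact upper edge lands in the last bin
    xi = np.where(x >= config.ccf_max - eps, n - 1, xi)
    yi = np.where(y >= config.ccf_max - eps, n - 1, yi)
    grid = np.zeros((n, n))
    np.add.at(grid, (xi, yi), 1)
    return grid


def _penalty_eigensystem(n: int) -> tuple[np.ndarray, np.ndarray]:
    """Eigendecomposition of the second-difference penalty D'D (size n)."""
    D = np.diff(np.eye(n), n=2, axis=0)
    w, U = np.linalg.eigh(D.T @ D)
    return w, U


def fit_surface(grid: np.ndarray, smoothing: float | None = None,
                config: PipelineConfig | None = None) -> np.ndarray:
    """Smooth the count grid with a tensor-product penalized smoothing spline.

    The surface minimises ``||grid - f||^2 + lambda * (roughness of f)``
    with a discrete second-difference roughness penalty applied along
    both axes with one common smoothing parameter lambda (a P-spline /
    Whittaker smoother — the grid-sampled form of a cubic smoothing
    spline).  By default lambda is selected by robust generalised
    cross-validation, computed exactly through the eigendecomposition of
    the penalty; the GCV denominator inflates the model degrees of
    freedom by ``gcv_gamma`` (default 2) because plain GCV is known to
    undersmooth on sparse count grids.  A fixed lambda can be forced via
    ``smoothing`` or the config.  The fitted surface is clipped at zero.

    The penalty annihilates constant and planar surfaces, so a constant
    grid is returned unchanged and lambda -> infinity tends to the
    best-fitting plane.
    """
    config = config or PipelineConfig()
    if grid.shape[0] < 4 or grid.shape[1] < 4:
        raise ValueError("grid must be at least 4x4 for a spline surface")
    if not np.all(np.isfinite(grid)):
        raise ValueError("non-finite values in histogram grid")
    w1, U1 = _penalty_eigensystem(grid.shape[0])
    w2, U2 = _penalty_eigensystem(grid.shape[1])
    Yt = U1.T @ grid @ U2
    wsum = w1[:, None] + w2[None, :]
    lam = smoothing if smoothing is not None else config.smoothing
    if lam is None:
        N = grid.size
        best = None
        for cand in np.logspace(-1, 5, 31):
            shrink = 1.0 / (1.0 + cand * wsum)
            rss = float(((Yt * (1.0 - shrink)) ** 2).sum())
            edf = float(shrink.sum())
            gcv = N * rss / max(N - config.gcv_gamma * edf, 1e-9) ** 2
            if best is None or gcv < best[0]:
                best = (gcv, cand)
        lam = best[1]
    shrink = 1.0 / (1.0 + lam * wsum)
    surface = U1 @ (Yt * shrink) @ U2.T
    return np.clip(surface, 0.0, None)


def find_peaks(surface: np.ndarray, floor_frac: float = 0.01) -> list[tuple[int, int]]:
    """Strict 8-neighbour local maxima of the surface above a noise floor.

    Peaks below ``floor_frac`` of the global maximum are treated as spline
    ripple and ignored.  If no strict maximum exists the global argmax is
    returned as a single-cluster fallback.
    """
    padded = np.pad(surface, 1, constant_values=-np.inf)
    centre = padded[1:-1, 1:-1]
    tol = 1e-9 * max(float(np.abs(surface).max()), 1.0)
    is_max = np.ones_like(surface, dtype=bool)
    for di in (-1, 0, 1):
        for dj in (-1, 0, 1):
            if di == 0 and dj == 0:
                continue
            is_max &= centre > padded[1 + di : padded.shape[0] - 1 + di,
                                      1 + dj : padded.shape[1] - 1 + dj] + tol
    floor = floor_frac * surface.max()
    is_max &= surface > floor
    peaks = sorted(zip(*np.nonzero(is_max)))
    if not peaks:
        peaks = [tuple(int(v) for v in np.unravel_index(np.argmax(surface), surface.shape))]
    return [(int(i), int(j)) for i, j in peaks]


def _peak_kind(i: int, j: int) -> str:
    if i > 0 and j > 0:
        return SHARED
    if j == 0 and i > 0:
        return PRIVATE_S1
    if i == 0 and j > 0:
        return PRIVATE_S2
    return "origin"  # (0,0): no mutation present anywhere, never a cluster


def _nearest_centre(point: np.ndarray, cands: list[CcfCluster]) -> CcfCluster | None:
    """Euclidean nearest; ties to the larger summed-CCF centre, then label."""
    if not cands:
        return None
    best = None
    for c in cands:
        d = float(np.hypot(point[0] - c.centre[0], point[1] - c.centre[1]))
        key = (round(d, 12), -sum(c.centre), c.label)
        if best is None or key < best[0]:
            best = (key, c)
    return best[1]


def assign_mutations(
    mutations: pd.DataFrame,
    centres: list[CcfCluster],
    config: PipelineConfig | None = None,
) -> tuple[list[CcfCluster], pd.Series]:
    """Nearest-centre assignment under the shared/private constraint.

    ``mutations`` needs columns ``ccf_1, ccf_2, kind`` (kind as labelled
    by the filter stage).  Private mutations with no admissible axis
    centre found a new centre at their own componentwise median CCF if at
    least ``min_cluster`` of them exist, and are otherwise excluded as
    ambiguous.  After assignment, clusters below the four-mutation minimum
    are deleted and their members re-assigned to the nearest surviving
    admissible centre.  Returns the surviving clusters and a Series
    mapping mutation id -> cluster label (NaN = excluded).
    """
    config = config or PipelineConfig()
    centres = [CcfCluster(c.label, c.centre, c.kind, []) for c in centres]

    def admissible(kind: str, pool: list[CcfCluster]) -> list[CcfCluster]:
        return [c for c in pool if c.kind == kind]

    # seed extra axis centres for orphan private mutations
    for kind, cols in ((PRIVATE_S1, ("ccf_1", 0)), (PRIVATE_S2, ("ccf_2", 1))):
        if admissible(kind, centres):
            continue
        orphans = mutations[mutations["kind"] == kind]
        if len(orphans) >= config.min_cluster:
            med = float(orphans[cols[0]].median())
            centre = (med, 0.0) if kind == PRIVATE_S1 else (0.0, med)
            centres.append(CcfCluster(f"ax{cols[1]+1}", centre, kind, []))

    assignment = pd.Series(np.nan, index=mutations.index, dtype=object)
    pool = centres
    while True:
        for c in pool:
            c.members = []
        for mid, row in mutations.iterrows():
            c = _nearest_centre(np.array([row["ccf_1"], row["ccf_2"]]), admissible(row["kind"], pool))
            if c is None:
                assignment.loc[mid] = np.nan
                continue
            c.members.append(mid)
            assignment.loc[mid] = c.label
        small = [c for c in pool if 0 < c.size < config.min_cluster]
        if not small:
            pool = [c for c in pool if c.size >= config.min_cluster]
            break
        # drop the smallest offending peak and re-assign everything
        drop = min(small, key=lambda c: (c.size, c.label))
        pool = [c for c in pool if c is not drop]
        if not pool:
            break
    labelled = {c.label for c in pool}
    assignment[~assignment.isin(labelled)] = np.nan
    return pool, assignment


def ccf_variance(depth, vaf, expected_vaf, floor_vaf=None):
    """Binomial sampling variance of a CCF estimate, per mutation and sample.

    var(CCF) = vaf (1 - vaf) / depth / E[VAF]^2; the VAF is floored at one
    read so absent calls still carry a finite detection-scale variance.
    """
    d = np.maximum(np.asarray(depth, dtype=float), 1.0)
    e = np.asarray(expected_vaf, dtype=float)
    v = np.asarray(vaf, dtype=float)
    v = np.maximum(np.nan_to_num(v), 1.0 / d)
    e = np.where(np.isfinite(e) & (e > 0), e, 0.5)
    return np.maximum(v * (1.0 - v) / d / e**2, 1e-6)


def _overdispersion_p(X: np.ndarray, V: np.ndarray) -> float:
    """Chi-square p-value that one centre explains the cluster's spread.

    Under a single clone, member CCFs scatter around the centre with the
    known binomial sampling variances; two merged clones inflate the
    weighted residual sum far beyond its chi-square reference.
    """
    from scipy import stats as _st

    w = 1.0 / V
    mu = (X * w).sum(0) / w.sum(0)
    chi2 = float((((X - mu) ** 2) / V).sum())
    dof = X.size - X.shape[1]
    return float(_st.chi2.sf(chi2, dof))


def _em_split(X: np.ndarray, V: np.ndarray, n_iter: int = 60) -> tuple[np.ndarray, np.ndarray]:
    """Two-component heteroskedastic Gaussian split; returns (means, labels)."""
    w = 1.0 / V
    mu = (X * w).sum(0) / w.sum(0)
    R = X - mu
    cov = (R[:, :, None] * R[:, None, :]).mean(0)
    evals, evecs = np.linalg.eigh(cov)
    direction = evecs[:, -1] * np.sqrt(max(evals[-1], 1e-6))
    means = np.stack([mu - direction, mu + direction])
    pi = np.array([0.5, 0.5])
    for _ in range(n_iter):
        log_r = np.stack([
            np.log(pi[k]) - 0.5 * (((X - means[k]) ** 2) / V).sum(1) for k in range(2)
        ])
        log_r -= log_r.max(0)
        r = np.exp(log_r)
        r /= r.sum(0)
        pi = r.mean(1)
        for k in range(2):
            wk = r[k][:, None] * w
            means[k] = (X * wk).sum(0) / np.maximum(wk.sum(0), 1e-12)
    return means, r.argmax(0)


def refine_clusters(
    clusters: list[CcfCluster],
    ccf_pair: pd.DataFrame,
    config: PipelineConfig | None = None,
    max_rounds: int = 4,
) -> list[CcfCluster]:
    """Split clusters whose spread exceeds their sampling noise.

    Adjacent clones closer than the smoothing resolution merge into one
    surface peak; because every mutation's CCF carries a known binomial
    sampling variance, such a merge is detectable as overdispersion (a
    chi-square test of the weighted residuals).  Flagged clusters are
    split by a two-component EM with per-mutation variances, and splits
    are accepted only when both halves meet the cluster minimum and the
    new centres are separated by at least two bin widths.  Requires
    ``var_1/var_2`` columns in ``ccf_pair``; without them the cluster
    list is returned unchanged.
    """
    config = config or PipelineConfig()
    if "var_1" not in ccf_pair.columns or not clusters:
        return clusters
    out = list(clusters)
    for _ in range(max_rounds):
        changed = False
        nxt: list[CcfCluster] = []
        for cl in out:
            if cl.size < 2 * config.min_cluster:
                nxt.append(cl)
                continue
            sub = ccf_pair.loc[cl.members]
            X = sub[["ccf_1", "ccf_2"]].to_numpy(dtype=float)
            V = sub[["var_1", "var_2"]].to_numpy(dtype=float)
            if cl.kind == PRIVATE_S1:
                X, V = X[:, :1], V[:, :1]
            elif cl.kind == PRIVATE_S2:
                X, V = X[:, 1:], V[:, 1:]
            if _overdispersion_p(X, V) >= config.split_alpha:
                nxt.append(cl)
                continue
            means, labels = _em_split(X, V)
            sizes = [(labels == k).sum() for k in range(2)]
            sep = float(np.linalg.norm(means[0] - means[1]))
            if min(sizes) < config.min_cluster or sep < 2 * config.bin_width:
                nxt.append(cl)
                continue
            for k in range(2):
                if cl.kind == PRIVATE_S1:
                    centre = (float(means[k][0]), 0.0)
                elif cl.kind == PRIVATE_S2:
                    centre = (0.0, float(means[k][0]))
                else:
                    centre = (float(means[k][0]), float(means[k][1]))
                nxt.append(CcfCluster(f"{cl.label}.{k+1}", centre, cl.kind,
                                      [m for m, lab in zip(cl.members, labels) if lab == k]))
            changed = True
        out = nxt
        if not changed:
            break
    return out


def merge_clusters(
    clusters: list[CcfCluster],
    ccf_pair: pd.DataFrame,
    config: PipelineConfig | None = None,
) -> list[CcfCluster]:
    """Merge same-kind clusters that one clone explains.

    The complement of :func:`refine_clusters`: when a broad clone is cut
    into several surface peaks, the union of two such fragments still
    scatters within its binomial sampling variance, so the pair is
    collapsed (weighted-mean centre).  Merging proceeds smallest-first
    against the nearest same-kind cluster until no union passes the
    overdispersion test.  Requires ``var_1/var_2`` columns.
    """
    config = config or PipelineConfig()
    if "var_1" not in ccf_pair.columns or len(clusters) < 2:
        return clusters
    out = [CcfCluster(c.label, c.centre, c.kind, list(c.members)) for c in clusters]

    def xv(members, kind):
        sub = ccf_pair.loc[members]
        X = sub[["ccf_1", "ccf_2"]].to_numpy(dtype=float)
        V = sub[["var_1", "var_2"]].to_numpy(dtype=float)
        if kind == PRIVATE_S1:
            return X[:, :1], V[:, :1]
        if kind == PRIVATE_S2:
            return X[:, 1:], V[:, 1:]
        return X, V

    while len(out) > 1:
        out.sort(key=lambda c: (c.size, c.label))
        merged = False
        for small in list(out):
            same = [c for c in out if c is not small and c.kind == small.kind]
            if not same:
                continue
            near = min(same, key=lambda c: float(np.linalg.norm(np.subtract(c.centre, small.centre))))
            members = small.members + near.members
            X, V = xv(members, small.kind)
            if _overdispersion_p(X, V) >= config.split_alpha:
                w = 1.0 / np.maximum(ccf_pair.loc[members, ["var_1", "var_2"]].to_numpy(dtype=float), 1e-9)
                Xa = ccf_pair.loc[members, ["ccf_1", "ccf_2"]].to_numpy(dtype=float)
                centre = (Xa * w).sum(0) / w.sum(0)
                if small.kind == PRIVATE_S1:
                    centre[1] = 0.0
                elif small.kind == PRIVATE_S2:
                    centre[0] = 0.0
                out.remove(small)
                out.remove(near)
                out.append(CcfCluster(near.label, tuple(float(v) for v in centre), small.kind, members))
                merged = True
                break
        if not merged:
            break
    return out


def cluster_pair(
    ccf_pair: pd.DataFrame,
    config: PipelineConfig | None = None,
    smoothing: float | None = None,
) -> tuple[list[CcfCluster], pd.Series, np.ndarray]:
    """Full 2D clustering of a pair: histogram -> surface -> peaks -> assignment.

    ``ccf_pair``: per-mutation table with ``ccf_1, ccf_2, kind`` columns
    (kind in shared/private_s1/private_s2).  Returns (clusters,
    assignment, smoothed surface).  Deterministic for fixed input and
    smoothing parameter.
    """
    config = config or PipelineConfig()
    grid = build_histogram(ccf_pair["ccf_1"], ccf_pair["ccf_2"], config)
    surface = fit_surface(grid, smoothing=smoothing, config=config)
    peaks = find_peaks(surface, config.peak_floor)
    cb = bin_centres(config)
    centres = []
    k = 0
    for i, j in peaks:
        kind = _peak_kind(i, j)
        if kind == "origin":
            continue
        x = 0.0 if kind == PRIVATE_S2 else float(cb[i])
        y = 0.0 if kind == PRIVATE_S1 else float(cb[j])
        k += 1
        centres.append(CcfCluster(f"k{k}", (x, y), kind))
    clusters, assignment = assign_mutations(ccf_pair, centres, config)
    refined = merge_clusters(refine_clusters(clusters, ccf_pair, config), ccf_pair, config)
    if len(refined) != len(clusters):
        clusters, assignment = assign_mutations(ccf_pair, refined, config)
    return clusters, assignment, surface


def plot_surface(surface: np.ndarray, clusters: list[CcfCluster],
                 config: PipelineConfig | None = None, path=None):
    """Diagnostic plot: smoothed CCF surface with cluster centres."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    config = config or PipelineConfig()
    fig, ax = plt.subplots(figsize=(5, 4.4))
    extent = (0, config.ccf_max, 0, config.ccf_max)
    ax.imshow(surface.T, origin="lower", extent=extent, aspect="equal", cmap="viridis")
    for c in clusters:
        ax.plot(*c.centre, marker="v", color="red", ms=8)
        ax.annotate(c.label, c.centre, color="white", fontsize=8)
    ax.set_xlabel("CCF sample 1")
    ax.set_ylabel("CCF sample 2")
    if path is not None:
        fig.savefig(path, dpi=120, bbox_inches="tight")
        plt.close(fig)
    return fig
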