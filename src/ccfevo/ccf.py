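"""Cancer cell fractions from read counts, purity and local copy number.

The model assigns every somatic mutation an *expected* variant allele
fraction under the assumption of clonality (every tumour cell carries the
mutation on ``m`` of its ``CN_t`` local copies, in a sample of purity
``p`` whose contaminating normal cells carry ``CN_n`` copies):

    E[VAF] = m * p / (p * CN_t + (1 - p) * CN_n)

The cancer cell fraction is the ratio of the observed to the expected
allele fraction, ``CCF = VAF / E[VAF]``.  On polyploid segments the
mutation multiplicity ``m`` is not identifiable from a single sample; by
default the feasible ``m`` in ``1..major_cn`` that brings the CCF closest
to 1 is chosen (clonality as the null hypothesis) and recorded, and the
full feasible set is exposed for conflict re-evaluation during tree
reconstruction.

CCFs are deliberately *not* truncated at 1: sampling noise and wrong
multiplicities push values above 1 and the downstream 2D clustering needs
to see that mass.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .config import PipelineConfig

#: flags attached to per-mutation, per-sample CCF records
FLAG_OK = ""
FLAG_UNEVALUABLE = "unevaluable"          # zero sequencing depth
FLAG_NO_SEGMENT = "no_segment"            # position not covered by a segment
FLAG_LOH_DELETED = "loh_deleted"          # homozygous deletion (major_cn = 0)


def expected_vaf(purity, total_cn, multiplicity, normal_cn=2):
    """Expected VAF of a clonal mutation; vectorised over numpy inputs.

    Raises
    ------
    ValueError
        if ``multiplicity`` exceeds ``total_cn`` anywhere, or parameters
        leave their domains (purity in (0, 1], positive copy numbers).
    """
    p = np.asarray(purity, dtype=float)
    cn = np.asarray(total_cn, dtype=float)
    m = np.asarray(multiplicity, dtype=float)
    if np.any((p <= 0) | (p > 1)):
        raise ValueError("purity must lie in (0, 1]")
    if np.any(cn < 1):
        raise ValueError("total_cn must be a positive integer")
    if np.any(m < 1):
        raise ValueError("multiplicity must be a positive integer")
    if np.any(m > cn):
        raise ValueError("multiplicity cannot exceed total copy number")
    out = m * p / (p * cn + (1.0 - p) * np.asarray(normal_cn, dtype=float))
    return out.item() if out.ndim == 0 else out


def enumerate_multiplicities(major_cn: int) -> list[int]:
    """Feasible mutation multiplicities on a segment: ``1..major_cn``.

    ``major_cn = 0`` (homozygous deletion) yields an empty set; callers
    must flag the mutation as lost rather than assign it a CCF.
    """
    if major_cn < 0:
        raise ValueError("major_cn must be non-negative")
    return list(range(1, int(major_cn) + 1))


def best_multiplicity(vaf: float, evaf_per_m: np.ndarray) -> int:
    """Index (1-based multiplicity) minimising |vaf/evaf - 1|."""
    ccfs = vaf / evaf_per_m
    return int(np.argmin(np.abs(ccfs - 1.0))) + 1


def _locate_segments(mut: pd.DataFrame, segs: pd.DataFrame) -> pd.DataFrame:
    """Attach (major_cn, minor_cn, subclonal_cn) of the covering segment.

    Segments must be non-overlapping per (sample, chrom); positions with
    no covering segment get NaN copy numbers.
    """
    out = mut.copy()
    out["major_cn"] = np.nan
    out["minor_cn"] = np.nan
    out["subclonal_cn"] = False
    for (sample, chrom), idx in mut.groupby(["sample", "chrom"]).groups.items():
        s = segs[(segs["sample"] == sample) & (segs["chrom"] == chrom)].sort_values("start")
        if s.empty:
            continue
        starts = s["start"].to_numpy()
        ends = s["end"].to_numpy()
        pos = mut.loc[idx, "pos"].to_numpy()
        k = np.searchsorted(starts, pos, side="right") - 1
        ok = (k >= 0) & (pos <= ends[np.clip(k, 0, len(ends) - 1)])
        kk = np.clip(k, 0, len(ends) - 1)
        out.loc[idx, "major_cn"] = np.where(ok, s["major_cn"].to_numpy()[kk], np.nan)
        out.loc[idx, "minor_cn"] = np.where(ok, s["minor_cn"].to_numpy()[kk], np.nan)
        out.loc[idx, "subclonal_cn"] = np.where(ok, s["subclonal_cn"].to_numpy()[kk], False)
    return out


def compute_ccf_table(
    mutations: pd.DataFrame,
    segments: pd.DataFrame,
    purity: dict[str, float],
    config: PipelineConfig | None = None,
) -> pd.DataFrame:
    """Per-mutation, per-sample CCF records.

    Parameters
    ----------
    mutations
        Long-format table, one row per (mutation_id, sample), with columns
        ``mutation_id, chrom, pos, sample, depth, alt_reads``.
    segments
        Allele-specific copy-number segments with columns
        ``sample, chrom, start, end, major_cn, minor_cn, subclonal_cn``.
    purity
        Per-sample tumour purity in (0, 1].

    Returns
    -------
    DataFrame with added columns ``vaf, total_cn, major_cn, minor_cn,
    multiplicity, expected_vaf, ccf, flag``.  Records with zero depth, no
    covering segment or a homozygously deleted segment are flagged, never
    silently dropped.
    """
    config = config or PipelineConfig()
    df = _locate_segments(mutations, segments)
    df["vaf"] = np.where(df["depth"] > 0, df["alt_reads"] / df["depth"].replace(0, np.nan), np.nan)
    df["total_cn"] = df["major_cn"] + df["minor_cn"]
    df["multiplicity"] = 0
    df["expected_vaf"] = np.nan
    df["ccf"] = np.nan
    df["flag"] = FLAG_OK

    df.loc[df["major_cn"].isna(), "flag"] = FLAG_NO_SEGMENT
    df.loc[df["major_cn"] == 0, "flag"] = FLAG_LOH_DELETED
    df.loc[df["depth"] == 0, "flag"] = FLAG_UNEVALUABLE

    evaluable = (df["flag"] == FLAG_OK)
    if evaluable.any():
        sub = df[evaluable]
        p = sub["sample"].map(purity).to_numpy(dtype=float)
        ncn = np.array([config.normal_cn_for(c) for c in sub["chrom"]], dtype=float)
        cn = sub["total_cn"].to_numpy(dtype=float)
        major = sub["major_cn"].to_numpy(dtype=int)
        vaf = sub["vaf"].to_numpy(dtype=float)
        max_m = int(major.max())
        # evaf for every candidate multiplicity, shape (n, max_m); m > major masked
        ms = np.arange(1, max_m + 1, dtype=float)
        evaf = ms[None, :] * p[:, None] / (p * cn + (1 - p) * ncn)[:, None]
        masked = np.where(ms[None, :] <= major[:, None], np.abs(vaf[:, None] / evaf - 1.0), np.inf)
        m_hat = np.argmin(masked, axis=1) + 1
        evaf_hat = evaf[np.arange(len(sub)), m_hat - 1]
        df.loc[evaluable, "multiplicity"] = m_hat
        df.loc[evaluable, "expected_vaf"] = evaf_hat
        df.loc[evaluable, "ccf"] = vaf / evaf_hat
    # subclonal_cn stays a separate annotation column: whether it excludes a
    # mutation depends on its CCF and on LOH states, decided at filter stage
    return df
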